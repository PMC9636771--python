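"""Reading and writing the pipeline's on-disk formats.

Channel stacks travel as per-channel single-page TIFFs (filename = marker
name) with a small JSON sidecar for geometry metadata; label layers as
32-bit integer TIFFs; tables as CSV; parameters as YAML.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import tifffile
import yaml

from ._core import ChannelStack, LabelLayer

__all__ = ["write_stack", "read_stack", "write_label_layer",
           "read_label_layer", "write_yaml", "read_yaml",
           "write_ground_truth", "read_ground_truth"]

_META = "stack_meta.json"


def write_stack(stack: ChannelStack, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, name in enumerate(stack.channel_names):
        tifffile.imwrite(directory / f"{name}.tiff",
                         stack.pixels[i].astype(np.float32))
    (directory / _META).write_text(json.dumps({
        "channel_names": stack.channel_names,
        "pixel_size_um": stack.pixel_size_um,
        "fov_id": stack.fov_id,
    }, indent=2))
    return directory


def read_stack(directory: str | Path) -> ChannelStack:
    directory = Path(directory)
    meta = json.loads((directory / _META).read_text())
    pixels = np.stack([
        tifffile.imread(directory / f"{name}.tiff").astype(np.float64)
        for name in meta["channel_names"]])
    return ChannelStack(pixels, meta["channel_names"],
                        pixel_size_um=meta["pixel_size_um"],
                        fov_id=meta["fov_id"])


def write_label_layer(layer: LabelLayer, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, layer.labels.astype(np.int32))
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({
        "layer_kind": layer.layer_kind,
        "object_class": layer.object_class,
        "provenance": _jsonable(layer.provenance),
    }, indent=2))
    return path


def read_label_layer(path: str | Path) -> LabelLayer:
    path = Path(path)
    labels = tifffile.imread(path).astype(np.int32)
    meta: dict[str, Any] = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return LabelLayer(labels, meta.get("layer_kind", "object"),
                      meta.get("object_class"), meta.get("provenance", {}))


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_yaml(data: Any, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(_jsonable(data), sort_keys=False))
    return path


def read_yaml(path: str | Path) -> Any:
    return yaml.safe_load(Path(path).read_text())


def write_ground_truth(truth, path: str | Path) -> Path:
    """JSON sidecar with the maps and overlap pairs; label layers are
    written separately as TIFFs next to it."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    base = path.with_suffix("")
    write_label_layer(truth.cell_labels, base.parent / f"{base.name}_cells.tiff")
    write_label_layer(truth.object_labels, base.parent / f"{base.name}_objects.tiff")
    write_label_layer(truth.nucleus_labels, base.parent / f"{base.name}_nuclei.tiff")
    payload = {
        "cell_class_of_label": {str(k): v for k, v in truth.cell_class_of_label.items()},
        "object_class_of_label": {str(k): v for k, v in truth.object_class_of_label.items()},
        "region_names": truth.region_names,
        "true_overlap_pairs": truth.true_overlap_pairs,
        "tissue_mask_area": int(truth.tissue_mask.sum()),
    }
    path.write_text(json.dumps(_jsonable(payload), indent=2))
    return path


def read_ground_truth(path: str | Path) -> dict[str, Any]:
    return json.loads(Path(path).read_text())
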