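"""From rasters to tables: per-object expression and FOV fingerprints.

Marker counts are summed over each labeled object and divided by its pixel
area (size normalization), then linearized with ``log(1+x)`` and scaled by a
per-channel quantile so values live on [0, 1].  FOV-level fingerprints are
per-marker mean pixel intensities, z-scored per marker and hierarchically
clustered (average linkage, Euclidean distance) on both axes.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.cluster.hierarchy import leaves_list, linkage

from ._core import ChannelStack, GeometryError, LabelLayer

__all__ = ["extract_expression", "transform_normalize", "global_fingerprint",
           "META_COLUMNS", "marker_columns"]

META_COLUMNS = ["object_id", "fov_id", "layer_kind", "object_class",
                "centroid_row", "centroid_col", "area_px", "lineage",
                "cluster_id", "anatomical_region", "de_novo_region",
                "true_class"]


def marker_columns(table: pd.DataFrame) -> list[str]:
    """Size-normalized marker columns of an object table."""
    return [c for c in table.columns
            if c not in META_COLUMNS and not c.startswith("raw_")]


def extract_expression(stack: ChannelStack,
                       layers: Mapping[str, LabelLayer] | LabelLayer,
                       markers: Sequence[str] | None = None) -> pd.DataFrame:
    """One row per labeled object with raw and size-normalized expression.

    ``layers`` maps an object class name to its label layer (or is a single
    layer).  ``raw_<marker>`` columns hold summed counts; plain marker
    columns hold counts per pixel, so ``raw = value * area_px`` exactly.
    """
    if isinstance(layers, LabelLayer):
        layers = {layers.object_class or layers.layer_kind: layers}
    markers = list(markers) if markers is not None else list(stack.channel_names)
    stack.require_channels(markers)
    frames = []
    for cls, layer in layers.items():
        layer.check_geometry(stack)
        ids = layer.label_ids
        if len(ids) == 0:
            continue
        areas = ndimage.sum_labels(np.ones(layer.labels.shape), layer.labels, ids)
        cent = np.asarray(ndimage.center_of_mass(
            np.ones(layer.labels.shape), layer.labels, ids))
        data = {
            "object_id": ids.astype(int),
            "fov_id": stack.fov_id,
            "layer_kind": layer.layer_kind,
            "object_class": cls,
            "centroid_row": cent[:, 0],
            "centroid_col": cent[:, 1],
            "area_px": areas.astype(float),
        }
        for m in markers:
            totals = ndimage.sum_labels(stack.channel(m), layer.labels, ids)
            data[f"raw_{m}"] = totals
            data[m] = totals / areas
        frames.append(pd.DataFrame(data))
    if not frames:
        cols = ["object_id", "fov_id", "layer_kind", "object_class",
                "centroid_row", "centroid_col", "area_px"]
        cols += [f"raw_{m}" for m in markers] + list(markers)
        return pd.DataFrame(columns=cols)
    return pd.concat(frames, ignore_index=True)


def transform_normalize(table: pd.DataFrame, q: float = 0.99,
                        markers: Sequence[str] | None = None) -> pd.DataFrame:
    """``x -> log(1+x)`` then scale by the per-channel ``q`` quantile.

    Quantiles use linear interpolation and are pooled over all rows of the
    table (so multi-FOV tables stay comparable across FOVs); values above
    the quantile clip to 1.  All-zero channels stay zero.  Monotone per
    channel: object ordering within a channel is preserved.
    """
    if not (0 < q <= 1):
        raise ValueError("q must be in (0, 1]")
    out = table.copy()
    for m in markers if markers is not None else marker_columns(table):
        x = np.log1p(out[m].to_numpy(dtype=float))
        if (x < 0).any():
            raise ValueError(f"negative expression in channel {m!r}")
        denom = np.quantile(x, q) if len(x) else 0.0
        if denom <= 0:
            if len(x) and x.max() > 0:
                warnings.warn(f"channel {m!r}: quantile {q} is zero; "
                              "scaling by the channel maximum instead")
                denom = x.max()
            else:
                out[m] = 0.0
                continue
        out[m] = np.clip(x / denom, 0.0, 1.0)
    return out


def global_fingerprint(stacks: Sequence[ChannelStack],
                       markers: Sequence[str]) -> dict:
    """FOV x marker z-score matrix with dendrogram leaf orders.

    Mean pixel intensity per marker per FOV, z-scored within each marker
    (so the fingerprint is invariant to per-marker affine rescaling);
    average-linkage hierarchical clustering of rows (FOVs) and columns
    (markers) with Euclidean distance.
    """
    if len(stacks) < 2:
        raise ValueError("global fingerprint needs at least 2 FOVs")
    markers = list(markers)
    means = np.array([[s.channel(m).mean() for m in markers] for s in stacks])
    mu = means.mean(axis=0)
    sd = means.std(axis=0)
    z = np.where(sd > 0, (means - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    fovs = [s.fov_id for s in stacks]
    zdf = pd.DataFrame(z, index=fovs, columns=markers)

    def leaf_order(mat: np.ndarray) -> list[int]:
        if mat.shape[0] < 2:
            return list(range(mat.shape[0]))
        return [int(i) for i in leaves_list(linkage(mat, method="average",
                                                    metric="euclidean"))]

    return {"zscores": zdf,
            "fov_order": leaf_order(z),
            "marker_order": leaf_order(z.T)}
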