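"""Discretization of tissue into biological units.

Two complementary routes are combined: nuclei-associated cells are obtained
by expanding nuclear masks (produced externally by a learned segmenter, or
by the built-in classical fallback), while non-nuclear structures — glial
processes, vessel boundaries, plaques, tangles — are captured by
threshold-based object segmentation (blur, threshold, connected components,
size filter).  Both label layers are kept intact and related through an
overlap table rather than merged destructively.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed

from ._core import ChannelStack, GeometryError, LabelLayer, relabel_contiguous

__all__ = ["EZSegParams", "MorphologyRecord", "fallback_nuclear_segment",
           "expand_nuclei", "ez_segment", "morphology_features",
           "morphology_table", "integrate_layers", "infer_cell_size_split"]


@dataclass
class EZSegParams:
    """Threshold-segmentation parameters for one object class.

    ``threshold`` is an absolute intensity when ``threshold_mode`` is
    ``"absolute"``, or a quantile of positive blurred pixel values when
    ``"quantile"``.
    """

    channels: list[str]
    object_class: str
    blur_sigma: float = 1.0
    threshold: float = 1.0
    threshold_mode: str = "absolute"  # "absolute" | "quantile"
    min_px: int = 10
    max_px: int = 10_000_000

    def __post_init__(self) -> None:
        if not (0 < self.min_px <= self.max_px):
            raise ValueError("need 0 < min_px <= max_px")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")
        if self.threshold_mode not in ("absolute", "quantile"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")


@dataclass
class MorphologyRecord:
    label: int
    area: float
    perimeter: float
    circularity: float
    eccentricity: float
    major_axis: float
    minor_axis: float
    centroid: tuple[float, float]


def fallback_nuclear_segment(nuclear_channel: np.ndarray,
                             min_px: int = 9, max_px: int = 10_000,
                             blur_sigma: float = 1.0) -> LabelLayer:
    """Classical nuclear segmentation: smooth, threshold, watershed split.

    A simple stand-in for an externally trained nuclear segmenter, adequate
    for round, well-separated phantom nuclei.
    """
    img = np.asarray(nuclear_channel, dtype=np.float64)
    if img.max() <= 0:
        return LabelLayer(np.zeros(img.shape, dtype=np.int32), "cell",
                          provenance={"op": "fallback_nuclear_segment"})
    smoothed = gaussian(img, blur_sigma, preserve_range=True) if blur_sigma > 0 else img
    positive = smoothed[smoothed > 0]
    thr = threshold_otsu(smoothed) if positive.size and smoothed.min() != smoothed.max() else 0
    binary = smoothed > thr
    dist = ndimage.distance_transform_edt(binary)
    peaks = peak_local_max(dist, labels=binary, min_distance=3,
                           exclude_border=False)
    markers = np.zeros(img.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    labels = watershed(-dist, markers, mask=binary)
    labels = _size_filter(labels, min_px, max_px)
    return LabelLayer(relabel_contiguous(labels), "cell",
                      provenance={"op": "fallback_nuclear_segment",
                                  "min_px": min_px, "max_px": max_px})


def expand_nuclei(nuclei: LabelLayer, distance_px: int = 3) -> LabelLayer:
    """Grow each nuclear label by up to ``distance_px`` (Euclidean).

    Contested pixels go to the nearest nucleus; exact distance ties go to
    the lower label id.  Label count and original nuclear pixels are
    preserved (partition refinement).
    """
    if distance_px < 0:
        raise ValueError("distance_px must be >= 0")
    labels = nuclei.labels
    out = labels.copy()
    ids = nuclei.label_ids
    if distance_px == 0 or len(ids) == 0:
        return LabelLayer(out, nuclei.layer_kind, nuclei.object_class,
                          provenance={"op": "expand_nuclei", "distance_px": distance_px,
                                      **nuclei.provenance})
    # distance from every background pixel to the nearest nucleus of any label
    dist_any = ndimage.distance_transform_edt(labels == 0)
    within = dist_any <= distance_px + 1e-9
    for lab in ids:  # ascending: lower label wins exact ties
        d = ndimage.distance_transform_edt(labels != lab)
        sel = (out == 0) & within & (d <= dist_any + 1e-6)
        out[sel] = lab
    return LabelLayer(out, nuclei.layer_kind, nuclei.object_class,
                      provenance={"op": "expand_nuclei",
                                  "distance_px": distance_px, **nuclei.provenance})


def _size_filter(labels: np.ndarray, min_px: int, max_px: int) -> np.ndarray:
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    bad = ids[(counts < min_px) | (counts > max_px)]
    if len(bad):
        labels = labels.copy()
        labels[np.isin(labels, bad)] = 0
    return labels


_EIGHT = np.ones((3, 3), dtype=int)  # 8-connectivity keeps thin processes intact


def ez_segment(stack: ChannelStack, params: EZSegParams) -> LabelLayer:
    """Threshold-based object segmentation of non-nuclear structures.

    The named channels are summed, Gaussian-blurred, thresholded, and split
    into 8-connected components; components outside ``[min_px, max_px]`` are
    discarded.  Raising the threshold never increases foreground area.
    """
    stack.require_channels(params.channels)
    img = sum(stack.channel(c) for c in params.channels)
    img = np.asarray(img, dtype=np.float64)
    if params.blur_sigma > 0:
        img = gaussian(img, params.blur_sigma, preserve_range=True)
    if params.threshold_mode == "quantile":
        positive = img[img > 0]
        if positive.size == 0:
            warnings.warn(f"{params.object_class}: quantile threshold on an "
                          "all-zero image; returning an empty layer")
            thr = np.inf
        else:
            thr = np.quantile(positive, params.threshold)
    else:
        thr = params.threshold
    binary = img > thr
    labels, _ = ndimage.label(binary, structure=_EIGHT)
    labels = _size_filter(labels, params.min_px, params.max_px)
    return LabelLayer(relabel_contiguous(labels), "object", params.object_class,
                      provenance={"op": "ez_segment", "channels": params.channels,
                                  "blur_sigma": params.blur_sigma,
                                  "threshold": params.threshold,
                                  "threshold_mode": params.threshold_mode,
                                  "min_px": params.min_px, "max_px": params.max_px})


def morphology_features(layer: LabelLayer) -> list[MorphologyRecord]:
    """Per-label shape descriptors; circularity is ``4*pi*A / P**2``."""
    records = []
    for rp in regionprops(layer.labels):
        perim = rp.perimeter
        circ = 4 * math.pi * rp.area / perim ** 2 if perim > 0 else float("nan")
        records.append(MorphologyRecord(
            label=int(rp.label), area=float(rp.area), perimeter=float(perim),
            circularity=float(circ), eccentricity=float(rp.eccentricity),
            major_axis=float(rp.axis_major_length),
            minor_axis=float(rp.axis_minor_length),
            centroid=(float(rp.centroid[0]), float(rp.centroid[1]))))
    return records


def morphology_table(layer: LabelLayer) -> pd.DataFrame:
    recs = morphology_features(layer)
    return pd.DataFrame([{
        "label": r.label, "area": r.area, "perimeter": r.perimeter,
        "circularity": r.circularity, "eccentricity": r.eccentricity,
        "major_axis": r.major_axis, "minor_axis": r.minor_axis,
        "centroid_row": r.centroid[0], "centroid_col": r.centroid[1],
    } for r in recs])


def infer_cell_size_split(areas: Sequence[float], quantile: float = 0.5
                          ) -> np.ndarray:
    """Optional morphology-based neuron-vs-glia split by nuclear area.

    Returns a boolean array marking the large-area fraction (putative
    neurons); the cutoff is an area quantile since no absolute threshold
    generalizes across magnifications.
    """
    areas = np.asarray(areas, dtype=float)
    if areas.size == 0:
        return np.zeros(0, dtype=bool)
    return areas > np.quantile(areas, quantile)


def integrate_layers(cells: LabelLayer, objects: Sequence[LabelLayer]
                     ) -> pd.DataFrame:
    """Relate cell and object layers without reassigning any pixel.

    Returns the overlap table: one row per (cell label, object layer,
    object label) pair sharing at least one pixel, with shared pixel counts.
    """
    rows = []
    for layer in objects:
        if layer.labels.shape != cells.labels.shape:
            raise GeometryError("cell and object layers differ in geometry")
        both = (cells.labels > 0) & (layer.labels > 0)
        if not both.any():
            continue
        pairs, counts = np.unique(
            np.stack([cells.labels[both], layer.labels[both]]),
            axis=1, return_counts=True)
        for (c, o), n in zip(pairs.T, counts):
            rows.append({"cell_label": int(c),
                         "object_class": layer.object_class or layer.layer_kind,
                         "object_label": int(o), "shared_px": int(n)})
    return pd.DataFrame(rows, columns=["cell_label", "object_class",
                                       "object_label", "shared_px"])
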