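"""Spatial statistics over discretized cells and proteopathy objects.

Implements the co-proximity null model (observed neighbor counts within a
pixel radius ``t`` against the count expected if candidate neighbors were
dispersed uniformly over the field: ``n_B * pi * t**2 / A_FOV``),
pixel-overlap association ratios, top-down anatomical composition,
bottom-up neighborhood profiling with region discovery and voronoi
expansion of the neuropil, and pixel-level synaptic coincidence scoring.

Distances for co-proximity are measured between object peripheries
(minimum Euclidean distance between boundary pixel centers); neighborhood
profiles and the voronoi expansion use centroids.  The expected-count disk
area carries no edge correction, a known bias near field borders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from sklearn.metrics import silhouette_score

from ._core import ChannelStack, GeometryError, LabelLayer
from .som import SelfOrganizingMap

__all__ = ["ProximityParams", "boundary_distances", "co_proximity",
           "association_ratio", "assign_anatomical", "composition_table",
           "neighborhood_profiles", "discover_regions", "voronoi_expand",
           "synaptic_coincidence", "DEFAULT_RADII", "DEFAULT_REGION_NAMES",
           "RegionMap"]

# Default pixel-radius grid for the multi-radius sweep; at 0.390625 um/px
# these correspond to ~10, 20, 39, 59, 78, 98 and 117 um.
DEFAULT_RADII: tuple[int, ...] = (25, 50, 100, 150, 200, 250, 300)

# Radius thresholds per proteopathy/vascular class: vessels interact at
# neurovascular-unit scale, tangles at mid range, plaques furthest.
DEFAULT_CLASS_RADII: dict[str, int] = {"endothelial": 25, "tangle": 50,
                                       "plaque": 100}

DEFAULT_REGION_NAMES = ["N", "G", "M", "AP", "TT"]

# High-resolution acquisition geometry: 400 um field at 1024 x 1024 px.
DEFAULT_PIXEL_SIZE_UM = 400.0 / 1024.0


def px_to_um(t_px: float, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> float:
    """Physical length of a pixel radius, in micrometers."""
    return t_px * pixel_size_um


@dataclass
class ProximityParams:
    """Radius grid, class pairs and field area for co-proximity."""

    radii: tuple[int, ...] = DEFAULT_RADII
    type_pairs: list[tuple[str, str]] = field(default_factory=list)
    fov_area_px: float | None = None  # defaults to the layer H*W

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.radii):
            raise ValueError("all radii must be positive")


def _boundary_points(labels: np.ndarray) -> dict[int, np.ndarray]:
    """Boundary pixel coordinates per label (object minus its erosion)."""
    out: dict[int, np.ndarray] = {}
    ids = np.unique(labels[labels > 0])
    if len(ids) == 0:
        return out
    objects = ndimage.find_objects(labels)
    for lab in ids:
        sl = objects[lab - 1]
        sub = labels[sl] == lab
        eroded = ndimage.binary_erosion(sub, border_value=0)
        boundary = sub & ~eroded
        rr, cc = np.nonzero(boundary)
        out[int(lab)] = np.column_stack([rr + sl[0].start, cc + sl[1].start])
    return out


def boundary_distances(layer_a: LabelLayer, layer_b: LabelLayer
                       ) -> pd.DataFrame:
    """Pairwise minimal periphery distance matrix (pixels).

    Rows are labels of ``layer_a``, columns labels of ``layer_b``.
    Overlapping or touching objects score 0.  When both arguments are the
    same layer the diagonal is set to NaN (an object is not its own
    neighbor).
    """
    layer_a.check_geometry(layer_b)
    pts_a = _boundary_points(layer_a.labels)
    pts_b = _boundary_points(layer_b.labels)
    same = layer_a.labels is layer_b.labels or np.array_equal(
        layer_a.labels, layer_b.labels)
    mat = np.full((len(pts_a), len(pts_b)), np.nan)
    trees = {lb: cKDTree(p) for lb, p in pts_b.items()}
    for i, (la, pa) in enumerate(pts_a.items()):
        for j, (lb, _) in enumerate(pts_b.items()):
            if same and la == lb:
                continue
            d, _ = trees[lb].query(pa, k=1)
            mat[i, j] = d.min()
    return pd.DataFrame(mat, index=list(pts_a), columns=list(pts_b))


def _neighbor_counts(pts_a: dict[int, np.ndarray],
                     pts_b: dict[int, np.ndarray], t: float,
                     exclude_self: bool) -> np.ndarray:
    """#B-objects whose periphery lies within t of each A-object's periphery."""
    if not pts_b:
        return np.zeros(len(pts_a))
    all_b = np.concatenate(list(pts_b.values()))
    owner = np.concatenate([np.full(len(p), lb) for lb, p in pts_b.items()])
    tree = cKDTree(all_b)
    counts = np.zeros(len(pts_a))
    for i, (la, pa) in enumerate(pts_a.items()):
        hits = tree.query_ball_point(pa, r=t)
        ids = {int(owner[j]) for lst in hits for j in lst}
        if exclude_self:
            ids.discard(int(la))
        counts[i] = len(ids)
    return counts


def co_proximity(layers: Mapping[str, LabelLayer], params: ProximityParams,
                 fov_id: str = "fov0") -> pd.DataFrame:
    """Observed vs expected neighbor counts per class pair and radius.

    observed  mean over A-objects of #{B : periphery distance <= t}
    expected  n_B * pi * t**2 / A_FOV  (uniform-dispersion null; for a
              class paired with itself the candidate count is n_B - 1)
    ratio     observed / expected, NaN-flagged when no B objects exist

    Returns one row per (pair, t) with columns fov_id, class_a, class_b,
    t, n_a, n_b, observed, expected, ratio.
    """
    pairs = params.type_pairs or [(a, b) for a in layers for b in layers]
    shapes = {tuple(l.labels.shape) for l in layers.values()}
    if len(shapes) > 1:
        raise GeometryError("layers differ in geometry")
    area = params.fov_area_px
    if area is None:
        h, w = next(iter(shapes))
        area = float(h * w)
    boundaries = {cls: _boundary_points(l.labels) for cls, l in layers.items()}
    rows = []
    for a, b in pairs:
        pts_a, pts_b = boundaries[a], boundaries[b]
        n_a, n_b = len(pts_a), len(pts_b)
        n_candidates = n_b - 1 if a == b else n_b
        for t in params.radii:
            if n_a == 0 or n_candidates <= 0:
                obs = exp = ratio = np.nan
            else:
                counts = _neighbor_counts(pts_a, pts_b, t, exclude_self=(a == b))
                obs = float(counts.mean())
                exp = n_candidates * np.pi * t * t / area
                ratio = obs / exp
            rows.append({"fov_id": fov_id, "class_a": a, "class_b": b,
                         "t": t, "n_a": n_a, "n_b": n_b,
                         "observed": obs, "expected": exp, "ratio": ratio})
    return pd.DataFrame(rows)


def association_ratio(table: pd.DataFrame, overlaps: pd.DataFrame,
                      proteopathy_class: str, by: str | None = "lineage",
                      valid_classes: Sequence[str] | None = None
                      ) -> pd.DataFrame:
    """Proteopathy-associated over proteopathy-free cell counts.

    A cell is associated when it shares at least one pixel with an object
    of ``proteopathy_class`` (from the overlap table).  Ratio of 1 means
    parity; a group with no proteopathy-free cells is flagged infinite.
    ``valid_classes`` names the segmented object classes; when omitted,
    the classes present in the overlap table stand in (a class absent
    from both is unknown).
    """
    if "object_class" not in overlaps.columns:
        raise ValueError("overlap table lacks object_class")
    known = set(valid_classes) if valid_classes is not None else \
        set(overlaps["object_class"].unique())
    if len(known) and proteopathy_class not in known:
        raise ValueError(f"unknown proteopathy class {proteopathy_class!r}; "
                         f"known classes: {sorted(known)}")
    assoc_labels = set(
        overlaps.loc[overlaps["object_class"] == proteopathy_class,
                     "cell_label"].astype(int))
    cells = table[table["layer_kind"] == "cell"] if "layer_kind" in table.columns else table
    is_assoc = cells["object_id"].astype(int).isin(assoc_labels)
    groups = cells[by] if by is not None and by in cells.columns else \
        pd.Series("all", index=cells.index)
    rows = []
    for g, idx in cells.groupby(groups).groups.items():
        a = int(is_assoc.loc[idx].sum())
        f = int(len(idx) - a)
        rows.append({"group": g, "proteopathy_class": proteopathy_class,
                     "n_associated": a, "n_free": f,
                     "ratio": (a / f) if f > 0 else float("inf")})
    return pd.DataFrame(rows)


def assign_anatomical(table: pd.DataFrame,
                      region_masks: Mapping[str, np.ndarray],
                      remainder: str = "other") -> pd.DataFrame:
    """Centroid-in-mask anatomical region assignment.

    Masks are tested in declared order; where they overlap the earlier
    region wins (a warning is emitted).  Centroids outside every mask fall
    into the ``remainder`` bucket.
    """
    out = table.copy()
    regions = np.full(len(out), remainder, dtype=object)
    rr = out["centroid_row"].to_numpy(dtype=float).round().astype(int)
    cc = out["centroid_col"].to_numpy(dtype=float).round().astype(int)
    claimed = None
    for name, mask in region_masks.items():
        mask = np.asarray(mask, dtype=bool)
        rrc = np.clip(rr, 0, mask.shape[0] - 1)
        ccc = np.clip(cc, 0, mask.shape[1] - 1)
        inside = mask[rrc, ccc]
        if claimed is None:
            claimed = np.zeros(mask.shape, dtype=bool)
        elif (claimed & mask).any():
            warnings.warn(f"anatomical mask {name!r} overlaps an earlier "
                          "mask; earlier region takes precedence")
        take = inside & (regions == remainder)
        regions[take] = name
        claimed |= mask
    out["anatomical_region"] = regions
    return out


def composition_table(table: pd.DataFrame, region_col: str,
                      class_col: str = "object_class") -> pd.DataFrame:
    """Per-region class proportions (rows sum to 1)."""
    counts = pd.crosstab(table[region_col], table[class_col])
    return counts.div(counts.sum(axis=1), axis=0)


def neighborhood_profiles(table: pd.DataFrame, radius_px: float = 50.0,
                          class_col: str = "object_class") -> pd.DataFrame:
    """Per-object local composition within a centroid radius (self included).

    Returns one proportion column per class; rows sum to 1.
    """
    if radius_px <= 0:
        raise ValueError("radius_px must be positive")
    pts = table[["centroid_row", "centroid_col"]].to_numpy(dtype=float)
    classes = sorted(table[class_col].unique())
    cls_idx = table[class_col].map({c: i for i, c in enumerate(classes)}).to_numpy()
    tree = cKDTree(pts)
    counts = np.zeros((len(table), len(classes)))
    for i, neighbors in enumerate(tree.query_ball_point(pts, r=radius_px)):
        for j in neighbors:
            counts[i, cls_idx[j]] += 1
    profiles = counts / counts.sum(axis=1, keepdims=True)
    return pd.DataFrame(profiles, columns=classes, index=table.index)


def discover_regions(profiles: pd.DataFrame, sample_ids: Sequence[str],
                     k_range: Sequence[int] = (2, 3, 4, 5, 6, 7, 8),
                     silhouette_floor: float = 0.2,
                     silhouette_rel_tol: float = 0.01, seed: int = 0,
                     grid: tuple[int, int] = (8, 8), epochs: int = 5
                     ) -> tuple[np.ndarray, int]:
    """Cluster pooled neighborhood profiles into common regions.

    Profiles from all samples are pooled and clustered (SOM nodes cut by
    average-linkage into k meta-clusters).  The chosen k is the smallest in
    ``k_range`` whose mean silhouette exceeds the floor, comes within
    ``silhouette_rel_tol`` of the best silhouette over the range, AND whose
    every cluster contains objects from every sample — the minimum number
    of regions common to all samples that still captures the profile
    structure.  If no k qualifies the best-silhouette k is returned with a
    warning.  Deterministic for a fixed seed.
    """
    from .phenotype import som_metacluster

    sample_ids = np.asarray(sample_ids)
    if len(sample_ids) != len(profiles):
        raise ValueError("sample_ids must match profiles")
    X = profiles.to_numpy(dtype=float)
    tbl = profiles.reset_index(drop=True)
    markers = list(profiles.columns)
    samples = np.unique(sample_ids)

    k_range = sorted(set(int(k) for k in k_range))
    results: dict[int, np.ndarray] = {}
    scores: dict[int, float] = {}
    for k in k_range:
        if k == 1:
            results[1] = np.ones(len(X), dtype=int)
            scores[1] = -1.0
            continue
        clustered, _ = som_metacluster(tbl, markers, grid=grid, n_meta=k,
                                       seed=seed, epochs=epochs)
        labels = clustered["cluster_id"].to_numpy()
        results[k] = labels
        if len(np.unique(labels)) < 2:
            scores[k] = -1.0
        else:
            # subsample for tractable silhouette on large tables
            if len(X) > 5000:
                rng = np.random.default_rng(seed)
                idx = rng.choice(len(X), 5000, replace=False)
                scores[k] = float(silhouette_score(X[idx], labels[idx]))
            else:
                scores[k] = float(silhouette_score(X, labels))

    def shared_by_all(labels: np.ndarray) -> bool:
        for c in np.unique(labels):
            present = np.unique(sample_ids[labels == c])
            if len(present) < len(samples):
                return False
        return True

    best_score = max(scores.values())
    for k in k_range:
        if k == 1 and len(k_range) == 1:
            return results[1], 1
        if k == 1:
            continue
        if (scores[k] > silhouette_floor
                and scores[k] >= best_score * (1 - silhouette_rel_tol)
                and shared_by_all(results[k])):
            return results[k], k
    best = max(scores, key=lambda k: scores[k])
    warnings.warn(f"no k in {k_range} met the silhouette floor "
                  f"{silhouette_floor} with all samples represented; "
                  f"returning best-silhouette k={best}")
    return results[best], best


@dataclass
class RegionMap:
    """Pixel-level de novo region labeling of the tissue."""

    labels: np.ndarray          # 0 outside tissue, 1..K region ids
    region_names: list[str]     # name per region id (index i -> id i+1)

    def name_of(self, region_id: int) -> str:
        return self.region_names[region_id - 1]


def voronoi_expand(centroids: np.ndarray, region_ids: np.ndarray,
                   tissue_mask: np.ndarray,
                   region_names: Sequence[str] | None = None) -> RegionMap:
    """Assign every tissue pixel the region of its nearest object centroid.

    Clusters the neuropil (the cell-free feltwork between somata) into the
    region of the closest region-labeled object.  Non-tissue pixels stay 0.
    Idempotent: re-running on the result changes nothing.
    """
    centroids = np.asarray(centroids, dtype=float)
    region_ids = np.asarray(region_ids, dtype=int)
    if len(centroids) == 0:
        raise ValueError("voronoi expansion needs at least one labeled object")
    if len(centroids) != len(region_ids):
        raise ValueError("centroids and region_ids must align")
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    tree = cKDTree(centroids)
    rr, cc = np.nonzero(tissue_mask)
    _, nearest = tree.query(np.column_stack([rr, cc]).astype(float), k=1)
    out = np.zeros(tissue_mask.shape, dtype=np.int32)
    out[rr, cc] = region_ids[nearest]
    if region_names is None:
        region_names = [str(i) for i in range(1, int(region_ids.max()) + 1)]
    return RegionMap(out, list(region_names))


def _positive(channel: np.ndarray, threshold: float | str) -> np.ndarray:
    if threshold == "otsu":
        from skimage.filters import threshold_otsu
        if channel.max() == channel.min():
            return channel > 0
        return channel >= threshold_otsu(channel)
    return channel > float(threshold)


def synaptic_coincidence(stack: ChannelStack, region_map: RegionMap,
                         pixel_thresholds: Mapping[str, float | str],
                         tau_channel: str = "PHF1-TAU",
                         amyloid_channel: str = "Abeta42",
                         kind: str = "excitatory") -> pd.DataFrame:
    """Fraction of synaptic pixels carrying proteopathy signal, per region.

    Excitatory synaptic pixels are SYP(+) AND PSD95(+) AND (VGLUT1(+) OR
    VGLUT2(+)); inhibitory are SYP(+) AND VGAT(+) AND GAD(+).  The output
    holds, per region and proteopathy channel, |synaptic AND proteopathy(+)|
    / |synaptic|; regions with no synaptic pixels are flagged NaN.
    """
    def pos(name: str) -> np.ndarray:
        return _positive(stack.channel(name), pixel_thresholds.get(name, "otsu"))

    if kind == "excitatory":
        stack.require_channels(["SYP", "PSD95", "VGLUT1", "VGLUT2"])
        synaptic = pos("SYP") & pos("PSD95") & (pos("VGLUT1") | pos("VGLUT2"))
    elif kind == "inhibitory":
        stack.require_channels(["SYP", "VGAT", "GAD"])
        synaptic = pos("SYP") & pos("VGAT") & pos("GAD")
    else:
        raise ValueError(f"unknown synapse kind {kind!r}")

    rows = []
    for rid, rname in enumerate(region_map.region_names, start=1):
        in_region = region_map.labels == rid
        syn = synaptic & in_region
        n_syn = int(syn.sum())
        for channel, label in ((tau_channel, "tau"), (amyloid_channel, "amyloid")):
            if not stack.has_channel(channel):
                continue
            if n_syn == 0:
                frac = float("nan")
            else:
                frac = float((syn & pos(channel)).sum() / n_syn)
            rows.append({"region": rname, "proteopathy": label,
                         "channel": channel, "n_synaptic_px": n_syn,
                         "fraction": frac})
    return pd.DataFrame(rows)
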