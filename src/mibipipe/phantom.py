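"""Synthetic tissue phantoms with complete ground truth.

The generator emulates the geometry of ion-beam-imaged hippocampal tissue:
round nuclei-bearing somata for neurons and glia, ramified glial processes,
elongated vessel profiles, plaque and tangle aggregates, marker-specific
mean intensities with Poisson (or Gaussian) count noise, a slide-background
channel that is high where tissue is absent, and optional linear spillover
between designated channel pairs.  Every placed structure is recorded in a
:class:`GroundTruth` so downstream segmentation, phenotyping and spatial
statistics can be scored against known answers.

Default geometry mirrors a high-resolution acquisition: a 400 um field
rastered at 1024 x 1024 px (0.390625 um/px), with a 512 x 512 low-resolution
variant obtained by halving ``raster_px``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line

from ._core import ChannelStack, LabelLayer

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "PlacementError",
    "generate_phantom",
    "generate_tile_grid",
    "slice_tiles",
    "generate_expression_table",
    "DEFAULT_MARKER_PROFILES",
    "DEFAULT_SHAPE_PARAMS",
]


class PlacementError(RuntimeError):
    """Requested structures cannot be placed without exceeding the field."""


# Mean ion counts per pixel for each structure class.  Values are modest
# (single-digit to low-double-digit counts) to mimic sparse TOF statistics.
DEFAULT_MARKER_PROFILES: dict[str, dict[str, float]] = {
    "neuron": {"MAP2": 8.0, "CD56": 4.0, "MFN2": 1.0, "HH3": 10.0},
    "microglia": {"Iba1": 8.0, "CD45": 6.0, "HH3": 8.0},
    "astrocyte": {"GFAP": 8.0, "HH3": 8.0},
    "endothelial": {"CD31": 8.0, "MCT1": 5.0, "CD105": 5.0, "HH3": 7.0},
    "plaque": {"Abeta42": 12.0, "PanAbeta": 8.0},
    "tangle": {"PHF1-TAU": 12.0},
}

# Geometry of each structure class, in pixels at the 1024-px raster.
DEFAULT_SHAPE_PARAMS: dict[str, dict[str, Any]] = {
    "neuron": {"soma_radius": 6, "nucleus_radius": 4},
    "microglia": {"soma_radius": 4, "nucleus_radius": 2, "n_processes": 4,
                  "process_len": 12},
    "astrocyte": {"soma_radius": 4, "nucleus_radius": 2, "n_processes": 5,
                  "process_len": 14},
    "endothelial": {"length": 24, "width": 4, "nucleus_radius": 2},
    "plaque": {"radius": 8, "irregularity": 0.0},
    "tangle": {"radius": 4, "irregularity": 0.0, "on_neuron_frac": 0.7},
}

CELL_CLASSES = ("neuron", "microglia", "astrocyte", "endothelial")
OBJECT_CLASSES = ("plaque", "tangle")

_MAX_TRIES = 400


@dataclass
class PhantomSpec:
    """Declarative description of one synthetic field of view."""

    field_width_um: float = 400.0
    raster_px: int = 1024
    n_cells_per_class: dict[str, int] = field(
        default_factory=lambda: {"neuron": 40, "microglia": 25,
                                 "astrocyte": 20, "endothelial": 10})
    n_objects_per_class: dict[str, int] = field(
        default_factory=lambda: {"plaque": 12, "tangle": 18})
    marker_profiles: dict[str, dict[str, float]] | None = None
    noise_model: str = "poisson"          # "poisson" | "gaussian" | "none"
    gaussian_sd: float = 1.0
    spillover_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    region_layout: list[dict[str, Any]] | None = None
    shape_params: dict[str, dict[str, Any]] | None = None
    bg_channel: str = "Au"
    bg_intensity: float = 30.0
    carbon_channel: str = "C12"
    carbon_intensity: float = 15.0
    empty_channel: str = "Empty139"
    slide_border_px: int = 0
    seed: int = 0
    fov_id: str = "phantom"

    def __post_init__(self) -> None:
        if self.field_width_um <= 0 or self.raster_px <= 0:
            raise ValueError("field_width_um and raster_px must be positive")
        for d in (self.n_cells_per_class, self.n_objects_per_class):
            for cls, n in d.items():
                if n < 0:
                    raise ValueError(f"negative count for class {cls!r}")
        for src, tgt, c in self.spillover_pairs:
            if not (0 <= c < 1):
                raise ValueError(f"spillover coefficient {c} not in [0, 1)")
        profiles = self.marker_profiles or DEFAULT_MARKER_PROFILES
        for cls, prof in profiles.items():
            for marker, mean in prof.items():
                if mean < 0:
                    raise ValueError(f"negative mean for {cls}/{marker}")

    @property
    def pixel_size_um(self) -> float:
        return self.field_width_um / self.raster_px

    @property
    def profiles(self) -> dict[str, dict[str, float]]:
        return self.marker_profiles or DEFAULT_MARKER_PROFILES

    @property
    def shapes(self) -> dict[str, dict[str, Any]]:
        merged = {k: dict(v) for k, v in DEFAULT_SHAPE_PARAMS.items()}
        for cls, params in (self.shape_params or {}).items():
            merged.setdefault(cls, {}).update(params)
        return merged

    @property
    def marker_names(self) -> list[str]:
        names: list[str] = []
        for prof in self.profiles.values():
            for m in prof:
                if m not in names:
                    names.append(m)
        return names


@dataclass
class GroundTruth:
    """Everything the generator knows about a phantom."""

    cell_labels: LabelLayer
    object_labels: LabelLayer
    cell_class_of_label: dict[int, str]
    object_class_of_label: dict[int, str]
    nucleus_labels: LabelLayer
    tissue_mask: np.ndarray
    planted_region_of_pixel: np.ndarray | None
    region_names: list[str]
    true_overlap_pairs: list[tuple[int, int, int]]  # (cell, object, shared px)

    @property
    def class_of_label(self) -> dict[tuple[str, int], str]:
        out = {("cell", k): v for k, v in self.cell_class_of_label.items()}
        out.update({("object", k): v for k, v in self.object_class_of_label.items()})
        return out

    def recompute_overlap_pairs(self) -> list[tuple[int, int, int]]:
        """Pixel-wise intersection of the two layers (the invariant oracle)."""
        return overlap_pairs(self.cell_labels.labels, self.object_labels.labels)


def overlap_pairs(cells: np.ndarray, objects: np.ndarray) -> list[tuple[int, int, int]]:
    both = (cells > 0) & (objects > 0)
    if not both.any():
        return []
    pairs, counts = np.unique(
        np.stack([cells[both], objects[both]]), axis=1, return_counts=True)
    out = [(int(c), int(o), int(n)) for (c, o), n in zip(pairs.T, counts)]
    return sorted(out)


# ---------------------------------------------------------------------------
# shape rasterization
# ---------------------------------------------------------------------------

def _disk_px(center: tuple[int, int], radius: float, shape: tuple[int, int],
             rng: np.random.Generator | None = None,
             irregularity: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    if irregularity <= 0 or rng is None:
        # +eps so the integer-grid disk includes dx^2+dy^2 == r^2 exactly
        return draw_disk(center, radius + 1e-4, shape=shape)
    # lobed disk: radius modulated around the perimeter
    k = int(rng.integers(3, 6))
    phase = rng.uniform(0, 2 * math.pi)
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    dr, dc = rr - center[0], cc - center[1]
    dist = np.hypot(dr, dc)
    theta = np.arctan2(dr, dc)
    rmax = radius * (1 + irregularity * np.sin(k * theta + phase))
    sel = dist <= rmax + 0.5
    return np.nonzero(sel)


def _capsule_px(center: tuple[int, int], length: int, width: int,
                angle: float, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Elongated vessel profile: a thick line segment."""
    half = length / 2
    dr, dc = math.sin(angle) * half, math.cos(angle) * half
    r0, c0 = int(round(center[0] - dr)), int(round(center[1] - dc))
    r1, c1 = int(round(center[0] + dr)), int(round(center[1] + dc))
    H, W = shape
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw_line(r0, c0, r1, c1)
    ok = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
    mask[rr[ok], cc[ok]] = True
    from scipy.ndimage import binary_dilation
    mask = binary_dilation(mask, iterations=max(1, width // 2))
    return np.nonzero(mask)


def _process_px(center: tuple[int, int], n_arms: int, length: int,
                shape: tuple[int, int], rng: np.random.Generator
                ) -> tuple[np.ndarray, np.ndarray]:
    """Thin ramified arms radiating from a soma (intensity only, unlabeled)."""
    H, W = shape
    rs, cs = [], []
    for _ in range(n_arms):
        ang = rng.uniform(0, 2 * math.pi)
        r1 = int(round(center[0] + math.sin(ang) * length))
        c1 = int(round(center[1] + math.cos(ang) * length))
        rr, cc = draw_line(center[0], center[1], r1, c1)
        ok = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
        rs.append(rr[ok])
        cs.append(cc[ok])
    return np.concatenate(rs), np.concatenate(cs)


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------

def _region_id_image(spec: PhantomSpec) -> tuple[np.ndarray | None, list[str]]:
    if not spec.region_layout:
        return None, []
    img = np.zeros((spec.raster_px, spec.raster_px), dtype=np.int32)
    names = []
    for i, reg in enumerate(spec.region_layout, start=1):
        names.append(reg["name"])
        r0, c0, r1, c1 = reg["rect"]
        img[r0:r1, c0:c1] = i
    return img, names


def _accept_position(spec: PhantomSpec, region_img: np.ndarray | None,
                     cls: str, pos: tuple[int, int],
                     rng: np.random.Generator) -> bool:
    if region_img is None or not spec.region_layout:
        return True
    rid = int(region_img[pos])
    mults = [float(reg.get("density", {}).get(cls, 1.0))
             for reg in spec.region_layout]
    mmax = max(mults + [1.0])
    m = 1.0 if rid == 0 else mults[rid - 1]
    return rng.uniform() < m / mmax


def generate_phantom(spec: PhantomSpec) -> tuple[ChannelStack, GroundTruth]:
    """Render one phantom field of view plus its full ground truth.

    Raises
    ------
    PlacementError
        If the requested structure counts cannot be placed without overlap
        inside the tissue area.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.raster_px
    shape = (n, n)
    shapes = spec.shapes
    profiles = spec.profiles

    tissue = np.ones(shape, dtype=bool)
    b = spec.slide_border_px
    if b > 0:
        tissue[:] = False
        tissue[b:-b, b:-b] = True

    region_img, region_names = _region_id_image(spec)

    cell_labels = np.zeros(shape, dtype=np.int32)
    nucleus_labels = np.zeros(shape, dtype=np.int32)
    object_labels = np.zeros(shape, dtype=np.int32)
    cell_class: dict[int, str] = {}
    object_class: dict[int, str] = {}
    # per-marker clean intensity maps
    intensity = {m: np.zeros(shape) for m in spec.marker_names}
    neuron_centers: list[tuple[int, int]] = []

    def place_footprint(extent: int, cls: str, occupied: np.ndarray,
                        near: tuple[int, int] | None = None) -> tuple[int, int]:
        margin = max(extent, b) + 1
        for _ in range(_MAX_TRIES):
            if near is not None:
                pos = (int(np.clip(near[0] + rng.integers(-3, 4), margin, n - margin - 1)),
                       int(np.clip(near[1] + rng.integers(-3, 4), margin, n - margin - 1)))
            else:
                if n - margin <= margin:
                    raise PlacementError(
                        f"{cls}: footprint {extent}px does not fit a {n}px field")
                pos = (int(rng.integers(margin, n - margin)),
                       int(rng.integers(margin, n - margin)))
                if not _accept_position(spec, region_img, cls, pos, rng):
                    continue
            if not occupied[pos]:
                return pos
        raise PlacementError(
            f"could not place requested {cls} after {_MAX_TRIES} tries; "
            f"reduce counts or enlarge the field")

    # --- cells -----------------------------------------------------------
    cell_occ = np.zeros(shape, dtype=bool)
    next_cell = 1
    for cls in CELL_CLASSES:
        count = spec.n_cells_per_class.get(cls, 0)
        sp = shapes[cls]
        for _ in range(count):
            if cls == "endothelial":
                extent = sp["length"] // 2 + sp["width"]
            else:
                extent = sp["soma_radius"] + 1
            for attempt in range(_MAX_TRIES):
                pos = place_footprint(extent, cls, cell_occ)
                if cls == "endothelial":
                    ang = rng.uniform(0, math.pi)
                    px = _capsule_px(pos, sp["length"], sp["width"], ang, shape)
                    guard = px
                else:
                    px = _disk_px(pos, sp["soma_radius"], shape)
                    # 2-px gap so touching somata never merge under
                    # 8-connectivity
                    guard = _disk_px(pos, sp["soma_radius"] + 2, shape)
                if not cell_occ[guard].any() and tissue[px].all():
                    break
            else:
                raise PlacementError(f"could not place {cls} body")
            cell_labels[px] = next_cell
            cell_occ[px] = True
            nuc = _disk_px(pos, sp["nucleus_radius"], shape)
            nucleus_labels[nuc] = next_cell
            cell_class[next_cell] = cls
            if cls == "neuron":
                neuron_centers.append(pos)
            # paint markers
            for marker, mean in profiles.get(cls, {}).items():
                if marker == "HH3":
                    intensity[marker][nuc] += mean
                else:
                    intensity[marker][px] += mean
            # thin unlabeled processes for ramified glia
            if sp.get("n_processes"):
                pr = _process_px(pos, sp["n_processes"], sp["process_len"],
                                 shape, rng)
                main = max((m for m in profiles.get(cls, {}) if m != "HH3"),
                           default=None, key=lambda m: profiles[cls][m])
                if main is not None:
                    intensity[main][pr] += profiles[cls][main] * 0.6
            next_cell += 1

    # --- acellular objects ----------------------------------------------
    obj_occ = np.zeros(shape, dtype=bool)
    next_obj = 1
    for cls in OBJECT_CLASSES:
        count = spec.n_objects_per_class.get(cls, 0)
        sp = shapes[cls]
        for _ in range(count):
            extent = int(sp["radius"] * (1 + sp.get("irregularity", 0.0))) + 1
            for attempt in range(_MAX_TRIES):
                near = None
                if (cls == "tangle" and neuron_centers
                        and rng.uniform() < sp.get("on_neuron_frac", 0.0)):
                    near = neuron_centers[int(rng.integers(len(neuron_centers)))]
                pos = place_footprint(extent, cls, obj_occ, near=near)
                px = _disk_px(pos, sp["radius"], shape, rng,
                              sp.get("irregularity", 0.0))
                # 4-px clearance keeps distinct aggregates resolvable after
                # the segmentation blur
                guard = _disk_px(pos, sp["radius"] + 4
                                 + sp["radius"] * sp.get("irregularity", 0.0),
                                 shape)
                if obj_occ[guard].any() or not tissue[px].all():
                    continue
                # plaques prefer acellular space
                if cls == "plaque" and cell_occ[px].any():
                    continue
                break
            else:
                raise PlacementError(f"could not place {cls}")
            object_labels[px] = next_obj
            obj_occ[px] = True
            object_class[next_obj] = cls
            for marker, mean in profiles.get(cls, {}).items():
                intensity[marker][px] += mean
            next_obj += 1

    # --- assemble channels ------------------------------------------------
    names = list(spec.marker_names)
    for extra in (spec.carbon_channel, spec.bg_channel, spec.empty_channel):
        if extra not in names:
            names.append(extra)
    maps = dict(intensity)
    maps[spec.carbon_channel] = np.where(tissue, spec.carbon_intensity, 0.0)
    maps[spec.bg_channel] = np.where(tissue, 0.0, spec.bg_intensity)
    maps[spec.empty_channel] = np.zeros(shape)

    # linear spillover (adduct/oxide contamination), applied to clean means
    for src, tgt, c in spec.spillover_pairs:
        maps[tgt] = maps[tgt] + c * maps[src]

    pixels = np.stack([maps[m] for m in names])
    if spec.noise_model == "poisson":
        pixels = rng.poisson(pixels).astype(np.float64)
    elif spec.noise_model == "gaussian":
        pixels = np.clip(pixels + rng.normal(0, spec.gaussian_sd, pixels.shape), 0, None)
    elif spec.noise_model == "none":
        pass
    else:
        raise ValueError(f"unknown noise model {spec.noise_model!r}")

    stack = ChannelStack(pixels, names, pixel_size_um=spec.pixel_size_um,
                         fov_id=spec.fov_id)
    truth = GroundTruth(
        cell_labels=LabelLayer(cell_labels, "cell", provenance={"op": "phantom"}),
        object_labels=LabelLayer(object_labels, "object", provenance={"op": "phantom"}),
        cell_class_of_label=cell_class,
        object_class_of_label=object_class,
        nucleus_labels=LabelLayer(nucleus_labels, "cell",
                                  provenance={"op": "phantom/nuclei"}),
        tissue_mask=tissue,
        planted_region_of_pixel=region_img,
        region_names=region_names,
        true_overlap_pairs=overlap_pairs(cell_labels, object_labels),
    )
    return stack, truth


# ---------------------------------------------------------------------------
# tiled fixtures
# ---------------------------------------------------------------------------

def slice_tiles(mosaic: ChannelStack, rows: int, cols: int,
                tile_px: int, overlap_frac: float
                ) -> tuple[list[ChannelStack], list[tuple[int, int]]]:
    """Cut a mosaic into a grid of crop-consistent tiles.

    Returns the tiles and their (row, col) pixel offsets in the mosaic.
    """
    if rows <= 0 or cols <= 0:
        raise ValueError("grid must be positive")
    if not (0 <= overlap_frac < 0.5):
        raise ValueError("overlap_frac must be in [0, 0.5)")
    stride = int(round(tile_px * (1 - overlap_frac)))
    tiles, offsets = [], []
    for i in range(rows):
        for j in range(cols):
            r0, c0 = i * stride, j * stride
            sub = mosaic.pixels[:, r0:r0 + tile_px, c0:c0 + tile_px]
            tiles.append(ChannelStack(sub.copy(), list(mosaic.channel_names),
                                      pixel_size_um=mosaic.pixel_size_um,
                                      fov_id=f"{mosaic.fov_id}_r{i}c{j}"))
            offsets.append((r0, c0))
    return tiles, offsets


def generate_tile_grid(spec: PhantomSpec, rows: int, cols: int,
                       overlap_frac: float
                       ) -> tuple[list[ChannelStack], list[tuple[int, int]],
                                  ChannelStack, GroundTruth]:
    """Phantom mosaic plus its tiling: fixture for stitch testing."""
    if rows <= 0 or cols <= 0:
        raise ValueError("grid must be positive")
    if not (0 <= overlap_frac < 0.5):
        raise ValueError("overlap_frac must be in [0, 0.5)")
    tile_px = spec.raster_px
    stride = int(round(tile_px * (1 - overlap_frac)))
    mosaic_px = tile_px + stride * (max(rows, cols) - 1)
    big = replace(spec, raster_px=mosaic_px,
                  field_width_um=spec.field_width_um * mosaic_px / tile_px,
                  fov_id=f"{spec.fov_id}_mosaic")
    mosaic, truth = generate_phantom(big)
    tiles, offsets = slice_tiles(mosaic, rows, cols, tile_px, overlap_frac)
    return tiles, offsets, mosaic, truth


# ---------------------------------------------------------------------------
# tabular fixtures
# ---------------------------------------------------------------------------

def generate_expression_table(n_per_class: Mapping[str, int],
                              class_means: Mapping[str, Mapping[str, float]],
                              noise_sd: float, seed: int = 0) -> pd.DataFrame:
    """Gaussian expression table with known class labels.

    One row per object; marker columns hold ``class mean + N(0, noise_sd)``.
    The ``true_class`` column enables recovery scoring of gating/clustering.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    markers: list[str] = []
    for prof in class_means.values():
        for m in prof:
            if m not in markers:
                markers.append(m)
    rows = []
    oid = 1
    for cls, count in n_per_class.items():
        prof = class_means[cls]
        for _ in range(count):
            vals = {m: float(prof.get(m, 0.0)) for m in markers}
            if noise_sd > 0:
                for m in markers:
                    vals[m] += rng.normal(0, noise_sd)
            rows.append({"object_id": oid, "true_class": cls, **vals})
            oid += 1
    cols = ["object_id", "true_class"] + markers
    return pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)
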