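"""Flat-field correction and mosaic assembly of tiled fields of view.

Tiles are registered by their declared grid offsets (acquisition offsets are
known in this modality), edge-cropped, flat-field corrected, feather-blended
in overlap zones, median-filtered, and optionally downsampled for display.
Quantitative tables are never derived from auto-scaled imagery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter, median_filter, zoom
from skimage.filters import threshold_otsu
from skimage.morphology import disk
from skimage.transform import resize

from ._core import ChannelStack, ConfigurationError

__all__ = ["TileLayout", "tissue_mask", "flatfield_correct", "crop_edges",
           "grid_stitch", "autoscale"]


@dataclass
class TileLayout:
    """Grid positions per tile plus overlap/crop fractions."""

    positions: list[tuple[int, int]]  # (row, col) grid indices, one per tile
    overlap_frac: float = 0.0
    crop_frac: float = 0.01

    def __post_init__(self) -> None:
        if len(set(self.positions)) != len(self.positions):
            raise ValueError("tile positions must be unique")
        if not (0 <= self.overlap_frac < 0.5):
            raise ValueError("overlap_frac must be in [0, 0.5)")
        if not (0 <= self.crop_frac <= 0.1):
            raise ValueError("crop_frac must be in [0, 0.1]")


def _otsu_mask(img: np.ndarray) -> np.ndarray:
    """Otsu foreground; constant images fall back to positivity."""
    if img.max() == img.min():
        return img > 0
    return img >= threshold_otsu(img)


def tissue_mask(stack: ChannelStack, carbon: str = "C12", gold: str = "Au",
                empty: str = "Empty139") -> np.ndarray:
    """Binary tissue mask: carbon-high AND NOT gold-high AND NOT empty-high."""
    stack.require_channels([carbon, gold, empty])
    return (_otsu_mask(stack.channel(carbon))
            & ~_otsu_mask(stack.channel(gold))
            & ~_otsu_mask(stack.channel(empty)))


def _response_map(img: np.ndarray, mask: np.ndarray, downsample: int,
                  smooth_sigma: float, eps: float) -> np.ndarray:
    H, W = img.shape
    small = resize(img, (max(1, H // downsample), max(1, W // downsample)),
                   anti_aliasing=True, preserve_range=True)
    small = gaussian_filter(small, smooth_sigma)
    m = resize(small, (H, W), preserve_range=True)
    inside = m[mask]
    mean = inside.mean() if inside.size else m.mean()
    if mean <= 0:
        mean = eps
    m = m / mean
    # guard zeros inside tissue with an additive epsilon
    return np.where(m <= eps, eps, m)


def flatfield_correct(tile: ChannelStack,
                      mode: Literal["per_channel", "all_channel"] = "per_channel",
                      mask: np.ndarray | None = None,
                      downsample: int = 8, smooth_sigma: float = 2.0,
                      eps: float = 1e-6) -> ChannelStack:
    """Divide out a smoothly varying intensity-response map.

    ``per_channel`` builds one map per channel from that channel alone;
    ``all_channel`` averages all channels into a single map (averaging out
    biologically distinct distributions, leaving the detector response).
    Maps are renormalized to mean 1 within the tissue mask so channel means
    are preserved.
    """
    if tile.pixels.size == 0:
        raise ValueError("empty tile")
    if mask is None:
        mask = np.ones(tile.shape, dtype=bool)
    out = tile.copy()
    if mode == "all_channel":
        m = _response_map(tile.pixels.mean(axis=0), mask, downsample,
                          smooth_sigma, eps)
        out.pixels = out.pixels / m[None]
    elif mode == "per_channel":
        for i in range(out.n_channels):
            m = _response_map(tile.pixels[i], mask, downsample, smooth_sigma, eps)
            out.pixels[i] = out.pixels[i] / m
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out


def crop_edges(tile: ChannelStack, crop_frac: float = 0.01) -> ChannelStack:
    """Remove ``floor(crop_frac * dim)`` pixels from each side."""
    if not (0 <= crop_frac <= 0.5):
        raise ValueError("crop_frac out of range")
    H, W = tile.shape
    dr, dc = int(crop_frac * H), int(crop_frac * W)
    if H - 2 * dr <= 0 or W - 2 * dc <= 0:
        raise ValueError("crop removes the whole tile")
    out = tile.copy()
    out.pixels = out.pixels[:, dr:H - dr or None, dc:W - dc or None].copy()
    return out


def _feather_weights(h: int, w: int, ramp: int) -> np.ndarray:
    """Separable linear ramp from the tile edge over ``ramp`` pixels."""
    def ramp1d(n: int) -> np.ndarray:
        x = np.ones(n)
        r = min(ramp, n // 2)
        if r > 0:
            edge = (np.arange(1, r + 1)) / (r + 1)
            x[:r] = edge
            x[n - r:] = edge[::-1]
        return x
    return np.outer(ramp1d(h), ramp1d(w))


def grid_stitch(tiles: Sequence[ChannelStack], layout: TileLayout,
                median_radius: int = 2, max_dim: int | None = None
                ) -> ChannelStack:
    """Assemble tiles into a mosaic at declared offsets.

    Overlap zones are linearly feather-blended; each channel then passes
    through a median filter (disk footprint of the given pixel radius); if
    ``max_dim`` is set the mosaic is downsampled so its largest spatial
    dimension does not exceed it.
    """
    if not tiles:
        raise ValueError("no tiles")
    shapes = {t.pixels.shape for t in tiles}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent tile shapes: {shapes}")
    names = tiles[0].channel_names
    for t in tiles:
        if t.channel_names != names:
            raise ValueError("tiles disagree on channel names")
    if len(tiles) != len(layout.positions):
        raise ValueError("layout does not match tile count")

    C, H, W = tiles[0].pixels.shape
    stride_r = int(round(H * (1 - layout.overlap_frac)))
    stride_c = int(round(W * (1 - layout.overlap_frac)))
    rows = [p[0] for p in layout.positions]
    cols = [p[1] for p in layout.positions]
    r_min, c_min = min(rows), min(cols)
    out_h = (max(rows) - r_min) * stride_r + H
    out_w = (max(cols) - c_min) * stride_c + W

    acc = np.zeros((C, out_h, out_w))
    wacc = np.zeros((out_h, out_w))
    ramp = max(H - stride_r, W - stride_c, 1)
    wtile = _feather_weights(H, W, ramp)
    for tile, (r, c) in zip(tiles, layout.positions):
        r0, c0 = (r - r_min) * stride_r, (c - c_min) * stride_c
        acc[:, r0:r0 + H, c0:c0 + W] += tile.pixels * wtile[None]
        wacc[r0:r0 + H, c0:c0 + W] += wtile
    mosaic = acc / np.where(wacc > 0, wacc, 1.0)[None]

    if median_radius > 0:
        foot = disk(median_radius)
        for i in range(C):
            mosaic[i] = median_filter(mosaic[i], footprint=foot)

    pixel_size = tiles[0].pixel_size_um
    if max_dim is not None and max(out_h, out_w) > max_dim:
        factor = max_dim / max(out_h, out_w)
        mosaic = np.stack([zoom(mosaic[i], factor, order=1) for i in range(C)])
        pixel_size = pixel_size / factor
    return ChannelStack(np.clip(mosaic, 0, None), list(names),
                        pixel_size_um=pixel_size, fov_id="mosaic")


def autoscale(channel: np.ndarray, low: float = 0.0, high: float = 1.0
              ) -> np.ndarray:
    """Linear auto-scaling for display only; never feed into tables."""
    lo, hi = channel.min(), channel.max()
    if hi == lo:
        return np.full_like(channel, low, dtype=np.float64)
    return low + (channel - lo) * (high - low) / (hi - lo)
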