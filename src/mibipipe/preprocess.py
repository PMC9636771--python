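"""Per-channel background removal, frequency-domain denoising and spillover
compensation of raw ion-count channel stacks.

Background on the bare gold slide correlates with the Au channel: a mask is
formed by Gaussian-smoothing the background channel (kernel radius ``R``) and
thresholding at a fraction ``T`` of its smoothed maximum; masked pixels are
zeroed in all other channels.  High-frequency content is treated as noise and
removed with a radially symmetric low-pass in Fourier space.  Spillover from
adducts and oxides is compensated pairwise: ``target <- max(target - c*source, 0)``
in configured list order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from ._core import ChannelStack, ConfigurationError

__all__ = ["PreprocessParams", "remove_background", "denoise_fft",
           "compensate_spillover", "preprocess_stack",
           "DEFAULT_SPILLOVER_PAIRS"]

# Channel pairs known to cross-contaminate through adducts and oxides.
DEFAULT_SPILLOVER_PAIRS: list[tuple[str, str, float]] = [
    ("pASyn", "Abeta", 0.1),
    ("Iba1", "PSD95", 0.1),
    ("GFAP", "CD105", 0.1),
    ("MBP", "MCT1", 0.1),
    ("MCT1", "CD33", 0.1),
    ("TAU", "MFN2", 0.1),
]


@dataclass
class PreprocessParams:
    """Knobs for the three preprocessing stages.

    ``T`` is the background threshold as a fraction of the smoothed
    background-channel maximum (stated range 0.1-0.2; default is the
    midpoint).  ``R`` is the Gaussian kernel radius in pixels.
    ``fft_cutoff`` is a normalized spatial frequency in (0, 0.5].
    """

    bg_channel: str = "Au"
    T: float = 0.15
    R: float = 1.0
    fft_cutoff: float = 0.3
    spillover_pairs: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0 <= self.T <= 1):
            raise ValueError("T must be in [0, 1]")
        if self.R < 0:
            raise ValueError("R must be >= 0")
        if not (0 < self.fft_cutoff <= 0.5):
            raise ValueError("fft_cutoff must be in (0, 0.5]")
        for src, tgt, c in self.spillover_pairs:
            if not (0 <= c < 1):
                raise ValueError(f"spillover coefficient {c} not in [0, 1)")


def background_mask(stack: ChannelStack, params: PreprocessParams) -> np.ndarray:
    """Boolean mask of slide-background pixels (True = background)."""
    bg = stack.channel(params.bg_channel)
    smoothed = gaussian_filter(bg, params.R) if params.R > 0 else bg
    peak = smoothed.max()
    if peak <= 0:
        return np.zeros_like(smoothed, dtype=bool)
    return smoothed >= params.T * peak


def remove_background(stack: ChannelStack, params: PreprocessParams) -> ChannelStack:
    """Zero slide-background pixels in every non-background channel."""
    if not stack.has_channel(params.bg_channel):
        raise ConfigurationError(f"background channel {params.bg_channel!r} missing")
    mask = background_mask(stack, params)
    out = stack.copy()
    bg_idx = stack.index(params.bg_channel)
    for i in range(out.n_channels):
        if i != bg_idx:
            out.pixels[i][mask] = 0.0
    return out


def denoise_fft(channel: np.ndarray, cutoff: float = 0.3) -> np.ndarray:
    """Radially symmetric low-pass filter of one channel.

    ``cutoff`` is in cycles/pixel; frequencies with radial magnitude above it
    are zeroed.  Negative ringing is clipped to zero.
    """
    if not (0 < cutoff <= 0.5):
        raise ValueError("cutoff must be in (0, 0.5]")
    channel = np.asarray(channel, dtype=np.float64)
    if not np.isfinite(channel).all():
        raise ValueError("channel contains non-finite pixels")
    fy = np.fft.fftfreq(channel.shape[0])[:, None]
    fx = np.fft.fftfreq(channel.shape[1])[None, :]
    radial = np.hypot(fy, fx)
    spectrum = np.fft.fft2(channel)
    spectrum[radial > cutoff] = 0.0
    out = np.fft.ifft2(spectrum).real
    return np.clip(out, 0.0, None)


def denoise_stack(stack: ChannelStack, cutoff: float = 0.3,
                  skip: Sequence[str] = ()) -> ChannelStack:
    out = stack.copy()
    for i, name in enumerate(out.channel_names):
        if name not in skip:
            out.pixels[i] = denoise_fft(out.pixels[i], cutoff)
    return out


def compensate_spillover(stack: ChannelStack,
                         pairs: Sequence[tuple[str, str, float]]) -> ChannelStack:
    """Sequential pairwise spillover subtraction, clipped at zero.

    Pairs are applied in list order on the evolving stack; for each
    ``(source, target, c)`` the target becomes ``max(target - c*source, 0)``.
    """
    out = stack.copy()
    for src, tgt, c in pairs:
        if not out.has_channel(src) or not out.has_channel(tgt):
            raise ConfigurationError(f"spillover pair ({src!r}, {tgt!r}) "
                                     "names an unknown channel")
        if not (0 <= c < 1):
            raise ValueError(f"spillover coefficient {c} not in [0, 1)")
        s = out.channel(src)
        t = out.channel(tgt)
        out.pixels[out.index(tgt)] = np.clip(t - c * s, 0.0, None)
    return out


def preprocess_stack(stack: ChannelStack, params: PreprocessParams,
                     denoise: bool = True,
                     denoise_skip: Sequence[str] = ()) -> ChannelStack:
    """Full per-FOV preprocessing: background, spillover, then denoising.

    The background mask is re-applied after the low-pass so that blur
    leakage cannot paint tissue signal back onto the bare slide.
    """
    out = remove_background(stack, params)
    if params.spillover_pairs:
        out = compensate_spillover(out, params.spillover_pairs)
    if denoise:
        out = denoise_stack(out, params.fft_cutoff,
                            skip=list(denoise_skip) + [params.bg_channel])
        out = remove_background(out, params)
    return out
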