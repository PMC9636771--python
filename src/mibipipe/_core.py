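"""Core raster containers shared by every pipeline stage.

A :class:`ChannelStack` is the universal currency for multichannel ion-count
images (one 2-D channel per antibody marker); a :class:`LabelLayer` is an
integer-labeled object mask (cells or acellular objects) tied to the same
geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Iterable, Mapping

import numpy as np

__all__ = ["ChannelStack", "LabelLayer", "ConfigurationError", "GeometryError"]


class ConfigurationError(ValueError):
    """A parameter block refers to channels or values that do not exist."""


class GeometryError(ValueError):
    """Two rasters that must share a pixel grid do not."""


@dataclass
class ChannelStack:
    """Named multichannel image with physical pixel-size metadata.

    Parameters
    ----------
    pixels
        Nonnegative array of shape ``(n_channels, height, width)``; ion
        counts (or count-like intensities) per pixel.
    channel_names
        One unique marker name per channel.
    pixel_size_um
        Physical edge length of one pixel in micrometers.
    fov_id
        Identifier of the field of view this stack was rastered from.
    """

    pixels: np.ndarray
    channel_names: list[str]
    pixel_size_um: float = 1.0
    fov_id: str = "fov0"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        self.channel_names = list(self.channel_names)
        if self.pixels.ndim != 3:
            raise ValueError(f"pixels must be (C, H, W); got shape {self.pixels.shape}")
        if len(self.channel_names) != self.pixels.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.pixels.shape[0]} channels"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    # -- access ------------------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial (height, width)."""
        return self.pixels.shape[1:]

    def index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise ConfigurationError(
                f"channel {name!r} not in stack ({', '.join(self.channel_names)})"
            ) from None

    def channel(self, name: str) -> np.ndarray:
        """Return the 2-D image for one named channel (a view)."""
        return self.pixels[self.index(name)]

    def has_channel(self, name: str) -> bool:
        return name in self.channel_names

    def copy(self) -> "ChannelStack":
        return replace(self, pixels=self.pixels.copy(),
                       channel_names=list(self.channel_names))

    def select(self, names: Iterable[str]) -> "ChannelStack":
        names = list(names)
        idx = [self.index(n) for n in names]
        return replace(self, pixels=self.pixels[idx].copy(), channel_names=names)

    def require_channels(self, names: Iterable[str]) -> None:
        missing = [n for n in names if n not in self.channel_names]
        if missing:
            raise ConfigurationError(f"missing channels: {missing}")


@dataclass
class LabelLayer:
    """Integer-labeled object mask.

    ``labels`` uses 0 for background and the contiguous set ``1..K`` for
    objects.  ``layer_kind`` distinguishes nuclei-associated cells from
    threshold-segmented acellular objects; ``provenance`` records the
    operation and parameters that produced the layer.
    """

    labels: np.ndarray
    layer_kind: str = "cell"  # "cell" | "object"
    object_class: str | None = None
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D image")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer image")
        if self.labels.min() < 0:
            raise ValueError("labels must be nonnegative")

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())

    @property
    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def is_contiguous(self) -> bool:
        ids = self.label_ids
        return len(ids) == 0 or (ids[0] == 1 and ids[-1] == len(ids))

    def check_geometry(self, other: "LabelLayer | ChannelStack") -> None:
        other_shape = other.shape if isinstance(other, ChannelStack) else other.labels.shape
        if tuple(self.labels.shape) != tuple(other_shape):
            raise GeometryError(
                f"geometry mismatch: {self.labels.shape} vs {other_shape}"
            )


def relabel_contiguous(labels: np.ndarray) -> np.ndarray:
    """Remap positive labels onto 1..K preserving order of first appearance
    of the sorted original ids."""
    out = np.zeros_like(labels, dtype=np.int32)
    for new, old in enumerate(np.unique(labels[labels > 0]), start=1):
        out[labels == old] = new
    return out


def class_map(layers: Mapping[str, LabelLayer]) -> dict[int, str]:
    """Flatten per-class layers into one label->class map (labels offset)."""
    mapping: dict[int, str] = {}
    offset = 0
    for cls, layer in layers.items():
        for lab in layer.label_ids:
            mapping[int(lab) + offset] = cls
        offset += layer.n_labels
    return mapping
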