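"""Shared in-memory containers for the image-analysis chain.

The containers are deliberately thin: a 2D intensity grid plus the physical
pixel size is all downstream morphometry needs, and keeping them as plain
dataclasses makes every stage trivially serializable for provenance.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "EnFaceImage",
    "FrameStack",
    "BinaryVesselMask",
    "SkeletonMask",
    "TransformEstimate",
]


@dataclass
class EnFaceImage:
    """A single en face angiogram: non-negative intensities on a square grid.

    Parameters
    ----------
    pixels : ndarray
        2D float array of intensities (arbitrary units, >= 0).
    pixel_size_mm : float
        Physical size of one pixel in millimetres (e.g. 3 mm / 304 px).
    device_meta : dict
        Free-form acquisition metadata; the quality gate looks for
        ``signal_strength_index`` and/or ``quality_score`` here.
    provenance : str
        One of ``raw``, ``corrected``, ``averaged``.
    """

    pixels: np.ndarray
    pixel_size_mm: float
    device_meta: dict[str, Any] = field(default_factory=dict)
    provenance: str = "raw"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2D array")
        if not self.pixel_size_mm > 0:
            raise ValueError("pixel_size_mm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def copy(self, **updates: Any) -> "EnFaceImage":
        kwargs: dict[str, Any] = dict(
            pixels=self.pixels.copy(),
            pixel_size_mm=self.pixel_size_mm,
            device_meta=dict(self.device_meta),
            provenance=self.provenance,
        )
        kwargs.update(updates)
        return EnFaceImage(**kwargs)


@dataclass
class FrameStack:
    """An ordered burst of en face frames of the same eye."""

    frames: list[EnFaceImage]
    reference_index: int = 0
    true_transforms: list[dict[str, Any]] | None = None

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("FrameStack needs at least one frame")
        shape = self.frames[0].shape
        px = self.frames[0].pixel_size_mm
        for f in self.frames:
            if f.shape != shape or f.pixel_size_mm != px:
                raise ValueError("all frames must share shape and pixel size")
        if not 0 <= self.reference_index < len(self.frames):
            raise ValueError("reference_index out of range")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class BinaryVesselMask:
    """Boolean vessel segmentation aligned with its source image."""

    pixels: np.ndarray
    pixel_size_mm: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2D")
        if not self.pixel_size_mm > 0:
            raise ValueError("pixel_size_mm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class SkeletonMask:
    """One-pixel-wide centerline mask derived from a vessel mask."""

    pixels: np.ndarray
    pixel_size_mm: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("skeleton must be 2D")
        if not self.pixel_size_mm > 0:
            raise ValueError("pixel_size_mm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class TransformEstimate:
    """Result of one registration stage."""

    stage: str  # translation | affine | elastic
    parameters: dict[str, Any]
    residual: float

    def __post_init__(self) -> None:
        if self.stage == "translation":
            shift = self.parameters.get("shift")
            if shift is None or len(shift) != 2:
                raise ValueError("translation stage carries exactly 2 parameters")
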