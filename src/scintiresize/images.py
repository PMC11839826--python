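"""Core image containers for photon-counting (scintigraphic) data.

The native unit of a planar scintigraphic image is the number of detected
gamma-photon events per pixel, so the fundamental container is an integer
:class:`CountImage`.  Pixel counts follow Poisson statistics: the variance of
a pixel equals its mean, hence the relative noise of a pixel with mean ``m``
is ``1/sqrt(m)``.  Real-valued grids (:class:`RealImage`) appear only as
intermediates — interpolated images, expected-count maps, and max-normalized
images fed to similarity metrics.

Coordinate convention throughout the package: row-major arrays, origin at the
top-left, 0-based pixel indices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = ["CountImage", "RealImage", "ResizeFactor", "relative_noise"]

#: The six standard planar projections of a lung ventilation-perfusion exam.
VIEW_LABELS = ("ANT", "POST", "LAO", "RPO", "LPO", "RAO")


def _as_readonly(a: np.ndarray) -> np.ndarray:
    a = np.ascontiguousarray(a)
    a.setflags(write=False)
    return a


@dataclass(frozen=True)
class CountImage:
    """A 2-D grid of detected photon events.

    Parameters
    ----------
    pixels
        2-D array of nonnegative integers (events per pixel).
    pixel_spacing_mm
        Physical edge length of a pixel in millimetres.
    view_label
        Optional planar projection label (``ANT``, ``POST``, ...).
    """

    pixels: np.ndarray
    pixel_spacing_mm: float = 1.0
    view_label: Optional[str] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {px.shape}")
        if not np.issubdtype(px.dtype, np.integer):
            if np.issubdtype(px.dtype, np.floating) and np.all(px == np.floor(px)):
                px = px.astype(np.int64)
            else:
                raise ValueError("CountImage pixels must be integers")
        if px.size and px.min() < 0:
            raise ValueError("CountImage pixels must be nonnegative")
        if not self.pixel_spacing_mm > 0:
            raise ValueError("pixel_spacing_mm must be positive")
        object.__setattr__(self, "pixels", _as_readonly(px.astype(np.int64)))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def total_counts(self) -> int:
        return int(self.pixels.sum())

    def relative_noise(self) -> np.ndarray:
        """Per-pixel relative noise ``1/sqrt(counts)`` (inf where counts are 0)."""
        return relative_noise(self.pixels)

    def as_real(self) -> "RealImage":
        return RealImage(
            self.pixels.astype(np.float64),
            pixel_spacing_mm=self.pixel_spacing_mm,
            view_label=self.view_label,
        )


@dataclass(frozen=True)
class RealImage:
    """A 2-D grid of nonnegative reals (interpolation or normalization output)."""

    values: np.ndarray
    pixel_spacing_mm: float = 1.0
    view_label: Optional[str] = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("RealImage values must be finite")
        if v.size and v.min() < 0:
            raise ValueError("RealImage values must be nonnegative")
        if not self.pixel_spacing_mm > 0:
            raise ValueError("pixel_spacing_mm must be positive")
        object.__setattr__(self, "values", _as_readonly(v))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def total(self) -> float:
        return float(self.values.sum())


@dataclass(frozen=True)
class ResizeFactor:
    """An integer resize factor ``f``.

    ``area_ratio`` (``f**2``) is the count multiplier when downsampling by
    summation; ``thin_probability`` (``1/f**2``) is the binomial success
    probability that rescales counts when upsampling.  Factors 2 and 4 are
    the validated cases.
    """

    f: int

    def __post_init__(self) -> None:
        if int(self.f) != self.f or self.f < 2:
            raise ValueError(f"resize factor must be an integer >= 2, got {self.f}")
        object.__setattr__(self, "f", int(self.f))

    @property
    def area_ratio(self) -> int:
        return self.f ** 2

    @property
    def thin_probability(self) -> float:
        return 1.0 / self.f ** 2


def relative_noise(pixels: np.ndarray) -> np.ndarray:
    """Relative noise of Poisson-distributed counts: ``std/mean = 1/sqrt(mean)``."""
    px = np.asarray(pixels, dtype=np.float64)
    with np.errstate(divide="ignore"):
        return 1.0 / np.sqrt(px)


def as_factor(f: "int | ResizeFactor") -> ResizeFactor:
    return f if isinstance(f, ResizeFactor) else ResizeFactor(int(f))
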