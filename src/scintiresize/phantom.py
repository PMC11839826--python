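"""Digital lung-phantom acquisition simulator.

Emulates a planar ventilation-perfusion (V/Q) acquisition of a torso phantom
whose only activity sits in two lung fields: a continuous activity map (an
expected-emission-rate field over a fixed field of view) is rendered onto the
standard acquisition grids (64x64, 128x128, 256x256 covering the same field
of view), and per-pixel Poisson counts are drawn to produce a dynamic series
of short frames.  Summing randomly chosen frames yields statistically
independent images at controllable count levels — the raw material for the
reference similarity curves.

The activity map lives on a fixed high-resolution "physical" grid (512x512
by default, a common multiple of the acquisition grids) so that rendering to
any acquisition grid is an exact block-sum integral and all grids image
literally the same object.  The map itself is parametric: two rotated
ellipses with a smooth multiplicative heterogeneity texture, distinct per
view through rotation/mirroring of the base geometry.  Attenuation, scatter,
collimator blur, decay and dead time are not modelled.

All randomness flows from one root seed; each (view, purpose) pair gets an
independent child stream derived via ``numpy.random.SeedSequence`` spawn
keys, so every simulation is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .images import VIEW_LABELS, CountImage, RealImage

__all__ = [
    "PhantomConfig",
    "ActivityMap",
    "DynamicSeries",
    "build_activity_map",
    "project_to_grid",
    "simulate_series",
    "simulate_view",
    "draw_frame_pair",
    "sum_frames",
]

#: Default pixel spacings (mm) per acquisition grid, zoom factor 1.45.
DEFAULT_SPACING_MM = {64: 6.59, 128: 3.29, 256: 1.64}

# Per-view geometry: (rotation of the torso in degrees, left-right mirror).
# Oblique views rotate the lung pair; posterior views mirror it.
_VIEW_GEOMETRY = {
    "ANT": (0.0, False),
    "POST": (0.0, True),
    "LAO": (-15.0, False),
    "RAO": (15.0, False),
    "LPO": (-15.0, True),
    "RPO": (15.0, True),
}


@dataclass(frozen=True)
class PhantomConfig:
    """Acquisition parameters of the simulated dynamic protocol.

    Defaults mirror a dynamic planar lung acquisition: 100 frames of 1 s at
    ~11 kcnts per frame (1.1 Mcnts total), acquired on 64/128/256 grids over
    a fixed field of view (zoom 1.45).
    """

    grids: tuple[int, ...] = (64, 128, 256)
    zoom: float = 1.45
    frame_total_counts: float = 11_000.0
    n_frames: int = 100
    pixel_spacing_mm: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_SPACING_MM)
    )
    seed: int = 0
    physical_res: int = 512

    def __post_init__(self) -> None:
        if self.frame_total_counts <= 0:
            raise ValueError("frame_total_counts must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        biggest = max(self.grids)
        for g in self.grids:
            if self.physical_res % g:
                raise ValueError(
                    f"grid {g} must divide the physical resolution {self.physical_res}"
                )
            if biggest % g:
                raise ValueError(f"grid {g} must divide the largest grid {biggest}")
        # Printed spacings are rounded, so check inverse proportionality to 1%.
        ref = self.spacing_for(biggest) * biggest
        for g in self.grids:
            if abs(self.spacing_for(g) * g - ref) > 0.01 * ref:
                raise ValueError(
                    "pixel spacings must be inversely proportional to grid size"
                )

    def spacing_for(self, grid: int) -> float:
        try:
            return self.pixel_spacing_mm[grid]
        except KeyError:
            # fall back to scaling from the largest configured grid
            biggest = max(self.pixel_spacing_mm)
            return self.pixel_spacing_mm[biggest] * biggest / grid

    @property
    def extent_mm(self) -> float:
        """Physical width/height of the (square) field of view."""
        biggest = max(self.grids)
        return self.spacing_for(biggest) * biggest

    def child_rng(self, *key: int) -> np.random.Generator:
        """Independent generator for a (view, grid, purpose) stream."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=tuple(key))
        )


@dataclass(frozen=True)
class ActivityMap:
    """Continuous expected-emission-rate field (counts/s per cell).

    The ground truth all acquisition grids image: activity confined to two
    lung fields on a zero background, defined on a high-resolution physical
    grid spanning ``extent_mm``.
    """

    field: np.ndarray
    extent_mm: float
    view_label: str

    def __post_init__(self) -> None:
        f = np.asarray(self.field, dtype=np.float64)
        if f.ndim != 2:
            raise ValueError("activity field must be 2-D")
        if f.min() < 0:
            raise ValueError("activity field must be nonnegative")
        if f.sum() <= 0:
            raise ValueError("activity field must have positive total rate")
        f = np.ascontiguousarray(f)
        f.setflags(write=False)
        object.__setattr__(self, "field", f)

    @property
    def total_rate(self) -> float:
        return float(self.field.sum())


@dataclass(frozen=True)
class DynamicSeries:
    """An ordered stack of fixed-duration count frames sharing grid and view."""

    stack: np.ndarray  # (n_frames, M, N) integer counts
    pixel_spacing_mm: float
    view_label: Optional[str] = None
    frame_duration_s: float = 1.0

    def __post_init__(self) -> None:
        s = np.asarray(self.stack)
        if s.ndim != 3 or s.shape[0] < 1:
            raise ValueError("stack must be (n_frames >= 1, M, N)")
        if not np.issubdtype(s.dtype, np.integer):
            raise ValueError("frames must hold integer counts")
        if s.min() < 0:
            raise ValueError("counts must be nonnegative")
        s = np.ascontiguousarray(s.astype(np.int64))
        s.setflags(write=False)
        object.__setattr__(self, "stack", s)

    @property
    def n_frames(self) -> int:
        return self.stack.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.stack.shape[1:]  # type: ignore[return-value]

    def __len__(self) -> int:
        return self.n_frames

    def frame(self, i: int) -> CountImage:
        return CountImage(self.stack[i], self.pixel_spacing_mm, self.view_label)

    @property
    def frames(self) -> list[CountImage]:
        return [self.frame(i) for i in range(self.n_frames)]


def _lung_profile(
    x: np.ndarray,
    y: np.ndarray,
    center: tuple[float, float],
    axes: tuple[float, float],
    tilt_deg: float,
) -> np.ndarray:
    """Smooth activity profile of one elliptical lung field (0 outside)."""
    t = np.deg2rad(tilt_deg)
    u = (x - center[0]) * np.cos(t) + (y - center[1]) * np.sin(t)
    v = -(x - center[0]) * np.sin(t) + (y - center[1]) * np.cos(t)
    r2 = (u / axes[0]) ** 2 + (v / axes[1]) ** 2
    inside = r2 < 1.0
    prof = np.zeros_like(r2)
    prof[inside] = (1.0 - r2[inside]) ** 0.35
    return prof


def build_activity_map(view: str, config: PhantomConfig) -> ActivityMap:
    """Construct the activity distribution seen from one planar view.

    Two tilted elliptical lung fields (the left slightly smaller, emulating
    the cardiac notch) on a zero background, modulated by a smooth
    low-frequency multiplicative texture drawn from the view's child stream,
    and normalized so the total emission rate equals
    ``config.frame_total_counts`` (counts per 1 s frame).  Deterministic for
    a fixed (view, config).
    """
    if view not in VIEW_LABELS:
        raise ValueError(f"unknown view {view!r}; expected one of {VIEW_LABELS}")
    n = config.physical_res
    angle, mirror = _VIEW_GEOMETRY[view]

    # cell-centre coordinates in [-1, 1], rotated/mirrored per view
    c = (np.arange(n) + 0.5) / n * 2.0 - 1.0
    x, y = np.meshgrid(c, c)
    if mirror:
        x = -x
    t = np.deg2rad(angle)
    xr = x * np.cos(t) - y * np.sin(t)
    yr = x * np.sin(t) + y * np.cos(t)

    # patient left lung appears on image right in the anterior view
    right = _lung_profile(xr, yr, (-0.40, 0.02), (0.26, 0.48), -8.0)
    left = _lung_profile(xr, yr, (0.40, -0.02), (0.23, 0.44), 8.0)
    mask = right + left

    # smooth multiplicative heterogeneity (beads / non-uniform filling)
    rng = config.child_rng(VIEW_LABELS.index(view), 0)
    noise = gaussian_filter(rng.standard_normal((n, n)), sigma=n / 20.0)
    sd = noise.std()
    if sd > 0:
        noise = noise / sd
    field = mask * np.exp(0.35 * noise)

    field *= config.frame_total_counts / field.sum()
    return ActivityMap(field, config.extent_mm, view)


def project_to_grid(
    amap: ActivityMap, grid: int, config: PhantomConfig
) -> RealImage:
    """Expected counts per pixel for one 1 s frame on an acquisition grid.

    Integrates (block-sums) the activity field over each pixel's physical
    footprint, so the total equals ``frame_total_counts`` at every grid and
    renderings at different grids are exactly nested: the projection at grid
    ``n`` equals the f x f block-sum of the projection at grid ``f*n``.
    """
    res = amap.field.shape[0]
    if grid < 1 or res % grid:
        raise ValueError(f"grid {grid} does not divide physical resolution {res}")
    f = res // grid
    expected = amap.field.reshape(grid, f, grid, f).sum(axis=(1, 3))
    return RealImage(expected, config.spacing_for(grid), amap.view_label)


def simulate_series(
    expected: RealImage, n_frames: int, rng: np.random.Generator
) -> DynamicSeries:
    """Draw a dynamic series of independent Poisson frames.

    Each frame pixel is an independent ``Poisson(expected)`` draw; frames are
    mutually independent 1 s acquisitions of the same scene.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if expected.values.min() < 0:
        raise ValueError("expected counts must be nonnegative")
    stack = rng.poisson(expected.values, size=(n_frames, *expected.shape))
    return DynamicSeries(stack, expected.pixel_spacing_mm, expected.view_label)


def simulate_view(
    view: str, grid: int, config: PhantomConfig, stream: int = 1
) -> DynamicSeries:
    """One-call simulation: activity map -> grid projection -> dynamic series.

    ``stream`` selects an independent child RNG stream, so two calls with
    different streams yield independent acquisitions of the same object.
    """
    amap = build_activity_map(view, config)
    expected = project_to_grid(amap, grid, config)
    rng = config.child_rng(VIEW_LABELS.index(view), grid, stream)
    return simulate_series(expected, config.n_frames, rng)


def draw_frame_pair(
    n_total: int, k: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Two disjoint sets of ``k`` distinct frame indices, uniformly sampled.

    Summing each set yields two statistically independent images at the same
    nominal count level.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if 2 * k > n_total:
        raise ValueError(f"cannot draw two disjoint sets of {k} from {n_total} frames")
    perm = rng.permutation(n_total)
    return perm[:k].copy(), perm[k : 2 * k].copy()


def sum_frames(series: DynamicSeries, indices: Sequence[int]) -> CountImage:
    """Elementwise sum of the selected frames (a longer virtual acquisition)."""
    idx = np.asarray(indices, dtype=np.intp)
    if idx.ndim != 1 or idx.size < 1:
        raise ValueError("indices must be a non-empty 1-D sequence")
    if np.unique(idx).size != idx.size:
        raise ValueError("frame indices must be distinct")
    if idx.min() < 0 or idx.max() >= series.n_frames:
        raise ValueError("frame index out of range")
    summed = series.stack[idx].sum(axis=0)
    return CountImage(summed, series.pixel_spacing_mm, series.view_label)
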