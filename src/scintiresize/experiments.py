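"""Permutation experiments: reference similarity curves and resizing studies.

The validation postulate: a successfully resized image of an object should be
as similar to a natively acquired image at the target grid as two
independently acquired native images are to each other.  Because every
acquisition carries its own Poisson noise, no single image is a ground
truth — all comparisons are between image *pairs*, and the benchmark is the
*reference similarity curve*: the mean (with a permutation confidence band)
of a similarity metric between two independent native images, as a function
of count level.

Count level is expressed as the number of summed 1 s frames (k of the 100
acquired), with nominal total counts k x ~11 kcnts; the full-count image
sums 50 frames (~550 kcnts) so that two disjoint full-count images can be
drawn from one 100-frame series.

Experiments (each mirrors one study arm):

* :func:`reference_curve` — native pair vs native pair (the benchmark).
* :func:`lowcount_curve` — pairs of binomially thinned full-count images,
  validating Poisson resampling as a low-count synthesizer.
* :func:`upsampling_experiment` — naive vs thinning-corrected upsampling
  against native images at the finer grid.
* :func:`downsampling_experiment` — bilinear vs window-summation
  downsampling against native images at the coarser grid.
* :func:`curve_agreement` — operationalizes "the curves overlap" as
  per-level confidence-interval intersection.

Confidence bands are 2.5th-97.5th percentiles over permutations (default
1,000; scaled runs use fewer).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .images import CountImage
from .phantom import DynamicSeries, draw_frame_pair, sum_frames
from .resize import (
    apply_global_scale,
    downsample_linear,
    downsample_window_sum,
    upsample_corrected,
    upsample_linear,
)
from .similarity import SsimParams, log_mse, normalize_max, ssim

__all__ = [
    "SimilarityCurve",
    "AgreementReport",
    "reference_curve",
    "lowcount_curve",
    "upsampling_experiment",
    "downsampling_experiment",
    "curve_agreement",
]

METRICS = ("ssim", "log_mse")
DEFAULT_LEVELS = (1, 2, 5, 10, 20, 35, 50)
FULL_COUNT_FRAMES = 50


@dataclass(frozen=True)
class SimilarityCurve:
    """Per-count-level mean of a similarity metric with a permutation CI band."""

    metric: str
    levels: np.ndarray  # number of summed frames, ascending
    nominal_kcnts: np.ndarray
    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_perm: int

    def __post_init__(self) -> None:
        for name in ("levels", "nominal_kcnts", "mean", "ci_low", "ci_high"):
            object.__setattr__(
                self, name, np.asarray(getattr(self, name), dtype=np.float64)
            )
        n = self.levels.size
        if any(
            getattr(self, f).size != n
            for f in ("nominal_kcnts", "mean", "ci_low", "ci_high")
        ):
            raise ValueError("curve fields must have consistent lengths")
        if n and self.n_perm < 2:
            raise ValueError("n_perm must be >= 2")
        if np.any(self.ci_low > self.mean + 1e-12) or np.any(
            self.mean > self.ci_high + 1e-12
        ):
            raise ValueError("confidence band must bracket the mean")


@dataclass(frozen=True)
class AgreementReport:
    """Quantified agreement of a test curve with a reference curve.

    ``overlap`` flags, per count level, whether the two confidence bands
    intersect; ``max_ci_distance`` is the largest gap between the bands in
    units of their mean half-width (0 when every pair of bands touches).
    """

    metric: str
    levels: np.ndarray
    overlap: np.ndarray
    overlap_fraction: float
    mean_abs_diff: float
    max_ci_distance: float


def _percentile_band(samples: np.ndarray) -> tuple[float, float, float]:
    return (
        float(samples.mean()),
        float(np.percentile(samples, 2.5)),
        float(np.percentile(samples, 97.5)),
    )


def _pair_metrics(
    a: CountImage, b: CountImage, metrics: Sequence[str], params: SsimParams
) -> dict[str, float]:
    an, bn = normalize_max(a), normalize_max(b)
    out = {}
    for m in metrics:
        if m == "ssim":
            out[m] = ssim(an, bn, params)
        elif m == "log_mse":
            out[m] = log_mse(an, bn)
        else:
            raise ValueError(f"unknown metric {m!r}")
    return out


def _build_curves(
    sample_fn,
    levels: Sequence[int],
    n_perm: int,
    metrics: Sequence[str],
    frame_total: float,
) -> dict[str, SimilarityCurve]:
    levels = sorted(int(k) for k in levels)
    acc: dict[str, list[tuple[float, float, float]]] = {m: [] for m in metrics}
    for k in levels:
        samples = {m: np.empty(n_perm) for m in metrics}
        for i in range(n_perm):
            vals = sample_fn(k)
            for m in metrics:
                samples[m][i] = vals[m]
        for m in metrics:
            acc[m].append(_percentile_band(samples[m]))
    kcnts = np.asarray(levels, dtype=float) * frame_total / 1000.0
    return {
        m: SimilarityCurve(
            metric=m,
            levels=np.asarray(levels, dtype=float),
            nominal_kcnts=kcnts,
            mean=np.array([t[0] for t in acc[m]]),
            ci_low=np.array([t[1] for t in acc[m]]),
            ci_high=np.array([t[2] for t in acc[m]]),
            n_perm=n_perm,
        )
        for m in metrics
    }


def _check_levels(levels: Sequence[int], max_level: int, what: str) -> None:
    for k in levels:
        if k < 1 or k > max_level:
            raise ValueError(f"count level {k} frames too large for {what}")


def reference_curve(
    series: DynamicSeries,
    levels: Sequence[int] = DEFAULT_LEVELS,
    n_perm: int = 1000,
    metrics: Sequence[str] = METRICS,
    rng: np.random.Generator | None = None,
    ssim_params: SsimParams | None = None,
    frame_total: float = 11_000.0,
) -> dict[str, SimilarityCurve]:
    """Similarity of two independent native images vs count level.

    Per permutation and level ``k``: draw two disjoint ``k``-frame subsets,
    sum each into an image, max-normalize, and score.  The resulting curves
    are the benchmark every resizing method is judged against.
    """
    rng = rng if rng is not None else np.random.default_rng()
    params = ssim_params or SsimParams()
    _check_levels(levels, series.n_frames // 2, "disjoint pairs from this series")

    def one(k: int) -> dict[str, float]:
        ia, ib = draw_frame_pair(series.n_frames, k, rng)
        return _pair_metrics(
            sum_frames(series, ia), sum_frames(series, ib), metrics, params
        )

    return _build_curves(one, levels, n_perm, metrics, frame_total)


def lowcount_curve(
    series: DynamicSeries,
    levels: Sequence[int] = DEFAULT_LEVELS,
    n_perm: int = 1000,
    metrics: Sequence[str] = METRICS,
    rng: np.random.Generator | None = None,
    ssim_params: SsimParams | None = None,
    frame_total: float = 11_000.0,
    full_frames: int = FULL_COUNT_FRAMES,
) -> dict[str, SimilarityCurve]:
    """Similarity of two synthesized low-count images vs count level.

    Per permutation: build two disjoint full-count images (``full_frames``
    frames each), thin each with ``p = level / full_frames`` (binomial
    thinning per pixel), then score.  If thinning faithfully emulates
    low-count acquisition, these curves overlap the reference curves.
    """
    from .resize import thin_poisson

    rng = rng if rng is not None else np.random.default_rng()
    params = ssim_params or SsimParams()
    if 2 * full_frames > series.n_frames:
        raise ValueError("series too short for two disjoint full-count images")
    _check_levels(levels, full_frames, "thinning from the full-count image")

    def one(k: int) -> dict[str, float]:
        ia, ib = draw_frame_pair(series.n_frames, full_frames, rng)
        p = k / full_frames
        a = thin_poisson(sum_frames(series, ia), p, rng)
        b = thin_poisson(sum_frames(series, ib), p, rng)
        return _pair_metrics(a, b, metrics, params)

    return _build_curves(one, levels, n_perm, metrics, frame_total)


def _grid_factor(src_shape: tuple[int, int], tgt_shape: tuple[int, int], up: bool) -> int:
    a, b = (tgt_shape, src_shape) if up else (src_shape, tgt_shape)
    if a[0] % b[0] or a[1] % b[1] or a[0] // b[0] != a[1] // b[1]:
        raise ValueError(f"grid mismatch: {src_shape} vs {tgt_shape}")
    f = a[0] // b[0]
    if f < 2:
        raise ValueError(f"grids must differ by an integer factor >= 2, got {f}")
    return f


def resize_once_up(
    src: CountImage, f: int, method: str, rng: np.random.Generator
):
    """One upsampling step by ``method`` ('naive' or 'corrected')."""
    if method == "naive":
        return apply_global_scale(upsample_linear(src, f), 1.0 / f**2)
    if method == "corrected":
        return upsample_corrected(src, f, rng)
    raise ValueError(f"unknown upsampling method {method!r}")


def resize_once_down(src: CountImage, f: int, method: str):
    """One downsampling step by ``method`` ('linear' or 'window_sum')."""
    if method == "linear":
        return downsample_linear(src, f, rescale=True)
    if method == "window_sum":
        return downsample_window_sum(src, f)
    raise ValueError(f"unknown downsampling method {method!r}")


def upsampling_experiment(
    src_series: DynamicSeries,
    tgt_series: DynamicSeries,
    method: str,
    levels: Sequence[int] = DEFAULT_LEVELS,
    n_perm: int = 1000,
    metrics: Sequence[str] = METRICS,
    rng: np.random.Generator | None = None,
    ssim_params: SsimParams | None = None,
    frame_total: float = 11_000.0,
) -> dict[str, SimilarityCurve]:
    """Similarity of upsampled images to native images at the finer grid.

    Per permutation and level ``k``: sum ``k`` random frames at the coarse
    source grid, upsample by ``method`` ('naive' = linear interpolation +
    global 1/f**2 scaling; 'corrected' = interpolation + rounding + binomial
    thinning), and score against an independently summed ``k``-frame native
    image at the target grid.
    """
    rng = rng if rng is not None else np.random.default_rng()
    params = ssim_params or SsimParams()
    f = _grid_factor(src_series.frame_shape, tgt_series.frame_shape, up=True)
    _check_levels(levels, min(src_series.n_frames, tgt_series.n_frames), "series")

    def one(k: int) -> dict[str, float]:
        si = rng.permutation(src_series.n_frames)[:k]
        ti = rng.permutation(tgt_series.n_frames)[:k]
        resized = resize_once_up(sum_frames(src_series, si), f, method, rng)
        native = sum_frames(tgt_series, ti)
        return _pair_metrics(resized, native, metrics, params)

    return _build_curves(one, levels, n_perm, metrics, frame_total)


def downsampling_experiment(
    src_series: DynamicSeries,
    tgt_series: DynamicSeries,
    method: str,
    levels: Sequence[int] = DEFAULT_LEVELS,
    n_perm: int = 1000,
    metrics: Sequence[str] = METRICS,
    rng: np.random.Generator | None = None,
    ssim_params: SsimParams | None = None,
    frame_total: float = 11_000.0,
) -> dict[str, SimilarityCurve]:
    """Similarity of downsampled images to native images at the coarser grid.

    Per permutation and level ``k``: sum ``k`` random frames at the fine
    source grid, downsample by ``method`` ('linear' = bilinear + f**2
    rescale; 'window_sum' = f x f block summation), and score against an
    independently summed native image at the coarse target grid.
    """
    rng = rng if rng is not None else np.random.default_rng()
    params = ssim_params or SsimParams()
    f = _grid_factor(src_series.frame_shape, tgt_series.frame_shape, up=False)
    _check_levels(levels, min(src_series.n_frames, tgt_series.n_frames), "series")

    def one(k: int) -> dict[str, float]:
        si = rng.permutation(src_series.n_frames)[:k]
        ti = rng.permutation(tgt_series.n_frames)[:k]
        resized = resize_once_down(sum_frames(src_series, si), f, method)
        native = sum_frames(tgt_series, ti)
        return _pair_metrics(resized, native, metrics, params)

    return _build_curves(one, levels, n_perm, metrics, frame_total)


def curve_agreement(
    test: SimilarityCurve, reference: SimilarityCurve
) -> AgreementReport:
    """Per-level CI-intersection test of a curve against a reference.

    Two bands "overlap" at a level when the closed intervals intersect.
    ``max_ci_distance`` normalizes the largest gap by the mean half-width of
    the two bands at that level, so 0 means every pair of bands touches and
    1 means some gap is as wide as a typical half-band.
    """
    if test.metric != reference.metric:
        raise ValueError(f"metric mismatch: {test.metric} vs {reference.metric}")
    if test.levels.size != reference.levels.size or not np.allclose(
        test.levels, reference.levels
    ):
        raise ValueError("curves must share count levels")
    overlap = (test.ci_low <= reference.ci_high) & (reference.ci_low <= test.ci_high)
    gap = np.maximum(
        0.0,
        np.maximum(test.ci_low - reference.ci_high, reference.ci_low - test.ci_high),
    )
    half_width = ((test.ci_high - test.ci_low) + (reference.ci_high - reference.ci_low)) / 4.0
    with np.errstate(divide="ignore", invalid="ignore"):
        dist = np.where(gap > 0, gap / np.where(half_width > 0, half_width, np.nan), 0.0)
    dist = np.nan_to_num(dist, nan=np.inf)
    return AgreementReport(
        metric=test.metric,
        levels=test.levels.copy(),
        overlap=overlap,
        overlap_fraction=float(overlap.mean()) if overlap.size else 1.0,
        mean_abs_diff=float(np.abs(test.mean - reference.mean).mean())
        if overlap.size
        else 0.0,
        max_ci_distance=float(dist.max()) if overlap.size else 0.0,
    )


def plot_curves(curves: dict[str, dict[str, SimilarityCurve]], path) -> None:
    """Write a quick-look figure: one panel per metric, one band per curve set.

    ``curves`` maps a label (e.g. 'reference', 'corrected') to a per-metric
    curve dict as returned by the experiment functions.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    metrics = sorted({m for d in curves.values() for m in d})
    fig, axes = plt.subplots(1, len(metrics), figsize=(5 * len(metrics), 4))
    axes = np.atleast_1d(axes)
    for ax, m in zip(axes, metrics):
        for label, d in curves.items():
            if m not in d:
                continue
            c = d[m]
            ax.plot(c.nominal_kcnts, c.mean, marker="o", label=label)
            ax.fill_between(c.nominal_kcnts, c.ci_low, c.ci_high, alpha=0.25)
        ax.set_xlabel("count level (kcnts)")
        ax.set_ylabel(m)
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
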