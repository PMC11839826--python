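"""Count- and noise-preserving resizing operators for count images.

Because a scintigraphic pixel records a Poisson-distributed number of events,
resizing must preserve two things at once: the total number of counts and the
Poisson character of the per-pixel noise.  Plain linear interpolation does
neither — upsampling by a factor ``f`` multiplies the total by ``f**2`` while
reusing each source count in many smoothed output pixels.

The operators here implement both the naive comparators and the corrected
recipes:

* :func:`thin_poisson` — binomial thinning: each pixel ``n`` is replaced by a
  ``Binomial(n, p)`` draw.  Thinning a Poisson variate yields a Poisson
  variate with mean scaled by ``p``, so this is the statistically faithful
  way to reduce counts.
* :func:`upsample_linear` / :func:`apply_global_scale` — naive upsampling and
  the global count correction.
* :func:`upsample_corrected` — linear interpolation, rounding, then binomial
  thinning with ``p = 1/f**2``; the thinning both restores the total count in
  expectation and injects the counting noise a native acquisition would have.
* :func:`downsample_linear` — naive bilinear downsampling (optionally
  rescaled by ``f**2``); for ``f > 2`` its kernel sees only the central 2x2
  neighbourhood of each block, which is exactly its failure mode.
* :func:`downsample_window_sum` — non-overlapping ``f x f`` block summation,
  mimicking acquisition with ``f``-times larger pixels; conserves counts
  exactly and preserves Poisson noise by construction.

Interpolation convention
------------------------
All linear resampling uses half-pixel-centre alignment with replicate
padding: output pixel ``j`` samples source coordinate
``(j + 0.5) * (n_src / n_dst) - 0.5``, clamped to the source extent.  Under
this convention a factor-``f`` upsample scales the total by exactly ``f**2``
(each source pixel receives total interpolation weight ``f`` per axis) and a
factor-2 downsample is exactly the 2x2 block mean.
"""

from __future__ import annotations

import numpy as np

from .images import CountImage, RealImage, ResizeFactor, as_factor

__all__ = [
    "thin_poisson",
    "upsample_linear",
    "apply_global_scale",
    "upsample_corrected",
    "downsample_linear",
    "downsample_window_sum",
]


def _linear_weight_matrix(n_src: int, n_dst: int) -> np.ndarray:
    """1-D linear resampling operator W (n_dst x n_src), half-pixel centres.

    Row ``j`` holds the interpolation weights of output sample ``j``; rows sum
    to 1.  Source coordinates outside the grid are clamped (replicate
    padding).  For power-of-two ratios every weight is an exact binary
    fraction, so the worked-example count arithmetic is exact in floats.
    """
    if n_src < 1 or n_dst < 1:
        raise ValueError("grid sizes must be positive")
    src = (np.arange(n_dst) + 0.5) * (n_src / n_dst) - 0.5
    src = np.clip(src, 0.0, n_src - 1.0)
    W = np.zeros((n_dst, n_src))
    if n_src == 1:
        W[:, 0] = 1.0
        return W
    i0 = np.minimum(np.floor(src).astype(np.intp), n_src - 2)
    w = src - i0
    rows = np.arange(n_dst)
    W[rows, i0] = 1.0 - w
    W[rows, i0 + 1] += w
    return W


def _resample_linear(values: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    Wr = _linear_weight_matrix(values.shape[0], out_shape[0])
    Wc = _linear_weight_matrix(values.shape[1], out_shape[1])
    return Wr @ values.astype(np.float64) @ Wc.T


def thin_poisson(
    img: CountImage, p: float, rng: np.random.Generator
) -> CountImage:
    """Binomial thinning: replace each pixel ``n`` by a ``Binomial(n, p)`` draw.

    Emulates a lower-count acquisition of the same scene: if the input pixels
    are Poisson with mean ``m``, the output pixels are Poisson with mean
    ``p*m``.  The output never exceeds the input elementwise and the expected
    total is ``p`` times the input total.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"thinning probability must be in [0, 1], got {p}")
    out = rng.binomial(img.pixels, p)
    return CountImage(out, img.pixel_spacing_mm, img.view_label)


def upsample_linear(img: "CountImage | RealImage", f: "int | ResizeFactor") -> RealImage:
    """Separable linear interpolation onto an ``(f*M) x (f*N)`` grid.

    Mean pixel value is preserved exactly, so the total is multiplied by
    exactly ``f**2``; pixel spacing is divided by ``f``.  This is the naive
    comparator: it inflates the total counts and smooths away the per-pixel
    Poisson noise.
    """
    fac = as_factor(f)
    values = img.pixels if isinstance(img, CountImage) else img.values
    out = _resample_linear(values, (values.shape[0] * fac.f, values.shape[1] * fac.f))
    return RealImage(out, img.pixel_spacing_mm / fac.f, img.view_label)


def apply_global_scale(img: RealImage, s: float) -> RealImage:
    """Multiply every value by ``s`` (the global count-scaling correction).

    After a factor-``f`` upsample, ``s = 1/f**2`` (e.g. ``(64/256)**2 = 1/16``
    for 64 -> 256) restores the original total.  Scaling corrects the counts
    but not the noise: the result is a smooth real-valued image, not one a
    camera could have produced.
    """
    if not s > 0:
        raise ValueError(f"scale factor must be positive, got {s}")
    return RealImage(img.values * s, img.pixel_spacing_mm, img.view_label)


def upsample_corrected(
    img: CountImage, f: "int | ResizeFactor", rng: np.random.Generator
) -> CountImage:
    """Count- and noise-preserving upsampling.

    Pipeline: linear interpolation to the target grid, rounding half-up to
    integers, then binomial thinning with ``p = 1/f**2``.  The thinning plays
    both roles of the global scaling correction and of noise injection: the
    expected total returns to (approximately) the source total, and each
    output pixel carries binomial noise with variance ``(1-p)`` times its
    mean — effectively Poisson for large ``f``.
    """
    fac = as_factor(f)
    up = upsample_linear(img, fac)
    rounded = np.floor(up.values + 0.5).astype(np.int64)  # round half up
    return thin_poisson(
        CountImage(rounded, up.pixel_spacing_mm, img.view_label),
        fac.thin_probability,
        rng,
    )


def downsample_linear(
    img: "CountImage | RealImage", f: "int | ResizeFactor", rescale: bool = False
) -> RealImage:
    """Naive bilinear downsampling by an integer factor ``f``.

    Samples the source at the target pixel centres under the half-pixel
    convention.  For ``f = 2`` each output pixel is exactly the mean of its
    2x2 block; for larger factors the bilinear kernel uses only the central
    2x2 neighbourhood of the mapped point and ignores the rest of the block.
    With ``rescale`` the result is multiplied by ``f**2`` to restore the
    nominal count scale (exactly equivalent to block summation when
    ``f = 2``, but not beyond).
    """
    fac = as_factor(f)
    values = img.pixels if isinstance(img, CountImage) else img.values
    M, N = values.shape
    if M % fac.f or N % fac.f:
        raise ValueError(
            f"image shape {values.shape} not divisible by factor {fac.f}"
        )
    out = _resample_linear(values, (M // fac.f, N // fac.f))
    if rescale:
        out = out * fac.area_ratio
    return RealImage(out, img.pixel_spacing_mm * fac.f, img.view_label)


def downsample_window_sum(img: CountImage, f: "int | ResizeFactor") -> CountImage:
    """Downsample by summing non-overlapping ``f x f`` pixel blocks.

    This mimics how a gamma camera would have binned the same detection
    events into ``f``-times larger pixels: total counts are conserved exactly
    and the output pixels remain Poisson distributed.
    """
    fac = as_factor(f)
    M, N = img.shape
    if M % fac.f or N % fac.f:
        raise ValueError(f"image shape {img.shape} not divisible by factor {fac.f}")
    blocks = img.pixels.reshape(M // fac.f, fac.f, N // fac.f, fac.f)
    out = blocks.sum(axis=(1, 3))
    return CountImage(out, img.pixel_spacing_mm * fac.f, img.view_label)
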