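"""Image similarity metrics: global SSIM and Log MSE on max-normalized images.

Two images of the same object acquired with the same protocol are never
identical — each carries its own realization of Poisson noise — so similarity
is always assessed between *pairs* of images.  Both metrics operate on images
normalized to [0, 1] by their own maximum pixel.

The SSIM here is the *global* single-window form: means, variances and the
covariance are computed once over the whole image,

    SSIM(x, y) = (2 mu_x mu_y + c1)(2 s_xy + c2)
                 / ((mu_x^2 + mu_y^2 + c1)(s_x^2 + s_y^2 + c2)),

with stabilizing constants c1 = k1*L and c2 = k2*L by default (k1 = 0.01,
k2 = 0.03, L the dynamic range, 1 after normalization).  The conventional
squared constants c1 = (k1*L)^2, c2 = (k2*L)^2 are available through
``constant_mode="squared"``.  Variances use the population convention
(divide by M*N).  A sliding-window Gaussian-weighted variant is exposed via
``windowed_ssim`` for sensitivity analysis only.

Log MSE is the base-10 logarithm of the pixelwise mean squared error; it is
undefined (raises) for identical images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .images import CountImage, RealImage

__all__ = [
    "SsimParams",
    "SimilarityResult",
    "normalize_max",
    "ssim",
    "mse",
    "log_mse",
    "compare",
]


@dataclass(frozen=True)
class SsimParams:
    """Stabilizing constants for SSIM.

    ``constant_mode="linear"`` gives c1 = k1*L, c2 = k2*L;
    ``"squared"`` gives the conventional c1 = (k1*L)**2, c2 = (k2*L)**2.
    """

    L: float = 1.0
    k1: float = 0.01
    k2: float = 0.03
    constant_mode: str = "linear"

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError("dynamic range L must be positive")
        if self.constant_mode not in ("linear", "squared"):
            raise ValueError(f"unknown constant_mode {self.constant_mode!r}")
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("SSIM constants must be positive")

    @property
    def c1(self) -> float:
        x = self.k1 * self.L
        return x * x if self.constant_mode == "squared" else x

    @property
    def c2(self) -> float:
        x = self.k2 * self.L
        return x * x if self.constant_mode == "squared" else x


@dataclass(frozen=True)
class SimilarityResult:
    ssim: float
    mse: float
    log_mse: float


def _values(img) -> np.ndarray:
    if isinstance(img, CountImage):
        return img.pixels.astype(np.float64)
    if isinstance(img, RealImage):
        return img.values
    return np.asarray(img, dtype=np.float64)


def normalize_max(img) -> RealImage:
    """Normalize an image to [0, 1] by dividing by its maximum pixel.

    Normalization is per image: each member of a pair is divided by its *own*
    maximum.  An all-zero image has no defined normalization and raises.
    """
    v = _values(img)
    m = v.max() if v.size else 0.0
    if m <= 0:
        raise ValueError("cannot max-normalize an image with no positive pixel")
    spacing = getattr(img, "pixel_spacing_mm", 1.0)
    view = getattr(img, "view_label", None)
    return RealImage(v / m, spacing, view)


def _check_shapes(x: np.ndarray, y: np.ndarray) -> None:
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")


def ssim(x, y, params: SsimParams | None = None) -> float:
    """Global (single-window) structural similarity of two images.

    Means, variances (population convention) and covariance are taken over
    the whole image.  The result lies in [-1, 1], equals 1 only for identical
    images, and is symmetric in its arguments.
    """
    params = params or SsimParams()
    xv, yv = _values(x), _values(y)
    _check_shapes(xv, yv)
    mu_x, mu_y = xv.mean(), yv.mean()
    var_x = xv.var()
    var_y = yv.var()
    cov = ((xv - mu_x) * (yv - mu_y)).mean()
    c1, c2 = params.c1, params.c2
    return float(
        (2 * mu_x * mu_y + c1)
        * (2 * cov + c2)
        / ((mu_x**2 + mu_y**2 + c1) * (var_x + var_y + c2))
    )


def windowed_ssim(x, y, params: SsimParams | None = None, win_size: int = 11) -> float:
    """Mean local SSIM with a Gaussian-weighted sliding window.

    Sensitivity-analysis variant only; all experiment curves use the global
    :func:`ssim`.  Requires scikit-image.
    """
    from skimage.metrics import structural_similarity

    params = params or SsimParams(constant_mode="squared")
    xv, yv = _values(x), _values(y)
    _check_shapes(xv, yv)
    if params.constant_mode != "squared":
        raise ValueError("windowed SSIM supports only the squared constant mode")
    return float(
        structural_similarity(
            xv,
            yv,
            win_size=win_size,
            gaussian_weights=True,
            data_range=params.L,
            K1=params.k1,
            K2=params.k2,
        )
    )


def mse(x, y) -> float:
    """Mean squared error: ``(1/MN) * sum((X - Y)**2)``."""
    xv, yv = _values(x), _values(y)
    _check_shapes(xv, yv)
    d = xv - yv
    return float((d * d).mean())


def log_mse(x, y) -> float:
    """Base-10 logarithm of the MSE; undefined (raises) when MSE is zero."""
    m = mse(x, y)
    if m <= 0:
        raise ValueError("log MSE undefined: images are identical (MSE = 0)")
    return float(np.log10(m))


def compare(x, y, params: SsimParams | None = None) -> SimilarityResult:
    """SSIM, MSE and Log MSE of a pair of (already normalized) images."""
    return SimilarityResult(ssim(x, y, params), mse(x, y), log_mse(x, y))
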