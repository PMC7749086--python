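"""Patch-level descriptors: region covariance, color histograms, and the
covariance-kernel descriptor (CKD).

A CKD fuses two complementary views of an H&E-stained image patch into a
single symmetric positive-definite (SPD) matrix:

* a 5x5 region covariance block ``C_z`` over per-pixel features
  ``[R, G, B, Gx, Gy]`` (normalized color + first-order luminance
  gradients), capturing local texture and shape;
* a 3x3 kernel block ``K_z`` of similarities between the per-channel
  color histograms, capturing global color correlations induced by the
  staining.

Both blocks are positive semidefinite; a small diagonal perturbation
``eps`` makes the 8x8 block-diagonal assembly strictly positive definite,
which is what permits SPD-manifold geometry downstream (see
:mod:`waidkit.spd`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import block_diag
from scipy.ndimage import correlate
from sklearn.metrics.pairwise import (
    chi2_kernel,
    linear_kernel,
    polynomial_kernel,
    rbf_kernel,
)

__all__ = [
    "PixelFeatureStack",
    "RegionCovariance",
    "ChannelHistograms",
    "HistogramKernel",
    "CKD",
    "extract_pixel_features",
    "compute_rcd",
    "compute_channel_histograms",
    "concat_nch",
    "compute_histogram_kernel",
    "assemble_ckd",
    "ckd_from_patch",
]

#: Luminance weights (ITU-R BT.601) used before gradient extraction.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

#: 3x3 Sobel stencils, applied by correlation with replicate padding.
SOBEL_X = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])
SOBEL_Y = SOBEL_X.T

HISTOGRAM_KERNELS = ("linear", "chi2", "rbf", "polynomial")


@dataclass(frozen=True)
class PixelFeatureStack:
    """Per-pixel 5-vectors for one patch: rows are pixels, columns are
    ``[R, G, B, Gx, Gy]`` with color in [0, 1]."""

    values: np.ndarray
    patch_shape: tuple[int, int]

    @property
    def n_pixels(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class RegionCovariance:
    """5x5 sample covariance of a :class:`PixelFeatureStack` (PSD)."""

    matrix: np.ndarray
    n_pixels: int


@dataclass(frozen=True)
class ChannelHistograms:
    """Per-channel color histograms, rows R/G/B, each normalized to sum 1."""

    H: np.ndarray
    b: int


@dataclass(frozen=True)
class HistogramKernel:
    """3x3 kernel matrix between the channel histograms."""

    K: np.ndarray
    kernel_name: str


@dataclass(frozen=True)
class CKD:
    """Covariance-kernel descriptor: ``blockdiag(C + eps*I5, K + eps*I3)``,
    an 8x8 SPD matrix."""

    matrix: np.ndarray
    eps: float
    block_dims: tuple[int, int] = (5, 3)

    @property
    def dim(self) -> int:
        return self.matrix.shape[0]


def _as_rgb_patch(patch: np.ndarray) -> np.ndarray:
    patch = np.asarray(patch)
    if patch.ndim != 3 or patch.shape[2] != 3:
        raise ValueError(
            f"expected an h x w x 3 RGB patch, got array of shape {patch.shape}"
        )
    return patch


def extract_pixel_features(patch: np.ndarray) -> PixelFeatureStack:
    """Compute the per-pixel feature stack ``f_i = [R, G, B, Gx, Gy]``.

    Color channels are 8-bit intensities divided by 255. Gradients are
    Sobel responses of the normalized luminance (replicate padding), so
    their magnitudes are O(1) and commensurate with the color columns.

    Parameters
    ----------
    patch : ndarray, shape (h, w, 3)
        8-bit RGB patch with h, w >= 3 (the Sobel stencil support).
    """
    patch = _as_rgb_patch(patch)
    h, w = patch.shape[:2]
    if h < 3 or w < 3:
        raise ValueError(f"patch {h}x{w} is smaller than the 3x3 gradient support")
    rgb = patch.astype(np.float64) / 255.0
    luma = rgb @ LUMA_WEIGHTS
    gx = correlate(luma, SOBEL_X, mode="nearest")
    gy = correlate(luma, SOBEL_Y, mode="nearest")
    values = np.column_stack(
        [rgb[..., 0].ravel(), rgb[..., 1].ravel(), rgb[..., 2].ravel(),
         gx.ravel(), gy.ravel()]
    )
    return PixelFeatureStack(values=values, patch_shape=(h, w))


def compute_rcd(stack: PixelFeatureStack) -> RegionCovariance:
    """Region covariance ``C_z = 1/(N-1) sum_i (f_i - mu)(f_i - mu)^T``."""
    values = stack.values
    n = values.shape[0]
    if n < 2:
        raise ValueError(f"covariance needs at least 2 pixels, got {n}")
    centered = values - values.mean(axis=0)
    cov = centered.T @ centered / (n - 1)
    cov = (cov + cov.T) / 2.0
    return RegionCovariance(matrix=cov, n_pixels=n)


def compute_channel_histograms(patch: np.ndarray, bins: int = 256) -> ChannelHistograms:
    """Normalized per-channel count histograms over equal-width bins on [0, 255].

    At the default ``bins=256`` each 8-bit intensity value maps to its own
    bin. Every row sums to 1.
    """
    patch = _as_rgb_patch(patch)
    if patch.size == 0:
        raise ValueError("empty patch")
    if bins < 2:
        raise ValueError(f"bins must be >= 2, got {bins}")
    n = patch.shape[0] * patch.shape[1]
    H = np.empty((3, bins))
    for c in range(3):
        counts, _ = np.histogram(patch[..., c].astype(np.float64), bins=bins,
                                 range=(0.0, 255.0))
        H[c] = counts / n
    return ChannelHistograms(H=H, b=bins)


def concat_nch(hist: ChannelHistograms) -> np.ndarray:
    """Normalized color histogram: row-major concatenation [R, G, B].

    Length ``3*b`` (768 at the default 256 bins); sums to 3 because each
    channel row is itself normalized to 1.
    """
    return hist.H.ravel(order="C").copy()


_KERNEL_FUNCS = {
    "linear": lambda H, p: linear_kernel(H),
    "chi2": lambda H, p: chi2_kernel(H, **p),
    "rbf": lambda H, p: rbf_kernel(H, **({"gamma": 1.0} | p)),
    "polynomial": lambda H, p: polynomial_kernel(H, **p),
}


def compute_histogram_kernel(
    hist: ChannelHistograms,
    kernel_name: str = "linear",
    kernel_params: dict | None = None,
) -> HistogramKernel:
    """3x3 kernel matrix ``K[c1, c2] = k(h_c1, h_c2)`` between channel rows.

    The linear kernel (``K = H H^T``, the Gram matrix of the rows) is the
    default; chi2 / rbf / polynomial kernels generalize it while keeping K
    symmetric PSD.
    """
    if kernel_name not in HISTOGRAM_KERNELS:
        raise ValueError(
            f"unknown histogram kernel {kernel_name!r}; choose from {HISTOGRAM_KERNELS}"
        )
    K = _KERNEL_FUNCS[kernel_name](hist.H, dict(kernel_params or {}))
    K = (K + K.T) / 2.0
    return HistogramKernel(K=K, kernel_name=kernel_name)


def default_eps(C: RegionCovariance, eps_scale: float = 1e-6) -> float:
    """Trace-scaled diagonal perturbation: ``eps_scale * max(1, tr(C)/d)``.

    Scaling by the mean diagonal of the covariance keeps the perturbation
    above round-off for high-variance patches while staying negligible
    relative to the signal.
    """
    d = C.matrix.shape[0]
    return eps_scale * max(1.0, float(np.trace(C.matrix)) / d)


def assemble_ckd(C: RegionCovariance, K: HistogramKernel,
                 eps: float | None = None, eps_scale: float = 1e-6) -> CKD:
    """Assemble ``blockdiag(C + eps*I, K + eps*I)``; strictly SPD for eps > 0.

    When ``eps`` is None it is derived from the covariance trace via
    :func:`default_eps`.
    """
    if eps is None:
        eps = default_eps(C, eps_scale)
    if eps <= 0:
        raise ValueError(f"eps must be > 0, got {eps}")
    d1 = C.matrix.shape[0]
    d2 = K.K.shape[0]
    mat = block_diag(C.matrix + eps * np.eye(d1), K.K + eps * np.eye(d2))
    return CKD(matrix=mat, eps=float(eps), block_dims=(d1, d2))


def ckd_from_patch(patch: np.ndarray, config: "DescriptorConfig | None" = None) -> CKD:
    """Full patch -> CKD composition; deterministic for a fixed config."""
    from .config import DescriptorConfig

    cfg = config or DescriptorConfig()
    stack = extract_pixel_features(patch)
    C = compute_rcd(stack)
    hist = compute_channel_histograms(patch, bins=cfg.bins)
    K = compute_histogram_kernel(hist, cfg.kernel, cfg.kernel_params)
    return assemble_ckd(C, K, eps_scale=cfg.eps_scale)
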