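"""Gaussian map smoothing, with and without missing-value awareness."""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve

__all__ = ["gaussian_kernel", "gaussian_smooth", "nan_aware_smooth"]

# map padding names -> scipy.ndimage boundary modes
_PAD_MODES = {"zero": "constant", "reflect": "mirror", "symmetric": "reflect"}
# map padding names -> np.pad modes (note ndimage/np.pad naming differs)
_NP_PAD = {"zero": "constant", "reflect": "reflect", "symmetric": "symmetric"}


def _convolve(values: np.ndarray, kern: np.ndarray, padding: str) -> np.ndarray:
    """Same-shape convolution; FFT path once direct cost gets heavy."""
    if kern.shape[0] <= 31:
        return ndimage.convolve(values, kern, mode=_PAD_MODES[padding], cval=0.0)
    half = kern.shape[0] // 2
    padded = np.pad(values, half, mode=_NP_PAD[padding])
    return fftconvolve(padded, kern, mode="valid")


def gaussian_kernel(sigma_bins: float) -> np.ndarray:
    """Unit-sum square Gaussian kernel of side ``2*ceil(2*sigma) + 1`` bins.

    The side rule keeps the kernel an odd number of pixels and at least four
    standard deviations wide.
    """
    half = math.ceil(2.0 * sigma_bins)
    ax = np.arange(-half, half + 1, dtype=float)
    X, Y = np.meshgrid(ax, ax, indexing="ij")
    k = np.exp(-(X**2 + Y**2) / (2.0 * sigma_bins**2))
    return k / k.sum()


def gaussian_smooth(values: np.ndarray, sigma_bins: float, padding: str = "zero") -> np.ndarray:
    """Smooth a map with a unit-sum Gaussian kernel.

    ``sigma_bins`` is the kernel standard deviation in bin units; 0 is a
    no-op.  Default zero padding means the output total can only lose mass
    at the edges.
    """
    if sigma_bins < 0:
        raise ValueError("sigma must be >= 0")
    if sigma_bins == 0:
        return values.copy()
    return _convolve(values, gaussian_kernel(sigma_bins), padding)


def nan_aware_smooth(values: np.ndarray, sigma_bins: float, padding: str = "zero") -> np.ndarray:
    """Gaussian smoothing that ignores missing (NaN) bins.

    Each output pixel is the kernel-weighted average over its non-missing
    neighbours (weights renormalized per pixel); missing bins stay missing
    and are never propagated.  An all-missing map is returned unchanged.
    """
    if sigma_bins < 0:
        raise ValueError("sigma must be >= 0")
    mask = np.isnan(values)
    if sigma_bins == 0 or mask.all():
        return values.copy()
    kern = gaussian_kernel(sigma_bins)
    filled = np.where(mask, 0.0, values)
    num = _convolve(filled, kern, padding)
    den = _convolve((~mask).astype(float), kern, padding)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[mask] = np.nan
    return out
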