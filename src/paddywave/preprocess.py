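"""Spectral transforms: SG smoothing, first derivative, continuum removal, CWT.

The four representations used throughout the analysis:

* OR — the original reflectance after Savitzky–Golay smoothing,
* FD — first derivative of OR (reflectance·nm⁻¹),
* CR — continuum removal, R divided by its upper-convex-hull envelope,
* CWT — continuous wavelet transform of OR at dyadic scales 2¹..2¹⁰.

The CWT is the discretization of W_f(a,b) = ∫ f(λ) ψ_{a,b}(λ) dλ with
ψ_{a,b}(λ) = a^{-1/2} ψ((λ−b)/a) on the 1 nm grid, with symmetric (mirror)
boundary extension; at scale 2¹⁰ the wavelet support exceeds the full
spectral range, so boundary handling matters and is pinned down here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve, savgol_filter

from .spectra_io import Spectrum

DEFAULT_SCALES = tuple(float(2 ** k) for k in range(1, 11))


def sg_smooth(s: Spectrum, window: int = 11, polyorder: int = 3) -> Spectrum:
    """Savitzky–Golay least-squares local-polynomial smoothing (the OR step)."""
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if polyorder >= window:
        raise ValueError("polyorder must be < window")
    if window >= s.wavelengths.size:
        raise ValueError(f"window {window} >= spectrum length {s.wavelengths.size}")
    sm = savgol_filter(s.reflectance, window, polyorder, mode="interp")
    return Spectrum(s.plot_id, s.stage, s.wavelengths, sm)


def first_derivative(s: Spectrum) -> Spectrum:
    """First derivative dR/dλ: central differences interior, one-sided ends."""
    if s.wavelengths.size < 3:
        raise ValueError("need at least 3 points to differentiate")
    d = np.gradient(s.reflectance, s.wavelengths)
    return Spectrum(s.plot_id, s.stage, s.wavelengths, d)


@dataclass
class ContinuumResult:
    """Upper convex hull continuum and the continuum-removed spectrum."""

    hull_wavelengths: np.ndarray  # hull vertices, nm
    continuum: np.ndarray  # R_C0 on the full grid
    removed: np.ndarray  # S_cr = R / R_C0, in (0, 1]


def _upper_hull_indices(w: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Andrew monotone-chain upper hull over (λ, R); endpoints always kept."""
    hull: list[int] = []
    for i in range(w.size):
        while len(hull) >= 2:
            i1, i2 = hull[-2], hull[-1]
            # pop i2 if it lies below the chord i1 -> i
            cross = (w[i2] - w[i1]) * (r[i] - r[i1]) - (r[i2] - r[i1]) * (w[i] - w[i1])
            if cross >= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    return np.asarray(hull, dtype=int)


def continuum_remove(s: Spectrum) -> ContinuumResult:
    """Continuum removal S_cr = R / R_C0 with R_C0 the upper convex hull.

    The hull is piecewise linear between its vertices; S_cr is 1 exactly at
    every vertex (grid endpoints included) and in (0, 1] everywhere.
    """
    w, r = s.wavelengths, s.reflectance
    if np.any(r <= 0):
        raise ValueError("continuum removal needs strictly positive reflectance")
    idx = _upper_hull_indices(w, r)
    continuum = np.interp(w, w[idx], r[idx])
    removed = r / continuum
    removed[idx] = 1.0  # exact at vertices despite rounding
    return ContinuumResult(w[idx], continuum, removed)


@dataclass
class WaveletPlane:
    """scale × band matrix of CWT coefficients for one spectrum."""

    scales: np.ndarray
    bands: np.ndarray
    coefficients: np.ndarray  # (n_scales, n_bands)

    def __post_init__(self) -> None:
        self.scales = np.asarray(self.scales, dtype=float)
        self.bands = np.asarray(self.bands, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (self.scales.size, self.bands.size):
            raise ValueError("coefficient matrix shape does not match scales × bands")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("non-finite wavelet coefficients")


def mexican_hat(x: np.ndarray) -> np.ndarray:
    """L2-normalised Mexican hat (negative second derivative of a Gaussian)."""
    x = np.asarray(x, dtype=float)
    return (2.0 / (np.sqrt(3.0) * np.pi ** 0.25)) * (1.0 - x ** 2) * np.exp(-0.5 * x ** 2)


def _mirror_extend(y: np.ndarray, pad: int) -> np.ndarray:
    """Half-sample symmetric extension by ``pad`` samples on each side.

    Works for pads longer than the signal (needed at scale 2¹⁰), where a
    single reflect-pad call would run out of samples.
    """
    n = y.shape[-1]
    idx = np.arange(-pad, n + pad) % (2 * n)
    idx = np.where(idx < n, idx, 2 * n - 1 - idx)
    return y[..., idx]


def _cwt_matrix(matrix: np.ndarray, dlam: float, scales) -> np.ndarray:
    """CWT of each row of ``matrix``; returns (n_rows, n_scales, n_bands)."""
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    out = np.empty((matrix.shape[0], len(scales), matrix.shape[1]))
    for k, a in enumerate(scales):
        half = int(np.ceil(8.0 * a / dlam))  # ψ < 1e-12 beyond |x| = 8
        offs = np.arange(-half, half + 1) * dlam
        kernel = mexican_hat(offs / a) / np.sqrt(a) * dlam
        padded = _mirror_extend(matrix, half)
        out[:, k, :] = fftconvolve(padded, kernel[None, :], mode="valid", axes=1)
    return out


def cwt_transform(s: Spectrum, scales=DEFAULT_SCALES, wavelet: str = "mexican_hat") -> WaveletPlane:
    """Continuous wavelet transform on the spectrum's uniform grid.

    Discretizes the defining integral as Σ_λ f(λ)·a^{-1/2}·ψ((λ−b)/a)·Δλ for
    every band b on the grid, one row per scale (10 dyadic scales 2..1024 by
    default). The kernel is truncated where ψ is below 1e-12 of its peak, so
    the sum matches the untruncated one to near machine precision.
    """
    if wavelet != "mexican_hat":
        raise ValueError(f"unknown wavelet {wavelet!r}")
    scales = np.asarray(scales, dtype=float)
    if np.any(scales <= 0):
        raise ValueError("scales must be positive")
    steps = np.diff(s.wavelengths)
    if not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
        raise ValueError("CWT requires a uniform wavelength grid")
    coeff = _cwt_matrix(s.reflectance[None, :], float(steps[0]), scales)[0]
    return WaveletPlane(scales, s.wavelengths, coeff)


def cwt_transform_set(matrix: np.ndarray, wavelengths: np.ndarray, scales=DEFAULT_SCALES) -> np.ndarray:
    """Vectorised CWT of a (n_plots, n_bands) matrix → (n_plots, n_scales, n_bands)."""
    steps = np.diff(wavelengths)
    if not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
        raise ValueError("CWT requires a uniform wavelength grid")
    return _cwt_matrix(matrix, float(steps[0]), np.asarray(scales, dtype=float))
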