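"""Headless plot helpers: transformed-spectra panels, wavelet planes and
correlation heatmaps. Cosmetic only — nothing downstream depends on them."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .preprocess import WaveletPlane
from .screening import CorrelationMap
from .spectra_io import SpectraSet


def plot_spectra(sset: SpectraSet, path: str | Path, title: str = "") -> Path:
    fig, ax = plt.subplots(figsize=(8, 4))
    for s in sset.spectra:
        ax.plot(s.wavelengths, s.reflectance, lw=0.5, alpha=0.6)
    ax.set_xlabel("wavelength (nm)")
    ax.set_ylabel("reflectance")
    ax.set_title(title or f"{sset.stage} canopy spectra (n={len(sset)})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_wavelet_plane(plane: WaveletPlane, path: str | Path, title: str = "") -> Path:
    fig, ax = plt.subplots(figsize=(8, 4))
    im = ax.pcolormesh(plane.bands, np.arange(len(plane.scales)), plane.coefficients, shading="auto")
    ax.set_yticks(np.arange(len(plane.scales)), [f"{s:g}" for s in plane.scales])
    ax.set_xlabel("wavelength (nm)")
    ax.set_ylabel("scale")
    ax.set_title(title or "CWT coefficients")
    fig.colorbar(im, ax=ax, label="coefficient")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_correlation(cmap: CorrelationMap, path: str | Path, title: str = "") -> Path:
    fig, ax = plt.subplots(figsize=(8, 4))
    if cmap.is_wavelet:
        piv = cmap.table.pivot(index="scale", columns="wavelength_nm", values="r").abs()
        im = ax.pcolormesh(piv.columns, np.arange(len(piv.index)), piv.to_numpy(), shading="auto")
        ax.set_yticks(np.arange(len(piv.index)), [f"{s:g}" for s in piv.index])
        ax.set_ylabel("scale")
        fig.colorbar(im, ax=ax, label="|r|")
    else:
        ax.plot(cmap.table["wavelength_nm"], cmap.table["r"], lw=0.8)
        ax.axhline(0, color="k", lw=0.5)
        ax.set_ylabel("r")
    ax.set_xlabel("wavelength (nm)")
    ax.set_title(title or f"yield correlation (n={cmap.n})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
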