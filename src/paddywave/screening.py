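"""Yield-sensitivity screening: Pearson correlation of bands, wavelet cells
and named features against plot yield, plus greedy selection of the most
informative, mutually separated predictors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .spectra_io import SpectraSet, YieldTable

log = logging.getLogger(__name__)


@dataclass
class CorrelationMap:
    """Per-label Pearson r against yield.

    ``table`` has columns ``wavelength_nm`` and ``r`` (band maps) plus
    ``scale`` for wavelet maps; ``n`` is the joined sample count. r is NaN
    for zero-variance labels.
    """

    table: pd.DataFrame
    n: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("correlation needs at least 3 joined plots")
        r = self.table["r"].to_numpy()
        if np.any(np.abs(r[np.isfinite(r)]) > 1 + 1e-12):
            raise ValueError("|r| > 1")

    @property
    def is_wavelet(self) -> bool:
        return "scale" in self.table.columns

    def best(self) -> pd.Series:
        """Row with the largest |r| (ties: lowest wavelength, then scale)."""
        t = self.table.dropna(subset=["r"]).copy()
        t["abs_r"] = t["r"].abs()
        keys = ["abs_r"] + (["wavelength_nm", "scale"] if self.is_wavelet else ["wavelength_nm"])
        asc = [False] + [True] * (len(keys) - 1)
        return t.sort_values(keys, ascending=asc, kind="mergesort").iloc[0]


def _pearson_columns(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of each column of x against y; zero-variance → NaN."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc ** 2).sum(axis=0))
    sy = np.sqrt((yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc[:, None]).sum(axis=0) / (sx * sy)
    r[sx == 0] = np.nan
    if sy == 0:
        raise ValueError("yield has zero variance")
    return r


def _join(plot_ids: list[str], matrix: np.ndarray, y: YieldTable) -> tuple[np.ndarray, np.ndarray]:
    ys = y.as_series()
    keep = [i for i, p in enumerate(plot_ids) if p in ys.index]
    if len(keep) < 3:
        raise ValueError(f"only {len(keep)} plots join spectra with yields; need >= 3")
    if len(keep) < len(plot_ids):
        log.warning("dropping %d plot(s) without yields", len(plot_ids) - len(keep))
    return matrix[keep], ys.loc[[plot_ids[i] for i in keep]].to_numpy()


def band_yield_correlation(
    sset: SpectraSet | tuple[list[str], np.ndarray, np.ndarray], y: YieldTable
) -> CorrelationMap:
    """Pearson r per band between a spectra/FD matrix and yield.

    Accepts a SpectraSet or a ``(plot_ids, wavelengths, matrix)`` triple so
    transformed matrices screen the same way as raw sets.
    """
    if isinstance(sset, SpectraSet):
        plot_ids, wavelengths, matrix = sset.plot_ids, sset.wavelengths, sset.matrix()
    else:
        plot_ids, wavelengths, matrix = sset
    x, yy = _join(list(plot_ids), matrix, y)
    r = _pearson_columns(x, yy)
    if np.isnan(r).any():
        log.warning("%d zero-variance band(s) have missing r", int(np.isnan(r).sum()))
    return CorrelationMap(pd.DataFrame({"wavelength_nm": wavelengths, "r": r}), len(yy))


def wavelet_yield_correlation(
    plot_ids: list[str], scales: np.ndarray, wavelengths: np.ndarray, cwt: np.ndarray, y: YieldTable
) -> CorrelationMap:
    """Pearson r per (scale, band) cell of stacked wavelet planes vs yield."""
    n_plots, n_scales, n_bands = cwt.shape
    x, yy = _join(list(plot_ids), cwt.reshape(n_plots, -1), y)
    r = _pearson_columns(x, yy).reshape(n_scales, n_bands)
    ss, ww = np.meshgrid(scales, wavelengths, indexing="ij")
    return CorrelationMap(
        pd.DataFrame({"scale": ss.ravel(), "wavelength_nm": ww.ravel(), "r": r.ravel()}), len(yy)
    )


def critical_r(n: int, alpha: float = 0.05) -> float:
    """Two-tailed Pearson significance bound r* = t*/√(t*² + n − 2)."""
    if n < 3:
        raise ValueError("need n >= 3")
    t_star = stats.t.ppf(1.0 - alpha / 2.0, n - 2)
    return float(t_star / np.sqrt(t_star ** 2 + n - 2))


def select_sensitive(
    cmap: CorrelationMap, r_min: float, top_k: int = 5, min_separation_nm: float = 10.0
) -> list[float] | list[tuple[float, float]]:
    """Greedy pick of labels by decreasing |r| with neighbour suppression.

    Labels with |r| ≥ r_min are taken best-first; a candidate within
    ``min_separation_nm`` of an already-picked label (at the same scale, for
    wavelet maps) is suppressed. Ties break toward the lower wavelength then
    lower scale. Returns wavelengths, or (scale, wavelength) pairs.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    t = cmap.table.dropna(subset=["r"]).copy()
    t = t[t["r"].abs() >= r_min]
    t["abs_r"] = t["r"].abs()
    keys = ["abs_r", "wavelength_nm"] + (["scale"] if cmap.is_wavelet else [])
    t = t.sort_values(keys, ascending=[False] + [True] * (len(keys) - 1), kind="mergesort")
    picked: list = []
    for row in t.itertuples():
        if cmap.is_wavelet:
            clash = any(s == row.scale and abs(w - row.wavelength_nm) < min_separation_nm for s, w in picked)
            label = (row.scale, row.wavelength_nm)
        else:
            clash = any(abs(w - row.wavelength_nm) < min_separation_nm for w in picked)
            label = row.wavelength_nm
        if not clash:
            picked.append(label)
        if len(picked) >= top_k:
            break
    return picked
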