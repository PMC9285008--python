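"""Per-plot scalar features: vegetation indices, tri-edge parameters,
edge combinations, and selected derivative/wavelet band values.

Feature columns are stage-tagged (``heading_NDVI``, ``flowering_FD_686``,
``heading_CWT_s8_732`` — sN labels the dyadic scale 2^N) so tables from
different growth stages can be fused column-wise for modeling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import DEFAULT_SCALES, cwt_transform_set, first_derivative, sg_smooth
from .spectra_io import STAGES, SpectraSet, Spectrum

log = logging.getLogger(__name__)

VI_NAMES = ("NDVI", "DVI", "RVI", "EVI")

#: Tri-edge windows (nm): steep-change regions of a green-vegetation spectrum.
DEFAULT_EDGE_WINDOWS = {"red": (680.0, 760.0), "blue": (490.0, 530.0), "yellow": (560.0, 640.0)}


def vegetation_index(
    s: Spectrum, name: str, red_nm: float = 670.0, nir_nm: float = 800.0, rvi_inverted: bool = False
) -> float:
    """Single-band vegetation index from R = s(red_nm), NIR = s(nir_nm).

    NDVI = (NIR−R)/(NIR+R); DVI = NIR−R; RVI = R/NIR (as defined here; the
    conventional NIR/R via ``rvi_inverted``); EVI = 2.5(NIR−R)/(1+NIR+2.4R).
    A zero denominator yields NaN (logged), never an exception.
    """
    r = s.value_at(red_nm)
    nir = s.value_at(nir_nm)
    if name == "NDVI":
        den = nir + r
    elif name == "RVI":
        den = r if rvi_inverted else nir
    elif name == "EVI":
        den = 1.0 + nir + 2.4 * r
    elif name == "DVI":
        return nir - r
    else:
        raise ValueError(f"unknown vegetation index {name!r}")
    if den == 0.0:
        log.warning("plot %s: %s denominator is zero; value set missing", s.plot_id, name)
        return float("nan")
    if name == "NDVI":
        return (nir - r) / den
    if name == "RVI":
        return (nir / r) if rvi_inverted else (r / nir)
    return 2.5 * (nir - r) / den


@dataclass
class TriEdgeParams:
    """Position (λ, nm), slope (D, max first derivative) and area (SD,
    integral of the first derivative) of the red, blue and yellow edges."""

    lambda_r: float
    lambda_b: float
    lambda_y: float
    d_r: float
    d_b: float
    d_y: float
    sd_r: float
    sd_b: float
    sd_y: float

    def as_dict(self) -> dict[str, float]:
        return {
            "lambda_r": self.lambda_r, "lambda_b": self.lambda_b, "lambda_y": self.lambda_y,
            "Dr": self.d_r, "Db": self.d_b, "Dy": self.d_y,
            "SDr": self.sd_r, "SDb": self.sd_b, "SDy": self.sd_y,
        }


def _edge(fd: Spectrum, lo: float, hi: float) -> tuple[float, float, float]:
    mask = (fd.wavelengths >= lo) & (fd.wavelengths <= hi)
    if not mask.any():
        raise ValueError(f"edge window [{lo}, {hi}] nm not covered by the spectrum grid")
    w = fd.wavelengths[mask]
    v = fd.reflectance[mask]
    i = int(np.argmax(v))  # first max → smallest wavelength on ties
    return float(w[i]), float(v[i]), float(np.trapezoid(v, w))


def tri_edge(fd: Spectrum, windows: dict[str, tuple[float, float]] | None = None) -> TriEdgeParams:
    """Tri-edge parameters from a first-derivative spectrum.

    Per window: D = maximum FD value (even where FD is negative throughout,
    as on the blue/yellow edges of a green canopy), λ = its wavelength
    (smallest on ties), SD = trapezoidal integral of FD over the window.
    """
    win = windows or DEFAULT_EDGE_WINDOWS
    lr, dr, sdr = _edge(fd, *win["red"])
    lb, db, sdb = _edge(fd, *win["blue"])
    ly, dy, sdy = _edge(fd, *win["yellow"])
    return TriEdgeParams(lr, lb, ly, dr, db, dy, sdr, sdb, sdy)


def edge_combinations(p: TriEdgeParams) -> dict[str, float]:
    """The eight difference / ratio / normalized edge-area combinations."""

    def ratio(a: float, b: float) -> float:
        return a / b if b != 0 else float("nan")

    return {
        "SDr_minus_SDb": p.sd_r - p.sd_b,
        "SDr_minus_SDy": p.sd_r - p.sd_y,
        "SDb_minus_SDy": p.sd_b - p.sd_y,
        "SDr_over_SDb": ratio(p.sd_r, p.sd_b),
        "SDr_over_SDy": ratio(p.sd_r, p.sd_y),
        "SDb_over_SDy": ratio(p.sd_b, p.sd_y),
        "SDr_SDb_norm": ratio(p.sd_r - p.sd_b, p.sd_r + p.sd_b),
        "SDr_SDy_norm": ratio(p.sd_r - p.sd_y, p.sd_r + p.sd_y),
    }


@dataclass
class StageTransforms:
    """Cached per-stage transforms so repeated feature builds are cheap.

    smoothed/fd are (n_plots, n_bands); cwt is (n_plots, n_scales, n_bands)
    and is only computed when requested.
    """

    stage: str
    plot_ids: list[str]
    wavelengths: np.ndarray
    smoothed: np.ndarray
    fd: np.ndarray
    scales: np.ndarray = field(default_factory=lambda: np.asarray(DEFAULT_SCALES))
    cwt: np.ndarray | None = None

    @classmethod
    def from_spectraset(
        cls, sset: SpectraSet, window: int = 11, polyorder: int = 3,
        with_cwt: bool = False, scales=DEFAULT_SCALES,
    ) -> "StageTransforms":
        smoothed, fd = [], []
        for sp in sset.spectra:
            sm = sg_smooth(sp, window, polyorder)
            smoothed.append(sm.reflectance)
            fd.append(first_derivative(sm).reflectance)
        smoothed = np.vstack(smoothed)
        fd = np.vstack(fd)
        cwt = cwt_transform_set(smoothed, sset.wavelengths, scales) if with_cwt else None
        return cls(sset.stage, sset.plot_ids, sset.wavelengths, smoothed, fd,
                   np.asarray(scales, dtype=float), cwt)

    def _band_index(self, nm: float) -> int:
        i = int(np.searchsorted(self.wavelengths, nm))
        if i >= self.wavelengths.size or self.wavelengths[i] != nm:
            raise KeyError(f"wavelength {nm} nm not on grid")
        return i

    def _scale_index(self, scale: float) -> int:
        hits = np.where(self.scales == scale)[0]
        if not hits.size:
            raise KeyError(f"scale {scale} not among {list(self.scales)}")
        return int(hits[0])

    def spectrum(self, i: int, which: str = "smoothed") -> Spectrum:
        arr = self.smoothed if which == "smoothed" else self.fd
        return Spectrum(self.plot_ids[i], self.stage, self.wavelengths, arr[i])


def _scale_label(scale: float) -> str:
    lvl = np.log2(scale)
    return f"s{int(round(lvl))}" if abs(lvl - round(lvl)) < 1e-9 else f"s{scale:g}"


def stage_features(
    t: StageTransforms,
    groups: set[str],
    fd_bands: list[float] | None = None,
    cwt_cells: list[tuple[float, float]] | None = None,
    edge_windows: dict[str, tuple[float, float]] | None = None,
    rvi_inverted: bool = False,
) -> pd.DataFrame:
    """Feature columns for one stage; column names are stage-tagged."""
    unknown = groups - {"VI", "EDGE", "FD", "CWT"}
    if unknown:
        raise ValueError(f"unknown feature group(s) {sorted(unknown)}")
    cols: dict[str, np.ndarray] = {}
    n = len(t.plot_ids)
    if "VI" in groups:
        for name in VI_NAMES:
            cols[f"{t.stage}_{name}"] = np.array(
                [vegetation_index(t.spectrum(i), name, rvi_inverted=rvi_inverted) for i in range(n)]
            )
    if "EDGE" in groups:
        edges = [tri_edge(t.spectrum(i, "fd"), edge_windows) for i in range(n)]
        for key in edges[0].as_dict():
            cols[f"{t.stage}_{key}"] = np.array([e.as_dict()[key] for e in edges])
        for key in edge_combinations(edges[0]):
            cols[f"{t.stage}_{key}"] = np.array([edge_combinations(e)[key] for e in edges])
    if "FD" in groups:
        for nm in fd_bands or []:
            name = f"{t.stage}_FD_{nm:g}"
            if name in cols:
                log.warning("duplicate requested FD band %g nm at %s; keeping one column", nm, t.stage)
                continue
            cols[name] = t.fd[:, t._band_index(nm)]
    if "CWT" in groups:
        if cwt_cells and t.cwt is None:
            raise ValueError("CWT features requested but transforms were built with with_cwt=False")
        for scale, nm in cwt_cells or []:
            name = f"{t.stage}_CWT_{_scale_label(scale)}_{nm:g}"
            if name in cols:
                log.warning("duplicate requested CWT cell (%g, %g nm) at %s", scale, nm, t.stage)
                continue
            cols[name] = t.cwt[:, t._scale_index(scale), t._band_index(nm)]
    return pd.DataFrame(cols, index=pd.Index(t.plot_ids, name="plot_id"))


def build_feature_table(
    transforms: dict[str, StageTransforms],
    groups: set[str] = frozenset({"VI", "FD"}),
    fd_bands: dict[str, list[float]] | None = None,
    cwt_cells: dict[str, list[tuple[float, float]]] | None = None,
    edge_windows: dict[str, tuple[float, float]] | None = None,
    rvi_inverted: bool = False,
) -> pd.DataFrame:
    """Plots × stage-tagged features across the requested stages.

    Plots missing any requested stage are excluded (and logged) rather than
    imputed; feature extraction is pure, so identical inputs give identical
    tables.
    """
    groups = set(groups)
    parts = []
    for stage in STAGES:
        if stage not in transforms:
            continue
        parts.append(
            stage_features(
                transforms[stage], groups,
                (fd_bands or {}).get(stage), (cwt_cells or {}).get(stage),
                edge_windows, rvi_inverted,
            )
        )
    if not parts:
        raise ValueError("no stages supplied")
    table = pd.concat(parts, axis=1, join="inner")
    full = set().union(*(set(p.index) for p in parts))
    dropped = sorted(full - set(table.index))
    if dropped:
        log.warning("excluding %d plot(s) missing a stage: %s", len(dropped), dropped)
    return table
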