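"""Reading, writing and regridding of canopy reflectance spectra and plot yields.

All downstream math assumes the canonical 1 nm grid 350..2500 nm (2151 bands),
which is the full range of a field spectroradiometer covering the visible,
NIR and SWIR regions. Instrument grids (e.g. 1.3 nm below 1000 nm, 2 nm above)
are unified onto it by linear interpolation, never extrapolation.

Interchange formats are plain CSV (UTF-8, "." decimal) and JSON so that round
trips are bit-stable and diffable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

STAGES = ("elongation", "heading", "flowering", "milky")

#: Canonical wavelength grid: 350..2500 nm, 1 nm step, 2151 bands.
CANONICAL_GRID = np.arange(350.0, 2501.0, 1.0)


def asd_grid() -> np.ndarray:
    """Instrument-style grid: 1.3 nm sampling below 1000 nm, 2 nm above."""
    vis = np.arange(350.0, 1000.0, 1.3)
    swir = np.arange(1000.0, 2500.0 + 1e-9, 2.0)
    return np.concatenate([vis, swir])


def _check_wavelengths(w: np.ndarray, context: str = "") -> None:
    if w.ndim != 1 or w.size < 2:
        raise ValueError(f"{context}need at least two wavelengths")
    diffs = np.diff(w)
    bad = np.where(diffs <= 0)[0]
    if bad.size:
        i = int(bad[0])
        raise ValueError(
            f"{context}wavelengths not strictly increasing: "
            f"{w[i]:g} nm followed by {w[i + 1]:g} nm (position {i + 1})"
        )


@dataclass
class Spectrum:
    """One plot-stage reflectance curve.

    wavelengths are nm, strictly increasing; reflectance is unitless (or
    nm^-1 for derivative spectra) and finite, one value per wavelength.
    """

    plot_id: str
    stage: str
    wavelengths: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.wavelengths.shape != self.reflectance.shape:
            raise ValueError("wavelengths and reflectance lengths differ")
        _check_wavelengths(self.wavelengths, f"plot {self.plot_id}: ")
        if not np.all(np.isfinite(self.reflectance)):
            raise ValueError(f"plot {self.plot_id}: non-finite reflectance")

    def value_at(self, nm: float) -> float:
        """Reflectance at an exact grid wavelength (no interpolation)."""
        idx = np.searchsorted(self.wavelengths, nm)
        if idx >= self.wavelengths.size or self.wavelengths[idx] != nm:
            raise KeyError(f"wavelength {nm} nm not on grid of plot {self.plot_id}")
        return float(self.reflectance[idx])


@dataclass
class YieldTable:
    """Per-plot grain yield, g·m⁻², strictly positive, unique plot ids."""

    plot_ids: list[str]
    yields: np.ndarray

    def __post_init__(self) -> None:
        self.plot_ids = [str(p) for p in self.plot_ids]
        self.yields = np.asarray(self.yields, dtype=float)
        if len(self.plot_ids) != self.yields.size:
            raise ValueError("plot_ids and yields lengths differ")
        if len(set(self.plot_ids)) != len(self.plot_ids):
            dupes = sorted({p for p in self.plot_ids if self.plot_ids.count(p) > 1})
            raise ValueError(f"duplicate plot_id(s): {dupes}")
        if np.any(~np.isfinite(self.yields)) or np.any(self.yields <= 0):
            raise ValueError("yields must be finite and > 0 g·m⁻²")

    def __len__(self) -> int:
        return len(self.plot_ids)

    def as_series(self) -> pd.Series:
        return pd.Series(self.yields, index=pd.Index(self.plot_ids, name="plot_id"), name="yield_g_per_m2")


@dataclass
class SpectraSet:
    """Spectra for many plots at one growth stage on a shared grid."""

    stage: str
    spectra: list[Spectrum] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        ids = [s.plot_id for s in self.spectra]
        if len(set(ids)) != len(ids):
            dupes = sorted({p for p in ids if ids.count(p) > 1})
            raise ValueError(f"duplicate plot_id(s) in SpectraSet: {dupes}")
        for s in self.spectra:
            if s.stage != self.stage:
                raise ValueError(f"plot {s.plot_id} has stage {s.stage}, set is {self.stage}")
            if not np.array_equal(s.wavelengths, self.spectra[0].wavelengths):
                raise ValueError(f"plot {s.plot_id} is on a different wavelength grid")

    def __len__(self) -> int:
        return len(self.spectra)

    @property
    def plot_ids(self) -> list[str]:
        return [s.plot_id for s in self.spectra]

    @property
    def wavelengths(self) -> np.ndarray:
        if not self.spectra:
            raise ValueError("empty SpectraSet has no grid")
        return self.spectra[0].wavelengths

    def matrix(self) -> np.ndarray:
        """(n_plots, n_bands) reflectance matrix, plot order preserved."""
        return np.vstack([s.reflectance for s in self.spectra])

    @classmethod
    def from_matrix(cls, stage: str, plot_ids: Sequence[str], wavelengths: np.ndarray, matrix: np.ndarray) -> "SpectraSet":
        matrix = np.asarray(matrix, dtype=float)
        return cls(stage, [Spectrum(str(p), stage, wavelengths, matrix[i]) for i, p in enumerate(plot_ids)])


# ---------------------------------------------------------------------------
# readers / writers


def _read_numeric_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    out = {}
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise ValueError(f"{path}: non-numeric value {df[col][bad[0]]!r} in column {col!r}, row {bad[0] + 2}")
        out[col] = vals
    return pd.DataFrame(out)


def read_spectra(path: str | Path, dialect: str = "wide", stage: str | None = None) -> SpectraSet:
    """Read a SpectraSet from CSV.

    wide: first column ``wavelength_nm``, one column per plot_id (``stage``
    argument required). long: columns ``plot_id,stage,wavelength_nm,reflectance``
    holding a single stage.
    """
    path = Path(path)
    if dialect == "wide":
        if stage is None:
            raise ValueError("wide dialect carries no stage column; pass stage=")
        df = _read_numeric_csv(path)
        if df.columns[0] != "wavelength_nm":
            raise ValueError(f"{path}: first column must be 'wavelength_nm', got {df.columns[0]!r}")
        w = df["wavelength_nm"].to_numpy(float)
        _check_wavelengths(w, f"{path}: ")
        plots = [c for c in df.columns if c != "wavelength_nm"]
        if len(set(plots)) != len(plots):
            raise ValueError(f"{path}: duplicate plot_id column")
        return SpectraSet(stage, [Spectrum(p, stage, w, df[p].to_numpy(float)) for p in plots])
    if dialect == "long":
        raw = pd.read_csv(path, dtype={"plot_id": str, "stage": str})
        need = {"plot_id", "stage", "wavelength_nm", "reflectance"}
        if not need.issubset(raw.columns):
            raise ValueError(f"{path}: long dialect needs columns {sorted(need)}")
        stages = raw["stage"].unique()
        if len(stages) != 1:
            raise ValueError(f"{path}: expected a single stage, found {sorted(stages)}")
        spectra = []
        for pid, grp in raw.groupby("plot_id", sort=False):
            w = grp["wavelength_nm"].to_numpy(float)
            _check_wavelengths(w, f"{path} plot {pid}: ")
            spectra.append(Spectrum(str(pid), stages[0], w, grp["reflectance"].to_numpy(float)))
        return SpectraSet(stages[0], spectra)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_spectra(sset: SpectraSet, path: str | Path) -> None:
    """Write a SpectraSet as wide CSV (wavelength_nm + one column per plot)."""
    df = pd.DataFrame({"wavelength_nm": sset.wavelengths})
    for s in sset.spectra:
        df[s.plot_id] = s.reflectance
    df.to_csv(path, index=False, float_format="%.12g")


def read_yields(path: str | Path) -> YieldTable:
    """Read a YieldTable from CSV with columns ``plot_id,yield_g_per_m2``."""
    raw = pd.read_csv(path, dtype={"plot_id": str})
    if not {"plot_id", "yield_g_per_m2"}.issubset(raw.columns):
        raise ValueError(f"{path}: need columns plot_id,yield_g_per_m2")
    y = pd.to_numeric(raw["yield_g_per_m2"], errors="coerce")
    bad = raw.index[y.isna()]
    if len(bad):
        raise ValueError(f"{path}: non-numeric yield in row {bad[0] + 2}")
    return YieldTable(list(raw["plot_id"]), y.to_numpy(float))


def write_yields(table: YieldTable, path: str | Path) -> None:
    pd.DataFrame({"plot_id": table.plot_ids, "yield_g_per_m2": table.yields}).to_csv(
        path, index=False, float_format="%.12g"
    )


def resample_to_grid(s: Spectrum, grid: np.ndarray) -> Spectrum:
    """Linearly interpolate a spectrum onto ``grid``; never extrapolates."""
    grid = np.asarray(grid, dtype=float)
    _check_wavelengths(grid, "target grid: ")
    if grid[0] < s.wavelengths[0] or grid[-1] > s.wavelengths[-1]:
        raise ValueError(
            f"target grid [{grid[0]:g}, {grid[-1]:g}] nm exceeds source range "
            f"[{s.wavelengths[0]:g}, {s.wavelengths[-1]:g}] nm; extrapolation refused"
        )
    return Spectrum(s.plot_id, s.stage, grid, np.interp(grid, s.wavelengths, s.reflectance))


def write_features(table: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table (plot_id index) as CSV with name-sorted columns."""
    df = table.copy()
    df = df[sorted(df.columns)]
    df.index.name = "plot_id"
    df.to_csv(path, float_format="%.12g")


def read_features(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="plot_id")


def write_report(report: dict | pd.DataFrame, path: str | Path) -> None:
    """Write a report as deterministic JSON (sorted keys, fixed layout)."""
    if isinstance(report, pd.DataFrame):
        report = {"rows": report.to_dict(orient="records")}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
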