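"""Synthetic multi-stage canopy reflectance trials with a known yield link.

Emulates a field experiment in which rice is grown at five nitrogen rates
(0–400 kg·ha⁻¹) across several varieties, 60 plots per trial-year, and the
canopy is measured with a full-range (350–2500 nm) spectroradiometer at four
phenological stages: elongation, heading, flowering and milky. Grain yield
(g·m⁻²) is tied to latent per-plot agronomic state (chlorophyll, leaf area
index, water status) so that every downstream step — transform, band
screening, stage fusion, regression — has a controllable signal to find.

The generator is phenomenological, not a radiative-transfer model: curves are
built from a flat soil line mixed with a canopy curve carrying pigment
absorption wells (450, 670 nm), a logistic red edge whose inflection shifts
with chlorophyll, an LAI-saturating NIR plateau, and water absorption wells
(1450, 1940 nm), plus heteroscedastic sensor noise inflated in the
atmospheric water-vapour windows.

Yield calibration targets the moments of the study design this emulates
(mean ≈ 686 g·m⁻², CV ≈ 0.16 for the training-year layout).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra_io import CANONICAL_GRID, STAGES, SpectraSet, YieldTable

#: Reference yield statistics of the emulated trial-years (per 60-plot year):
#: min, max, mean, sd, variance, CV of grain yield in g·m⁻².
REFERENCE_YIELD_STATS = {
    "training": {"n": 60, "min": 520.0, "max": 925.0, "mean": 686.3, "sd": 107.9, "variance": 11633.7, "cv": 0.16},
    "validation_1": {"n": 60, "min": 450.0, "max": 925.0, "mean": 659.6, "sd": 102.1, "variance": 10417.3, "cv": 0.15},
    "validation_2": {"n": 60, "min": 443.0, "max": 788.0, "mean": 600.6, "sd": 74.0, "variance": 5469.7, "cv": 0.12},
}

# per-stage latent multipliers: canopy peaks at heading/flowering, is still
# building at elongation and senescing by the milky stage
_STAGE_MULT = {
    "elongation": {"chl": 0.75, "lai": 0.65, "wat": 0.90},
    "heading": {"chl": 1.00, "lai": 1.00, "wat": 1.00},
    "flowering": {"chl": 0.95, "lai": 1.00, "wat": 0.95},
    "milky": {"chl": 0.65, "lai": 0.85, "wat": 0.75},
}


@dataclass
class SynthConfig:
    """Trial-design knobs.

    stage_weights are the g·m⁻² yield contributions of unit canopy response
    at each stage, ordered (elongation, heading, flowering, milky); the
    default makes heading ≈ flowering the dominant stages.
    """

    n_plots: int = 60
    n_levels: tuple[float, ...] = (0.0, 100.0, 200.0, 300.0, 400.0)  # kg N ha^-1
    n_varieties: int = 3
    stage_weights: tuple[float, float, float, float] = (95.0, 180.0, 165.0, 85.0)
    yield_base: float = 372.0  # g·m⁻²
    yield_noise_sd: float = 40.0  # g·m⁻²
    sensor_noise_sd: float = 0.004  # reflectance units
    # fertility response: fert = fert_floor + fert_gain * N/(N + n_half)
    n_half: float = 230.0
    fert_floor: float = 0.20
    fert_gain: float = 0.80
    variety_spread: float = 0.06  # +/- offset of extreme varieties on fert
    plot_sd: float = 0.04  # plot-level fertility noise on fert
    stage_shock_sd: float = 0.15  # independent per-stage growth shocks on fert
    seed: int = 0
    plot_prefix: str = "P"

    def __post_init__(self) -> None:
        if self.n_plots <= 0:
            raise ValueError("n_plots must be > 0")
        if self.yield_noise_sd < 0 or self.sensor_noise_sd < 0 or self.plot_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if len(self.stage_weights) != 4 or not np.all(np.isfinite(self.stage_weights)):
            raise ValueError("stage_weights must be 4 finite values")
        if self.n_varieties <= 0 or not self.n_levels:
            raise ValueError("need at least one variety and one N level")


def red_edge_inflection(chl: float | np.ndarray) -> float | np.ndarray:
    """Planted red-edge inflection wavelength (nm) for a chlorophyll proxy.

    Shifts from ~690 nm at zero chlorophyll towards ~740 nm at saturation —
    the classic red-edge displacement with canopy greenness.
    """
    return 690.0 + 50.0 * chl / (chl + 0.9)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def leaf_canopy_reflectance(
    chl: float,
    lai: float,
    wat: float,
    grid: np.ndarray = CANONICAL_GRID,
    sensor_noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Canopy reflectance curve in (0,1) for one plot-stage latent state.

    Components: Gaussian chlorophyll absorption wells at 450 and 670 nm whose
    depth saturates in ``chl``; a logistic red edge rising to the NIR plateau
    with inflection at :func:`red_edge_inflection`; soil/canopy mixing via
    fractional cover 1−exp(−k·LAI); water wells at 1450 and 1940 nm deepening
    with ``wat``; optional additive noise, 3× inflated inside the 1350–1450
    and 1800–1950 nm water-vapour windows.
    """
    if chl < 0 or lai < 0 or wat < 0:
        raise ValueError("latent proxies must be positive")
    lam = np.asarray(grid, dtype=float)

    vis_base = 0.12
    d450 = 0.085 * chl / (chl + 0.40)
    d670 = 0.095 * chl / (chl + 0.35)
    # red well is asymmetric: broad short-wavelength shoulder, fast recovery
    # toward the red edge so the well does not distort the edge position
    sig670 = np.where(lam <= 670.0, 26.0, 8.0)
    vis = vis_base - d450 * np.exp(-0.5 * ((lam - 450.0) / 24.0) ** 2) \
                   - d670 * np.exp(-0.5 * ((lam - 670.0) / sig670) ** 2)

    plateau = 0.50
    edge = _sigmoid((lam - red_edge_inflection(chl)) / 9.0)
    canopy = vis + (plateau - vis) * edge

    # gentle SWIR roll-off of the vegetated curve beyond ~1300 nm
    canopy = canopy * (1.0 - 0.45 * _sigmoid((lam - 1700.0) / 300.0))

    dw1 = 0.55 * wat / (wat + 0.6)
    dw2 = 0.65 * wat / (wat + 0.6)
    canopy = canopy * (1.0 - dw1 * np.exp(-0.5 * ((lam - 1450.0) / 35.0) ** 2))
    canopy = canopy * (1.0 - dw2 * np.exp(-0.5 * ((lam - 1940.0) / 45.0) ** 2))

    soil = 0.28  # flat dry-soil line
    fcover = 1.0 - np.exp(-0.55 * lai)
    refl = fcover * canopy + (1.0 - fcover) * soil

    if sensor_noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        mult = np.ones_like(lam)
        mult[((lam >= 1350) & (lam <= 1450)) | ((lam >= 1800) & (lam <= 1950))] = 3.0
        refl = refl + rng.normal(0.0, sensor_noise_sd, lam.size) * mult
    return np.clip(refl, 1e-4, 0.999)


def _canopy_response(chl: np.ndarray, lai: np.ndarray) -> np.ndarray:
    """Unitless (0,1)-ish canopy response entering the yield link."""
    return 0.6 * (1.0 - np.exp(-0.55 * lai)) + 0.4 * chl / (chl + 0.8)


def simulate_latents(cfg: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per plot × stage latent state (chlorophyll/LAI/water proxies).

    Fertility is a saturating function of N rate plus a variety offset and
    plot-level noise; stage trajectories are fixed multipliers of it.
    """
    n = cfg.n_plots
    n_rates = np.array([cfg.n_levels[i % len(cfg.n_levels)] for i in range(n)], dtype=float)
    varieties = np.array([(i // len(cfg.n_levels)) % cfg.n_varieties for i in range(n)])
    if cfg.n_varieties > 1:
        v_off = (varieties / (cfg.n_varieties - 1) * 2.0 - 1.0) * cfg.variety_spread
    else:
        v_off = np.zeros(n)
    eps = rng.normal(0.0, cfg.plot_sd, n)
    fert = np.clip(cfg.fert_floor + cfg.fert_gain * n_rates / (n_rates + cfg.n_half) + v_off + eps, 0.02, 1.3)
    # independent per-stage growth shocks: weather / phenology variation that
    # makes each stage carry its own share of the yield signal, so fusing
    # stages is genuinely informative rather than redundant
    shocks = rng.normal(0.0, cfg.stage_shock_sd, (n, len(STAGES)))

    rows = []
    for i in range(n):
        pid = f"{cfg.plot_prefix}{i + 1:02d}"
        for j, stage in enumerate(STAGES):
            m = _STAGE_MULT[stage]
            f_s = float(np.clip(fert[i] + shocks[i, j], 0.02, 1.3))
            rows.append(
                {
                    "plot_id": pid,
                    "stage": stage,
                    "n_rate": n_rates[i],
                    "variety": int(varieties[i]),
                    "chlorophyll_proxy": 2.2 * f_s * m["chl"],
                    "lai_proxy": 4.5 * f_s * m["lai"],
                    "water_proxy": 1.5 * f_s * m["wat"],
                }
            )
    return pd.DataFrame(rows)


def simulate_trial(
    cfg: SynthConfig | None = None, seed: int | None = None
) -> tuple[dict[str, SpectraSet], YieldTable, pd.DataFrame]:
    """Simulate one 60-plot trial-year.

    Returns stage-keyed SpectraSets on the canonical grid, the YieldTable and
    the latent state. Yield = base + Σ_s w_s·g(chl_s, lai_s) + N(0, σ_y),
    clipped positive. Fully deterministic under a fixed seed.
    """
    cfg = cfg if cfg is not None else SynthConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    latents = simulate_latents(cfg, rng)

    sets: dict[str, SpectraSet] = {}
    for stage in STAGES:
        sub = latents[latents["stage"] == stage]
        mat = np.vstack(
            [
                leaf_canopy_reflectance(
                    row.chlorophyll_proxy, row.lai_proxy, row.water_proxy,
                    CANONICAL_GRID, cfg.sensor_noise_sd, rng,
                )
                for row in sub.itertuples()
            ]
        )
        sets[stage] = SpectraSet.from_matrix(stage, list(sub["plot_id"]), CANONICAL_GRID, mat)

    pivot_chl = latents.pivot(index="plot_id", columns="stage", values="chlorophyll_proxy")
    pivot_lai = latents.pivot(index="plot_id", columns="stage", values="lai_proxy")
    plot_ids = sets["elongation"].plot_ids  # original plot order
    w = dict(zip(STAGES, cfg.stage_weights))
    g = sum(
        w[stage] * _canopy_response(pivot_chl.loc[plot_ids, stage].to_numpy(), pivot_lai.loc[plot_ids, stage].to_numpy())
        for stage in STAGES
    )
    yields = cfg.yield_base + g + rng.normal(0.0, cfg.yield_noise_sd, len(plot_ids))
    yields = np.clip(yields, 1.0, None)
    return sets, YieldTable(plot_ids, yields), latents


def validation2_config(cfg: SynthConfig) -> SynthConfig:
    """Perturbed design for the independent second validation trial.

    Different variety panel (2 varieties, wider spread) and a weaker
    fertility response (mixed-nutrient trial), shifting and tightening the
    yield distribution. The latent→spectrum and latent→yield links are the
    crop's physiology and stay untouched, so a good model should transfer.
    """
    return dataclasses.replace(
        cfg,
        n_varieties=2,
        variety_spread=0.10,
        n_half=300.0,
        fert_floor=0.14,
        fert_gain=0.50,
        yield_noise_sd=cfg.yield_noise_sd * 0.85,
    )


@dataclass
class Benchmark:
    """A train trial plus two validation trials with disjoint plot ids."""

    train: tuple[dict[str, SpectraSet], YieldTable, pd.DataFrame]
    validation1: tuple[dict[str, SpectraSet], YieldTable, pd.DataFrame]
    validation2: tuple[dict[str, SpectraSet], YieldTable, pd.DataFrame]


def make_three_year_benchmark(cfg: SynthConfig | None = None, seeds: tuple[int, int, int] = (1, 2, 3)) -> Benchmark:
    """Train / validation-1 / validation-2 trials mimicking a three-year study.

    Validation 2 uses :func:`validation2_config` so it is an independent
    design (different varieties and fertility mix), not just a new draw.
    """
    cfg = cfg if cfg is not None else SynthConfig()
    if len(set(seeds)) != 3:
        raise ValueError("seeds must be three distinct integers")
    c1 = dataclasses.replace(cfg, plot_prefix="Y1_P")
    c2 = dataclasses.replace(cfg, plot_prefix="Y2_P")
    c3 = dataclasses.replace(validation2_config(cfg), plot_prefix="Y3_P")
    return Benchmark(
        train=simulate_trial(c1, seeds[0]),
        validation1=simulate_trial(c2, seeds[1]),
        validation2=simulate_trial(c3, seeds[2]),
    )
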