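"""Yield models: multi-stage feature fusion, multivariate stepwise regression
(MSR), random-forest regression, the R²/RMSE/MAPE evaluation triple, and the
full stage-combination × transform-set model grid.

MSR is forward entry / backward removal on partial-F p-values: at each pass
the candidate with the smallest entry p-value below ``p_enter`` joins the
model, then any retained variable whose p-value has risen above ``p_remove``
is dropped; the loop terminates at a fixed point. For a single variable the
partial F test equals the square of its coefficient t test, which is what is
computed here.

MAPE follows the convention with the *predicted* value in the denominator
(switchable to the observed value). R² is the standard 1 − SSE/SST.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

from . import screening
from .features import StageTransforms, build_feature_table
from .spectra_io import STAGES, YieldTable
from .synthetic_data import Benchmark

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# stage fusion

def stage_combinations(stages: tuple[str, ...] = STAGES) -> list[tuple[str, ...]]:
    """All non-empty stage subsets in canonical order: singles, pairs,
    triples, then the full combination (15 for four stages)."""
    out: list[tuple[str, ...]] = []
    for k in range(1, len(stages) + 1):
        out.extend(itertools.combinations(stages, k))
    return out


def fuse_stages(tables: dict[str, pd.DataFrame], combo: tuple[str, ...]) -> pd.DataFrame:
    """Column-wise concatenation of per-stage feature tables for ``combo``."""
    if not combo:
        raise ValueError("empty stage combination")
    missing = [s for s in combo if s not in tables]
    if missing:
        raise KeyError(f"no feature table for stage(s) {missing}")
    return pd.concat([tables[s] for s in combo], axis=1, join="inner")


# ---------------------------------------------------------------------------
# stepwise regression

@dataclass
class MSRModel:
    """y = b0 + Σ b_i·x_i over the retained features."""

    intercept: float
    coefficients: dict[str, float]
    p_enter: float
    p_remove: float

    @property
    def retained(self) -> list[str]:
        return list(self.coefficients)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        y = np.full(len(X), self.intercept)
        for name, b in self.coefficients.items():
            y = y + b * X[name].to_numpy(float)
        return y


def _ols_pvalues(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """OLS with intercept; returns (coefs incl. intercept, two-sided p-values
    of the non-intercept coefficients, SSE)."""
    n, k = X.shape
    A = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    sse = float(resid @ resid)
    dof = n - k - 1
    if dof <= 0:
        return beta, np.zeros(k), sse
    sst = float(((y - y.mean()) ** 2).sum())
    if sst <= 1e-20 * n * (float(np.abs(y).mean()) ** 2 + 1.0):
        return beta, np.ones(k), sse  # constant target: nothing to explain
    if sse <= 1e-12 * max(sst, 1.0):
        # perfect fit: a coefficient is "significant" iff it is genuinely
        # nonzero at the scale of the data (the t statistic is 0/0 here)
        scale_x = X.std(axis=0) + 1e-300
        scale_y = max(np.sqrt(sst / max(n - 1, 1)), 1e-300)
        pvals = np.where(np.abs(beta[1:]) * scale_x > 1e-8 * scale_y, 0.0, 1.0)
        return beta, pvals, sse
    sigma2 = sse / dof
    cov = sigma2 * np.linalg.pinv(A.T @ A)
    se = np.sqrt(np.maximum(np.diag(cov), 1e-300))
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals[1:]), dof)
    return beta, pvals, sse


def _condition_number(X: np.ndarray) -> float:
    A = np.column_stack([np.ones(X.shape[0]), X])
    s = np.linalg.svd(A, compute_uv=False)
    return float(s[0] / s[-1]) if s[-1] > 0 else np.inf


def fit_msr(
    X: pd.DataFrame, y: YieldTable | np.ndarray, p_enter: float = 0.05, p_remove: float = 0.10
) -> MSRModel:
    """Forward-entry / backward-removal stepwise OLS on partial-F p-values.

    Candidates enter smallest-p first (ties resolved by column order) while
    p < p_enter; after each entry, retained variables with p > p_remove are
    removed largest-p first. Candidates making the design numerically
    collinear (condition number > 1e10) are skipped and logged. Returns the
    fixed point; with no admissible candidate, the intercept-only model.
    """
    if p_enter > p_remove:
        raise ValueError("p_enter must be <= p_remove")
    if isinstance(y, YieldTable):
        yy = y.as_series().loc[X.index].to_numpy(float)
    else:
        yy = np.asarray(y, dtype=float)
    X = X.select_dtypes(include=[np.number]).dropna(axis=1)
    names = list(X.columns)
    if len(yy) <= 2:
        raise ValueError("need more than 2 samples")
    retained: list[str] = []
    while True:
        changed = False
        # entry step
        candidates = [c for c in names if c not in retained]
        best_p, best_c = None, None
        for c in candidates:
            cols = retained + [c]
            mat = X[cols].to_numpy(float)
            if len(yy) <= len(cols) + 1:
                continue
            if _condition_number(mat) > 1e10:
                log.warning("skipping collinear candidate %s", c)
                continue
            _, pvals, _ = _ols_pvalues(mat, yy)
            p = pvals[-1]
            if p < p_enter and (best_p is None or p < best_p):
                best_p, best_c = p, c
        if best_c is not None:
            retained.append(best_c)
            changed = True
        # removal step: drop worst offender until all survive
        while len(retained) > 0:
            _, pvals, _ = _ols_pvalues(X[retained].to_numpy(float), yy)
            worst = int(np.argmax(pvals))
            if pvals[worst] > p_remove:
                log.info("removing %s (p=%.3g)", retained[worst], pvals[worst])
                retained.pop(worst)
                changed = True
            else:
                break
        if not changed:
            break
    if not retained:
        log.warning("no candidate passed entry; intercept-only model")
        return MSRModel(float(np.mean(yy)), {}, p_enter, p_remove)
    beta, _, _ = _ols_pvalues(X[retained].to_numpy(float), yy)
    return MSRModel(float(beta[0]), dict(zip(retained, beta[1:])), p_enter, p_remove)


# ---------------------------------------------------------------------------
# random forest

@dataclass
class RFModel:
    """Bootstrap-aggregated regression trees; prediction = tree mean."""

    n_trees: int
    max_features: int
    seed: int
    estimator: RandomForestRegressor = field(repr=False)
    feature_names: list[str] = field(default_factory=list)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.estimator.predict(X[self.feature_names].to_numpy(float))


def fit_rf(X: pd.DataFrame, y: YieldTable | np.ndarray, n_trees: int = 500, seed: int = 0) -> RFModel:
    """Random forest regression with max_features = ⌈p/3⌉ (regression
    convention); deterministic under a fixed seed."""
    if isinstance(y, YieldTable):
        yy = y.as_series().loc[X.index].to_numpy(float)
    else:
        yy = np.asarray(y, dtype=float)
    if len(yy) < 5:
        raise ValueError("random forest needs at least 5 samples")
    X = X.select_dtypes(include=[np.number]).dropna(axis=1)
    mf = max(1, int(np.ceil(X.shape[1] / 3)))
    est = RandomForestRegressor(n_estimators=n_trees, max_features=mf, random_state=seed, n_jobs=1)
    est.fit(X.to_numpy(float), yy)
    return RFModel(n_trees, mf, seed, est, list(X.columns))


# ---------------------------------------------------------------------------
# evaluation

@dataclass
class EvalMetrics:
    """R² (1 − SSE/SST), RMSE (g·m⁻²) and MAPE (%) for a prediction set."""

    r_squared: float
    rmse: float
    mape: float
    n: int


def evaluate(obs, pred, mape_denominator: str = "predicted") -> EvalMetrics:
    """The three model-test indicators.

    R² = 1 − Σ(x−x̂)²/Σ(x−x̄)²; RMSE = √(Σ(x−x̂)²/n);
    MAPE = (Σ|x−x̂|/denom)/n × 100 with denom the predicted value by
    default (``mape_denominator="observed"`` for the usual convention).
    A zero denominator makes MAPE NaN (logged).
    """
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("obs and pred must be equal-length with n >= 2")
    sst = float(((obs - obs.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError("observed values have zero variance")
    sse = float(((obs - pred) ** 2).sum())
    rmse = float(np.sqrt(sse / obs.size))
    denom = pred if mape_denominator == "predicted" else obs
    if np.any(denom == 0):
        log.warning("zero %s value; MAPE set missing", mape_denominator)
        mape = float("nan")
    else:
        mape = float(np.mean(np.abs((obs - pred) / denom)) * 100.0)
    return EvalMetrics(1.0 - sse / sst, rmse, mape, int(obs.size))


# ---------------------------------------------------------------------------
# the full model grid

TRANSFORM_SETS = ("FD-VI", "CWT-FD-VI")


def _trial_transforms(trial, with_cwt: bool, window: int = 11, polyorder: int = 3) -> dict[str, StageTransforms]:
    sets, _, _ = trial
    return {
        stage: StageTransforms.from_spectraset(sets[stage], window, polyorder, with_cwt=with_cwt)
        for stage in sets
    }


def select_training_bands(
    transforms: dict[str, StageTransforms], y: YieldTable,
    alpha: float = 0.05, top_k: int = 5, min_separation_nm: float = 10.0,
) -> tuple[dict[str, list[float]], dict[str, list[tuple[float, float]]]]:
    """Per-stage sensitive FD bands and CWT cells, screened on training data
    only (the leakage guard: selection never sees validation yields)."""
    fd_bands: dict[str, list[float]] = {}
    cwt_cells: dict[str, list[tuple[float, float]]] = {}
    for stage, t in transforms.items():
        cmap = screening.band_yield_correlation((t.plot_ids, t.wavelengths, t.fd), y)
        r_min = screening.critical_r(cmap.n, alpha)
        fd_bands[stage] = list(screening.select_sensitive(cmap, r_min, top_k, min_separation_nm))
        if t.cwt is not None:
            wmap = screening.wavelet_yield_correlation(t.plot_ids, t.scales, t.wavelengths, t.cwt, y)
            cwt_cells[stage] = list(screening.select_sensitive(wmap, r_min, top_k, min_separation_nm))
    return fd_bands, cwt_cells


def _metrics_row(prefix: str, m: EvalMetrics) -> dict[str, float]:
    return {f"{prefix}_r2": m.r_squared, f"{prefix}_rmse": m.rmse, f"{prefix}_mape": m.mape, f"{prefix}_n": m.n}


def stage_combination_grid(
    benchmark: Benchmark,
    transform_sets: tuple[str, ...] = TRANSFORM_SETS,
    combos: list[tuple[str, ...]] | None = None,
    algorithms: tuple[str, ...] = ("MSR", "RF"),
    n_trees: int = 500,
    rf_seed: int = 0,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    top_k: int = 5,
    alpha: float = 0.05,
    min_separation_nm: float = 10.0,
    mape_denominator: str = "predicted",
) -> pd.DataFrame:
    """Fit and evaluate every (transform set × stage combination × algorithm).

    Feature groups: FD-VI = vegetation indices + screened FD bands;
    CWT-FD-VI additionally includes screened wavelet cells. Screening uses
    the training trial only; metrics are reported for the training set and
    both validation sets (disjoint plot namespaces guarantee no leakage).
    60 rows under the defaults (2 × 15 × 2).
    """
    combos = combos if combos is not None else stage_combinations()
    need_cwt = any("CWT" in ts for ts in transform_sets)
    tr_t = _trial_transforms(benchmark.train, with_cwt=need_cwt)
    v1_t = _trial_transforms(benchmark.validation1, with_cwt=need_cwt)
    v2_t = _trial_transforms(benchmark.validation2, with_cwt=need_cwt)
    y_tr = benchmark.train[1]
    y_v1 = benchmark.validation1[1]
    y_v2 = benchmark.validation2[1]
    assert not (set(y_tr.plot_ids) & set(y_v1.plot_ids) | set(y_tr.plot_ids) & set(y_v2.plot_ids))

    fd_bands, cwt_cells = select_training_bands(tr_t, y_tr, alpha, top_k, min_separation_nm)

    rows = []
    for ts in transform_sets:
        groups = {"VI", "FD"} | ({"CWT"} if "CWT" in ts else set())
        cells = cwt_cells if "CWT" in ts else None
        feat_tr = {s: build_feature_table({s: tr_t[s]}, groups, fd_bands, cells) for s in tr_t}
        feat_v1 = {s: build_feature_table({s: v1_t[s]}, groups, fd_bands, cells) for s in v1_t}
        feat_v2 = {s: build_feature_table({s: v2_t[s]}, groups, fd_bands, cells) for s in v2_t}
        for combo in combos:
            X_tr = fuse_stages(feat_tr, combo)
            X_v1 = fuse_stages(feat_v1, combo)
            X_v2 = fuse_stages(feat_v2, combo)
            ytr = y_tr.as_series().loc[X_tr.index].to_numpy()
            for algo in algorithms:
                if algo == "MSR":
                    model = fit_msr(X_tr, ytr, p_enter, p_remove)
                elif algo == "RF":
                    model = fit_rf(X_tr, ytr, n_trees, rf_seed)
                else:
                    raise ValueError(f"unknown algorithm {algo!r}")
                row = {"stage_combination": "-".join(combo), "transform_set": ts, "algorithm": algo}
                row.update(_metrics_row("train", evaluate(ytr, model.predict(X_tr), mape_denominator)))
                for tag, Xv, yv in (("val1", X_v1, y_v1), ("val2", X_v2, y_v2)):
                    yo = yv.as_series().loc[Xv.index].to_numpy()
                    row.update(_metrics_row(tag, evaluate(yo, model.predict(Xv), mape_denominator)))
                rows.append(row)
    return pd.DataFrame(rows)


def run_directional_study(
    n_seeds: int = 20, base_seed: int = 0, n_trees: int = 500
) -> pd.DataFrame:
    """Held-out accuracy of the RF model across benchmark replicates.

    For each replicate: validation-1 R² of the four-stage fusion and of each
    single stage, under both transform sets. Used to check the qualitative
    orderings (wavelet features help; fusing stages helps) without claiming
    the field study's absolute accuracies.
    """
    from .synthetic_data import SynthConfig, make_three_year_benchmark

    combos = [(s,) for s in STAGES] + [STAGES]
    frames = []
    for i in range(n_seeds):
        s = base_seed + 1000 * i
        bench = make_three_year_benchmark(SynthConfig(), seeds=(s + 11, s + 22, s + 33))
        rep = stage_combination_grid(
            bench, combos=combos, algorithms=("RF",), n_trees=n_trees, rf_seed=base_seed
        )
        rep["replicate"] = i
        frames.append(rep)
    return pd.concat(frames, ignore_index=True)
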