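"""Monte-Carlo comparison of ML and regularized Bayes estimators.

Metrics per scenario cell: RMSE = sqrt(mean (est - beta_b)^2) over
replications, and relative bias = mean(est - beta_b) / beta_b (undefined
when beta_b = 0).  Monte-Carlo standard errors accompany both.  ML failures
from occasional near-zero between-variance estimates are included as
computed by default — those extreme values are a real property of ML that
the comparison is meant to show — with an optional winsorizing diagnostic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateVarianceError
from .model import compute_sufficient_stats, ml_estimate
from .regularize import GridSpec, grid_search_prior, bayes_estimate
from .simulate import ScenarioSpec, generate_dataset

__all__ = ["ScenarioResult", "run_scenario", "summarize_by_design",
           "results_to_frame", "ESTIMATOR_NAMES"]

ESTIMATOR_NAMES = ("ml", "rb_plugin", "rb_true")


@dataclass(frozen=True)
class ScenarioResult:
    """Metrics for one simulation cell."""

    spec: ScenarioSpec
    reps: int
    rmse: dict
    rmse_mc_se: dict
    rel_bias: dict
    rel_bias_mc_se: dict
    rel_bias_defined: bool
    failures: dict

    def as_row(self) -> dict:
        row = {"icc_x": self.spec.icc_x, "J": self.spec.J, "n": self.spec.n,
               "beta_b": self.spec.beta_b, "beta_w": self.spec.beta_w,
               "icc_y": self.spec.icc_y, "reps": self.reps}
        for est in self.rmse:
            row[f"rmse_{est}"] = self.rmse[est]
            row[f"rmse_mc_se_{est}"] = self.rmse_mc_se[est]
            row[f"rel_bias_{est}"] = self.rel_bias[est]
            row[f"rel_bias_mc_se_{est}"] = self.rel_bias_mc_se[est]
            row[f"failures_{est}"] = self.failures[est]
        return row


def _estimates_one_rep(spec: ScenarioSpec, rep: int,
                       estimators, grid: GridSpec) -> dict:
    data = generate_dataset(spec, rep)
    stats = compute_sufficient_stats(data)
    out = {}
    names = [e for e in estimators if isinstance(e, str)]
    beta_ml = None
    if any(e in names for e in ("ml", "rb_plugin")):
        try:
            beta_ml = ml_estimate(stats)
        except DegenerateVarianceError:
            beta_ml = math.nan
    if "ml" in names:
        out["ml"] = beta_ml
    if "rb_plugin" in names:
        if beta_ml is None or not np.isfinite(beta_ml):
            out["rb_plugin"] = math.nan
        else:
            prior, _ = grid_search_prior(stats, beta_ml, grid)
            out["rb_plugin"] = bayes_estimate(stats, prior)
    if "rb_true" in names:
        prior, _ = grid_search_prior(stats, spec.beta_b, grid)
        out["rb_true"] = bayes_estimate(stats, prior)
    for e in estimators:
        if not isinstance(e, str):            # (name, callable) pair
            name, fn = e
            out[name] = fn(data)
    return out


def run_scenario(spec: ScenarioSpec,
                 estimators: Sequence[str] = ESTIMATOR_NAMES,
                 grid: GridSpec = GridSpec(),
                 winsorize_at: Optional[float] = None) -> ScenarioResult:
    """Replicate one design cell and score each estimator.

    ``estimators`` entries are the built-in names ("ml", "rb_plugin",
    "rb_true") or ``(name, callable)`` pairs mapping a GroupedData to an
    estimate (useful for baselines and testing).  ``winsorize_at`` (absolute
    error bound) is a diagnostic knob only and defaults to off.  Failed
    replications (ML undefined on an exactly zero between-variance estimate)
    are recorded per estimator as NaN and counted in ``failures``, never
    silently dropped; metrics are computed over the finite values.
    """
    names = []
    for est in estimators:
        if isinstance(est, str):
            if est not in ESTIMATOR_NAMES:
                raise ValueError(f"unknown estimator {est!r}")
            names.append(est)
        else:
            names.append(est[0])
    errors = {name: np.empty(spec.reps) for name in names}
    for rep in range(spec.reps):
        ests = _estimates_one_rep(spec, rep, estimators, grid)
        for name in names:
            errors[name][rep] = ests[name] - spec.beta_b

    rmse, rmse_se, rbias, rbias_se, failures = {}, {}, {}, {}, {}
    defined = spec.beta_b != 0.0
    for est in errors:
        err = errors[est]
        bad = ~np.isfinite(err)
        failures[est] = int(bad.sum())
        err = err[~bad]
        if winsorize_at is not None:
            err = np.clip(err, -winsorize_at, winsorize_at)
        sq = err**2
        mse = sq.mean()
        rmse[est] = float(np.sqrt(mse))
        # delta method: se(RMSE) = se(MSE) / (2 RMSE)
        se_mse = sq.std(ddof=1) / np.sqrt(len(sq))
        rmse_se[est] = float(se_mse / (2 * rmse[est])) if rmse[est] > 0 else 0.0
        if defined:
            rbias[est] = float(err.mean() / spec.beta_b)
            rbias_se[est] = float(err.std(ddof=1) / np.sqrt(len(err))
                                  / abs(spec.beta_b))
        else:
            rbias[est] = math.nan
            rbias_se[est] = math.nan
    return ScenarioResult(spec=spec, reps=spec.reps, rmse=rmse,
                          rmse_mc_se=rmse_se, rel_bias=rbias,
                          rel_bias_mc_se=rbias_se,
                          rel_bias_defined=defined, failures=failures)


def results_to_frame(results: Iterable[ScenarioResult]) -> pd.DataFrame:
    """Tidy one-row-per-cell table of scenario results."""
    return pd.DataFrame([r.as_row() for r in results])


def summarize_by_design(results: Iterable[ScenarioResult]) -> pd.DataFrame:
    """Average RMSE and relative bias within each (n, J) combination.

    Missing cells (factor combinations not covered by the input) are left as
    NaN, never imputed; ``n_scenarios`` reports per-cell coverage.  Winner
    columns flag the estimator with the smallest RMSE and the smallest
    absolute relative bias in each cell.
    """
    df = results_to_frame(results)
    if df.empty:
        return df
    ests = [c[len("rmse_"):] for c in df.columns
            if c.startswith("rmse_") and not c.startswith("rmse_mc_se_")]
    agg = {"n_scenarios": ("reps", "size")}
    for e in ests:
        agg[f"rmse_{e}"] = (f"rmse_{e}", "mean")
        agg[f"rel_bias_{e}"] = (f"rel_bias_{e}", "mean")
    out = df.groupby(["n", "J"]).agg(**agg)
    rmse_cols = [f"rmse_{e}" for e in ests]
    bias_cols = [f"rel_bias_{e}" for e in ests]
    out["winner_rmse"] = (out[rmse_cols].idxmin(axis=1)
                          .str.replace("rmse_", "", regex=False))
    out["winner_abs_rel_bias"] = (out[bias_cols].abs().idxmin(axis=1)
                                  .str.replace("rel_bias_", "", regex=False))
    return out.reset_index()
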