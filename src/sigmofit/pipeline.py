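"""The Monte Carlo model-selection pipeline.

For every configured noise level and replicate, all candidate sigmoid
families are fitted to the perturbed curve and the full set of
goodness-of-fit measures is recorded.  Two summaries are produced:

* **measure averaging** -- per (noise s.d., model) means of adjusted
  R^2, AICc, BIC, residual variance, reduced chi-square and the
  per-iteration Akaike weights;
* **best-model selection** -- per iteration, the winning model under
  each criterion (highest adjusted R^2, lowest AICc, lowest BIC, lowest
  residual variance, reduced chi-square closest to 1), tabulated as
  selection counts and as the percentage of iterations recovering the
  generating ("true") model.

Non-converged fits are dropped from that iteration's cohort (for both
Akaike weights and selection) and tallied in a failure table; with the
default design their incidence is far below 1%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .fitting import FitOptions, DEFAULT_OPTIONS, fit_model
from .gof import GOFMeasures, akaike_weights, compute_measures
from .models import MODEL_REGISTRY, get_model
from .simulate import SimulationConfig, dataset_rng, make_true_curve, perturb

__all__ = ["CRITERIA", "run_simulation", "select_best", "aggregate",
           "SelectionTable"]

#: selection criteria and their direction, in reporting order
CRITERIA: tuple = ("r2_adj_max", "aicc_min", "bic_min", "res_var_min",
                   "red_chi2_nearest_1")

_MEASURE_COLUMNS = ["r2", "r2_adj", "log_lik", "aic", "aicc", "bic",
                    "res_var", "red_chi2"]


@dataclass(frozen=True)
class SelectionTable:
    """Aggregated simulation output.

    Attributes
    ----------
    mean_measures : pandas.DataFrame
        Per (sd, model): mean of each measure over converged iterations
        plus the mean Akaike weight (``akaike_weight`` column).
    selection_counts : pandas.DataFrame
        Per (sd, criterion, model): number of iterations in which that
        model won under that criterion.
    true_model_pct : pandas.DataFrame
        Per (sd, criterion): percentage of iterations selecting the
        true model.
    failures : pandas.DataFrame
        Per (sd, model): count of non-converged fits.
    """

    mean_measures: pd.DataFrame
    selection_counts: pd.DataFrame
    true_model_pct: pd.DataFrame
    failures: pd.DataFrame


def _criterion_score(row_measures: Mapping[str, float], criterion: str) -> float:
    """Lower-is-better score of one model under one criterion."""
    if criterion == "r2_adj_max":
        return -row_measures["r2_adj"]
    if criterion == "aicc_min":
        return row_measures["aicc"]
    if criterion == "bic_min":
        return row_measures["bic"]
    if criterion == "res_var_min":
        return row_measures["res_var"]
    if criterion == "red_chi2_nearest_1":
        return abs(row_measures["red_chi2"] - 1.0)
    raise ValueError(f"unknown criterion {criterion!r}")


def select_best(measures: Sequence[GOFMeasures], criterion: str) -> str:
    """The winning model id for one iteration under one criterion.

    Ties (probability ~0 for continuous measures, but possible in
    constructed data) break deterministically: fewer parameters first,
    then registry order.
    """
    converged = [m for m in measures if m.converged]
    if not converged:
        raise ValueError("no converged model in this iteration")
    order = {mid: i for i, mid in enumerate(MODEL_REGISTRY)}
    best = min(
        converged,
        key=lambda m: (_criterion_score(
            {"r2_adj": m.r2_adj, "aicc": m.aicc, "bic": m.bic,
             "res_var": m.res_var, "red_chi2": m.red_chi2}, criterion),
            m.p, order[m.model_id]),
    )
    return best.model_id


def run_simulation(config: SimulationConfig,
                   fit_options: FitOptions = DEFAULT_OPTIONS,
                   progress: Optional[callable] = None) -> pd.DataFrame:
    """Run the full Monte Carlo study.

    Returns a long-format DataFrame with one row per
    (sd, iteration, model) carrying every goodness-of-fit measure, the
    within-iteration Akaike weight and the convergence flag.
    Deterministic given ``config.seed``.
    """
    true_curve = make_true_curve(config)
    model_ids = config.model_ids()
    specs = [get_model(mid) for mid in model_ids]
    rows: List[dict] = []

    for sd in config.noise_sds:
        for it in range(config.n_reps):
            rng = dataset_rng(config.seed, sd, it)
            data = perturb(true_curve, sd, rng)
            iter_measures = []
            for j, spec in enumerate(specs):
                opts = FitOptions(**{**fit_options.__dict__,
                                     "seed": (config.seed + 1) * 1000003
                                     + it * 97 + j})
                fit = fit_model(spec, data, opts)
                m = compute_measures(fit, data.y, sigma=sd,
                                     k_convention=config.k_convention)
                iter_measures.append(m)
            aicc_vec = np.array([m.aicc for m in iter_measures])
            weights = akaike_weights(aicc_vec)
            for m, w in zip(iter_measures, weights):
                rows.append({
                    "sd": sd, "iteration": it, "model": m.model_id,
                    "p": m.p, "n": m.n,
                    **{col: getattr(m, col) for col in _MEASURE_COLUMNS},
                    "akaike_weight": w if m.converged else np.nan,
                    "converged": m.converged,
                })
            if progress is not None and (it + 1) % 200 == 0:
                progress(sd, it + 1)

    df = pd.DataFrame(rows)
    df["model"] = pd.Categorical(df["model"], categories=list(model_ids),
                                 ordered=True)
    return df


def _criterion_score_column(conv: pd.DataFrame, criterion: str) -> pd.Series:
    if criterion == "r2_adj_max":
        return -conv["r2_adj"]
    if criterion == "aicc_min":
        return conv["aicc"]
    if criterion == "bic_min":
        return conv["bic"]
    if criterion == "res_var_min":
        return conv["res_var"]
    if criterion == "red_chi2_nearest_1":
        return (conv["red_chi2"] - 1.0).abs()
    raise ValueError(f"unknown criterion {criterion!r}")


def _selections_frame(records: pd.DataFrame) -> pd.DataFrame:
    """Per (sd, iteration, criterion) winning model, from long records."""
    order = {mid: i for i, mid in enumerate(MODEL_REGISTRY)}
    conv = records[records["converged"]].copy()
    conv["order"] = conv["model"].map(order).astype(int)
    frames = []
    for criterion in CRITERIA:
        tmp = conv.assign(score=_criterion_score_column(conv, criterion))
        tmp = tmp.sort_values(["sd", "iteration", "score", "p", "order"],
                              kind="mergesort")
        win = (tmp.groupby(["sd", "iteration"], observed=True, sort=True)
               .head(1))
        frames.append(pd.DataFrame({
            "sd": win["sd"].to_numpy(),
            "iteration": win["iteration"].to_numpy(),
            "criterion": criterion,
            "selected_model": win["model"].astype(str).to_numpy(),
        }))
    return pd.concat(frames, ignore_index=True)


def aggregate(records: pd.DataFrame,
              true_model: str = "L3") -> SelectionTable:
    """Build both study summaries from the long-format measure records."""
    conv = records[records["converged"]]
    mean_cols = ["r2_adj", "aicc", "bic", "res_var", "red_chi2",
                 "akaike_weight"]
    mean_measures = (conv.groupby(["sd", "model"], observed=True)[mean_cols]
                     .mean().reset_index())

    selections = _selections_frame(records)
    counts = (selections.groupby(["sd", "criterion"], observed=True)
              ["selected_model"].value_counts().rename("count")
              .reset_index())

    pct_rows = []
    for (sd, criterion), grp in selections.groupby(["sd", "criterion"],
                                                   observed=True):
        pct = 100.0 * (grp["selected_model"] == true_model).mean()
        pct_rows.append({"sd": sd, "criterion": criterion,
                         "n_iterations": len(grp), "true_model_pct": pct})
    true_model_pct = pd.DataFrame(pct_rows)

    failures = (records[~records["converged"]]
                .groupby(["sd", "model"], observed=True).size()
                .rename("n_failed").reset_index())

    return SelectionTable(mean_measures, counts, true_model_pct, failures)
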