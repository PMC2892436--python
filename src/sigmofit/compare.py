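"""Model-comparison report for a single (x, y) curve.

Fits a set of candidate sigmoid families to one dataset and tabulates
R^2, adjusted R^2, AICc, BIC, Akaike weights and residual variance,
ranked by AICc.  This is the per-dataset workflow the simulation study
evaluates in bulk: judging a model only by its (always high) R^2 hides
evidence ratios that AICc-based Akaike weights expose directly.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fitting import Dataset, FitOptions, DEFAULT_OPTIONS, fit_model
from .gof import akaike_weights, compute_measures
from .models import MODEL_IDS, get_model

__all__ = ["compare_models"]


def compare_models(data: Dataset,
                   models: Optional[Sequence[str]] = None,
                   sigma: Optional[float] = None,
                   k_convention: str = "p+1",
                   fit_options: FitOptions = DEFAULT_OPTIONS) -> pd.DataFrame:
    """Fit candidate models to one curve and rank them by AICc.

    Parameters
    ----------
    data : Dataset
        The curve; for log-x families x must be strictly positive.
    models : sequence of str, optional
        Candidate model ids; defaults to all nine registered families.
    sigma : float, optional
        Known measurement s.d.; enables the reduced chi-square column.

    Returns
    -------
    pandas.DataFrame
        One row per requested model (converged fits ranked by AICc,
        failed fits last) with the fitted parameters and all measures.
    """
    model_ids = tuple(models) if models else MODEL_IDS
    rows = []
    for mid in model_ids:
        spec = get_model(mid)
        if data.n < spec.n_params + 1:
            raise ValueError(
                f"{mid} needs at least {spec.n_params + 1} points")
        fit = fit_model(spec, data, fit_options)
        m = compute_measures(fit, data.y, sigma=sigma,
                             k_convention=k_convention)
        rows.append({
            "model": mid, "p": m.p, "converged": m.converged,
            "params": tuple(np.round(fit.params, 10)) if fit.converged else (),
            "r2": m.r2, "r2_adj": m.r2_adj, "aicc": m.aicc, "bic": m.bic,
            "res_var": m.res_var, "red_chi2": m.red_chi2, "rss": fit.rss,
        })
    table = pd.DataFrame(rows)
    if not table["converged"].any():
        raise RuntimeError("all candidate fits failed")
    table["akaike_weight"] = akaike_weights(table["aicc"].to_numpy())
    table = table.sort_values(
        ["converged", "aicc"], ascending=[False, True], kind="mergesort",
    ).reset_index(drop=True)
    return table
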