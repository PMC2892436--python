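"""Goodness-of-fit measures for nonlinear least-squares fits.

Implements the classical per-fit statistics used to judge and compare
sigmoidal regressions:

* coefficient of determination ``R^2 = 1 - RSS/TSS`` and its
  degrees-of-freedom adjusted form,
* the profile Gaussian log-likelihood of the residuals and the
  information criteria AIC, small-sample AICc and BIC built on it,
* Akaike weights over a model cohort,
* residual variance ``RSS/(n - p)``,
* chi-square and reduced chi-square against a known measurement s.d.

The effective parameter count ``k`` entering AIC/AICc/BIC counts the
estimated error variance in addition to the ``p`` structural curve
parameters (``k = p + 1``), the convention used by likelihood-based
``logLik``/``AIC`` machinery for regression models with Gaussian errors.
Differences between models with equal ``p`` are unaffected by this
choice; set ``k_convention="p"`` to drop the variance term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .fitting import FitResult

__all__ = [
    "GOFMeasures",
    "r_squared",
    "r_squared_adj",
    "log_lik_gaussian",
    "aic",
    "aicc",
    "bic",
    "akaike_weights",
    "residual_variance",
    "chi_square",
    "reduced_chi_square",
    "compute_measures",
    "PerfectFitError",
]

_LN_2PI = math.log(2.0 * math.pi)


class PerfectFitError(ArithmeticError):
    """Zero residual sum-of-squares: the Gaussian likelihood is unbounded."""


def r_squared(y: Sequence[float], fitted: Sequence[float]) -> float:
    """``1 - RSS/TSS``, the most general coefficient of determination.

    ``TSS`` is the total sum of squares about the mean of ``y``.  For a
    nonlinear fit this quantity is *not* a variance decomposition and can
    be negative; it equals 1 only for a perfect fit.
    """
    y = np.asarray(y, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    if y.shape != fitted.shape or y.ndim != 1 or y.size < 2:
        raise ValueError("y and fitted must be equal-length vectors (n >= 2)")
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        raise ValueError("y is constant (TSS = 0); R^2 undefined")
    rss = float(np.sum((y - fitted) ** 2))
    return 1.0 - rss / tss


def r_squared_adj(r2: float, n: int, p: int) -> float:
    """Adjusted R^2: ``1 - (1 - R^2) * (n - 1)/(n - p)``."""
    if p < 1 or n <= p:
        raise ValueError("require n > p >= 1")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p)


def log_lik_gaussian(residuals: Sequence[float]) -> float:
    """Profile Gaussian log-likelihood of least-squares residuals, in nats.

    With the error variance profiled out at its MLE ``RSS/N`` this is
    ``-(N/2) * (ln 2*pi + ln(RSS/N) + 1)``.

    Raises
    ------
    PerfectFitError
        If ``RSS == 0`` (the likelihood is unbounded).
    """
    residuals = np.asarray(residuals, dtype=float)
    n = residuals.size
    if n < 1:
        raise ValueError("need at least one residual")
    rss = float(np.dot(residuals, residuals))
    if rss <= 0.0:
        raise PerfectFitError("RSS = 0: unbounded Gaussian likelihood")
    return -0.5 * n * (_LN_2PI + math.log(rss / n) + 1.0)


def aic(log_lik: float, k: int) -> float:
    """Akaike information criterion ``2k - 2 ln L``."""
    return 2.0 * k - 2.0 * log_lik


def aicc(aic_value: float, n: int, k: int) -> float:
    """Small-sample corrected AIC: ``AIC + 2k(k+1)/(n - k - 1)``."""
    if n - k - 1 <= 0:
        raise ValueError("AICc requires n > k + 1")
    return aic_value + 2.0 * k * (k + 1) / (n - k - 1)


def bic(log_lik: float, n: int, k: int) -> float:
    """Bayesian information criterion ``k ln n - 2 ln L``."""
    return k * math.log(n) - 2.0 * log_lik


def akaike_weights(criterion_values: Sequence[float]) -> np.ndarray:
    """Akaike weights ``w_i = exp(-D_i/2) / sum_k exp(-D_k/2)``.

    ``D_i`` is each value's difference from the cohort minimum, so the
    result is invariant under adding a constant to all inputs.
    Non-finite entries (failed fits) receive weight 0 and are excluded
    from the normalisation.
    """
    v = np.asarray(criterion_values, dtype=float)
    if v.size == 0:
        raise ValueError("empty criterion vector")
    finite = np.isfinite(v)
    if not finite.any():
        raise ValueError("no finite criterion values")
    w = np.zeros_like(v)
    delta = v[finite] - v[finite].min()
    ew = np.exp(-0.5 * delta)
    w[finite] = ew / ew.sum()
    return w


def residual_variance(rss: float, n: int, p: int) -> float:
    """``RSS/(n - p)``: noise-variance estimate under the fitted model."""
    if n <= p:
        raise ValueError("require n > p")
    return rss / (n - p)


def chi_square(residuals: Sequence[float], sigma: float) -> float:
    """``sum(residual_i^2 / sigma^2)`` for a known measurement s.d."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    residuals = np.asarray(residuals, dtype=float)
    return float(np.dot(residuals, residuals)) / sigma**2


def reduced_chi_square(residuals: Sequence[float], sigma: float,
                       n: int, p: int) -> float:
    """Chi-square per degree of freedom, ``chi^2 / (n - p)``.

    Approximately 1 when the fitted model is adequate and ``sigma`` is
    the true noise s.d.; much larger values flag lack of fit.
    """
    if n <= p:
        raise ValueError("require n > p")
    return chi_square(residuals, sigma) / (n - p)


@dataclass(frozen=True)
class GOFMeasures:
    """The per-fit statistics for one model on one dataset."""

    model_id: str
    n: int
    p: int
    r2: float
    r2_adj: float
    log_lik: float
    aic: float
    aicc: float
    bic: float
    res_var: float
    red_chi2: float  # NaN when no known sigma was supplied
    converged: bool = True


def _nan_measures(model_id: str, n: int, p: int) -> GOFMeasures:
    nan = float("nan")
    return GOFMeasures(model_id, n, p, nan, nan, nan, nan, nan, nan, nan,
                       nan, False)


def compute_measures(fit: FitResult, y: Sequence[float],
                     sigma: Optional[float] = None,
                     k_convention: str = "p+1") -> GOFMeasures:
    """All goodness-of-fit measures for one :class:`FitResult`.

    Parameters
    ----------
    fit : FitResult
        The fitted model; a non-converged fit yields all-NaN measures
        flagged ``converged=False``.
    y : array-like
        The observed response the model was fitted to.
    sigma : float, optional
        Known measurement s.d. for (reduced) chi-square; NaN if omitted.
    k_convention : {"p+1", "p"}
        Effective parameter count for the information criteria (see
        module docstring).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    p = fit.n_params
    if not fit.converged:
        return _nan_measures(fit.model_id, n, p)
    if k_convention == "p+1":
        k = p + 1
    elif k_convention == "p":
        k = p
    else:
        raise ValueError("k_convention must be 'p+1' or 'p'")

    r2 = r_squared(y, fit.fitted)
    ll = log_lik_gaussian(fit.residuals)
    a = aic(ll, k)
    rc = (reduced_chi_square(fit.residuals, sigma, n, p)
          if sigma is not None else float("nan"))
    return GOFMeasures(
        model_id=fit.model_id, n=n, p=p,
        r2=r2,
        r2_adj=r_squared_adj(r2, n, p),
        log_lik=ll,
        aic=a,
        aicc=aicc(a, n, k),
        bic=bic(ll, n, k),
        res_var=residual_variance(fit.rss, n, p),
        red_chi2=rc,
        converged=True,
    )
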