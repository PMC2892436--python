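"""Nonlinear least-squares fitting of sigmoidal models.

Thin, deterministic wrapper around :func:`scipy.optimize.least_squares`
(trust-region reflective / Levenberg-Marquardt) with a self-start from
:mod:`sigmofit.models` and a jittered-restart retry policy.  A fit that
fails to converge is returned flagged (``converged=False``), never
raised, so simulation loops can account for failures explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from .models import ModelSpec, eval_model, self_start

__all__ = ["Dataset", "FitOptions", "FitResult", "fit_model"]


@dataclass(frozen=True)
class Dataset:
    """One (x, y) curve, optionally with its known noise s.d.

    ``true_sd`` is the a-priori measurement uncertainty; it is consumed
    only by the reduced chi-square statistic and is recorded by the
    simulator that generated the data.
    """

    x: np.ndarray
    y: np.ndarray
    true_sd: Optional[float] = None

    def __post_init__(self):
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if self.x.ndim != 1 or self.x.shape != self.y.shape:
            raise ValueError("x and y must be 1-d arrays of equal length")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("x must be strictly increasing")

    @property
    def n(self) -> int:
        return int(self.x.size)


@dataclass(frozen=True)
class FitOptions:
    """Optimiser controls.

    ``n_restarts`` jittered restarts (multiplicative Gaussian factors of
    s.d. ``jitter_sd`` on the self-start vector) are attempted when the
    initial attempt fails or to escape a poor local minimum; restart
    noise is drawn from a generator seeded by ``seed`` so fits are
    reproducible.
    """

    xtol: float = 1e-8
    ftol: float = 1e-8
    gtol: float = 1e-8
    max_nfev: int = 1000
    n_restarts: int = 3
    jitter_sd: float = 0.1
    seed: int = 0
    bounds: Optional[Tuple[Sequence[float], Sequence[float]]] = None


DEFAULT_OPTIONS = FitOptions()


@dataclass(frozen=True)
class FitResult:
    """Outcome of one least-squares fit of one model to one dataset."""

    model_id: str
    params: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    rss: float
    converged: bool
    n_iter: int = 0
    message: str = ""

    @property
    def n_params(self) -> int:
        return int(self.params.size)


def _attempt(spec: ModelSpec, data: Dataset, theta0: np.ndarray,
             opts: FitOptions):
    def resid(theta):
        return spec._eval(theta, data.x) - data.y

    try:
        if opts.bounds is None:
            sol = least_squares(
                resid, theta0, method="lm",
                xtol=opts.xtol, ftol=opts.ftol, gtol=opts.gtol,
                max_nfev=opts.max_nfev,
            )
        else:
            sol = least_squares(
                resid, theta0, method="trf", bounds=opts.bounds,
                xtol=opts.xtol, ftol=opts.ftol, gtol=opts.gtol,
                max_nfev=opts.max_nfev,
            )
    except (ValueError, FloatingPointError):
        return None
    if not np.all(np.isfinite(sol.x)):
        return None
    return sol


def fit_model(spec: ModelSpec, data: Dataset,
              opts: FitOptions = DEFAULT_OPTIONS) -> FitResult:
    """Fit ``spec`` to ``data`` by nonlinear least squares.

    Returns a :class:`FitResult`; non-convergence (including a failing
    self-start) is reported via ``converged=False`` rather than raised.
    """
    theta0 = self_start(spec, data.x, data.y)

    best = None
    rng = None
    for attempt in range(opts.n_restarts + 1):
        if attempt == 0:
            start = theta0
        else:
            if rng is None:
                rng = np.random.default_rng(
                    np.random.SeedSequence([opts.seed, 0x5F17]))
            start = theta0 * rng.normal(1.0, opts.jitter_sd, theta0.size)
        sol = _attempt(spec, data, start, opts)
        if sol is not None and sol.status > 0:
            best = sol
            break

    if best is None:
        return FitResult(spec.model_id, np.full(spec.n_params, np.nan),
                         np.full(data.n, np.nan), np.full(data.n, np.nan),
                         np.nan, False, 0, "no successful optimisation")

    fitted = eval_model(spec, best.x, data.x)
    residuals = data.y - fitted
    rss = float(np.dot(residuals, residuals))
    return FitResult(spec.model_id, np.asarray(best.x, dtype=float), fitted,
                     residuals, rss, True, int(best.nfev), best.message)
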