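"""Sigmoidal model families for dose-response and amplification-curve fitting.

Nine classical sigmoid families are provided, addressable by the string
identifiers ``L5, L4, L3, B5, B4, B3, W4, W3, baro5``:

* **L5 / L4 / L3** -- five/four/three-parameter log-logistic models,
  sigmoidal in ``log(x)``::

      f(x) = c + (d - c) / (1 + exp(b * (ln x - ln e)))**f

  with ``f = 1`` fixed for L4 and additionally ``c = 0`` for L3.

* **B5 / B4 / B3** -- the logistic counterparts, sigmoidal in ``x``
  itself (linear abscissa)::

      f(x) = c + (d - c) / (1 + exp(b * (x - e)))**f

* **W4 / W3** -- Weibull-type (Gompertz / double-exponential) models,
  asymmetric about the inflection::

      f(x) = c + (d - c) * exp(-exp(b * (ln x - ln e)))

* **baro5** -- the five-parameter baroreflex-style sigmoid (after
  Ricketts & Head), with two slope parameters ``b1, b2`` blended by a
  smooth logistic weight so the slope transitions continuously through
  the midpoint; here in its log-x form, so that ``b1 = b2`` collapses
  it to the four-parameter log-logistic::

      u      = ln x - ln e
      g(x)   = 1 / (1 + exp(h * u)),   h = 2*b1*b2 / (b1 + b2)
      f(x)   = c + (d - c) / (1 + g(x)*exp(b1*u) + (1 - g(x))*exp(b2*u))

Parameter conventions throughout: ``b`` slope (negative for curves that
increase with x under these sign conventions), ``c`` lower asymptote,
``d`` upper asymptote, ``e`` midpoint (the x, or the x whose log, gives
the half-way response), ``f`` asymmetry.

Each family carries a self-start heuristic (:func:`self_start`) based on
linearising the sigmoid (logit or complementary log-log transform of the
range-scaled response), which yields starting values close enough for a
local least-squares optimiser on any monotone sigmoid-shaped dataset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Sequence, Tuple

import numpy as np

__all__ = [
    "ModelSpec",
    "MODEL_REGISTRY",
    "MODEL_IDS",
    "get_model",
    "eval_model",
    "self_start",
    "DegenerateDataError",
]


class DegenerateDataError(ValueError):
    """Raised when data carry no usable sigmoid signal (e.g. constant y)."""


@dataclass(frozen=True)
class ModelSpec:
    """One sigmoidal model family: its parameters and evaluation rule.

    Attributes
    ----------
    model_id : str
        Registry identifier (``"L3"``, ``"baro5"``, ...).
    param_names : tuple of str
        Ordered parameter names; its length is the parameter count ``p``.
    log_x : bool
        True when the family is sigmoidal in ``log(x)`` and hence
        requires strictly positive abscissa values.
    """

    model_id: str
    param_names: Tuple[str, ...]
    log_x: bool
    _eval: Callable[[np.ndarray, np.ndarray], np.ndarray]
    _init: Callable[[np.ndarray, np.ndarray], np.ndarray]

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def __call__(self, params: Sequence[float], x: Sequence[float]) -> np.ndarray:
        return eval_model(self, params, x)


def _check_x(spec: ModelSpec, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if spec.log_x and np.any(x <= 0):
        raise ValueError(
            f"model {spec.model_id} is defined on log(x); x must be strictly positive"
        )
    return x


def eval_model(spec: ModelSpec, params: Sequence[float], x: Sequence[float]) -> np.ndarray:
    """Evaluate a model family at ``params`` on the abscissa vector ``x``."""
    params = np.asarray(params, dtype=float)
    if params.shape != (spec.n_params,):
        raise ValueError(
            f"model {spec.model_id} expects {spec.n_params} parameters "
            f"{spec.param_names}, got shape {params.shape}"
        )
    x = _check_x(spec, x)
    return spec._eval(params, x)


def self_start(spec: ModelSpec, x: Sequence[float], y: Sequence[float]) -> np.ndarray:
    """Heuristic starting parameter vector for fitting ``spec`` to (x, y).

    The returned vector is finite and evaluable on ``x``; for monotone
    sigmoid-shaped data the implied asymptotes bracket the data range.

    Raises
    ------
    DegenerateDataError
        If ``y`` is (numerically) constant.
    ValueError
        If lengths differ or there are fewer than ``n_params + 1`` points.
    """
    x = _check_x(spec, np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if x.size < spec.n_params + 1:
        raise ValueError(
            f"need at least {spec.n_params + 1} points to start {spec.model_id}"
        )
    if np.ptp(y) <= 0 or not np.isfinite(np.ptp(y)):
        raise DegenerateDataError("y is constant; no sigmoid can be started")
    theta = spec._init(x, y)
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):  # pragma: no cover - defensive
        raise DegenerateDataError("self-start produced non-finite values")
    return theta


# ---------------------------------------------------------------------------
# evaluation rules


def _eval_L5(p: np.ndarray, x: np.ndarray) -> np.ndarray:
    b, c, d, e, f = p
    z = np.clip(b * (np.log(x) - np.log(e)), -700, 700)
    return c + (d - c) / (1.0 + np.exp(z)) ** f


def _eval_L4(p: np.ndarray, x: np.ndarray) -> np.ndarray:
    b, c, d, e = p
    z = np.clip(b * (np.log(x) - np.log(e)), -700, 700)
    return c + (d - c) / (1.0 + np.exp(z))


def _eval_L3(p: np.ndarray, x: np.ndarray) -> np.ndarray:
    b, d, e = p
    z = np.clip(b * (np.log(x) - np.log(e)), -700, 700)
    return d / (1.0 + np.exp(z))


def _eval_B5(p: np.ndarray, x: np.ndarray) -> np.ndarray:
    b, c, d, e, f = p
    z = np.clip(b * (x - e), -700, 700)
    return c + (d - c) / (1.0 + np.exp(z)) ** f


def _eval_B4(p: np.ndarray, x: np.ndarray) -> np.ndarray:
    b, c, d, e = p
    z = np.clip(b * (x - e), -700, 700)
    return c + (d - c) / (1.0 + np.exp(z))


def _eval_B3(p: np.ndarray, x: np.ndarray) -> np.ndarray:
    b, d, e = p
    z = np.clip(b * (x - e), -700, 700)
    return d / (1.0 + np.exp(z))


def _eval_W4(p: np.ndarray, x: np.ndarray) -> np.ndarray:
    b, c, d, e = p
    z = np.clip(b * (np.log(x) - np.log(e)), -700, 700)
    return c + (d - c) * np.exp(-np.exp(z))


def _eval_W3(p: np.ndarray, x: np.ndarray) -> np.ndarray:
    b, d, e = p
    z = np.clip(b * (np.log(x) - np.log(e)), -700, 700)
    return d * np.exp(-np.exp(z))


def _eval_baro5(p: np.ndarray, x: np.ndarray) -> np.ndarray:
    b1, b2, c, d, e = p
    denom = b1 + b2
    # harmonic-mean slope drives the transition weight; with b1 = b2 = b
    # the weight cancels and the model collapses to the 4-parameter
    # log-logistic, whatever h is, so the degenerate case is harmless
    h = 2.0 * b1 * b2 / denom if denom != 0.0 else 0.0
    u = np.log(x) - np.log(e)
    g = 1.0 / (1.0 + np.exp(np.clip(h * u, -700, 700)))
    z1 = np.exp(np.clip(b1 * u, -700, 700))
    z2 = np.exp(np.clip(b2 * u, -700, 700))
    return c + (d - c) / (1.0 + g * z1 + (1.0 - g) * z2)


# ---------------------------------------------------------------------------
# self-start heuristics
#
# All sigmoids here are linearised by transforming the range-scaled
# response: logit for the logistic kernels, log(-log) for the Weibull
# kernel, against u = ln x (log-x families) or u = x.  A least-squares
# line through the transformed interior points recovers slope b and
# midpoint e directly; asymptote starts come from the data range.

_EPS = 1e-3


def _range_starts(y: np.ndarray, with_c: bool) -> Tuple[float, float]:
    lo, hi = float(np.min(y)), float(np.max(y))
    span = hi - lo
    # pad so the started asymptotes strictly bracket the data
    c0 = lo - 0.01 * span if with_c else 0.0
    d0 = hi + 0.01 * span
    return c0, d0


def _linearise(u: np.ndarray, z: np.ndarray, transform: str) -> Tuple[float, float]:
    """Fit a line t(z) = a + s*u through interior points; return (s, a)."""
    keep = (z > _EPS) & (z < 1.0 - _EPS)
    if keep.sum() < 2:
        keep = (z > 0.0) & (z < 1.0)
    zz = np.clip(z[keep], _EPS / 10, 1.0 - _EPS / 10)
    uu = u[keep]
    if transform == "logit":
        t = np.log(zz / (1.0 - zz))
    else:  # complementary log-log
        t = np.log(-np.log(zz))
    if uu.size < 2 or np.ptp(uu) == 0:
        raise DegenerateDataError("too few interior points to linearise sigmoid")
    s, a = np.polyfit(uu, t, 1)
    return float(s), float(a)


def _init_logistic(x: np.ndarray, y: np.ndarray, *, log_x: bool, with_c: bool,
                   with_f: bool) -> np.ndarray:
    c0, d0 = _range_starts(y, with_c)
    u = np.log(x) if log_x else x
    z = (y - c0) / (d0 - c0)
    # model: logit(z) = -b*(u - u_e)  =>  slope of logit on u is -b
    s, a = _linearise(u, z, "logit")
    if s == 0:
        raise DegenerateDataError("flat linearised slope")
    b0 = -s
    ue = -a / s
    e0 = float(np.exp(ue)) if log_x else float(ue)
    if log_x and not (np.min(x) / 4 < e0 < np.max(x) * 4):
        e0 = float(np.sqrt(np.min(x) * np.max(x)))
    params = [b0]
    if with_c:
        params.append(c0)
    params += [d0, e0]
    if with_f:
        params.append(1.0)
    return np.asarray(params)


def _init_weibull(x: np.ndarray, y: np.ndarray, *, with_c: bool) -> np.ndarray:
    c0, d0 = _range_starts(y, with_c)
    u = np.log(x)
    z = (y - c0) / (d0 - c0)
    # model: z = exp(-exp(b*(u - u_e)))  =>  log(-log z) = b*(u - u_e)
    s, a = _linearise(u, z, "cloglog")
    if s == 0:
        raise DegenerateDataError("flat linearised slope")
    b0 = s
    ue = -a / s
    e0 = float(np.exp(ue))
    if not (np.min(x) / 4 < e0 < np.max(x) * 4):
        e0 = float(np.sqrt(np.min(x) * np.max(x)))
    params = [b0]
    if with_c:
        params.append(c0)
    params += [d0, e0]
    return np.asarray(params)


def _init_baro5(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    b0, c0, d0, e0 = _init_logistic(x, y, log_x=True, with_c=True, with_f=False)
    # start the two slopes slightly apart so the transition weight has
    # a gradient at the starting point
    return np.asarray([1.05 * b0, 0.95 * b0, c0, d0, e0])


# ---------------------------------------------------------------------------
# registry, in the fixed order used for reporting and tie-breaking

MODEL_REGISTRY: Dict[str, ModelSpec] = {}


def _register(spec: ModelSpec) -> None:
    MODEL_REGISTRY[spec.model_id] = spec


_register(ModelSpec("L5", ("b", "c", "d", "e", "f"), True, _eval_L5,
                    lambda x, y: _init_logistic(x, y, log_x=True, with_c=True, with_f=True)))
_register(ModelSpec("L4", ("b", "c", "d", "e"), True, _eval_L4,
                    lambda x, y: _init_logistic(x, y, log_x=True, with_c=True, with_f=False)))
_register(ModelSpec("L3", ("b", "d", "e"), True, _eval_L3,
                    lambda x, y: _init_logistic(x, y, log_x=True, with_c=False, with_f=False)))
_register(ModelSpec("B5", ("b", "c", "d", "e", "f"), False, _eval_B5,
                    lambda x, y: _init_logistic(x, y, log_x=False, with_c=True, with_f=True)))
_register(ModelSpec("B4", ("b", "c", "d", "e"), False, _eval_B4,
                    lambda x, y: _init_logistic(x, y, log_x=False, with_c=True, with_f=False)))
_register(ModelSpec("B3", ("b", "d", "e"), False, _eval_B3,
                    lambda x, y: _init_logistic(x, y, log_x=False, with_c=False, with_f=False)))
_register(ModelSpec("W4", ("b", "c", "d", "e"), True, _eval_W4,
                    lambda x, y: _init_weibull(x, y, with_c=True)))
_register(ModelSpec("W3", ("b", "d", "e"), True, _eval_W3,
                    lambda x, y: _init_weibull(x, y, with_c=False)))
_register(ModelSpec("baro5", ("b1", "b2", "c", "d", "e"), True, _eval_baro5,
                    _init_baro5))

MODEL_IDS: Tuple[str, ...] = tuple(MODEL_REGISTRY)


def get_model(model_id: str) -> ModelSpec:
    """Look up a registered model family by identifier."""
    try:
        return MODEL_REGISTRY[model_id]
    except KeyError:
        raise KeyError(
            f"unknown model {model_id!r}; available: {', '.join(MODEL_IDS)}"
        ) from None
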