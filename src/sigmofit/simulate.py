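"""Monte Carlo data supply: the 'true' sigmoid and its noisy perturbations.

The study design emulated here starts from a three-parameter
log-logistic curve with ``b = -9.90, d = 11.07, e = 24.75`` evaluated on
the integer grid ``x = 10..35`` (n = 26) -- a shape typical of qPCR
amplification curves, where x counts PCR cycles on a linear, equidistant
scale.  Each replicate adds i.i.d. homoscedastic Gaussian noise
(mean 0) to the noiseless fitted values; the default noise levels
s.d. = 0.01, 0.02, 0.05, 0.1, 0.2, 0.4 span roughly 0.1% to 4% of the
response range, and 2000 replicates are drawn per level.

Reproducibility: every (noise s.d., iteration) pair owns an independent
RNG sub-stream derived from the master seed and the decimal encoding of
the s.d., so the same datasets are produced regardless of how many
replicates or which noise levels a particular run requests.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Tuple

import numpy as np

from .fitting import Dataset
from .models import get_model, eval_model

__all__ = ["SimulationConfig", "make_true_curve", "perturb", "dataset_rng",
           "DEFAULT_NOISE_SDS", "TRUE_PARAMS"]

TRUE_PARAMS: Tuple[float, float, float] = (-9.90, 11.07, 24.75)
DEFAULT_NOISE_SDS: Tuple[float, ...] = (0.01, 0.02, 0.05, 0.1, 0.2, 0.4)


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one Monte Carlo study.

    Defaults encode the reference design: true model L3 with the printed
    parameters on x = 10..35, six noise levels, 2000 replicates each.
    """

    true_model: str = "L3"
    true_params: Tuple[float, ...] = TRUE_PARAMS
    x_start: float = 10.0
    x_stop: float = 35.0
    n_points: int = 26
    noise_sds: Tuple[float, ...] = DEFAULT_NOISE_SDS
    n_reps: int = 2000
    seed: int = 0
    models: Tuple[str, ...] = ()  # empty = all registered models
    k_convention: str = "p+1"

    def __post_init__(self):
        object.__setattr__(self, "true_params", tuple(float(v) for v in self.true_params))
        object.__setattr__(self, "noise_sds", tuple(float(s) for s in self.noise_sds))
        object.__setattr__(self, "models", tuple(self.models))
        if any(s <= 0 for s in self.noise_sds):
            raise ValueError("noise s.d. values must be positive")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.n_points < 2 or self.x_stop <= self.x_start:
            raise ValueError("x grid must be increasing with >= 2 points")
        spec = get_model(self.true_model)
        if len(self.true_params) != spec.n_params:
            raise ValueError(
                f"{self.true_model} needs {spec.n_params} parameters")

    @property
    def x_grid(self) -> np.ndarray:
        return np.linspace(self.x_start, self.x_stop, self.n_points)

    def model_ids(self) -> Tuple[str, ...]:
        from .models import MODEL_IDS
        return self.models if self.models else MODEL_IDS

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**{k: v for k, v in d.items()})


def make_true_curve(config: SimulationConfig) -> Dataset:
    """The deterministic noiseless curve of the configured true model."""
    spec = get_model(config.true_model)
    x = config.x_grid
    y = eval_model(spec, config.true_params, x)
    return Dataset(x, y)


def dataset_rng(seed: int, sd: float, iteration: int) -> np.random.Generator:
    """The dedicated RNG sub-stream for one (noise s.d., iteration) cell.

    The s.d. enters through a fixed-point decimal encoding so that the
    stream identity does not depend on the position of the s.d. in the
    configured list.
    """
    sd_key = int(round(sd * 10**9))
    ss = np.random.SeedSequence(entropy=int(seed),
                                spawn_key=(sd_key, int(iteration)))
    return np.random.default_rng(ss)


def perturb(true_curve: Dataset, sd: float,
            rng: np.random.Generator) -> Dataset:
    """One noisy replicate: true values plus i.i.d. N(0, sd^2) noise."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    noise = rng.normal(0.0, sd, true_curve.n)
    return Dataset(true_curve.x, true_curve.y + noise, true_sd=sd)
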