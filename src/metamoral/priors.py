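"""Prior distributions over model parameters.

The softmax inverse temperature tau has a lognormal(0, 1.4) prior, chosen
so that 90% of its mass falls between 1/10 and 10. The model-free learning
rate alpha is Uniform[0, 1]. The beta-Bernoulli prior pseudo-count a0 has
a Gamma(shape 2.57, rate 0.54) prior, placing 90% of its mass between 1
and 10 (equivalent to between 1 and 10 previously seen outcomes of each
valence). The constant models' choice rate theta is Uniform[0, 1].
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .models import ModelId, ModelParams, param_names

__all__ = ["PRIORS", "log_prior_density", "sample_params", "prior_mass"]

#: scipy frozen distributions, keyed by parameter name.
PRIORS: dict[str, stats.rv_continuous] = {
    "tau": stats.lognorm(s=1.4, scale=1.0),
    "alpha": stats.uniform(0.0, 1.0),
    "a0": stats.gamma(a=2.57, scale=1.0 / 0.54),
    "theta": stats.uniform(0.0, 1.0),
}


def log_prior_density(model_id: ModelId, params: ModelParams) -> float:
    """Joint log prior density of a model's parameters; -inf off support."""
    total = 0.0
    for name in param_names(ModelId(model_id)):
        value = getattr(params, name)
        if value is None:
            raise ValueError(f"parameter {name!r} is required but unset")
        total += PRIORS[name].logpdf(value)
    return float(total)


def sample_params(model_id: ModelId, rng: np.random.Generator) -> ModelParams:
    """Draw one parameter set from the model's prior."""
    draws = {
        name: float(PRIORS[name].ppf(rng.random()))
        for name in param_names(ModelId(model_id))
    }
    return ModelParams(**draws)


def prior_mass(name: str, lo: float, hi: float) -> float:
    """Prior probability that a parameter falls in [lo, hi]."""
    dist = PRIORS[name]
    return float(dist.cdf(hi) - dist.cdf(lo))
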