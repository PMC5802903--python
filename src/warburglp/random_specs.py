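"""Randomized scenario generator for solver/oracle cross-validation.

The distributions are fixed constants of the validation suite: cheap-pathway
costs uniform on [0, 5] (with a small floor on alpha1 + alpha2 so pure
fermentation stays bounded), respiration cost uniform above the most
expensive cheap pathway, budget uniform on [1, 1000], and the uptake cap
either absent (half the draws) or uniform up to twice the cap at which it
stops binding.  Reversibility is a fair coin.
"""

from __future__ import annotations

import numpy as np

from .model_core import UNLIMITED, ModelSpec

#: Default seed of the cross-validation suite.
DEFAULT_SEED = 42

ALPHA_CHEAP_HIGH = 5.0
ALPHA3_MARGIN = 0.1
ALPHA3_HIGH = 100.0
GAMMA_RANGE = (1.0, 1000.0)
MIN_CHEAP_SUM = 1e-3


def random_spec(rng: np.random.Generator) -> ModelSpec:
    """Draw one valid scenario from the documented distributions."""
    while True:
        alpha1, alpha2, alpha2_rev = rng.uniform(0.0, ALPHA_CHEAP_HIGH, size=3)
        if alpha1 + alpha2 >= MIN_CHEAP_SUM:
            break
    alpha3 = rng.uniform(max(alpha1, alpha2, alpha2_rev) + ALPHA3_MARGIN, ALPHA3_HIGH)
    gamma = rng.uniform(*GAMMA_RANGE)
    if rng.random() < 0.5:
        v1 = UNLIMITED
    else:
        v1 = rng.uniform(0.0, 2.0 * gamma / (alpha1 + alpha2))
    return ModelSpec.from_values(
        alpha1=alpha1,
        alpha2=alpha2,
        alpha2_rev=alpha2_rev,
        alpha3=alpha3,
        Gamma=gamma,
        V1=v1,
        fermentation_reversible=bool(rng.random() < 0.5),
    )


def random_specs(n: int, seed: int = DEFAULT_SEED):
    """Yield ``n`` scenarios from a generator seeded with ``seed``."""
    rng = np.random.default_rng(seed)
    for _ in range(n):
        yield random_spec(rng)
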