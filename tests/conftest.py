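import math

import numpy as np
import pytest

from insightrl.bandit import make_standard_schedule
from insightrl.model import ModelParameters, simulate_agent


@pytest.fixture(scope="session")
def standard_schedule():
    return make_standard_schedule()


@pytest.fixture(scope="session")
def typical_params():
    """An agent at the analyzed cohort's mean traits."""
    return ModelParameters(
        beta=0.85, mu=0.48, nu=0.52, alpha_pos=0.42, alpha_neg=0.59, lam=0.51, phi=0.0
    )


@pytest.fixture(scope="session")
def typical_record(standard_schedule, typical_params):
    record, _ = simulate_agent(typical_params, standard_schedule, seed=1234)
    return record


def scalar_loglik(choices, rewards, p) -> float:
    """Per-trial brute-force likelihood oracle in explicit scalar arithmetic.

    Recomputes each trial's softmax probability independently with plain
    ``math`` calls; deliberately naive and separate from the package's
    vectorized/jitted implementation.
    """
    q_right = 0.0
    q_left = 0.0
    total = 0.0
    for c, r in zip(choices, rewards):
        e_right = math.exp(p.beta * q_right)
        e_left = math.exp(p.beta * q_left)
        prob = (e_right if c == 0 else e_left) / (e_right + e_left)
        total += math.log(prob)
        if r > 0:
            u = r ** p.mu
        elif r < 0:
            u = -p.lam * (-r) ** p.nu
        else:
            u = 0.0
        q = q_right if c == 0 else q_left
        d = u - q
        a = p.alpha_pos if d >= 0 else p.alpha_neg
        q = q + a * d + p.phi
        if c == 0:
            q_right = q
        else:
            q_left = q
    return total


def sample_sane_params(rng: np.random.Generator) -> ModelParameters:
    """Random parameters in the cohort-plausible regime (no exp overflow in
    the scalar oracle)."""
    return ModelParameters(
        beta=float(rng.uniform(0.05, 3.0)),
        mu=float(rng.uniform(0.1, 1.2)),
        nu=float(rng.uniform(0.1, 1.2)),
        alpha_pos=float(rng.uniform(0.05, 0.95)),
        alpha_neg=float(rng.uniform(0.05, 0.95)),
        lam=float(rng.uniform(0.1, 2.0)),
        phi=float(rng.normal(0.0, 1.0)),
    )
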