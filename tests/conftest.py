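import numpy as np
import pytest

import spikebench as sb


@pytest.fixture(scope="session")
def m1_small():
    """Small center-out scenario shared by read-only tests."""
    return sb.make_scenario("m1_like", n_neurons=4, seed=11, n_trials=40)


@pytest.fixture(scope="session")
def cosine_sim():
    """Strongly modulated cosine-tuned neuron without slow gain noise.

    Directions are drawn uniformly so every angle is exercised; the true
    conditional rate is available for oracle comparisons.
    """
    rng = np.random.default_rng(5)
    n = 12_000
    theta = rng.uniform(-np.pi, np.pi, n)
    b0, m, theta_pref = float(np.log(0.5)), 1.5, np.pi / 3
    lam = np.exp(b0 + m * np.cos(theta - theta_pref))
    y = rng.poisson(lam)
    return {
        "theta": theta,
        "y": y,
        "lam": lam,
        "b0": b0,
        "m": m,
        "theta_pref": theta_pref,
    }


@pytest.fixture()
def trig_design(cosine_sim):
    return sb.trig_direction_features(cosine_sim["theta"])
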