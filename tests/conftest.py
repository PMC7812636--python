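"""Shared fixtures.

Everything is generated at test time from fixed seeds; no binary fixtures
are stored.  Session-scoped fixtures cache the expensive rendered sessions
so several test modules can share one simulation.
"""

import numpy as np
import pytest

from dyadflow import synthetic
from dyadflow.io import default_montage


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def coop_session():
    """One coupled cooperative session (gain 0.25, seed 42)."""
    return synthetic.simulate_session("d00", "CoopNT", 0.25, seed=42)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Three dyads, all three conditions — the smallest legal cohort."""
    return synthetic.simulate_cohort(n_dyads=3, master_seed=7)


def make_var2(n: int, c: float, seed: int, noise: float = 1.0) -> np.ndarray:
    """Unidirectional one-lag pair: y_t = c * x_{t-1} + e_y, x white.

    The classic analytic benchmark: GC(x->y) -> ln(1 + c^2) as n -> inf
    (unit innovation variances), GC(y->x) -> 0.
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n + 1)
    y = c * x[:-1] + noise * rng.standard_normal(n)
    return np.column_stack([x[1:], y])
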