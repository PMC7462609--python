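import numpy as np
import pytest

import gddm
from gddm.io import FixtureSpec, generate_fixture

#: Coherence levels of a random-dot motion task (maximum 0.512).
COHERENCES = (0.0, 0.032, 0.064, 0.128, 0.256, 0.512)
DDM_TRUTH = {"mu0": 5.0, "B0": 1.0, "t_nd": 0.2}


@pytest.fixture(scope="session")
def benchmark_entry():
    """Constant-coefficient DDM (mu=2, sigma=1.5, B=1) with a closed form."""
    return gddm.get_model("benchmark_constant")


@pytest.fixture(scope="session")
def benchmark_analytic():
    """Analytic reference for the benchmark model at a given dt."""
    def _ref(dt, t_dur=2.0):
        return gddm.solve_analytic(mu=2.0, sigma=1.5, B=1.0, t_dur=t_dur, dt=dt)
    return _ref


@pytest.fixture(scope="session")
def small_ddm_dataset():
    """Synthetic 3-parameter DDM dataset (1200 trials) with known truth."""
    fx = FixtureSpec(model="ddm", truth=DDM_TRUTH,
                     condition_grid=tuple({"coherence": c} for c in COHERENCES),
                     n_per_condition=200, seed=101)
    dataset, truth = generate_fixture(fx)
    return dataset, truth


def mse_bins(sol, ref):
    err = np.concatenate([sol.upper - ref.upper, sol.lower - ref.lower])
    return float(np.mean(err**2))
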