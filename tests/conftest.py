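import numpy as np
import pandas as pd
import pytest

from gaclock.io import BetaMatrix
from gaclock.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small strong-signal cohort shared across tests (read-only)."""
    cfg = SimConfig.for_signal_fraction(
        0.8, n_samples=200, n_probes=500, n_active=15, seed=5, missing_rate=0.01
    )
    bm, sheet, truth = simulate_cohort(cfg)
    return cfg, bm, sheet, truth


@pytest.fixture()
def random_beta_matrix():
    def _make(n_probes=20, n_samples=8, seed=1, missing_rate=0.0):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0, 1, size=(n_probes, n_samples))
        if missing_rate:
            vals[rng.random(vals.shape) < missing_rate] = np.nan
        return BetaMatrix(
            pd.DataFrame(
                vals,
                index=[f"cg{i:05d}" for i in range(n_probes)],
                columns=[f"S{j}" for j in range(n_samples)],
            )
        )

    return _make
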