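import numpy as np
import pandas as pd
import pytest

from mrmediation.instruments import InstrumentSet
from mrmediation.synthetic import TruthConfig, simulate_study


def make_iv(bx, sx, by, sy, pval_exposure=None, pval_outcome=None,
            n_exposure=50_000, n_outcome=50_000) -> InstrumentSet:
    """Assemble an InstrumentSet directly from effect arrays."""
    bx = np.asarray(bx, float)
    k = len(bx)
    sx = np.broadcast_to(np.asarray(sx, float), (k,))
    by = np.asarray(by, float)
    sy = np.broadcast_to(np.asarray(sy, float), (k,))
    from scipy import stats

    pe = pval_exposure if pval_exposure is not None else 2 * stats.norm.sf(np.abs(bx / sx))
    po = pval_outcome if pval_outcome is not None else 2 * stats.norm.sf(np.abs(by / sy))
    table = pd.DataFrame({
        "variant_id": [f"rs{i + 1}" for i in range(k)],
        "beta_exposure": bx, "se_exposure": sx,
        "pval_exposure": np.maximum(pe, 1e-300), "n_exposure": n_exposure,
        "beta_outcome": by, "se_outcome": sy,
        "pval_outcome": np.maximum(po, 1e-300), "n_outcome": n_outcome,
        "eaf": 0.3, "f_statistic": (bx / sx) ** 2,
    })
    return InstrumentSet(table)


def random_iv(rng, k=20) -> InstrumentSet:
    """A random, well-conditioned instrument set for oracle comparisons."""
    bx = rng.normal(0.0, 0.08, k)
    bx += np.sign(bx) * 0.02  # keep denominators away from zero
    sx = rng.uniform(0.003, 0.01, k)
    sy = rng.uniform(0.003, 0.01, k)
    by = 0.2 * bx + rng.normal(0.0, 0.05, k)
    return make_iv(bx, sx, by, sy)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def default_study():
    """One simulated study under the default generative conditions."""
    return simulate_study(TruthConfig(seed=11))


@pytest.fixture(scope="session")
def null_study():
    """A study with no causal paths and no pleiotropy."""
    return simulate_study(TruthConfig(
        seed=12, exposure_mediator_effect=0.0, mediator_outcome_effect=0.0,
        exposure_outcome_direct=0.0,
    ))
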