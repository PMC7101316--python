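import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from ssgse.inference import MCMCConfig
from ssgse.io import GeneStats, complete_summary_stats
from ssgse.simulate import assign_truth, simulate_summary_stats


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fast_cfg():
    """Short chains for unit tests; enough sweeps for stable PIP means."""
    return MCMCConfig(n_sweeps=400, burn_in=200, seed=7, em_max_iter=50,
                      em_tol=1e-3, em_n_sweeps=200)


@pytest.fixture
def small_stats(rng) -> GeneStats:
    """200-gene summary statistics drawn from the mixture model."""
    truth = assign_truth(200, 0.1, -2.0, 1.0, rng=rng)
    return simulate_summary_stats(truth, sigma_beta2=9.0, rng=rng)


@pytest.fixture
def model_dataset(rng):
    """Model-simulated dataset with truth: (stats, truth), p=2000, tau=(-2,1)."""
    truth = assign_truth(2000, 0.1, -2.0, 1.0, rng=rng)
    stats = simulate_summary_stats(truth, sigma_beta2=9.0, rng=rng)
    return stats, truth


def make_stats(beta, se, gene_ids=None) -> GeneStats:
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(len(beta))]
    df = pd.DataFrame({"gene_id": gene_ids, "beta_hat": beta, "se": se})
    return complete_summary_stats(
        df, {"gene_id": "gene_id", "beta_hat": "beta_hat", "se": "se"}
    )
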