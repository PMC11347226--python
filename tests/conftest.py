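import numpy as np
import pandas as pd
import pytest

from screentriage.quant import LibraryDesign
from screentriage.simulate import ScreenSimParams, simulate_library, simulate_screen_counts


@pytest.fixture(scope="session")
def full_params() -> ScreenSimParams:
    """The published library design: 92 genes x 5 guides + 18 NTCs."""
    return ScreenSimParams(n_genes=92, guides_per_gene=5, n_ntc=18, seed=11)


@pytest.fixture(scope="session")
def full_library(full_params) -> LibraryDesign:
    return simulate_library(full_params)


@pytest.fixture(scope="session")
def small_screen():
    """A small planted screen shared across stats/triage tests."""
    params = ScreenSimParams(
        n_genes=12,
        guides_per_gene=5,
        n_ntc=18,
        contexts=("invitro", "invivo", "fibroblast"),
        replicates_per_context=3,
        depth=2000.0,
        dispersion=0.05,
        planted_effects={
            "G0001": {"invitro": -2.0, "invivo": -2.0, "fibroblast": -0.3},
            "G0002": {"invitro": -2.0},
        },
        seed=5,
    )
    design = simulate_library(params)
    table = simulate_screen_counts(design, params)
    return params, design, table


def nb_counts(rng: np.random.Generator, mu, alpha: float, size) -> np.ndarray:
    """NB(mu, var = mu + alpha mu^2) draws; Poisson when alpha = 0."""
    if alpha == 0:
        return rng.poisson(mu, size=size)
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + np.asarray(mu, dtype=float)), size=size)


@pytest.fixture
def null_count_matrix():
    """Null NB count matrix (no effects), 3 treated vs 3 vehicle."""
    rng = np.random.default_rng(42)
    counts = pd.DataFrame(
        nb_counts(rng, 1000.0, 0.05, (400, 6)), columns=[f"s{i}" for i in range(6)]
    )
    groups = pd.Series(["treated"] * 3 + ["vehicle"] * 3, index=counts.columns)
    return counts, groups
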