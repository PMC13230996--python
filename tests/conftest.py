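import numpy as np
import pandas as pd
import pytest

from csitme import synthdata
from csitme.core_io import ExpressionMatrix


@pytest.fixture(scope="session")
def planted_cohort():
    """Small two-cell-type cohort with one planted bin9 interaction."""
    cfg = synthdata.SimulationConfig(
        n_cell_types=2, n_genes=250, n_samples=300, k_true=3,
        planted_csis=(synthdata.PlantedCSI("ct1", 0, "ct2", 1, "bin9", 1.0),),
        seed=11,
    )
    return synthdata.gen_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no planted interactions (survival independent of states)."""
    cfg = synthdata.SimulationConfig(
        n_cell_types=2, n_genes=150, n_samples=250, k_true=3, seed=7
    )
    return synthdata.gen_cohort(cfg)


@pytest.fixture
def tiny_expr():
    vals = pd.DataFrame(
        [[1.0, 2.0], [3.0, 4.5], [0.0, 7.0]],
        index=["g1", "g2", "g3"], columns=["s1", "s2"],
    )
    return ExpressionMatrix(cell_type="toy", values=vals)


def planted_source_matrix(n_genes, n_samples, k, noise_sd, seed):
    """Expression with k planted Laplace sources (helper for recovery tests)."""
    rng = np.random.default_rng(seed)
    S = rng.laplace(0, 1 / np.sqrt(2), size=(k, n_samples))
    A = rng.standard_normal((n_genes, k))
    base = rng.uniform(2, 8, n_genes)
    logx = base[:, None] + A @ S + rng.normal(0, noise_sd, (n_genes, n_samples))
    tpm = np.clip(2.0 ** logx - 1.0, 0, None)
    expr = ExpressionMatrix(
        cell_type="sim",
        values=pd.DataFrame(
            tpm,
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"s{j}" for j in range(n_samples)],
        ),
    )
    return expr, S
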