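import numpy as np
import pytest

import lupine as lp


def make_qm(values, protein_ids=None, sample_ids=None, **kwargs) -> lp.QuantMatrix:
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return lp.QuantMatrix(
        values=values,
        protein_ids=protein_ids or [f"P{i}" for i in range(n)],
        sample_ids=sample_ids or [f"S{j}" for j in range(m)],
        **kwargs,
    )


@pytest.fixture
def tiny_qm() -> lp.QuantMatrix:
    """4 proteins × 3 samples with two missing entries."""
    values = np.array(
        [
            [1.0, 2.0, np.nan],
            [4.0, np.nan, 6.0],
            [7.0, 8.0, 9.0],
            [0.5, 1.5, 2.5],
        ]
    )
    return make_qm(values)


@pytest.fixture(scope="session")
def normal_qm() -> lp.QuantMatrix:
    """1,000 × 200 matrix of i.i.d. standard-normal values, no missingness."""
    rng = np.random.default_rng(2024)
    return lp.QuantMatrix(
        values=rng.standard_normal((1000, 200)),
        protein_ids=[f"P{i}" for i in range(1000)],
        sample_ids=[f"S{j}" for j in range(200)],
    )


@pytest.fixture(scope="session")
def default_sim():
    """Observed matrix + ground truth from the default simulation spec."""
    return lp.simulate_cohorts(lp.SimSpec(seed=11))


@pytest.fixture(scope="session")
def sim_masks(default_sim):
    observed, _ = default_sim
    return lp.mnar_partition(observed, lp.PartitionParams(seed=1))


@pytest.fixture(scope="session")
def fitted_ensemble(default_sim, sim_masks):
    """Three small models trained on the default simulated matrix."""
    observed, _ = default_sim
    cfg = lp.ModelConfig(
        n_protein_factors=16,
        n_sample_factors=16,
        n_hidden_layers=1,
        n_nodes_per_layer=64,
        max_epochs=200,
    )
    return lp.fit_ensemble(
        observed, sim_masks, n_models=3, seed=7, configs=[cfg] * 3
    )
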