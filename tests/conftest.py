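import numpy as np
import pytest

from beeadmix import admixture, simulate


@pytest.fixture(scope="session")
def small_study():
    """A modest reference + Panama-admixed cohort shared across tests."""
    cfg = simulate.SimulationConfig(seed=1, n_sites=1200)
    return simulate.simulate_admixture_study(
        cfg, preset="panama", n_references=8, n_admixed=8
    )


@pytest.fixture(scope="session")
def labeled_model(small_study):
    """A fitted, lineage-labeled K=4 model on the small cohort."""
    model = admixture.fit_admixture(
        small_study.ds, k=4, n_restarts=4, seed=1, search_iters=60,
        max_iter=600, tol=1e-5,
    )
    ref_map = {
        i: row.population
        for i, row in small_study.sample_info.iterrows()
        if row.role == "reference"
    }
    return admixture.label_clusters(model, ref_map)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
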