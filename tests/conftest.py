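import numpy as np
import pytest

import geoconn as g


@pytest.fixture(scope="session")
def default_cohort():
    """Reference-design cohort (195 subjects) with 4 labeled components."""
    cfg = g.CohortConfig(component_labels=("DMN", "OTC", "PVC", "DAN"), seed=11)
    return cfg, g.generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_edges(default_cohort):
    _, cohort = default_cohort
    return g.compute_edge_vectors(cohort.timeseries)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
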