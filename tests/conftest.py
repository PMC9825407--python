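import numpy as np
import pytest

import cytoresponse as cr
from cytoresponse.som import pool_cells

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale cohort: 4 patients, 3 batches, 150 cells per sample."""
    return cr.CohortSpec(n_patients=4, n_batches=3, cells_per_sample=150, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return cr.generate_cohort(small_spec)


@pytest.fixture(scope="session")
def normalized_small(small_cohort, small_spec):
    panel = small_spec.panel
    order = list(small_cohort.manifest["sample_id"])
    tables, maps = cr.normalize_cohort(
        [small_cohort.samples[s] for s in order],
        small_cohort.references(),
        "B3",
        panel,
    )
    return dict(zip(order, tables)), maps


@pytest.fixture(scope="session")
def trained_model(normalized_small, small_spec):
    panel = small_spec.panel
    training = [
        t
        for t in normalized_small[0].values()
        if (t.sample_role == "patient" and t.timepoint_h == 0.0)
        or t.sample_role == "healthy_donor"
    ]
    X = pool_cells(training, panel.clustering, seed=0)
    model = cr.train_som(X, panel, cr.SOMConfig(seed=0))
    return cr.metacluster(model, k=10, seed=0), training, X
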