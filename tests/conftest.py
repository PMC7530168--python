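import numpy as np
import pytest

import connectopred as cp
from connectopred.backbone import build_backbone
from connectopred.models import TLCNNSpec, TrainConfig

#: planted effect edges used across learning/interpretation tests:
#: two positive and one negative score-coupled connection
PLANTED_EDGES = ((10, 60, 0.8), (37, 50, 0.8), (25, 72, -0.8))


@pytest.fixture(scope="session")
def atlas():
    return cp.load_atlas()


@pytest.fixture(scope="session")
def shared_backbone():
    """One frozen backbone per test session (feature cache is shared)."""
    return build_backbone()


@pytest.fixture(scope="session")
def null_cohort():
    """Small cohort with no planted effects."""
    return cp.generate_cohort(cp.GeneratorConfig(n=40, seed=7))


@pytest.fixture(scope="session")
def planted_cohort():
    """Cohort with strongly score-coupled edges (separable)."""
    return cp.generate_cohort(
        cp.GeneratorConfig(n=40, effect_edges=PLANTED_EDGES, seed=3)
    )


@pytest.fixture(scope="session")
def tiny_fitted_tlcnn(planted_cohort, shared_backbone):
    """A cheap trained TL-CNN shared by model/interpretation tests."""
    spec = TLCNNSpec(
        train_config=TrainConfig(epochs=3, seed=0), backbone=shared_backbone
    )
    train = planted_cohort.subset(range(30))
    val = planted_cohort.subset(range(30, 40))
    return spec.fit(train, val)
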