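import numpy as np
import pandas as pd
import pytest

from crossneuro.homology import (
    load_homology_registry,
    load_reference_effects,
    pair_effects,
    reference_effect_tables,
)
from crossneuro.synthetic import CohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def registry():
    return load_homology_registry()


@pytest.fixture(scope="session")
def reference_effects():
    return load_reference_effects()


@pytest.fixture(scope="session")
def paired_reference(registry):
    human, mouse = reference_effect_tables()
    return pair_effects(human, mouse, registry)


@pytest.fixture()
def small_human_cohort():
    """Quick human-like cohort: 60/sex, 10 regions, a modest planted effect."""
    spec = CohortSpec(
        n_female=60,
        n_male=60,
        region_labels=[f"r{i}" for i in range(10)],
        true_sex_beta=0.3,
        ttv_sex_shift=1.0,
        seed=7,
    )
    return simulate_cohort(spec, "human")


def make_mouse_cohort(n_per_sex=60, n_regions=10, seed=0, **kw):
    spec = CohortSpec(
        n_female=n_per_sex,
        n_male=n_per_sex,
        region_labels=[f"r{i}" for i in range(n_regions)],
        age_range=(56.0, 90.0),
        seed=seed,
        **kw,
    )
    return simulate_cohort(spec, "mouse")
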