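import numpy as np
import pytest

from devgeom import synthgen
from devgeom.rsm import SimilarityMatrix


def tiny_spec(**overrides) -> synthgen.CohortSpec:
    """Desk-scale cohort spec used across the suite."""
    defaults = dict(n_children=4, n_adults=4, n_vertices=60, seed=11)
    defaults.update(overrides)
    return synthgen.CohortSpec(**defaults)


def null_spec(**overrides) -> synthgen.CohortSpec:
    """Structureless cohort: all category structure strengths at zero."""
    defaults = dict(
        n_children=4,
        n_adults=4,
        n_vertices=40,
        animacy_strength=0.0,
        word_axis_strength=0.0,
        subject_noise_sd=0.0,
        seed=29,
    )
    defaults.update(overrides)
    return synthgen.CohortSpec(**defaults)


def random_symmetric_sm(seed: int) -> SimilarityMatrix:
    rng = np.random.default_rng(seed)
    m = rng.uniform(-0.9, 0.9, size=(5, 5))
    return SimilarityMatrix(values=(m + m.T) / 2)


@pytest.fixture(scope="session")
def small_cohort():
    return synthgen.generate_cohort(tiny_spec())


@pytest.fixture(scope="session")
def rh_vlpfc_adults(small_cohort):
    return synthgen.subset(small_cohort, "adult", "RH", "VLPFC")
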