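import numpy as np
import pandas as pd
import pytest

from sphingonet import CohortConfig, LipidMatrix, SpeciesPanel, default_species_panel, generate_cohort
from sphingonet.panel import parse_species_id


@pytest.fixture(scope="session")
def panel():
    return default_species_panel()


@pytest.fixture(scope="session")
def mini_panel():
    """Two-class 4+4 species panel for correlation simulation studies."""
    ids = ["CER16", "CER18", "CER20", "CER22", "LCER14", "LCER16", "LCER18", "LCER22"]
    return SpeciesPanel(tuple(parse_species_id(s) for s in ids))


@pytest.fixture(scope="session")
def small_cohort():
    """One modest synthetic cohort shared across read-only tests."""
    cfg = CohortConfig(n_subjects=500, seed=11)
    clinical, matrix, labels = generate_cohort(cfg)
    return cfg, clinical, matrix, labels


def make_matrix(values, species, classes, subjects=None):
    """Tiny LipidMatrix from an array + explicit class assignment."""
    values = np.asarray(values, dtype=float)
    idx = subjects if subjects is not None else pd.RangeIndex(values.shape[0], name="subject_id")
    abund = pd.DataFrame(values, index=idx, columns=species)
    return LipidMatrix(abund, pd.Series(classes, index=species, name="class_id"))


@pytest.fixture
def toy_matrix_factory():
    return make_matrix
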