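import numpy as np
import pytest

from hbosprof.hbos_model import fit_model
from hbosprof.synthetic import (
    HAIRPIN_SPEC,
    HELIX_SPEC,
    TRIPEPTIDE_SPEC,
    build_peptide,
    default_generative_spec,
    sample_features,
)


@pytest.fixture(scope="session")
def tripeptide():
    """Gly-Leu-Ser ideal-geometry tripeptide."""
    return build_peptide(TRIPEPTIDE_SPEC, entry_id="TRIP")


@pytest.fixture(scope="session")
def helix():
    """Ideal alpha-helical 12-mer (phi=303, psi=313)."""
    return build_peptide(HELIX_SPEC, entry_id="HELX")


@pytest.fixture(scope="session")
def hairpin():
    """Antiparallel beta-hairpin 14-mer with a type I' turn."""
    return build_peptide(HAIRPIN_SPEC, entry_id="HAIR")


@pytest.fixture(scope="session")
def gen_spec():
    return default_generative_spec()


@pytest.fixture(scope="session")
def small_records(gen_spec):
    return sample_features(gen_spec, 6000, seed=7)


@pytest.fixture(scope="session")
def small_model(small_records):
    return fit_model(small_records)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
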