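import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from ta3scan.itc import BindingModel, TitrationSetup
from ta3scan.synthetic import FamilySpec, make_toxin_family


@pytest.fixture(scope="session")
def table2_setup() -> TitrationSetup:
    """The titration geometry used throughout: 3 uM RNA in a 1.4 mL cell,
    40 uM protein in the syringe, 30 x 8 uL injections, 15 C."""
    return TitrationSetup.uniform(3.0, 40.0, 30, 8.0)


@pytest.fixture(scope="session")
def two_site_model() -> BindingModel:
    return BindingModel.two_site_sequential(2.08e-9, 0.18e-9, -30.25, -44.38)


@pytest.fixture(scope="session")
def one_site_model() -> BindingModel:
    return BindingModel.one_site(47.3e-9, -35.75)


@pytest.fixture(scope="session")
def five_plus_two_family():
    """Five 3-member clusters plus two singletons, 97%/80% identity design."""
    spec = FamilySpec(
        n_clusters=7,
        members_per_cluster=[3, 3, 3, 3, 3, 1, 1],
        seq_length=150,
        within_identity=0.97,
        between_identity=0.80,
        seed=11,
    )
    return make_toxin_family(spec)


def random_rna(rng: np.random.Generator, n: int, alphabet: str = "ACGU") -> str:
    return "".join(alphabet[i] for i in rng.integers(len(alphabet), size=n))


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(4, size=n))


def random_protein(rng: np.random.Generator, n: int) -> str:
    aa = "ACDEFGHIKLMNPQRSTVWY"
    return "".join(aa[i] for i in rng.integers(20, size=n))
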