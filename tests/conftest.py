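import numpy as np
import pytest

from pepforge.fixtures import (
    FamilySpec, generate_families, generate_tagged_db, label_families,
)
from pepforge.peptide_io import Peptide, PeptideDataset


@pytest.fixture(scope="session")
def family_dataset():
    """Small labeled homologous-family dataset with ground-truth map."""
    spec = FamilySpec(
        n_families=10, family_size_min=5, family_size_max=5,
        mutation_rate=0.1, seed_length_min=25, seed_length_max=35, seed=7,
    )
    ds, fam = generate_families(spec)
    return label_families(ds, fam, seed=7), fam


@pytest.fixture(scope="session")
def tagged_db():
    return generate_tagged_db(n=1000, seed=11)


@pytest.fixture
def toy_dataset():
    return PeptideDataset(
        [
            Peptide("p1", "ACDEFGHIKL", label=1),
            Peptide("p2", "ACDEFGHIKM", label=1),
            Peptide("p3", "WWWWYYYYRR", label=0),
            Peptide("p4", "KLMNPQRSTV", label=0),
        ],
        name="toy",
    )


@pytest.fixture(scope="session")
def separable_vectors():
    """Linearly separable vectors with a wide class margin, id-keyed."""
    rng = np.random.default_rng(5)
    vectors, labels = {}, {}
    for i in range(60):
        label = i % 2
        v = rng.normal(0, 0.3, size=8)
        v[0] += 3.0 if label else -3.0
        vectors[f"s{i:02d}"] = v
        labels[f"s{i:02d}"] = label
    return vectors, labels
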