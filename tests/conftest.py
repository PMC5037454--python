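import pytest

from hydclass.refdb import ClassLabel, ReferenceDatabase, SequenceRecord
from hydclass.synthetic import FamilySpec, default_reference_specs, generate_reference


@pytest.fixture(scope="session")
def small_reference():
    """3 well-separated short families + 1 decoy family, with mock domains."""
    specs = [
        FamilySpec(ClassLabel.parse("1a"), n_members=6, seed_length=80,
                   substitution_rate=0.1, indel_rate=0.0, rng_seed=11),
        FamilySpec(ClassLabel.parse("3b"), n_members=6, seed_length=80,
                   substitution_rate=0.1, indel_rate=0.0, rng_seed=12),
        FamilySpec(ClassLabel.parse("A"), n_members=6, seed_length=80,
                   substitution_rate=0.1, indel_rate=0.0, rng_seed=13),
    ]
    decoys = [
        FamilySpec(ClassLabel.parse("Nuo"), n_members=6, seed_length=80,
                   substitution_rate=0.1, indel_rate=0.0, rng_seed=14),
    ]
    return generate_reference(specs, decoys)


@pytest.fixture(scope="session")
def small_db(small_reference):
    return small_reference[0]


@pytest.fixture(scope="session")
def mock_backend(small_reference):
    return small_reference[1]


@pytest.fixture(scope="session")
def toy_db():
    """Tiny hand-built database for exact-value tests."""
    records = [
        SequenceRecord(id="a", residues="MKLVINGKQWE"),
        SequenceRecord(id="b", residues="MKLVINGKQWD"),
        SequenceRecord(id="c", residues="PPPWWWCCCHH"),
    ]
    labels = {
        "a": ClassLabel.parse("1a"),
        "b": ClassLabel.parse("1a"),
        "c": ClassLabel.parse("3b"),
    }
    return ReferenceDatabase(records=records, labels=labels)
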