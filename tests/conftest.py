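import pytest

from ecaudit.simulate import (
    SuperfamilyConfig,
    gen_paper_scale_fixture,
    gen_superfamily,
)


@pytest.fixture(scope="session")
def paper_fixture():
    """453-record evidence fixture with the audited study's structure."""
    return gen_paper_scale_fixture(rng_seed=11)


@pytest.fixture(scope="session")
def two_subgroup_family():
    """Small two-subgroup paralog family (20 sequences each, L=120)."""
    cfg = SuperfamilyConfig(
        n_subgroups=2,
        seqs_per_subgroup=20,
        seq_length=120,
        within_identity=0.8,
        between_identity=0.45,
        rng_seed=1,
    )
    return gen_superfamily(cfg)


@pytest.fixture(scope="session")
def ten_subgroup_family():
    """Ten-subgroup family with 3-residue planted signatures (L=120)."""
    cfg = SuperfamilyConfig(
        n_subgroups=10,
        seqs_per_subgroup=5,
        seq_length=120,
        within_identity=0.8,
        between_identity=0.45,
        signature_positions=3,
        rng_seed=7,
    )
    return gen_superfamily(cfg)
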