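import pytest

from refdbkit.synth import FixtureSpec, generate_reference_db


@pytest.fixture(scope="session")
def small_db():
    """12 species x 5 members, clean (no injected defects)."""
    spec = FixtureSpec(seed=11, n_genera_per_family=2, n_species_per_genus=3,
                       seqs_per_species=5)
    return generate_reference_db(spec)


@pytest.fixture(scope="session")
def noisy_db():
    """Database with planted quality defects and ambiguous labels."""
    spec = FixtureSpec(
        seed=23,
        homopolymer_injection=(9, 0.1),
        ambiguous_base_injection=(6, 0.1),
        truncation_injection=(100, 0.1),
        ambiguous_label_fraction=0.25,
    )
    return generate_reference_db(spec)
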