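import pytest

from crossvar import GenomeLayout, end_to_end_fixture


@pytest.fixture(scope="session")
def clean_sim():
    return end_to_end_fixture("clean", seed=7)


@pytest.fixture(scope="session")
def paperlike_sim():
    return end_to_end_fixture("paperlike", seed=11)


@pytest.fixture(scope="session")
def adversarial_sim():
    return end_to_end_fixture("adversarial", seed=13)


@pytest.fixture
def small_layout():
    return GenomeLayout(
        {"chr1": 5_000_000, "chr2": 4_000_000, "chrX": 2_000_000},
        sex_chroms={"chrX"},
    )
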