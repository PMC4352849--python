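import pytest

import strpop as sp


@pytest.fixture(scope="session")
def han_freqs_printed():
    """Bundled 21-locus frequency table, printed 4-decimal values."""
    return sp.datasets.load_han_guanzhong_frequencies()


@pytest.fixture(scope="session")
def han_freqs_counts():
    """Bundled table with frequencies re-derived from integer gene-copy counts."""
    return sp.datasets.load_han_guanzhong_frequencies(count_reconstructed=True)


@pytest.fixture(scope="session")
def han_params():
    """Printed per-locus parameter rows (PD, PIC, PE, TPI, HO, HE, HWE p)."""
    return sp.datasets.load_han_guanzhong_parameters()


@pytest.fixture(scope="session")
def small_study():
    """A small deterministic multi-population study for structural tests."""
    cfg = sp.SimConfig(
        n_populations=3,
        n_individuals=60,
        n_loci=6,
        alleles_per_locus=(3, 8),
        fst=0.03,
        microvariant_rate=0.25,
        seed=20240917,
    )
    return sp.make_study_fixture(cfg)
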