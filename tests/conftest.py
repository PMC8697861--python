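import numpy as np
import pytest

from crisprstop.core import GenomePanel, NucleotideSequence, CodingRegion
from crisprstop.synthetic_data import ConservedSite, make_provirus_family, make_test_amplicon


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def small_panel():
    """3-subtype panel with one conserved and one subtype-private stop-guide site."""
    panel, truth = make_provirus_family(
        seed=1,
        conserved_sites=(
            ConservedSite(gene="gag", codon_index=30, codon="CAG"),
            ConservedSite(gene="pol", codon_index=60, codon="CAA", shared_by=(0,)),
        ),
    )
    return panel, truth


@pytest.fixture(scope="session")
def amplicon():
    """Deterministic 180-nt amplicon with a single-C editing window ('+' guide)."""
    return make_test_amplicon(seed=5)


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
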