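import numpy as np
import pytest

from msh3rep.locus import default_locus, reference_bank


@pytest.fixture(scope="session")
def locus():
    return default_locus()


@pytest.fixture(scope="session")
def bank(locus):
    return reference_bank(locus)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_hap(locus, allele, alts=()):
    """Haplotype helper: everything ref except the listed alt variant ids."""
    from msh3rep.locus import Haplotype

    return Haplotype(
        allele, {v.id: ("alt" if v.id in alts else "ref") for v in locus.variants}
    )
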