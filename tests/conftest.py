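import pytest

from cicfusion.reference import DomainAnnotation
from cicfusion.simulate import make_toy_reference


@pytest.fixture(scope="session")
def toy5():
    """Toy 5' partner: 40-codon CDS with a C-terminal focal domain."""
    return make_toy_reference(
        "CIC",
        utr5_len=12,
        n_codons=40,
        utr3_len=15,
        domains=(DomainAnnotation("C1", 30, 35, "synthetic"),),
        seed=11,
    )


@pytest.fixture(scope="session")
def toy3():
    """Toy 3' partner: 30-codon CDS, long 3' UTR, one N-terminal domain."""
    return make_toy_reference(
        "DUX4",
        utr5_len=8,
        n_codons=30,
        utr3_len=60,
        domains=(DomainAnnotation("HOX1", 5, 10, "synthetic"),),
        seed=22,
    )
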