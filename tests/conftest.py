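import numpy as np
import pytest

from orfstat import CodonUsage
from orfstat.rcodon import RcodonSpec, make_fixture, simulate, synthetic_usage


@pytest.fixture
def uniform_usage() -> CodonUsage:
    return CodonUsage.uniform()


@pytest.fixture
def skewed_usage() -> CodonUsage:
    """A strictly positive, clearly non-uniform codon usage."""
    rng = np.random.default_rng(42)
    return CodonUsage(rng.dirichlet(np.full(64, 2.0)), source="dirichlet-42")


@pytest.fixture
def bacterial_usage() -> CodonUsage:
    return synthetic_usage(gc_content=0.5, bias=0.4, seed=3)


@pytest.fixture
def toy_genome(tmp_path, bacterial_usage):
    """A small annotated genome whose genes are stop-free Rcodon segments.

    Gives broad codon coverage so all six frame probabilities are strictly
    positive; genes alternate strands with short random spacers.
    """
    import orfstat

    rng = np.random.default_rng(9)
    genes = []
    for i in range(20):
        body = simulate(RcodonSpec(bacterial_usage, 3 * int(rng.integers(50, 300)), seed=100 + i))
        codons = [body[j : j + 3] for j in range(0, len(body), 3)]
        codons = [c for c in codons if c not in ("TAA", "TAG", "TGA")]
        genes.append(("ATG" + "".join(codons) + "TAA", "+" if i % 2 == 0 else "-"))
    spacers = [simulate(RcodonSpec(bacterial_usage, 30, seed=500 + i)) for i in range(21)]
    path = tmp_path / "toy.gb"
    make_fixture(genes, spacers=spacers, path=path)
    return orfstat.read_genome(path)
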