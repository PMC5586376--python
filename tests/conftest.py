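import numpy as np
import pytest

from mutdet.genes import GeneModel, IntervalSet


@pytest.fixture
def tiny_genome():
    """12 bp sequence with two CG dinucleotides (positions 3-4 and 9-10)."""
    return {"chr1": "TTACGCATGCGA"}


@pytest.fixture
def tiny_gene():
    return GeneModel("g1", "chr1", "+", [(0, 12)])


def random_reference(rng: np.random.Generator, length: int,
                     n_exons: int = 3, n_islands: int = 2):
    """A random sequence with random exons and islands, for oracle tests."""
    seq = "".join(rng.choice(list("ACGTN"), size=length,
                             p=[0.28, 0.2, 0.2, 0.28, 0.04]))
    cuts = sorted(rng.integers(0, length, 2 * n_exons).tolist())
    exons = [(cuts[2 * i], cuts[2 * i + 1]) for i in range(n_exons)
             if cuts[2 * i] < cuts[2 * i + 1]]
    if not exons:
        exons = [(0, length)]
    ivs = []
    for _ in range(n_islands):
        s = int(rng.integers(0, length))
        e = min(s + int(rng.integers(1, max(length // 4, 2))), length)
        if s < e:
            ivs.append((s, e))
    islands = IntervalSet({"chr1": ivs} if ivs else {})
    strand = "+" if rng.random() < 0.5 else "-"
    gene = GeneModel("g", "chr1", strand, exons)
    return seq, gene, islands
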