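import numpy as np
import pytest

from regulonkit.genome import GeneFeature, GenomeRecord


def make_genome(genome_id, contig_seq, features, contig_id="c1"):
    return GenomeRecord(genome_id, [(contig_id, contig_seq)], features)


def random_dna(rng, n, gc=0.5):
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join("ACGT"[i] for i in rng.choice(4, size=n, p=p))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_genome():
    """Three + strand genes and one - strand gene on a 2 kb contig."""
    r = np.random.default_rng(7)
    seq = random_dna(r, 2000)
    feats = [
        GeneFeature("gA", "c1", 100, 400, "+", translation="M" * 99),
        GeneFeature("gB", "c1", 450, 700, "+", translation="M" * 83),
        GeneFeature("gC", "c1", 780, 1000, "+", translation="M" * 73),
        GeneFeature("gD", "c1", 1200, 1500, "-", translation="M" * 99),
    ]
    return make_genome("toy", seq, feats)
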