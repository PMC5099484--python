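import numpy as np
import pytest

from mitokit.seqio import Feature, GenomeRecord
from mitokit.simulate import SimConfig, simulate_mitogenome


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture()
def toy_record():
    """Small circular record with two genes and an intron-bearing gene."""
    seq = list("ACGT" * 500)  # 2000 bp, overwritten below
    g1 = "ATG" + "GCT" * 30 + "TAA"  # 96 bp
    g2 = "ATG" + "CCA" * 40 + "TGA"  # 126 bp
    seq[100 : 100 + len(g1)] = list(g1)
    seq[300 : 300 + 60] = list(g2[:60])
    seq[460 : 460 + len(g2) - 60] = list(g2[60:])
    feats = [
        Feature("g1", "CDS", "+", [(100, 100 + len(g1))]),
        Feature("g2", "CDS", "+", [(300, 360), (460, 460 + len(g2) - 60)]),
        Feature("g2", "intron", "+", [(360, 460)], notes={"intron_index": 1}),
        Feature("trnA", "tRNA", "+", [(700, 770)]),
        Feature("rrn5", "rRNA", "-", [(900, 1020)]),
    ]
    return GenomeRecord("toy", "".join(seq), "circular", feats)


@pytest.fixture(scope="session")
def planted_genome():
    """Mid-size genome with one of everything planted (session-cached)."""
    config = SimConfig(
        seed=421,
        genome_length=30_000,
        gene_catalog=[("nad1", 150), ("cox1", 200, (180, 180, 240)), ("atp9", 90)],
        planted_ssrs=[("TTTTA", 5), ("A", 9)],
        planted_tandems=[("TAAGTGAAATAAAAT", 2)],
        planted_dispersed=[(1200, 99.6, "DR", 2), (600, 99.0, "IR", 2)],
    )
    record, truth = simulate_mitogenome(config)
    return config, record, truth
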