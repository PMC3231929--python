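from __future__ import annotations

import pytest

from fgdpipe.pairwise import all_vs_all
from fgdpipe.simulate import demo_config, simulate_pangenome

DEMO_SEED = 1


@pytest.fixture(scope="session")
def demo_sim():
    """The bundled 5-genome demonstration pangenome, fixed seed."""
    cfg = demo_config(seed=DEMO_SEED)
    genomes, proteomes, truth = simulate_pangenome(cfg)
    return cfg, genomes, proteomes, truth


@pytest.fixture(scope="session")
def demo_table(demo_sim):
    _, _, proteomes, _ = demo_sim
    return all_vs_all(proteomes)


@pytest.fixture(scope="session")
def demo_genome_map(demo_sim):
    _, genomes, _, _ = demo_sim
    return {g.genome_id: g for g in genomes}


MINI_GENBANK = """\
LOCUS       TOY001                    100 bp    DNA     linear   BCT 01-JAN-2000
DEFINITION  toy record.
ACCESSION   TOY001
FEATURES             Location/Qualifiers
     source          1..100
     CDS             1..30
                     /locus_tag="TOY_0001"
                     /product="hypothetical protein"
                     /translation="MKLVVLGSDG"
     CDS             complement(41..70)
                     /locus_tag="TOY_0002"
                     /product="transposase"
     CDS             72..95
                     /locus_tag="TOY_0003"
                     /product="decayed thing"
                     /pseudo
ORIGIN
        1 atgaaactgg ttgttctggg ttctgacggc taatttacca gaccatagcg ataacgcata
       61 gagtgagtaa ccatggctaa cgcatagagt gagtaaccat
//
"""


@pytest.fixture()
def mini_genbank(tmp_path):
    p = tmp_path / "toy.gbk"
    p.write_text(MINI_GENBANK)
    return p
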