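import numpy as np
import pytest

from prgtyper import (ScoringParams, SimConfig, build_prg_from_db,
                      generate_allele_db, merge_gene)
from prgtyper.kmer import build_graph_kmer_index
from prgtyper.prg import build_gene_graph
from prgtyper.simulate import make_toy_fixture


def quals_of(qstring):
    return [ord(c) - 33 for c in qstring]


@pytest.fixture(scope="session")
def toy():
    return make_toy_fixture()


@pytest.fixture(scope="session")
def toy_seg(toy):
    return merge_gene([toy["exonic"]], toy["genomic"], toy["regional"])


@pytest.fixture(scope="session")
def toy_prg(toy_seg):
    return build_gene_graph(toy_seg, pbs_exons=(1,))


@pytest.fixture(scope="session")
def std_cfg():
    """The default study conditions (3 loci x 10 alleles, 2x100bp)."""
    return SimConfig(seed=3)


@pytest.fixture(scope="session")
def std_db(std_cfg):
    return generate_allele_db(std_cfg)


@pytest.fixture(scope="session")
def std_prg(std_db):
    # a shorter spacer keeps the session graph compact; spacer levels
    # carry no k-mers either way
    return build_prg_from_db(std_db, spacer_length=300)


@pytest.fixture(scope="session")
def std_index(std_prg):
    return build_graph_kmer_index(std_prg, 31)


@pytest.fixture(scope="session")
def params():
    return ScoringParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
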