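import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prgtyper import (FilterThresholds, SimConfig, build_background_kmer_set,
                      build_graph_kmer_index, build_prg_from_db, canonical,
                      filter_read_pair, generate_allele_db, make_background,
                      revcomp, simulate_diploid_reads)
from prgtyper.bruteforce import enumerate_path_sequences
from prgtyper.errors import IndexError_
from prgtyper.kmer import BackgroundKmerSet
from prgtyper.merge import Segment, SegmentedGene
from prgtyper.prg import build_gene_graph
from prgtyper.simulate import simulate_background_pairs


def prg_of(*rows):
    seqs = {f"G*{i + 1:02d}": r for i, r in enumerate(rows)}
    seg = SegmentedGene(locus="G", segments=[Segment("genomic", "exon_1", seqs)])
    return build_gene_graph(seg, pbs_exons=(1,))


class TestGraphKmerIndex:
    def test_linear_graph_indexes_n_minus_k_plus_one_positions(self):
        idx = build_graph_kmer_index(prg_of("ACGTACGT"), 4)
        assert idx.total_kmers == 5
        for km, walks in idx.entries.items():
            for _start, labels in walks:
                assert labels.replace("-", "") == km

    def test_snp_bubble_variants_match_path_enumeration(self):
        prg = prg_of("ACGTACGT", "ACGGACGT")
        idx = build_graph_kmer_index(prg, 4)
        expected = set()
        for path in enumerate_path_sequences(prg.labels):
            expected.update(path[i:i + 4] for i in range(len(path) - 3))
        assert set(idx.entries) == expected
        # every window covering the bubble column has both variants
        for i in range(1, 4):
            a = "ACGTACGT"[i:i + 4]
            b = "ACGGACGT"[i:i + 4]
            assert a in idx.entries and b in idx.entries and a != b

    def test_kmers_span_graph_encoded_gaps_at_full_length(self):
        prg = prg_of("ACGTACGT", "ACG-ACGT")
        idx = build_graph_kmer_index(prg, 4)
        assert "ACGA" in idx.entries  # spans the deletion
        walks = [w for w in idx.entries["ACGA"] if "-" in w[1]]
        assert walks and all(
            w[1].replace("-", "") == "ACGA" for w in walks)

    def test_index_complete_for_every_allele_substring(self, std_db, std_prg,
                                                       std_index):
        k = std_index.k
        for locus in ["L1"]:
            for a in std_db.allele_ids(locus):
                for _start, frag in std_prg.allele_paths[a]:
                    seq = frag.replace("-", "")
                    for i in range(len(seq) - k + 1):
                        assert seq[i:i + k] in std_index.entries

    def test_spacer_n_kmers_are_excluded(self, std_index):
        assert not any("N" in km for km in std_index.entries)

    def test_blowup_guard_aborts_with_window_diagnostic(self):
        rows = ["".join(np.random.default_rng(s).choice(list("ACGT"), 40))
                for s in range(10)]
        prg = prg_of(*rows)
        with pytest.raises(IndexError_, match="level"):
            build_graph_kmer_index(prg, 31, max_walks_per_window=50)


class TestBackgroundSet:
    def test_palindromic_kmer(self):
        bg = build_background_kmer_set(["ACGT"], 4)
        assert bg.kmers == {"ACGT"}

    def test_reverse_complement_closure(self):
        bg = build_background_kmer_set(["AAAA"], 4)
        assert bg.kmers == {"AAAA", "TTTT"}

    def test_empty_input_gives_empty_set(self):
        assert build_background_kmer_set([], 4).kmers == set()

    def test_n_containing_kmers_skipped(self):
        bg = build_background_kmer_set(["AANAA"], 2)
        assert bg.kmers == {"AA", "TT"}


@pytest.fixture(scope="module")
def small():
    cfg = SimConfig(seed=21, n_loci=1, n_alleles=4, n_genomic=2, coverage=4.0)
    db = generate_allele_db(cfg)
    prg = build_prg_from_db(db, spacer_length=50)
    idx = build_graph_kmer_index(prg, 31)
    return cfg, db, prg, idx


class TestFilter:
    def test_perfect_prg_pair_is_kept(self, small):
        cfg, db, prg, idx = small
        empty_bg = BackgroundKmerSet(31, set())
        thr = FilterThresholds()
        cfg0 = SimConfig(**{**cfg.__dict__, "error_rate": 0.0})
        pairs = simulate_diploid_reads(db, {"L1": ("L1*01", "L1*02")}, cfg0,
                                       np.random.default_rng(5))
        for p in pairs[:20]:
            d = filter_read_pair(p.r1, p.r2, idx, empty_bg, thr)
            assert d.keep and d.positive_fraction == 1.0 and d.has_unique

    def test_background_pair_discarded_by_positive_selection(self, small):
        cfg, db, prg, idx = small
        rng = np.random.default_rng(6)
        ref = make_background(5000, rng)
        bg = build_background_kmer_set([ref], 31)
        thr = FilterThresholds()
        for p in simulate_background_pairs(ref, 20, cfg, rng):
            d = filter_read_pair(p.r1, p.r2, idx, bg, thr)
            assert not d.keep and d.reason == "positive_selection"

    def test_shared_homology_discarded_by_negative_selection(self, small):
        """A region present verbatim in both PRG and background yields
        pairs that pass positive selection but fail both negative
        clauses."""
        cfg, db, prg, idx = small
        rng = np.random.default_rng(7)
        shared = db.full_haplotype("L1", "L1*01")
        ref = make_background(2000 + len(shared), rng, embed=shared)
        bg = build_background_kmer_set([ref], 31)
        thr = FilterThresholds()
        pos = ref.find(shared)
        reasons = set()
        for p in simulate_background_pairs(
                ref, 30, cfg, rng, region=(pos + 50, pos + len(shared) - 50)):
            d = filter_read_pair(p.r1, p.r2, idx, bg, thr)
            assert not d.keep
            reasons.add(d.reason)
        assert reasons == {"negative_selection"}

    def test_mate_shorter_than_k_reported_too_short(self, small):
        _, _, _, idx = small
        d = filter_read_pair("ACGT", "A" * 40, idx,
                             BackgroundKmerSet(31, set()), FilterThresholds())
        assert not d.keep and d.reason == "too_short"

    def test_keep_rate_under_one_percent_errors(self, std_db, std_index):
        """Error-free pairs are all kept; at 1% uniform error the keep
        rate stays at or above 95% over 1000+ pairs."""
        cfg1 = SimConfig(**{**std_db.config.__dict__, "error_rate": 0.01,
                            "coverage": 40.0})
        truth = {"L1": ("L1*02", "L1*06"), "L2": ("L2*03", "L2*04"),
                 "L3": ("L3*01", "L3*10")}
        pairs = simulate_diploid_reads(std_db, truth, cfg1,
                                       np.random.default_rng(8))
        assert len(pairs) >= 1000
        empty_bg = BackgroundKmerSet(31, set())
        thr = FilterThresholds()
        kept = sum(filter_read_pair(p.r1, p.r2, std_index, empty_bg, thr).keep
                   for p in pairs)
        assert kept / len(pairs) >= 0.95

    def test_decisions_are_deterministic(self, small):
        cfg, db, prg, idx = small
        rng = np.random.default_rng(9)
        ref = make_background(3000, rng)
        bg = build_background_kmer_set([ref], 31)
        p = simulate_background_pairs(ref, 1, cfg, rng)[0]
        d1 = filter_read_pair(p.r1, p.r2, idx, bg, FilterThresholds())
        d2 = filter_read_pair(p.r1, p.r2, idx, bg, FilterThresholds())
        assert d1 == d2


def test_canonical_is_min_of_strands():
    assert canonical("TTTT") == "AAAA"
    assert canonical("ACGT") == "ACGT"
    assert revcomp("ACGTN") == "NACGT"


dna = st.text(alphabet="ACGT", min_size=1, max_size=40)


@settings(derandomize=True, max_examples=200)
@given(dna)
def test_revcomp_is_an_involution_and_canonical_strand_agnostic(s):
    assert revcomp(revcomp(s)) == s
    assert canonical(s) == canonical(revcomp(s))
    assert canonical(s) <= s


@settings(derandomize=True, max_examples=100)
@given(st.lists(dna, max_size=4), st.integers(min_value=2, max_value=6))
def test_background_set_closed_under_reverse_complement(seqs, k):
    bg = build_background_kmer_set(seqs, k)
    assert {revcomp(km) for km in bg.kmers} == bg.kmers
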