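import numpy as np
import pytest

from prgtyper import (GraphAlignment, InsertSizeModel, PairedAlignment,
                      ScoringParams, align_read, align_read_full,
                      align_read_pair, extend_seed, find_seeds,
                      pair_and_score, phred_to_eps, posterior_and_select,
                      revcomp)
from prgtyper.bruteforce import best_path_alignment_score
from prgtyper.kmer import build_graph_kmer_index
from prgtyper.merge import Segment, SegmentedGene
from prgtyper.prg import build_gene_graph
from prgtyper.simulate import random_prg_fixture, sample_read_from_prg


def prg_of(*rows, locus="G"):
    seqs = {f"{locus}*{i + 1:02d}": r for i, r in enumerate(rows)}
    seg = SegmentedGene(locus=locus, segments=[
        Segment("genomic", "exon_1", seqs)])
    return build_gene_graph(seg, pbs_exons=(1,))


@pytest.fixture(scope="module")
def linear200():
    rng = np.random.default_rng(42)
    seq = "".join(np.array(list("ACGT"))[rng.integers(4, size=200)])
    return seq, prg_of(seq)


class TestSeeds:
    def test_perfect_read_yields_single_covering_seed(self, linear200):
        seq, prg = linear200
        idx = build_graph_kmer_index(prg, 31)
        read = seq[60:110]
        seeds = find_seeds(read, idx, 31)
        assert len(seeds) == 1
        s = seeds[0]
        assert (s.read_start, s.read_end) == (0, 50)
        assert s.start_level == 60
        assert s.labels == read

    def test_mismatch_splits_chain_into_two_seeds(self, linear200):
        seq, prg = linear200
        idx = build_graph_kmer_index(prg, 31)
        read = list(seq[50:150])
        true = read[50]
        read[50] = {"A": "C", "C": "A", "G": "T", "T": "G"}[true]
        read = "".join(read)
        seeds = find_seeds(read, idx, 31)
        spans = sorted((s.read_start, s.read_end) for s in seeds)
        assert spans == [(0, 50), (51, 100)]

    def test_absent_read_gives_no_seeds(self, linear200):
        _, prg = linear200
        idx = build_graph_kmer_index(prg, 31)
        assert find_seeds("A" * 50, idx, 31) == []

    def test_seeds_match_bruteforce_exact_matches(self):
        """Seed spans agree with brute-force enumeration of all exact
        substring/walk matches on a small bubbly graph."""
        from prgtyper.bruteforce import enumerate_path_sequences
        rng = np.random.default_rng(1)
        prg = random_prg_fixture(rng, n_cols=60, n_variant_cols=3)
        idx = build_graph_kmer_index(prg, 8)
        read = sample_read_from_prg(prg, rng, length=30, error_rate=0.1)
        seeds = find_seeds(read, idx, 8)
        paths = enumerate_path_sequences(prg.labels)
        # every maximal >=8bp exact match interval must appear as a seed
        expected = set()
        for i in range(len(read)):
            for j in range(i + 8, len(read) + 1):
                if any(read[i:j] in p for p in paths):
                    expected.add((i, j))
        maximal = {(i, j) for (i, j) in expected
                   if (i - 1, j) not in expected and (i, j + 1) not in expected}
        got = {(s.read_start, s.read_end) for s in seeds}
        assert maximal <= got


class TestExtension:
    def test_error_free_read_scores_sum_of_log_matches(self, linear200):
        seq, prg = linear200
        idx = build_graph_kmer_index(prg, 31)
        read = seq[30:120]
        quals = [30] * len(read)
        params = ScoringParams()
        alns = align_read(read, quals, prg, idx, params)
        best = alns[0]
        eps = phred_to_eps(quals, params.eps_floor)
        assert best.score == pytest.approx(float(np.log1p(-eps).sum()))
        assert all(lab is not None and j is not None
                   for _lvl, lab, j in best.columns)

    def test_gap_edges_are_traversed_free_of_charge(self):
        base = "ACGTACGTTGCAACGTTACGGATC"
        deleted = base[:10] + "---" + base[13:]
        prg = prg_of(base, deleted)
        idx = build_graph_kmer_index(prg, 8)
        read = base[:10] + base[13:]  # the deletion allele's sequence
        quals = [30] * len(read)
        params = ScoringParams()
        alns = align_read(read, quals, prg, idx, params)
        best = alns[0]
        eps = phred_to_eps(quals, params.eps_floor)
        assert best.score == pytest.approx(float(np.log1p(-eps).sum()))
        assert "-" in best.walk  # walk spans the graph-encoded gap

    def test_extension_contains_seed_and_handles_mismatch(self, linear200):
        seq, prg = linear200
        idx = build_graph_kmer_index(prg, 31)
        read = list(seq[50:150])
        read[10] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[10]]
        read = "".join(read)
        quals = [30] * len(read)
        params = ScoringParams()
        alns = align_read(read, quals, prg, idx, params)
        best = alns[0]
        eps = phred_to_eps(quals, params.eps_floor)
        expected = float(np.log1p(-eps).sum()) \
            - float(np.log1p(-eps[10])) + float(np.log(eps[10] / 3))
        assert best.score == pytest.approx(expected)

    def test_score_never_improves_with_an_extra_mismatch(self, linear200,
                                                         rng):
        seq, prg = linear200
        idx = build_graph_kmer_index(prg, 31)
        params = ScoringParams()
        for _ in range(10):
            start = int(rng.integers(0, 100))
            read = seq[start:start + 80]
            quals = [30] * 80
            base = align_read(read, quals, prg, idx, params)[0].score
            pos = int(rng.integers(0, 80))
            mut = list(read)
            mut[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mut[pos]]
            worse = align_read("".join(mut), quals, prg, idx, params)
            assert not worse or worse[0].score <= base + 1e-9


class TestOracleEquivalence:
    def test_ml_score_equals_bruteforce_best_path(self):
        params = ScoringParams()
        rng = np.random.default_rng(77)
        for _ in range(25):
            prg = random_prg_fixture(rng, n_cols=int(rng.integers(50, 110)),
                                     n_variant_cols=int(rng.integers(2, 7)))
            read = sample_read_from_prg(
                prg, rng, length=int(rng.integers(40, 100)),
                error_rate=float(rng.choice([0.0, 0.02, 0.05])))
            quals = rng.integers(15, 41, size=len(read))
            eps = phred_to_eps(quals, params.eps_floor)
            aln = align_read_full(read, quals, prg, params, clip=False)
            oracle = best_path_alignment_score(
                prg.labels, read, eps, params.gap_open, params.gap_extend)
            assert aln.score == pytest.approx(oracle, abs=1e-9)

    def test_strand_symmetry(self):
        """Aligning the reverse complement on the other strand yields
        the mirror alignment with identical score."""
        params = ScoringParams()
        rng = np.random.default_rng(13)
        for _ in range(5):
            prg = random_prg_fixture(rng, n_cols=70, n_variant_cols=3)
            read = sample_read_from_prg(prg, rng, length=50, error_rate=0.02)
            quals = list(rng.integers(20, 41, size=len(read)))
            fwd = align_read_full(read, quals, prg, params, clip=False)
            rev = align_read_full(revcomp(read), quals[::-1], prg, params,
                                  strand="-", clip=False)
            assert fwd.score == pytest.approx(rev.score, abs=1e-9)


def _mk_aln(mate, strand, start, seq, score):
    cols = [(start + i, c, i) for i, c in enumerate(seq)]
    a = GraphAlignment(mate=mate, strand=strand, columns=cols, clip_left=0,
                       clip_right=0, score=score, oriented_seq=seq,
                       oriented_eps=np.full(len(seq), 1e-3))
    return a


class TestPairing:
    def test_cartesian_product_of_candidates(self):
        model = InsertSizeModel(100, 10)
        params = ScoringParams()
        a1s = [_mk_aln(1, "+", s, "ACGT", -1.0) for s in (0, 10, 20)]
        a2s = [_mk_aln(2, "-", s, "TTTT", -2.0) for s in (80, 90)]
        pairs = pair_and_score(a1s, a2s, model, params)
        assert len(pairs) == 6

    def test_proper_pair_at_mean_insert_gets_density_mode(self):
        model = InsertSizeModel(100, 10)
        params = ScoringParams()
        a1 = _mk_aln(1, "+", 0, "ACGT", -1.0)
        a2 = _mk_aln(2, "-", 96, "TTTT", -2.0)
        (pair,) = pair_and_score([a1], [a2], model, params)
        assert pair.proper and pair.insert_size == 100
        assert pair.log_likelihood == pytest.approx(
            -3.0 + model.logpdf(100.0))

    def test_improper_orientation_gets_flat_penalty(self):
        model = InsertSizeModel(100, 10)
        params = ScoringParams()
        a1 = _mk_aln(1, "+", 0, "ACGT", -1.0)
        a2 = _mk_aln(2, "+", 96, "TTTT", -2.0)
        (pair,) = pair_and_score([a1], [a2], model, params)
        assert not pair.proper
        assert pair.log_likelihood == pytest.approx(
            -3.0 + params.improper_pair_penalty)

    def test_empty_candidate_lists_give_empty_output(self):
        assert pair_and_score([], [], InsertSizeModel(100, 10),
                              ScoringParams()) == []


class TestPosterior:
    def _pair(self, ll, start2=50, seq2="TTTT"):
        a1 = _mk_aln(1, "+", 0, "ACGT", ll / 2)
        a2 = _mk_aln(2, "-", start2, seq2, ll / 2)
        return PairedAlignment(a1, a2, start2 + 4, True, ll)

    def test_single_candidate_has_posterior_one_everywhere(self):
        sel, mapq, (q1, q2) = posterior_and_select([self._pair(-5.0)])
        assert mapq == 1.0
        assert np.allclose(q1, 1.0) and np.allclose(q2, 1.0)

    def test_equal_candidates_split_mass_on_divergent_columns(self):
        p1 = self._pair(-5.0, start2=50)
        p2 = self._pair(-5.0, start2=60)
        sel, mapq, (q1, q2) = posterior_and_select([p1, p2])
        assert p1.posterior == pytest.approx(0.5)
        assert p2.posterior == pytest.approx(0.5)
        assert np.allclose(q1, 1.0)   # mate 1 placed identically in both
        assert np.allclose(q2, 0.5)   # mate 2 differs between candidates

    def test_posteriors_sum_to_one(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 12))
            pairs = [self._pair(float(-rng.random() * 40))
                     for _ in range(n)]
            posterior_and_select(pairs)
            assert abs(sum(p.posterior for p in pairs) - 1.0) < 1e-9

    def test_empty_candidate_list_is_an_error(self):
        with pytest.raises(ValueError):
            posterior_and_select([])


class TestReadPairDriver:
    def test_pair_with_seedless_mate_is_unmapped(self, linear200):
        seq, prg = linear200
        idx = build_graph_kmer_index(prg, 31)
        r1 = seq[10:90]
        r2 = "A" * 60
        res = align_read_pair(r1, [30] * 80, r2, [30] * 60, prg, idx,
                              ScoringParams(), InsertSizeModel(150, 30))
        assert res is None

    def test_proper_pair_aligns_and_normalizes(self, linear200):
        seq, prg = linear200
        idx = build_graph_kmer_index(prg, 31)
        r1 = seq[10:90]
        r2 = revcomp(seq[120:190])
        res = align_read_pair(r1, [30] * 80, r2, [30] * 70, prg, idx,
                              ScoringParams(), InsertSizeModel(180, 40))
        sel, mapq, _posq, pairs = res
        assert sel.proper
        assert abs(sum(p.posterior for p in pairs) - 1.0) < 1e-9
        assert sel.insert_size == 180
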