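import math

import numpy as np
import pytest

from prgtyper import (ScoringParams, call_best_guess, genotype_posterior,
                      kmer_coverage, unaccounted_columns)
from prgtyper.genotype import (PairPosterior, ReadEvidence, _genotype_codes,
                               likelihood_matrix, pair_likelihood,
                               read_likelihood)
from prgtyper.merge import Segment, SegmentedGene
from prgtyper.prg import build_gene_graph


def evidence(locus, n_pbs, reads):
    """reads: list of (positions, residue string, eps)."""
    ev = ReadEvidence(locus=locus, pbs_levels=list(range(n_pbs)))
    code = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4, "-": 5}
    for i, (pos, res, eps) in enumerate(reads):
        ev.read_ids.append(f"r{i}")
        ev.positions.append(np.asarray(pos))
        ev.residues.append(np.asarray([code[c] for c in res]))
        ev.eps.append(np.full(len(pos), eps))
    return ev


PARAMS = ScoringParams()


class TestReadLikelihood:
    def test_error_free_read_against_its_own_allele(self):
        ev = evidence("G", 8, [(range(8), "ACGTACGT", 1e-3)])
        ll = read_likelihood(ev.positions[0], ev.residues[0], ev.eps[0],
                             _genotype_codes("ACGTACGT"), PARAMS)
        assert ll == pytest.approx(8 * math.log1p(-1e-3))

    def test_one_differing_column_costs_match_minus_mismatch(self):
        ev = evidence("G", 8, [(range(8), "ACGTACGT", 1e-3)])
        args = (ev.positions[0], ev.residues[0], ev.eps[0])
        ll_same = read_likelihood(*args, _genotype_codes("ACGTACGT"), PARAMS)
        ll_diff = read_likelihood(*args, _genotype_codes("ACGTACGA"), PARAMS)
        delta = math.log1p(-1e-3) - math.log(1e-3 / 3)
        assert ll_same - ll_diff == pytest.approx(delta)

    def test_q30_likelihood_ratio_at_single_differing_column(self):
        """One read covering the single column where two alleles differ,
        at Q30: the likelihood ratio is (1-1e-3)/(1e-3/3)."""
        ev = evidence("G", 1, [([0], "A", 1e-3)])
        args = (ev.positions[0], ev.residues[0], ev.eps[0])
        la = read_likelihood(*args, _genotype_codes("A"), PARAMS)
        lb = read_likelihood(*args, _genotype_codes("C"), PARAMS)
        assert math.exp(la - lb) == pytest.approx((1 - 1e-3) / (1e-3 / 3))

    def test_gap_columns(self):
        ev = evidence("G", 4, [(range(4), "AC-G", 1e-3)])
        args = (ev.positions[0], ev.residues[0], ev.eps[0])
        both_gap = read_likelihood(*args, _genotype_codes("AC-G"), PARAMS)
        assert both_gap == pytest.approx(3 * math.log1p(-1e-3))  # gap/gap = 0
        read_gap = read_likelihood(*args, _genotype_codes("ACTG"), PARAMS)
        assert read_gap == pytest.approx(3 * math.log1p(-1e-3)
                                         + PARAMS.gap_open)
        allele_n = read_likelihood(*args, _genotype_codes("NC-G"), PARAMS)
        assert allele_n == pytest.approx(both_gap)


class TestPairLikelihood:
    @pytest.fixture()
    def two_allele(self):
        genotypes = {"x": "ACGTACGT", "y": "ACGTACGA"}
        ev = evidence("G", 8, [
            (range(8), "ACGTACGT", 1e-3),
            (range(8), "ACGTACGA", 1e-3),
            ([4, 5, 6, 7], "ACGT", 1e-3),
        ])
        names, L = likelihood_matrix(ev, genotypes, PARAMS)
        return ev, names, L

    def test_homozygous_collapse_is_exact(self, two_allele):
        _ev, names, L = two_allele
        for i in range(2):
            assert pair_likelihood(L, i, i) == pytest.approx(
                float(L[:, i].sum()), abs=1e-12)

    def test_pair_symmetry_is_exact(self, two_allele):
        _ev, _names, L = two_allele
        assert pair_likelihood(L, 0, 1) == pair_likelihood(L, 1, 0)

    def test_two_by_two_table_matches_hand_computation(self, two_allele):
        _ev, names, L = two_allele
        got = pair_likelihood(L, 0, 1)
        expected = sum(
            math.log(0.5 * math.exp(L[r, 0]) + 0.5 * math.exp(L[r, 1]))
            for r in range(L.shape[0]))
        assert got == pytest.approx(expected, abs=1e-9)


class TestGenotypePosterior:
    def test_single_allele_posterior_one(self):
        ev = evidence("G", 4, [(range(4), "ACGT", 1e-3)])
        post = genotype_posterior(ev, {"x": "ACGT"}, PARAMS)
        assert post.posterior == {("x", "x"): 1.0}

    def test_all_unordered_pairs_evaluated(self):
        ev = evidence("G", 4, [(range(4), "ACGT", 1e-3)])
        genotypes = {f"a{i}": g for i, g in enumerate(
            ["ACGT", "ACGA", "ACTT", "AGGT", "TCGT"])}
        post = genotype_posterior(ev, genotypes, PARAMS)
        assert len(post.posterior) == 5 * 6 // 2
        assert abs(sum(post.posterior.values()) - 1.0) < 1e-9

    def test_adding_consistent_reads_never_lowers_true_pair_posterior(self):
        genotypes = {"x": "ACGTACGT", "y": "ACGTTCGA", "z": "GCGAACGT"}
        reads = [(range(8), "ACGTACGT", 1e-3), (range(8), "ACGTTCGA", 1e-3)]
        prev = 0.0
        for n in (1, 2, 4, 8):
            ev = evidence("G", 8, (reads * n)[: 2 * n])
            post = genotype_posterior(ev, genotypes, PARAMS)
            cur = post.posterior[("x", "y")]
            assert cur >= prev - 1e-12
            prev = cur


class TestBestGuess:
    def _post(self, d):
        alleles = sorted({a for pair in d for a in pair})
        return PairPosterior("G", alleles,
                             {k: math.log(max(v, 1e-300)) for k, v in d.items()},
                             dict(d))

    def test_concentrated_posterior_gives_q1_q2_one(self):
        call = call_best_guess(self._post({("x", "y"): 1.0}))
        assert {call.allele1, call.allele2} == {"x", "y"}
        assert call.q1 == pytest.approx(1.0)
        assert call.q2 == pytest.approx(1.0)

    def test_marginal_counts_homozygous_pair_once(self):
        call = call_best_guess(self._post({("x", "x"): 0.6, ("x", "y"): 0.4}))
        assert call.allele1 == "x"
        assert call.q1 == pytest.approx(1.0)
        assert call.allele2 == "x"
        assert call.q2 == pytest.approx(0.6)

    def test_uniform_posterior_breaks_ties_lexicographically(self):
        call = call_best_guess(self._post(
            {("x", "x"): 1 / 3, ("x", "y"): 1 / 3, ("y", "y"): 1 / 3}))
        assert call.allele1 == "x"
        assert call.q1 == pytest.approx(2 / 3)


@pytest.fixture(scope="module")
def planted():
    """Three alleles; z differs from both x and y at exactly 3 PBS
    columns (positions 2, 5, 8)."""
    x = "ACGTACGTACGT"
    z = list(x)
    for p in (2, 5, 8):
        z[p] = {"A": "T", "C": "G", "G": "C", "T": "A"}[z[p]]
    z = "".join(z)
    y = x[:-1] + ("A" if x[-1] != "A" else "C")
    seg = SegmentedGene(locus="G", segments=[
        Segment("genomic", "exon_1", {"x": x, "y": y, "z": z})])
    prg = build_gene_graph(seg, pbs_exons=(1,))
    return prg, x, y, z


class TestQualityMetrics:
    def test_unaccounted_columns_equal_planted_differences(self, planted):
        prg, x, y, z = planted
        reads = [(range(12), z, 1e-3)] * 10  # deep error-free z pileup
        ev = evidence("G", 12, reads)
        assert unaccounted_columns(ev, x, y) == 3

    def test_homozygous_truth_called_correctly_has_no_residuals(self, planted):
        prg, x, y, z = planted
        ev = evidence("G", 12, [(range(12), x, 1e-3)] * 10)
        assert unaccounted_columns(ev, x, x) == 0

    def test_low_depth_columns_are_ignored(self, planted):
        prg, x, y, z = planted
        ev = evidence("G", 12, [(range(12), z, 1e-3)] * 3)
        assert unaccounted_columns(ev, x, y, min_depth=5) == 0

    def test_kmer_coverage_one_under_tiling_reads(self, planted):
        prg, x, y, z = planted
        k = 6
        reads = [x[i:i + 8] for i in range(0, len(x) - 7)]
        from prgtyper.genotype import read_kmer_set
        cov = kmer_coverage(prg, "G", "xG", read_kmer_set(reads, k), k=k)
        assert cov == 1.0

    def test_kmer_coverage_zero_without_reads(self, planted):
        prg, *_ = planted
        assert kmer_coverage(prg, "G", "xG", set(), k=6) == 0.0
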