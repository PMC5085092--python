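"""Diploid genotype inference at G group resolution.

Let R be the set of paired-end read alignments overlapping the
peptide-binding site (PBS) of a locus.  For an allele a with PBS
genotype g_a and a read r with aligned PBS columns O_r = {(g_r, g_a)},
the likelihood is

    L(r | a)        = prod over O_r of score(g_r, g_a)
    L(r | (a1,a2))  = 1/2 L(r | a1) + 1/2 L(r | a2)
    L(R | (a1,a2))  = prod over r of L(r | (a1,a2))

with score the base-quality-aware alignment scoring function (match
log(1-eps), mismatch log(eps/3), read base against allele gap and read
gap against allele base are gap penalties, gap against gap is free,
'N' matches anything).  The likelihood over all unordered allele pairs
is normalized to a posterior; the first best-guess allele is the one
with the highest marginal probability of occurring at least once
(quality Q1), the second is chosen from the pairs containing the first
by highest absolute pair probability (quality Q2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import PairedAlignment, ScoringParams
from .kmer import canonical
from .prg import PRG

_BASE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4, "-": 5}


@dataclass
class ReadEvidence:
    """PBS-overlapping alignment columns of the reads at one locus.

    Per read: integer positions into the locus's ordered PBS levels,
    the read residue codes (0..3 bases, 5 gap) and per-column error
    probabilities.  Both mates contribute columns.
    """

    locus: str
    pbs_levels: list[int]
    read_ids: list[str] = field(default_factory=list)
    positions: list[np.ndarray] = field(default_factory=list)
    residues: list[np.ndarray] = field(default_factory=list)
    eps: list[np.ndarray] = field(default_factory=list)

    @property
    def n_reads(self) -> int:
        return len(self.read_ids)


def collect_evidence(locus: str, prg: PRG,
                     alignments: list[tuple[str, PairedAlignment]]
                     ) -> ReadEvidence:
    """Restrict selected ML alignments to the locus's PBS levels.

    Reads whose fixed maximum-likelihood alignment overlaps no PBS
    level of the locus are excluded (they carry no evidence here).
    """
    pbs = prg.pbs_levels(locus)
    level_pos = {lvl: i for i, lvl in enumerate(pbs)}
    ev = ReadEvidence(locus=locus, pbs_levels=pbs)
    for read_id, pair in alignments:
        pos, res, eps = [], [], []
        for aln in (pair.alignment1, pair.alignment2):
            for lvl, (gr, e) in sorted(aln.level_to_gr().items()):
                if lvl in level_pos:
                    pos.append(level_pos[lvl])
                    res.append(_BASE[gr])
                    eps.append(e)
        if pos:
            ev.read_ids.append(read_id)
            ev.positions.append(np.asarray(pos, dtype=np.int64))
            ev.residues.append(np.asarray(res, dtype=np.int64))
            ev.eps.append(np.asarray(eps, dtype=np.float64))
    return ev


def _genotype_codes(genotype: str) -> np.ndarray:
    return np.asarray([_BASE[c] for c in genotype], dtype=np.int64)


def read_likelihood(positions: np.ndarray, residues: np.ndarray,
                    eps: np.ndarray, genotype_codes: np.ndarray,
                    params: ScoringParams) -> float:
    """log L(r | a): sum of column scores over the read's PBS overlap."""
    ga = genotype_codes[positions]
    gr = residues
    e = np.clip(eps, params.eps_floor, 0.75)
    read_gap = gr == 5
    allele_gap = ga == 5
    allele_n = ga == 4
    score = np.empty(len(gr))
    match = np.log1p(-e)
    mismatch = np.log(e / 3.0)
    both = read_gap & allele_gap
    score[:] = np.where(gr == ga, match, mismatch)
    score[allele_n & ~read_gap] = match[allele_n & ~read_gap]
    score[read_gap ^ allele_gap] = params.gap_open
    score[both] = 0.0
    return float(score.sum())


def likelihood_matrix(ev: ReadEvidence, genotypes: dict[str, str],
                      params: ScoringParams):
    """log L(r | a) for every read x allele; alleles in sorted order."""
    names = sorted(genotypes)
    codes = [_genotype_codes(genotypes[a]) for a in names]
    L = np.empty((ev.n_reads, len(names)))
    for i in range(ev.n_reads):
        for j, gc in enumerate(codes):
            L[i, j] = read_likelihood(ev.positions[i], ev.residues[i],
                                      ev.eps[i], gc, params)
    return names, L


def pair_likelihood(L: np.ndarray, i: int, j: int) -> float:
    """log L(R | (a_i, a_j)) from the per-read log-likelihood matrix."""
    return float(np.sum(np.logaddexp(L[:, i], L[:, j]) - np.log(2.0)))


@dataclass
class PairPosterior:
    """Posterior over unordered allele pairs at one locus."""

    locus: str
    alleles: list[str]
    log_likelihood: dict[tuple[str, str], float]
    posterior: dict[tuple[str, str], float]

    def marginal(self, allele: str) -> float:
        """Probability that the allele occurs at least once."""
        return sum(p for pair, p in self.posterior.items() if allele in pair)


def genotype_posterior(ev: ReadEvidence, genotypes: dict[str, str],
                       params: ScoringParams) -> PairPosterior:
    """Likelihood over all unordered pairs (incl. homozygous), normalized."""
    if not genotypes:
        raise ValueError("no candidate alleles")
    names, L = likelihood_matrix(ev, genotypes, params)
    pairs = [(names[i], names[j]) for i in range(len(names))
             for j in range(i, len(names))]
    lls = np.array([pair_likelihood(L, names.index(a), names.index(b))
                    for a, b in pairs])
    post = np.exp(lls - lls.max())
    post /= post.sum()
    return PairPosterior(
        locus=ev.locus, alleles=names,
        log_likelihood=dict(zip(pairs, lls.tolist())),
        posterior=dict(zip(pairs, post.tolist())))


@dataclass
class GenotypeCall:
    locus: str
    allele1: str
    q1: float
    allele2: str
    q2: float
    n_reads: int = 0
    kmer_coverage: dict[str, float] = field(default_factory=dict)
    unaccounted_columns: int = 0


def call_best_guess(post: PairPosterior) -> GenotypeCall:
    """Two-step best-guess call with marginal / pair-probability scores.

    Allele 1 maximises the marginal probability of occurring at least
    once (homozygous pairs counted once); allele 2 maximises the
    absolute posterior among pairs containing allele 1.  Ties break
    lexicographically.
    """
    marginals = {a: post.marginal(a) for a in post.alleles}
    allele1 = min(marginals, key=lambda a: (-marginals[a], a))
    q1 = marginals[allele1]
    best_pair, q2 = None, -1.0
    for pair, p in sorted(post.posterior.items()):
        if allele1 in pair and p > q2:
            best_pair, q2 = pair, p
    allele2 = best_pair[1] if best_pair[0] == allele1 else best_pair[0]
    return GenotypeCall(locus=post.locus, allele1=allele1, q1=q1,
                        allele2=allele2, q2=q2)


def kmer_coverage(prg: PRG, locus: str, group_name: str,
                  read_kmers: set[str], k: int = 31) -> float:
    """Fraction of the called allele's k-mers observed in the reads.

    The allele's k-mers are taken over the un-gapped sequence of each
    of the representative's path fragments (k-mers are never read
    across the junction between non-contiguous fragments of exon-only
    alleles); membership is strand-agnostic (both sides canonicalized).
    """
    rep = prg.g_groups(locus)[group_name]["representative"]
    kmers: set[str] = set()
    for _start, frag in prg.allele_paths[rep]:
        seq = frag.replace("-", "")
        kmers.update(canonical(seq[i:i + k]) for i in range(len(seq) - k + 1)
                     if "N" not in seq[i:i + k])
    if not kmers:
        return 0.0
    return len(kmers & read_kmers) / len(kmers)


def read_kmer_set(reads, k: int = 31) -> set[str]:
    """Canonicalized k-mers of the kept sample reads."""
    out: set[str] = set()
    for seq in reads:
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            km = seq[i:i + k]
            if "N" not in km:
                out.add(canonical(km))
    return out


def unaccounted_columns(ev: ReadEvidence, genotype1: str, genotype2: str,
                        min_depth: int = 5, min_freq: float = 0.2) -> int:
    """PBS pileup columns with residual high-frequency evidence.

    Counts columns (depth >= min_depth) where some residue reaches
    within-column frequency >= min_freq yet differs from both called
    alleles' genotypes at that column.
    """
    n_pos = len(ev.pbs_levels)
    counts = np.zeros((n_pos, 6), dtype=np.int64)
    for pos, res in zip(ev.positions, ev.residues):
        np.add.at(counts, (pos, res), 1)
    g1 = _genotype_codes(genotype1)
    g2 = _genotype_codes(genotype2)
    n_cols = 0
    for p in range(n_pos):
        depth = counts[p].sum()
        if depth < min_depth:
            continue
        for code in range(6):
            if code == 4:
                continue  # N reads never count as residual evidence
            if counts[p, code] / depth >= min_freq \
                    and code != g1[p] and code != g2[p]:
                n_cols += 1
                break
    return n_cols


def genotype_locus(locus: str, prg: PRG,
                   alignments: list[tuple[str, PairedAlignment]],
                   params: ScoringParams, read_kmers: set[str] | None = None,
                   k: int = 31, min_depth: int = 5) -> GenotypeCall | None:
    """Full typing of one locus from selected ML alignments.

    Returns None when no read overlaps the PBS ("no data").
    """
    ev = collect_evidence(locus, prg, alignments)
    if ev.n_reads == 0:
        return None
    groups = prg.g_groups(locus)
    genotypes = {name: info["genotype"] for name, info in groups.items()}
    post = genotype_posterior(ev, genotypes, params)
    call = call_best_guess(post)
    call.n_reads = ev.n_reads
    call.unaccounted_columns = unaccounted_columns(
        ev, genotypes[call.allele1], genotypes[call.allele2],
        min_depth=min_depth)
    if read_kmers is not None:
        for name in {call.allele1, call.allele2}:
            call.kmer_coverage[name] = kmer_coverage(prg, locus, name,
                                                     read_kmers, k=k)
    return call
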