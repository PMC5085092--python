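"""Seed-and-extend alignment of paired-end reads to the PRG.

Seeds are maximal exact matches between read substrings and gap-
skipping graph walks, found through the k-mer index and chained over
successive read offsets.  Each seed is extended left and right by
banded affine-gap dynamic programming over the leveled graph; '-'
(graph gap) edges are traversed free of charge and consume no read
base.  Candidate alignments of the two mates are combined into paired
alignments scored by individual alignment score, orientation and
insert size; softmax normalization yields a posterior over candidate
pairs, the maximum-likelihood pair (treated as fixed downstream), a
mapping quality and per-position alignment qualities.

Scoring is base-quality aware: a match scores log(1 - eps), a mismatch
log(eps / 3), with eps the Phred error probability of the read base
(floored to avoid -inf).  'N' graph edges match any base.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import norm

from .kmer import KmerIndex, revcomp
from .prg import PRG

NEG = -1.0e30


def _close(a, b, tol=1e-6):
    """Traceback value matching; tolerant to float re-association between
    the vectorized forward pass and the incremental candidate expressions
    (equal-scoring branches are interchangeable)."""
    return abs(a - b) <= tol


@dataclass
class ScoringParams:
    """Alignment scoring constants (natural-log units)."""

    gap_open: float = math.log(0.01)      # ~ -4.605
    gap_extend: float = math.log(0.1)     # ~ -2.303
    clip_penalty: float = math.log(0.25)  # ~ -1.386 per clipped base
    improper_pair_penalty: float = -13.8
    score_drop: float = 25.0
    eps_floor: float = 1e-4
    band_pad: int = 48
    max_seeds_per_read: int = 24
    min_seed_length: int | None = None    # None -> index k

    def __post_init__(self):
        if not (self.gap_open <= 0 and self.gap_extend <= 0
                and self.clip_penalty <= 0):
            raise ValueError("log penalties must be <= 0")


def phred_to_eps(quals, floor: float = 1e-4) -> np.ndarray:
    """Phred qualities -> error probabilities, floored away from 0."""
    q = np.asarray(quals, dtype=np.float64)
    return np.clip(10.0 ** (-q / 10.0), floor, 0.75)


@dataclass
class InsertSizeModel:
    """Normal model of the paired-end insert size, in graph levels."""

    mean: float = 350.0
    sd: float = 50.0

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("insert size sd must be positive")

    def logpdf(self, insert: float) -> float:
        return float(norm.logpdf(insert, self.mean, self.sd))

    @classmethod
    def estimate(cls, inserts) -> "InsertSizeModel":
        """Robust median/MAD fit from observed proper-pair inserts."""
        arr = np.asarray(list(inserts), dtype=np.float64)
        if arr.size < 3:
            raise ValueError("need at least 3 inserts to estimate the model")
        med = float(np.median(arr))
        mad = float(np.median(np.abs(arr - med)))
        return cls(mean=med, sd=max(1.0, 1.4826 * mad))


@dataclass
class SeedMatch:
    """A maximal exact match between an oriented read and a graph walk."""

    read_start: int   # 0-based half-open, oriented-read coordinates
    read_end: int
    start_level: int
    labels: str       # walk edge labels, may include '-'
    mate: int = 1
    strand: str = "+"

    @property
    def end_level(self) -> int:
        return self.start_level + len(self.labels)


@dataclass
class GraphAlignment:
    """One candidate alignment of one (oriented) mate.

    ``columns`` lists traversed levels and consumed read bases in
    order: (level, label, read_index).  A graph-gap traversal has
    label '-' and no read index; a read deletion has a non-gap label
    and no read index; a read insertion has no level and no label.
    Read indices refer to the oriented read (reverse-complemented for
    '-' strand alignments).
    """

    mate: int
    strand: str
    columns: list[tuple[int | None, str | None, int | None]]
    clip_left: int
    clip_right: int
    score: float
    oriented_seq: str = ""
    oriented_eps: np.ndarray | None = None

    @property
    def start_level(self) -> int:
        for lvl, _, _ in self.columns:
            if lvl is not None:
                return lvl
        raise ValueError("alignment traverses no levels")

    @property
    def end_level(self) -> int:
        """One past the last traversed level."""
        for lvl, _, _ in reversed(self.columns):
            if lvl is not None:
                return lvl + 1
        raise ValueError("alignment traverses no levels")

    @property
    def walk(self) -> str:
        return "".join(lab for lvl, lab, _ in self.columns if lvl is not None)

    def read_to_level(self) -> dict[int, int | None]:
        """Oriented read index -> level (None for inserted bases)."""
        return {j: lvl for lvl, _, j in self.columns if j is not None}

    def level_to_gr(self) -> dict[int, tuple[str, float]]:
        """Level -> (read base or '-', eps); one entry per traversed level."""
        out: dict[int, tuple[str, float]] = {}
        for lvl, _, j in self.columns:
            if lvl is None:
                continue
            if j is None:
                out[lvl] = ("-", 0.0)
            else:
                out[lvl] = (self.oriented_seq[j], float(self.oriented_eps[j]))
        return out

    def key(self):
        return (self.mate, self.strand, self.clip_left, self.clip_right,
                tuple(self.columns))


@dataclass
class PairedAlignment:
    alignment1: GraphAlignment
    alignment2: GraphAlignment
    insert_size: int
    proper: bool
    log_likelihood: float
    posterior: float = 0.0


# ----------------------------------------------------------------------
# seed finding
# ----------------------------------------------------------------------

def _kmer_hits(seq: str, index: KmerIndex):
    k = index.k
    hits: dict[int, list[tuple[int, str]]] = {}
    get = index.entries.get
    for i in range(len(seq) - k + 1):
        w = get(seq[i:i + k])
        if w:
            hits[i] = w
    return hits


def _chain_hits(hits, k: int) -> list[tuple[int, int, str]]:
    """Chain k-mer hits at successive read offsets into maximal exact
    matches.  Two hits chain when their read offsets are successive and
    the second walk extends the first by one character-consuming step.
    Returns deduplicated (read_start, start_level, labels) triples."""
    finished: list[list] = []
    open_chains: list[list] = []  # [read_start, start_level, labels, (ls, ll)]
    last_offset = None
    for i in sorted(hits):
        if last_offset is not None and i != last_offset + 1:
            finished.extend(open_chains)
            open_chains = []
        new_open: list[list] = []
        extended_ids: set[int] = set()
        for start_level, labels in hits[i]:
            matched = False
            for c in open_chains:
                ls, ll = c[3]
                t = next(q for q, ch in enumerate(ll) if ch != "-")
                if (start_level == ls + t + 1
                        and ll[t + 1:] == labels[:len(ll) - t - 1]):
                    ext = labels[len(ll) - t - 1:]
                    new_open.append([c[0], c[1], c[2] + ext,
                                     (start_level, labels)])
                    extended_ids.add(id(c))
                    matched = True
            if not matched:
                new_open.append([i, start_level, labels, (start_level, labels)])
        finished.extend(c for c in open_chains if id(c) not in extended_ids)
        open_chains = new_open
        last_offset = i
    finished.extend(open_chains)
    return sorted({(c[0], c[1], c[2]) for c in finished})


def find_seeds(read: str, index: KmerIndex,
               min_seed: int | None = None) -> list[SeedMatch]:
    """Maximal exact matches of an oriented read against graph walks.

    K-mer hits whose graph walks and read offsets are both successive
    are chained; chains shorter than ``min_seed`` characters are
    dropped; the output is deduplicated and sorted.
    """
    k = index.k
    if min_seed is None:
        min_seed = k
    if len(read) < k:
        return []
    hits = _kmer_hits(read, index)
    if not hits:
        return []
    seeds = []
    for read_start, start_level, labels in _chain_hits(hits, k):
        length = sum(1 for c in labels if c != "-")
        if length < min_seed:
            continue
        seeds.append(SeedMatch(read_start=read_start,
                               read_end=read_start + length,
                               start_level=start_level, labels=labels))
    return seeds


# ----------------------------------------------------------------------
# DP extension engine
# ----------------------------------------------------------------------

def _sub_vectors(read: str, eps: np.ndarray) -> dict[str, np.ndarray]:
    """Per-label substitution score vectors over read positions."""
    match = np.log1p(-eps)
    mismatch = np.log(eps / 3.0)
    rb = np.frombuffer(read.encode(), dtype=np.uint8)
    out = {}
    for c in "ACGT":
        out[c] = np.where(rb == ord(c), match, mismatch)
    out["N"] = match.copy()
    return out


class _DP:
    """Affine-gap DP of a read (fragment) against a window of levels.

    States per (boundary, read position): M (last op consumed a level
    and a base, or start), Ix (open read-insertion run), D (open
    read-deletion run).  '-' edges propagate all states unchanged at
    zero cost.  ``free_start`` allows the alignment to begin at any
    boundary (fitting alignment); otherwise it is anchored at boundary
    0, read position 0.  With ``clip`` the read may be soft-clipped at
    either end at ``clip_penalty`` per base.
    """

    def __init__(self, window_labels, read: str, eps: np.ndarray,
                 params: ScoringParams, free_start: bool, clip: bool,
                 drop: float | None = None):
        self.window = window_labels
        self.read = read
        self.m = len(read)
        self.params = params
        self.free_start = free_start
        self.clip = clip
        self.drop = drop
        self.subv = _sub_vectors(read, eps) if read else {}
        self.Ms: list[np.ndarray] = []
        self.Ixs: list[np.ndarray] = []
        self.Ds: list[np.ndarray] = []
        self._run()

    def _start_vec(self) -> np.ndarray:
        v = np.full(self.m + 1, NEG)
        if self.clip:
            v[:] = self.params.clip_penalty * np.arange(self.m + 1)
        else:
            v[0] = 0.0
        return v

    def _scan_insertions(self, M, Ix):
        m = self.m
        if m == 0:
            return Ix
        po, pe = self.params.gap_open, self.params.gap_extend
        base = np.maximum(M + po, Ix + pe)
        u = base - pe * np.arange(m + 1)
        cm = np.maximum.accumulate(u)
        out = Ix.copy()
        out[1:] = np.maximum(out[1:], cm[:-1] + pe * np.arange(m))
        return out

    def _run(self):
        p = self.params
        start = self._start_vec()
        if self.free_start:
            M = start.copy()
        else:
            # anchored at boundary 0, read position 0 (seed extension);
            # clipping only ever applies at the far end
            M = np.full(self.m + 1, NEG)
            M[0] = 0.0
        Ix = np.full(self.m + 1, NEG)
        D = np.full(self.m + 1, NEG)
        best_end = NEG
        self.stopped_at = None
        for b in range(len(self.window) + 1):
            if self.free_start and b > 0:
                M = np.maximum(M, start)
            Ix = self._scan_insertions(M, Ix)
            self.Ms.append(M)
            self.Ixs.append(Ix)
            self.Ds.append(D)
            if self.drop is not None:
                col_best = max(M.max(), Ix.max(), D.max())
                end_here = self._end_score_at(b)
                best_end = max(best_end, end_here)
                if col_best < best_end - self.drop:
                    self.stopped_at = b
                    break
            if b == len(self.window):
                break
            labs = self.window[b]
            nongap = [c for c in labs if c != "-"]
            newM = np.full(self.m + 1, NEG)
            newIx = np.full(self.m + 1, NEG)
            newD = np.full(self.m + 1, NEG)
            if nongap:
                E = np.maximum(np.maximum(M, Ix), D)
                if self.m:
                    bestsub = self.subv[nongap[0]]
                    for c in nongap[1:]:
                        bestsub = np.maximum(bestsub, self.subv[c])
                    newM[1:] = E[:-1] + bestsub
                newD = np.maximum(M + p.gap_open, D + p.gap_extend)
            if "-" in labs:
                newM = np.maximum(newM, M)
                newIx = np.maximum(newIx, Ix)
                newD = np.maximum(newD, D)
            M, Ix, D = newM, newIx, newD

    def _end_score_at(self, b: int) -> float:
        M, Ix, D = self.Ms[b], self.Ixs[b], self.Ds[b]
        col = np.maximum(np.maximum(M, Ix), D)
        if self.clip:
            tail = self.params.clip_penalty * (self.m - np.arange(self.m + 1))
            return float((col + tail).max())
        return float(col[self.m])

    def best_end(self) -> tuple[float, int, int, str]:
        """(score, boundary, read position, state) of the best end."""
        best = (NEG, 0, self.m, "M")
        for b in range(len(self.Ms)):
            M, Ix, D = self.Ms[b], self.Ixs[b], self.Ds[b]
            col = np.maximum(np.maximum(M, Ix), D)
            if self.clip:
                tail = self.params.clip_penalty * (self.m - np.arange(self.m + 1))
                tot = col + tail
                j = int(np.argmax(tot))
                sc = float(tot[j])
            else:
                j = self.m
                sc = float(col[j])
            if sc > best[0]:
                for st, arr in (("M", M), ("Ix", Ix), ("D", D)):
                    if arr[j] == col[j]:
                        best = (sc, b, j, st)
                        break
        return best

    def traceback(self, b: int, j: int, state: str):
        """Columns (window index, label, read index) from start to (b, j)."""
        p = self.params
        cols: list[tuple[int | None, str | None, int | None]] = []
        while True:
            M, Ix, D = self.Ms[b], self.Ixs[b], self.Ds[b]
            if state == "M":
                v = M[j]
                if b > 0:
                    pl = self.window[b - 1]
                    Mp, Ixp, Dp = self.Ms[b - 1], self.Ixs[b - 1], self.Ds[b - 1]
                    moved = False
                    if j > 0:
                        nongap = [c for c in pl if c != "-"]
                        # deterministic label preference: exact base, 'N', rest
                        rb = self.read[j - 1]
                        order = ([c for c in nongap if c == rb]
                                 + [c for c in nongap if c == "N" and rb != "N"]
                                 + sorted(c for c in nongap
                                          if c != rb and c != "N"))
                        Ep = np.maximum(np.maximum(Mp, Ixp), Dp)
                        for c in order:
                            if _close(v, Ep[j - 1] + self.subv[c][j - 1]):
                                cols.append((b - 1, c, j - 1))
                                for st, arr in (("M", Mp), ("Ix", Ixp), ("D", Dp)):
                                    if arr[j - 1] == Ep[j - 1]:
                                        state = st
                                        break
                                b, j = b - 1, j - 1
                                moved = True
                                break
                    if not moved and "-" in pl and _close(v, Mp[j]):
                        cols.append((b - 1, "-", None))
                        b = b - 1
                        moved = True
                    if moved:
                        continue
                break  # start of alignment
            if state == "Ix":
                v = Ix[j]
                if j > 0 and _close(v, M[j - 1] + p.gap_open):
                    cols.append((None, None, j - 1))
                    j, state = j - 1, "M"
                    continue
                if j > 0 and _close(v, Ix[j - 1] + p.gap_extend):
                    cols.append((None, None, j - 1))
                    j = j - 1
                    continue
                if b > 0 and "-" in self.window[b - 1] \
                        and _close(v, self.Ixs[b - 1][j]):
                    cols.append((b - 1, "-", None))
                    b = b - 1
                    continue
                raise AssertionError("broken Ix traceback")
            # state == "D"
            v = D[j]
            if b > 0:
                pl = self.window[b - 1]
                nongap = sorted(c for c in pl if c != "-")
                Mp, Dp = self.Ms[b - 1], self.Ds[b - 1]
                if nongap and _close(v, Mp[j] + p.gap_open):
                    cols.append((b - 1, nongap[0], None))
                    b, state = b - 1, "M"
                    continue
                if nongap and _close(v, Dp[j] + p.gap_extend):
                    cols.append((b - 1, nongap[0], None))
                    b = b - 1
                    continue
                if "-" in pl and _close(v, Dp[j]):
                    cols.append((b - 1, "-", None))
                    b = b - 1
                    continue
            raise AssertionError("broken D traceback")
        cols.reverse()
        if not self.free_start and (b != 0 or j != 0):
            raise AssertionError("anchored traceback did not reach the origin")
        return cols, b, j


# ----------------------------------------------------------------------
# seed extension and candidate generation
# ----------------------------------------------------------------------

def _seed_columns(seed: SeedMatch):
    cols = []
    j = seed.read_start
    for i, c in enumerate(seed.labels):
        lvl = seed.start_level + i
        if c == "-":
            cols.append((lvl, "-", None))
        else:
            cols.append((lvl, c, j))
            j += 1
    return cols


def _seed_score(seed: SeedMatch, eps: np.ndarray) -> float:
    return float(np.log1p(-eps[seed.read_start:seed.read_end]).sum())


def extend_seed(seed: SeedMatch, read: str, eps: np.ndarray, prg: PRG,
                params: ScoringParams, clip: bool = True,
                use_drop: bool = True) -> GraphAlignment:
    """Best-scoring alignment containing the seed.

    Left and right of the exact match the read is extended by banded
    affine DP; with ``clip`` the extension may terminate early (score
    drop) and soft-clip the remaining bases.
    """
    m = len(read)
    drop = params.score_drop if (use_drop and clip) else None
    # right extension
    r_read = read[seed.read_end:]
    r_eps = eps[seed.read_end:]
    right_cols: list = []
    right_score = 0.0
    clip_right = 0
    if r_read:
        w_hi = min(prg.n_levels, seed.end_level + len(r_read) + params.band_pad)
        dp = _DP(prg.labels[seed.end_level:w_hi], r_read, r_eps, params,
                 free_start=False, clip=clip, drop=drop)
        sc, b, j, st = dp.best_end()
        cols, b0, j0 = dp.traceback(b, j, st)
        # anchored: trace must reach (0, 0)
        right_score = sc
        clip_right = m - seed.read_end - j
        right_cols = [(seed.end_level + wb if wb is not None else None, lab,
                       seed.read_end + rj if rj is not None else None)
                      for wb, lab, rj in cols]
    # left extension: reverse read prefix and levels
    l_read = read[:seed.read_start][::-1]
    l_eps = eps[:seed.read_start][::-1]
    left_cols: list = []
    left_score = 0.0
    clip_left = 0
    if l_read:
        w_lo = max(0, seed.start_level - len(l_read) - params.band_pad)
        window = prg.labels[w_lo:seed.start_level][::-1]
        dp = _DP(window, l_read, l_eps, params, free_start=False, clip=clip,
                 drop=drop)
        sc, b, j, st = dp.best_end()
        cols, _, _ = dp.traceback(b, j, st)
        left_score = sc
        clip_left = seed.read_start - j
        rev = []
        for wb, lab, rj in cols:
            lvl = seed.start_level - 1 - wb if wb is not None else None
            ridx = seed.read_start - 1 - rj if rj is not None else None
            rev.append((lvl, lab, ridx))
        left_cols = rev[::-1]
    score = _seed_score(seed, eps) + left_score + right_score
    return GraphAlignment(mate=seed.mate, strand=seed.strand,
                          columns=left_cols + _seed_columns(seed) + right_cols,
                          clip_left=clip_left, clip_right=clip_right,
                          score=score)


def align_read(read: str, quals, prg: PRG, index: KmerIndex,
               params: ScoringParams, mate: int = 1) -> list[GraphAlignment]:
    """All candidate alignments of one mate (both strands, deduplicated)."""
    min_seed = params.min_seed_length or index.k
    out: dict = {}
    for strand in "+-":
        oread = read if strand == "+" else revcomp(read)
        oeps = phred_to_eps(quals, params.eps_floor)
        if strand == "-":
            oeps = oeps[::-1].copy()
        seeds = find_seeds(oread, index, min_seed)
        if not seeds:
            continue
        seeds.sort(key=lambda s: (-(s.read_end - s.read_start),
                                  s.read_start, s.start_level))
        for seed in seeds[:params.max_seeds_per_read]:
            seed = replace(seed, mate=mate, strand=strand)
            aln = extend_seed(seed, oread, oeps, prg, params)
            aln.oriented_seq = oread
            aln.oriented_eps = oeps
            out.setdefault(aln.key(), aln)
    return sorted(out.values(),
                  key=lambda a: (-a.score, a.start_level, a.strand, a.walk))


def align_read_full(read: str, quals, prg: PRG, params: ScoringParams,
                    strand: str = "+", clip: bool = False) -> GraphAlignment:
    """Unseeded, unbanded fitting alignment against the whole graph.

    The read may start and end at any level; with ``clip`` disabled
    every read base is aligned.  Used for exhaustive-search validation
    against the brute-force path oracle.
    """
    oread = read if strand == "+" else revcomp(read)
    oeps = phred_to_eps(quals, params.eps_floor)
    if strand == "-":
        oeps = oeps[::-1].copy()
    dp = _DP(prg.labels, oread, oeps, params, free_start=True, clip=clip,
             drop=None)
    sc, b, j, st = dp.best_end()
    cols, b0, j0 = dp.traceback(b, j, st)
    aln = GraphAlignment(mate=1, strand=strand, columns=cols,
                         clip_left=j0, clip_right=len(oread) - j,
                         score=sc, oriented_seq=oread, oriented_eps=oeps)
    return aln


# ----------------------------------------------------------------------
# pairing, posterior, selection
# ----------------------------------------------------------------------

def pair_and_score(alns1: list[GraphAlignment], alns2: list[GraphAlignment],
                   model: InsertSizeModel,
                   params: ScoringParams) -> list[PairedAlignment]:
    """Cartesian product of mate alignments with paired-end scoring.

    A proper pair has mates on opposite strands in forward/reverse
    orientation with a non-negative implied insert; its pair score adds
    the insert-size log density.  Improper pairs receive the configured
    flat log penalty instead.
    """
    pairs = []
    for a1 in alns1:
        for a2 in alns2:
            lo = min(a1.start_level, a2.start_level)
            hi = max(a1.end_level, a2.end_level)
            insert = hi - lo
            left, right = (a1, a2) if a1.start_level <= a2.start_level else (a2, a1)
            proper = (a1.strand != a2.strand and left.strand == "+"
                      and right.strand == "-" and insert >= 0)
            ll = a1.score + a2.score
            if proper:
                ll += model.logpdf(insert)
            else:
                ll += params.improper_pair_penalty
            pairs.append(PairedAlignment(a1, a2, insert, proper, ll))
    return pairs


def posterior_and_select(pairs: list[PairedAlignment]):
    """Softmax posterior over candidate pairs; ML pair and qualities.

    Returns (selected pair, mapping quality, per-position qualities for
    mate 1 and mate 2).  The per-position quality of an aligned base is
    the total posterior mass of candidate pairs that place the same
    read base at the same level as the selected pair does.
    """
    if not pairs:
        raise ValueError("cannot select from an empty candidate list")
    lls = np.array([p.log_likelihood for p in pairs])
    post = np.exp(lls - lls.max())
    post /= post.sum()
    for p, q in zip(pairs, post):
        p.posterior = float(q)
    order = sorted(
        range(len(pairs)),
        key=lambda i: (-pairs[i].log_likelihood,
                       min(pairs[i].alignment1.start_level,
                           pairs[i].alignment2.start_level),
                       pairs[i].alignment1.walk, pairs[i].alignment2.walk))
    sel = pairs[order[0]]
    mapq = sel.posterior

    def per_position(mate_idx):
        sel_aln = sel.alignment1 if mate_idx == 1 else sel.alignment2
        placements = sel_aln.read_to_level()
        m = len(sel_aln.oriented_seq)
        qual = np.zeros(m)
        maps = []
        for p in pairs:
            a = p.alignment1 if mate_idx == 1 else p.alignment2
            maps.append((a.read_to_level(), p.posterior))
        for j, lvl in placements.items():
            s = 0.0
            for mp, w in maps:
                if j in mp and mp[j] == lvl:
                    s += w
            qual[j] = s
        return qual

    return sel, mapq, (per_position(1), per_position(2))


def align_read_pair(r1: str, q1, r2: str, q2, prg: PRG, index: KmerIndex,
                    params: ScoringParams, model: InsertSizeModel):
    """Full treatment of one read pair.

    Returns (selected PairedAlignment, mapping quality, per-position
    qualities, all candidate pairs), or None if either mate produced no
    seeded candidate (the pair is then recorded unmapped and excluded
    from genotyping).
    """
    alns1 = align_read(r1, q1, prg, index, params, mate=1)
    alns2 = align_read(r2, q2, prg, index, params, mate=2)
    if not alns1 or not alns2:
        return None
    pairs = pair_and_score(alns1, alns2, model, params)
    sel, mapq, posq = posterior_and_select(pairs)
    return sel, mapq, posq, pairs
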