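"""Brute-force reference implementations for validation.

These routines deliberately share no machinery with the production
graph aligner: paths are enumerated exhaustively and each is scored by
a plain, loop-based sequence-to-sequence fitting alignment.  They are
only feasible on small graphs (the caller is expected to keep the
number of source-to-sink paths modest) and exist so that the seed-and-
extend aligner can be checked against an exhaustive search.
"""

from __future__ import annotations

import itertools
import math


def enumerate_path_sequences(labels, max_paths: int = 100_000) -> list[str]:
    """All distinct un-gapped source-to-sink path sequences of a graph.

    ``labels`` is the per-level tuple of edge labels (the PRG's edge
    set).  The count of raw paths is the product of the per-level label
    counts; a guard raises if it exceeds ``max_paths``.
    """
    n_paths = 1
    for ls in labels:
        n_paths *= len(ls)
        if n_paths > max_paths:
            raise ValueError(f"more than {max_paths} source-to-sink paths")
    seqs = set()
    for combo in itertools.product(*labels):
        seqs.add("".join(c for c in combo if c != "-"))
    return sorted(seqs)


def fitting_alignment_score(read: str, ref: str, eps,
                            gap_open: float, gap_extend: float) -> float:
    """Best score of aligning the whole read within the reference.

    Affine gaps; free reference prefix/suffix; every read base is
    consumed (no clipping).  Match scores log(1 - eps_j), mismatch
    log(eps_j / 3); an 'N' in the reference matches anything.  Direct
    insertion<->deletion transitions are disallowed.  Plain O(n*m)
    loops — this is the oracle, kept independent of the graph DP.
    """
    NEG = -1.0e30
    m = len(read)
    n = len(ref)
    match = [math.log1p(-e) for e in eps]
    mismatch = [math.log(e / 3.0) for e in eps]
    # state arrays indexed by read position j, iterated over ref position
    M = [NEG] * (m + 1)
    Ix = [NEG] * (m + 1)
    D = [NEG] * (m + 1)
    M[0] = 0.0
    for j in range(1, m + 1):
        Ix[j] = max(M[j - 1] + gap_open, Ix[j - 1] + gap_extend)
    best = max(M[m], Ix[m], D[m])
    for i in range(1, n + 1):
        c = ref[i - 1]
        nM = [NEG] * (m + 1)
        nIx = [NEG] * (m + 1)
        nD = [NEG] * (m + 1)
        nM[0] = 0.0  # free reference prefix
        nD[0] = max(M[0] + gap_open, D[0] + gap_extend)
        for j in range(1, m + 1):
            sub = match[j - 1] if (c == read[j - 1] or c == "N") \
                else mismatch[j - 1]
            nM[j] = max(M[j - 1], Ix[j - 1], D[j - 1]) + sub
            nD[j] = max(M[j] + gap_open, D[j] + gap_extend)
        for j in range(1, m + 1):
            nIx[j] = max(nM[j - 1] + gap_open, nIx[j - 1] + gap_extend)
        M, Ix, D = nM, nIx, nD
        best = max(best, M[m], Ix[m], D[m])
    return best


def best_path_alignment_score(labels, read: str, eps, gap_open: float,
                              gap_extend: float,
                              max_paths: int = 100_000) -> float:
    """Best fitting-alignment score of the read over every graph path."""
    best = -math.inf
    for ref in enumerate_path_sequences(labels, max_paths=max_paths):
        s = fitting_alignment_score(read, ref, eps, gap_open, gap_extend)
        if s > best:
            best = s
    return best
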