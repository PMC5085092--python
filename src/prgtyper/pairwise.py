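"""Built-in progressive aligner used to re-align flank sequences.

PRG construction needs a multiple alignment of the (un-gapped) flank
sequences left and right of each consensus region.  Rather than
requiring an external aligner binary, this module ships a deliberately
simple progressive scheme: pairwise global (Needleman-Wunsch)
alignment with match +1, mismatch -1, gap -2, guide order = input
order.  Any callable with the same contract (set of un-gapped strings
in, rectangular gapped MSA out, each input reproduced exactly by its
row minus gaps) can be plugged in instead.
"""

from __future__ import annotations

import numpy as np

MATCH = 1.0
MISMATCH = -1.0
GAP = -2.0


def global_align(a: str, b: str, match: float = MATCH, mismatch: float = MISMATCH,
                 gap: float = GAP) -> tuple[str, str]:
    """Global alignment of two strings; returns the gapped pair.

    Ties are broken deterministically: diagonal, then up (gap in b),
    then left (gap in a).
    """
    n, m = len(a), len(b)
    S = np.empty((n + 1, m + 1), dtype=np.float64)
    S[0, :] = np.arange(m + 1) * gap
    S[:, 0] = np.arange(n + 1) * gap
    if n and m:
        bb = np.frombuffer(b.encode(), dtype=np.uint8)
        for i in range(1, n + 1):
            sub = np.where(bb == ord(a[i - 1]), match, mismatch)
            row_prev = S[i - 1]
            diag = row_prev[:-1] + sub
            up = row_prev[1:] + gap
            best = np.maximum(diag, up)
            # left-moves are sequential along j; short python loop
            row = S[i]
            prev = row[0]
            for j in range(1, m + 1):
                v = best[j - 1]
                left = prev + gap
                if left > v:
                    v = left
                row[j] = v
                prev = v
    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        v = S[i, j]
        if i > 0 and j > 0:
            sub = match if a[i - 1] == b[j - 1] else mismatch
            if v == S[i - 1, j - 1] + sub:
                out_a.append(a[i - 1])
                out_b.append(b[j - 1])
                i -= 1
                j -= 1
                continue
        if i > 0 and v == S[i - 1, j] + gap:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
            continue
        out_a.append("-")
        out_b.append(b[j - 1])
        j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b))


def _merge_into_profile(rows: dict[str, str], consensus: str,
                        name: str, seq: str) -> tuple[dict[str, str], str]:
    """Align `seq` to `consensus` and merge it into the profile rows."""
    acons, aseq = global_align(consensus, seq)
    # positions where the consensus acquired a new gap => insert a gap
    # column into every existing row ("once a gap, always a gap")
    new_rows = {k: [] for k in rows}
    new_row: list[str] = []
    new_cons: list[str] = []
    ci = 0  # index into old consensus columns
    for ca, cb in zip(acons, aseq):
        if ca == "-":
            for k in new_rows:
                new_rows[k].append("-")
            new_cons.append(cb)
        else:
            for k in new_rows:
                new_rows[k].append(rows[k][ci])
            new_cons.append(ca if ca != "-" else cb)
            ci += 1
        new_row.append(cb)
    out = {k: "".join(v) for k, v in new_rows.items()}
    out[name] = "".join(new_row)
    return out, "".join(_consensus_char(out, j) for j in range(len(new_cons)))


def _consensus_char(rows: dict[str, str], j: int) -> str:
    counts: dict[str, int] = {}
    for s in rows.values():
        c = s[j]
        if c != "-":
            counts[c] = counts.get(c, 0) + 1
    if not counts:
        return "-"
    # most frequent, ties broken lexicographically
    return min(counts, key=lambda c: (-counts[c], c))


def progressive_msa(sequences: dict[str, str]) -> dict[str, str]:
    """Align a set of un-gapped sequences into a rectangular gapped MSA.

    Guide order is the input (insertion) order.  Empty sequences are
    supported and become all-gap rows; if every sequence is empty the
    result is a zero-column alignment.
    """
    names = list(sequences)
    nonempty = [n for n in names if sequences[n]]
    if not nonempty:
        return {n: "" for n in names}
    first = nonempty[0]
    rows = {first: sequences[first]}
    consensus = sequences[first]
    for name in nonempty[1:]:
        rows, consensus = _merge_into_profile(rows, consensus, name, sequences[name])
    width = len(next(iter(rows.values())))
    for n in names:
        if n not in rows:
            rows[n] = "-" * width
    return {n: rows[n] for n in names}


def consensus_string(rows: dict[str, str]) -> str:
    """Per-column majority character of a gapped block ('-' if all-gap)."""
    if not rows:
        return ""
    width = len(next(iter(rows.values())))
    return "".join(_consensus_char(rows, j) for j in range(width))


def thread_to_block(rows: dict[str, str], seq: str) -> str:
    """Thread an un-gapped sequence through an existing alignment block.

    Returns a gapped row of exactly the block's width whose non-gap
    characters spell `seq`.  Raises ValueError if the sequence needs an
    insertion relative to the block (cannot be represented without
    changing the block's columns).
    """
    # all-gap columns keep a placeholder so they stay distinguishable
    # from gaps introduced by the aligner itself
    cons = consensus_string(rows).replace("-", "x")
    acons, aseq = global_align(cons, seq)
    if "-" in acons:
        raise ValueError(
            "sequence requires an insertion relative to the alignment block"
        )
    assert len(aseq) == len(cons)
    return aseq
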