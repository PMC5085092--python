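"""Graph k-mer index, background k-mer set and the read-pair pre-filter.

The index maps every k-character gap-skipping walk of the PRG to its
graph positions and drives both seed finding and the positive arm of
the read filter.  The background set holds k-mers of reference
sequence outside the PRG (closed under reverse complement) and drives
the negative arm: read pairs whose k-mer content is explained by the
background and that carry no PRG-unique k-mer are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import IndexError_
from .prg import PRG

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(s: str) -> str:
    return s.translate(_RC)[::-1]


def canonical(s: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    r = revcomp(s)
    return s if s <= r else r


@dataclass
class KmerIndex:
    k: int
    #: k-mer -> list of graph walks (start level, edge label string);
    #: the walk's labels minus '-' spell the key
    entries: dict[str, list[tuple[int, str]]] = field(default_factory=dict)

    @property
    def total_kmers(self) -> int:
        """Number of indexed k-mer walk positions."""
        return sum(len(v) for v in self.entries.values())

    @property
    def distinct_kmers(self) -> int:
        return len(self.entries)

    def contains(self, kmer: str) -> bool:
        """Strand-agnostic membership (forward k-mers are stored)."""
        return kmer in self.entries or revcomp(kmer) in self.entries


def build_graph_kmer_index(prg: PRG, k: int,
                           max_walks_per_window: int = 2_000_000) -> KmerIndex:
    """Enumerate every k-character gap-skipping walk of the graph.

    '-' edges contribute no character; walks start and end on non-gap
    edges, so every entry has exactly k characters.  Walks containing a
    literal 'N' (spacer runs in particular) are dropped: seeds are
    exact string matches over {A,C,G,T}, so N-containing entries could
    never be hit.  A per-window guard aborts with a diagnostic if the
    number of walks through any start level explodes.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = prg.labels
    n = prg.n_levels
    entries: dict[str, list[tuple[int, str]]] = {}
    for start in range(n):
        if all(c in "-N" for c in labels[start]):
            continue
        # DFS over (level, chars collected, walk labels)
        stack: list[tuple[int, list[str], list[str]]] = []
        for c in labels[start]:
            if c not in "-N":
                stack.append((start + 1, [c], [c]))
        produced = 0
        while stack:
            lvl, chars, walk = stack.pop()
            if len(chars) == k:
                produced += 1
                if produced > max_walks_per_window:
                    raise IndexError_(
                        f"k-mer walk blow-up at level {start}: more than "
                        f"{max_walks_per_window} walks in one window")
                entries.setdefault("".join(chars), []).append(
                    (start, "".join(walk)))
                continue
            if lvl >= n:
                continue
            for c in labels[lvl]:
                if c == "N":
                    continue
                if c == "-":
                    stack.append((lvl + 1, chars, walk + [c]))
                else:
                    stack.append((lvl + 1, chars + [c], walk + [c]))
    for v in entries.values():
        v.sort()
    return KmerIndex(k=k, entries=entries)


@dataclass
class BackgroundKmerSet:
    k: int
    kmers: set[str] = field(default_factory=set)

    def contains(self, kmer: str) -> bool:
        return kmer in self.kmers


def build_background_kmer_set(ref_sequences, k: int) -> BackgroundKmerSet:
    """K-mers of un-gapped reference sequences outside the PRG.

    Both forward and reverse-complement k-mers are included; k-mers
    containing 'N' are skipped.
    """
    kmers: set[str] = set()
    for seq in ref_sequences:
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            km = seq[i:i + k]
            if "N" in km:
                continue
            kmers.add(km)
            kmers.add(revcomp(km))
    return BackgroundKmerSet(k=k, kmers=kmers)


@dataclass
class FilterThresholds:
    """Keep/discard thresholds of the read-pair pre-filter.

    A pair is kept iff (a) the fraction of its pooled k-mers present in
    the PRG strictly exceeds ``positive_fraction``, and (b) at least
    one mate carries a k-mer unique to the PRG (present in the index,
    absent from the background), or at least one mate has a background
    k-mer fraction strictly below ``background_fraction``.  With
    ``require_unique`` false the unique-k-mer arm of (b) is skipped and
    only the background-fraction arm applies.
    """

    positive_fraction: float = 0.30
    background_fraction: float = 0.45
    require_unique: bool = True
    #: optional Phred floor: k-mers touching a base below this quality
    #: are ignored entirely (default: off)
    min_base_quality: int | None = None

    def __post_init__(self):
        for v in (self.positive_fraction, self.background_fraction):
            if not 0.0 <= v <= 1.0:
                raise ValueError("filter proportions must lie in [0, 1]")


@dataclass
class FilterDecision:
    keep: bool
    reason: str | None  # None | "too_short" | "positive_selection" | "negative_selection"
    positive_fraction: float
    background_fractions: tuple[float, float]
    has_unique: bool


def _mate_kmers(seq: str, quals, k: int, qfloor: int | None) -> list[str]:
    out = []
    for i in range(len(seq) - k + 1):
        if qfloor is not None and quals is not None:
            if min(quals[i:i + k]) < qfloor:
                continue
        out.append(seq[i:i + k])
    return out


def filter_read_pair(r1: str, r2: str, index: KmerIndex,
                     background: BackgroundKmerSet, thr: FilterThresholds,
                     q1=None, q2=None) -> FilterDecision:
    """Positive/negative k-mer selection for one read pair."""
    k = index.k
    if len(r1) < k or len(r2) < k:
        return FilterDecision(False, "too_short", 0.0, (0.0, 0.0), False)
    mates = [_mate_kmers(r1.upper(), q1, k, thr.min_base_quality),
             _mate_kmers(r2.upper(), q2, k, thr.min_base_quality)]
    pooled = mates[0] + mates[1]
    if not pooled:
        return FilterDecision(False, "too_short", 0.0, (0.0, 0.0), False)

    n_pos = sum(1 for km in pooled if index.contains(km))
    pos_frac = n_pos / len(pooled)

    bg_fracs = []
    has_unique = False
    for kms in mates:
        if not kms:
            bg_fracs.append(0.0)
            continue
        n_bg = 0
        for km in kms:
            in_bg = background.contains(canonical(km))
            if in_bg:
                n_bg += 1
            elif index.contains(km):
                has_unique = True
        bg_fracs.append(n_bg / len(kms))
    bg_fracs = tuple(bg_fracs)

    if not pos_frac > thr.positive_fraction:
        return FilterDecision(False, "positive_selection", pos_frac, bg_fracs,
                              has_unique)
    negative_ok = min(bg_fracs) < thr.background_fraction
    if thr.require_unique and has_unique:
        negative_ok = True
    if not negative_ok:
        return FilterDecision(False, "negative_selection", pos_frac, bg_fracs,
                              has_unique)
    return FilterDecision(True, None, pos_frac, bg_fracs, has_unique)
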