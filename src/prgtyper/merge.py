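"""Merging tiered MSAs into a per-gene segmented alignment.

The construction follows the consensus switch-point rule: for every
allele shared between an inner (higher-resolution, e.g. exonic) and an
outer (e.g. genomic) alignment, the first and last non-gap columns of
its inner row are collected into P_L and P_R; the consensus region is
[G_L, G_R] with G_L = max(P_L), G_R = min(P_R).  The inner alignment
restricted to the consensus columns becomes a segment of the gene; the
outer sequence left and right of each consensus region is re-aligned
into flank segments.  Outer-only alleles are threaded through the
consensus block by global alignment against the block consensus.

The same rule is applied recursively to embed the merged gene into the
regional-haplotype (padding) tier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .errors import ConstructionError
from .msa import MSA
from .pairwise import progressive_msa, thread_to_block

log = logging.getLogger(__name__)


@dataclass
class SwitchPoints:
    """Per-allele and consensus switch columns (1-based, inner MSA)."""

    p_left: dict[str, int]
    p_right: dict[str, int]
    g_left: int
    g_right: int

    @property
    def P_L(self) -> set[int]:
        return set(self.p_left.values())

    @property
    def P_R(self) -> set[int]:
        return set(self.p_right.values())


@dataclass
class Segment:
    """One rectangular block of the merged gene alignment.

    Alleles absent from the segment simply have no row here (e.g.
    exon-only alleles are absent from intron/flank segments).
    """

    source_tier: str
    feature: str
    rows: dict[str, str]

    @property
    def n_columns(self) -> int:
        if not self.rows:
            return 0
        return len(next(iter(self.rows.values())))

    def restrict(self, start: int, stop: int) -> "Segment":
        return Segment(self.source_tier, self.feature,
                       {a: s[start:stop] for a, s in self.rows.items()})


@dataclass
class SegmentedGene:
    locus: str
    segments: list[Segment]
    #: characters of inner-only alleles dropped outside the consensus
    #: region (allele -> (left string, right string)); normally empty.
    trimmed: dict[str, tuple[str, str]] = field(default_factory=dict)

    @property
    def alleles(self) -> list[str]:
        seen: dict[str, None] = {}
        for seg in self.segments:
            for a in seg.rows:
                seen.setdefault(a)
        return list(seen)

    def fragments(self, allele_id: str) -> list[tuple[int, str]]:
        """Maximal runs of consecutive segments containing the allele.

        Returns (start segment index, concatenated gapped string) per
        run; zero-width segments never break a run.
        """
        runs: list[tuple[int, str]] = []
        cur_start = None
        cur: list[str] = []
        for i, seg in enumerate(self.segments):
            if allele_id in seg.rows:
                if cur_start is None:
                    cur_start = i
                cur.append(seg.rows[allele_id])
            elif seg.n_columns > 0 and cur_start is not None:
                runs.append((cur_start, "".join(cur)))
                cur_start, cur = None, []
        if cur_start is not None:
            runs.append((cur_start, "".join(cur)))
        return runs

    def reconstruct(self, allele_id: str) -> list[str]:
        """Un-gapped sequence of each contiguous fragment of the allele."""
        return [s.replace("-", "") for _, s in self.fragments(allele_id)]


def compute_switch_points(inner: MSA, outer: MSA) -> SwitchPoints:
    """Consensus switch columns between an inner and an outer MSA.

    Requires shared alleles; for each, the un-gapped inner sequence
    must be a substring of the un-gapped outer sequence.
    """
    shared = [a for a in inner.sequences if a in outer.sequences]
    if not shared:
        raise ConstructionError(
            f"{inner.locus}: no shared alleles between {inner.tier} and "
            f"{outer.tier} tiers"
        )
    for a in shared:
        if inner.ungapped(a) not in outer.ungapped(a):
            raise ConstructionError(
                f"{inner.locus}: shared allele {a!r}: un-gapped {inner.tier} "
                f"sequence is not a substring of the {outer.tier} sequence"
            )
    p_left: dict[str, int] = {}
    p_right: dict[str, int] = {}
    for a in shared:
        row = inner.sequences[a]
        first = next(i for i, c in enumerate(row) if c != "-")
        last = next(i for i in range(len(row) - 1, -1, -1) if row[i] != "-")
        p_left[a] = first + 1  # 1-based
        p_right[a] = last + 1
    g_left = max(p_left.values())
    g_right = min(p_right.values())
    if g_left > g_right:
        raise ConstructionError(
            f"{inner.locus}: consensus region empty (G_L={g_left} > G_R={g_right})"
        )
    return SwitchPoints(p_left, p_right, g_left, g_right)


def _col_of_char(row: str, char_index: int) -> int:
    """0-based column of the char_index-th (0-based) non-gap character.

    char_index == number of non-gap chars returns n_columns (one past
    the end).
    """
    seen = 0
    for col, c in enumerate(row):
        if c != "-":
            if seen == char_index:
                return col
            seen += 1
    return len(row)


def _chars_before_col(row: str, col: int) -> int:
    """Number of non-gap characters strictly before 0-based column."""
    return sum(1 for c in row[:col] if c != "-")


def _switch_points_rows(rows: dict[str, str], shared: list[str], locus: str
                        ) -> SwitchPoints:
    p_left, p_right = {}, {}
    for a in shared:
        row = rows[a]
        nz = [i for i, c in enumerate(row) if c != "-"]
        p_left[a] = nz[0] + 1
        p_right[a] = nz[-1] + 1
    g_left = max(p_left.values())
    g_right = min(p_right.values())
    if g_left > g_right:
        raise ConstructionError(f"{locus}: consensus region empty")
    return SwitchPoints(p_left, p_right, g_left, g_right)


def _merge_rows_into_outer(
    locus: str,
    blocks: list[dict[str, str]],
    block_tiers: list[str],
    block_features: list[str],
    outer_rows: dict[str, str],
    outer_tier: str,
    flank_features: list[str],
    realign=progressive_msa,
    trimmed: dict[str, tuple[str, str]] | None = None,
) -> list[Segment]:
    """Merge one or more inner blocks into an outer alignment.

    Core routine shared by the exon->genomic and gene->regional merge
    steps.  Each block is a rectangular dict of gapped rows; blocks are
    located in the outer sequences left to right via the shared
    alleles' consensus-trimmed substrings.
    """
    n_blocks = len(blocks)
    outer_ids = list(outer_rows)
    outer_ungapped = {a: outer_rows[a].replace("-", "") for a in outer_ids}

    # consensus column range per block, plus the trimmed middle rows
    sps: list[SwitchPoints] = []
    middles: list[dict[str, str]] = []
    for b, rows in enumerate(blocks):
        shared = [a for a in rows if a in outer_rows]
        if not shared:
            raise ConstructionError(
                f"{locus}: block {b + 1}: no alleles shared with the "
                f"{outer_tier} tier"
            )
        sp = _switch_points_rows(rows, shared, locus)
        sps.append(sp)
        mid = {a: s[sp.g_left - 1: sp.g_right] for a, s in rows.items()}
        middles.append(mid)
        if trimmed is not None:
            for a, s in rows.items():
                if a in outer_rows:
                    continue  # shared chars migrate to the flanks
                left = s[: sp.g_left - 1].replace("-", "")
                right = s[sp.g_right:].replace("-", "")
                if left or right:
                    log.warning(
                        "%s: allele %s loses %d char(s) outside the consensus "
                        "region of block %d", locus, a, len(left) + len(right),
                        b + 1)
                    trimmed[a] = (left, right)

    # cut positions in each outer allele's un-gapped coordinates
    shared_cuts: dict[str, list[tuple[int, int]]] = {}
    for a in outer_ids:
        if all(a in blocks[b] for b in range(n_blocks)):
            cuts: list[tuple[int, int]] = []
            prev = 0
            for b in range(n_blocks):
                mid_seq = middles[b][a].replace("-", "")
                o = outer_ungapped[a].find(mid_seq, prev)
                if o < 0:
                    raise ConstructionError(
                        f"{locus}: block {b + 1}: consensus substring of "
                        f"shared allele {a!r} not found in its {outer_tier} "
                        f"sequence"
                    )
                if mid_seq and outer_ungapped[a].find(mid_seq, o + 1) >= 0:
                    log.warning(
                        "%s: block %d: consensus substring of %s occurs more "
                        "than once in the %s sequence; using the leftmost "
                        "occurrence", locus, b + 1, a, outer_tier)
                cuts.append((o, o + len(mid_seq)))
                prev = o + len(mid_seq)
            shared_cuts[a] = cuts

    if not shared_cuts:
        raise ConstructionError(
            f"{locus}: no allele is shared with every inner block")

    # consensus boundary columns in the outer MSA (for outer-only alleles):
    # max over shared alleles of the start column, min of the end column —
    # mirroring the G_L = max / G_R = min rule.
    col_bounds: list[tuple[int, int]] = []
    for b in range(n_blocks):
        starts, ends = [], []
        for a, cuts in shared_cuts.items():
            lc, rc = cuts[b]
            starts.append(_col_of_char(outer_rows[a], lc))
            if rc > lc:
                ends.append(_col_of_char(outer_rows[a], rc - 1) + 1)
            else:
                ends.append(_col_of_char(outer_rows[a], lc))
        col_bounds.append((max(starts), min(ends)))
    for b in range(1, n_blocks):
        if col_bounds[b][0] < col_bounds[b - 1][1]:
            raise ConstructionError(
                f"{locus}: consensus regions of blocks {b} and {b + 1} "
                f"overlap in the {outer_tier} alignment")

    # cut positions for outer-only alleles, via the boundary columns
    all_cuts: dict[str, list[tuple[int, int]]] = dict(shared_cuts)
    for a in outer_ids:
        if a in shared_cuts:
            continue
        cuts = []
        for b in range(n_blocks):
            c0, c1 = col_bounds[b]
            cuts.append((_chars_before_col(outer_rows[a], c0),
                         _chars_before_col(outer_rows[a], c1)))
        all_cuts[a] = cuts

    # thread outer-only middles through each block
    for b in range(n_blocks):
        for a in outer_ids:
            if a in middles[b]:
                continue
            lc, rc = all_cuts[a][b]
            sub = outer_ungapped[a][lc:rc]
            try:
                middles[b][a] = thread_to_block(middles[b], sub)
            except ValueError as e:
                raise ConstructionError(
                    f"{locus}: block {b + 1}: cannot thread {outer_tier}-only "
                    f"allele {a!r} through the consensus block: {e}") from e

    # flank segments: re-align the outer substrings between blocks
    segments: list[Segment] = []
    for b in range(n_blocks + 1):
        flank_seqs = {}
        for a in outer_ids:
            start = 0 if b == 0 else all_cuts[a][b - 1][1]
            stop = len(outer_ungapped[a]) if b == n_blocks else all_cuts[a][b][0]
            flank_seqs[a] = outer_ungapped[a][start:stop]
        flank_rows = realign(flank_seqs)
        widths = {len(s) for s in flank_rows.values()}
        if len(widths) > 1:
            raise ConstructionError(
                f"{locus}: flank re-alignment produced a ragged block")
        for a, s in flank_rows.items():
            if s.replace("-", "") != flank_seqs[a]:
                raise ConstructionError(
                    f"{locus}: flank re-alignment corrupted allele {a!r}")
        segments.append(Segment(outer_tier, flank_features[b], flank_rows))
        if b < n_blocks:
            segments.append(Segment(block_tiers[b], block_features[b], middles[b]))
    return segments


def merge_tiers(inner: MSA, outer: MSA, realign=progressive_msa,
                feature: str = "exon_1", flank_features: list[str] | None = None,
                ) -> SegmentedGene:
    """Base case: merge a single inner block into an outer alignment."""
    return merge_blocks([inner], outer, realign=realign,
                        block_features=[feature],
                        flank_features=flank_features)


def merge_blocks(inners: list[MSA], outer: MSA, realign=progressive_msa,
                 block_features: list[str] | None = None,
                 flank_features: list[str] | None = None) -> SegmentedGene:
    """Merge ordered inner blocks (e.g. one per exon) into the outer MSA."""
    if not inners:
        raise ConstructionError("no inner blocks to merge")
    locus = outer.locus
    if block_features is None:
        block_features = [f"exon_{i + 1}" for i in range(len(inners))]
    if flank_features is None:
        flank_features = (["UTR"] +
                          [f"intron_{i + 1}" for i in range(len(inners) - 1)] +
                          ["UTR"])
    trimmed: dict[str, tuple[str, str]] = {}
    segments = _merge_rows_into_outer(
        locus,
        [m.sequences for m in inners],
        [m.tier for m in inners],
        block_features,
        outer.sequences,
        outer.tier,
        flank_features,
        realign=realign,
        trimmed=trimmed,
    )
    return SegmentedGene(locus=locus, segments=segments, trimmed=trimmed)


def merge_regional(seg: SegmentedGene, regional: MSA, realign=progressive_msa
                   ) -> SegmentedGene:
    """Embed a merged gene into the regional-haplotype (padding) tier.

    Applies the base-case rule recursively: the gene alignment,
    restricted to the alleles present in every segment, plays the role
    of the inner MSA; the regional haplotypes are the outer alignment.
    """
    locus = seg.locus
    full_ids = [a for a in seg.alleles
                if all(a in s.rows for s in seg.segments if s.n_columns > 0)]
    if not full_ids:
        raise ConstructionError(f"{locus}: no allele spans every gene segment")
    widths = [s.n_columns for s in seg.segments]
    virtual = {a: "".join(s.rows.get(a, "") for s in seg.segments)
               for a in full_ids}

    shared = [a for a in full_ids if a in regional.sequences]
    if not shared:
        raise ConstructionError(
            f"{locus}: no alleles shared between the gene and the "
            f"regional_haplotype tier")
    sp = _switch_points_rows(virtual, shared, locus)
    g0, g1 = sp.g_left - 1, sp.g_right  # 0-based half-open virtual columns

    # map the trimmed virtual column range back onto per-segment ranges
    offsets = []
    acc = 0
    for w in widths:
        offsets.append(acc)
        acc += w
    keep: list[tuple[int, int]] = []
    for off, w in zip(offsets, widths):
        lo = max(g0, off) - off
        hi = min(g1, off + w) - off
        keep.append((lo, max(lo, hi)))

    trimmed = dict(seg.trimmed)
    for a in seg.alleles:
        if a in regional.sequences:
            continue
        frags = seg.fragments(a)
        for start_idx, gapped in frags:
            off0 = offsets[start_idx]
            lost_left = gapped[: max(0, g0 - off0)].replace("-", "")
            end_excess = (off0 + len(gapped)) - g1
            lost_right = (gapped[len(gapped) - end_excess:].replace("-", "")
                          if end_excess > 0 else "")
            if lost_left or lost_right:
                log.warning("%s: allele %s loses %d char(s) trimming to the "
                            "regional consensus", locus, a,
                            len(lost_left) + len(lost_right))
                trimmed[a] = (lost_left, lost_right)

    inner_rows = {a: v[g0:g1] for a, v in virtual.items()}
    outer_segments = _merge_rows_into_outer(
        locus,
        [inner_rows],
        ["genomic"],
        ["__gene__"],
        regional.sequences,
        regional.tier,
        ["padding", "padding"],
        realign=realign,
    )
    assert len(outer_segments) == 3
    left_pad, gene_block, right_pad = outer_segments

    # re-split the merged gene block into the original segments, with
    # regional-only threaded rows distributed across them
    new_segments: list[Segment] = [left_pad]
    pos = 0
    for s, (lo, hi), off in zip(seg.segments, keep, offsets):
        w = hi - lo
        rows: dict[str, str] = {}
        for a in gene_block.rows:
            rows[a] = gene_block.rows[a][pos:pos + w]
        for a in s.rows:
            if a in rows:
                continue
            # partially-present allele (e.g. exon-only): its own row,
            # restricted to the kept columns of this segment
            rows[a] = s.rows[a][lo:hi]
        if w > 0:
            new_segments.append(Segment(s.source_tier, s.feature, rows))
        pos += w
    new_segments.append(right_pad)
    return SegmentedGene(locus=locus, segments=new_segments, trimmed=trimmed)


def merge_gene(exonic_blocks: list[MSA], genomic: MSA,
               regional: MSA | None = None, realign=progressive_msa,
               block_features: list[str] | None = None) -> SegmentedGene:
    """Full per-gene merge: exon blocks -> genomic -> regional padding."""
    seg = merge_blocks(exonic_blocks, genomic, realign=realign,
                       block_features=block_features)
    if regional is not None:
        seg = merge_regional(seg, regional, realign=realign)
    return seg
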