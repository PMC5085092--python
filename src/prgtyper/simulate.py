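"""Synthetic allele databases, diploid samples and paired-end reads.

The generator emulates the structure of a curated HLA-style allele
database: a handful of paralogous loci; many alleles known only at
exon resolution and fewer with full genomic or regional-haplotype
sequence (tiers nest: regional ids within genomic ids within exonic
ids); inter-allele divergence concentrated in the peptide-binding-site
exons; occasional small indels.  Because variants are planted against
an explicit per-locus column coordinate system, the tiered MSAs are
exact by construction (true homology, no aligner involved) and every
read's origin is recorded, so downstream modules can be tested against
known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .kmer import revcomp
from .msa import MSA

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for the synthetic data generator.

    Defaults model a compact desk-scale version of a whole-genome HLA
    typing experiment: three loci with ten known alleles each (four
    with genomic sequence, two embedded in regional haplotypes), ~2%
    inter-allele divergence at the peptide-binding site, PCR-free
    2x100bp paired reads at 30x diploid coverage with 0.2% base errors.
    """

    n_loci: int = 3
    n_alleles: int = 10          # alleles per locus (all have exon records)
    n_genomic: int = 4           # of which: full genomic sequence
    n_regional: int = 2          # of which: regional haplotype w/ padding
    locus_classes: tuple[str, ...] = ("I", "II", "I")
    utr_length: int = 60
    exon_lengths: tuple[int, ...] = (90, 210, 210)
    intron_lengths: tuple[int, ...] = (120, 120)
    padding_length: int = 500
    pbs_divergence: float = 0.02     # per-column substitution rate, PBS exons
    offpbs_divergence: float = 0.005  # other exons, introns, UTRs, padding
    interlocus_divergence: float = 0.15
    #: expected small indels per genomic-tier allele, planted in
    #: non-coding gene-body features (introns/UTRs)
    indels_per_allele: float = 0.5
    #: exon indel events per locus (coding indels are rare in curated
    #: allele alignments; each event is owned by one random allele)
    exon_indels_per_locus: int = 1
    indel_max_len: int = 4
    #: optionally plant an identical exon between two loci:
    #: (locus_a index, locus_b index, exon number)
    paralog_exon: tuple[int, int, int] | None = None
    read_length: int = 100
    fragment_mean: float = 350.0
    fragment_sd: float = 50.0
    error_rate: float = 0.002
    coverage: float = 30.0       # total diploid depth
    seed: int = 0

    def __post_init__(self):
        for r in (self.pbs_divergence, self.offpbs_divergence,
                  self.interlocus_divergence, self.error_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if not (self.n_regional <= self.n_genomic <= self.n_alleles):
            raise ValueError("tiers must nest: n_regional <= n_genomic <= n_alleles")
        if len(self.exon_lengths) != len(self.intron_lengths) + 1:
            raise ValueError("need one fewer intron than exons")

    def locus_names(self) -> list[str]:
        return [f"L{i + 1}" for i in range(self.n_loci)]

    def pbs_exons(self, locus_index: int) -> tuple[int, ...]:
        cls = self.locus_classes[locus_index % len(self.locus_classes)]
        return (2, 3) if cls == "I" else (2,)


@dataclass
class LocusData:
    """One locus's master alignment: columns, features and allele rows."""

    locus: str
    features: list[str]                  # per master column
    rows: dict[str, str]                 # allele -> gapped row, all columns
    pbs_exons: tuple[int, ...]

    def full_haplotype(self, allele_id: str) -> str:
        return self.rows[allele_id].replace("-", "")


@dataclass
class AlleleDB:
    """Tiered MSAs plus the truth registry for every locus."""

    config: SimConfig
    loci: dict[str, LocusData] = field(default_factory=dict)

    def exonic_msas(self, locus: str) -> list[MSA]:
        ld = self.loci[locus]
        out = []
        n_exons = len(self.config.exon_lengths)
        for e in range(1, n_exons + 1):
            idx = [i for i, f in enumerate(ld.features) if f == f"exon_{e}"]
            seqs = {a: "".join(row[i] for i in idx)
                    for a, row in ld.rows.items()}
            out.append(MSA(tier="exonic", locus=locus, sequences=seqs))
        return out

    def genomic_msa(self, locus: str) -> MSA:
        ld = self.loci[locus]
        cfg = self.config
        idx = [i for i, f in enumerate(ld.features) if f != "padding"]
        ids = list(ld.rows)[:cfg.n_genomic]
        return MSA(tier="genomic", locus=locus,
                   sequences={a: "".join(ld.rows[a][i] for i in idx)
                              for a in ids})

    def regional_msa(self, locus: str) -> MSA:
        ld = self.loci[locus]
        ids = list(ld.rows)[:self.config.n_regional]
        return MSA(tier="regional_haplotype", locus=locus,
                   sequences={a: ld.rows[a] for a in ids})

    def full_haplotype(self, locus: str, allele_id: str) -> str:
        return self.loci[locus].full_haplotype(allele_id)

    def allele_ids(self, locus: str) -> list[str]:
        return list(self.loci[locus].rows)


def _layout(cfg: SimConfig) -> list[str]:
    feats: list[str] = ["padding"] * cfg.padding_length
    feats += ["UTR"] * cfg.utr_length
    for e, elen in enumerate(cfg.exon_lengths, start=1):
        feats += [f"exon_{e}"] * elen
        if e <= len(cfg.intron_lengths):
            feats += [f"intron_{e}"] * cfg.intron_lengths[e - 1]
    feats += ["UTR"] * cfg.utr_length
    feats += ["padding"] * cfg.padding_length
    return feats


def _mutate(seq: np.ndarray, mask: np.ndarray, rate: float,
            rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    hit = np.where(mask & (rng.random(len(seq)) < rate))[0]
    for i in hit:
        choices = [b for b in "ACGT" if b != out[i]]
        out[i] = choices[rng.integers(3)]
    return out


def _pbs_mask(features: list[str], pbs_exons: tuple[int, ...]) -> np.ndarray:
    wanted = {f"exon_{k}" for k in pbs_exons}
    return np.array([f in wanted for f in features])


def _interior(mask: np.ndarray, features: list[str], margin: int = 2
              ) -> np.ndarray:
    """Positions of the mask at least ``margin`` columns away from any
    mask edge or feature-block boundary (indels planted here never touch
    block edges, keeping switch-point boundaries gap-free)."""
    n = len(mask)
    out = mask.copy()
    for j in range(n):
        if not mask[j]:
            continue
        lo, hi = max(0, j - margin), min(n, j + margin + 1)
        if not mask[lo:hi].all() or len(set(features[lo:hi])) > 1:
            out[j] = False
    return out


def generate_allele_db(cfg: SimConfig) -> AlleleDB:
    """Generate tiered MSAs and full haplotypes for every locus.

    Fully deterministic under ``cfg.seed``.  PBS genotypes are kept
    distinct between alleles (each allele founds its own G group)
    unless the configured PBS divergence is zero.
    """
    rng = np.random.default_rng(cfg.seed)
    features = _layout(cfg)
    n_cols = len(features)
    root = _BASES[rng.integers(4, size=n_cols)]
    db = AlleleDB(config=cfg)
    ancestors: dict[int, np.ndarray] = {}
    for li, locus in enumerate(cfg.locus_names()):
        anc = _mutate(root, np.ones(n_cols, bool), cfg.interlocus_divergence,
                      rng)
        ancestors[li] = anc
    if cfg.paralog_exon is not None:
        la, lb, exon = cfg.paralog_exon
        mask = np.array([f == f"exon_{exon}" for f in features])
        ancestors[lb][mask] = ancestors[la][mask]

    for li, locus in enumerate(cfg.locus_names()):
        anc = ancestors[li]
        pbs_exons = cfg.pbs_exons(li)
        pbs = _pbs_mask(features, pbs_exons)
        exon_mask = np.array([f.startswith("exon") for f in features])
        body_mask = np.array([f != "padding" for f in features])
        paralog_frozen = np.zeros(n_cols, bool)
        if cfg.paralog_exon is not None and li in cfg.paralog_exon[:2]:
            # the shared exon is frozen in both loci so the planted
            # homology is verbatim
            paralog_frozen = np.array(
                [f == f"exon_{cfg.paralog_exon[2]}" for f in features])

        rows_chars: dict[str, np.ndarray] = {}
        insertions: list[tuple[int, str, str]] = []  # (after col, allele, seq)
        seen_pbs: dict[str, str] = {}
        for ai in range(cfg.n_alleles):
            allele = f"{locus}*{ai + 1:02d}"
            genomic = ai < cfg.n_genomic
            regional = ai < cfg.n_regional
            sub_mask = exon_mask.copy()
            if genomic:
                sub_mask |= body_mask
            if regional:
                sub_mask |= np.ones(n_cols, bool)
            sub_mask &= ~paralog_frozen
            mutable_pbs = bool((sub_mask & pbs).any())
            for attempt in range(20):
                row = _mutate(anc, sub_mask & pbs, cfg.pbs_divergence, rng)
                row = _mutate(row, sub_mask & ~pbs, cfg.offpbs_divergence, rng)
                key = "".join(row[pbs])
                if cfg.pbs_divergence == 0 or not mutable_pbs \
                        or key not in seen_pbs:
                    break
            else:
                raise RuntimeError(
                    f"{locus}: could not generate a distinct PBS genotype "
                    f"for {allele}")
            seen_pbs.setdefault(key, allele)
            rows_chars[allele] = row

            # non-coding indels for genomic-tier alleles; coding-exon
            # indels are planted separately (bounded per locus) below
            if genomic:
                interior = _interior(body_mask & ~exon_mask, features)
                cand = np.where(interior & ~paralog_frozen)[0]
                for _ in range(rng.poisson(cfg.indels_per_allele)):
                    if len(cand) == 0:
                        break
                    pos = int(cand[rng.integers(len(cand))])
                    length = int(rng.integers(1, cfg.indel_max_len + 1))
                    if rng.random() < 0.5:
                        stop = min(pos + length, n_cols)
                        if interior[pos:stop].all():
                            rows_chars[allele][pos:stop] = "-"
                    else:
                        seq = "".join(_BASES[rng.integers(4, size=length)])
                        insertions.append((pos, allele, seq))

        # a bounded number of coding-exon indel events per locus, each
        # owned by one random allele
        exon_interior = _interior(exon_mask, features)
        exon_cand = np.where(exon_interior & ~paralog_frozen)[0]
        allele_names = list(rows_chars)
        for _ in range(cfg.exon_indels_per_locus):
            if len(exon_cand) == 0:
                break
            owner = allele_names[int(rng.integers(len(allele_names)))]
            pos = int(exon_cand[rng.integers(len(exon_cand))])
            length = int(rng.integers(1, cfg.indel_max_len + 1))
            if rng.random() < 0.5:
                stop = min(pos + length, n_cols)
                if exon_interior[pos:stop].all():
                    rows_chars[owner][pos:stop] = "-"
            else:
                seq = "".join(_BASES[rng.integers(4, size=length)])
                insertions.append((pos, owner, seq))

        # expand insertion columns into the master alignment
        ins_by_col: dict[int, list[tuple[str, str]]] = {}
        for pos, allele, seq in insertions:
            ins_by_col.setdefault(pos, []).append((allele, seq))
        out_feats: list[str] = []
        out_rows: dict[str, list[str]] = {a: [] for a in rows_chars}
        for j in range(n_cols):
            out_feats.append(features[j])
            for a in rows_chars:
                out_rows[a].append(rows_chars[a][j])
            for owner, seq in ins_by_col.get(j, ()):
                for c in seq:
                    out_feats.append(features[j])
                    for a in rows_chars:
                        out_rows[a].append(c if a == owner else "-")
        db.loci[locus] = LocusData(
            locus=locus, features=out_feats,
            rows={a: "".join(v) for a, v in out_rows.items()},
            pbs_exons=pbs_exons)
    return db


# ----------------------------------------------------------------------
# read simulation
# ----------------------------------------------------------------------

@dataclass
class SimulatedPair:
    read_id: str
    r1: str
    q1: str
    r2: str
    q2: str
    locus: str
    allele: str
    fragment_start: int
    fragment_length: int
    n_errors: int


def _phred_char(error_rate: float) -> str:
    q = 40 if error_rate <= 0 else int(round(-10 * np.log10(error_rate)))
    return chr(33 + max(2, min(q, 40)))


def _plant_errors(seq: str, rate: float, rng: np.random.Generator
                  ) -> tuple[str, int]:
    if rate <= 0:
        return seq, 0
    arr = np.array(list(seq))
    hit = np.where(rng.random(len(arr)) < rate)[0]
    for i in hit:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr), len(hit)


def simulate_diploid_reads(db: AlleleDB, truth: dict[str, tuple[str, str]],
                           cfg: SimConfig | None = None,
                           rng: np.random.Generator | None = None,
                           sample: str = "S0") -> list[SimulatedPair]:
    """Paired-end reads from a diploid sample with recorded truth.

    ``truth`` maps locus -> (allele1, allele2).  Fragments are drawn
    uniformly along each haplotype with normal lengths, sequenced from
    both ends in forward/reverse orientation, and errors planted at the
    configured rate with Phred qualities that encode that rate.
    """
    cfg = cfg or db.config
    rng = rng or np.random.default_rng(cfg.seed + 1)
    rl = cfg.read_length
    qchar = _phred_char(cfg.error_rate)
    pairs: list[SimulatedPair] = []
    for locus in sorted(truth):
        a1, a2 = truth[locus]
        for hap_no, allele in enumerate((a1, a2)):
            hap = db.full_haplotype(locus, allele)
            L = len(hap)
            n_frags = max(1, int(round(cfg.coverage / 2 * L / (2 * rl))))
            for f in range(n_frags):
                for _ in range(100):
                    fl = int(round(rng.normal(cfg.fragment_mean,
                                              cfg.fragment_sd)))
                    if rl <= fl <= L:
                        break
                else:
                    fl = min(L, max(rl, int(cfg.fragment_mean)))
                start = int(rng.integers(0, L - fl + 1))
                frag = hap[start:start + fl]
                fwd = frag[:rl]
                rev = revcomp(frag[-rl:])
                fwd, e1 = _plant_errors(fwd, cfg.error_rate, rng)
                rev, e2 = _plant_errors(rev, cfg.error_rate, rng)
                if rng.random() < 0.5:
                    r1, r2 = fwd, rev
                else:
                    r1, r2 = rev, fwd
                pairs.append(SimulatedPair(
                    read_id=f"{sample}:{locus}:h{hap_no + 1}:{f}",
                    r1=r1, q1=qchar * rl, r2=r2, q2=qchar * rl,
                    locus=locus, allele=allele, fragment_start=start,
                    fragment_length=fl, n_errors=e1 + e2))
    return pairs


def make_background(length: int, rng: np.random.Generator,
                    embed: str | None = None) -> str:
    """Random reference sequence outside the PRG, optionally embedding
    a verbatim copy of PRG sequence (shared-homology fixture)."""
    seq = "".join(_BASES[rng.integers(4, size=length)])
    if embed:
        pos = length // 2
        seq = seq[:pos] + embed + seq[pos + len(embed):]
    return seq


def simulate_background_pairs(ref: str, n_pairs: int, cfg: SimConfig,
                              rng: np.random.Generator,
                              region: tuple[int, int] | None = None
                              ) -> list[SimulatedPair]:
    """Error-model-matched read pairs from a background reference."""
    rl = cfg.read_length
    qchar = _phred_char(cfg.error_rate)
    lo, hi = region if region else (0, len(ref))
    out = []
    for f in range(n_pairs):
        fl = int(round(rng.normal(cfg.fragment_mean, cfg.fragment_sd)))
        fl = max(rl, min(fl, hi - lo))
        start = int(rng.integers(lo, hi - fl + 1))
        frag = ref[start:start + fl]
        fwd, _ = _plant_errors(frag[:rl], cfg.error_rate, rng)
        rev, _ = _plant_errors(revcomp(frag[-rl:]), cfg.error_rate, rng)
        out.append(SimulatedPair(
            read_id=f"bg:{f}", r1=fwd, q1=qchar * rl, r2=rev, q2=qchar * rl,
            locus="", allele="", fragment_start=start, fragment_length=fl,
            n_errors=0))
    return out


def build_prg_from_db(db: AlleleDB, spacer_length: int = 2000):
    """Merge every locus of a synthetic database and build the joint PRG."""
    from .merge import merge_gene
    from .prg import build_gene_graph, build_joint_prg

    gene_prgs = []
    for li, locus in enumerate(db.loci):
        seg = merge_gene(db.exonic_msas(locus), db.genomic_msa(locus),
                         db.regional_msa(locus))
        gene_prgs.append(build_gene_graph(
            seg, pbs_exons=db.config.pbs_exons(li)))
    return build_joint_prg(gene_prgs, spacer_length=spacer_length)


def random_prg_fixture(rng: np.random.Generator, n_cols: int = 80,
                       n_variant_cols: int = 6, gap_prob: float = 0.3):
    """A small random PRG with a bounded number of source-sink paths.

    Starts from a random linear sequence and plants ``n_variant_cols``
    biallelic columns (SNP or deletion bubbles), so the graph has
    exactly 2**n_variant_cols source-to-sink paths — small enough for
    exhaustive path enumeration.  Built through the regular segment
    machinery so the production code path is exercised.
    """
    from .merge import Segment, SegmentedGene
    from .prg import build_gene_graph

    anc = _BASES[rng.integers(4, size=n_cols)]
    var_cols = sorted(rng.choice(np.arange(1, n_cols - 1), size=n_variant_cols,
                                 replace=False))
    alt = anc.copy()
    for j in var_cols:
        if rng.random() < gap_prob:
            alt[j] = "-"
        else:
            choices = [b for b in "ACGT" if b != anc[j]]
            alt[j] = choices[rng.integers(3)]
    seg = SegmentedGene(locus="RND", segments=[Segment(
        "genomic", "exon_1",
        {"RND*01": "".join(anc), "RND*02": "".join(alt)})])
    return build_gene_graph(seg, pbs_exons=(1,))


def sample_read_from_prg(prg, rng: np.random.Generator, length: int = 80,
                         error_rate: float = 0.02) -> str:
    """A read drawn from a uniformly random source-sink path of a small
    graph, with substitution errors planted at ``error_rate``."""
    chars = []
    for ls in prg.labels:
        c = ls[rng.integers(len(ls))]
        if c != "-":
            chars.append(c)
    seq = "".join(chars)
    if len(seq) <= length:
        read = seq
    else:
        start = int(rng.integers(0, len(seq) - length + 1))
        read = seq[start:start + length]
    read, _ = _plant_errors(read, error_rate, rng)
    return read


# ----------------------------------------------------------------------
# the shipped toy fixture
# ----------------------------------------------------------------------

def make_toy_fixture() -> dict[str, MSA]:
    """Hand-built tiered MSAs of one small gene.

    Two regional haplotypes, two genomic alleles and four exonic
    alleles; the two genomic identifiers are shared across tiers.  The
    exon row of shared allele TOY*01 begins with two gap columns
    followed by ACGT, so its left switch point contributes the value 3
    to P_L; consensus switch points are G_L=3, G_R=10.
    """
    exonic = MSA(tier="exonic", locus="TOY", sequences={
        "TOY*01": "--ACGTACGT--",
        "TOY*02": "TTACGTACGTAA",
        "TOY*03": "--ACGAACGT--",
        "TOY*04": "--ACGTACGA--",
    })
    genomic = MSA(tier="genomic", locus="TOY", sequences={
        "TOY*01": "GGGG--ACGTACGT--CCCC",
        "TOY*02": "GGGATTACGTACGTAACCTT",
    })
    regional = MSA(tier="regional_haplotype", locus="TOY", sequences={
        "TOY*01": "ACAC" + "GGGG--ACGTACGT--CCCC" + "GTGT",
        "TOY*02": "ACAC" + "GGGATTACGTACGTAACCTT" + "GTGT",
    })
    return {"exonic": exonic, "genomic": genomic, "regional": regional}
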