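"""End-to-end orchestration and the versioned on-disk formats.

Stages communicate through documented text files so each is testable
in isolation: aligned FASTA MSAs in, PRG text + JSON sidecar, kept
FASTQ plus a TSV filter decision log, an alignment TSV consumed by the
genotyper, and a final calls TSV.

MSA file naming convention: ``<locus>.exonic.fasta`` (single exon
block) or ``<locus>.exonic_<i>.fasta`` (one per exon, 1-based),
``<locus>.genomic.fasta``, ``<locus>.regional_haplotype.fasta``.
"""

from __future__ import annotations

import dataclasses
import logging
import re
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .align import InsertSizeModel, ScoringParams, align_read_pair
from .errors import PipelineError
from .genotype import genotype_locus, read_kmer_set
from .kmer import (FilterThresholds, KmerIndex, build_background_kmer_set,
                   build_graph_kmer_index, filter_read_pair)
from .merge import merge_gene
from .msa import read_msa
from .prg import PBS_EXONS_CLASS_I, PBS_EXONS_CLASS_II, PRG, build_gene_graph, \
    build_joint_prg

log = logging.getLogger(__name__)

ALIGNMENT_FORMAT_VERSION = 1
CALLS_COLUMNS = ["Locus", "Chromosome", "Allele", "Q1", "Q2", "KmerCoverage",
                 "UnaccountedColumns", "NReads"]


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    msa_dir: str = ""
    out_dir: str = "prgtyper_out"
    r1: str = ""
    r2: str = ""
    background: str = ""
    loci: list[str] = field(default_factory=list)
    #: locus -> "I" or "II" (peptide-binding-site exon choice)
    locus_classes: dict[str, str] = field(default_factory=dict)
    k: int = 31
    padding: int = 500
    spacer: int = 2000
    positive_fraction: float = 0.30
    background_fraction: float = 0.45
    insert_mean: float = 350.0
    insert_sd: float = 50.0
    min_depth: int = 5
    seed: int = 0
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(
                f"config: unknown keys {sorted(unknown)}; known keys are "
                f"{sorted(known)}")
        return cls(**data)

    def echo(self, out_dir: Path) -> None:
        with open(out_dir / "config_used.yaml", "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _pbs_exons_for(locus: str, classes: dict[str, str]):
    cls = classes.get(locus, "I")
    return PBS_EXONS_CLASS_I if cls == "I" else PBS_EXONS_CLASS_II


def discover_msas(msa_dir) -> dict[str, dict]:
    """Scan a directory for tiered MSA files, grouped per locus."""
    msa_dir = Path(msa_dir)
    out: dict[str, dict] = {}
    pat = re.compile(
        r"^(?P<locus>[^.]+)\.(?P<tier>exonic(?:_\d+)?|genomic|"
        r"regional_haplotype)\.fasta$")
    for p in sorted(msa_dir.glob("*.fasta")):
        m = pat.match(p.name)
        if not m:
            continue
        locus = m.group("locus")
        tier = m.group("tier")
        entry = out.setdefault(locus, {"exonic": [], "genomic": None,
                                       "regional": None})
        if tier.startswith("exonic"):
            entry["exonic"].append(p)
        elif tier == "genomic":
            entry["genomic"] = p
        else:
            entry["regional"] = p
    for locus, entry in out.items():
        entry["exonic"].sort()
        if not entry["exonic"] or entry["genomic"] is None:
            raise PipelineError(
                f"build-prg: locus {locus!r} needs at least one exonic MSA "
                f"and a genomic MSA in {msa_dir}")
    if not out:
        raise PipelineError(f"build-prg: no MSA files found in {msa_dir}")
    return out


def build_prg_from_dir(msa_dir, locus_classes: dict[str, str] | None = None,
                       spacer: int = 2000) -> PRG:
    """Read tiered MSAs, merge each gene and build the joint PRG."""
    locus_classes = locus_classes or {}
    found = discover_msas(msa_dir)
    gene_prgs = []
    for locus in sorted(found):
        entry = found[locus]
        exonic = [read_msa(p, "exonic", locus) for p in entry["exonic"]]
        genomic = read_msa(entry["genomic"], "genomic", locus)
        regional = (read_msa(entry["regional"], "regional_haplotype", locus)
                    if entry["regional"] else None)
        seg = merge_gene(exonic, genomic, regional)
        gene_prgs.append(build_gene_graph(
            seg, pbs_exons=_pbs_exons_for(locus, locus_classes)))
    return build_joint_prg(gene_prgs, spacer_length=spacer)


# ----------------------------------------------------------------------
# FASTQ streaming
# ----------------------------------------------------------------------

def read_fastq_pairs(r1_path, r2_path):
    """Yield (id, seq1, quals1, seq2, quals2); mates paired by order."""
    from Bio import SeqIO
    for p in (r1_path, r2_path):
        if not Path(p).exists():
            raise PipelineError(f"missing mate file: {p}")
    it1 = SeqIO.parse(str(r1_path), "fastq")
    it2 = SeqIO.parse(str(r2_path), "fastq")
    for rec1, rec2 in zip(it1, it2):
        yield (rec1.id, str(rec1.seq).upper(),
               rec1.letter_annotations["phred_quality"],
               str(rec2.seq).upper(),
               rec2.letter_annotations["phred_quality"])


def write_fastq(records, path) -> None:
    with open(path, "w") as fh:
        for rid, seq, quals in records:
            q = "".join(chr(33 + min(q, 60)) for q in quals)
            fh.write(f"@{rid}\n{seq}\n+\n{q}\n")


# ----------------------------------------------------------------------
# filter stage
# ----------------------------------------------------------------------

def run_filter(prg: PRG, r1_path, r2_path, background_seqs, k: int,
               thr: FilterThresholds, out_prefix,
               index: KmerIndex | None = None) -> tuple[int, int]:
    """Filter mate files; write kept FASTQs and a TSV decision log."""
    if index is None:
        index = build_graph_kmer_index(prg, k)
    background = build_background_kmer_set(background_seqs, k)
    kept1, kept2 = [], []
    n_kept = n_total = 0
    out_prefix = Path(out_prefix)
    with open(str(out_prefix) + ".decisions.tsv", "w") as logfh:
        logfh.write("read_id\tkeep\treason\tpositive_fraction\t"
                    "background_fraction_1\tbackground_fraction_2\n")
        for rid, s1, q1, s2, q2 in read_fastq_pairs(r1_path, r2_path):
            n_total += 1
            d = filter_read_pair(s1, s2, index, background, thr, q1=q1, q2=q2)
            logfh.write(
                f"{rid}\t{int(d.keep)}\t{d.reason or '.'}\t"
                f"{d.positive_fraction:.4f}\t{d.background_fractions[0]:.4f}\t"
                f"{d.background_fractions[1]:.4f}\n")
            if d.keep:
                n_kept += 1
                kept1.append((rid, s1, q1))
                kept2.append((rid, s2, q2))
    write_fastq(kept1, str(out_prefix) + ".r1.fastq")
    write_fastq(kept2, str(out_prefix) + ".r2.fastq")
    return n_kept, n_total


# ----------------------------------------------------------------------
# alignment stage and its TSV format
# ----------------------------------------------------------------------

def _encode_mate(aln) -> tuple[str, str, str]:
    """ops string over traversed levels + quality string of consumed bases."""
    lvl_map = {}
    quals = []
    for lvl, lab, j in aln.columns:
        if lvl is None:
            continue
        if j is None:
            lvl_map[lvl] = "-"
        else:
            lvl_map[lvl] = aln.oriented_seq[j]
            quals.append(int(round(-10 * np.log10(aln.oriented_eps[j]))))
    levels = sorted(lvl_map)
    ops = "".join(lvl_map[lvl] for lvl in levels)
    qstr = "".join(chr(33 + min(q, 60)) for q in quals)
    return str(levels[0]), ops, qstr


def write_alignments(results, path) -> None:
    """One row per selected paired alignment.

    Columns: read id, mapping quality, per-mate (strand, start level,
    ops, quals) and run-length-free per-position qualities; ops is the
    read base placed at each traversed level or '-' for levels crossed
    without consuming a base.
    """
    with open(path, "w") as fh:
        fh.write(f"#prgtyper-alignments\tversion={ALIGNMENT_FORMAT_VERSION}\n")
        fh.write("read_id\tmapq\tstrand1\tstart1\tops1\tquals1\t"
                 "strand2\tstart2\tops2\tquals2\n")
        for rid, (sel, mapq, _posq, _pairs) in results:
            f1 = _encode_mate(sel.alignment1)
            f2 = _encode_mate(sel.alignment2)
            fh.write(f"{rid}\t{mapq:.6f}\t{sel.alignment1.strand}\t"
                     f"{f1[0]}\t{f1[1]}\t{f1[2]}\t{sel.alignment2.strand}\t"
                     f"{f2[0]}\t{f2[1]}\t{f2[2]}\n")


def load_alignments(path):
    """Re-load selected paired alignments (genotyping-sufficient view)."""
    from .align import GraphAlignment, PairedAlignment
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#prgtyper-alignments"):
            raise PipelineError(f"{path}: not an alignment TSV")
        fh.readline()  # column names
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            rid, mapq = parts[0], float(parts[1])
            alns = []
            for mate, off in ((1, 2), (2, 6)):
                strand, start, ops, qstr = parts[off:off + 4]
                start = int(start)
                cols = []
                seq = []
                eps = []
                j = 0
                qi = 0
                for i, c in enumerate(ops):
                    if c == "-":
                        cols.append((start + i, "-", None))
                    else:
                        cols.append((start + i, c, j))
                        seq.append(c)
                        eps.append(10 ** (-(ord(qstr[qi]) - 33) / 10))
                        j += 1
                        qi += 1
                alns.append(GraphAlignment(
                    mate=mate, strand=strand, columns=cols, clip_left=0,
                    clip_right=0, score=0.0, oriented_seq="".join(seq),
                    oriented_eps=np.array(eps)))
            pa = PairedAlignment(alns[0], alns[1], 0, True, 0.0,
                                 posterior=mapq)
            out.append((rid, pa))
    return out


def run_align(prg: PRG, index: KmerIndex, r1_path, r2_path,
              params: ScoringParams, model: InsertSizeModel, out_path,
              ) -> tuple[int, int]:
    """Align all pairs of two mate files; returns (aligned, total)."""
    results = []
    n_total = 0
    for rid, s1, q1, s2, q2 in read_fastq_pairs(r1_path, r2_path):
        n_total += 1
        res = align_read_pair(s1, q1, s2, q2, prg, index, params, model)
        if res is not None:
            results.append((rid, res))
    write_alignments(results, out_path)
    return len(results), n_total


# ----------------------------------------------------------------------
# typing stage
# ----------------------------------------------------------------------

def run_type(prg: PRG, alignments, loci: list[str], params: ScoringParams,
             out_path, read_seqs=None, k: int = 31, min_depth: int = 5
             ) -> dict[str, object]:
    """Genotype each locus from selected alignments; write calls TSV."""
    read_kmers = read_kmer_set(read_seqs, k) if read_seqs is not None else None
    calls = {}
    with open(out_path, "w") as fh:
        fh.write("\t".join(CALLS_COLUMNS) + "\n")
        for locus in loci:
            call = genotype_locus(locus, prg, alignments, params,
                                  read_kmers=read_kmers, k=k,
                                  min_depth=min_depth)
            calls[locus] = call
            if call is None:
                log.warning("locus %s: no PBS-overlapping reads — no call",
                            locus)
                continue
            for chrom, allele in enumerate([call.allele1, call.allele2],
                                           start=1):
                cov = call.kmer_coverage.get(allele, float("nan"))
                fh.write(f"{locus}\t{chrom}\t{allele}\t{call.q1:.6f}\t"
                         f"{call.q2:.6f}\t{cov:.4f}\t"
                         f"{call.unaccounted_columns}\t{call.n_reads}\n")
    return calls


# ----------------------------------------------------------------------
# full pipeline
# ----------------------------------------------------------------------

def run_pipeline(cfg: RunConfig) -> dict[str, object]:
    """build-prg -> filter -> align -> type, with file handoffs."""
    logging.basicConfig(level=getattr(logging, cfg.verbosity, logging.INFO),
                        stream=sys.stderr)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.echo(out)
    for p in (cfg.r1, cfg.r2):
        if not Path(p).exists():
            raise PipelineError(f"input: missing mate file {p}")

    log.info("stage build-prg")
    prg = build_prg_from_dir(cfg.msa_dir, cfg.locus_classes, cfg.spacer)
    prg.save(out / "graph.prg")

    log.info("stage filter")
    background_seqs = []
    if cfg.background:
        from Bio import SeqIO
        background_seqs = [str(r.seq).upper()
                           for r in SeqIO.parse(cfg.background, "fasta")]
    thr = FilterThresholds(positive_fraction=cfg.positive_fraction,
                           background_fraction=cfg.background_fraction)
    index = build_graph_kmer_index(prg, cfg.k)
    n_kept, n_total = run_filter(prg, cfg.r1, cfg.r2, background_seqs,
                                 cfg.k, thr, out / "filtered", index=index)
    log.info("filter kept %d/%d pairs", n_kept, n_total)

    log.info("stage align")
    params = ScoringParams()
    model = InsertSizeModel(mean=cfg.insert_mean, sd=cfg.insert_sd)
    n_aln, _ = run_align(prg, index, out / "filtered.r1.fastq",
                         out / "filtered.r2.fastq", params, model,
                         out / "alignments.tsv")
    log.info("aligned %d pairs", n_aln)

    log.info("stage type")
    loci = cfg.loci or prg.loci
    alignments = load_alignments(out / "alignments.tsv")
    read_seqs = []
    for _rid, s1, _q1, s2, _q2 in read_fastq_pairs(
            out / "filtered.r1.fastq", out / "filtered.r2.fastq"):
        read_seqs.extend([s1, s2])
    calls = run_type(prg, alignments, loci, params, out / "calls.tsv",
                     read_seqs=read_seqs, k=cfg.k, min_depth=cfg.min_depth)
    return {"prg": prg, "calls": calls, "n_kept": n_kept,
            "n_aligned": n_aln, "out_dir": out}
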