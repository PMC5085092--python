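"""The leveled population reference graph (PRG).

The graph is a leveled DAG over single-character edge labels in which
orthologous and identical regions are collapsed locally: there is one
node per level boundary, and the edges between boundaries L and L+1
are the distinct characters observed in alignment column L among the
alleles threading that segment.  '-' is a graph-encoded gap (an edge
consuming no read base); 'N' is a literal wildcard base.  Each input
allele is recorded as one or more contiguous path fragments (exon-only
alleles have no representation in intron or padding segments).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .errors import ConstructionError
from .merge import SegmentedGene

FORMAT_VERSION = 1

#: default peptide-binding-site exons by gene class
PBS_EXONS_CLASS_I = (2, 3)
PBS_EXONS_CLASS_II = (2,)


@dataclass
class PRG:
    #: sorted tuple of edge labels per level (index = level, 0-based)
    labels: list[tuple[str, ...]]
    #: (locus, feature) per level; spacer levels use ("", "spacer")
    features: list[tuple[str, str]]
    #: allele id -> list of path fragments (start level, label string)
    allele_paths: dict[str, list[tuple[int, str]]]
    #: locus -> exon numbers whose levels form the peptide-binding site
    pbs_exons: dict[str, tuple[int, ...]] = field(default_factory=dict)

    @property
    def n_levels(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return sum(len(ls) for ls in self.labels)

    @property
    def loci(self) -> list[str]:
        seen: dict[str, None] = {}
        for locus, _ in self.features:
            if locus:
                seen.setdefault(locus)
        return list(seen)

    def alleles_at(self, locus: str) -> list[str]:
        out = []
        for a, frags in self.allele_paths.items():
            lvl = frags[0][0]
            if 0 <= lvl < self.n_levels and self.features[lvl][0] == locus:
                out.append(a)
        return out

    def path_sequence(self, allele_id: str) -> str:
        """Un-gapped concatenation of the allele's path fragments."""
        return "".join(s.replace("-", "")
                       for _, s in self.allele_paths[allele_id])

    def level_char(self, allele_id: str, level: int) -> str | None:
        """Edge label the allele takes at a level, or None if not covered."""
        for start, s in self.allele_paths[allele_id]:
            if start <= level < start + len(s):
                return s[level - start]
        return None

    def pbs_levels(self, locus: str) -> list[int]:
        wanted = {f"exon_{k}" for k in self.pbs_exons.get(locus, ())}
        return [i for i, (loc, feat) in enumerate(self.features)
                if loc == locus and feat in wanted]

    def pbs_genotype(self, allele_id: str, locus: str) -> str:
        """Edge labels (including '-') along the peptide-binding site."""
        levels = self.pbs_levels(locus)
        chars = []
        for lvl in levels:
            c = self.level_char(allele_id, lvl)
            if c is None:
                raise ConstructionError(
                    f"allele {allele_id!r} does not traverse PBS level {lvl} "
                    f"of locus {locus!r}")
            chars.append(c)
        return "".join(chars)

    def g_groups(self, locus: str) -> dict[str, dict]:
        """Group alleles with identical PBS genotype into G groups.

        Returns group name -> {"members": [...], "genotype": str,
        "representative": str}.  The group is named after its
        lexicographically smallest member with a 'G' suffix.
        """
        by_genotype: dict[str, list[str]] = {}
        for a in sorted(self.alleles_at(locus)):
            by_genotype.setdefault(self.pbs_genotype(a, locus), []).append(a)
        out: dict[str, dict] = {}
        for genotype, members in by_genotype.items():
            rep = min(members)
            out[rep + "G"] = {"members": members, "genotype": genotype,
                              "representative": rep}
        return dict(sorted(out.items()))

    # ------------------------------------------------------------------
    # serialization (text + JSON sidecar); round-trip is lossless
    # ------------------------------------------------------------------

    def save(self, path) -> None:
        path = str(path)
        with open(path, "w") as fh:
            fh.write(f"#PRG\tversion={FORMAT_VERSION}\tn_levels={self.n_levels}\n")
            for lvl, ls in enumerate(self.labels):
                for lab in ls:
                    fh.write(f"{lvl}\tn{lvl}\tn{lvl + 1}\t{lab}\n")
            for allele in sorted(self.allele_paths):
                for start, s in self.allele_paths[allele]:
                    fh.write(f"P\t{allele}\t{start}\t{s}\n")
            prev = None
            start = 0
            for lvl, (locus, feat) in enumerate(self.features + [(None, None)]):
                if (locus, feat) != prev:
                    if prev is not None:
                        fh.write(f"A\t{start}\t{lvl}\t{prev[0]}\t{prev[1]}\n")
                    prev = (locus, feat)
                    start = lvl
        with open(path + ".json", "w") as fh:
            json.dump({"version": FORMAT_VERSION,
                       "pbs_exons": {k: list(v)
                                     for k, v in sorted(self.pbs_exons.items())}},
                      fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "PRG":
        path = str(path)
        with open(path) as fh:
            header = fh.readline().rstrip("\n")
            if not header.startswith("#PRG"):
                raise ConstructionError(f"{path}: not a PRG file")
            meta = dict(kv.split("=") for kv in header.split("\t")[1:])
            n_levels = int(meta["n_levels"])
            labels: list[set[str]] = [set() for _ in range(n_levels)]
            features: list[tuple[str, str]] = [("", "")] * n_levels
            allele_paths: dict[str, list[tuple[int, str]]] = {}
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if parts[0] == "P":
                    _, allele, start, s = parts
                    allele_paths.setdefault(allele, []).append((int(start), s))
                elif parts[0] == "A":
                    _, start, stop, locus, feat = parts
                    for lvl in range(int(start), int(stop)):
                        features[lvl] = (locus, feat)
                else:
                    lvl = int(parts[0])
                    labels[lvl].add(parts[3])
        with open(path + ".json") as fh:
            side = json.load(fh)
        return cls(labels=[tuple(sorted(ls)) for ls in labels],
                   features=features,
                   allele_paths=allele_paths,
                   pbs_exons={k: tuple(v)
                              for k, v in side.get("pbs_exons", {}).items()})


def build_gene_graph(seg: SegmentedGene,
                     pbs_exons: tuple[int, ...] = PBS_EXONS_CLASS_I) -> PRG:
    """Build the leveled graph for one merged gene.

    One level per alignment column across all segments; one edge per
    distinct (column, character) pair among the rows threading that
    segment, so that alleles sharing a column character share the edge.
    """
    labels: list[tuple[str, ...]] = []
    features: list[tuple[str, str]] = []
    for s in seg.segments:
        w = s.n_columns
        for j in range(w):
            col = {row[j] for row in s.rows.values()}
            labels.append(tuple(sorted(col)))
            features.append((seg.locus, s.feature))
    offsets = []
    acc = 0
    for s in seg.segments:
        offsets.append(acc)
        acc += s.n_columns
    allele_paths: dict[str, list[tuple[int, str]]] = {}
    for a in seg.alleles:
        frags = []
        for start_idx, gapped in seg.fragments(a):
            frags.append((offsets[start_idx], gapped))
        allele_paths[a] = frags
    return PRG(labels=labels, features=features, allele_paths=allele_paths,
               pbs_exons={seg.locus: tuple(pbs_exons)})


def build_joint_prg(gene_prgs: list[PRG], spacer_length: int = 2000) -> PRG:
    """Concatenate gene graphs, separated by runs of 'N' spacer levels.

    The spacer prevents k-mers from spanning two genes; its levels are
    annotated ("", "spacer") and are excluded from the k-mer index.
    """
    if not gene_prgs:
        raise ConstructionError("cannot build a joint PRG from zero genes")
    labels: list[tuple[str, ...]] = []
    features: list[tuple[str, str]] = []
    allele_paths: dict[str, list[tuple[int, str]]] = {}
    pbs_exons: dict[str, tuple[int, ...]] = {}
    for i, prg in enumerate(gene_prgs):
        if i > 0:
            labels.extend([("N",)] * spacer_length)
            features.extend([("", "spacer")] * spacer_length)
        offset = len(labels)
        labels.extend(prg.labels)
        features.extend(prg.features)
        for a, frags in prg.allele_paths.items():
            if a in allele_paths:
                raise ConstructionError(
                    f"duplicate allele id {a!r} across gene graphs")
            allele_paths[a] = [(start + offset, s) for start, s in frags]
        pbs_exons.update(prg.pbs_exons)
    return PRG(labels=labels, features=features, allele_paths=allele_paths,
               pbs_exons=pbs_exons)


def allele_pbs_genotypes(prg: PRG, locus: str) -> dict[str, str]:
    """PBS genotype string for every allele at a locus."""
    if locus not in prg.loci:
        raise ConstructionError(f"locus {locus!r} not present in the PRG")
    if not prg.pbs_levels(locus):
        raise ConstructionError(f"no PBS levels defined for locus {locus!r}")
    return {a: prg.pbs_genotype(a, locus) for a in sorted(prg.alleles_at(locus))}
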