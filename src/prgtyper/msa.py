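"""Rectangular gapped alignments of named allele sequences at one tier.

An :class:`MSA` holds one tier of input data for one gene: exon-only
sequences, full genomic (UTR/exon/intron) sequences, or regional
haplotypes carrying non-genic padding.  Columns are 1-based when
reported to users; internal slicing is 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO

from .errors import MsaFormatError

TIERS = ("exonic", "genomic", "regional_haplotype")

#: Characters allowed in an alignment row.  IMGT-dialect '.' gaps are
#: normalised to '-' on input; '*' (unknown) is rejected.
ALPHABET = frozenset("ACGTN-")


@dataclass
class MSA:
    """A rectangular gapped alignment of allele sequences at one tier."""

    tier: str
    locus: str
    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_columns(self) -> int:
        if not self.sequences:
            return 0
        return len(next(iter(self.sequences.values())))

    @property
    def allele_ids(self) -> list[str]:
        return list(self.sequences)

    def validate(self) -> None:
        if self.tier not in TIERS:
            raise MsaFormatError(f"unknown tier {self.tier!r}; expected one of {TIERS}")
        if not self.sequences:
            raise MsaFormatError(f"{self.locus}/{self.tier}: alignment has no records")
        ncol = self.n_columns
        if ncol == 0:
            raise MsaFormatError(f"{self.locus}/{self.tier}: zero-width alignment")
        for i, (name, seq) in enumerate(self.sequences.items(), start=1):
            if len(seq) != ncol:
                raise MsaFormatError(
                    f"{self.locus}/{self.tier}: ragged alignment — record {i} "
                    f"({name!r}) has length {len(seq)}, expected {ncol}"
                )
            bad = set(seq) - ALPHABET
            if bad:
                raise MsaFormatError(
                    f"{self.locus}/{self.tier}: record {name!r} contains "
                    f"unsupported characters {sorted(bad)}"
                )
            if set(seq) == {"-"}:
                raise MsaFormatError(
                    f"{self.locus}/{self.tier}: record {name!r} is all gaps"
                )

    def ungapped(self, allele_id: str) -> str:
        """The allele's sequence with all gap characters removed."""
        return self.sequences[allele_id].replace("-", "")

    def restrict(self, start: int, stop: int) -> "MSA":
        """Sub-alignment over 0-based half-open column interval [start, stop)."""
        return MSA(
            tier=self.tier,
            locus=self.locus,
            sequences={a: s[start:stop] for a, s in self.sequences.items()},
        )


def _normalise(seq: str, name: str, context: str) -> str:
    s = seq.upper().replace(".", "-")
    bad = set(s) - ALPHABET
    if bad:
        raise MsaFormatError(
            f"{context}: record {name!r} contains unsupported characters "
            f"{sorted(bad)} (note: '*' unknown-residue markers are not accepted)"
        )
    return s


def read_msa(path, tier: str, locus: str) -> MSA:
    """Read an aligned FASTA file into an :class:`MSA`.

    Accepts the IMGT dialect: '.' is treated as a gap and normalised to
    '-'; '*' (unknown residue) is rejected with a clear message.  All
    records must have identical length; the error for a ragged file
    names the first offending record.
    """
    context = f"{path} ({locus}/{tier})"
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise MsaFormatError(f"{context}: empty file or no FASTA records")
    sequences: dict[str, str] = {}
    ncol = None
    for i, rec in enumerate(records, start=1):
        if rec.id in sequences:
            raise MsaFormatError(f"{context}: duplicate allele id {rec.id!r}")
        seq = _normalise(str(rec.seq), rec.id, context)
        if ncol is None:
            ncol = len(seq)
        elif len(seq) != ncol:
            raise MsaFormatError(
                f"{context}: ragged alignment — record {i} ({rec.id!r}) has "
                f"length {len(seq)}, expected {ncol}"
            )
        sequences[rec.id] = seq
    return MSA(tier=tier, locus=locus, sequences=sequences)


def write_msa(msa: MSA, path) -> None:
    with open(path, "w") as fh:
        for name, seq in msa.sequences.items():
            fh.write(f">{name}\n{seq}\n")
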