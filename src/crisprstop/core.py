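"""Sequence domain types, coordinate conventions, translation and FASTA/GenBank I/O.

Coordinate convention: every coordinate crossing a module boundary is 1-based
inclusive on the forward strand, matching how positions are reported in the
guide-design tables this package emits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

VALID_ALPHABET = frozenset("ACGTN")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Malformed input file (empty FASTA record, unreadable FASTQ, ...)."""


class LookupFailure(KeyError):
    """A requested gene/CDS could not be located."""


def normalize_residues(residues: str) -> str:
    """Uppercase, map U->T, and map anything outside {A,C,G,T} to N."""
    s = residues.upper().replace("U", "T")
    if not set(s) <= VALID_ALPHABET:
        n_bad = sum(c not in VALID_ALPHABET for c in s)
        logger.warning("mapped %d non-ACGT symbol(s) to N", n_bad)
        s = "".join(c if c in VALID_ALPHABET else "N" for c in s)
    return s


@dataclass(frozen=True)
class NucleotideSequence:
    """A named DNA sequence over {A,C,G,T,N}, uppercase canonical form."""

    identifier: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise FormatError(f"empty sequence for record {self.identifier!r}")
        if not set(self.residues) <= VALID_ALPHABET:
            raise ValueError(
                f"record {self.identifier!r} contains symbols outside A/C/G/T/N; "
                "normalize with normalize_residues() first"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class CodingRegion:
    """An in-frame CDS on a parent sequence, 1-based inclusive, forward-strand coords.

    ``inferred`` marks regions recovered by ORF scanning rather than read from an
    annotated CDS feature.
    """

    parent: str
    start: int
    end: int
    strand: str = "+"
    name: str = ""
    inferred: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"bad CDS bounds {self.start}..{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if (self.end - self.start + 1) % 3 != 0:
            raise ValueError(
                f"CDS {self.name!r} length {self.end - self.start + 1} not a multiple of 3"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    def validate_against(self, seq: NucleotideSequence) -> None:
        if self.end > len(seq):
            raise ValueError(
                f"CDS {self.name!r} end {self.end} exceeds sequence length {len(seq)}"
            )

    def extract(self, seq: NucleotideSequence) -> str:
        """Return the coding-strand sequence of the region (5'->3' of the ORF)."""
        self.validate_against(seq)
        sub = seq.residues[self.start - 1 : self.end]
        return reverse_complement(sub) if self.strand == "-" else sub


@dataclass
class GenomePanel:
    """Ordered collection of labelled genomes with their coding regions."""

    entries: list[tuple[str, NucleotideSequence, list[CodingRegion]]] = field(
        default_factory=list
    )

    def __post_init__(self) -> None:
        labels = [label for label, _, _ in self.entries]
        if len(set(labels)) != len(labels):
            raise ValueError("panel labels must be unique")

    @property
    def labels(self) -> list[str]:
        return [label for label, _, _ in self.entries]

    def add(
        self, label: str, seq: NucleotideSequence, regions: Iterable[CodingRegion] = ()
    ) -> None:
        if label in self.labels:
            raise ValueError(f"duplicate panel label {label!r}")
        self.entries.append((label, seq, list(regions)))

    def genome(self, label: str) -> NucleotideSequence:
        for lab, seq, _ in self.entries:
            if lab == label:
                return seq
        raise LookupFailure(f"no genome labelled {label!r}")

    def region(self, label: str, gene_name: str) -> CodingRegion:
        for lab, _, regions in self.entries:
            if lab != label:
                continue
            for r in regions:
                if r.name.lower() == gene_name.lower():
                    return r
            raise LookupFailure(f"genome {label!r} has no gene {gene_name!r}")
        raise LookupFailure(f"no genome labelled {label!r}")

    def cds_sequence(self, label: str, gene_name: str) -> str:
        return self.region(label, gene_name).extract(self.genome(label))


def reverse_complement(residues: str) -> str:
    """Watson-Crick reverse complement; N maps to N."""
    if not set(residues) <= VALID_ALPHABET:
        raise ValueError("reverse_complement requires normalized A/C/G/T/N input")
    return residues.translate(_COMPLEMENT)[::-1]


def translate(cds_residues: str) -> str:
    """Translate an in-frame CDS with the standard code.

    Stops emit '*' and translation continues to the end (premature-stop detection
    is the caller's job); codons containing N emit 'X'.
    """
    if len(cds_residues) % 3 != 0:
        raise ValueError(f"CDS length {len(cds_residues)} is not a multiple of 3")
    return str(Seq(cds_residues).translate())


def read_fasta(path: str | Path) -> list[NucleotideSequence]:
    """Read a (multi-)FASTA file into normalized NucleotideSequence records."""
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = normalize_residues(str(rec.seq))
        if not residues:
            raise FormatError(f"empty sequence for record {rec.id!r} in {path}")
        records.append(NucleotideSequence(identifier=rec.id, residues=residues))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[NucleotideSequence], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA wrapped at ``width`` columns."""
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.identifier}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def _longest_orf(residues: str, min_len: int = 900) -> CodingRegion | None:
    """Longest ATG..stop ORF of at least ``min_len`` nt on either strand."""
    best: tuple[int, int, str] | None = None  # (start0, end0_exclusive, strand)
    for strand, seq in (("+", residues), ("-", reverse_complement(residues))):
        n = len(seq)
        for frame in range(3):
            start0 = None
            for i in range(frame, n - 2, 3):
                codon = seq[i : i + 3]
                if start0 is None:
                    if codon == "ATG":
                        start0 = i
                elif codon in STOP_CODONS:
                    length = i + 3 - start0
                    if length >= min_len and (best is None or length > best[1] - best[0]):
                        if strand == "+":
                            best = (start0, i + 3, "+")
                        else:
                            best = (n - (i + 3), n - start0, "-")
                    start0 = None
    if best is None:
        return None
    s0, e0, strand = best
    return CodingRegion(parent="", start=s0 + 1, end=e0, strand=strand, inferred=True)


def read_genbank_cds(
    path: str | Path, gene_name: str
) -> tuple[NucleotideSequence, CodingRegion]:
    """Read a GenBank flat file and locate the CDS for ``gene_name``.

    Matches the gene/product qualifiers of CDS features case-insensitively as a
    substring. When no annotated CDS matches, falls back to the longest open
    reading frame of at least 900 nt (retroviral core genes exceed 1 kb; the
    threshold avoids spurious short ORFs) and flags the result as inferred.
    """
    path = Path(path)
    rec = SeqIO.read(str(path), "genbank")
    seq = NucleotideSequence(rec.id or rec.name, normalize_residues(str(rec.seq)))
    needle = gene_name.lower()
    for feat in rec.features:
        if feat.type != "CDS":
            continue
        tags = feat.qualifiers.get("gene", []) + feat.qualifiers.get("product", [])
        if any(needle in t.lower() for t in tags):
            start = int(feat.location.start) + 1
            end = int(feat.location.end)
            strand = "-" if feat.location.strand == -1 else "+"
            region = CodingRegion(
                parent=seq.identifier, start=start, end=end, strand=strand, name=gene_name
            )
            region.validate_against(seq)
            return seq, region
    orf = _longest_orf(seq.residues)
    if orf is None:
        raise LookupFailure(
            f"no CDS annotated for {gene_name!r} in {path} and no ORF >= 900 nt found"
        )
    logger.warning(
        "no annotated CDS for %r in %s; falling back to longest ORF %d..%d (%s)",
        gene_name, path, orf.start, orf.end, orf.strand,
    )
    return seq, CodingRegion(
        parent=seq.identifier,
        start=orf.start,
        end=orf.end,
        strand=orf.strand,
        name=gene_name,
        inferred=True,
    )
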