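"""Window-restricted C-to-T quantification from amplicon deep sequencing.

Reads are globally aligned to the amplicon reference (match +1, mismatch -1,
gap open -5, gap extend -1; best of both orientations; rejected below 70%
identity), piled up per reference column, and the headline statistic is the
percentage of indel-free aligned reads that carry the target-C conversion in
the base-editing window (16-19 bp upstream of the PAM by default). For a
guide on the amplicon's reverse strand a guide-strand C->T is counted as
G->A on the reference.

Reads with an insertion or deletion overlapping the window +/- 5 bp are
excluded from the headline denominator and reported separately, since indels
near the window make the substitution call alignment-ambiguous.
"""

from __future__ import annotations

import gzip
import logging
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import Align, SeqIO

from .core import FormatError, normalize_residues, reverse_complement
from .guide_design import EditorProfile

logger = logging.getLogger(__name__)

BASES = "ACGTN"

# Alignment scoring; the 70% identity floor and the fast-path mismatch bound
# are logged into every run report.
MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1, -1, -5, -1
MIN_IDENTITY = 0.70
FASTPATH_MAX_MISMATCHES = 6  # ungapped provably optimal below this (see methods)
INDEL_FLANK = 5
QUALITY_FLOOR = 20
MERGE_MIN_OVERLAP = 20
MERGE_MIN_IDENTITY = 0.90


@dataclass(frozen=True)
class AmpliconReference:
    """An amplicon with the coordinates of the guide it was designed around.

    ``guide_start`` is the 1-based amplicon coordinate of the protospacer's
    5' base: for a '+' guide the protospacer occupies
    [guide_start, guide_start+L-1]; for a '-' guide it occupies
    [guide_start-L+1, guide_start] on the forward strand (guide orientation
    runs right to left).
    """

    residues: str
    guide_seq: str
    guide_start: int
    guide_strand: str = "+"

    def __post_init__(self) -> None:
        L = len(self.guide_seq)
        if self.guide_strand == "+":
            found = self.residues[self.guide_start - 1 : self.guide_start - 1 + L]
        else:
            found = reverse_complement(
                self.residues[self.guide_start - L : self.guide_start]
            )
        if found != self.guide_seq:
            raise ValueError(
                f"protospacer not found at declared coordinates: expected "
                f"{self.guide_seq}, found {found}"
            )

    def window_columns(self, profile: EditorProfile) -> list[int]:
        """1-based amplicon columns of the editing window, 5'->3' in guide orientation."""
        lo, hi = profile.window_span
        if self.guide_strand == "+":
            return [self.guide_start + q - 1 for q in range(lo, hi + 1)]
        return [self.guide_start - (q - 1) for q in range(lo, hi + 1)]

    def window_c_columns(self, profile: EditorProfile) -> list[int]:
        """Window columns whose guide-strand base is C (reference C or G by strand)."""
        want = "C" if self.guide_strand == "+" else "G"
        return [c for c in self.window_columns(profile) if self.residues[c - 1] == want]


@dataclass(frozen=True)
class ReadAlignment:
    """A global alignment of one (possibly orientation-flipped) read."""

    ref_aln: str
    read_aln: str
    score: float
    identity: float
    flipped: bool


@dataclass
class SubstitutionTable:
    """Per-position base counts plus the headline window C-to-T percentage."""

    counts: pd.DataFrame
    n_reads_total: int
    n_reads_aligned: int
    n_reads_rejected: int
    n_reads_indel_near_window: int
    n_reads_denominator: int
    n_reads_converted: int
    window_c_to_t_percent: float | None
    per_window_position_percent: dict[int, float] = field(default_factory=dict)
    applicable: bool = True


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = MATCH
_aligner.mismatch_score = MISMATCH
_aligner.open_gap_score = GAP_OPEN
_aligner.extend_gap_score = GAP_EXTEND


def _ungapped_mismatches(read: str, ref: str) -> int:
    return sum(a != b for a, b in zip(read, ref))


def _identity(ref_aln: str, read_aln: str) -> float:
    matches = sum(a == b and a != "-" for a, b in zip(ref_aln, read_aln))
    return matches / len(ref_aln)


def _full_alignment(read: str, ref: str) -> tuple[str, str, float]:
    aln = _aligner.align(ref, read)[0]
    return str(aln[0]), str(aln[1]), aln.score


def align_read(
    read: str, reference: AmpliconReference, min_identity: float = MIN_IDENTITY
) -> ReadAlignment | None:
    """Globally align a read (best orientation) to the amplicon; None if rejected.

    Same-length reads within a few substitutions of the reference take an
    ungapped fast path, which is score-equivalent to the full dynamic program
    under this scoring scheme; everything else runs the full affine-gap
    alignment in both orientations.
    """
    if len(read) < 30:
        return None
    ref = reference.residues
    read_rc = reverse_complement(read)
    if len(read) == len(ref):
        mm_f = _ungapped_mismatches(read, ref)
        mm_r = _ungapped_mismatches(read_rc, ref)
        mm, seq, flipped = min((mm_f, read, False), (mm_r, read_rc, True))
        if mm <= FASTPATH_MAX_MISMATCHES:
            score = (len(ref) - mm) * MATCH + mm * MISMATCH
            identity = sum(
                a == b for a, b in zip(seq, ref)
            ) / len(ref)
            if identity < min_identity:
                return None
            return ReadAlignment(ref, seq, score, identity, flipped)
    best = None
    for seq, flipped in ((read, False), (read_rc, True)):
        ref_aln, read_aln, score = _full_alignment(seq, ref)
        if best is None or score > best[2]:
            best = (ref_aln, read_aln, score, flipped)
    ref_aln, read_aln, score, flipped = best
    identity = _identity(ref_aln, read_aln)
    if identity < min_identity:
        return None
    return ReadAlignment(ref_aln, read_aln, score, identity, flipped)


def pileup(alignments: list[ReadAlignment], reference: AmpliconReference) -> pd.DataFrame:
    """Per-reference-position counts of A/C/G/T/N, deletions and insertions.

    Insertions are attributed to the preceding reference column (column 0 for
    an insertion before the first reference base).
    """
    n = len(reference.residues)
    counts = np.zeros((n, 7), dtype=np.int64)  # A C G T N del ins-after
    base_idx = {b: i for i, b in enumerate(BASES)}
    for aln in alignments:
        ref_pos = 0  # 0-based index of next reference base
        pending_ins = False
        for rb, qb in zip(aln.ref_aln, aln.read_aln):
            if rb == "-":
                # insertion: attribute once per event to the preceding column
                if not pending_ins and ref_pos > 0:
                    counts[ref_pos - 1, 6] += 1
                pending_ins = True
                continue
            pending_ins = False
            if qb == "-":
                counts[ref_pos, 5] += 1
            else:
                counts[ref_pos, base_idx[qb]] += 1
            ref_pos += 1
    df = pd.DataFrame(counts, columns=["A", "C", "G", "T", "N", "del", "ins_after"])
    df.insert(0, "position", np.arange(1, n + 1))
    df.insert(1, "ref_base", list(reference.residues))
    return df


def _read_base_at_columns(aln: ReadAlignment, columns: set[int]) -> dict[int, str]:
    """Read base ('-' for deletion) at each requested 1-based reference column."""
    out = {}
    ref_pos = 0
    for rb, qb in zip(aln.ref_aln, aln.read_aln):
        if rb == "-":
            continue
        ref_pos += 1
        if ref_pos in columns:
            out[ref_pos] = qb
    return out


def _has_indel_near(aln: ReadAlignment, lo: int, hi: int) -> bool:
    """True iff the alignment has a gap touching reference columns [lo, hi]."""
    ref_pos = 0
    for rb, qb in zip(aln.ref_aln, aln.read_aln):
        if rb == "-":
            # insertion sits between ref_pos and ref_pos+1
            if lo - 1 <= ref_pos <= hi:
                return True
            continue
        ref_pos += 1
        if qb == "-" and lo <= ref_pos <= hi:
            return True
    return False


def window_substitution(
    alignments: list[ReadAlignment],
    reference: AmpliconReference,
    profile: EditorProfile = EditorProfile(),
    target_offset: int | None = None,
    n_reads_total: int | None = None,
    n_reads_rejected: int = 0,
) -> SubstitutionTable:
    """Summarise window C->T conversion over accepted alignments.

    ``target_offset`` is the 1-based offset of the designated target C within
    the editing window (guide orientation); defaults to the 5'-most window C.
    Headline percentage = 100 x (indel-free aligned reads carrying the
    target-C conversion) / (indel-free aligned reads with a call at the
    target column). Reads with an indel within the window +/- 5 bp, or an N
    at the target column, are excluded from the denominator.
    """
    table = pileup(alignments, reference)
    win_cols = reference.window_columns(profile)
    c_cols = reference.window_c_columns(profile)
    lo, hi = min(win_cols), max(win_cols)
    converted_base = "T" if reference.guide_strand == "+" else "A"

    per_pos = {}
    for col in c_cols:
        row = table.iloc[col - 1]
        denom = int(row[["A", "C", "G", "T"]].sum())
        per_pos[col] = _round2(100.0 * int(row[converted_base]) / denom) if denom else 0.0

    if not c_cols:
        return SubstitutionTable(
            counts=table,
            n_reads_total=n_reads_total if n_reads_total is not None else len(alignments),
            n_reads_aligned=len(alignments),
            n_reads_rejected=n_reads_rejected,
            n_reads_indel_near_window=0,
            n_reads_denominator=0,
            n_reads_converted=0,
            window_c_to_t_percent=None,
            per_window_position_percent=per_pos,
            applicable=False,
        )

    if target_offset is None:
        target_col = c_cols[0]
    else:
        win_seq_cols = win_cols  # already 5'->3' in guide orientation
        if not 1 <= target_offset <= len(win_seq_cols):
            raise ValueError(f"target_offset {target_offset} outside window")
        target_col = win_seq_cols[target_offset - 1]
        if target_col not in c_cols:
            raise ValueError("target_offset does not point at a window C")

    n_indel = 0
    n_denom = 0
    n_conv = 0
    for aln in alignments:
        if _has_indel_near(aln, lo - INDEL_FLANK, hi + INDEL_FLANK):
            n_indel += 1
            continue
        base = _read_base_at_columns(aln, {target_col}).get(target_col, "-")
        if base in ("N", "-"):
            continue
        n_denom += 1
        if base == converted_base:
            n_conv += 1

    headline = _round2(100.0 * n_conv / n_denom) if n_denom else None
    return SubstitutionTable(
        counts=table,
        n_reads_total=n_reads_total if n_reads_total is not None else len(alignments),
        n_reads_aligned=len(alignments),
        n_reads_rejected=n_reads_rejected,
        n_reads_indel_near_window=n_indel,
        n_reads_denominator=n_denom,
        n_reads_converted=n_conv,
        window_c_to_t_percent=headline,
        per_window_position_percent=per_pos,
    )


def _open_maybe_gz(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fastq(path: str | Path) -> list[tuple[str, str, list[int]]]:
    """Read FASTQ (optionally gzipped) as (id, residues, phred qualities)."""
    records = []
    try:
        with _open_maybe_gz(path) as fh:
            for rec in SeqIO.parse(fh, "fastq"):
                records.append(
                    (
                        rec.id,
                        normalize_residues(str(rec.seq)),
                        rec.letter_annotations["phred_quality"],
                    )
                )
    except ValueError as exc:
        raise FormatError(f"unreadable FASTQ {path}: {exc}") from exc
    if not records:
        raise FormatError(f"no reads in {path}")
    return records


def quality_mask(residues: str, quals: list[int], floor: int = QUALITY_FLOOR) -> str:
    """Mask bases below the Phred floor to N."""
    return "".join(
        b if q >= floor else "N" for b, q in zip(residues, quals)
    )


def merge_pair(
    r1: str, r2: str, min_overlap: int = MERGE_MIN_OVERLAP,
    min_identity: float = MERGE_MIN_IDENTITY,
) -> str | None:
    """Merge a read pair by 3' overlap of R1 with reverse-complemented R2.

    Returns the merged sequence, or None when no overlap of at least
    ``min_overlap`` nt reaches ``min_identity`` (caller falls back to R1).
    """
    r2rc = reverse_complement(r2)
    best = None
    for o in range(min(len(r1), len(r2rc)), min_overlap - 1, -1):
        a, b = r1[-o:], r2rc[:o]
        ident = sum(x == y for x, y in zip(a, b)) / o
        if ident >= min_identity:
            best = r1 + r2rc[o:]
            break
    return best


def quantify(
    r1_path: str | Path,
    reference: AmpliconReference,
    r2_path: str | Path | None = None,
    profile: EditorProfile = EditorProfile(),
    target_offset: int | None = None,
    quality_floor: int = QUALITY_FLOOR,
) -> tuple[SubstitutionTable, dict]:
    """Full FASTQ -> SubstitutionTable pipeline with a machine-readable run report."""
    reads1 = read_fastq(r1_path)
    reads2 = read_fastq(r2_path) if r2_path is not None else None
    if reads2 is not None and len(reads2) != len(reads1):
        raise FormatError("paired FASTQ files differ in read count")

    n_merged = 0
    n_r1_only = 0
    sequences: list[str] = []
    for i, (_, seq1, q1) in enumerate(reads1):
        masked1 = quality_mask(seq1, q1, quality_floor)
        if reads2 is None:
            sequences.append(masked1)
            continue
        _, seq2, q2 = reads2[i]
        masked2 = quality_mask(seq2, q2, quality_floor)
        merged = merge_pair(masked1, masked2)
        if merged is not None:
            n_merged += 1
            sequences.append(merged)
        else:
            n_r1_only += 1
            sequences.append(masked1)

    alignments = []
    n_rejected = 0
    haplotypes: Counter[tuple[str, str]] = Counter()
    for seq in sequences:
        aln = align_read(seq, reference)
        if aln is None:
            n_rejected += 1
            continue
        alignments.append(aln)
        haplotypes[(aln.ref_aln, aln.read_aln)] += 1

    table = window_substitution(
        alignments,
        reference,
        profile,
        target_offset=target_offset,
        n_reads_total=len(sequences),
        n_reads_rejected=n_rejected,
    )
    report = {
        "n_reads_total": len(sequences),
        "n_pairs_merged": n_merged,
        "n_pairs_r1_only": n_r1_only,
        "n_reads_aligned": table.n_reads_aligned,
        "n_reads_rejected": n_rejected,
        "n_reads_indel_near_window": table.n_reads_indel_near_window,
        "n_reads_denominator": table.n_reads_denominator,
        "n_reads_converted": table.n_reads_converted,
        "window_c_to_t_percent": table.window_c_to_t_percent,
        "per_window_position_percent": {
            str(k): v for k, v in table.per_window_position_percent.items()
        },
        "parameters": {
            "match": MATCH,
            "mismatch": MISMATCH,
            "gap_open": GAP_OPEN,
            "gap_extend": GAP_EXTEND,
            "min_identity": MIN_IDENTITY,
            "quality_floor": quality_floor,
            "merge_min_overlap": MERGE_MIN_OVERLAP,
            "merge_min_identity": MERGE_MIN_IDENTITY,
            "indel_flank": INDEL_FLANK,
            "window_from": profile.window_from,
            "window_to": profile.window_to,
            "pam_pattern": profile.pam_pattern,
        },
        "top_haplotypes": [
            {
                "ref": ref_aln,
                "read": read_aln,
                "count": count,
                "frequency": round(count / max(len(alignments), 1), 6),
            }
            for (ref_aln, read_aln), count in haplotypes.most_common(20)
        ],
    }
    return table, report


def haplotype_gallery(report: dict) -> str:
    """Plain-text alignment gallery of the most frequent read haplotypes."""
    lines = []
    for i, h in enumerate(report["top_haplotypes"], 1):
        lines.append(f"# haplotype {i}: {h['count']} reads ({100 * h['frequency']:.2f}%)")
        lines.append(h["ref"])
        lines.append(
            "".join("|" if a == b and a != "-" else " " for a, b in zip(h["ref"], h["read"]))
        )
        lines.append(h["read"])
        lines.append("")
    return "\n".join(lines)
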