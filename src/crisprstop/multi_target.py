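"""Guide x genome presence matrix: which guides hit every subtype simultaneously.

A guide is "present" in a genome iff its full 23-mer (20-nt protospacer + PAM)
occurs as an exact substring of the searched region on either strand, with the
PAM matched under IUPAC semantics. Mismatch tolerance is configurable but
defaults to 0 — the strictest reading of targeting the same region in all
subtypes at once. Search is restricted to the named gene's CDS when
coordinates are known, since designs are organised per gene.
"""

from __future__ import annotations

import pandas as pd

from .core import CodingRegion, GenomePanel, NucleotideSequence, reverse_complement
from .guide_design import IUPAC, EditorProfile


def _count_occurrences(
    proto: str, pam_pattern: str, haystack: str, max_mismatches: int
) -> int:
    """Occurrences of protospacer+PAM in ``haystack`` (one strand).

    Mismatches are counted on the protospacer only; the PAM must always match
    its IUPAC pattern.
    """
    L, P = len(proto), len(pam_pattern)
    count = 0
    for i in range(len(haystack) - L - P + 1):
        pam = haystack[i + L : i + L + P]
        if any(b == "N" or b not in IUPAC[p] for b, p in zip(pam, pam_pattern)):
            continue
        mm = sum(a != b for a, b in zip(haystack[i : i + L], proto))
        if mm <= max_mismatches:
            count += 1
    return count


def count_guide_occurrences(
    protospacer: str,
    genome: NucleotideSequence,
    region: CodingRegion | None = None,
    pam_pattern: str = "NGG",
    max_mismatches: int = 0,
) -> int:
    """Occurrences of the guide site in the region (or whole genome), both strands."""
    if region is not None:
        haystack = region.extract(genome)
    else:
        haystack = genome.residues
    return _count_occurrences(
        protospacer, pam_pattern, haystack, max_mismatches
    ) + _count_occurrences(
        protospacer, pam_pattern, reverse_complement(haystack), max_mismatches
    )


def guide_present(
    protospacer: str,
    genome: NucleotideSequence,
    region: CodingRegion | None = None,
    pam_pattern: str = "NGG",
    max_mismatches: int = 0,
) -> bool:
    """True iff the guide site occurs at least once (both strands searched)."""
    return (
        count_guide_occurrences(protospacer, genome, region, pam_pattern, max_mismatches)
        > 0
    )


def presence_matrix(
    design: pd.DataFrame,
    panel: GenomePanel,
    gene_name: str | None = None,
    profile: EditorProfile = EditorProfile(),
    max_mismatches: int = 0,
    restrict_to_gene: bool = True,
) -> pd.DataFrame:
    """Fill the guide x genome presence matrix for a design table.

    One row per unique (gene, protospacer) in ``design``; one presence column
    per panel genome plus ``all_present`` and per-genome occurrence counts
    (presence is boolean but proviral targets are often multi-copy). Row order
    follows the design table.
    """
    if design.empty:
        cols = ["gene", "protospacer"] + panel.labels + ["all_present"]
        return pd.DataFrame(columns=cols)
    seen: list[tuple[str, str]] = []
    meta: dict[tuple[str, str], dict] = {}
    for _, row in design.iterrows():
        key = (row["gene"], row["protospacer"])
        if key not in meta:
            seen.append(key)
            meta[key] = {
                "gene": row["gene"],
                "direction": row["direction"],
                "stop_route": row["stop_route"],
                "protospacer": row["protospacer"],
                "window": row["window"],
                "cds_position": row["cds_position"],
            }
    rows = []
    for key in seen:
        rec = dict(meta[key])
        gene = gene_name or rec["gene"]
        counts = {}
        for label, genome, _ in panel.entries:
            region = None
            if restrict_to_gene:
                try:
                    region = panel.region(label, gene)
                except KeyError:
                    region = None
            counts[label] = count_guide_occurrences(
                rec["protospacer"], genome, region, profile.pam_pattern, max_mismatches
            )
        for label in panel.labels:
            rec[label] = counts[label] > 0
            rec[f"{label}_occurrences"] = counts[label]
        rec["all_present"] = all(counts[label] > 0 for label in panel.labels)
        rows.append(rec)
    return pd.DataFrame(rows)


def render_ox(matrix: pd.DataFrame, labels: list[str]) -> pd.DataFrame:
    """Render boolean presence columns as o/x for display and TSV export."""
    out = matrix.copy()
    for label in labels:
        out[label] = out[label].map({True: "o", False: "x"})
    out["all_present"] = out["all_present"].map({True: "o", False: "x"})
    return out
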