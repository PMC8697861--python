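"""CRISPR-STOP guide design for cytidine base editors.

Enumerates SpCas9 protospacers on both strands of a coding sequence, extracts
the base-editing window (for Target-AID: 16-19 bp upstream of the PAM, i.e.
protospacer positions 2-5 counted 5'->3'), simulates C->T conversion of the
window cytosines, and keeps guides whose edit turns an in-frame CAA/CAG/CGA
codon into a stop codon (TAA/TAG/TGA) — or, through the antisense strand, an
in-frame TGG (coding-strand G->A) into TAG/TGA/TAA.

The protospacer base adjacent to the PAM is counted as 1 bp upstream of it, so
with a 20-nt protospacer the 16-19 bp window covers protospacer positions 2-5.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core import (
    STOP_CODONS,
    GenomePanel,
    NucleotideSequence,
    reverse_complement,
)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

SENSE_ROUTES = {"CAA": "TAA", "CAG": "TAG", "CGA": "TGA"}


def matches_iupac(sequence: str, pattern: str) -> bool:
    """True iff ``sequence`` matches the IUPAC ``pattern`` (equal lengths)."""
    if len(sequence) != len(pattern):
        return False
    return all(base in IUPAC[p] for base, p in zip(sequence, pattern))


@dataclass(frozen=True)
class EditorProfile:
    """Base-editor geometry: PAM, protospacer length and editing window.

    ``window_from``/``window_to`` are distances in bp upstream of the PAM; the
    defaults (16-19) are the Target-AID quantification window and map to
    protospacer positions 2-5.
    """

    pam_pattern: str = "NGG"
    protospacer_length: int = 20
    window_from: int = 16
    window_to: int = 19

    def __post_init__(self) -> None:
        if not (1 <= self.window_from <= self.window_to <= self.protospacer_length):
            raise ValueError("require 1 <= window_from <= window_to <= protospacer_length")
        if not self.pam_pattern or not set(self.pam_pattern) <= set(IUPAC):
            raise ValueError(f"bad PAM pattern {self.pam_pattern!r}")

    @property
    def pam_length(self) -> int:
        return len(self.pam_pattern)

    @property
    def window_span(self) -> tuple[int, int]:
        """1-based protospacer positions (5'->3') covered by the window."""
        return (
            self.protospacer_length - self.window_to + 1,
            self.protospacer_length - self.window_from + 1,
        )


@dataclass(frozen=True)
class GuideCandidate:
    """A protospacer+PAM site with its editing window.

    ``cds_position`` is the 1-based CDS coordinate of the protospacer 5' base
    for '+' guides; for '-' guides it is the forward-strand coordinate of the
    PAM-distal protospacer end (this package's convention, see methods note).
    ``window_c_offsets`` are 1-based offsets of cytosines within the window,
    counted 5'->3' in guide orientation.
    """

    protospacer: str
    pam: str
    direction: str
    cds_position: int
    window: str
    window_c_offsets: tuple[int, ...]


@dataclass(frozen=True)
class StopPrediction:
    """Outcome of applying a window C->T edit set to the CDS."""

    edited_c_positions: frozenset[int]
    pre_codon: str = ""
    post_codon: str = ""
    creates_stop: bool = False
    stop_codon: str = ""
    route_label: str = ""


def enumerate_protospacers(
    cds: NucleotideSequence | str, profile: EditorProfile = EditorProfile()
) -> list[GuideCandidate]:
    """All protospacer+PAM sites on both strands of ``cds``.

    A site is a ``protospacer_length``-mer immediately followed 3' by a
    PAM-matching k-mer; candidates containing N in the protospacer or PAM are
    dropped (an N can be confirmed neither as a C nor as PAM-matching). Output
    is ordered by coding-strand coordinate, '+' before '-' at a tie.
    """
    seq = cds.residues if isinstance(cds, NucleotideSequence) else cds
    L, P = profile.protospacer_length, profile.pam_length
    pam_rc = reverse_complement(profile.pam_pattern)  # IUPAC-complement pattern
    out: list[tuple[int, int, GuideCandidate]] = []
    for i in range(len(seq) - L - P + 1):
        proto = seq[i : i + L]
        pam = seq[i + L : i + L + P]
        if "N" not in proto and "N" not in pam and matches_iupac(pam, profile.pam_pattern):
            out.append((i, 0, _make_candidate(proto, pam, "+", i + 1, profile)))
        # minus-strand site occupying the same forward footprint [i, i+L+P):
        # forward layout is revcomp(PAM) then revcomp(protospacer)
        pam_fwd = seq[i : i + P]
        proto_fwd = seq[i + P : i + P + L]
        if (
            "N" not in proto_fwd
            and "N" not in pam_fwd
            and matches_iupac(pam_fwd, pam_rc)
        ):
            proto = reverse_complement(proto_fwd)
            pam = reverse_complement(pam_fwd)
            # PAM-distal protospacer end = guide 5' base = rightmost forward base
            out.append((i, 1, _make_candidate(proto, pam, "-", i + P + L, profile)))
    out.sort(key=lambda t: (t[0], t[1]))
    return [c for _, _, c in out]


def _make_candidate(
    proto: str, pam: str, direction: str, cds_position: int, profile: EditorProfile
) -> GuideCandidate:
    lo, hi = profile.window_span
    window = proto[lo - 1 : hi]
    offsets = tuple(k + 1 for k, b in enumerate(window) if b == "C")
    return GuideCandidate(
        protospacer=proto,
        pam=pam,
        direction=direction,
        cds_position=cds_position,
        window=window,
        window_c_offsets=offsets,
    )


def extract_window(
    candidate: GuideCandidate, profile: EditorProfile = EditorProfile()
) -> tuple[str, tuple[int, ...]]:
    """The editing-window substring and 1-based offsets of its cytosines."""
    lo, hi = profile.window_span
    window = candidate.protospacer[lo - 1 : hi]
    return window, tuple(k + 1 for k, b in enumerate(window) if b == "C")


def simulate_edits(candidate: GuideCandidate) -> list[frozenset[int]]:
    """Candidate edit sets: every single window C, plus the all-C set (deduplicated)."""
    cs = candidate.window_c_offsets
    if not cs:
        return []
    sets = [frozenset({c}) for c in cs]
    full = frozenset(cs)
    if full not in sets:
        sets.append(full)
    return sets


def _window_offset_to_cds_index(
    candidate: GuideCandidate, offset: int, profile: EditorProfile
) -> int:
    """0-based CDS index of the coding-strand base hit by window offset ``offset``."""
    lo, _ = profile.window_span
    proto_pos = lo + offset - 1  # 1-based position within the protospacer
    if candidate.direction == "+":
        return candidate.cds_position - 1 + proto_pos - 1
    # '-' guides: cds_position is the forward coordinate of the guide 5' base
    return candidate.cds_position - 1 - (proto_pos - 1)


def predict_stop(
    cds_residues: str,
    candidate: GuideCandidate,
    edit_set: frozenset[int] | set[int],
    profile: EditorProfile = EditorProfile(),
) -> StopPrediction:
    """Apply a window C->T edit set and report whether a premature stop appears.

    Edits are C->T on the guide strand; for '-' guides that is G->A on the
    coding strand. "Premature" means a new in-frame stop strictly before the
    CDS's terminal codon. The route label is the pre-edit codon for sense
    routes; for antisense routes it is the guide-strand (reverse-complement)
    rendering of the post-edit codon, or of the pre-edit codon when both
    guanines convert.
    """
    edit_set = frozenset(edit_set)
    n = len(cds_residues)
    indices = [_window_offset_to_cds_index(candidate, off, profile) for off in edit_set]
    if any(i < 0 or i >= n for i in indices):
        raise ValueError("candidate edit positions fall outside the CDS")
    edited = list(cds_residues)
    for i in indices:
        base = edited[i]
        if candidate.direction == "+":
            if base != "C":
                raise ValueError(f"expected C at CDS index {i}, found {base}")
            edited[i] = "T"
        else:
            if base != "G":
                raise ValueError(f"expected G at CDS index {i}, found {base}")
            edited[i] = "A"
    last_codon_idx = n // 3 - 1
    affected = sorted({i // 3 for i in indices})
    for ci in affected:
        pre = cds_residues[ci * 3 : ci * 3 + 3]
        post = "".join(edited[ci * 3 : ci * 3 + 3])
        if post in STOP_CODONS and pre not in STOP_CODONS and ci < last_codon_idx:
            if candidate.direction == "+":
                label = pre
            elif pre == "TGG" and post == "TAA":
                label = reverse_complement(pre)  # both Gs converted
            else:
                label = reverse_complement(post)
            return StopPrediction(
                edited_c_positions=edit_set,
                pre_codon=pre,
                post_codon=post,
                creates_stop=True,
                stop_codon=post,
                route_label=label,
            )
    ci = affected[0]
    return StopPrediction(
        edited_c_positions=edit_set,
        pre_codon=cds_residues[ci * 3 : ci * 3 + 3],
        post_codon="".join(edited[ci * 3 : ci * 3 + 3]),
        creates_stop=False,
    )


_SENSE_ORDER = {"CAA": 0, "CAG": 1, "CGA": 2}
_ANTISENSE_ORDER = {"CCA": 0, "TCA": 1, "CTA": 2}


def _route_sort_key(direction: str, route_label: str, cds_position: int) -> tuple:
    if direction == "+":
        return (0, _SENSE_ORDER.get(route_label, 9), cds_position)
    return (1, _ANTISENSE_ORDER.get(route_label, 9), cds_position)


def design_stop_guides(
    panel: GenomePanel,
    gene_name: str,
    profile: EditorProfile = EditorProfile(),
) -> pd.DataFrame:
    """Design premature-stop guides for ``gene_name`` across every panel genome.

    For each genome: enumerate protospacers over the gene's CDS, extract the
    editing window, and keep candidates for which some C->T edit set creates a
    premature stop. One row per (genome, candidate); the single-C edit set is
    preferred as the designated target C when several sets create a stop.
    """
    rows = []
    for label, seq, _ in panel.entries:
        region = panel.region(label, gene_name)  # raises LookupFailure if absent
        cds = region.extract(seq)
        for cand in enumerate_protospacers(cds, profile):
            stop_sets = []
            prediction = None
            for es in simulate_edits(cand):
                pred = predict_stop(cds, cand, es, profile)
                if pred.creates_stop:
                    stop_sets.append(es)
                    if prediction is None or len(es) < len(prediction.edited_c_positions):
                        prediction = pred
            if prediction is None:
                continue
            target_c = min(min(es) for es in stop_sets if len(es) == min(map(len, stop_sets)))
            rows.append(
                {
                    "genome": label,
                    "gene": gene_name,
                    "direction": cand.direction,
                    "stop_route": prediction.route_label,
                    "protospacer": cand.protospacer,
                    "pam": cand.pam,
                    "window": cand.window,
                    "cds_position": cand.cds_position,
                    "target_c_offset": target_c,
                    "stop_codon": prediction.stop_codon,
                    "edit_sets": ";".join(
                        ",".join(map(str, sorted(es))) for es in stop_sets
                    ),
                    "creates_stop": True,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "genome", "gene", "direction", "stop_route", "protospacer", "pam",
            "window", "cds_position", "target_c_offset", "stop_codon",
            "edit_sets", "creates_stop",
        ],
    )
    if len(df):
        df = df.sort_values(
            by=["genome", "direction", "stop_route", "cds_position"],
            key=lambda col: col.map(
                lambda v: (_SENSE_ORDER | _ANTISENSE_ORDER).get(v, v)
            )
            if col.name == "stop_route"
            else col,
            kind="stable",
        ).reset_index(drop=True)
    return df


def stop_routes_by_exhaustion() -> dict[str, set[tuple[str, str]]]:
    """Enumerate, over all 64 codons, which single-base edits create a stop.

    Returns the sense (C->T) and antisense (coding-strand G->A) routes. Used
    both as documentation of the CRISPR-STOP codon set and as an oracle in the
    test suite.
    """
    bases = "ACGT"
    codons = [a + b + c for a in bases for b in bases for c in bases]
    sense, antisense = set(), set()
    for codon in codons:
        if codon in STOP_CODONS:
            continue
        for i, b in enumerate(codon):
            if b == "C":
                post = codon[:i] + "T" + codon[i + 1 :]
                if post in STOP_CODONS:
                    sense.add((codon, post))
            if b == "G":
                post = codon[:i] + "A" + codon[i + 1 :]
                if post in STOP_CODONS:
                    antisense.add((codon, post))
    return {"sense_c_to_t": sense, "antisense_g_to_a": antisense}
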