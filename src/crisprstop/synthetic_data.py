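"""Synthetic inputs at desk scale: a diverged proviral-like genome family with
controlled guide-site conservation, and amplicon FASTQ read sets with known
C->T edit fractions, sequencing-error rates and indel fractions.

The genome family emulates a small set of homologous retroviral subtypes that
share (or do not share) exact stop-codon-editable guide sites inside their
core genes; the read simulator emulates a merged paired-end amplicon
sequencing run over one guide target. Identical seed and parameters produce
byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import CodingRegion, GenomePanel, NucleotideSequence, reverse_complement
from .edit_quant import AmpliconReference
from .guide_design import SENSE_ROUTES, EditorProfile

SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]

DEFAULT_GENE_LAYOUT = (("gag", 301, 900), ("pol", 1301, 1200), ("env", 2601, 900))


class GenerationError(RuntimeError):
    """Infeasible synthetic-genome layout (overlapping constraints)."""


@dataclass(frozen=True)
class ConservedSite:
    """A stop-editable guide cassette seeded into a gene of the ancestor.

    ``codon_index`` is the 0-based codon within the gene's CDS that carries the
    editable codon; the cassette places an NGG PAM so that the codon's C falls
    in the 16-19 bp editing window. ``shared_by`` limits the site to a subset
    of subtypes (None = conserved in all); non-carriers get the PAM disrupted.
    """

    gene: str
    codon_index: int
    codon: str = "CAG"
    shared_by: tuple[int, ...] | None = None


@dataclass
class SimTruth:
    """Everything needed to reproduce and verify a synthetic dataset."""

    seed: int
    parameters: dict = field(default_factory=dict)
    realized: dict = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"seed": self.seed, **self.parameters, "realized": self.realized},
                      fh, indent=2, sort_keys=True)
            fh.write("\n")


def _random_cds(rng: np.random.Generator, n_codons: int) -> list[str]:
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    return [SENSE_CODONS[i] for i in idx]


def _seed_cassette(
    codons: list[str], site: ConservedSite, rng: np.random.Generator
) -> tuple[int, int]:
    """Install an editable codon + in-window NGG PAM around ``site``.

    With the codon's C at CDS position t = 3*ci+1, the protospacer starts at
    t-2 (placing the C at window offset 2) and the PAM GG lands on bases 2-3
    of codon ci+6. Returns the protospacer footprint (start, end), 1-based on
    the CDS. Raises GenerationError when the cassette does not fit.
    """
    ci = site.codon_index
    if site.codon not in SENSE_ROUTES:
        raise GenerationError(f"site codon {site.codon!r} is not C->T stop-editable")
    if ci < 1 or ci + 6 >= len(codons):
        raise GenerationError(
            f"codon index {ci} leaves no room for a protospacer+PAM cassette"
        )
    codons[ci] = site.codon
    # previous codon must not end in C (keeps the seeded C the only upstream
    # window C, so the designated target is unambiguous)
    while codons[ci - 1][2] == "C":
        codons[ci - 1] = SENSE_CODONS[rng.integers(0, len(SENSE_CODONS))]
    first = codons[ci + 6][0]
    if first == "T":  # avoid TGG: it is itself antisense-editable
        first = "A"
    codons[ci + 6] = first + "GG"
    t = 3 * ci + 1
    return t - 2, t + 20


def _sanitize_cassette_neighborhood(
    codons: list[str],
    site_footprints: list[tuple[int, int]],
    fixed_positions: set[int],
    rng: np.random.Generator,
    profile: EditorProfile,
    max_rounds: int = 60,
) -> None:
    """Break every unintended stop-guide whose footprint touches a protected span.

    The +/- 23 bp protection around a seeded cassette is exempt from
    divergence, so any other stop-creating guide inside it would be trivially
    conserved across all subtypes and the seeded site would no longer be the
    unique shared target. PAM bases of such guides are flipped (to non-G/non-C)
    wherever that does not touch a cassette-constrained position or create a
    stop codon.
    """
    from .guide_design import enumerate_protospacers, predict_stop, simulate_edits

    intended = {lo for lo, _ in site_footprints}
    spans = [(max(1, lo - 23), hi + 23) for lo, hi in site_footprints]
    for _ in range(max_rounds):
        cds = "".join(codons)
        offenders = []
        for cand in enumerate_protospacers(cds, profile):
            if cand.direction == "+":
                f_lo, f_hi = cand.cds_position, cand.cds_position + 22
                pam_gg = (cand.cds_position + 21, cand.cds_position + 22)
            else:
                f_lo, f_hi = cand.cds_position - 22, cand.cds_position
                pam_gg = (f_lo, f_lo + 1)  # forward-strand CC of the minus PAM
            if f_lo in intended and cand.direction == "+":
                continue
            if not any(lo <= f_hi and f_lo <= hi for lo, hi in spans):
                continue
            if any(
                predict_stop(cds, cand, es, profile).creates_stop
                for es in simulate_edits(cand)
            ):
                offenders.append(pam_gg)
        if not offenders:
            return
        changed = False
        for pam_gg in offenders:
            for pos1 in pam_gg:
                if pos1 in fixed_positions or not 1 <= pos1 <= len(codons) * 3:
                    continue
                ci, within = divmod(pos1 - 1, 3)
                codon = list(codons[ci])
                avoid = {"G", "C", codon[within]}
                for new in [b for b in "AT" if b not in avoid] + ["A", "T"]:
                    trial = codon.copy()
                    trial[within] = new
                    if "".join(trial) not in ("TAA", "TAG", "TGA"):
                        codons[ci] = "".join(trial)
                        changed = True
                        break
                if changed:
                    break
            if changed:
                break
        if not changed:
            raise GenerationError(
                "could not sanitize cassette neighborhood (constraints too tight)"
            )
    raise GenerationError("cassette neighborhood sanitation did not converge")


def _disrupt_pam(residues: list[str], cds_start: int, codon_index: int) -> None:
    """Break the cassette PAM (GG -> AT) in a genome that must not carry the site."""
    pam_codon_start0 = cds_start - 1 + 3 * (codon_index + 6)
    residues[pam_codon_start0 + 1] = "A"
    residues[pam_codon_start0 + 2] = "T"


def make_provirus_family(
    seed: int,
    n_subtypes: int = 3,
    gene_layout: tuple[tuple[str, int, int], ...] = DEFAULT_GENE_LAYOUT,
    divergence: float = 0.10,
    conserved_sites: tuple[ConservedSite, ...] = (),
    genome_length: int | None = None,
) -> tuple[GenomePanel, SimTruth]:
    """Generate an ancestor provirus and ``n_subtypes`` diverged descendants.

    ``gene_layout`` gives (name, 1-based start, length) per CDS; lengths must
    be multiples of 3. Subtypes differ from the ancestor by random
    substitutions at the stated per-site divergence, never touching any
    conserved-site footprint +/- 23 bp and never creating a premature stop
    inside a CDS. Sites whose ``shared_by`` excludes a subtype get their PAM
    deterministically disrupted there.
    """
    if not 2 <= n_subtypes <= 8:
        raise GenerationError("n_subtypes must be between 2 and 8")
    rng = np.random.default_rng(seed)
    for name, start, length in gene_layout:
        if length % 3 != 0:
            raise GenerationError(f"gene {name} length {length} not a multiple of 3")
    if genome_length is None:
        genome_length = max(start + length - 1 for _, start, length in gene_layout) + 300
    spans = sorted((start, start + length - 1, name) for name, start, length in gene_layout)
    for (s1, e1, n1), (s2, e2, n2) in zip(spans, spans[1:]):
        if s2 <= e1:
            raise GenerationError(f"genes {n1} and {n2} overlap")
    if spans[-1][1] > genome_length:
        raise GenerationError("gene layout exceeds genome length")

    # ancestor: random intergenic bases + stop-free random CDSs
    residues = [ "ACGT"[i] for i in rng.integers(0, 4, size=genome_length) ]
    regions: list[CodingRegion] = []
    protected: list[tuple[int, int]] = []  # 1-based genome spans never mutated
    truth_sites = []
    profile = EditorProfile()
    for name, start, length in gene_layout:
        codons = _random_cds(rng, length // 3)
        footprints: list[tuple[int, int]] = []
        fixed: set[int] = set()
        for site in conserved_sites:
            if site.gene != name:
                continue
            foot_lo, foot_hi = _seed_cassette(codons, site, rng)
            footprints.append((foot_lo, foot_hi))
            t = 3 * site.codon_index + 1
            fixed.update({t, t + 1, t + 2, t + 19, t + 20})
            g_lo = start - 1 + foot_lo
            g_hi = start - 1 + foot_hi
            protected.append((max(1, g_lo - 23), min(genome_length, g_hi + 23)))
            truth_sites.append(
                {
                    "gene": name,
                    "codon": site.codon,
                    "codon_index": site.codon_index,
                    "cds_position": foot_lo,
                    "shared_by": list(site.shared_by) if site.shared_by else None,
                }
            )
        if footprints:
            _sanitize_cassette_neighborhood(codons, footprints, fixed, rng, profile)
        cds = "".join(codons)
        residues[start - 1 : start - 1 + length] = list(cds)
        regions.append(
            CodingRegion(parent="ancestor", start=start, end=start + length - 1,
                         strand="+", name=name)
        )
    # record protospacers from the finished ancestor
    for rec in truth_sites:
        gstart = next(s for n, s, _ in gene_layout if n == rec["gene"])
        p0 = gstart - 1 + rec["cds_position"] - 1
        rec["protospacer"] = "".join(residues[p0 : p0 + 20])
        rec["pam"] = "".join(residues[p0 + 20 : p0 + 23])

    ancestor = "".join(residues)
    cds_spans = [(start, start + length - 1) for _, start, length in gene_layout]

    def in_protected(pos1: int) -> bool:
        return any(lo <= pos1 <= hi for lo, hi in protected)

    def containing_cds(pos1: int) -> tuple[int, int] | None:
        for lo, hi in cds_spans:
            if lo <= pos1 <= hi:
                return lo, hi
        return None

    panel = GenomePanel()
    for k in range(n_subtypes):
        sub = list(ancestor)
        mutate = rng.random(genome_length) < divergence
        for pos0 in np.flatnonzero(mutate):
            pos1 = int(pos0) + 1
            if in_protected(pos1):
                continue
            alternatives = [b for b in "ACGT" if b != sub[pos0]]
            new = alternatives[rng.integers(0, 3)]
            span = containing_cds(pos1)
            if span is not None:
                lo = span[0]
                codon_start0 = pos0 - ((pos1 - lo) % 3)
                codon = sub[codon_start0 : codon_start0 + 3]
                codon[pos0 - codon_start0] = new
                if "".join(codon) in ("TAA", "TAG", "TGA"):
                    continue  # skip mutations that would truncate the CDS
            sub[pos0] = new
        for rec in truth_sites:
            if rec["shared_by"] is not None and k not in rec["shared_by"]:
                gstart = next(s for n, s, _ in gene_layout if n == rec["gene"])
                _disrupt_pam(sub, gstart, rec["codon_index"])
        label = f"subtype-{chr(ord('A') + k)}"
        seq = NucleotideSequence(label, "".join(sub))
        panel.add(
            label,
            seq,
            [CodingRegion(parent=label, start=r.start, end=r.end, strand=r.strand,
                          name=r.name) for r in regions],
        )

    truth = SimTruth(
        seed=seed,
        parameters={
            "n_subtypes": n_subtypes,
            "divergence": divergence,
            "genome_length": genome_length,
            "gene_layout": [list(g) for g in gene_layout],
            "sites": truth_sites,
        },
    )
    return panel, truth


def make_test_amplicon(
    seed: int,
    length: int = 180,
    guide_start: int = 80,
    guide_strand: str = "+",
    codon: str = "CAG",
) -> AmpliconReference:
    """A random amplicon carrying one stop-editable guide site for read simulation.

    The target C sits at window offset 2 (17 bp upstream of the PAM); the rest
    of the amplicon is random with no other C (or G, for '-' guides) inside the
    editing window, so the designated target C is unambiguous.
    """
    rng = np.random.default_rng(seed)
    if codon not in SENSE_ROUTES:
        raise GenerationError(f"codon {codon!r} is not C->T stop-editable")
    residues = ["ACGT"[i] for i in rng.integers(0, 4, size=length)]
    # build the site in guide orientation: proto[0] random-nonC, then window
    # offset 1 non-C, C at offset 2 starting the editable codon, PAM NGG
    site = ["A"] + ["T"] + list(codon) + [
        "ACGT"[i] for i in rng.integers(0, 4, size=15)
    ] + ["A", "G", "G"]
    # window = site positions 2-5 (1-based) = [T, C, A, G/A]: only one C
    site_seq = "".join(site)
    if guide_strand == "+":
        start0 = guide_start - 1
        residues[start0 : start0 + 23] = list(site_seq)
    else:
        # guide 5' base at forward coordinate guide_start
        start0 = guide_start - 20  # proto occupies [guide_start-19, guide_start]
        residues[start0 - 3 : start0 + 20] = list(reverse_complement(site_seq))
    amplicon = "".join(residues)
    return AmpliconReference(
        residues=amplicon,
        guide_seq=site_seq[:20],
        guide_start=guide_start,
        guide_strand=guide_strand,
    )


def simulate_amplicon_reads(
    reference: AmpliconReference,
    seed: int,
    n_reads: int = 1000,
    edit_fraction: float = 0.0,
    error_rate: float = 0.0,
    indel_fraction: float = 0.0,
    co_conversion: float = 0.3,
    profile: EditorProfile = EditorProfile(),
    paired: bool = False,
    read_length: int | None = None,
    quality_char: str = "F",  # Phred+33 'F' = Q37
    out_r1: str | Path | None = None,
    out_r2: str | Path | None = None,
    truth_path: str | Path | None = None,
) -> tuple[SimTruth, list[str]]:
    """Simulate an amplicon read set with known edit fraction and error model.

    Per read: with probability ``edit_fraction`` the designated target C is
    converted to T (guide-strand sense; each secondary window C converts
    independently with probability ``co_conversion`` on edited reads); with
    probability ``indel_fraction`` a 1-3 nt insertion or deletion lands
    uniformly within the window +/- 5 bp; every base then errs independently
    with probability ``error_rate`` (uniform over the three alternatives).
    """
    for name, rate in (("edit_fraction", edit_fraction), ("error_rate", error_rate),
                       ("indel_fraction", indel_fraction), ("co_conversion", co_conversion)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    rng = np.random.default_rng(seed)
    ref = reference.residues
    n = len(ref)
    c_cols = reference.window_c_columns(profile)
    if not c_cols:
        raise ValueError("editing window contains no targetable C")
    target_col = c_cols[0]
    secondary = [c for c in c_cols if c != target_col]
    converted = "T" if reference.guide_strand == "+" else "A"
    win_cols = reference.window_columns(profile)
    indel_lo = max(1, min(win_cols) - 5)
    indel_hi = min(n, max(win_cols) + 5)

    edited_flags = rng.random(n_reads) < edit_fraction
    indel_flags = rng.random(n_reads) < indel_fraction
    n_errors = 0

    reads: list[str] = []
    for i in range(n_reads):
        bases = list(ref)
        if edited_flags[i]:
            bases[target_col - 1] = converted
            for col in secondary:
                if rng.random() < co_conversion:
                    bases[col - 1] = converted
        if indel_flags[i]:
            size = int(rng.integers(1, 4))
            pos0 = int(rng.integers(indel_lo - 1, indel_hi))
            if rng.random() < 0.5:
                ins = "".join("ACGT"[j] for j in rng.integers(0, 4, size=size))
                bases[pos0:pos0] = list(ins)
            else:
                del bases[pos0 : pos0 + size]
        if error_rate > 0.0:
            errs = np.flatnonzero(rng.random(len(bases)) < error_rate)
            for pos0 in errs:
                alts = [b for b in "ACGT" if b != bases[pos0]]
                bases[pos0] = alts[int(rng.integers(0, 3))]
            n_errors += len(errs)
        reads.append("".join(bases))

    truth = SimTruth(
        seed=seed,
        parameters={
            "n_reads": n_reads,
            "edit_fraction": edit_fraction,
            "error_rate": error_rate,
            "indel_fraction": indel_fraction,
            "co_conversion": co_conversion,
            "paired": paired,
            "read_length": read_length,
            "amplicon_length": n,
            "guide_start": reference.guide_start,
            "guide_strand": reference.guide_strand,
            "target_column": target_col,
        },
        realized={
            "n_edited_reads": int(edited_flags.sum()),
            "n_indel_reads": int(indel_flags.sum()),
            "n_error_bases": int(n_errors),
        },
    )

    if out_r1 is not None:
        if paired:
            rl = read_length or max(2 * n // 3, 40)
            with open(out_r1, "w") as f1, open(out_r2, "w") as f2:
                for i, seq in enumerate(reads):
                    r1 = seq[:rl]
                    r2 = reverse_complement(seq[-rl:])
                    f1.write(f"@read{i} seed={seed} 1\n{r1}\n+\n{quality_char * len(r1)}\n")
                    f2.write(f"@read{i} seed={seed} 2\n{r2}\n+\n{quality_char * len(r2)}\n")
        else:
            with open(out_r1, "w") as f1:
                for i, seq in enumerate(reads):
                    f1.write(f"@read{i} seed={seed}\n{seq}\n+\n{quality_char * len(seq)}\n")
    if truth_path is not None:
        truth.write(truth_path)
    return truth, reads
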