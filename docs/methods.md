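# Methods

## Editing-window model

The base editor is described by an `EditorProfile`: PAM pattern (IUPAC,
default `NGG`), protospacer length (default 20 nt) and a window given as
distances in bp upstream of the PAM (defaults 16–19). Counting the
PAM-adjacent protospacer base as 1 bp upstream, the default window maps to
protospacer positions 2–5 (5′→3′). This is the only counting convention
under which all 26 published PERV guide windows reproduce from their
23-mers, and the package asserts that reproduction in its test suite.
Target-AID is sometimes described as editing 3–5 bases around 18 bp upstream
of the PAM; the 16–19 bp window is the form used for quantification and is
the default here, with both bounds configurable.

A guide is a stop guide when some subset of its window cytosines, converted
C→T on the guide strand (equivalently G→A on the coding strand for
antisense guides), creates an in-frame stop strictly before the CDS's
terminal codon. Candidate edit sets are every single window C plus the all-C
set; a guide is retained if any set creates a stop, all stop-creating sets
are reported, and the smallest one defines the designated target C.
Re-creating the natural terminal stop does not count as premature. By
exhaustive enumeration over all 64 codons the sense routes are exactly
CAA→TAA, CAG→TAG, CGA→TGA and the antisense routes exactly TGG→TAG and
TGG→TGA; the suite re-derives this from the genetic code independently.

### Coordinate and labelling conventions

External coordinates are 1-based inclusive. For '+' guides, `cds_position`
is the CDS coordinate of the protospacer's 5′ base. Published tables do not
state a minus-strand convention, so this package defines its own: a '−'
guide is reported at the forward-strand coordinate of its PAM-distal
(guide-5′) protospacer end. Route labels: sense routes are labelled by the
pre-edit codon (CAA/CAG/CGA); antisense routes by the guide-strand (reverse
complement) rendering of the post-edit codon — CTA for TGG→TAG, TCA for
TGG→TGA — and CCA (the pre-edit codon's complement) when both guanines
convert. These are this package's own labelling rules, chosen to be
deterministic and invertible rather than to reverse-engineer any published
table's convention. Design rows sort by direction (+ first), then route
class (CAA, CAG, CGA / CCA, TCA, CTA), then position.

Strand symmetry: protospacer enumeration is fully symmetric under reverse
complementation of the input (verified property). The stop-filtered design
table is **not**, and cannot be: premature-stop detection is frame-specific,
and the reverse complement of a CDS is a different reading frame (TGG→TGA in
the forward frame reads CCA→TCA, Pro→Ser, in the reverse frame). What does
hold, and is tested, is invariance to which genome strand a gene is
annotated on: a CDS stored on the '−' strand designs identically to the same
CDS stored on '+'.

## Cross-subtype presence

A guide is present in a genome iff its full 23-mer (protospacer + PAM)
occurs as an exact substring of the searched region on either strand, with
the PAM matched under IUPAC semantics. Exact matching is the strictest
reading of "targets all subtypes simultaneously"; a mismatch budget is
available (`max_mismatches`, default 0, counted on the protospacer only).
Search is restricted to the named gene's CDS when coordinates are known,
since designs are organised per gene; whole-genome search is the fallback.
Presence is boolean (≥1 occurrence) but occurrence counts are reported too,
because proviral targets are typically multi-copy.

## Quantification

Alignment is global (Needleman–Wunsch with affine gaps via Biopython's
PairwiseAligner): match +1, mismatch −1, gap open −5, gap extend −1, best of
both read orientations, rejection below 70 % identity over alignment
columns. These constants are package choices, echoed into every run report.
Same-length reads with ≤6 ungapped mismatches take a fast path that skips
the dynamic program: under this scoring, converting k mismatches to matches
by introducing gaps gains 2k but costs at least 12 (two gap opens) plus 2
(two sacrificed match columns), so gapped alignments cannot win until k ≥ 8.
Oracle tests compare both paths against an independent Gotoh implementation.

Reads below 30 nt are rejected. Bases under Phred 20 are masked to N before
alignment; N neither matches nor counts as a conversion, and a read with N
at the target column contributes no call. Paired reads are merged when the
R1/R2 reverse-complement overlap reaches ≥20 nt at ≥90 % identity, taking
the longest such overlap; otherwise R1 alone is used and the choice is
counted in the run report.

The headline statistic is per-read, not per-position: the percentage of
indel-free aligned reads whose designated target C reads as the converted
base. Reads with an insertion or deletion overlapping the window ±5 bp are
excluded from the denominator and reported separately — indels that close to
the window make the substitution call alignment-ambiguous. Per-position
percentages over all window Cs are emitted alongside, so a per-position
reading can be recovered. No background subtraction is performed.
Percentages are rounded half-up to 2 decimals. In the pileup, deletions are
counted per deleted reference column and insertions are attributed once per
event to the preceding reference column.

## Synthetic data

The provirus family generator emulates a small set of homologous retroviral
subtypes: an ancestor with intergenic flanks and stop-free random CDSs
(*gag*/*pol*/*env* by default, 900–1200 nt each), from which each subtype is
derived by independent per-site substitutions. The default divergence of
0.10 substitutions/site reflects the roughly ten-percent nucleotide
divergence separating retroviral subtypes; mutations that would create an
in-frame stop are skipped. Seeded guide cassettes (an editable codon whose C
sits at window offset 2, with the PAM's GG placed two codons' distance
downstream in-frame) are protected from divergence within ±23 bp; because a
protected span would also freeze any *other* stop guide that happens to
overlap it, the generator rewrites such bystander sites in the ancestor
(flipping one non-constrained PAM base) until the seeded cassette is the
only stop guide touching its protected span. Sites can be restricted to a
subset of carrier subtypes, in which case non-carriers get the cassette PAM
deterministically disrupted (GG→AT). All randomness flows from one
explicitly seeded generator; identical seed and parameters give
byte-identical FASTA/FASTQ/JSON outputs.

The read simulator emulates a merged single-amplicon sequencing run: per
read, the target C converts with probability f (secondary window Cs convert
with a co-conversion probability, default 0.3, a free parameter with no
published value); a 1–3 nt indel lands uniformly within the window ±5 bp
with probability d; uniform substitution error e is overlaid per base;
qualities are constant Q37 so that quality masking is exercised only by
dedicated low-quality tests. It does not model quality- or
position-dependent MiSeq error profiles, PCR bias, chimeras, or multi-copy
heterogeneity across proviral integration sites — so passing recovery tests
demonstrate estimator correctness under binomial sampling with uniform
noise, not robustness to real instrument artifacts.

## Problem sizes and tolerances

The recovery experiments use 50,000 reads per data set at the published
per-colony substitution percentages with e = 0.1 % and d = 1 %; at that
depth 3 binomial SEs are ≈0.65 points, and the acceptance tests assert
recovery within 0.75 points (3 SEs plus a small allowance for error-induced
bias, which is bounded by e·100 points and is ≈0.17 points here). Oracle
equivalence runs over ≥100 randomized instances; estimator-consistency
checks use 8 seeds at depths 100/1,000/10,000. The end-to-end panel test
uses the default ~4.4 kb genome, three subtypes and fixed seeds; the
conserved-versus-private truth is recovered deterministically.

## Known limitations

* Guide efficiency, chromatin context and off-target activity are out of
  scope; the design filter is purely sequence-based.
* Accession-based reproduction of published guide positions requires the
  GenBank records, which are not bundled; the GenBank reader and position
  logic are tested on constructed records instead.
* The "bystander beyond window" behaviour of real deaminases (occasional
  edits at positions outside 16–19) is not modelled: window Cs are the only
  editable bases.
* The minus-strand position and route-label conventions are this package's
  own (documented above) and may differ from other tools' renderings.
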