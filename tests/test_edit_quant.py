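"""Read alignment, pileup and the window C-to-T substitution statistic."""

import math

import numpy as np
import pytest

from crisprstop.core import reverse_complement
from crisprstop.edit_quant import (
    AmpliconReference,
    ReadAlignment,
    align_read,
    merge_pair,
    pileup,
    quality_mask,
    quantify,
    window_substitution,
)
from crisprstop.guide_design import EditorProfile
from crisprstop.synthetic_data import make_test_amplicon, simulate_amplicon_reads

from conftest import random_seq

PROFILE = EditorProfile()
NEG = float("-inf")


def gotoh_score(a, b, match=1, mismatch=-1, open_=-5, ext=-1):
    """Independent quadratic-time affine-gap global alignment score (Gotoh)."""
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)
    Iy = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = open_ + (i - 1) * ext
    for j in range(1, m + 1):
        Iy[0, j] = open_ + (j - 1) * ext
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]) + s
            Ix[i, j] = max(M[i - 1, j] + open_, Ix[i - 1, j] + ext, Iy[i - 1, j] + open_)
            Iy[i, j] = max(M[i, j - 1] + open_, Iy[i, j - 1] + ext, Ix[i, j - 1] + open_)
    return max(M[n, m], Ix[n, m], Iy[n, m])


def _write_fastq(path, reads, qual_char="F"):
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            q = qual_char * len(seq) if isinstance(qual_char, str) else qual_char[i]
            fh.write(f"@r{i}\n{seq}\n+\n{q}\n")


class TestAlignRead:
    def test_identical_read(self, amplicon):
        aln = align_read(amplicon.residues, amplicon)
        assert aln is not None
        assert aln.identity == 1.0
        assert aln.score == len(amplicon.residues)
        assert not aln.flipped
        assert aln.read_aln == aln.ref_aln

    def test_reverse_complement_read(self, amplicon):
        aln = align_read(reverse_complement(amplicon.residues), amplicon)
        assert aln is not None and aln.flipped and aln.identity == 1.0

    def test_short_read_rejected(self, amplicon):
        assert align_read("ACGTACGT", amplicon) is None

    def test_garbage_rejected(self, amplicon, rng):
        junk = random_seq(rng, len(amplicon.residues))
        assert align_read(junk, amplicon) is None

    @pytest.mark.parametrize("seed", range(12))
    def test_score_matches_dp_oracle_noisy_reads(self, seed, amplicon):
        """Reads derived from the reference by substitutions and indels score
        identically to an independent Gotoh dynamic program."""
        rng = np.random.default_rng(300 + seed)
        read = list(amplicon.residues)
        for _ in range(int(rng.integers(0, 12))):
            pos = int(rng.integers(0, len(read)))
            read[pos] = "ACGT"[rng.integers(0, 4)]
        if seed % 2:  # half the cases get an indel to force the full DP path
            pos = int(rng.integers(10, len(read) - 10))
            if rng.random() < 0.5:
                del read[pos : pos + int(rng.integers(1, 4))]
            else:
                read[pos:pos] = ["ACGT"[i] for i in rng.integers(0, 4, size=2)]
        read = "".join(read)
        aln = align_read(read, amplicon, min_identity=0.0)
        assert aln is not None
        assert aln.score == gotoh_score(amplicon.residues, read)

    @pytest.mark.parametrize("seed", range(3))
    def test_score_matches_dp_oracle_random_pairs(self, seed):
        """Fully random 100-nt pairs (no identity filter) score identically."""
        rng = np.random.default_rng(400 + seed)
        ref = random_seq(rng, 100)
        proto_start = 40
        # ensure the declared protospacer matches whatever is at the coords
        reference = AmpliconReference(
            residues=ref, guide_seq=ref[proto_start - 1 : proto_start + 19],
            guide_start=proto_start, guide_strand="+",
        )
        read = random_seq(rng, 100)
        aln = align_read(read, reference, min_identity=0.0)
        expected = max(
            gotoh_score(ref, read), gotoh_score(ref, reverse_complement(read))
        )
        assert aln.score == expected


class TestPileup:
    def test_perfect_reads(self, amplicon):
        alns = [align_read(amplicon.residues, amplicon) for _ in range(10)]
        table = pileup(alns, amplicon)
        for _, row in table.iterrows():
            assert row[row.ref_base] == 10
            assert row["del"] == 0 and row["ins_after"] == 0

    def test_single_substitution_column(self, amplicon):
        target_col = amplicon.window_c_columns(PROFILE)[0]
        edited = list(amplicon.residues)
        edited[target_col - 1] = "T"
        alns = [align_read(amplicon.residues, amplicon) for _ in range(9)]
        alns.append(align_read("".join(edited), amplicon))
        table = pileup(alns, amplicon)
        row = table.iloc[target_col - 1]
        assert row["C"] == 9 and row["T"] == 1

    def test_gap_attribution(self):
        ref = "ACGTACGTAC"
        reference = AmpliconReference(
            residues=ref + "T" * 13 + "TTCAGGTTAAGAAGGGACCTTGG",
            guide_seq="TTCAGGTTAAGAAGGGACCT", guide_start=24, guide_strand="+",
        )
        # deletion of ref cols 3-4; insertion of 2 nt after ref col 7
        n = len(reference.residues)
        ref_aln = reference.residues[:7] + "--" + reference.residues[7:]
        read_aln = reference.residues[:2] + "--" + reference.residues[4:7] + "GG" + reference.residues[7:]
        aln = ReadAlignment(ref_aln, read_aln, 0, 1.0, False)
        table = pileup([aln], reference)
        assert table.iloc[2]["del"] == 1 and table.iloc[3]["del"] == 1
        assert table.iloc[6]["ins_after"] == 1
        assert int(table["ins_after"].sum()) == 1

    def test_counts_match_simulation_truth(self, amplicon):
        """With no indels/errors, pileup counts at the target column must equal
        the generator's realized edited-read count exactly."""
        truth, reads = simulate_amplicon_reads(
            amplicon, seed=9, n_reads=400, edit_fraction=0.3, co_conversion=0.0,
        )
        alns = [align_read(r, amplicon) for r in reads]
        table = pileup(alns, amplicon)
        col = truth.parameters["target_column"]
        n_edit = truth.realized["n_edited_reads"]
        assert table.iloc[col - 1]["T"] == n_edit
        assert table.iloc[col - 1]["C"] == 400 - n_edit
        # every non-window column is untouched
        other = table.drop(index=[col - 1])
        assert all(row[row.ref_base] == 400 for _, row in other.iterrows())


class TestWindowSubstitution:
    def test_all_unedited_zero_percent(self, amplicon):
        alns = [align_read(amplicon.residues, amplicon) for _ in range(10)]
        t = window_substitution(alns, amplicon)
        assert t.window_c_to_t_percent == 0.00

    def test_hand_counted_thirty_percent(self, amplicon):
        target_col = amplicon.window_c_columns(PROFILE)[0]
        edited = list(amplicon.residues)
        edited[target_col - 1] = "T"
        reads = [amplicon.residues] * 7 + ["".join(edited)] * 3
        alns = [align_read(r, amplicon) for r in reads]
        t = window_substitution(alns, amplicon)
        assert t.window_c_to_t_percent == 30.00
        assert t.n_reads_denominator == 10 and t.n_reads_converted == 3
        assert t.per_window_position_percent[target_col] == 30.00

    def test_no_window_c_not_applicable(self):
        proto = "TTGAGTTAAGAAGGGAATTT"  # window TGAG: no C
        ref = "A" * 30 + proto + "TGG" + "A" * 30
        reference = AmpliconReference(ref, proto, 31, "+")
        alns = [align_read(ref, reference)]
        t = window_substitution(alns, reference)
        assert not t.applicable and t.window_c_to_t_percent is None

    def test_base_counts_partition_aligned_reads(self, amplicon):
        _, reads = simulate_amplicon_reads(
            amplicon, seed=21, n_reads=300, edit_fraction=0.4, error_rate=0.002,
            indel_fraction=0.05,
        )
        alns = [align_read(r, amplicon) for r in reads]
        alns = [a for a in alns if a is not None]
        t = window_substitution(alns, amplicon)
        sums = t.counts[["A", "C", "G", "T", "N", "del"]].sum(axis=1)
        assert (sums == len(alns)).all()

    def test_binomial_recovery(self, amplicon):
        """Injected fraction recovered within 3 binomial SEs at n=20,000."""
        f = 0.35
        n = 20_000
        _, reads = simulate_amplicon_reads(
            amplicon, seed=77, n_reads=n, edit_fraction=f, error_rate=0.001,
        )
        alns = [align_read(r, amplicon) for r in reads]
        t = window_substitution(alns, amplicon)
        se = math.sqrt(f * (1 - f) / n) * 100
        assert abs(t.window_c_to_t_percent - 100 * f) < 3 * se + 0.2


class TestQuantify:
    def test_zero_fraction(self, amplicon, tmp_path):
        simulate_amplicon_reads(
            amplicon, seed=3, n_reads=50, edit_fraction=0.0,
            out_r1=tmp_path / "r1.fq",
        )
        table, report = quantify(tmp_path / "r1.fq", amplicon)
        assert table.window_c_to_t_percent == 0.00

    def test_full_fraction(self, amplicon, tmp_path):
        simulate_amplicon_reads(
            amplicon, seed=4, n_reads=50, edit_fraction=1.0,
            out_r1=tmp_path / "r1.fq",
        )
        table, _ = quantify(tmp_path / "r1.fq", amplicon)
        assert table.window_c_to_t_percent == 100.00

    def test_paired_end_merge(self, amplicon, tmp_path):
        simulate_amplicon_reads(
            amplicon, seed=6, n_reads=40, edit_fraction=0.5, paired=True,
            out_r1=tmp_path / "r1.fq", out_r2=tmp_path / "r2.fq",
        )
        table, report = quantify(tmp_path / "r1.fq", amplicon, r2_path=tmp_path / "r2.fq")
        assert report["n_pairs_merged"] == 40
        assert table.n_reads_aligned == 40

    def test_quality_masking_excludes_target_calls(self, amplicon, tmp_path):
        # every read edited, but the target base has Phred 2 -> masked to N,
        # so no read contributes a call at the target column
        target_col = amplicon.window_c_columns(PROFILE)[0]
        edited = list(amplicon.residues)
        edited[target_col - 1] = "T"
        read = "".join(edited)
        quals = ["F"] * len(read)
        quals[target_col - 1] = "#"  # Phred 2
        _write_fastq(tmp_path / "r1.fq", [read] * 5, qual_char=["".join(quals)] * 5)
        table, _ = quantify(tmp_path / "r1.fq", amplicon)
        assert table.n_reads_denominator == 0
        assert table.window_c_to_t_percent is None

    def test_indel_reads_excluded_from_denominator(self, amplicon, tmp_path):
        truth, _ = simulate_amplicon_reads(
            amplicon, seed=8, n_reads=600, edit_fraction=0.5, indel_fraction=0.2,
            out_r1=tmp_path / "r1.fq",
        )
        table, _ = quantify(tmp_path / "r1.fq", amplicon)
        n_indel = truth.realized["n_indel_reads"]
        assert table.n_reads_indel_near_window == n_indel
        assert table.n_reads_denominator == 600 - n_indel
        f_hat = table.window_c_to_t_percent
        se = math.sqrt(0.25 / table.n_reads_denominator) * 100
        assert abs(f_hat - 50.0) < 3 * se

    def test_strand_correctness(self, tmp_path):
        """A '-'-guide dataset quantifies identically to the mirrored dataset
        quantified with the '+' guide."""
        minus_ref = make_test_amplicon(seed=13, guide_strand="-", guide_start=110)
        truth, reads = simulate_amplicon_reads(
            minus_ref, seed=14, n_reads=500, edit_fraction=0.42, error_rate=0.001,
        )
        plus_ref = AmpliconReference(
            residues=reverse_complement(minus_ref.residues),
            guide_seq=minus_ref.guide_seq,
            guide_start=len(minus_ref.residues) - minus_ref.guide_start + 1,
            guide_strand="+",
        )
        _write_fastq(tmp_path / "minus.fq", reads)
        _write_fastq(tmp_path / "plus.fq", [reverse_complement(r) for r in reads])
        t_minus, _ = quantify(tmp_path / "minus.fq", minus_ref)
        t_plus, _ = quantify(tmp_path / "plus.fq", plus_ref)
        assert t_minus.window_c_to_t_percent == t_plus.window_c_to_t_percent
        assert t_minus.n_reads_denominator == t_plus.n_reads_denominator
        n = len(minus_ref.residues)
        mirrored_pp = {
            n - col + 1: pct for col, pct in t_plus.per_window_position_percent.items()
        }
        assert t_minus.per_window_position_percent == mirrored_pp
        # base counts mirror with complementation (no indels simulated)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for base in "ACGT":
            lhs = t_minus.counts[base].to_numpy()
            rhs = t_plus.counts[comp[base]].to_numpy()[::-1]
            assert (lhs == rhs).all()

    def test_estimator_consistency(self, amplicon):
        """Mean absolute error of the estimate shrinks as read depth grows."""
        f = 0.5
        maes = []
        for n in (100, 1000, 10000):
            errs = []
            for seed in range(8):
                _, reads = simulate_amplicon_reads(
                    amplicon, seed=1000 + seed, n_reads=n, edit_fraction=f,
                    error_rate=0.001,
                )
                alns = [align_read(r, amplicon) for r in reads]
                t = window_substitution(alns, amplicon)
                errs.append(abs(t.window_c_to_t_percent - 100 * f))
            maes.append(float(np.mean(errs)))
        assert maes[0] > maes[1] > maes[2]

    def test_error_robustness_bias_bound(self, amplicon):
        """With uniform error e, the estimator's bias stays below 100*e points
        (errors inflate C->T only at ~e/3 and deplete edited Ts at ~e)."""
        f, e, n = 0.5, 0.005, 20_000
        _, reads = simulate_amplicon_reads(
            amplicon, seed=55, n_reads=n, edit_fraction=f, error_rate=e,
        )
        alns = [align_read(r, amplicon) for r in reads]
        t = window_substitution(alns, amplicon)
        expected = 100 * (f * (1 - e) + (1 - f) * e / 3)
        se = math.sqrt(f * (1 - f) / n) * 100
        assert abs(t.window_c_to_t_percent - expected) < 3 * se
        assert abs(expected - 100 * f) < 100 * e


class TestMergeAndMask:
    def test_merge_exact_overlap(self):
        full = "GATTACAGGCTTACGTGACCATTGTCAGCAATCGGATGCT"  # 40 nt, 20-nt overlap
        r1, r2 = full[:30], reverse_complement(full[-30:])
        assert merge_pair(r1, r2) == full

    def test_merge_fails_without_overlap(self, rng):
        assert merge_pair(random_seq(rng, 40), random_seq(rng, 40)) is None

    def test_quality_mask(self):
        assert quality_mask("ACGT", [40, 5, 40, 19]) == "ANGN"


def test_quantify_reads_gzipped_fastq(amplicon, tmp_path):
    import gzip

    _, reads = simulate_amplicon_reads(amplicon, seed=12, n_reads=30, edit_fraction=1.0)
    with gzip.open(tmp_path / "r1.fq.gz", "wt") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@r{i}\n{seq}\n+\n{'F' * len(seq)}\n")
    table, _ = quantify(tmp_path / "r1.fq.gz", amplicon)
    assert table.window_c_to_t_percent == 100.00
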