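#!/usr/bin/env python
"""Simulate amplicon deep-sequencing read sets at the published editing rates.

For each of the four published colony substitution rates (gag 63.15/52.12%,
pol 54.60/47.83%) simulate 50,000 single-end amplicon reads carrying the
target-C conversion at that fraction, plus 0.1% uniform per-base error and 1%
indel reads. FASTQ files go to scratch/ (they are bulky); the ground-truth
JSON per run goes to results/.
"""

import argparse
import json
from pathlib import Path

from crisprstop.synthetic_data import make_test_amplicon, simulate_amplicon_reads

ROOT = Path(__file__).resolve().parents[1]

RATES = {
    "gag_colony1": 63.15,
    "gag_colony3": 52.12,
    "pol_colony1": 54.60,
    "pol_colony3": 47.83,
}
N_READS = 50_000


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-reads", type=int, default=N_READS)
    args = parser.parse_args()

    scratch = ROOT / "scratch" / "reads"
    scratch.mkdir(parents=True, exist_ok=True)
    (ROOT / "results").mkdir(exist_ok=True)

    manifest = {}
    for i, (label, rate) in enumerate(RATES.items()):
        reference = make_test_amplicon(seed=args.seed + i)
        truth, _ = simulate_amplicon_reads(
            reference,
            seed=args.seed + 100 + i,
            n_reads=args.n_reads,
            edit_fraction=rate / 100.0,
            error_rate=0.001,
            indel_fraction=0.01,
            out_r1=scratch / f"{label}.fq",
            truth_path=ROOT / "results" / f"reads_truth_{label}.json",
        )
        manifest[label] = {
            "fastq": str(scratch / f"{label}.fq"),
            "injected_percent": rate,
            "n_reads": args.n_reads,
            "guide_seq": reference.guide_seq,
            "guide_start": reference.guide_start,
            "guide_strand": reference.guide_strand,
            "amplicon": reference.residues,
            "realized_edited_reads": truth.realized["n_edited_reads"],
        }
        print(f"{label}: {args.n_reads} reads at {rate}% "
              f"({truth.realized['n_edited_reads']} edited) -> {label}.fq")
    with open(ROOT / "results" / "read_sets_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")


if __name__ == "__main__":
    main()
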