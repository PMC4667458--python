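#!/usr/bin/env python
"""Differential-regulation filtering of the simulated time courses.

Computes pseudocounted log2 ratios against the t = 0 reference, applies the
two retention rules (threshold at the lipid-accumulation timepoints; sustained
same-sign run of >= 30 min), and scores the decisions against the planted
truth of the filter benchmark. Writes log_ratios.tsv and filter_report.tsv
per bundle under results/filtering/.
"""

import argparse
import json
from pathlib import Path

from lipidtrn.expression import read_expression_tsv, write_matrix_tsv
from lipidtrn.filtering import compute_log_ratios, filter_transcripts

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--simdir", type=Path, default=ROOT / "results" / "sim")
    parser.add_argument("--outdir", type=Path, default=ROOT / "results" / "filtering")
    args = parser.parse_args()

    for name in ("noiseless", "noisy"):
        expr = read_expression_tsv(args.simdir / "filter_bench" / f"expression_{name}.tsv")
        truth = json.loads((args.simdir / "filter_bench" / f"truth_{name}.json").read_text())
        ratios = compute_log_ratios(expr)
        report = filter_transcripts(ratios)
        outdir = args.outdir / name
        outdir.mkdir(parents=True, exist_ok=True)
        write_matrix_tsv(ratios.data, outdir / "log_ratios.tsv")
        report.to_tsv(outdir / "filter_report.tsv")
        agree = sum(report.rule_for(t) == rule for t, rule in truth.items()) / len(truth)
        nulls = [t for t, rule in truth.items() if rule == "none"]
        fp = sum(t in report.kept for t in nulls)
        print(
            f"{name}: kept {len(report.kept)}/{len(truth)}; rule agreement {100 * agree:.2f} %; "
            f"false positives {fp}/{len(nulls)} ({100 * fp / len(nulls):.2f} %)"
        )

    expr = read_expression_tsv(args.simdir / "regulator_bench" / "expression.tsv")
    ratios = compute_log_ratios(expr)
    report = filter_transcripts(ratios)
    outdir = args.outdir / "regulator_bench"
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix_tsv(ratios.data, outdir / "log_ratios.tsv")
    report.to_tsv(outdir / "filter_report.tsv")
    print(f"regulator_bench: kept {len(report.kept)}/{len(ratios.transcript_ids)} transcripts")


if __name__ == "__main__":
    main()
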