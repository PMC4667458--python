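#!/usr/bin/env python
"""Generate the synthetic study inputs used by the downstream analysis steps.

Writes three bundles under results/sim/:
  regulator_bench/   20 regulators, 60 modules in 10 waves, 10 planted
                     influences, log-ratio noise sigma = 0.1 (15-min sampling)
  wave_bench/        12 modules in 6 waves with crossings in the densely
                     sampled first hour, noiseless (for timestamp recovery)
  filter_bench/      transcripts planted to pass rule 1 only, rule 2 only,
                     both, or neither (noiseless and sigma = 0.1 variants)
"""

import argparse
import json
from pathlib import Path

from lipidtrn.pipeline import write_id_column, write_modules_tsv
from lipidtrn.synthetic import (
    default_trn_spec,
    simulate_expression,
    simulate_filter_bench,
    wave_bench_spec,
)

ROOT = Path(__file__).resolve().parent.parent


def dump_bundle(outdir: Path, spec):
    outdir.mkdir(parents=True, exist_ok=True)
    expr, assignment, tr_ids, truth = simulate_expression(spec)
    expr.to_tsv(outdir / "expression.tsv")
    write_modules_tsv(assignment, outdir / "modules.tsv")
    if tr_ids:
        write_id_column(tr_ids, outdir / "regulators.tsv", "tr_id")
    doc = {
        "edges": [list(e) for e in truth.edges],
        "module_kind": {k: list(v) for k, v in truth.module_kind.items()},
        "module_crossing": truth.module_crossing,
        "kept_rule": truth.kept_rule,
    }
    (outdir / "ground_truth.json").write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")
    return expr, assignment, tr_ids, truth


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path, default=ROOT / "results" / "sim")
    args = parser.parse_args()

    expr, assignment, tr_ids, _ = dump_bundle(args.outdir / "regulator_bench", default_trn_spec(args.seed))
    print(
        f"regulator_bench: {len(expr.transcript_ids)} transcripts "
        f"({len(assignment)} modules, {len(tr_ids)} regulators) -> {args.outdir / 'regulator_bench'}"
    )

    expr, assignment, _, _ = dump_bundle(args.outdir / "wave_bench", wave_bench_spec(args.seed))
    print(f"wave_bench: {len(expr.transcript_ids)} transcripts ({len(assignment)} modules)")

    fdir = args.outdir / "filter_bench"
    fdir.mkdir(parents=True, exist_ok=True)
    for name, sigma in (("noiseless", 0.0), ("noisy", 0.1)):
        expr, truth = simulate_filter_bench(args.seed, noise_sigma=sigma)
        expr.to_tsv(fdir / f"expression_{name}.tsv")
        (fdir / f"truth_{name}.json").write_text(json.dumps(truth, indent=1, sort_keys=True) + "\n")
        print(f"filter_bench/{name}: {len(expr.transcript_ids)} transcripts (sigma={sigma})")


if __name__ == "__main__":
    main()
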