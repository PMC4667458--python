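"""Recovery benchmarks run against planted synthetic ground truth.

Each function regenerates its inputs from a seed, runs the relevant pipeline
stage, and scores the result against what the generator planted. Oracles used
for cross-validation (the element-wise log-ratio loop, the cobrapy LP) are
deliberately separate code paths from the implementation they check.
"""

from __future__ import annotations

import math

import numpy as np

from .expression import ExpressionMatrix
from .filtering import compute_log_ratios, filter_transcripts
from .metabolic import KnockdownConfig, MetabolicModel, fba, rho
from .pipeline import PipelineConfig, run_pipeline, write_id_column, write_modules_tsv
from .smoothing import smooth_and_resample
from .synthetic import (
    TRN_BENCH_LAG_STEP,
    default_trn_spec,
    random_toy_network,
    simulate_expression,
    simulate_filter_bench,
    simulate_toy_metabolic_model,
    wave_bench_spec,
)
from .trn import infer_influences
from .waves import assign_stage, classify_modules

__all__ = [
    "log_ratio_oracle_error",
    "filter_recovery",
    "wave_recovery",
    "influence_recovery",
    "lp_cross_validation",
    "rho_fixture_outcomes",
    "pipeline_determinism",
]


def log_ratio_oracle_error(seed: int, n_matrices: int = 100, shape=(12, 6)) -> float:
    """Max |implementation - brute force| of the log2 ratio over random matrices."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    times = np.linspace(0, 480, shape[1])
    worst = 0.0
    for _ in range(n_matrices):
        x = rng.gamma(1.0, 50.0, size=shape)
        expr = ExpressionMatrix(
            pd.DataFrame(x, index=[f"t{i}" for i in range(shape[0])], columns=times)
        )
        got = compute_log_ratios(expr).values
        oracle = np.array(
            [
                [math.log2((x[i, j] + 1.0) / (x[i, 0] + 1.0)) for j in range(shape[1])]
                for i in range(shape[0])
            ]
        )
        worst = max(worst, float(np.abs(got - oracle).max()))
    return worst


def filter_recovery(seed: int, *, n_null_noisy: int = 2000) -> dict:
    """Planted-rule agreement at sigma = 0 and false-positive rate at sigma = 0.1."""
    expr0, truth0 = simulate_filter_bench(seed, noise_sigma=0.0, n_null=200)
    rep0 = filter_transcripts(compute_log_ratios(expr0))
    agree = np.mean([rep0.rule_for(t) == rule for t, rule in truth0.items()])

    expr1, _ = simulate_filter_bench(
        seed + 1, n_rule1=0, n_rule2=0, n_both=0, n_null=n_null_noisy, noise_sigma=0.1
    )
    rep1 = filter_transcripts(compute_log_ratios(expr1))
    fpr = len(rep1.kept) / n_null_noisy
    return {
        "noiseless_agreement": float(agree),
        "false_positive_rate": float(fpr),
        "n_scored": len(truth0),
        "n_null": n_null_noisy,
    }


def wave_recovery(seed: int) -> dict:
    """Noiseless dynamics-class accuracy and worst twofold-crossing timestamp error."""
    expr, assignment, _, truth = simulate_expression(wave_bench_spec(seed, noise_sigma=0.0))
    ratios = compute_log_ratios(expr)
    mods = classify_modules(ratios, assignment)
    class_ok = [
        (md.dynamics, md.direction) == truth.module_kind[md.module_id] for md in mods
    ]
    ts_err = [abs(md.timestamp - truth.module_crossing[md.module_id]) for md in mods]
    stage_ok = (
        assign_stage(12.0) == "early" and assign_stage(44.0) == "mid" and assign_stage(109.0) == "late"
    )
    return {
        "class_accuracy": float(np.mean(class_ok)),
        "max_timestamp_error_min": float(max(ts_err)),
        "stage_labels_ok": bool(stage_ok),
        "n_modules": len(mods),
    }


def influence_recovery(seeds, *, lag_step: float = TRN_BENCH_LAG_STEP) -> dict:
    """Precision/recall/lag/sign scoring of the regulator benchmark over seeds."""
    precisions, recalls, lag_errs, sign_hits, sign_total = [], [], [], 0, 0
    for seed in seeds:
        spec = default_trn_spec(int(seed))
        expr, assignment, tr_ids, truth = simulate_expression(spec)
        ratios = compute_log_ratios(expr)
        report = filter_transcripts(ratios)
        mods = classify_modules(ratios, assignment)
        tr_profiles = {
            t: smooth_and_resample(ratios.times, ratios.profile(t), source_id=t)
            for t in tr_ids
            if t in report.kept
        }
        module_profiles = {md.module_id: md.profile for md in mods}
        edges = infer_influences(tr_profiles, module_profiles, lag_step=lag_step)
        true_lookup = {(e[0], e[1]): (e[2], e[3]) for e in truth.edges}
        recovered = {(e.tr_id, e.module_id) for e in edges}
        tp = recovered & set(true_lookup)
        precisions.append(len(tp) / max(len(recovered), 1))
        recalls.append(len(tp) / len(true_lookup))
        for e in edges:
            key = (e.tr_id, e.module_id)
            if key in true_lookup:
                lag_errs.append(abs(e.lag - true_lookup[key][0]))
                sign_hits += e.sign == true_lookup[key][1]
                sign_total += 1
    return {
        "precision_min": float(min(precisions)),
        "precision_mean": float(np.mean(precisions)),
        "recall_min": float(min(recalls)),
        "recall_mean": float(np.mean(recalls)),
        "max_lag_error_min": float(max(lag_errs)) if lag_errs else float("nan"),
        "lag_step_min": float(lag_step),
        "sign_accuracy": sign_hits / max(sign_total, 1),
        "n_seeds": len(list(seeds)),
    }


def _cobra_objective(model: MetabolicModel, objective_id: str) -> float:
    import cobra

    cm = cobra.Model(model.id)
    mets = {m: cobra.Metabolite(m) for m in model.metabolites}
    rxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id)
        cr.lower_bound = -1e6 if math.isinf(r.lb) else r.lb
        cr.upper_bound = 1e6 if math.isinf(r.ub) else r.ub
        rxns.append(cr)
    cm.add_reactions(rxns)
    for r, cr in zip(model.reactions, rxns):
        cr.add_metabolites({mets[m]: c for m, c in r.stoich.items()})
    cm.objective = objective_id
    return float(cm.slim_optimize())


def lp_cross_validation(seed: int, n_networks: int = 20) -> dict:
    """Compare the HiGHS-based FBA with an independent cobrapy solve, plus the
    fixture networks; report the worst objective gap and mass-balance residual."""
    rng = np.random.default_rng(seed)
    worst_gap = 0.0
    worst_balance = 0.0
    cases = [(random_toy_network(rng), "OBJ") for _ in range(n_networks)]
    for kind in ("chain", "branch", "isozyme"):
        model, _ = simulate_toy_metabolic_model(kind)
        cases.append((model, "BM_TAG"))
        cases.append((model, "EX_TAG"))
    for model, objective in cases:
        sol = fba(model, objective)
        worst_gap = max(worst_gap, abs(sol.objective_value - _cobra_objective(model, objective)))
        S = model.stoichiometric_matrix()
        v = np.array([sol.fluxes[r] for r in model.reaction_ids])
        worst_balance = max(worst_balance, float(np.abs(S @ v).max()))
    return {
        "max_objective_gap": float(worst_gap),
        "max_mass_balance_violation": float(worst_balance),
        "n_networks": len(cases),
    }


def rho_fixture_outcomes() -> dict:
    """The four analytic knockdown outcomes of the toy fixtures."""
    branch, _ = simulate_toy_metabolic_model("branch")
    chain, _ = simulate_toy_metabolic_model("chain")
    iso, _ = simulate_toy_metabolic_model("isozyme")
    null = rho(branch, "gene_without_reactions")
    branch_kd = rho(branch, "gC", KnockdownConfig(kd_factor=2.0))
    chain_kd = rho(chain, "g1", KnockdownConfig(kd_factor=16.0))
    iso_kd = rho(iso, "g1", KnockdownConfig(kd_factor=16.0))
    return {
        "rho_null": null.rho,
        "rho_branch": branch_kd.rho,
        "chain_bm_ratio": chain_kd.bm_ratio,
        "chain_viable": chain_kd.viable,
        "rho_isozyme": iso_kd.rho,
    }


def pipeline_determinism(workdir, seed: int) -> dict:
    """Run the full pipeline twice on the same bundle; compare output hashes."""
    from pathlib import Path

    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    spec = default_trn_spec(seed, n_null_transcripts=20)
    expr, assignment, tr_ids, _ = simulate_expression(spec)
    expr.to_tsv(workdir / "expression.tsv")
    write_modules_tsv(assignment, workdir / "modules.tsv")
    write_id_column(tr_ids, workdir / "regulators.tsv", "tr_id")
    model, _ = simulate_toy_metabolic_model("branch")
    model.to_json(workdir / "model.json")
    with open(workdir / "id_map.tsv", "w") as fh:
        fh.write("transcript_id\tmodel_gene_id\n")
        for tid, gene in (("M13_T01", "gC"), ("M13_T02", "gB"), ("M13_T03", "gD")):
            fh.write(f"{tid}\t{gene}\n")

    manifests = []
    for run_dir in ("run1", "run2"):
        cfg = PipelineConfig(
            expression_tsv=workdir / "expression.tsv",
            outdir=workdir / run_dir,
            modules_tsv=workdir / "modules.tsv",
            regulators_tsv=workdir / "regulators.tsv",
            model_path=workdir / "model.json",
            id_map_tsv=workdir / "id_map.tsv",
            knockdown=KnockdownConfig(kd_factor=2.0),
            lag_step=TRN_BENCH_LAG_STEP,
            seed=seed,
        )
        manifests.append(run_pipeline(cfg))
    identical = manifests[0]["outputs"] == manifests[1]["outputs"]
    return {
        "identical": bool(identical),
        "n_outputs": len(manifests[0]["outputs"]),
        "stages_completed": sum(
            1 for s in manifests[0]["stages"].values() if s.get("status") == "completed"
        ),
    }
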