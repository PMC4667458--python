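"""End-to-end orchestration: filter -> waves -> regulator influences -> knockdown screen.

Each stage reads the previous stage's in-memory results, writes its artifact
as TSV with a parameter header, and is skipped (with a warning in the
manifest) when its inputs are absent. A JSON manifest records parameters,
stage status and SHA-256 hashes of every output file so that reruns can be
checked for byte-identity.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .expression import ExpressionMatrix, read_expression_tsv, write_matrix_tsv
from .filtering import FilterConfig, compute_log_ratios, filter_transcripts
from .metabolic import KnockdownConfig, load_model, screen_targets, targets_to_frame
from .smoothing import smooth_and_resample
from .trn import LagWindow, edges_to_frame, infer_influences
from .waves import classify_modules, group_into_waves, waves_to_frame

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    expression_tsv: str | Path
    outdir: str | Path
    modules_tsv: str | Path | None = None
    regulators_tsv: str | Path | None = None
    model_path: str | Path | None = None
    id_map_tsv: str | Path | None = None  # transcript_id -> model gene id
    s_down_tsv: str | Path | None = None
    p_down_tsv: str | Path | None = None
    filter: FilterConfig = field(default_factory=FilterConfig)
    grid_step_min: float = 1.0
    lam: float | None = None  # None = GCV-automatic smoothing penalty
    window: LagWindow = field(default_factory=LagWindow)
    lag_step: float = 1.0
    percentile: float = 5.0
    pool: str = "best"
    knockdown: KnockdownConfig = field(default_factory=KnockdownConfig)
    seed: int = 0


def read_modules_tsv(path) -> dict[str, list[str]]:
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = list(df.columns[:2])
    out: dict[str, list[str]] = {}
    for mod, tid in zip(df[cols[0]].astype(str), df[cols[1]].astype(str)):
        out.setdefault(mod, []).append(tid)
    return out


def _read_id_column(path) -> list[str]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [str(v) for v in df[df.columns[0]]]


def write_modules_tsv(assignment: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("module_id\ttranscript_id\n")
        for mod in sorted(assignment):
            for tid in assignment[mod]:
                fh.write(f"{mod}\t{tid}\n")


def write_id_column(ids, path, column: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"{column}\n")
        for i in ids:
            fh.write(f"{i}\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _df_to_tsv(df: pd.DataFrame, path: Path, header_lines: list[str]) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def run_pipeline(cfg: PipelineConfig, expr: ExpressionMatrix | None = None) -> dict:
    """Execute every runnable stage and return the manifest (also written to disk)."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {
            "fold_threshold": cfg.filter.fold_threshold,
            "lipid_timepoints": list(cfg.filter.lipid_timepoints),
            "min_period": cfg.filter.min_period,
            "lipid_rule_mode": cfg.filter.lipid_rule_mode,
            "grid_step_min": cfg.grid_step_min,
            "lam": cfg.lam,
            "lag_window": [cfg.window.min_lag, cfg.window.max_lag],
            "lag_step": cfg.lag_step,
            "percentile": cfg.percentile,
            "pool": cfg.pool,
            "kd_factor": cfg.knockdown.kd_factor,
            "viability_fraction": cfg.knockdown.viability_fraction,
            "gpr_mode": cfg.knockdown.gpr_mode,
        },
        "stages": {},
        "outputs": {},
    }
    param_header = [f"{k} = {v}" for k, v in manifest["parameters"].items()]

    # -- stage 1: filtering -------------------------------------------------
    expr = expr if expr is not None else read_expression_tsv(cfg.expression_tsv)
    ratios = compute_log_ratios(expr)
    report = filter_transcripts(ratios, cfg.filter)
    ratios_path = outdir / "log_ratios.tsv"
    write_matrix_tsv(ratios.data, ratios_path, header_lines=param_header)
    report_path = outdir / "filter_report.tsv"
    report.to_tsv(report_path)
    manifest["stages"]["filtering"] = {
        "status": "completed",
        "n_transcripts": len(ratios.transcript_ids),
        "n_kept": len(report.kept),
    }

    # -- stage 2: waves -----------------------------------------------------
    waves = None
    if cfg.modules_tsv is None:
        manifest["stages"]["waves"] = {"status": "skipped", "reason": "no module assignment"}
        warnings.warn("waves stage skipped: no module assignment supplied")
    else:
        assignment = read_modules_tsv(cfg.modules_tsv)
        kept = report.kept
        assignment = {
            m: [t for t in ts if t in kept] for m, ts in assignment.items()
        }
        assignment = {m: ts for m, ts in assignment.items() if ts}
        module_dyn = classify_modules(
            ratios,
            assignment,
            fold_threshold=cfg.filter.fold_threshold,
            grid_step_min=cfg.grid_step_min,
            lam=cfg.lam,
        )
        waves = group_into_waves(
            module_dyn,
            ratios,
            assignment,
            fold_threshold=cfg.filter.fold_threshold,
            grid_step_min=cfg.grid_step_min,
            lam=cfg.lam,
        )
        _df_to_tsv(waves_to_frame(waves), outdir / "waves.tsv", param_header)
        manifest["stages"]["waves"] = {
            "status": "completed",
            "n_modules": len(assignment),
            "n_waves": len(waves),
            "n_flat": sum(1 for md in module_dyn if md.dynamics == "flat"),
        }

    # -- stage 3: regulator influences -------------------------------------
    if cfg.modules_tsv is None or cfg.regulators_tsv is None:
        manifest["stages"]["trn"] = {"status": "skipped", "reason": "modules or regulator list missing"}
        warnings.warn("trn stage skipped: modules or regulator list missing")
    else:
        regulators = _read_id_column(cfg.regulators_tsv)
        scored_trs = [t for t in regulators if t in report.kept]
        tr_profiles = {
            t: smooth_and_resample(
                ratios.times,
                ratios.profile(t),
                source_id=t,
                grid_step_min=cfg.grid_step_min,
                lam=cfg.lam,
            )
            for t in scored_trs
        }
        module_profiles = {md.module_id: md.profile for md in module_dyn}
        edges = infer_influences(
            tr_profiles,
            module_profiles,
            window=cfg.window,
            lag_step=cfg.lag_step,
            percentile=cfg.percentile,
            pool=cfg.pool,
        )
        _df_to_tsv(edges_to_frame(edges), outdir / "influences.tsv", param_header)
        manifest["stages"]["trn"] = {
            "status": "completed",
            "n_regulators_scored": len(scored_trs),
            "n_edges": len(edges),
        }

    # -- stage 4: knockdown screen ------------------------------------------
    if cfg.model_path is None:
        manifest["stages"]["fbakd"] = {"status": "skipped", "reason": "no metabolic model"}
        warnings.warn("fbakd stage skipped: no metabolic model supplied")
    else:
        model = load_model(cfg.model_path)
        candidates = sorted(report.kept)
        if cfg.id_map_tsv is not None:
            id_map = pd.read_csv(cfg.id_map_tsv, sep="\t", comment="#")
            tcol, gcol = id_map.columns[:2]
            mapping = dict(zip(id_map[tcol].astype(str), id_map[gcol].astype(str)))
            unmapped = [t for t in candidates if t not in mapping]
            candidates = sorted({mapping[t] for t in candidates if t in mapping})
            manifest["stages"].setdefault("fbakd", {})["n_unmapped_transcripts"] = len(unmapped)
        model_genes = model.genes
        candidates = [g for g in candidates if g in model_genes]
        results = screen_targets(model, candidates, cfg.knockdown)
        _df_to_tsv(targets_to_frame(results), outdir / "knockdown_screen.tsv", param_header)
        manifest["stages"].setdefault("fbakd", {}).update(
            {
                "status": "completed",
                "n_candidates": len(candidates),
                "n_targets": sum(1 for r in results if r.viable and r.rho is not None and r.rho > 1),
            }
        )

    for p in sorted(outdir.glob("*.tsv")):
        manifest["outputs"][p.name] = _sha256(p)
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
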