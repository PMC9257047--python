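"""End-to-end pipeline: screen -> pairs -> signature -> characterization.

Given an expression matrix, clinical table, immune gene set and optional
infiltration / checkpoint inputs, the pipeline runs every stage in order,
writes each stage's table to a run directory, and emits a machine-readable
JSON run summary.  Identical configuration + seed produce a byte-identical
summary.  Any stage that legitimately empties (no DE irlncRNAs, no
significant pair, ...) halts the run with the halting stage and reason
recorded in the summary — never a silent fallback.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .assoc import (
    checkpoint_contrast,
    coexpression_list,
    gsea_permutation,
    infiltration_association,
    single_gene_analysis,
)
from .pairs import (
    NoSignature,
    build_pair_matrix,
    evaluate_signature,
    frequency_filter,
    pair_cox_screen,
    select_final_pair,
)
from .screen import ScreenConfig, run_screen
from .simulate import ExpressionMatrix

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "EmptyStage"]


class EmptyStage(RuntimeError):
    """A stage produced an empty result; carries the stage name."""

    def __init__(self, stage: str, reason: str):
        super().__init__(f"{stage}: {reason}")
        self.stage = stage
        self.reason = reason


@dataclass
class PipelineConfig:
    """Every tunable of the full run; defaults are the published thresholds."""

    screen: ScreenConfig = field(default_factory=ScreenConfig)
    pair_freq_lo: float = 0.2
    pair_freq_hi: float = 0.8
    pair_cox_p_max: float = 0.05
    lasso_folds: int = 10
    lambda_rule: str = "lambda.min"
    gsea_n_perm: int = 1000
    gsea_weight: float = 1.0
    coexpr_r_min: float = 0.5
    coexpr_p_max: float = 0.001
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class PipelineResult:
    summary: dict
    signature: object | None = None
    outputs: dict = field(default_factory=dict)

    @property
    def halted(self) -> bool:
        return self.summary.get("halt_stage") is not None


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return [_jsonable(v) for v in x]
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    return x


def run_pipeline(
    expr: ExpressionMatrix,
    clinical: pd.DataFrame,
    lnc_ids: list[str],
    immune_gene_ids: list[str],
    config: PipelineConfig | None = None,
    infiltration: pd.DataFrame | None = None,
    checkpoint_genes: list[str] | None = None,
    gene_sets: dict[str, list[str]] | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run every stage in order and assemble the run summary.

    Listwise deletion: tumor samples lacking clinical rows are dropped
    from survival stages (counts recorded in the summary).
    """
    config = config or PipelineConfig()
    outputs: dict = {}
    summary: dict = {
        "config": _jsonable(config.to_dict()),
        "n_tumor": len(expr.tumor_samples),
        "n_normal": len(expr.normal_samples),
        "n_clinical_matched": int(
            sum(s in clinical.index for s in expr.tumor_samples)
        ),
        "halt_stage": None,
        "halt_reason": None,
        "flags": [],
    }

    def _halt(stage: str, reason: str) -> PipelineResult:
        summary["halt_stage"] = stage
        summary["halt_reason"] = reason
        if out_dir is not None:
            _write_outputs(out_dir, outputs, summary)
        return PipelineResult(summary=summary, outputs=outputs)

    # --- stage 1-2: screens -------------------------------------------------
    report = run_screen(expr, lnc_ids, immune_gene_ids, clinical, config.screen)
    summary["counts"] = report.counts
    summary["flags"].extend(report.flags)
    outputs["screen_de"] = report.de_records
    outputs["screen_unicox"] = report.unicox_table
    outputs["screen_multicox"] = report.multicox_table
    if not report.irlncrna_ids:
        return _halt("immune_correlation_screen", "no immune-related lncRNAs")
    if report.de_records.empty:
        return _halt("de_screen", "no differentially expressed irlncRNAs")
    if len(report.multicox_survivors) < 2:
        return _halt(
            "survival_screen",
            "fewer than 2 prognostic DEirlncRNAs; no pairs can be formed",
        )

    # --- stage 3: pair matrix and signature ---------------------------------
    pm = build_pair_matrix(expr, report.multicox_survivors)
    summary["n_pairs_total"] = len(pm)
    pm_f = frequency_filter(pm, config.pair_freq_lo, config.pair_freq_hi)
    summary["n_pairs_in_band"] = len(pm_f)
    outputs["pair_matrix"] = pm_f.values
    if len(pm_f) == 0:
        return _halt("frequency_filter", "no pair inside the 20-80% band")
    screened = pair_cox_screen(pm_f, clinical, config.pair_cox_p_max)
    outputs["pair_cox"] = screened
    summary["n_pairs_prognostic"] = int(screened["kept"].sum())
    if not screened["kept"].any():
        return _halt("pair_cox_screen", "no pair passed the univariate Cox screen")

    sig = select_final_pair(
        screened,
        pm_f,
        report.de_records,
        expr,
        clinical,
        n_folds=config.lasso_folds,
        seed=config.seed,
        lambda_rule=config.lambda_rule,
    )
    if isinstance(sig, NoSignature):
        summary["flags"].extend(sig.flags)
        return _halt("select_final_pair", sig.reason)
    summary["flags"].extend(sig.flags)
    summary["signature"] = {
        "pair": list(sig.pair),
        "hazardous": sig.hazardous,
        "protective": sig.protective,
        "rule": sig.rule,
        "group_sizes": sig.group_sizes,
    }
    outputs["signature_risk"] = sig.risk.to_frame()
    if sig.selection_table is not None:
        outputs["signature_selection"] = sig.selection_table

    # --- stage 4: evaluation ------------------------------------------------
    ev = evaluate_signature(sig, clinical)
    summary["evaluation"] = {
        "logrank_chi2": round(float(ev["logrank"].chi2), 10),
        "logrank_p": float(ev["logrank"].p),
        "riskScore_uni_HR": float(ev["unicox"].loc["riskScore", "HR"]),
        "riskScore_uni_p": float(ev["unicox"].loc["riskScore", "p"]),
        "riskScore_multi_HR": float(ev["multicox"].loc["riskScore", "HR"]),
        "riskScore_multi_p": float(ev["multicox"].loc["riskScore", "p"]),
    }
    outputs["eval_unicox"] = ev["unicox"]
    outputs["eval_multicox"] = ev["multicox"]
    outputs["km_high"] = ev["km_high"].to_frame()
    outputs["km_low"] = ev["km_low"].to_frame()

    # --- stage 5: downstream characterization -------------------------------
    if infiltration is not None:
        try:
            infil_tab = infiltration_association(infiltration, sig)
            outputs["infiltration"] = infil_tab
            summary["infiltration_significant"] = int(infil_tab["significant"].sum())
        except ValueError as exc:
            summary["flags"].append(f"infiltration association skipped: {exc}")
    if checkpoint_genes:
        outputs["checkpoints"] = checkpoint_contrast(expr, checkpoint_genes, sig)
    member_reports = {}
    for gid in sig.pair:
        rep = single_gene_analysis(expr, gid, clinical)
        member_reports[gid] = {
            "tumor_vs_normal_p": rep["tumor_vs_normal"].p,
            "tumor_vs_normal_direction": rep["tumor_vs_normal"].direction,
            "median_split_logrank_p": rep["median_split_logrank"].p,
        }
        outputs[f"single_gene_unicox_{gid}"] = rep["unicox"]
        outputs[f"single_gene_multicox_{gid}"] = rep["multicox"]
    summary["single_gene"] = member_reports
    if gene_sets:
        gsea = gsea_permutation(
            expr,
            sig.hazardous,
            gene_sets,
            n_perm=config.gsea_n_perm,
            seed=config.seed,
            weight_p=config.gsea_weight,
        )
        outputs["gsea"] = pd.DataFrame(
            [
                (r.set_name, r.es, r.nes, r.p_perm, r.n_hit)
                for r in gsea
            ],
            columns=["set_name", "ES", "NES", "p_perm", "n_hit"],
        ).set_index("set_name")
        summary["gsea_top_set"] = max(gsea, key=lambda r: r.nes if np.isfinite(r.nes) else -np.inf).set_name
    coex = coexpression_list(
        expr, sig.pair, config.coexpr_r_min, config.coexpr_p_max
    )
    outputs["coexpression_genes"] = pd.DataFrame({"gene_id": coex}).set_index("gene_id")
    summary["n_coexpression_genes"] = len(coex)

    if out_dir is not None:
        _write_outputs(out_dir, outputs, summary)
    return PipelineResult(summary=summary, signature=sig, outputs=outputs)


def _write_outputs(out_dir, outputs: dict, summary: dict) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, table in outputs.items():
        if isinstance(table, pd.DataFrame):
            table.to_csv(out / f"{name}.tsv", sep="\t", float_format="%.10g")
    (out / "run_summary.json").write_text(
        json.dumps(_jsonable(summary), indent=2, sort_keys=True) + "\n"
    )
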