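"""End-to-end pipeline: simulate (optional) -> quantify -> call -> test -> model.

``run_full_pipeline`` executes every stage from a single config dict and a
seed, and emits one JSON-serializable report: a two-group copy-number summary
table, a per-gene differential methylation table, per-family benchmark
metrics, averaged ROC coordinates, and the final INDEX model.  Identical
config + seed gives an identical report.
"""

from __future__ import annotations

import dataclasses
import json
import tempfile
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import calling, difftest, model as dxmodel, qpcr, simulate
from .panel import write_cpg_bed, write_panel_fasta

__all__ = ["DEFAULT_CONFIG", "run_full_pipeline", "save_report"]

DEFAULT_CONFIG: dict[str, Any] = {
    "panel": {"n_genes": 9, "length_range": (170, 270), "min_cpg": 4},
    "cohort": {},  # overrides for default_cohort_spec fields
    "reads": {"reads_per_amplicon": 300},  # ReadSimParams overrides
    "qpcr": {},  # QpcrSimParams overrides
    "calling": {"min_coverage": 8},
    "test": {"alpha": 0.05},
    "benchmark": {
        "n_splits": 200,
        "train_fraction": 0.7,
        "families": ["elastic_net"],
    },
}


def _merge(base: dict, override: dict | None) -> dict:
    out = {k: dict(v) if isinstance(v, dict) else v for k, v in base.items()}
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def _jsonable(x):
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple, np.ndarray)):
        return [_jsonable(v) for v in x]
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, float) and not np.isfinite(x):
        return None
    return x


def run_full_pipeline(
    config: dict | None = None,
    seed: int = 0,
    workdir: str | Path | None = None,
) -> dict:
    """Run the full synthetic study and return the report dict.

    ``config`` overrides :data:`DEFAULT_CONFIG` section-wise.  All randomness
    derives from ``seed``.  FASTQ intermediates are written under ``workdir``
    (a temporary directory when omitted).
    """
    cfg = _merge(DEFAULT_CONFIG, config)
    tmp = None
    if workdir is None:
        tmp = tempfile.TemporaryDirectory(prefix="cfmethdx_")
        workdir = tmp.name
    workdir = Path(workdir)
    try:
        # -- simulate ------------------------------------------------------
        panel = simulate.generate_panel(seed=seed, **cfg["panel"])
        spec = simulate.default_cohort_spec(seed=seed)
        spec = dataclasses.replace(spec, **cfg["cohort"], seed=seed)
        cohort = simulate.simulate_cohort(spec)
        read_params = simulate.ReadSimParams(seed=seed + 1, **cfg["reads"])
        reads_dir = workdir / "reads"
        fastq_pairs = simulate.simulate_bisulfite_reads(panel, cohort, read_params, reads_dir)
        qpcr_params = simulate.QpcrSimParams(seed=seed + 2, **cfg["qpcr"])
        standards, cq_sheet = simulate.simulate_qpcr(cohort, qpcr_params)
        write_panel_fasta(panel, workdir / "panel.fasta")
        write_cpg_bed(panel, workdir / "panel_cpg.bed")

        # -- quantify ------------------------------------------------------
        curve = qpcr.fit_standard_curve(standards)
        quants = qpcr.quantify_sample_sheet(cq_sheet, curve)
        labels = pd.Series(
            cq_sheet["group"].to_numpy(), index=cq_sheet["sample_id"].to_numpy()
        )
        comparison = qpcr.summarize_groups(quants, list(labels))

        # -- call ----------------------------------------------------------
        matrix, percentages, call_qc = calling.call_cohort(
            fastq_pairs, panel, **cfg["calling"]
        )

        # -- differential methylation -------------------------------------
        gene_results, n_sig = difftest.differential_methylation_tests(
            matrix, labels, alpha=cfg["test"]["alpha"]
        )

        # -- diagnostic model ----------------------------------------------
        copies = pd.Series(
            {q.sample_id: q.copies_per_reaction for q in quants}, dtype=float
        )
        table = dxmodel.build_feature_table(percentages, copies, labels)
        bm_cfg = dict(cfg["benchmark"])
        scheme = dxmodel.SplitScheme(
            n_splits=bm_cfg.pop("n_splits"),
            train_fraction=bm_cfg.pop("train_fraction"),
            seed=seed + 3,
        )
        families = bm_cfg.pop("families")
        bench = dxmodel.repeated_holdout_benchmark(
            table, scheme, families=families, **bm_cfg
        )

        enet = bench.get("elastic_net")
        if enet is not None and enet.tuned:
            tuned = enet.tuned
            alpha_star = float(np.median([t[0] for t in tuned]))
            lam_star = float(np.median([t[1] for t in tuned]))
        else:
            alpha_star, lam_star, _ = dxmodel.tune_hyperparameters(
                table.X.to_numpy(dtype=float), table.y,
                alphas=dxmodel.FAST_TUNE["alphas"],
                n_lambda=dxmodel.FAST_TUNE["n_lambda"],
                k=dxmodel.FAST_TUNE["k"], seed=seed + 4,
            )
        index_model = dxmodel.finalize_index_model(table, alpha_star, lam_star)

        roc_family = enet or next(iter(bench.values()))
        youden_i = int(np.argmax(roc_family.mean_tpr - roc_family.fpr_grid))
        report = {
            "seed": seed,
            "n_samples": int(len(cohort)),
            "group_summary": comparison.to_dict(),
            "standard_curve": dataclasses.asdict(curve),
            "gene_tests": difftest.results_frame(gene_results).to_dict(orient="records"),
            "n_significant_genes": int(n_sig),
            "call_qc": call_qc,
            "benchmark": {name: r.summary for name, r in bench.items()},
            "mean_roc": {
                "family": roc_family.family,
                "fpr": roc_family.fpr_grid.tolist(),
                "tpr": roc_family.mean_tpr.tolist(),
            },
            "youden_optimal_fpr_tpr": [
                float(roc_family.fpr_grid[youden_i]),
                float(roc_family.mean_tpr[youden_i]),
            ],
            "index_model": index_model.to_dict(),
        }
        return _jsonable(report)
    finally:
        if tmp is not None:
            tmp.cleanup()


def save_report(report: dict, out_dir: str | Path) -> Path:
    """Write the report as JSON plus a short human-readable summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    g = report["group_summary"]
    lines = [
        "# cfmethdx pipeline report",
        "",
        f"Samples: {report['n_samples']} (seed {report['seed']})",
        "",
        "## Copy-number summary (per reaction)",
        f"case mean/median: {g['case_mean']:.0f} / {g['case_median']:.0f}",
        f"control mean/median: {g['control_mean']:.0f} / {g['control_median']:.0f}",
        f"difference of means/medians: {g['difference_of_means']:.0f} / {g['difference_of_medians']:.0f}",
        f"factor of means/medians: {g['factor_means']} / {g['factor_medians']}",
        f"ANOVA F = {g['anova_f']:.2f}, p = {g['anova_p']:.3g}"
        if g["anova_f"] is not None else "ANOVA omitted",
        "",
        "## Differential methylation",
        f"significant genes (alpha): {report['n_significant_genes']}",
    ]
    for row in report["gene_tests"]:
        pv = "NA" if row["p_value"] is None else f"{row['p_value']:.3g}"
        lines.append(
            f"  {row['gene']}: p={pv} {row['direction'] or ''}"
            f"{' *' if row['significant'] else ''}"
        )
    lines.append("")
    lines.append("## Benchmark (means over splits)")
    for name, s in report["benchmark"].items():
        lines.append(
            f"  {name}: AUC={s['mean_auc']:.3f} sens={s['mean_sensitivity']:.3f} "
            f"spec={s['mean_specificity']:.3f} acc={s['mean_accuracy']:.3f}"
        )
    (out_dir / "report.md").write_text("\n".join(lines) + "\n")
    return out_dir / "report.json"
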