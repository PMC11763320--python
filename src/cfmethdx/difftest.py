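"""Per-gene differential methylation: chi-square test of homogeneity.

For each amplicon, raw methylated (C) and unmethylated (T) counts over its
retained CpG sites are pooled within the case and control groups into a 2x2
table and compared with Pearson's chi-square test of homogeneity (df = 1, no
continuity correction), one p-value per gene, as in a per-amplicon
differential methylation screen.  Direction is hypo when the pooled case
rate is below the pooled control rate.  Per-gene alpha with no multiplicity
correction is the default; Benjamini-Hochberg is available behind a flag.
A per-site 2xk variant (df = k-1) is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calling import SiteCountMatrix

__all__ = [
    "GeneTestResult",
    "pool_counts",
    "chi_square_homogeneity",
    "classify_genes",
    "differential_methylation_tests",
    "results_frame",
]


@dataclass(frozen=True)
class GeneTestResult:
    """Chi-square homogeneity result for one gene's pooled C/T counts."""

    gene_symbol: str
    case_c: int
    case_t: int
    control_c: int
    control_t: int
    chi2: float | None
    df: int | None
    p_value: float | None
    direction: str | None = None  # "hypo" | "hyper"
    significant: bool | None = None
    skipped: str | None = None  # reason when not testable

    @property
    def case_rate(self) -> float:
        tot = self.case_c + self.case_t
        return self.case_c / tot if tot else float("nan")

    @property
    def control_rate(self) -> float:
        tot = self.control_c + self.control_t
        return self.control_c / tot if tot else float("nan")

    @property
    def table(self) -> np.ndarray:
        return np.array([[self.case_c, self.case_t], [self.control_c, self.control_t]])


def _labels_map(labels) -> Mapping[str, str]:
    if isinstance(labels, pd.Series):
        return labels.to_dict()
    return dict(labels)


def pool_counts(matrix: SiteCountMatrix, labels, gene: str) -> np.ndarray:
    """Pooled 2x2 (group x {C, T}) raw counts over the gene's retained sites.

    ``labels`` maps sample_id to "case"/"control".  Raises if the gene has no
    retained site or a group is absent.
    """
    if matrix.retained_mask is None:
        raise RuntimeError("call filter_sites before pool_counts")
    lab = _labels_map(labels)
    groups = set(lab.values())
    if not {"case", "control"} <= groups:
        raise ValueError("labels must contain both 'case' and 'control'")
    kept = matrix.retained_mask[matrix.retained_mask].index
    df = matrix.counts[matrix.counts["gene"] == gene]
    df = df.set_index(["gene", "pos"])
    df = df[df.index.isin(kept)].reset_index()
    if df.empty:
        raise ValueError(f"{gene}: no retained CpG sites")
    df = df.assign(group=df["sample_id"].map(lab))
    pooled = df.groupby("group")[["c_count", "t_count"]].sum()
    return np.array(
        [
            [int(pooled.loc["case", "c_count"]), int(pooled.loc["case", "t_count"])],
            [int(pooled.loc["control", "c_count"]), int(pooled.loc["control", "t_count"])],
        ]
    )


def chi_square_homogeneity(table) -> tuple[float, int, float]:
    """Pearson chi-square of homogeneity on a 2xk count table.

    No continuity correction; expected counts from row/column margins;
    df = k-1 (1 for the default 2x2).  Raises on a zero margin.
    """
    table = np.asarray(table, dtype=np.int64)
    if table.ndim != 2 or table.shape[0] != 2 or table.shape[1] < 2:
        raise ValueError("table must be 2xk with k >= 2")
    if (table < 0).any():
        raise ValueError("counts must be >= 0")
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise ValueError("zero margin: test undefined")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


def classify_genes(
    results: Sequence[GeneTestResult],
    alpha: float = 0.05,
    adjust: str | None = None,
) -> tuple[list[GeneTestResult], int]:
    """Annotate direction and significance; return results and the count of
    significant genes.

    ``adjust="bh"`` applies Benjamini-Hochberg to the p-values before the
    alpha cut (off by default).  Direction is hypo when the pooled case rate
    is below the control rate, hyper otherwise.
    """
    testable = [r for r in results if r.p_value is not None]
    pvals = {r.gene_symbol: r.p_value for r in testable}
    if adjust == "bh" and testable:
        adj = stats.false_discovery_control(
            [r.p_value for r in testable], method="bh"
        )
        pvals = {r.gene_symbol: float(p) for r, p in zip(testable, adj)}
    elif adjust not in (None, "bh"):
        raise ValueError(f"unknown adjustment {adjust!r}")

    out = []
    n_sig = 0
    for r in results:
        if r.p_value is None:
            out.append(r)
            continue
        direction = "hypo" if r.case_rate < r.control_rate else "hyper"
        sig = bool(pvals[r.gene_symbol] < alpha)
        n_sig += sig
        out.append(replace(r, direction=direction, significant=sig))
    return out, n_sig


def differential_methylation_tests(
    matrix: SiteCountMatrix,
    labels,
    alpha: float = 0.05,
    mode: str = "pooled",
    adjust: str | None = None,
) -> tuple[list[GeneTestResult], int]:
    """Chi-square homogeneity test for every panel gene.

    ``mode="pooled"`` (default) tests one pooled 2x2 table per gene;
    ``mode="per_site"`` tests the 2xk table of per-site C counts (df = k-1).
    Genes with no retained sites or a zero margin yield a skipped record.
    """
    results = []
    for target in matrix.panel:
        gene = target.gene_symbol
        try:
            table = pool_counts(matrix, labels, gene)
        except ValueError:
            results.append(
                GeneTestResult(gene, 0, 0, 0, 0, None, None, None, skipped="no_retained_sites")
            )
            continue
        if mode == "per_site":
            stat_table = _per_site_table(matrix, labels, gene)
        elif mode == "pooled":
            stat_table = table
        else:
            raise ValueError(f"unknown mode {mode!r}")
        try:
            chi2, df, p = chi_square_homogeneity(stat_table)
        except ValueError:
            results.append(
                GeneTestResult(
                    gene, int(table[0, 0]), int(table[0, 1]), int(table[1, 0]),
                    int(table[1, 1]), None, None, None, skipped="zero_margin",
                )
            )
            continue
        results.append(
            GeneTestResult(
                gene, int(table[0, 0]), int(table[0, 1]), int(table[1, 0]),
                int(table[1, 1]), chi2, df, p,
            )
        )
    return classify_genes(results, alpha=alpha, adjust=adjust)


def _per_site_table(matrix: SiteCountMatrix, labels, gene: str) -> np.ndarray:
    """2xk table of per-retained-site C counts by group (k = retained sites)."""
    lab = _labels_map(labels)
    kept = matrix.retained_mask[matrix.retained_mask].index
    df = matrix.counts[matrix.counts["gene"] == gene].set_index(["gene", "pos"])
    df = df[df.index.isin(kept)].reset_index()
    df = df.assign(group=df["sample_id"].map(lab))
    pivot = df.pivot_table(index="group", columns="pos", values="c_count", aggfunc="sum")
    return pivot.loc[["case", "control"]].to_numpy(dtype=np.int64)


def results_frame(results: Sequence[GeneTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene_symbol for r in results],
            "case_c": [r.case_c for r in results],
            "case_t": [r.case_t for r in results],
            "control_c": [r.control_c for r in results],
            "control_t": [r.control_t for r in results],
            "case_rate": [r.case_rate for r in results],
            "control_rate": [r.control_rate for r in results],
            "chi2": [r.chi2 for r in results],
            "p_value": [r.p_value for r in results],
            "direction": [r.direction for r in results],
            "significant": [r.significant for r in results],
            "skipped": [r.skipped for r in results],
        }
    )
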