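"""Absolute cf-DNA quantification from qPCR Cq values.

A standard curve (ordinary least squares of Cq on log10 copies) converts Cq
triplicates to absolute copy numbers; group summaries compare cases and
controls with per-group mean/median/max/min, differences and ratios of the
group means and medians, and a one-way ANOVA on raw copy numbers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardCurve",
    "QuantResult",
    "CohortComparison",
    "InsufficientStandardsError",
    "fit_standard_curve",
    "quantify_sample",
    "summarize_groups",
    "compare_copy_numbers",
]

#: (serum_ml, eluate_ul, reaction_input_ul): 1 mL serum, 50 uL eluate, 5 uL
#: per reaction, i.e. copies/mL serum = 10x copies/reaction.
DEFAULT_VOLUMES = (1.0, 50.0, 5.0)


class InsufficientStandardsError(ValueError):
    """Fewer than three distinct standard concentrations."""


def _round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class StandardCurve:
    """Fitted Cq = intercept + slope*log10(copies) line.

    ``efficiency`` is the amplification efficiency E = 10^(-1/slope) - 1
    (E = 1 means perfect doubling).  ``positive_slope`` flags a physically
    implausible fit.
    """

    slope: float
    intercept: float
    r_squared: float
    efficiency: float
    positive_slope: bool = False

    def copies_from_cq(self, cq: float | np.ndarray) -> np.ndarray:
        """Invert the line: copies = 10^((Cq - intercept)/slope)."""
        return np.power(10.0, (np.asarray(cq, dtype=float) - self.intercept) / self.slope)


def fit_standard_curve(standards: Sequence[tuple[float, float]] | pd.DataFrame) -> StandardCurve:
    """OLS fit of Cq against log10(copies) over the standard series.

    ``standards`` is an iterable of (copies, cq) pairs or a DataFrame with
    ``copies`` and ``cq`` columns; replicates at a concentration are all used.
    """
    if isinstance(standards, pd.DataFrame):
        copies = standards["copies"].to_numpy(dtype=float)
        cq = standards["cq"].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(standards), dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("standards must be (copies, cq) pairs")
        copies, cq = arr[:, 0], arr[:, 1]
    if (copies <= 0).any():
        raise ValueError("all standard copies must be > 0")
    if np.unique(copies).size < 3:
        raise InsufficientStandardsError(
            "need at least 3 distinct standard concentrations"
        )
    fit = stats.linregress(np.log10(copies), cq)
    slope = float(fit.slope)
    positive = slope >= 0
    if positive:
        warnings.warn("standard curve has non-negative slope", stacklevel=2)
        efficiency = float("nan")
    else:
        efficiency = 10.0 ** (-1.0 / slope) - 1.0
    return StandardCurve(
        slope=slope,
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        efficiency=efficiency,
        positive_slope=positive,
    )


@dataclass(frozen=True)
class QuantResult:
    """Absolute quantification of one sample from its Cq replicates.

    ``copies_per_reaction`` is the mean of the per-replicate back-computed
    copy numbers; ``cv`` their coefficient of variation.  ``high_cv`` is a QC
    flag only, never a rejection.
    """

    sample_id: str
    cq_values: tuple[float, ...]
    copies_per_reaction: float
    copies_per_ml_serum: float
    cv: float
    high_cv: bool = False


def quantify_sample(
    sample_id: str,
    cq_values: Sequence[float],
    curve: StandardCurve,
    volumes: tuple[float, float, float] = DEFAULT_VOLUMES,
    cv_threshold: float = 0.35,
) -> QuantResult:
    """Back-compute copies per replicate, average, and scale to per-mL serum."""
    cq = np.asarray(list(cq_values), dtype=float)
    if cq.size == 0:
        raise ValueError(f"{sample_id}: empty Cq list")
    if not np.isfinite(cq).all():
        raise ValueError(f"{sample_id}: non-finite Cq value")
    if curve.positive_slope or curve.slope >= 0:
        raise ValueError("standard curve slope must be negative")
    per_rep = curve.copies_from_cq(cq)
    mean = float(per_rep.mean())
    cv = float(per_rep.std(ddof=1) / mean) if per_rep.size > 1 and mean > 0 else 0.0
    serum_ml, eluate_ul, input_ul = volumes
    scale = (eluate_ul / input_ul) / serum_ml
    return QuantResult(
        sample_id=sample_id,
        cq_values=tuple(float(x) for x in cq),
        copies_per_reaction=mean,
        copies_per_ml_serum=mean * scale,
        cv=cv,
        high_cv=cv > cv_threshold,
    )


@dataclass(frozen=True)
class CohortComparison:
    """Case/control copy-number summary in the style of a two-group table."""

    case_mean: float
    case_median: float
    case_max: float
    case_min: float
    control_mean: float
    control_median: float
    control_max: float
    control_min: float
    difference_of_means: float
    difference_of_medians: float
    factor_means: float  # ratio of means, reported at 1 decimal (half-up)
    factor_medians: float  # ratio of medians, reported at 1 decimal (half-up)
    anova_f: float | None
    anova_p: float | None
    anova_df: tuple[int, int] | None
    anova_omitted: bool = False
    log_scale: bool = False

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["anova_df"] = list(self.anova_df) if self.anova_df else None
        return d


def compare_copy_numbers(
    copies: Sequence[float],
    labels: Sequence[str],
    log_scale: bool = False,
) -> CohortComparison:
    """Group summary + one-way ANOVA of copy numbers labelled case/control.

    The ANOVA runs on raw copy numbers by default (``log_scale=True`` tests
    log10 copies instead).  Ratios are case/control, rounded half-up to one
    decimal only for the reported factor fields.
    """
    copies = np.asarray(list(copies), dtype=float)
    labels = np.asarray(list(labels))
    case = copies[labels == "case"]
    control = copies[labels == "control"]
    if case.size == 0 or control.size == 0:
        raise ValueError("both groups must be nonempty")

    if case.size < 2 or control.size < 2:
        f = p = df = None
        omitted = True
    else:
        x_case, x_control = (np.log10(case), np.log10(control)) if log_scale else (case, control)
        res = stats.f_oneway(x_case, x_control)
        f, p = float(res.statistic), float(res.pvalue)
        df = (1, case.size + control.size - 2)
        omitted = False

    return CohortComparison(
        case_mean=float(case.mean()),
        case_median=float(np.median(case)),
        case_max=float(case.max()),
        case_min=float(case.min()),
        control_mean=float(control.mean()),
        control_median=float(np.median(control)),
        control_max=float(control.max()),
        control_min=float(control.min()),
        difference_of_means=float(case.mean() - control.mean()),
        difference_of_medians=float(np.median(case) - np.median(control)),
        factor_means=_round_half_up(case.mean() / control.mean()),
        factor_medians=_round_half_up(np.median(case) / np.median(control)),
        anova_f=f,
        anova_p=p,
        anova_df=df,
        anova_omitted=omitted,
        log_scale=log_scale,
    )


def summarize_groups(
    quants: Sequence[QuantResult],
    labels: Sequence[str],
    log_scale: bool = False,
    use_per_ml: bool = False,
) -> CohortComparison:
    """Cohort comparison from quantified samples (per-reaction copies by default)."""
    attr = "copies_per_ml_serum" if use_per_ml else "copies_per_reaction"
    return compare_copy_numbers([getattr(q, attr) for q in quants], labels, log_scale)


# ---------------------------------------------------------------------------
# tabular IO


def quantify_sample_sheet(
    samples: pd.DataFrame,
    curve: StandardCurve,
    volumes: tuple[float, float, float] = DEFAULT_VOLUMES,
) -> list[QuantResult]:
    """Quantify every row of a sample sheet with ``sample_id`` and cq columns."""
    cq_cols = [c for c in samples.columns if c.startswith("cq")]
    if not cq_cols:
        raise ValueError("sample sheet must contain cq columns (cq1, cq2, ...)")
    return [
        quantify_sample(str(row["sample_id"]), [row[c] for c in cq_cols], curve, volumes)
        for _, row in samples.iterrows()
    ]


def quant_results_frame(quants: Sequence[QuantResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [q.sample_id for q in quants],
            "copies_per_reaction": [q.copies_per_reaction for q in quants],
            "copies_per_ml_serum": [q.copies_per_ml_serum for q in quants],
            "cv": [q.cv for q in quants],
            "high_cv": [q.high_cv for q in quants],
        }
    )
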