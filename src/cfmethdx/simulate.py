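"""Synthetic study generator: panel, cohort, bisulfite reads, qPCR measurements.

Everything downstream of the wet lab is exercisable on data produced here with
known ground truth: a nine-gene amplicon panel, a case/control cohort with
log-normal cell-free DNA copy numbers and beta-distributed per-sample gene
methylation levels, paired-end bisulfite amplicon reads with imperfect
conversion and sequencing error, and a qPCR standard series plus per-sample
Cq triplicates.

The defaults emulate the study conditions the pipeline targets: 38 cases and
40 controls, a ~3.9x case/control median copy-number ratio with heavy right
tails, nine amplicons of which four (DIP2C, DNMT1, RRP1, USP1) are
hypomethylated in cases by 15 percentage points, 2x150 paired-end reads, and
a standard series spanning 200,000 down to 2 copies per reaction.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import BASES, BASE_INDEX, C, T, decode, encode, phred33, revcomp
from .panel import DEFAULT_GENES, DEFAULT_HYPO_GENES, AmpliconTarget, find_cpg_sites

__all__ = [
    "CohortSpec",
    "GroupCopyModel",
    "ReadSimParams",
    "QpcrSimParams",
    "default_cohort_spec",
    "generate_panel",
    "simulate_cohort",
    "simulate_bisulfite_reads",
    "simulate_qpcr",
]


# ---------------------------------------------------------------------------
# panel generation


def generate_panel(
    n_genes: int = 9,
    length_range: tuple[int, int] = (170, 270),
    min_cpg: int = 4,
    seed: int = 0,
    gene_symbols: Sequence[str] | None = None,
) -> list[AmpliconTarget]:
    """Generate random amplicon targets with at least ``min_cpg`` CpGs each.

    For ``n_genes`` up to nine the default gene symbols are the diagnostic
    panel genes (CALD1 ... DNMT1); beyond nine, synthetic GENE10... names are
    appended.  The default length range keeps every amplicon reconstructable
    from a 2x150 overlapping read pair.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if min_cpg < 1:
        raise ValueError("min_cpg must be >= 1")
    lo, hi = length_range
    if lo > hi or lo < 80 or hi > 400:
        raise ValueError("length_range must lie within [80, 400]")
    if min_cpg > lo // 3:
        raise ValueError(
            f"cannot place {min_cpg} CpGs in amplicons as short as {lo} nt"
        )
    if gene_symbols is None:
        gene_symbols = list(DEFAULT_GENES[:n_genes]) + [
            f"GENE{i + 1}" for i in range(len(DEFAULT_GENES), n_genes)
        ]
    if len(gene_symbols) != n_genes:
        raise ValueError("gene_symbols length must equal n_genes")

    rng = np.random.default_rng(seed)
    panel = []
    for gene in gene_symbols:
        length = int(rng.integers(lo, hi + 1))
        seq = rng.choice(BASES, size=length)
        # plant CpGs until the rescan finds enough (planting may disturb others)
        for _ in range(100):
            positions = find_cpg_sites(decode(seq))
            if len(positions) >= min_cpg:
                break
            p = int(rng.integers(0, length - 1))
            seq[p], seq[p + 1] = C, ord("G")
        else:  # pragma: no cover - bounded by the min_cpg precondition
            raise RuntimeError(f"failed to place {min_cpg} CpGs in {gene}")
        panel.append(AmpliconTarget(gene, decode(seq), positions))
    return panel


# ---------------------------------------------------------------------------
# cohort truth


@dataclass(frozen=True)
class GroupCopyModel:
    """Log-normal copy-number model for one group (natural-log scale)."""

    log_mean: float
    log_sd: float

    def __post_init__(self) -> None:
        if self.log_sd < 0:
            raise ValueError("log_sd must be >= 0")


@dataclass
class CohortSpec:
    """Ground-truth cohort description: sizes, copy models, methylation levels.

    ``gene_meth_levels`` maps gene symbol to (case_level, control_level) true
    methylation fractions; the same gene list applies to both groups by
    construction.  Per-sample levels are drawn from a beta distribution with
    the group mean and concentration ``meth_concentration`` (larger = less
    between-subject spread).
    """

    n_cases: int = 38
    n_controls: int = 40
    copy_number_model: Mapping[str, GroupCopyModel] = field(
        default_factory=lambda: {
            "case": GroupCopyModel(math.log(8602.0), 1.0),
            "control": GroupCopyModel(math.log(2224.0), 1.0),
        }
    )
    gene_meth_levels: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    meth_concentration: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 2 or self.n_controls < 2:
            raise ValueError("n_cases and n_controls must be >= 2")
        if set(self.copy_number_model) != {"case", "control"}:
            raise ValueError("copy_number_model must have 'case' and 'control' entries")
        for gene, (mc, mn) in self.gene_meth_levels.items():
            if not (0.0 <= mc <= 1.0 and 0.0 <= mn <= 1.0):
                raise ValueError(f"{gene}: methylation fractions must lie in [0, 1]")
        if self.meth_concentration <= 0:
            raise ValueError("meth_concentration must be > 0")

    @property
    def genes(self) -> list[str]:
        return list(self.gene_meth_levels)


def default_cohort_spec(seed: int = 0, hypo_shift: float = 0.15) -> CohortSpec:
    """The default study conditions: 38/40 cohort, 3.9x median copy ratio,
    four genes hypomethylated in cases by ``hypo_shift`` (fraction units)."""
    base = {
        "CALD1": 0.50, "RRP1": 0.55, "FN1": 0.62, "DIP2C": 0.55, "RMI2": 0.45,
        "TDRD5": 0.70, "USP1": 0.55, "HDAC1": 0.35, "DNMT1": 0.55,
    }
    levels = {
        g: ((m - hypo_shift, m) if g in DEFAULT_HYPO_GENES else (m, m))
        for g, m in base.items()
    }
    return CohortSpec(gene_meth_levels=levels, seed=seed)


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw the per-sample ground truth table.

    Returns one row per sample with columns ``sample_id``, ``group``,
    ``true_copies`` and ``meth_<gene>`` (true methylation fraction).
    """
    if not spec.gene_meth_levels:
        raise ValueError("spec.gene_meth_levels must name at least one gene")
    rng = np.random.default_rng(spec.seed)
    rows = []
    for group, n, prefix in (
        ("case", spec.n_cases, "EM"),
        ("control", spec.n_controls, "CT"),
    ):
        model = spec.copy_number_model[group]
        copies = rng.lognormal(mean=model.log_mean, sigma=model.log_sd, size=n)
        meth = {}
        for gene, (m_case, m_control) in spec.gene_meth_levels.items():
            m = m_case if group == "case" else m_control
            if m in (0.0, 1.0):
                meth[gene] = np.full(n, m)
            else:
                a = m * spec.meth_concentration
                b = (1.0 - m) * spec.meth_concentration
                meth[gene] = np.clip(rng.beta(a, b, size=n), 0.0, 1.0)
        for i in range(n):
            row = {
                "sample_id": f"{prefix}{i + 1:03d}",
                "group": group,
                "true_copies": float(copies[i]),
            }
            row.update({f"meth_{g}": float(meth[g][i]) for g in spec.gene_meth_levels})
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bisulfite read simulation


@dataclass
class ReadSimParams:
    """Bisulfite amplicon read model.

    ``conversion_efficiency`` is the probability an unmethylated C reads as T;
    ``methylated_protection`` the probability a methylated C stays C.  Errors
    are uniform substitutions.  Qualities are constant ``base_quality`` with an
    optional low-quality 3' tail of ``tail_length`` bases at ``tail_quality``.
    """

    read_length: int = 150
    reads_per_amplicon: int = 1000
    conversion_efficiency: float = 0.99
    methylated_protection: float = 0.995
    error_rate: float = 0.001
    base_quality: int = 30
    tail_length: int = 0
    tail_quality: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("conversion_efficiency", "methylated_protection", "error_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.read_length < 30:
            raise ValueError("read_length must be >= 30")
        if self.reads_per_amplicon < 1:
            raise ValueError("reads_per_amplicon must be >= 1")


def _molecule_matrix(
    target: AmpliconTarget,
    meth_level: float,
    n_reads: int,
    params: ReadSimParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate bisulfite-converted top-strand molecules as an (n, L) byte matrix."""
    tmpl = encode(target.sequence)
    mat = np.tile(tmpl, (n_reads, 1))
    cpg = np.array(target.cpg_positions, dtype=np.intp)

    methylated = rng.random((n_reads, cpg.size)) < meth_level
    stays_c = np.where(
        methylated,
        rng.random((n_reads, cpg.size)) < params.methylated_protection,
        rng.random((n_reads, cpg.size)) >= params.conversion_efficiency,
    )
    mat[:, cpg] = np.where(stays_c, C, T)

    non_cpg_c = np.setdiff1d(np.flatnonzero(tmpl == C), cpg)
    if non_cpg_c.size:
        converted = rng.random((n_reads, non_cpg_c.size)) < params.conversion_efficiency
        mat[:, non_cpg_c] = np.where(converted, T, C)

    if params.error_rate > 0:
        err = rng.random(mat.shape) < params.error_rate
        n_err = int(err.sum())
        if n_err:
            shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
            mat[err] = BASES[(BASE_INDEX[mat[err]] + shift) % 4]
    return mat


def _quality_string(length: int, params: ReadSimParams) -> str:
    q = np.full(length, params.base_quality, dtype=np.uint8)
    if params.tail_length > 0:
        q[max(0, length - params.tail_length):] = params.tail_quality
    return phred33(q)


def simulate_bisulfite_reads(
    panel: Sequence[AmpliconTarget],
    cohort_truth: pd.DataFrame,
    params: ReadSimParams,
    out_dir: str | Path,
) -> dict[str, tuple[Path, Path]]:
    """Write per-sample paired FASTQ (gzip, Phred+33) for every panel amplicon.

    R1 is the 5' read of the converted top strand, R2 the reverse complement
    of its 3' end; pairs overlap whenever the amplicon is shorter than twice
    the read length.  Read names encode ``sample:gene:index`` so simulator
    truth can serve as an assignment oracle.  Returns
    ``{sample_id: (r1_path, r2_path)}``.
    """
    if not panel:
        raise ValueError("panel must be non-empty")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, tuple[Path, Path]] = {}
    for s_idx, row in enumerate(cohort_truth.itertuples(index=False)):
        sample = row.sample_id
        rng = np.random.default_rng([params.seed, s_idx])
        p1 = out_dir / f"{sample}_R1.fastq.gz"
        p2 = out_dir / f"{sample}_R2.fastq.gz"
        with open(p1, "wb") as f1, open(p2, "wb") as f2, \
                gzip.GzipFile(fileobj=f1, mode="wb", mtime=0) as gz1, \
                gzip.GzipFile(fileobj=f2, mode="wb", mtime=0) as gz2:
            for target in panel:
                level = float(getattr(row, f"meth_{target.gene_symbol}"))
                mat = _molecule_matrix(
                    target, level, params.reads_per_amplicon, params, rng
                )
                L = mat.shape[1]
                rlen = min(params.read_length, L)
                r1 = mat[:, :rlen]
                r2 = revcomp(mat)[:, :rlen]
                qual = _quality_string(rlen, params)
                chunks1, chunks2 = [], []
                for i in range(mat.shape[0]):
                    name = f"{sample}:{target.gene_symbol}:{i}"
                    chunks1.append(f"@{name}/1\n{decode(r1[i])}\n+\n{qual}\n")
                    chunks2.append(f"@{name}/2\n{decode(r2[i])}\n+\n{qual}\n")
                gz1.write("".join(chunks1).encode("ascii"))
                gz2.write("".join(chunks2).encode("ascii"))
        paths[sample] = (p1, p2)
    return paths


# ---------------------------------------------------------------------------
# qPCR simulation


@dataclass
class QpcrSimParams:
    """Cq measurement model: Cq = intercept + slope*log10(copies) + noise.

    The default slope -3.3219 (= -1/log10(2)) is perfect doubling; the
    default standard series is a ten-fold dilution of a 200,000 copies/uL
    calibrator down to 2 copies (five decades).
    """

    true_slope: float = -3.3219
    true_intercept: float = 38.0
    cq_noise_sd: float = 0.15
    standard_copies: tuple[float, ...] = (2e5, 2e4, 2e3, 2e2, 2e1, 2e0)
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_slope >= 0:
            raise ValueError("true_slope must be negative")
        if self.cq_noise_sd < 0:
            raise ValueError("cq_noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        copies = np.asarray(self.standard_copies, dtype=float)
        if (copies <= 0).any():
            raise ValueError("standard copies must be > 0")
        span = np.log10(copies.max()) - np.log10(copies.min())
        if span < 3.0:
            raise ValueError("standard series must span >= 3 log10 decades")


def _cq(copies: np.ndarray, params: QpcrSimParams, rng: np.random.Generator) -> np.ndarray:
    mu = params.true_intercept + params.true_slope * np.log10(copies)
    if params.cq_noise_sd == 0:
        return mu
    return mu + rng.normal(0.0, params.cq_noise_sd, size=np.shape(mu))


def simulate_qpcr(
    cohort_truth: pd.DataFrame, params: QpcrSimParams
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the standard series and per-sample Cq triplicates.

    Returns ``(standards, samples)``: standards with columns
    ``copies, replicate, cq``; samples with ``sample_id, group,
    cq1..cq<n_replicates>``.
    """
    copies = cohort_truth["true_copies"].to_numpy(dtype=float)
    if (copies <= 0).any():
        raise ValueError("true_copies must be > 0 for all samples")
    rng = np.random.default_rng(params.seed)

    std_rows = []
    for q in params.standard_copies:
        cqs = _cq(np.full(params.n_replicates, float(q)), params, rng)
        std_rows.extend(
            {"copies": float(q), "replicate": r + 1, "cq": float(c)}
            for r, c in enumerate(cqs)
        )
    standards = pd.DataFrame(std_rows)

    reps = _cq(
        np.repeat(copies, params.n_replicates).reshape(-1, params.n_replicates),
        params,
        rng,
    )
    samples = pd.DataFrame(
        {
            "sample_id": cohort_truth["sample_id"].to_numpy(),
            "group": cohort_truth["group"].to_numpy(),
        }
    )
    for r in range(params.n_replicates):
        samples[f"cq{r + 1}"] = reps[:, r]
    return standards, samples
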