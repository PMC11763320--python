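"""Paired bisulfite amplicon reads -> filtered per-CpG counts -> gene methylation.

Stages, all ungapped (amplicons are short, primer-anchored, substitution-
dominated):

1. overlap merging of read pairs, disagreements resolved to the higher-Phred
   base (tie -> R1);
2. assignment of merged reads to panel amplicons against bisulfite-expected
   references (non-CpG C expects T, CpG C accepts C or T), both orientations;
3. per-CpG C/T/other counting, with bisulfite conversion efficiency estimated
   from non-CpG cytosines as QC;
4. site filtering (minimum per-sample coverage; constant pooled methylation),
   library-size normalization by the average total read count, and
   coverage-weighted gene-level methylation percentages.

Per-site methylation rate is C/(C+T) at the targeted position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from ._seq import C, T, Y, decode, encode, qual_from_string, revcomp
from .panel import AmpliconTarget, panel_genes

__all__ = [
    "MergedRead",
    "MergeResult",
    "AssignmentResult",
    "SiteCountMatrix",
    "merge_read_pair",
    "bisulfite_reference",
    "assign_to_amplicon",
    "count_cpg_sites",
    "build_site_matrix",
    "filter_sites",
    "normalize_libraries",
    "gene_methylation_percentages",
    "call_sample",
    "call_cohort",
]


# ---------------------------------------------------------------------------
# read pair merging


@dataclass
class MergedRead:
    sequence: str
    qualities: np.ndarray  # Phred scores, same length as sequence
    source_pair_id: str = ""

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=np.int16)
        if len(self.sequence) != self.qualities.size:
            raise ValueError("sequence and qualities must have equal length")


@dataclass
class MergeResult:
    """Outcome of one merge attempt: ``merged`` or a rejection ``reason``."""

    merged: MergedRead | None
    reason: str | None = None  # "too_short" | "no_overlap"
    offset: int | None = None
    n_mismatches: int | None = None


def _merge_offsets(len1: int, len2: int, min_overlap: int) -> list[tuple[int, int, int]]:
    """Candidate (d, start, end) offsets of r2rc within r1 coordinates,
    sorted by preference: larger overlap first, then smaller |d|, then d."""
    cands = []
    for d in range(-(len2 - min_overlap), len1 - min_overlap + 1):
        s, e = max(0, d), min(len1, d + len2)
        if e - s >= min_overlap:
            cands.append((d, s, e))
    cands.sort(key=lambda c: (-(c[2] - c[1]), abs(c[0]), c[0]))
    return cands


def _build_merged(
    a: np.ndarray, q1: np.ndarray, b: np.ndarray, q2: np.ndarray, d: int
) -> tuple[np.ndarray, np.ndarray]:
    """Consensus of r1 (a) and reverse-complemented r2 (b) at offset ``d``.

    Works on 2-D batches (reads x bases) with a shared offset.
    """
    len1, len2 = a.shape[1], b.shape[1]
    s, e = max(0, d), min(len1, d + len2)
    span_start, span_end = min(0, d), max(len1, d + len2)
    L = span_end - span_start
    n = a.shape[0]
    seq = np.zeros((n, L), dtype=np.uint8)
    qual = np.zeros((n, L), dtype=np.int16)
    b0 = d - span_start  # column of b[0] in merged coordinates
    a0 = -span_start
    seq[:, b0:b0 + len2] = b
    qual[:, b0:b0 + len2] = q2
    seq[:, a0:a0 + len1] = a
    qual[:, a0:a0 + len1] = q1
    if e > s:
        a_ov, q1_ov = a[:, s:e], q1[:, s:e]
        b_ov, q2_ov = b[:, s - d:e - d], q2[:, s - d:e - d]
        take_b = q2_ov > q1_ov  # tie -> r1 base
        sl = slice(a0 + s, a0 + e)
        seq[:, sl] = np.where(take_b, b_ov, a_ov)
        qual[:, sl] = np.maximum(q1_ov, q2_ov)
    return seq, qual


def _as_qual(qual, length: int) -> np.ndarray:
    if qual is None:
        return np.full(length, 30, dtype=np.int16)
    if isinstance(qual, str):
        return qual_from_string(qual)
    return np.asarray(qual, dtype=np.int16)


def merge_read_pair(
    r1_seq: str,
    r2_seq: str,
    r1_qual=None,
    r2_qual=None,
    *,
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.1,
    pair_id: str = "",
) -> MergeResult:
    """Merge a read pair by its best ungapped overlap.

    ``r2_seq`` is supplied in sequencing orientation and reverse-complemented
    internally.  The best overlap is the candidate with the lowest mismatch
    fraction (ties: larger overlap, then smaller shift); candidates above
    ``max_mismatch_frac`` or shorter than ``min_overlap`` are rejected.
    """
    len1, len2 = len(r1_seq), len(r2_seq)
    if min(len1, len2) < min_overlap:
        return MergeResult(None, "too_short")
    a = encode(r1_seq)
    q1 = _as_qual(r1_qual, len1)
    b = revcomp(encode(r2_seq))
    q2 = _as_qual(r2_qual, len2)[::-1]

    best = None  # (frac, d, mism)
    for d, s, e in _merge_offsets(len1, len2, min_overlap):
        mism = int(np.count_nonzero(a[s:e] != b[s - d:e - d]))
        frac = mism / (e - s)
        if frac <= max_mismatch_frac and (best is None or frac < best[0]):
            best = (frac, d, mism)
    if best is None:
        return MergeResult(None, "no_overlap")
    _, d, mism = best
    seq, qual = _build_merged(a[None, :], q1[None, :], b[None, :], q2[None, :], d)
    merged = MergedRead(decode(seq[0]), qual[0], pair_id)
    return MergeResult(merged, None, offset=d, n_mismatches=mism)


def _merge_batch(
    r1_mat: np.ndarray,
    q1_mat: np.ndarray,
    r2_mat: np.ndarray,
    q2_mat: np.ndarray,
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.1,
):
    """Batched merge of equal-length read pairs.

    Returns (groups, rejected) where groups is a list of
    ``(offset, indices, seq_matrix, qual_matrix)`` and rejected an index
    array of pairs with no acceptable overlap.
    """
    n, len1 = r1_mat.shape
    len2 = r2_mat.shape[1]
    b_mat = revcomp(r2_mat)
    q2_rev = q2_mat[:, ::-1]
    if min(len1, len2) < min_overlap:
        return [], np.arange(n)
    cands = _merge_offsets(len1, len2, min_overlap)
    fracs = np.empty((len(cands), n))
    for i, (d, s, e) in enumerate(cands):
        mism = np.count_nonzero(r1_mat[:, s:e] != b_mat[:, s - d:e - d], axis=1)
        fracs[i] = mism / (e - s)
    fracs_ok = np.where(fracs <= max_mismatch_frac, fracs, np.inf)
    best_idx = np.argmin(fracs_ok, axis=0)  # first minimum = preferred candidate
    best_frac = fracs_ok[best_idx, np.arange(n)]
    rejected = np.flatnonzero(~np.isfinite(best_frac))
    groups = []
    for ci in np.unique(best_idx[np.isfinite(best_frac)]):
        idx = np.flatnonzero((best_idx == ci) & np.isfinite(best_frac))
        d = cands[ci][0]
        seq, qual = _build_merged(r1_mat[idx], q1_mat[idx], b_mat[idx], q2_rev[idx], d)
        groups.append((d, idx, seq, qual))
    return groups, rejected


# ---------------------------------------------------------------------------
# amplicon assignment


def bisulfite_reference(target: AmpliconTarget) -> np.ndarray:
    """Bisulfite-expected top-strand pattern: non-CpG C -> T, CpG C -> Y
    (matches C or T), all other bases exact."""
    ref = encode(target.sequence)
    ref[ref == C] = T
    ref[np.asarray(target.cpg_positions, dtype=np.intp)] = Y
    return ref


def _pattern_mismatch(ref_slice: np.ndarray, read_slice: np.ndarray) -> np.ndarray:
    """Per-read mismatch counts of read rows against a reference pattern."""
    match = (read_slice == ref_slice) | (
        (ref_slice == Y) & ((read_slice == C) | (read_slice == T))
    )
    return np.count_nonzero(~match, axis=-1)


@dataclass
class AssignmentResult:
    gene_symbol: str | None
    reason: str | None = None  # "too_short" | "no_match" | "ambiguous"
    offset: int | None = None
    reverse: bool = False
    score: float | None = None


def _assign_offsets(
    read_len: int, ref_len: int, min_len: int, max_shift: int | None
) -> list[tuple[int, int, int]]:
    lo, hi = -(read_len - min_len), ref_len - min_len
    if max_shift is not None:
        lo, hi = max(lo, -max_shift), min(hi, (ref_len - read_len) + max_shift)
    cands = []
    for d in range(lo, hi + 1):
        s, e = max(0, d), min(ref_len, d + read_len)
        if e - s >= min_len:
            cands.append((d, s, e))
    cands.sort(key=lambda c: (-(c[2] - c[1]), abs(c[0]), c[0]))
    return cands


def _assign_batch(
    mat: np.ndarray,
    panel: Sequence[AmpliconTarget],
    refs: Sequence[np.ndarray],
    max_mismatch_frac: float = 0.1,
    min_assign_len: int = 40,
    max_shift: int | None = None,
):
    """Assign a batch of equal-length reads to panel amplicons.

    Returns arrays (gene_idx, offset, reverse, score); gene_idx -1 encodes
    unassigned (no qualifying gene) and -2 an ambiguous tie between genes.
    """
    n, L = mat.shape
    n_genes = len(panel)
    rc = revcomp(mat)
    best_frac = np.full((n_genes, n), np.inf)
    best_d = np.zeros((n_genes, n), dtype=np.int32)
    best_rev = np.zeros((n_genes, n), dtype=bool)
    for g, ref in enumerate(refs):
        cands = _assign_offsets(L, ref.shape[0], min_assign_len, max_shift)
        if not cands:
            continue
        for reverse, m in ((False, mat), (True, rc)):
            for d, s, e in cands:
                frac = _pattern_mismatch(ref[s:e], m[:, s - d:e - d]) / (e - s)
                better = frac < best_frac[g]
                best_d[g][better] = d
                best_rev[g][better] = reverse
                best_frac[g][better] = frac[better]
    order = np.argsort(best_frac, axis=0, kind="stable")
    top = order[0]
    ar = np.arange(n)
    top_frac = best_frac[top, ar]
    gene_idx = np.where(top_frac <= max_mismatch_frac, top, -1).astype(np.int64)
    if n_genes > 1:
        second_frac = best_frac[order[1], ar]
        gene_idx[(gene_idx >= 0) & (second_frac == top_frac)] = -2
    return gene_idx, best_d[top, ar], best_rev[top, ar], top_frac


def assign_to_amplicon(
    read: MergedRead | str,
    panel: Sequence[AmpliconTarget],
    max_mismatch_frac: float = 0.1,
    min_assign_len: int = 40,
    max_shift: int | None = None,
) -> AssignmentResult:
    """Assign one merged read to the unique best-matching panel amplicon.

    Both orientations are scored against each bisulfite-expected reference at
    every ungapped offset (restrictable to ``max_shift`` around the anchored
    position); the read is assigned to the unique gene with minimal mismatch
    fraction at most ``max_mismatch_frac``, else unassigned.
    """
    if not panel:
        raise ValueError("panel must be non-empty")
    seq = read.sequence if isinstance(read, MergedRead) else read
    if len(seq) < min_assign_len:
        return AssignmentResult(None, "too_short")
    refs = [bisulfite_reference(t) for t in panel]
    gene_idx, d, rev, frac = _assign_batch(
        encode(seq)[None, :], panel, refs, max_mismatch_frac, min_assign_len, max_shift
    )
    gi = int(gene_idx[0])
    if gi == -1:
        return AssignmentResult(None, "no_match", score=float(frac[0]))
    if gi == -2:
        return AssignmentResult(None, "ambiguous", score=float(frac[0]))
    return AssignmentResult(
        panel[gi].gene_symbol,
        offset=int(d[0]),
        reverse=bool(rev[0]),
        score=float(frac[0]),
    )


# ---------------------------------------------------------------------------
# CpG counting


def _non_cpg_c_positions(target: AmpliconTarget) -> np.ndarray:
    tmpl = encode(target.sequence)
    return np.setdiff1d(
        np.flatnonzero(tmpl == C), np.asarray(target.cpg_positions, dtype=np.intp)
    )


class _CountAccumulator:
    """Per-sample accumulation of CpG C/T/other counts and conversion QC."""

    def __init__(self, panel: Sequence[AmpliconTarget]):
        self.panel = list(panel)
        self.c = {t.gene_symbol: np.zeros(t.n_cpg, dtype=np.int64) for t in panel}
        self.t = {t.gene_symbol: np.zeros(t.n_cpg, dtype=np.int64) for t in panel}
        self.other = {t.gene_symbol: np.zeros(t.n_cpg, dtype=np.int64) for t in panel}
        self.conv_c = 0  # unconverted calls at non-CpG C positions
        self.conv_t = 0

    def add(self, target: AmpliconTarget, mat: np.ndarray, d: int) -> None:
        """Tally an (n, L) matrix of reads oriented to ref coords at offset d."""
        L = mat.shape[1]
        g = target.gene_symbol
        for si, p in enumerate(target.cpg_positions):
            j = p - d
            if 0 <= j < L:
                col = mat[:, j]
                nc = int(np.count_nonzero(col == C))
                nt = int(np.count_nonzero(col == T))
                self.c[g][si] += nc
                self.t[g][si] += nt
                self.other[g][si] += col.size - nc - nt
        for p in _non_cpg_c_positions(target):
            j = p - d
            if 0 <= j < L:
                col = mat[:, j]
                self.conv_c += int(np.count_nonzero(col == C))
                self.conv_t += int(np.count_nonzero(col == T))

    def frame(self, sample_id: str) -> pd.DataFrame:
        rows = []
        for t in self.panel:
            g = t.gene_symbol
            for si, p in enumerate(t.cpg_positions):
                rows.append(
                    (sample_id, g, int(p),
                     int(self.c[g][si]), int(self.t[g][si]), int(self.other[g][si]))
                )
        return pd.DataFrame(
            rows,
            columns=["sample_id", "gene", "pos", "c_count", "t_count", "other_count"],
        )

    @property
    def conversion_estimate(self) -> float:
        tot = self.conv_c + self.conv_t
        return self.conv_t / tot if tot else float("nan")


def count_cpg_sites(
    assigned: Iterable[tuple[str, str, int]],
    panel: Sequence[AmpliconTarget],
    sample_id: str = "S",
) -> pd.DataFrame:
    """Count C/T/other at every panel CpG from ``(sequence, gene, offset)``
    triples of reads already oriented to reference coordinates.

    Returns a long table with one row per panel CpG site (uncovered sites
    have zero coverage); per-site methylation rate is c/(c+t).
    """
    by_gene = {t.gene_symbol: t for t in panel}
    acc = _CountAccumulator(panel)
    for seq, gene, d in assigned:
        acc.add(by_gene[gene], encode(seq)[None, :], d)
    df = acc.frame(sample_id)
    cov = df["c_count"] + df["t_count"]
    df["rate"] = np.where(cov > 0, df["c_count"] / cov.replace(0, 1), np.nan)
    return df


# ---------------------------------------------------------------------------
# site matrix, filters, normalization, gene-level percentages


@dataclass
class SiteCountMatrix:
    """Per sample x CpG site raw counts plus filter mask and normalization.

    ``counts`` is long-form over the full sample x panel-site grid (uncovered
    sites carry zero counts).  ``retained_mask`` is indexed by (gene, pos);
    ``norm_factors`` by sample (NaN for excluded zero-count samples).  Raw
    integer counts are never altered; normalized counts are derived views.
    """

    counts: pd.DataFrame
    panel: list[AmpliconTarget]
    samples: list[str]
    sample_totals: pd.Series
    retained_mask: pd.Series | None = None
    norm_factors: pd.Series | None = None
    excluded_samples: list[str] = field(default_factory=list)
    flagged_genes: list[str] = field(default_factory=list)

    def coverage_pivot(self) -> pd.DataFrame:
        """(gene, pos) x sample coverage (c+t)."""
        df = self.counts.assign(cov=self.counts.c_count + self.counts.t_count)
        return df.pivot_table(
            index=["gene", "pos"], columns="sample_id", values="cov", fill_value=0
        )[self.samples]

    def normalized_counts(self) -> pd.DataFrame:
        """Raw counts scaled by per-sample normalization factors (fractional)."""
        if self.norm_factors is None:
            raise RuntimeError("call normalize_libraries first")
        df = self.counts.copy()
        f = df["sample_id"].map(self.norm_factors)
        for col in ("c_count", "t_count", "other_count"):
            df[col] = df[col] * f
        return df


def build_site_matrix(
    counts: pd.DataFrame | Iterable[pd.DataFrame],
    panel: Sequence[AmpliconTarget],
    sample_totals: pd.Series | dict | None = None,
) -> SiteCountMatrix:
    """Assemble per-sample count tables into a full-grid SiteCountMatrix."""
    if not isinstance(counts, pd.DataFrame):
        counts = pd.concat(list(counts), ignore_index=True)
    samples = list(pd.unique(counts["sample_id"]))
    grid = pd.MultiIndex.from_tuples(
        [(s, t.gene_symbol, p) for s in samples for t in panel for p in t.cpg_positions],
        names=["sample_id", "gene", "pos"],
    )
    full = (
        counts.set_index(["sample_id", "gene", "pos"])[
            ["c_count", "t_count", "other_count"]
        ]
        .reindex(grid, fill_value=0)
        .reset_index()
    )
    if sample_totals is None:
        tot = full.groupby("sample_id", sort=False)[
            ["c_count", "t_count", "other_count"]
        ].sum()
        sample_totals = tot.sum(axis=1)
    sample_totals = pd.Series(sample_totals, dtype=float)[samples]
    return SiteCountMatrix(full, list(panel), samples, sample_totals)


def filter_sites(matrix: SiteCountMatrix, min_coverage: int = 8) -> pd.Series:
    """Site retention mask: drop a site if any sample has coverage below
    ``min_coverage`` or if its pooled methylation rate is exactly 0 or 1.

    The mask is stored on the matrix; counts are never deleted.
    """
    cov = matrix.coverage_pivot()
    min_ok = cov.min(axis=1) >= min_coverage
    pooled = matrix.counts.groupby(["gene", "pos"], sort=False)[
        ["c_count", "t_count"]
    ].sum()
    pooled = pooled.reindex(cov.index)
    non_constant = (pooled["c_count"] > 0) & (pooled["t_count"] > 0)
    mask = (min_ok & non_constant).rename("retained")
    matrix.retained_mask = mask
    return mask


def normalize_libraries(
    matrix: SiteCountMatrix, sample_totals: pd.Series | None = None
) -> pd.Series:
    """Per-sample factors factor_i = mean_j(total_j) / total_i from total
    assigned read counts; zero-count samples are excluded with a QC flag
    (factor NaN) and do not enter the mean."""
    totals = matrix.sample_totals if sample_totals is None else pd.Series(sample_totals, dtype=float)
    totals = totals[matrix.samples]
    positive = totals[totals > 0]
    excluded = [s for s in matrix.samples if s not in positive.index]
    if positive.empty:
        raise ValueError("no sample has a positive total read count")
    factors = positive.mean() / totals
    factors[totals <= 0] = np.nan
    factors = factors.rename("norm_factor")
    matrix.norm_factors = factors
    matrix.excluded_samples = excluded
    return factors


def gene_methylation_percentages(
    matrix: SiteCountMatrix, method: str = "pooled"
) -> pd.DataFrame:
    """Per sample x gene methylation percent over retained sites.

    ``pooled`` (default) is coverage-weighted: 100 * sum(c) / sum(c+t);
    ``mean`` averages per-site rates unweighted.  Genes with no retained
    sites yield NaN and are flagged on the matrix.
    """
    if matrix.retained_mask is None:
        raise RuntimeError("call filter_sites before gene_methylation_percentages")
    genes = panel_genes(matrix.panel)
    kept = matrix.retained_mask[matrix.retained_mask].index
    df = matrix.counts.set_index(["gene", "pos"])
    df = df[df.index.isin(kept)].reset_index()
    out = pd.DataFrame(index=pd.Index(matrix.samples, name="sample_id"), columns=genes, dtype=float)
    if not df.empty:
        if method == "pooled":
            g = df.groupby(["sample_id", "gene"], sort=False)[["c_count", "t_count"]].sum()
            pct = 100.0 * g["c_count"] / (g["c_count"] + g["t_count"])
        elif method == "mean":
            cov = df["c_count"] + df["t_count"]
            df = df.assign(rate=np.where(cov > 0, df["c_count"] / cov.replace(0, 1), np.nan))
            pct = 100.0 * df.groupby(["sample_id", "gene"], sort=False)["rate"].mean()
        else:
            raise ValueError(f"unknown method {method!r}")
        wide = pct.unstack("gene")
        out.loc[wide.index, wide.columns] = wide
    matrix.flagged_genes = [g for g in genes if out[g].isna().all()]
    return out


# ---------------------------------------------------------------------------
# per-sample and cohort pipelines


def _read_fastq_pairs(r1_path, r2_path):
    """Yield (name, seq1, qual1, seq2, qual2) from a FASTQ pair."""
    with pysam.FastxFile(str(r1_path)) as f1, pysam.FastxFile(str(r2_path)) as f2:
        for e1, e2 in zip(f1, f2):
            yield e1.name, e1.sequence, e1.quality, e2.sequence, e2.quality


def call_sample(
    r1_path,
    r2_path,
    panel: Sequence[AmpliconTarget],
    sample_id: str | None = None,
    *,
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.1,
    min_assign_len: int = 40,
    max_shift: int | None = 4,
) -> tuple[pd.DataFrame, dict]:
    """Merge, assign and count one sample's FASTQ pair.

    Returns the per-site count table and a QC dict (pair/merge/assignment
    counts and rates, estimated bisulfite conversion rate, and — when read
    names carry ``sample:gene:index`` simulator truth — assignment accuracy).
    """
    if sample_id is None:
        sample_id = Path(str(r1_path)).name.split("_R1")[0]
    refs = [bisulfite_reference(t) for t in panel]
    by_gene = {t.gene_symbol: t for t in panel}

    batches: dict[tuple[int, int], list] = {}
    n_pairs = 0
    for name, s1, q1, s2, q2 in _read_fastq_pairs(r1_path, r2_path):
        n_pairs += 1
        batches.setdefault((len(s1), len(s2)), []).append((name, s1, q1, s2, q2))

    acc = _CountAccumulator(panel)
    n_merged = n_assigned = n_truth = n_truth_correct = 0
    for (l1, l2), items in batches.items():
        names = [it[0] for it in items]
        r1 = np.frombuffer("".join(it[1] for it in items).encode(), np.uint8).reshape(-1, l1)
        r2 = np.frombuffer("".join(it[3] for it in items).encode(), np.uint8).reshape(-1, l2)
        q1 = np.frombuffer("".join(it[2] for it in items).encode(), np.uint8).reshape(-1, l1).astype(np.int16) - 33
        q2 = np.frombuffer("".join(it[4] for it in items).encode(), np.uint8).reshape(-1, l2).astype(np.int16) - 33
        groups, _rej = _merge_batch(r1, q1, r2, q2, min_overlap, max_mismatch_frac)
        for _d, idx, seq_mat, _qual in groups:
            n_merged += idx.size
            gene_idx, offs, revs, _frac = _assign_batch(
                seq_mat, panel, refs, max_mismatch_frac, min_assign_len, max_shift
            )
            ok = gene_idx >= 0
            n_assigned += int(ok.sum())
            # simulator truth (read name "sample:gene:i") as assignment oracle
            for row in np.flatnonzero(ok):
                parts = names[idx[row]].split(":")
                if len(parts) == 3 and parts[1] in by_gene:
                    n_truth += 1
                    if parts[1] == panel[gene_idx[row]].gene_symbol:
                        n_truth_correct += 1
            for g in np.unique(gene_idx[ok]):
                sel = ok & (gene_idx == g)
                for rev in (False, True):
                    sel_o = sel & (revs == rev)
                    if not sel_o.any():
                        continue
                    m = seq_mat[sel_o]
                    if rev:
                        m = revcomp(m)
                    for d in np.unique(offs[sel_o]):
                        acc.add(panel[g], m[offs[sel_o] == d], int(d))

    counts = acc.frame(sample_id)
    qc = {
        "sample_id": sample_id,
        "n_pairs": n_pairs,
        "n_merged": n_merged,
        "n_assigned": n_assigned,
        "merge_rate": n_merged / n_pairs if n_pairs else float("nan"),
        "assignment_rate": n_assigned / n_pairs if n_pairs else float("nan"),
        "conversion_rate_estimate": acc.conversion_estimate,
        "assignment_accuracy_vs_truth": (
            n_truth_correct / n_truth if n_truth else float("nan")
        ),
    }
    return counts, qc


def call_cohort(
    fastq_pairs: dict[str, tuple],
    panel: Sequence[AmpliconTarget],
    min_coverage: int = 8,
    **call_opts,
) -> tuple[SiteCountMatrix, pd.DataFrame, list[dict]]:
    """Run :func:`call_sample` over a cohort and build the filtered,
    normalized matrix plus gene-level methylation percentages."""
    frames, qcs, totals = [], [], {}
    for sample, (p1, p2) in fastq_pairs.items():
        counts, qc = call_sample(p1, p2, panel, sample, **call_opts)
        frames.append(counts)
        qcs.append(qc)
        totals[sample] = qc["n_assigned"]
    matrix = build_site_matrix(frames, panel, pd.Series(totals, dtype=float))
    mask = filter_sites(matrix, min_coverage=min_coverage)
    if not mask.any():
        raise ValueError("all CpG sites were filtered out")
    normalize_libraries(matrix)
    percentages = gene_methylation_percentages(matrix)
    return matrix, percentages, qcs
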