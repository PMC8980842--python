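"""Normalization, expression thresholds, subsampling and differential expression.

Array-style matrices are quantile normalized and log2 transformed; miRNA
counts are converted to counts per million (cpm) and a miRNA is called
expressed when it reaches 2 cpm in at least half the samples of one group.
The group-comparison screen is Welch's t-test on log2 values with
Benjamini-Hochberg control of the false discovery rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix, ExpressionMatrix, NormalizedMatrix, SampleAnnotation

__all__ = [
    "quantile_log_normalize",
    "cpm_normalize",
    "filter_expressed",
    "subsample_library",
    "threshold_stability",
    "differential_expression",
    "bh_fdr",
    "ThresholdStabilityReport",
    "PreprocessError",
]

LOG_OFFSET = 0.5  # pseudo-cpm added before log2


class PreprocessError(ValueError):
    pass


def quantile_log_normalize(matrix: ExpressionMatrix) -> NormalizedMatrix:
    """Quantile-normalize sample columns to a common distribution, then log2.

    The target distribution is the vector of row means of the column-sorted
    matrix; tied values within a column receive the mean of their quantile
    values.  Requires strictly positive intensities.
    """
    X = matrix.data.to_numpy(dtype=float)
    if (X <= 0).any():
        raise PreprocessError("quantile_log_normalize requires strictly positive intensities")
    target = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(target)
        assigned[order] = target
        # ties share the mean of their quantile values
        s = pd.Series(assigned).groupby(pd.Series(col), sort=False).transform("mean")
        out[:, j] = s.to_numpy()
    normed = pd.DataFrame(np.log2(out), index=matrix.data.index, columns=matrix.data.columns)
    return NormalizedMatrix(normed, kind=matrix.kind, norm="quantile-log2")


def cpm_normalize(
    counts: CountMatrix, log: bool = False, offset: float = LOG_OFFSET
) -> NormalizedMatrix:
    """Counts per million; optionally log2(cpm + offset)."""
    lib = counts.library_sizes
    zero = lib.index[lib == 0].tolist()
    if zero:
        raise PreprocessError(f"zero library size for samples: {zero}")
    cpm = counts.data / lib.to_numpy() * 1e6
    if log:
        return NormalizedMatrix(np.log2(cpm + offset), kind=counts.kind, norm="log2cpm")
    return NormalizedMatrix(cpm, kind=counts.kind, norm="cpm")


def filter_expressed(
    cpm: NormalizedMatrix,
    annotation: SampleAnnotation,
    cutoff: float = 2.0,
    min_fraction: float = 0.5,
) -> list[str]:
    """Features with cpm >= cutoff in >= min_fraction of samples of some group.

    The 2-cpm default is the small RNA-seq expression threshold; the
    per-library call is lifted to cohort level so one analysis set exists.
    """
    if cutoff < 0:
        raise PreprocessError("cutoff must be non-negative")
    if cpm.norm != "cpm":
        raise PreprocessError("filter_expressed expects a cpm-normalized matrix")
    passed = cpm.data >= cutoff
    keep = np.zeros(cpm.data.shape[0], dtype=bool)
    for level in annotation.group_levels():
        cols = [s for s in annotation.samples_in_group(level) if s in cpm.data.columns]
        if not cols:
            continue
        frac = passed[cols].mean(axis=1)
        keep |= (frac >= min_fraction).to_numpy()
    return [f for f, k in zip(cpm.feature_ids, keep) if k]


def subsample_library(
    counts: pd.Series | np.ndarray,
    depth: int,
    n_reps: int,
    seed: int,
) -> list[np.ndarray]:
    """Resample a single library to a smaller depth, without replacement.

    Reads are physical objects, so each replicate is a multivariate
    hypergeometric draw from the read multiset; every replicate sums to
    ``depth`` exactly.
    """
    vec = np.asarray(counts, dtype=np.int64)
    total = int(vec.sum())
    if depth > total:
        raise PreprocessError(f"depth {depth} exceeds library size {total}")
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_hypergeometric(vec, depth, size=n_reps, method="marginals")
    return [draws[i] for i in range(n_reps)]


@dataclass
class ThresholdStabilityReport:
    """Subsampling depth-stability of the expressed-miRNA call.

    ``expressed`` has one row per (depth, replicate, cutoff) with the number
    of miRNAs at or above the cpm cutoff; ``r_squared`` has one row per
    (depth, replicate) with the R^2 of subsampled vs full-library log2 cpm
    over miRNAs expressed in the full library.
    """

    expressed: pd.DataFrame
    r_squared: pd.DataFrame


def threshold_stability(
    counts: pd.Series,
    depths: list[int],
    cutoffs: list[float],
    n_reps: int = 3,
    seed: int = 0,
    r2_cutoff: float = 2.0,
    offset: float = LOG_OFFSET,
) -> ThresholdStabilityReport:
    """Replicate the cpm-threshold subsampling experiment on one library."""
    vec = np.asarray(counts, dtype=np.int64)
    total = int(vec.sum())
    full_cpm = vec / total * 1e6
    full_expressed = full_cpm >= r2_cutoff
    full_log = np.log2(full_cpm + offset)

    exp_rows, r2_rows = [], []
    for d_i, depth in enumerate(depths):
        reps = subsample_library(vec, int(depth), n_reps, seed=seed + d_i)
        for r_i, rep in enumerate(reps):
            cpm = rep / depth * 1e6
            for cutoff in cutoffs:
                exp_rows.append(
                    {
                        "depth": int(depth),
                        "replicate": r_i,
                        "cutoff": cutoff,
                        "n_expressed": int((cpm >= cutoff).sum()),
                    }
                )
            sub_log = np.log2(cpm + offset)
            x, y = full_log[full_expressed], sub_log[full_expressed]
            if np.allclose(x, y):
                r2 = 1.0
            else:
                r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
            r2_rows.append({"depth": int(depth), "replicate": r_i, "r_squared": r2})
    return ThresholdStabilityReport(pd.DataFrame(exp_rows), pd.DataFrame(r2_rows))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise PreprocessError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    matrix: ExpressionMatrix,
    annotation: SampleAnnotation,
    case_label: str = "case",
    control_label: str = "control",
) -> pd.DataFrame:
    """Welch two-sample t-test per feature on log-scale values.

    Returns a DataFrame indexed by feature with columns ``log2fc`` (case
    minus control mean), ``stat``, ``pvalue``, ``qvalue`` and a
    ``zero_variance`` flag.  Features with zero variance in both groups get
    p = 1 and are flagged.
    """
    case_cols = [s for s in annotation.samples_in_group(case_label) if s in matrix.data.columns]
    ctrl_cols = [s for s in annotation.samples_in_group(control_label) if s in matrix.data.columns]
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise PreprocessError("each group needs at least two samples")

    A = matrix.data[case_cols].to_numpy()
    B = matrix.data[ctrl_cols].to_numpy()
    log2fc = A.mean(axis=1) - B.mean(axis=1)
    both_const = (A.var(axis=1) == 0) & (B.var(axis=1) == 0)

    with np.errstate(divide="ignore", invalid="ignore"):
        stat, pval = stats.ttest_ind(A, B, axis=1, equal_var=False)
    stat = np.asarray(stat, dtype=float)
    pval = np.asarray(pval, dtype=float)
    if both_const.any():
        warnings.warn(
            f"{int(both_const.sum())} features have zero variance in both groups; p set to 1",
            stacklevel=2,
        )
        stat[both_const] = np.nan
        pval[both_const] = 1.0
    pval = np.nan_to_num(pval, nan=1.0)
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "stat": stat,
            "pvalue": pval,
            "qvalue": bh_fdr(pval),
            "zero_variance": both_const,
        },
        index=matrix.data.index,
    )
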