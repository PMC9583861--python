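"""Count-matrix normalization and highly-expressed isomiR calling.

Matrices are pandas DataFrames with features in rows and samples in
columns.  The normalization path mirrors the standard small-RNA / RNA-seq
recipe: remove low-expressed features, compute TMM (trimmed mean of
M-values) scaling factors, convert to RPM (isomiRs) or FPKM (genes, using
a transcript-length table), and log2-transform with a pseudocount.

The TMM implementation follows Robinson & Oshlack (2010) and the edgeR
``calcNormFactors`` conventions: the reference sample is the one whose
upper quartile of count fractions is closest to the mean upper quartile;
M and A values are computed on features positive in both the sample and
the reference; both M and A are rank-trimmed (30% / 5% by default); the
factor is the precision-weighted mean of the surviving M values, and the
factors are rescaled to have geometric mean 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class ExpressionError(ValueError):
    pass


def validate_count_matrix(counts: pd.DataFrame) -> None:
    """Check the count-matrix contract: unique axes, finite non-negative values."""
    if counts.index.has_duplicates:
        raise ExpressionError("duplicate feature ids in count matrix")
    if counts.columns.has_duplicates:
        raise ExpressionError("duplicate sample ids in count matrix")
    values = counts.to_numpy()
    if values.size and (not np.isfinite(values).all() or (values < 0).any()):
        raise ExpressionError("count matrix must be finite and non-negative")


@dataclass(frozen=True)
class HighlyExpressedSet:
    """Minimal set of isomiRs jointly covering >= ``fraction`` of cohort reads."""

    cohort_id: str | None
    isomirs: tuple[str, ...]
    coverage_fraction: float


def filter_low_expressed(
    counts: pd.DataFrame,
    min_count: int = 10,
    min_total: int = 15,
    min_samples: int | None = None,
) -> pd.DataFrame:
    """Drop features not reaching ``min_count`` in ``min_samples`` samples
    or whose total across samples is below ``min_total``.

    ``min_samples`` defaults to min(n_samples, 10).  Row order of the
    surviving features is preserved.
    """
    if min_count < 0 or min_total < 0 or (min_samples is not None and min_samples < 0):
        raise ExpressionError("filter thresholds must be non-negative")
    validate_count_matrix(counts)
    if counts.empty:
        return counts.copy()
    if min_samples is None:
        min_samples = min(counts.shape[1], 10)
    enough_samples = (counts >= min_count).sum(axis=1) >= min_samples
    enough_total = counts.sum(axis=1) >= min_total
    return counts.loc[enough_samples & enough_total].copy()


def _quantile_type7(values: np.ndarray, p: float) -> float:
    # R's default quantile algorithm, used by edgeR when picking the reference
    return float(np.quantile(values, p, method="linear"))


def tmm_factors(
    counts: pd.DataFrame,
    logratio_trim: float = 0.3,
    abs_trim: float = 0.05,
) -> pd.Series:
    """Per-sample TMM scaling factors (geometric mean 1)."""
    validate_count_matrix(counts)
    if counts.shape[1] < 2:
        raise ExpressionError("TMM requires at least two samples")
    data = counts.to_numpy(dtype=float)
    lib = data.sum(axis=0)
    if (lib <= 0).any():
        raise ExpressionError("every sample must have a positive library size")

    # reference sample: upper quartile of count fractions closest to the mean
    f75 = np.array([_quantile_type7(data[:, j] / lib[j], 0.75) for j in range(data.shape[1])])
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    ref = data[:, ref_idx]
    n_ref = lib[ref_idx]

    log_factors = np.zeros(data.shape[1])
    for j in range(data.shape[1]):
        obs = data[:, j]
        n_obs = lib[j]
        mask = (obs > 0) & (ref > 0)
        if not mask.any():
            raise ExpressionError(
                f"sample {counts.columns[j]!r} shares no positive feature with the reference"
            )
        o = obs[mask]
        r = ref[mask]
        m = np.log2((o / n_obs) / (r / n_ref))
        a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
        # asymptotic (delta-method) variance of M; weights are its inverse
        v = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)

        if np.abs(m).max() < 1e-6:
            continue  # sample identical (up to scaling) to the reference

        n = m.size
        lo_m = math.floor(n * logratio_trim) + 1
        hi_m = n + 1 - lo_m
        lo_a = math.floor(n * abs_trim) + 1
        hi_a = n + 1 - lo_a
        rank_m = stats.rankdata(m)
        rank_a = stats.rankdata(a)
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if not keep.any():
            continue
        w = 1.0 / v[keep]
        f = float(np.sum(w * m[keep]) / np.sum(w))
        if np.isfinite(f):
            log_factors[j] = f

    factors = 2.0 ** log_factors
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def normalize(
    counts: pd.DataFrame,
    factors: pd.Series,
    lengths: pd.Series | None = None,
) -> pd.DataFrame:
    """TMM-scaled RPM, or FPKM when a transcript-length table is given.

    RPM = count / (library_size * factor) * 1e6, with library size the raw
    column sum; FPKM additionally divides by (length / 1e3).
    """
    validate_count_matrix(counts)
    factors = factors.reindex(counts.columns)
    if factors.isna().any() or (factors <= 0).any():
        raise ExpressionError("need one positive factor per sample")
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise ExpressionError("every sample must have a positive library size")
    rpm = counts / (lib * factors) * 1e6
    if lengths is None:
        return rpm
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = counts.index[lengths.isna()][:5].tolist()
        raise ExpressionError(f"missing transcript length for genes {missing}")
    if (lengths < 1).any():
        raise ExpressionError("transcript lengths must be >= 1 nt")
    return rpm.div(lengths / 1e3, axis=0)


def log2_transform(matrix: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Elementwise log2(x + pseudocount)."""
    values = matrix.to_numpy()
    if values.size and (values < 0).any():
        raise ExpressionError("log2 transform requires non-negative values")
    return np.log2(matrix + pseudocount)


def call_highly_expressed(
    counts: pd.DataFrame,
    fraction: float = 0.95,
    cohort_id: str | None = None,
) -> HighlyExpressedSet:
    """Minimal isomiR set accounting for ``fraction`` of cohort reads.

    Features are ranked by raw read total pooled over all samples of the
    cohort (ties broken by name); the shortest prefix whose cumulative
    share reaches the fraction is returned.
    """
    if not 0.0 < fraction <= 1.0:
        raise ExpressionError("fraction must lie in (0, 1]")
    validate_count_matrix(counts)
    totals = counts.sum(axis=1)
    grand = float(totals.sum())
    if grand <= 0:
        raise ExpressionError("cannot call highly expressed isomiRs on all-zero counts")
    order = sorted(totals.index, key=lambda name: (-totals[name], name))
    cum = 0.0
    chosen: list[str] = []
    for name in order:
        chosen.append(name)
        cum += float(totals[name])
        if cum / grand >= fraction:
            break
    return HighlyExpressedSet(
        cohort_id=cohort_id,
        isomirs=tuple(chosen),
        coverage_fraction=cum / grand,
    )
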