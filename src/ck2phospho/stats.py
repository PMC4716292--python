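"""Normalisation, transformation and three-class differential statistics.

Abundances are mean-normalised per sample (each column scaled so all
column totals equal the pre-scaling mean total), then arcsinh-transformed
to stabilise variance for t statistics. Each row is classified between
two groups as UP / DOWN (pooled two-sample t, p < alpha, |fold change| >
1.5), UNCHANGED (TOST equivalence, p < alpha, |fold change| < 1.5), or
UNCLASSIFIED. Fold changes are ratios of within-group means on the
normalised raw scale; the tests run on the transformed scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import SampleDesign, group_samples

LABEL_UP = "UP"
LABEL_DOWN = "DOWN"
LABEL_UNCHANGED = "UNCHANGED"
LABEL_UNCLASSIFIED = "UNCLASSIFIED"
LABELS = (LABEL_UP, LABEL_DOWN, LABEL_UNCHANGED, LABEL_UNCLASSIFIED)


class DomainError(ValueError):
    """Input outside the mathematical domain of an operation."""


@dataclass(frozen=True)
class ClassificationThresholds:
    """Decision thresholds for the three-class rule.

    ``tost_margin`` is the equivalence margin on the arcsinh scale;
    arcsinh(x) ~ ln(2x) at typical intensities, so ln(1.5) corresponds to
    a 1.5-fold ratio, mirroring the differential fold-change bound.
    """

    alpha_diff: float = 0.05
    fc_min_diff: float = 1.5
    alpha_tost: float = 0.05
    fc_max_equiv: float = 1.5
    tost_margin: float = math.log(1.5)

    def __post_init__(self) -> None:
        if min(self.alpha_diff, self.alpha_tost, self.tost_margin) <= 0:
            raise ValueError("thresholds must be positive")
        if self.fc_min_diff <= 1 or self.fc_max_equiv <= 1:
            raise ValueError("fold-change thresholds must exceed 1")


def normalize_samples(matrix: pd.DataFrame) -> pd.DataFrame:
    """Mean-normalise sample columns.

    Each column is scaled by (mean column total) / (its total), so every
    column total equals the pre-scaling mean total.
    """
    if matrix.shape[0] < 1:
        raise ValueError("empty abundance matrix")
    if (matrix.to_numpy() < 0).any():
        raise DomainError("negative abundances on the raw scale")
    totals = matrix.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero) > 0:
        raise ValueError(f"samples with zero total intensity: {list(zero.index)}")
    return matrix * (totals.mean() / totals)


def arcsinh_transform(x):
    """Variance-stabilising arcsinh, ln(x + sqrt(x^2 + 1)); requires x >= 0."""
    arr = np.asarray(x, dtype=float)
    if (arr < 0).any():
        raise DomainError("arcsinh_transform is restricted to non-negative abundances")
    out = np.arcsinh(arr)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def _pooled(xs: np.ndarray, ys: np.ndarray) -> tuple[float, float, int]:
    """(delta, standard error of delta, degrees of freedom) for the pooled test."""
    nx, ny = len(xs), len(ys)
    if nx < 2 or ny < 2:
        raise ValueError("each group needs at least 2 replicates")
    df = nx + ny - 2
    sp2 = ((nx - 1) * xs.var(ddof=1) + (ny - 1) * ys.var(ddof=1)) / df
    se = math.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    return float(ys.mean() - xs.mean()), se, df


def two_sample_t(xs: Sequence[float], ys: Sequence[float]) -> float:
    """Two-tailed p-value of the equal-variance two-sample t-test.

    Degenerate zero-variance data use the limit convention: p = 1 for
    equal means, p = 0 otherwise.
    """
    xs, ys = np.asarray(xs, float), np.asarray(ys, float)
    delta, se, df = _pooled(xs, ys)
    if se == 0.0:
        return 1.0 if delta == 0.0 else 0.0
    return float(2.0 * sps.t.sf(abs(delta) / se, df))


def tost_equivalence(xs: Sequence[float], ys: Sequence[float], margin: float) -> float:
    """Two one-sided tests (TOST) p-value for equivalence within +/-margin.

    p = max of the one-sided pooled-t p-values against the null hypotheses
    delta <= -margin and delta >= +margin; small p declares the group means
    statistically equivalent.
    """
    if margin <= 0:
        raise ValueError("TOST margin must be positive")
    xs, ys = np.asarray(xs, float), np.asarray(ys, float)
    delta, se, df = _pooled(xs, ys)
    if se == 0.0:
        return 0.0 if abs(delta) < margin else 1.0
    p_lower = float(sps.t.sf((delta + margin) / se, df))  # H0: delta <= -margin
    p_upper = float(sps.t.cdf((delta - margin) / se, df))  # H0: delta >= +margin
    return max(p_lower, p_upper)


def fold_change(mean_a: float, mean_b: float, floor: float) -> tuple[float, float]:
    """Signed (b/a) and absolute fold change with a positive floor on means."""
    if floor <= 0:
        raise ValueError("floor must be positive")
    if mean_a < 0 or mean_b < 0:
        raise DomainError("means must be non-negative")
    fc = max(mean_b, floor) / max(mean_a, floor)
    return fc, max(fc, 1.0 / fc)


def classify(
    t_p: float,
    tost_p: Optional[float],
    fc: float,
    abs_fc: float,
    thresholds: ClassificationThresholds = ClassificationThresholds(),
) -> str:
    """Apply the three-class rule; differential classes take precedence.

    The fold-change bounds make the classes mutually exclusive except at
    |FC| exactly equal to the threshold, which is UNCLASSIFIED under the
    strict inequalities.
    """
    if not math.isfinite(t_p):
        return LABEL_UNCLASSIFIED
    if t_p < thresholds.alpha_diff and abs_fc > thresholds.fc_min_diff:
        return LABEL_UP if fc > 1 else LABEL_DOWN
    if (
        tost_p is not None
        and math.isfinite(tost_p)
        and tost_p < thresholds.alpha_tost
        and abs_fc < thresholds.fc_max_equiv
    ):
        return LABEL_UNCHANGED
    return LABEL_UNCLASSIFIED


def default_floor(matrix: pd.DataFrame) -> float:
    """Half the smallest positive normalised value; guards zero means."""
    vals = matrix.to_numpy()
    positive = vals[vals > 0]
    if positive.size == 0:
        raise ValueError("matrix has no positive values")
    return float(positive.min() / 2.0)


def differential_analysis(
    matrix: pd.DataFrame,
    design: Sequence[SampleDesign],
    group_a: str,
    group_b: str,
    thresholds: ClassificationThresholds = ClassificationThresholds(),
    *,
    normalized: bool = False,
    floor: Optional[float] = None,
) -> pd.DataFrame:
    """Full two-group differential table for an abundance matrix.

    ``matrix`` has one row per motif/protein (index = key) and one column
    per sample. Group ``a`` is the reference: fold change is b over a.
    Returns columns key, mean_a, mean_b, fold_change, abs_fold_change,
    t_p, tost_p, label.
    """
    groups = group_samples(design)
    for g in (group_a, group_b):
        if g not in groups:
            raise ValueError(f"group {g!r} not in design")
        if len(groups[g]) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 replicates")
    norm = matrix if normalized else normalize_samples(matrix)
    if floor is None:
        floor = default_floor(norm)
    trans = pd.DataFrame(
        arcsinh_transform(norm.to_numpy()), index=norm.index, columns=norm.columns
    )
    a_cols, b_cols = groups[group_a], groups[group_b]
    rows = []
    for key in norm.index:
        mean_a = float(norm.loc[key, a_cols].mean())
        mean_b = float(norm.loc[key, b_cols].mean())
        fc, abs_fc = fold_change(mean_a, mean_b, floor)
        xs = trans.loc[key, a_cols].to_numpy(float)
        ys = trans.loc[key, b_cols].to_numpy(float)
        t_p = two_sample_t(xs, ys)
        tost_p = tost_equivalence(xs, ys, thresholds.tost_margin)
        rows.append(
            {
                "key": key,
                "mean_a": mean_a,
                "mean_b": mean_b,
                "fold_change": fc,
                "abs_fold_change": abs_fc,
                "t_p": t_p,
                "tost_p": tost_p,
                "label": classify(t_p, tost_p, fc, abs_fc, thresholds),
            }
        )
    return pd.DataFrame(rows)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional; off by default in
    the classification, which follows raw p < alpha rules)."""
    p = np.asarray(pvalues, float)
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.clip(adjusted, 0, 1)
    return out
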