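"""Class-separation screening: Student's t-test per feature, Benjamini-
Hochberg FDR adjustment, significance counting and ranking.

The test is the classical equal-variance two-sample t-test between poor-
and good-outcome patients; a constant feature (zero pooled variance) is
assigned p = 1 with a warning rather than dropped, so feature universes
stay aligned across cohorts. Ranking for downstream signature selection
uses raw p-values; the BH-adjusted values gate only significance counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_io import ValidationError
from .features import FeatureMatrix


@dataclass
class SignificanceConfig:
    """FDR threshold for calling a feature significant (default 0.1)."""

    fdr_threshold: float = 0.1

    def __post_init__(self) -> None:
        if not 0 < self.fdr_threshold < 1:
            raise ValidationError("fdr_threshold must be in (0, 1)")


def student_t_test(
    values: Sequence[float], labels: Sequence[int]
) -> tuple[float, float]:
    """Two-sided pooled-variance t-test between the label-1 and label-0 groups.

    Returns (t statistic, p-value); p comes from the t distribution with
    n1 + n2 - 2 degrees of freedom. Both groups need >= 2 members. A zero
    pooled variance yields (0, 1) with a warning (constant feature).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    g1, g0 = values[labels == 1], values[labels == 0]
    if len(g1) < 2 or len(g0) < 2:
        raise ValidationError(
            f"both outcome groups need >= 2 patients (got {len(g1)} and {len(g0)})"
        )
    if np.var(g1, ddof=1) == 0 and np.var(g0, ddof=1) == 0:
        warnings.warn("constant feature: p-value set to 1", UserWarning, stacklevel=2)
        return 0.0, 1.0
    t, p = stats.ttest_ind(g1, g0, equal_var=True)
    return float(t), float(p)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Sort ascending, multiply p(i) by m/i, enforce monotonicity from the
    largest rank down, cap at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compute_significance(fm: FeatureMatrix, outcome: Sequence[int]) -> pd.DataFrame:
    """Screen every feature of a matrix against the outcome labels.

    Returns a table with columns feature_id, t_stat, p_value, p_adjusted,
    rank. Rank is 1-based by ascending raw p-value with ties broken by
    ascending feature id.
    """
    labels = np.asarray(outcome)
    X = fm.values.to_numpy(dtype=float)
    g1, g0 = X[:, labels == 1], X[:, labels == 0]
    if g1.shape[1] < 2 or g0.shape[1] < 2:
        raise ValidationError(
            f"both outcome groups need >= 2 patients (got {g1.shape[1]} and {g0.shape[1]})"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(g1, g0, axis=1, equal_var=True)
    constant = (np.var(g1, axis=1) == 0) & (np.var(g0, axis=1) == 0)
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature(s): p-value set to 1",
            UserWarning,
            stacklevel=2,
        )
        t = np.where(constant, 0.0, t)
        p = np.where(constant, 1.0, p)
    table = pd.DataFrame(
        {
            "feature_id": [str(f) for f in fm.values.index],
            "t_stat": t,
            "p_value": p,
            "p_adjusted": bh_adjust(p),
        }
    )
    order = np.lexsort((table["feature_id"].to_numpy(), table["p_value"].to_numpy()))
    rank = np.empty(len(table), dtype=np.int64)
    rank[order] = np.arange(1, len(table) + 1)
    table["rank"] = rank
    return table


def count_significant(table: pd.DataFrame, config: SignificanceConfig) -> int:
    """Number of features with BH-adjusted p <= the FDR threshold."""
    if len(table) == 0:
        return 0
    return int((table["p_adjusted"] <= config.fdr_threshold).sum())


def rank_features(table: pd.DataFrame, top_n: int) -> list[str]:
    """The top_n feature ids by ascending raw p-value (ties by feature id)."""
    if top_n > len(table):
        raise ValidationError(f"top_n={top_n} exceeds the {len(table)} features")
    ordered = table.sort_values(["p_value", "feature_id"], kind="mergesort")
    return list(ordered["feature_id"].head(top_n))


def write_significance_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


__all__ = [
    "SignificanceConfig",
    "student_t_test",
    "bh_adjust",
    "compute_significance",
    "count_significant",
    "rank_features",
    "write_significance_table",
]
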