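"""Cross-cohort stability of top-ranked feature signatures.

For each cohort the top-160 most significant features (raw p-value rank)
are reduced to a 160-gene signature: node-based types map one feature to
one gene; edge types pool endpoint genes of top-ranked edges in rank order
until 160 genes are collected. Every unordered cohort pair is then scored
by the fold change observed-overlap / expected-overlap, where the expected
overlap of two independent k-of-N draws is k^2 / N, and the geometric mean
of the fold changes over all pairs summarizes a feature type's robustness.

A zero observed overlap is replaced by a configurable pseudocount (default
0.5) before the ratio so that log-scale summaries stay defined. Degree
diagnostics (mean/median network degree of each cohort's signature genes)
expose the hub bias that can inflate apparent edge-feature robustness.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .data_io import ValidationError
from .features import FeatureType
from .network import GeneNetwork, degree_summary


@dataclass
class RobustnessConfig:
    top_k_genes: int = 160
    zero_overlap_pseudocount: float = 0.5

    def __post_init__(self) -> None:
        if self.top_k_genes < 1:
            raise ValidationError("top_k_genes must be positive")
        if self.zero_overlap_pseudocount < 0:
            raise ValidationError("pseudocount must be nonnegative")


@dataclass
class RobustnessResult:
    """Pairwise overlap records plus the geometric-mean summary."""

    feature_type: str
    pairwise: pd.DataFrame  # cohort_a, cohort_b, observed, expected, fold
    geometric_mean_fold: float
    degree_diagnostics: pd.DataFrame  # cohort, mean_degree, median_degree


def select_top_genes(
    table: pd.DataFrame,
    ftype: FeatureType | str,
    provenance: Mapping[str, frozenset[str]],
    config: RobustnessConfig = RobustnessConfig(),
) -> list[str]:
    """Reduce a significance table to its top-``top_k_genes`` gene signature.

    Node-based types: the genes of the top-ranked features, one per feature.
    Edge types: walk edges in rank order inserting endpoint genes into an
    ordered set; stop once it holds >= top_k_genes genes, then truncate to
    the first top_k_genes in insertion order.
    """
    if isinstance(ftype, str):
        ftype = FeatureType.parse(ftype)
    from .significance import rank_features  # local import avoids a cycle

    k = config.top_k_genes
    if not ftype.is_edge_based:
        if len(table) < k:
            raise ValidationError(
                f"only {len(table)} features, cannot select {k} genes"
            )
        return rank_features(table, k)

    seen: dict[str, None] = {}  # insertion-ordered set
    for fid in rank_features(table, len(table)):
        for gene in sorted(provenance[fid]):
            seen.setdefault(gene, None)
        if len(seen) >= k:
            break
    if len(seen) < k:
        raise ValidationError(
            f"edge ranking yields only {len(seen)} genes, cannot reach {k}"
        )
    return list(seen)[:k]


def overlap_fold_change(
    set_a: Iterable[str],
    set_b: Iterable[str],
    universe_size: int,
    config: RobustnessConfig = RobustnessConfig(),
) -> tuple[int, float, float]:
    """(observed, expected, fold) overlap of two equal-size gene signatures.

    expected = k^2 / N is kept at full precision; fold uses the pseudocount
    when the observed overlap is below it.
    """
    a, b = set(set_a), set(set_b)
    if len(a) != len(b):
        raise ValidationError(f"signature sizes differ: {len(a)} vs {len(b)}")
    k = len(a)
    if universe_size < k:
        raise ValidationError("universe smaller than signature")
    observed = len(a & b)
    expected = k * k / universe_size
    fold = max(observed, config.zero_overlap_pseudocount) / expected
    return observed, expected, fold


def robustness_summary(
    per_cohort_sets: Mapping[str, Sequence[str]],
    universe_size: int,
    network: Optional[GeneNetwork] = None,
    config: RobustnessConfig = RobustnessConfig(),
    feature_type: str = "",
) -> RobustnessResult:
    """Score all unordered cohort pairs and summarize by geometric mean.

    With c cohorts there are C(c, 2) pairwise records (66 for 12 cohorts).
    Degree diagnostics are computed per cohort when a network is supplied.
    """
    cohorts = list(per_cohort_sets)
    if len(cohorts) < 2:
        raise ValidationError("need at least 2 cohorts")
    rows = []
    for a, b in combinations(cohorts, 2):
        obs, exp, fold = overlap_fold_change(
            per_cohort_sets[a], per_cohort_sets[b], universe_size, config
        )
        rows.append((a, b, obs, exp, fold))
    pairwise = pd.DataFrame(
        rows, columns=["cohort_a", "cohort_b", "observed", "expected", "fold"]
    )
    geo = float(np.exp(np.mean(np.log(pairwise["fold"].to_numpy()))))

    diag_rows = []
    if network is not None:
        for c in cohorts:
            summ = degree_summary(network, per_cohort_sets[c])
            diag_rows.append((c, summ.mean_degree, summ.median_degree))
    diagnostics = pd.DataFrame(
        diag_rows, columns=["cohort", "mean_degree", "median_degree"]
    )
    return RobustnessResult(
        feature_type=feature_type,
        pairwise=pairwise,
        geometric_mean_fold=geo,
        degree_diagnostics=diagnostics,
    )


def write_robustness_report(results: Sequence[RobustnessResult], path: str | Path) -> None:
    """All pairwise records of several feature types in one TSV."""
    frames = []
    for res in results:
        frame = res.pairwise.copy()
        frame.insert(0, "feature_type", res.feature_type)
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


__all__ = [
    "RobustnessConfig",
    "RobustnessResult",
    "select_top_genes",
    "overlap_fold_change",
    "robustness_summary",
    "write_robustness_report",
]
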