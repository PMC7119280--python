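"""Synthetic multi-cohort expression studies with planted network
structure, distributed class signal, and cohort batch effects.

The generator emulates the statistical situation the pipeline targets:
genes organized in co-regulated modules (a latent activity per module that
all member genes load on), an outcome signal carried by the *latent
activities* of a few differential modules — so the per-gene effect is weak
but the module-aggregated effect is strong — and a systematic per-cohort,
per-gene offset uncorrelated with outcome (batch effect). The ground-truth
interaction network is the union of within-module cliques.

Model, per patient p in cohort c with class y (poor = 1, good = 0):

    a_m(p) ~ N(+-delta/2, 1)   for differential modules (sign from y),
    a_m(p) ~ N(0, 1)           otherwise,
    x_g(p) = lambda * a_{m(g)}(p) + b_{c,g} + eps_{g,p},

with b_{c,g} ~ N(0, batch_sd^2) and eps ~ N(0, noise_sd^2) independent.
After generation every gene row is mean-centered (per-gene centering).

An alternative "single_gene" signal mode plants the class shift directly on
one gene per differential module instead of on the latent activity, giving
the opposite regime in which neighborhood aggregation dilutes the signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .data_io import ExpressionDataset, ValidationError
from .network import GeneNetwork

#: Per-study (poor, good) patient counts of the 12-cohort breast-cancer
#: compendium the generator's multi-cohort layout mirrors.
REFERENCE_COHORTS: tuple[tuple[str, int, int], ...] = (
    ("Desmedt", 56, 127),
    ("Hatzis", 102, 48),
    ("Ivshina", 30, 72),
    ("Loi", 24, 33),
    ("Pawitan", 33, 114),
    ("Miller", 21, 68),
    ("Minn", 21, 44),
    ("Schmidt", 24, 145),
    ("Symmans", 37, 187),
    ("WangY", 10, 42),
    ("WangYE", 88, 169),
    ("Zhang", 9, 112),
)

#: Default single-cohort layout: one balanced mid-sized study.
DEFAULT_COHORTS: tuple[tuple[str, int, int], ...] = (("cohort1", 100, 200),)


@dataclass
class SimulationConfig:
    """Study-condition parameters of the generator.

    Defaults describe the weak-per-gene, module-distributed signal regime:
    modules of 10 genes, 10 of 50 modules differential, a latent class
    shift of 0.5 latent-SD, gene loading 0.6 against unit residual noise,
    and a 0.3-SD cohort batch offset.
    """

    n_genes: int = 500
    module_size: int = 10
    n_modules_differential: int = 10
    effect_size: float = 0.5  # delta, class shift of latent activity (latent-SD units)
    gene_loading: float = 0.6  # lambda, module-activity weight per gene
    noise_sd: float = 1.0
    cohorts: tuple[tuple[str, int, int], ...] = DEFAULT_COHORTS  # (name, n_poor, n_good)
    batch_sd: float = 0.3
    seed: int = 0
    signal_mode: str = "module"  # or "single_gene"
    centering: str = "per_gene"  # recorded in provenance; per-gene is applied

    def __post_init__(self) -> None:
        if self.n_genes % self.module_size:
            raise ValidationError("n_genes must be divisible by module_size")
        if self.n_modules_differential > self.n_genes // self.module_size:
            raise ValidationError("more differential modules than modules")
        if min(self.noise_sd, self.batch_sd) < 0:
            raise ValidationError("standard deviations must be nonnegative")
        if self.signal_mode not in ("module", "single_gene"):
            raise ValidationError("signal_mode must be 'module' or 'single_gene'")
        if not self.cohorts or any(p + g < 1 for _, p, g in self.cohorts):
            raise ValidationError("every cohort needs at least one patient")
        names = [c[0] for c in self.cohorts]
        if len(set(names)) != len(names):
            raise ValidationError("cohort names must be unique")


@dataclass
class SyntheticStudy:
    """A generated dataset with its ground truth."""

    dataset: ExpressionDataset
    true_network: GeneNetwork
    differential_genes: frozenset[str]
    config: SimulationConfig


def _gene_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_study(config: SimulationConfig) -> SyntheticStudy:
    """Draw one study; bitwise deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n_modules = config.n_genes // config.module_size
    genes = _gene_ids(config.n_genes)
    module_of = np.repeat(np.arange(n_modules), config.module_size)

    patient_ids, outcome, cohort = [], [], []
    for name, n_poor, n_good in config.cohorts:
        for i in range(n_poor + n_good):
            patient_ids.append(f"{name}_P{i + 1:04d}")
            outcome.append(1 if i < n_poor else 0)
            cohort.append(name)
    y = np.asarray(outcome, dtype=np.int8)
    n_patients = len(patient_ids)

    # latent module activities, class-shifted for differential modules
    activities = rng.standard_normal((n_patients, n_modules))
    shift = np.where(y == 1, config.effect_size / 2, -config.effect_size / 2)
    diff_modules = np.arange(config.n_modules_differential)
    if config.signal_mode == "module":
        activities[:, diff_modules] += shift[:, None]

    cohort_names = [c[0] for c in config.cohorts]
    batch = rng.normal(0.0, config.batch_sd, size=(len(cohort_names), config.n_genes))
    cohort_idx = np.asarray([cohort_names.index(c) for c in cohort])

    noise = rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_patients))
    values = (
        config.gene_loading * activities[:, module_of].T
        + batch[cohort_idx, :].T
        + noise
    )

    if config.signal_mode == "single_gene":
        # one signal-carrying gene per differential module
        carrier_rows = diff_modules * config.module_size
        values[carrier_rows, :] += config.effect_size / 2 * np.where(y == 1, 1, -1)
        differential = frozenset(genes[r] for r in carrier_rows)
    else:
        differential = frozenset(
            genes[r] for r in np.flatnonzero(np.isin(module_of, diff_modules))
        )

    values = values - values.mean(axis=1, keepdims=True)  # per-gene centering

    frame = pd.DataFrame(values, index=genes, columns=patient_ids)
    dataset = ExpressionDataset(
        values=frame,
        outcome=pd.Series(y, index=frame.columns, name="outcome"),
        cohort=pd.Series(cohort, index=frame.columns, name="cohort"),
    )
    edges = [
        (genes[i], genes[j])
        for m in range(n_modules)
        for i in range(m * config.module_size, (m + 1) * config.module_size)
        for j in range(i + 1, (m + 1) * config.module_size)
    ]
    network = GeneNetwork(
        edges=edges,
        nodes=genes,
        provenance={"kind": "module_cliques", "module_size": config.module_size},
    )
    return SyntheticStudy(dataset, network, differential, config)


def reference_cohorts(scale: float = 1.0) -> tuple[tuple[str, int, int], ...]:
    """The 12-study cohort layout, optionally scaled (counts rounded,
    floored at 1 patient per class)."""
    out = []
    for name, n_poor, n_good in REFERENCE_COHORTS:
        out.append(
            (
                name,
                max(1, int(np.floor(scale * n_poor + 0.5))),
                max(1, int(np.floor(scale * n_good + 0.5))),
            )
        )
    return tuple(out)


def generate_multi_cohort_study(
    scale: float = 1.0, config: Optional[SimulationConfig] = None, **overrides
) -> SyntheticStudy:
    """A study whose 12 cohorts mirror the reference compendium's sizes and
    class imbalance, scalable for quick runs."""
    base = config if config is not None else SimulationConfig()
    return generate_study(replace(base, cohorts=reference_cohorts(scale), **overrides))


__all__ = [
    "SimulationConfig",
    "SyntheticStudy",
    "REFERENCE_COHORTS",
    "reference_cohorts",
    "generate_study",
    "generate_multi_cohort_study",
]
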