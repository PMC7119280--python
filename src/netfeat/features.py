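"""The 15 feature types: per-patient scalars computed from a gene's
expression and its network neighborhood.

A *geneset* is a gene together with its direct neighbors in a network.
Node-based operators (MEAN, MAX, MIN, MED, VAR) summarize the geneset's
expression per patient; NO averages the neighbors only; Edge features sum
the two endpoint expressions of each network edge; Gene is the raw
expression with no network. Each operator crossed with a network context
(co-expression "CE" or protein-protein interaction "PPI") gives the 15
types: Gene, CENO, CEMEAN, CEMAX, CEMIN, CEMED, CEVAR, CEEdge and the PPI
counterparts.

Conventions (see docs/methods.md): VAR is the population variance
(denominator = geneset size), the median of an even-sized geneset is the
mean of the two central values, and NO for an isolated (degree-0) gene
falls back to the gene's own expression.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .data_io import ExpressionDataset, ValidationError
from .network import GeneNetwork

OPERATORS = ("NO", "MEAN", "MAX", "MIN", "MED", "VAR", "Edge")
NETWORK_CONTEXTS = ("CE", "PPI")

#: All 15 feature type names.
FEATURE_TYPE_NAMES = ("Gene",) + tuple(
    f"{ctx}{op}" for ctx in NETWORK_CONTEXTS for op in OPERATORS
)

#: The eight component types of the CNF ensemble.
CNF_COMPONENT_NAMES = tuple(
    f"{ctx}{op}" for ctx in NETWORK_CONTEXTS for op in ("MEAN", "MAX", "MIN", "MED")
)


@dataclass(frozen=True)
class FeatureType:
    """One of the 15 feature types, split into operator and network context.

    ``Gene`` has context None; every other operator requires a network.
    """

    operator: str
    context: Optional[str] = None

    def __post_init__(self) -> None:
        if self.operator == "Gene":
            if self.context is not None:
                raise ValidationError("Gene features take no network context")
        elif self.operator not in OPERATORS:
            raise ValidationError(f"unknown operator {self.operator!r}")
        elif self.context not in NETWORK_CONTEXTS:
            raise ValidationError(
                f"operator {self.operator} requires context CE or PPI"
            )

    @classmethod
    def parse(cls, name: str) -> "FeatureType":
        if name == "Gene":
            return cls("Gene")
        for ctx in NETWORK_CONTEXTS:
            if name.startswith(ctx) and name[len(ctx):] in OPERATORS:
                return cls(name[len(ctx):], ctx)
        raise ValidationError(f"unknown feature type {name!r}")

    @property
    def name(self) -> str:
        return self.operator if self.context is None else f"{self.context}{self.operator}"

    @property
    def is_edge_based(self) -> bool:
        return self.operator == "Edge"

    @property
    def needs_network(self) -> bool:
        return self.operator != "Gene"

    def __str__(self) -> str:  # pragma: no cover
        return self.name


@dataclass
class FeatureMatrix:
    """Features x patients values with per-feature gene provenance.

    Provenance of a node-based feature is {gene} | neighbors(gene); of an
    edge feature, its two endpoints. Feature ids are gene ids for node-based
    types and ``geneA|geneB`` (endpoints sorted) for edge types.
    """

    values: pd.DataFrame
    ftype: FeatureType
    provenance: dict[str, frozenset[str]]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]


def edge_feature_id(a: str, b: str) -> str:
    return "|".join(sorted((a, b)))


_NODE_STATS = {
    "MEAN": lambda block: block.mean(axis=0),
    "MAX": lambda block: block.max(axis=0),
    "MIN": lambda block: block.min(axis=0),
    "MED": lambda block: np.median(block, axis=0),
    "VAR": lambda block: block.var(axis=0),  # population variance
}


def compute_features(
    dataset: ExpressionDataset,
    ftype: FeatureType | str,
    network: Optional[GeneNetwork] = None,
) -> FeatureMatrix:
    """Compute one feature type for every patient.

    Each patient is handled independently (no cross-patient statistics).
    Rows are ordered by sorted gene id (node-based) or sorted edge id.
    """
    if isinstance(ftype, str):
        ftype = FeatureType.parse(ftype)
    if ftype.needs_network and network is None:
        raise ValidationError(f"feature type {ftype.name} requires a network")

    vals = dataset.values
    if ftype.operator == "Gene":
        genes = sorted(map(str, vals.index))
        out = vals.loc[genes].copy()
        prov = {g: frozenset([g]) for g in genes}
        return FeatureMatrix(values=out, ftype=ftype, provenance=prov)

    missing = network.nodes - set(map(str, vals.index))
    if missing:
        raise ValidationError(
            f"network gene(s) missing from expression matrix: {sorted(missing)[:5]}"
        )
    arr = vals.to_numpy(dtype=float)
    row_of = {str(g): i for i, g in enumerate(vals.index)}

    if ftype.is_edge_based:
        edges = network.sorted_edges()
        ids = [edge_feature_id(a, b) for a, b in edges]
        out = np.empty((len(edges), arr.shape[1]))
        for r, (a, b) in enumerate(edges):
            out[r] = arr[row_of[a]] + arr[row_of[b]]
        prov = {edge_feature_id(a, b): frozenset((a, b)) for a, b in edges}
        return FeatureMatrix(
            values=pd.DataFrame(out, index=ids, columns=vals.columns),
            ftype=ftype,
            provenance=prov,
        )

    genes = network.sorted_nodes()
    out = np.empty((len(genes), arr.shape[1]))
    prov = {}
    stat = _NODE_STATS.get(ftype.operator)
    for r, g in enumerate(genes):
        nbrs = network.neighbors(g)
        prov[g] = frozenset([g]) | frozenset(nbrs)
        if ftype.operator == "NO":
            # degree-0 fallback: the gene's own expression
            rows = [row_of[h] for h in sorted(nbrs)] or [row_of[g]]
            out[r] = arr[rows].mean(axis=0)
        else:
            rows = [row_of[g]] + [row_of[h] for h in sorted(nbrs)]
            out[r] = stat(arr[rows])
    return FeatureMatrix(
        values=pd.DataFrame(out, index=genes, columns=vals.columns),
        ftype=ftype,
        provenance=prov,
    )


def feature_universe_size(network: GeneNetwork, ftype: FeatureType | str) -> int:
    """Number of features the type yields: |nodes| node-based, |edges| edge-based."""
    if isinstance(ftype, str):
        ftype = FeatureType.parse(ftype)
    return network.n_edges if ftype.is_edge_based else network.n_nodes


def write_feature_matrix(fm: FeatureMatrix, path: str | Path) -> None:
    out = fm.values.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


__all__ = [
    "FeatureType",
    "FeatureMatrix",
    "FEATURE_TYPE_NAMES",
    "CNF_COMPONENT_NAMES",
    "compute_features",
    "feature_universe_size",
    "edge_feature_id",
    "write_feature_matrix",
]
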