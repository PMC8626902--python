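"""Regulatory network construction, export and comparison.

Every feature called significant in a target gene's regression model becomes
a directed edge feature → target, weighted by the fitted coefficient; the
edge sign (positive/negative) encodes activation versus repression.
Methylation features are distinct nodes namespaced ``METH:<gene>`` so they
never collide with the gene's expression node.  Networks can be exported as
SIF (sign encoded in the relation), GraphML, or a TSV edge list, and compared
against an externally produced ranked edge list (e.g. a mutual-information
network): per-target and pooled feature overlap plus Spearman rank agreement
between |coefficient| and the reference score on shared features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .genomic import METHYL_PREFIX
from .regression import RegressionModel

EXPR = "EXPR"
METHYL = "METHYL"


@dataclass
class RegulatoryNetwork:
    """A directed, signed, weighted feature → target-gene graph."""

    graph: nx.DiGraph
    gene_set: str | None = None
    level: str | None = None

    @property
    def edges(self) -> list[tuple[str, str, dict]]:
        return sorted(self.graph.edges(data=True), key=lambda e: (e[0], e[1]))

    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def _feature_node(feature_name: str) -> tuple[str, str]:
    """Map a matrix column name to (node name, feature kind)."""
    if feature_name.startswith(METHYL_PREFIX):
        return feature_name, METHYL
    return feature_name, EXPR


def build_network(
    models: Iterable[RegressionModel],
    gene_set: str | None = None,
    level: str | None = None,
) -> RegulatoryNetwork:
    """Build the network of all significant (feature, target) pairs.

    Target genes are always present as nodes, even with no incoming edge.
    The edge count equals the summed significant-feature counts, asserted.
    """
    graph = nx.DiGraph()
    expected_edges = 0
    for model in sorted(models, key=lambda m: m.target_gene):
        if level is not None and model.level != level:
            raise ValueError(
                f"model of {model.target_gene} is at level {model.level}, expected {level}"
            )
        graph.add_node(model.target_gene, is_target=True)
        sig = model.significant_features()
        expected_edges += len(sig)
        for feature, coef in sorted(sig.items()):
            node, kind = _feature_node(feature)
            if not graph.has_node(node):
                graph.add_node(node, is_target=False)
            graph.add_edge(
                node, model.target_gene,
                weight=float(coef),
                sign="positive" if coef > 0 else "negative",
                kind=kind,
            )
    assert graph.number_of_edges() == expected_edges
    return RegulatoryNetwork(graph=graph, gene_set=gene_set, level=level)


def export_network(network: RegulatoryNetwork, path, format: str = "tsv") -> None:
    """Write a network as SIF, GraphML, or a TSV edge list (deterministic order)."""
    path = Path(path)
    if format == "sif":
        with open(path, "w") as fh:
            for src, tgt, attrs in network.edges:
                rel = "activates" if attrs["sign"] == "positive" else "represses"
                fh.write(f"{src}\t{rel}\t{tgt}\n")
            for node in sorted(network.graph.nodes):
                if network.graph.degree(node) == 0:
                    fh.write(f"{node}\n")
    elif format == "tsv":
        rows = [
            {"regulator": s, "target": t, "weight": a["weight"],
             "sign": a["sign"], "kind": a["kind"]}
            for s, t, a in network.edges
        ]
        df = pd.DataFrame(rows, columns=["regulator", "target", "weight", "sign", "kind"])
        df.to_csv(path, sep="\t", index=False)
    elif format == "graphml":
        g = nx.DiGraph()
        g.add_nodes_from(sorted(network.graph.nodes(data=True)))
        g.add_edges_from(network.edges)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network_tsv(path) -> RegulatoryNetwork:
    df = pd.read_csv(path, sep="\t")
    graph = nx.DiGraph()
    for row in df.itertuples(index=False):
        graph.add_node(row.target, is_target=True)
        if not graph.has_node(row.regulator):
            graph.add_node(row.regulator, is_target=False)
        graph.add_edge(row.regulator, row.target,
                       weight=float(row.weight), sign=row.sign, kind=row.kind)
    return RegulatoryNetwork(graph=graph)


def read_reference_edges(path) -> pd.DataFrame:
    """Read an external ranked edge list: regulator, target, score (TSV)."""
    df = pd.read_csv(path, sep="\t")
    required = {"regulator", "target", "score"}
    if not required <= set(df.columns):
        raise ValueError(f"reference edge list must have columns {sorted(required)}")
    return df


def compare_with_reference(
    network: RegulatoryNetwork,
    reference_edges: pd.DataFrame,
) -> dict:
    """Overlap and ranking agreement against an external ranked edge list.

    For each target with at least one model edge: the fraction of the model's
    regulators present among the reference's regulators of the same target,
    and the Spearman correlation between |coefficient| and reference score on
    the shared regulators (NaN if fewer than two are shared).  Targets absent
    from the reference are excluded from the aggregates and listed.  Both the
    per-target mean overlap and the pooled (edge-weighted) overlap are
    reported.
    """
    ref_by_target: dict[str, dict[str, float]] = {}
    for row in reference_edges.itertuples(index=False):
        ref_by_target.setdefault(str(row.target), {})[str(row.regulator)] = float(row.score)

    per_target = []
    missing = []
    pooled_shared = pooled_model = 0
    for target in sorted({t for _, t, _ in network.edges}):
        preds = {
            src: abs(attrs["weight"])
            for src, _tgt, attrs in network.graph.in_edges(target, data=True)
        }
        if target not in ref_by_target:
            missing.append(target)
            continue
        ref = ref_by_target[target]
        shared = sorted(set(preds) & set(ref))
        overlap = len(shared) / len(preds)
        if len(shared) >= 2:
            rho = float(spearmanr([preds[f] for f in shared],
                                  [ref[f] for f in shared]).statistic)
        else:
            rho = float("nan")
        pooled_shared += len(shared)
        pooled_model += len(preds)
        per_target.append({
            "target": target, "n_model_features": len(preds),
            "n_shared": len(shared), "overlap": overlap, "spearman_rho": rho,
        })
    table = pd.DataFrame(
        per_target,
        columns=["target", "n_model_features", "n_shared", "overlap", "spearman_rho"],
    )
    return {
        "per_target": table,
        "pooled_overlap": pooled_shared / pooled_model if pooled_model else float("nan"),
        "mean_overlap": float(table["overlap"].mean()) if len(table) else float("nan"),
        "mean_spearman_rho": (
            float(np.nanmean(rhos)) if len(rhos := table["spearman_rho"].dropna()) else float("nan")
        ),
        "targets_missing_from_reference": missing,
    }
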