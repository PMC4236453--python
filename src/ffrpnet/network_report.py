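"""Assembly of the multi-evidence divergence network.

Nodes are TFs, condition sets, and effector-preference clusters; typed edges
carry the statistic that defines them and are included only when they pass
their stated thresholds:

- ``coexpression``: Spearman rho >= 0.5 and p <= 0.05;
- ``target_overlap``: Bonferroni-corrected hypergeometric p <= 0.05 and
  percent overlap >= 50 (correction over all TF pairs);
- ``conditional_regulation``: BH q <= 0.05 and |median r| >= 0.4, with the
  activator/repressor role as an attribute;
- ``motif_similarity``: optional pass-through of an external motif-comparison
  table (its own corrected q <= 0.05);
- ``effector_preference``: membership of a TF in an effector cluster.
"""

from __future__ import annotations

import math
from pathlib import Path

import networkx as nx
import pandas as pd

COEXPRESSION = "coexpression"
TARGET_OVERLAP = "target_overlap"
MOTIF_SIMILARITY = "motif_similarity"
EFFECTOR_PREFERENCE = "effector_preference"
CONDITIONAL_REGULATION = "conditional_regulation"


def assemble_network(tfs,
                     coexpression_edges: pd.DataFrame | None = None,
                     overlap_results: pd.DataFrame | None = None,
                     conditional_results: pd.DataFrame | None = None,
                     effector_clusters: dict[str, int] | None = None,
                     motif_similarity: pd.DataFrame | None = None,
                     rho_cutoff: float = 0.5, p_cutoff: float = 0.05,
                     overlap_percent_cutoff: float = 50.0,
                     q_cutoff: float = 0.05, min_abs_r: float = 0.4,
                     n_overlap_tests: int | None = None) -> nx.MultiGraph:
    """Build the evidence network from upstream result tables."""
    g = nx.MultiGraph()
    tfs = sorted(tfs)
    for tf in tfs:
        g.add_node(tf, kind="tf")

    def check_node(name: str) -> None:
        if name not in g:
            raise KeyError(f"edge references unknown node {name!r}")

    if coexpression_edges is not None:
        for _, row in coexpression_edges.iterrows():
            check_node(row["tf_a"])
            check_node(row["tf_b"])
            if row["rho"] >= rho_cutoff and row["pvalue"] <= p_cutoff:
                g.add_edge(row["tf_a"], row["tf_b"], key=COEXPRESSION,
                           kind=COEXPRESSION, rho=float(row["rho"]),
                           pvalue=float(row["pvalue"]))

    if overlap_results is not None:
        m = n_overlap_tests if n_overlap_tests is not None \
            else math.comb(len(tfs), 2)
        for _, row in overlap_results.iterrows():
            check_node(row["tf_a"])
            check_node(row["tf_b"])
            p_bonf = min(1.0, float(row["pvalue"]) * m)
            if p_bonf <= p_cutoff and row["percent_overlap"] >= overlap_percent_cutoff:
                g.add_edge(row["tf_a"], row["tf_b"], key=TARGET_OVERLAP,
                           kind=TARGET_OVERLAP, k=int(row["k"]),
                           percent_overlap=float(row["percent_overlap"]),
                           pvalue=float(row["pvalue"]),
                           bonferroni_p=p_bonf)

    if conditional_results is not None:
        for _, row in conditional_results.iterrows():
            check_node(row["tf"])
            if row["bh_q"] <= q_cutoff and abs(row["median_r"]) >= min_abs_r:
                cs = str(row["condition_set"])
                if cs not in g:
                    g.add_node(cs, kind="condition_set")
                g.add_edge(row["tf"], cs, key=CONDITIONAL_REGULATION,
                           kind=CONDITIONAL_REGULATION, role=str(row["role"]),
                           median_r=float(row["median_r"]),
                           bh_q=float(row["bh_q"]))

    if effector_clusters is not None:
        for tf in sorted(effector_clusters):
            check_node(tf)
            label = f"effector_cluster_{effector_clusters[tf]}"
            if label not in g:
                g.add_node(label, kind="effector_cluster")
            g.add_edge(tf, label, key=EFFECTOR_PREFERENCE,
                       kind=EFFECTOR_PREFERENCE)

    if motif_similarity is not None:
        for _, row in motif_similarity.iterrows():
            check_node(row["tf_a"])
            check_node(row["tf_b"])
            if row["qvalue"] <= q_cutoff:
                g.add_edge(row["tf_a"], row["tf_b"], key=MOTIF_SIMILARITY,
                           kind=MOTIF_SIMILARITY, qvalue=float(row["qvalue"]))
    return g


def export_network(network: nx.MultiGraph, path, fmt: str = "graphml") -> None:
    """Write the network (GraphML is a lossless round trip; SIF types only)."""
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(network, path)
    elif fmt == "sif":
        with path.open("w") as fh:
            for u, v, key in network.edges(keys=True):
                fh.write(f"{u}\t{key}\t{v}\n")
            for node in nx.isolates(network):
                fh.write(f"{node}\n")
    else:
        raise ValueError(f"unsupported format {fmt!r}")


def read_network(path) -> nx.MultiGraph:
    return nx.read_graphml(Path(path), force_multigraph=True)


def edge_summary(network: nx.MultiGraph) -> pd.DataFrame:
    """All edges with their defining statistics, one row per edge."""
    rows = []
    for u, v, key, data in network.edges(keys=True, data=True):
        stats = {k: val for k, val in data.items() if k != "kind"}
        rows.append({"node_a": u, "node_b": v, "kind": data.get("kind", key),
                     **stats})
    return pd.DataFrame(rows)
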