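"""Thresholded gene co-expression networks and cross-species intersection.

Within a species, every gene pair is correlated across all samples
(phases pooled) and an undirected edge is kept iff |r| >= 0.95 and
p <= 0.05 (boundary inclusive), with the edge sign recorded.  Two
species' networks are intersected through an ortholog map: an edge is
common iff both endpoints map and the mapped edge exists in the other
network with the same sign.  No multiple-testing correction is applied;
at these r thresholds the correlation floor dominates.
"""

from __future__ import annotations

import itertools
import logging
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .de import ExpressionStudy
from .stats import DegenerateDataError, pearson

__all__ = [
    "build_network",
    "intersect_networks",
    "shared_interactions_summary",
    "network_to_sif",
]

logger = logging.getLogger(__name__)


def build_network(
    study: ExpressionStudy,
    genes: Iterable[str] | None = None,
    r_abs_min: float = 0.95,
    p_max: float = 0.05,
) -> nx.Graph:
    """Build the co-expression network over a gene subset.

    Constant-expression genes are excluded with a logged warning, not an
    error.  Node attribute ``species`` and edge attributes ``r``, ``p``,
    ``sign`` are set.
    """
    gene_list = list(genes) if genes is not None else list(study.norm.index)
    if not gene_list:
        raise ValueError("gene subset must be non-empty")
    if study.norm.shape[1] < 3:
        raise ValueError("need at least 3 samples to correlate")
    missing = [g for g in gene_list if g not in study.norm.index]
    if missing:
        raise KeyError(f"genes absent from study: {missing[:5]}")
    matrix = study.norm.loc[gene_list]
    constant = matrix.std(axis=1) == 0
    if constant.any():
        dropped = list(matrix.index[constant])
        logger.warning(
            "%s: excluding %d constant-expression genes from network",
            study.species,
            len(dropped),
        )
        matrix = matrix[~constant]

    g = nx.Graph(species=study.species, r_abs_min=r_abs_min, p_max=p_max)
    g.add_nodes_from(matrix.index)
    values = matrix.to_numpy(dtype=float)
    names = list(matrix.index)
    for i, j in itertools.combinations(range(len(names)), 2):
        try:
            res = pearson(values[i], values[j])
        except DegenerateDataError:  # pragma: no cover - constants dropped above
            continue
        if abs(res.r) >= r_abs_min and res.p <= p_max:
            g.add_edge(
                names[i],
                names[j],
                r=res.r,
                p=res.p,
                sign=1 if res.r > 0 else -1,
            )
    return g


def intersect_networks(
    net_a: nx.Graph,
    net_b: nx.Graph,
    mapping: Mapping[str, str],
    match_sign: bool = True,
) -> list[tuple[tuple[str, str], tuple[str, str], int]]:
    """Common interactions between two networks under an ortholog map.

    ``mapping`` sends net_a gene ids to net_b gene ids.  An edge (a1, a2)
    is common iff both endpoints map into net_b and the mapped edge
    exists there — with the same sign when ``match_sign`` (positive edges
    must match positive).  The result is symmetric in argument order up
    to id relabeling.
    """
    common = []
    for a1, a2, data in net_a.edges(data=True):
        b1 = mapping.get(a1)
        b2 = mapping.get(a2)
        if b1 is None or b2 is None:
            continue
        if not net_b.has_edge(b1, b2):
            continue
        if match_sign and net_b.edges[b1, b2]["sign"] != data["sign"]:
            continue
        e_a = tuple(sorted((a1, a2)))
        e_b = tuple(sorted((b1, b2)))
        common.append((e_a, e_b, data["sign"]))
    common.sort()
    return common


def shared_interactions_summary(
    nets: Mapping[str, nx.Graph],
    maps: Mapping[tuple[str, str], Mapping[str, str]],
    match_sign: bool = True,
) -> dict[str, int]:
    """Common-edge counts per species pair (zero allowed)."""
    out: dict[str, int] = {}
    for (sa, sb), mapping in maps.items():
        shared = intersect_networks(nets[sa], nets[sb], mapping, match_sign)
        out[f"{sa}~{sb}"] = len(shared)
    return out


def network_to_sif(net: nx.Graph) -> tuple[pd.DataFrame, pd.DataFrame]:
    """SIF edge list plus an attribute table (Cytoscape-compatible)."""
    sif_rows = []
    attr_rows = []
    for a, b, data in sorted(net.edges(data=True)):
        relation = "pos" if data["sign"] > 0 else "neg"
        sif_rows.append({"source": a, "relation": relation, "target": b})
        attr_rows.append(
            {"source": a, "target": b, "r": data["r"], "p": data["p"], "sign": data["sign"]}
        )
    return pd.DataFrame(sif_rows), pd.DataFrame(attr_rows)
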