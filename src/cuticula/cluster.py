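"""Hierarchical clustering with multiscale-bootstrap cluster support.

Samples (expression) or individuals (CHC profiles) are clustered by
complete linkage on correlation (1 - r) or Euclidean distances.  Each
internal node receives an ordinary bootstrap proportion (BP) and an
approximately unbiased probability (AU) from the multiscale bootstrap:
features are resampled with replacement to a grid of sizes round(n*rho)
for rho in 0.5..1.4, the per-scale containment frequency BP(rho) is
probit-transformed and fitted by weighted least squares to

    Phi^-1(1 - BP(rho)) = v * sqrt(rho) + c / sqrt(rho)

and AU = 1 - Phi(v - c).  Clusters with AU > 95 are the conventionally
significant ones.  Items are never resampled, so the item set is
identical across bootstrap trees; cluster identity is the leaf set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm

__all__ = [
    "DistanceSpec",
    "SupportedDendrogram",
    "ClusterNode",
    "distance_matrix",
    "hclust_complete",
    "multiscale_bootstrap",
    "DEFAULT_SCALES",
]

DEFAULT_SCALES: tuple[float, ...] = tuple(np.round(np.arange(0.5, 1.41, 0.1), 1))


@dataclass(frozen=True)
class DistanceSpec:
    """Distance metric for item profiles; linkage is always complete."""

    metric: str = "correlation"  # "correlation" (1 - Pearson r) or "euclidean"

    def __post_init__(self):
        if self.metric not in ("correlation", "euclidean"):
            raise ValueError("metric must be 'correlation' or 'euclidean'")


@dataclass
class ClusterNode:
    """One internal node of the supported dendrogram."""

    leaves: frozenset[int]
    height: float
    bp: float | None = None      # raw containment % at rho = 1
    au: float | None = None      # approximately unbiased support %
    v: float | None = None       # fitted signed distance
    c: float | None = None       # fitted curvature
    n_scales: int = 0


@dataclass
class SupportedDendrogram:
    """Complete-linkage merge tree with per-node BP/AU support."""

    labels: tuple[str, ...]
    linkage_matrix: np.ndarray
    nodes: list[ClusterNode] = field(default_factory=list)
    scales: tuple[float, ...] = DEFAULT_SCALES
    b_per_scale: int = 0
    seed: int | None = None

    def node_for(self, leaf_labels: Sequence[str]) -> ClusterNode | None:
        """Look up the internal node whose leaf set matches the labels."""
        want = frozenset(self.labels.index(l) for l in leaf_labels)
        for node in self.nodes:
            if node.leaves == want:
                return node
        return None

    def to_table(self) -> pd.DataFrame:
        rows = []
        for node in self.nodes:
            rows.append(
                {
                    "leaves": "|".join(sorted(self.labels[i] for i in node.leaves)),
                    "n_leaves": len(node.leaves),
                    "height": node.height,
                    "bp": node.bp,
                    "au": node.au,
                    "v": node.v,
                    "c": node.c,
                    "n_scales": node.n_scales,
                }
            )
        return pd.DataFrame(rows).sort_values("n_leaves").reset_index(drop=True)

    def to_newick(self) -> str:
        """Newick string with AU/BP per internal node as a node label."""
        n = len(self.labels)
        support = {node.leaves: node for node in self.nodes}
        children: dict[int, tuple[int, int]] = {}
        heights = np.zeros(2 * n - 1)
        leafsets: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
        for k, (a, b, h, _) in enumerate(self.linkage_matrix):
            node_id = n + k
            children[node_id] = (int(a), int(b))
            heights[node_id] = h
            leafsets[node_id] = leafsets[int(a)] | leafsets[int(b)]

        def fmt(x: float | None) -> str:
            return "NA" if x is None else f"{x:.1f}"

        def render(node_id: int, parent_height: float) -> str:
            blen = max(parent_height - heights[node_id], 0.0)
            if node_id < n:
                return f"{self.labels[node_id]}:{blen:.6g}"
            a, b = children[node_id]
            inner = ",".join(
                render(c, heights[node_id]) for c in sorted((a, b))
            )
            node = support.get(leafsets[node_id])
            label = f"au{fmt(node.au)}_bp{fmt(node.bp)}" if node else ""
            return f"({inner}){label}:{blen:.6g}"

        root = 2 * n - 2
        return render(root, heights[root]) + ";"


def distance_matrix(data: np.ndarray | pd.DataFrame, spec: DistanceSpec) -> np.ndarray:
    """Symmetric item-by-item distance matrix; rows of ``data`` are items."""
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need a 2-D array with at least 2 items")
    if spec.metric == "euclidean":
        d = squareform(pdist(arr, metric="euclidean"))
    else:
        if np.any(arr.std(axis=1) == 0):
            raise ValueError("correlation distance undefined for constant item profiles")
        r = np.corrcoef(arr)
        d = 1.0 - r
        np.fill_diagonal(d, 0.0)
        d = np.clip(d, 0.0, 2.0)
    return d


def hclust_complete(dist: np.ndarray) -> np.ndarray:
    """Complete-linkage agglomeration; returns a scipy linkage matrix."""
    dist = np.asarray(dist, dtype=float)
    if dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    return linkage(squareform(dist, checks=False), method="complete")


def _leafsets(linkage_matrix: np.ndarray, n: int) -> list[frozenset[int]]:
    """Leaf sets of the internal nodes, in merge order."""
    sets: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
    out = []
    for a, b, _, _ in linkage_matrix:
        merged = sets[int(a)] | sets[int(b)]
        sets.append(merged)
        out.append(merged)
    return out


def _fit_au(counts: np.ndarray, scales: np.ndarray, b: int) -> tuple[float | None, ...]:
    """AU/v/c from per-scale containment counts.

    Degenerate nodes resolve without a fit: contained in every replicate
    at every scale -> AU 100; never contained -> AU 0.  Otherwise the
    probit-transformed frequencies are fitted by WLS over the scales with
    0 < BP < 1 (all scales, clipped, when fewer than two are interior).
    """
    bp = counts / b
    if np.all(counts == b):
        return 100.0, 0.0, 0.0, len(scales)
    if np.all(counts == 0):
        return 0.0, None, None, 0
    interior = (counts > 0) & (counts < b)
    if interior.sum() >= 2:
        use = interior
    else:
        use = np.ones_like(interior, dtype=bool)
    eps = 1.0 / (2 * b)
    bp_use = np.clip(bp[use], eps, 1 - eps)
    rho = scales[use]
    z = norm.ppf(1 - bp_use)
    x = np.sqrt(rho)
    design = np.column_stack([x, 1.0 / x])
    w = b * norm.pdf(z) ** 2 / (bp_use * (1 - bp_use))
    wsq = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(design * wsq[:, None], z * wsq, rcond=None)
    v, c = float(coef[0]), float(coef[1])
    au = 100.0 * (1.0 - norm.cdf(v - c))
    return au, v, c, int(use.sum())


def multiscale_bootstrap(
    data: np.ndarray | pd.DataFrame,
    spec: DistanceSpec = DistanceSpec(),
    scales: Sequence[float] = DEFAULT_SCALES,
    b_per_scale: int = 1000,
    seed: int | None = None,
    labels: Sequence[str] | None = None,
) -> SupportedDendrogram:
    """Cluster items (rows) with AU/BP support from feature resampling.

    ``data`` is items x features; features (columns) are resampled with
    replacement to round(n_features * rho) for each scale rho, the data
    is re-clustered, and each observed node's leaf set is counted when it
    reappears.  ``b_per_scale`` replicates are drawn per scale.
    """
    if isinstance(data, pd.DataFrame):
        if labels is None:
            labels = tuple(str(i) for i in data.index)
        arr = data.to_numpy(dtype=float)
    else:
        arr = np.asarray(data, dtype=float)
        if labels is None:
            labels = tuple(str(i) for i in range(arr.shape[0]))
    n_items, n_features = arr.shape
    if n_items < 3:
        raise ValueError("need at least 3 items to support clusters")
    if b_per_scale < 100:
        raise ValueError("b_per_scale must be >= 100")
    scales_arr = np.asarray(scales, dtype=float)

    obs_linkage = hclust_complete(distance_matrix(arr, spec))
    obs_leafsets = _leafsets(obs_linkage, n_items)
    heights = obs_linkage[:, 2]
    index_of = {ls: i for i, ls in enumerate(obs_leafsets)}
    counts = np.zeros((len(scales_arr), len(obs_leafsets)), dtype=np.int64)

    rng = np.random.default_rng(seed)
    use_corr = spec.metric == "correlation"
    for si, rho in enumerate(scales_arr):
        m = max(2, int(round(n_features * rho)))
        for _ in range(b_per_scale):
            cols = rng.integers(0, n_features, size=m)
            sub = arr[:, cols]
            if use_corr:
                with np.errstate(invalid="ignore", divide="ignore"):
                    r = np.corrcoef(sub)
                d = 1.0 - np.nan_to_num(r, nan=0.0)
                np.fill_diagonal(d, 0.0)
                condensed = squareform(np.clip(d, 0.0, 2.0), checks=False)
            else:
                condensed = pdist(sub, metric="euclidean")
            z = linkage(condensed, method="complete")
            for ls in _leafsets(z, n_items):
                idx = index_of.get(ls)
                if idx is not None:
                    counts[si, idx] += 1

    # raw BP reported at the scale closest to rho = 1
    rho1 = int(np.argmin(np.abs(scales_arr - 1.0)))
    nodes: list[ClusterNode] = []
    for i, ls in enumerate(obs_leafsets):
        au, v, c, n_used = _fit_au(counts[:, i], scales_arr, b_per_scale)
        nodes.append(
            ClusterNode(
                leaves=ls,
                height=float(heights[i]),
                bp=100.0 * counts[rho1, i] / b_per_scale,
                au=au,
                v=v,
                c=c,
                n_scales=n_used,
            )
        )
    return SupportedDendrogram(
        labels=tuple(labels),
        linkage_matrix=obs_linkage,
        nodes=nodes,
        scales=tuple(scales_arr),
        b_per_scale=b_per_scale,
        seed=seed,
    )
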