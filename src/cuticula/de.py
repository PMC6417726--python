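"""Differential expression between developmental phases.

Genes (or de novo contigs) are called differentially expressed between
two phases with a per-gene negative-binomial Wald test (method-of-moments
dispersion, floored at zero) and/or an exact label-permutation test, with
Benjamini–Hochberg adjustment across genes.  ``method="both"`` requires
significance from both routes, emulating the two-package intersection
rule.  The filter applies the published thresholds boundary-inclusively:
q < 0.05, |log2FC| >= 1, and a per-phase mean abundance floor of 5
(FPKM-like, counts-per-million here).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import bh_adjust, two_proportion_z

__all__ = [
    "ExpressionStudy",
    "normalize",
    "test_de",
    "filter_degs",
    "upregulation_summary",
    "compare_proportions",
]


@dataclass
class ExpressionStudy:
    """A per-species expression study.

    ``counts`` is a gene x sample integer matrix, ``norm`` its
    library-size-normalized counterpart (CPM convention), and ``meta``
    holds one row per sample column with ``sample_id``, ``species``,
    ``phase`` and ``replicate``.
    """

    species: str
    counts: pd.DataFrame
    norm: pd.DataFrame
    meta: pd.DataFrame

    @classmethod
    def from_counts(
        cls, species: str, counts: pd.DataFrame, meta: pd.DataFrame,
        lengths: pd.Series | None = None,
        method: str = "median_ratio",
    ) -> "ExpressionStudy":
        study = cls(species, counts, normalize(counts, lengths, method), meta)
        study.validate()
        return study

    def validate(self) -> None:
        vals = self.counts.to_numpy()
        if np.any(vals < 0):
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.meta["sample_id"])
        if missing:
            raise ValueError(f"metadata missing for samples: {sorted(missing)}")
        reps = self.meta.groupby("phase")["sample_id"].count()
        if (reps < 2).any():
            raise ValueError("each phase needs at least 2 replicates")

    def phases(self) -> list[str]:
        seen: list[str] = []
        for ph in self.meta["phase"]:
            if ph not in seen:
                seen.append(ph)
        return seen

    def samples_for(self, phase: str) -> list[str]:
        sel = self.meta[self.meta["phase"] == phase].sort_values("replicate")
        return list(sel["sample_id"])


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (composition-robust).

    Per sample, the median over genes of count / geometric-mean count,
    taken over genes expressed in every sample.  Robust to asymmetric
    differential expression, which biases total-count scaling: a sample
    is not called deeper merely because a minority of genes is strongly
    upregulated in it.
    """
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if positive.sum() < 10:
        raise ValueError("too few all-positive genes for median-of-ratios")
    logs = np.log(arr[positive])
    log_gm = logs.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logs - log_gm, axis=0))
    return pd.Series(sf, index=counts.columns)


def normalize(
    counts: pd.DataFrame,
    lengths: pd.Series | None = None,
    method: str = "cpm",
) -> pd.DataFrame:
    """Library-size normalization.

    ``method="cpm"`` scales each sample to a common total of one million
    (counts-per-million convention); ``method="median_ratio"`` divides by
    median-of-ratios size factors instead, then rescales so the mean
    normalized library is one million, keeping values on a CPM-like
    scale while staying robust to library-composition shifts.  Both are
    scale-invariant in depth: doubling one library's depth leaves its
    normalized values unchanged.  With ``lengths`` (bases) the values
    are additionally divided by transcript length in kilobases (an
    FPKM-like quantity).
    """
    libsize = counts.sum(axis=0).astype(float)
    if (libsize == 0).any():
        raise ValueError("empty library (all-zero sample column)")
    if method == "cpm":
        out = counts.astype(float).div(libsize, axis=1) * 1e6
    elif method == "median_ratio":
        try:
            sf = size_factors(counts)
        except ValueError:
            sf = libsize / libsize.mean()
        scaled = counts.astype(float).div(sf, axis=1)
        out = scaled * (1e6 / (scaled.sum(axis=0).mean()))
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    if lengths is not None:
        kb = lengths.reindex(counts.index).astype(float) / 1000.0
        if kb.isna().any() or (kb <= 0).any():
            raise ValueError("lengths must be positive and cover every gene")
        out = out.div(kb, axis=0)
    return out


def _nb_wald(
    a_vals: np.ndarray, b_vals: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-gene NB Wald test on two groups of normalized counts.

    Per gene, group means mu_A, mu_B and a pooled method-of-moments
    dispersion alpha = max(0, (s2 - mu)/mu^2) feed the Wald statistic on
    the log fold change via the delta method:
    Var(log mu_hat) = (mu + alpha mu^2) / (n mu^2).
    Returns (z, p); genes with zero counts in both groups get p = 1.
    """
    n_a, n_b = a_vals.shape[1], b_vals.shape[1]
    mu_a = a_vals.mean(axis=1)
    mu_b = b_vals.mean(axis=1)
    s2_a = a_vals.var(axis=1, ddof=1)
    s2_b = b_vals.var(axis=1, ddof=1)
    mu_bar = (mu_a + mu_b) / 2
    s2_bar = (s2_a + s2_b) / 2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(mu_bar > 0, (s2_bar - mu_bar) / mu_bar**2, 0.0)
    alpha = np.clip(np.nan_to_num(alpha), 0.0, None)
    # floor means so SE and log are defined for one-sided-zero genes
    fa = np.maximum(mu_a, 0.5)
    fb = np.maximum(mu_b, 0.5)
    var_log_a = (fa + alpha * fa**2) / (n_a * fa**2)
    var_log_b = (fb + alpha * fb**2) / (n_b * fb**2)
    z = (np.log(fb) - np.log(fa)) / np.sqrt(var_log_a + var_log_b)
    from scipy.stats import norm

    p = 2 * norm.sf(np.abs(z))
    untestable = (mu_a == 0) & (mu_b == 0)
    p = np.where(untestable, 1.0, p)
    z = np.where(untestable, 0.0, z)
    return z, p


def _rank_perm(a_vals: np.ndarray, b_vals: np.ndarray) -> np.ndarray:
    """Exact permutation test on replicate labels.

    All C(n_a+n_b, n_a) relabelings of the pooled samples (20 splits at
    3 vs 3); two-sided p is the fraction of splits whose absolute
    mean difference reaches the observed one.  The observed labeling is
    included, so the smallest attainable p is 1/#splits.
    """
    pooled = np.hstack([a_vals, b_vals])
    n_total = pooled.shape[1]
    n_a = a_vals.shape[1]
    obs = np.abs(b_vals.mean(axis=1) - a_vals.mean(axis=1))
    stats = []
    for combo in itertools.combinations(range(n_total), n_a):
        mask = np.zeros(n_total, dtype=bool)
        mask[list(combo)] = True
        stats.append(np.abs(pooled[:, ~mask].mean(axis=1) - pooled[:, mask].mean(axis=1)))
    stat_matrix = np.stack(stats)  # splits x genes
    # tolerance guards against float jitter when comparing equal statistics
    hits = (stat_matrix >= obs[None, :] - 1e-12).sum(axis=0)
    return hits / stat_matrix.shape[0]


def test_de(
    study: ExpressionStudy,
    phase_a: str,
    phase_b: str,
    method: str = "nb_wald",
) -> pd.DataFrame:
    """Test every gene for differential expression between two phases.

    Returns one record per gene with columns ``gene``, ``comparison``,
    ``log2fc`` (log2 of (mean_b+1)/(mean_a+1) of normalized abundance),
    ``p``, ``q`` (BH across genes), per-phase means, ``direction`` (the
    upregulated phase, consistent with the sign of log2fc) and
    ``untestable`` for all-zero rows.
    """
    if method not in ("nb_wald", "rank_perm", "both"):
        raise ValueError(f"unknown method {method!r}")
    for ph in (phase_a, phase_b):
        if ph not in set(study.meta["phase"]):
            raise ValueError(f"phase {ph!r} absent from study")
    a_cols = study.samples_for(phase_a)
    b_cols = study.samples_for(phase_b)
    a_vals = study.norm[a_cols].to_numpy(dtype=float)
    b_vals = study.norm[b_cols].to_numpy(dtype=float)

    if method in ("nb_wald", "both"):
        _, p_nb = _nb_wald(a_vals, b_vals)
    if method in ("rank_perm", "both"):
        p_perm = _rank_perm(a_vals, b_vals)
    if method == "nb_wald":
        p = p_nb
    elif method == "rank_perm":
        p = p_perm
    else:
        # intersection rule: significant only when both routes are
        p = np.maximum(p_nb, p_perm)

    mu_a = a_vals.mean(axis=1)
    mu_b = b_vals.mean(axis=1)
    log2fc = np.log2((mu_b + 1.0) / (mu_a + 1.0))
    untestable = (mu_a == 0) & (mu_b == 0)
    p = np.where(untestable, 1.0, p)
    q = bh_adjust(p)
    direction = np.where(log2fc > 0, phase_b, np.where(log2fc < 0, phase_a, "none"))
    return pd.DataFrame(
        {
            "gene": study.counts.index,
            "comparison": f"{phase_a}_vs_{phase_b}",
            "log2fc": log2fc,
            "p": p,
            "q": q,
            f"mean_{phase_a}": mu_a,
            f"mean_{phase_b}": mu_b,
            "mean_a": mu_a,
            "mean_b": mu_b,
            "direction": direction,
            "untestable": untestable,
        }
    ).reset_index(drop=True)


def filter_degs(
    records: pd.DataFrame,
    q_max: float = 0.05,
    min_abs_log2fc: float = 1.0,
    min_abundance: float = 5.0,
) -> pd.DataFrame:
    """Apply the DEG thresholds, boundary-inclusive exactly as printed.

    Kept iff q < q_max AND |log2FC| >= min_abs_log2fc AND the larger of
    the two phase means >= min_abundance (a gene expressed in only one
    phase stays testable).
    """
    keep = (
        (records["q"] < q_max)
        & (records["log2fc"].abs() >= min_abs_log2fc)
        & (records[["mean_a", "mean_b"]].max(axis=1) >= min_abundance)
        & ~records["untestable"]
    )
    return records[keep].reset_index(drop=True)


def upregulation_summary(deg_sets: dict[str, pd.DataFrame]) -> dict:
    """Venn partition and per-direction upregulation percentages.

    ``deg_sets`` maps comparison name to its filtered DEG table.  The
    universe is the union of genes over all comparisons (the species'
    DEG/DEC universe); percentages are taken over it.  The Venn partition
    over comparison membership is exhaustive and disjoint.
    """
    universe: set[str] = set()
    members: dict[str, set[str]] = {}
    for comp, table in deg_sets.items():
        genes = set(table["gene"])
        members[comp] = genes
        universe |= genes
    total = len(universe)

    comparisons = sorted(members)
    venn: dict[str, int] = {}
    for r in range(1, len(comparisons) + 1):
        for subset in itertools.combinations(comparisons, r):
            inside = set.intersection(*(members[c] for c in subset)) if subset else set()
            outside = set.union(
                *(members[c] for c in comparisons if c not in subset), set()
            )
            venn["&".join(subset)] = len(inside - outside)

    directions: dict[str, dict] = {}
    for comp, table in deg_sets.items():
        for phase, sub in table.groupby("direction"):
            if phase == "none":
                continue
            key = f"{comp}:{phase}_up"
            count = int(sub["gene"].nunique())
            directions[key] = {
                "count": count,
                "percent": 100.0 * count / total if total else 0.0,
            }
    return {
        "universe_size": total,
        "venn": venn,
        "directions": directions,
    }


def compare_proportions(
    summary_a: dict, summary_b: dict, category: str
) -> tuple[float, float]:
    """Two-proportion z-test on one upregulation category between species.

    The category count is taken over each species' DEG universe.
    """
    try:
        k1 = summary_a["directions"][category]["count"]
        k2 = summary_b["directions"][category]["count"]
    except KeyError as exc:
        raise KeyError(f"category {category!r} missing from summary") from exc
    n1 = summary_a["universe_size"]
    n2 = summary_b["universe_size"]
    return two_proportion_z(k1, n1, k2, n2)
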