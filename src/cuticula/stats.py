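"""Shared statistical primitives.

Every analysis stage funnels its inference through this module: Pearson
correlation with the t-transform p-value, the pooled two-proportion z-test,
Benjamini–Hochberg adjustment, the Shapiro–Wilk normality gate, one-way
ANOVA with Tukey's HSD, Kruskal–Wallis with the Conover–Iman post hoc and
Bonferroni correction, Student's t, and the compact-letter display that
turns an all-pairs significance matrix into the lowercase letters used to
annotate group comparisons.

All tests are two-tailed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationResult",
    "PairwiseLetters",
    "DegenerateDataError",
    "pearson",
    "two_proportion_z",
    "bh_adjust",
    "shapiro_wilk",
    "students_t",
    "anova_tukey",
    "kruskal_conover",
    "compact_letter_display",
]


class DegenerateDataError(ValueError):
    """Raised when the requested statistic is undefined for the input."""


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation between two paired sequences.

    Attributes
    ----------
    r : product-moment correlation coefficient in [-1, 1].
    n : number of paired observations.
    p : two-tailed p-value from t = r*sqrt((n-2)/(1-r^2)) on n-2 df.
    """

    r: float
    n: int
    p: float

    def to_dict(self) -> dict:
        return {"r": self.r, "n": self.n, "p": self.p}


@dataclass(frozen=True)
class PairwiseLetters:
    """Compact-letter display over an all-pairs comparison.

    Two groups share a letter iff their pairwise comparison was not
    significant at ``alpha``.  ``pvalues[i, j]`` is the (adjusted, where a
    correction applies) p-value for groups ``groups[i]`` vs ``groups[j]``.
    """

    groups: tuple[str, ...]
    letters: Mapping[str, str]
    pvalues: np.ndarray
    alpha: float
    test: str = ""
    statistics: Mapping[str, float] = field(default_factory=dict)

    def share_letter(self, a: str, b: str) -> bool:
        return bool(set(self.letters[a]) & set(self.letters[b]))

    def to_dict(self) -> dict:
        return {
            "groups": list(self.groups),
            "letters": dict(self.letters),
            "pvalues": self.pvalues.tolist(),
            "alpha": self.alpha,
            "test": self.test,
            "statistics": dict(self.statistics),
        }


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if np.any(~np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment correlation with its two-tailed p-value.

    Requires equal lengths >= 3 and non-zero variance in both sequences;
    a constant input raises :class:`DegenerateDataError` rather than
    silently returning NaN.
    """
    xa = _as_float_array(x, "x")
    ya = _as_float_array(y, "y")
    if len(xa) != len(ya):
        raise ValueError("x and y must have equal length")
    n = len(xa)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise DegenerateDataError("correlation undefined for zero-variance input")
    r, p = sps.pearsonr(xa, ya)
    return CorrelationResult(r=float(r), n=n, p=float(p))


def two_proportion_z(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z-test, two-tailed.

    z = (p1 - p2) / sqrt(p*(1-p*)(1/n1 + 1/n2)) with p* the pooled
    proportion (k1+k2)/(n1+n2).
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0:
            raise ValueError("sample sizes must be positive")
        if not 0 <= k <= n:
            raise ValueError("counts must satisfy 0 <= k <= n")
    pooled = (k1 + k2) / (n1 + n2)
    if pooled == 0.0 or pooled == 1.0:
        raise DegenerateDataError("pooled proportion is degenerate (0 or 1)")
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (k1 / n1 - k2 / n2) / se
    p = 2 * sps.norm.sf(abs(z))
    return float(z), float(p)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, order-preserving."""
    pa = _as_float_array(pvals, "pvals")
    if len(pa) == 0:
        return pa
    return multipletests(pa, method="fdr_bh")[1]


def shapiro_wilk(values: Sequence[float]) -> tuple[float, float]:
    va = _as_float_array(values, "values")
    if np.ptp(va) == 0:
        raise DegenerateDataError("Shapiro-Wilk undefined for constant data")
    w, p = sps.shapiro(va)
    return float(w), float(p)


def students_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sample Student's t (pooled variance), two-tailed."""
    aa = _as_float_array(a, "a")
    ba = _as_float_array(b, "b")
    if len(aa) < 2 or len(ba) < 2:
        raise ValueError("each sample needs at least 2 observations")
    t, p = sps.ttest_ind(aa, ba, equal_var=True)
    if np.isnan(t):  # both samples constant and equal
        raise DegenerateDataError("t-test undefined for zero pooled variance")
    return float(t), float(p)


def compact_letter_display(
    groups: Sequence[str], significant: np.ndarray
) -> dict[str, str]:
    """Insert-and-absorb compact-letter display.

    Parameters
    ----------
    groups : group labels; letter order follows this order.
    significant : boolean matrix, ``significant[i, j]`` True when groups i
        and j differ significantly.

    Two groups share a letter iff their comparison is non-significant —
    the display reproduces exactly the significance matrix it was built
    from.
    """
    k = len(groups)
    sig = np.asarray(significant, dtype=bool)
    if sig.shape != (k, k):
        raise ValueError("significance matrix shape mismatch")
    # columns are sets of group indices that may share a letter
    columns: list[set[int]] = [set(range(k))]
    for i, j in itertools.combinations(range(k), 2):
        if not sig[i, j]:
            continue
        for col in [c for c in columns if i in c and j in c]:
            columns.remove(col)
            columns.append(col - {i})
            columns.append(col - {j})
        # absorb: drop columns contained in another
        columns = [
            c
            for c in columns
            if c and not any(c < other for other in columns)
        ]
        # deduplicate while keeping order
        seen: list[set[int]] = []
        for c in columns:
            if c not in seen:
                seen.append(c)
        columns = seen
    # deterministic letter ordering: sort columns by smallest member index
    columns.sort(key=lambda c: (min(c), sorted(c)))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for pos, col in enumerate(columns):
        letter = alphabet[pos % len(alphabet)] * (1 + pos // len(alphabet))
        for i in sorted(col):
            letters[groups[i]] += letter
    return letters


def _validate_groups(groups: Sequence[Sequence[float]], min_n: int = 2) -> list[np.ndarray]:
    arrays = [_as_float_array(g, f"group {i}") for i, g in enumerate(groups)]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for i, g in enumerate(arrays):
        if len(g) < min_n:
            raise ValueError(f"group {i} has fewer than {min_n} observations")
    return arrays


def anova_tukey(
    groups: Sequence[Sequence[float]],
    alpha: float = 0.05,
    labels: Sequence[str] | None = None,
) -> PairwiseLetters:
    """One-way ANOVA followed by Tukey's HSD over all pairs.

    Pairwise p-values come from the studentized-range distribution; the
    letters encode the resulting significance matrix at ``alpha``.
    """
    arrays = _validate_groups(groups)
    k = len(arrays)
    names = tuple(labels) if labels is not None else tuple(f"g{i}" for i in range(k))
    f_stat, f_p = sps.f_oneway(*arrays)
    hsd = sps.tukey_hsd(*arrays)
    pmat = np.asarray(hsd.pvalue, dtype=float)
    np.fill_diagonal(pmat, 1.0)
    letters = compact_letter_display(names, pmat < alpha)
    return PairwiseLetters(
        groups=names,
        letters=letters,
        pvalues=pmat,
        alpha=alpha,
        test="anova_tukey",
        statistics={"F": float(f_stat), "anova_p": float(f_p)},
    )


def conover_iman(
    groups: Sequence[Sequence[float]],
) -> tuple[np.ndarray, np.ndarray, float]:
    """Conover–Iman pairwise rank comparisons after Kruskal–Wallis.

    Ranks all observations jointly with midranks for ties, then compares
    rank means with t statistics using the pooled rank variance

        S^2 = (sum R_i^2 - N (N+1)^2 / 4) / (N - 1)

    scaled by (N - 1 - H)/(N - k), on N - k degrees of freedom, where H is
    the tie-corrected Kruskal–Wallis statistic.  Returns (t matrix, raw
    two-tailed p matrix, H).
    """
    arrays = _validate_groups(groups, min_n=1)
    k = len(arrays)
    pooled = np.concatenate(arrays)
    n_total = len(pooled)
    if np.ptp(pooled) == 0:
        raise DegenerateDataError("all values tied; rank test undefined")
    h_stat, _ = sps.kruskal(*arrays)
    ranks = sps.rankdata(pooled)
    sizes = np.array([len(g) for g in arrays])
    bounds = np.cumsum(sizes)
    rank_groups = np.split(ranks, bounds[:-1])
    rank_means = np.array([rg.mean() for rg in rank_groups])
    s2 = (np.sum(ranks**2) - n_total * (n_total + 1) ** 2 / 4) / (n_total - 1)
    df = n_total - k
    scale = s2 * (n_total - 1 - h_stat) / df
    tmat = np.zeros((k, k))
    pmat = np.ones((k, k))
    for i, j in itertools.combinations(range(k), 2):
        se = np.sqrt(scale * (1 / sizes[i] + 1 / sizes[j]))
        t = (rank_means[i] - rank_means[j]) / se
        p = 2 * sps.t.sf(abs(t), df)
        tmat[i, j] = t
        tmat[j, i] = -t
        pmat[i, j] = pmat[j, i] = p
    return tmat, pmat, float(h_stat)


def kruskal_conover(
    groups: Sequence[Sequence[float]],
    alpha: float = 0.05,
    labels: Sequence[str] | None = None,
    correction: str = "bonferroni",
) -> PairwiseLetters:
    """Kruskal–Wallis with the Conover–Iman post hoc and Bonferroni letters."""
    arrays = _validate_groups(groups)
    k = len(arrays)
    names = tuple(labels) if labels is not None else tuple(f"g{i}" for i in range(k))
    tmat, pmat, h_stat = conover_iman(arrays)
    _, kw_p = sps.kruskal(*arrays)
    if correction == "bonferroni":
        m = k * (k - 1) // 2
        padj = np.minimum(pmat * m, 1.0)
    elif correction == "none":
        padj = pmat.copy()
    else:
        raise ValueError(f"unknown correction: {correction!r}")
    np.fill_diagonal(padj, 1.0)
    letters = compact_letter_display(names, padj < alpha)
    return PairwiseLetters(
        groups=names,
        letters=letters,
        pvalues=padj,
        alpha=alpha,
        test="kruskal_conover",
        statistics={"H": h_stat, "kw_p": float(kw_p)},
    )
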