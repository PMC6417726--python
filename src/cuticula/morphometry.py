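"""Cuticle-thickness comparisons across developmental phases.

The decision tree mirrors how such measurement sets are analyzed:
exactly two phases -> Student's t-test; three or more phases -> a
Shapiro–Wilk gate on pooled per-phase-demeaned residuals chooses between
one-way ANOVA with Tukey's HSD (residuals normal) and Kruskal–Wallis
with the Conover–Iman post hoc and Bonferroni correction (residuals
non-normal).  Output is the compact-letter display: phases sharing a
letter do not differ significantly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import (
    DegenerateDataError,
    PairwiseLetters,
    anova_tukey,
    compact_letter_display,
    kruskal_conover,
    shapiro_wilk,
    students_t,
)

__all__ = ["validate_thickness", "choose_test", "compare_phases"]


def validate_thickness(data: pd.DataFrame) -> list[str]:
    """Check the (phase, thickness_um) table; returns the phase order."""
    if not {"phase", "thickness_um"} <= set(data.columns):
        raise ValueError("thickness table needs 'phase' and 'thickness_um' columns")
    if (data["thickness_um"] <= 0).any():
        raise ValueError("thickness measurements must be positive")
    phases = list(dict.fromkeys(data["phase"]))
    if len(phases) < 2:
        raise ValueError("need at least 2 phases")
    counts = data.groupby("phase")["thickness_um"].count()
    if (counts < 2).any():
        raise ValueError("each phase needs at least 2 measurements")
    return phases


def choose_test(data: pd.DataFrame, alpha: float = 0.05) -> str:
    """Pick the comparison branch for a thickness dataset.

    Two phases -> ``students_t`` regardless of normality.  Otherwise a
    single Shapiro–Wilk gate on pooled per-phase-demeaned residuals:
    p >= alpha -> ``anova_tukey``; p < alpha -> ``kruskal_conover``.
    Constant data raises (the normality test is undefined).
    """
    phases = validate_thickness(data)
    if len(phases) == 2:
        return "students_t"
    residuals = (
        data["thickness_um"] - data.groupby("phase")["thickness_um"].transform("mean")
    ).to_numpy(dtype=float)
    if np.ptp(residuals) == 0:
        raise DegenerateDataError("constant thickness data: normality gate undefined")
    _, sw_p = shapiro_wilk(residuals)
    return "anova_tukey" if sw_p >= alpha else "kruskal_conover"


def compare_phases(data: pd.DataFrame, alpha: float = 0.05) -> tuple[PairwiseLetters, dict]:
    """Run the chosen branch and emit letters plus a test report."""
    phases = validate_thickness(data)
    branch = choose_test(data, alpha)
    groups = [
        data.loc[data["phase"] == ph, "thickness_um"].to_numpy(dtype=float)
        for ph in phases
    ]
    report: dict = {"branch": branch, "alpha": alpha, "phases": phases}
    if branch == "students_t":
        t, p = students_t(groups[0], groups[1])
        sig = np.array([[False, p < alpha], [p < alpha, False]])
        letters = PairwiseLetters(
            groups=tuple(phases),
            letters=compact_letter_display(phases, sig),
            pvalues=np.array([[1.0, p], [p, 1.0]]),
            alpha=alpha,
            test="students_t",
            statistics={"t": t, "p": p},
        )
    elif branch == "anova_tukey":
        letters = anova_tukey(groups, alpha=alpha, labels=phases)
    else:
        letters = kruskal_conover(groups, alpha=alpha, labels=phases)
    report["statistics"] = dict(letters.statistics)
    report["letters"] = dict(letters.letters)
    return letters, report
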