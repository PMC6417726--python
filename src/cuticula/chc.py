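"""Cuticular hydrocarbon quantification from GC-MS peak tables.

Relative profiles are percent-of-total peak area per individual (over
all compounds or per CHC class).  Absolute amounts (micrograms per bee)
come from internal-standard calibration: a line, amount = a * (analyte
area / internal-standard area) + b, is fitted per n-alkane standard
(C23, C25, C32) over a 6-level series, each compound is assigned a curve
by carbon number (<= C24 -> C23; C25–C29 -> C25; C30–C35 -> C32), and
predicted extract concentrations are scaled by extract volume and
divided by the pool size.  Per-peak and per-class phase comparisons use
ANOVA with Tukey's HSD; a PCA on the percent table ranks the compounds
driving phase separation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress
from sklearn.decomposition import PCA

from .stats import PairwiseLetters, anova_tukey

__all__ = [
    "CalibrationCurve",
    "normalize_relative",
    "fit_calibration",
    "assign_curve",
    "absolute_quantify",
    "per_peak_phase_test",
    "per_class_phase_test",
    "pca_loadings",
]

logger = logging.getLogger(__name__)

CHC_CLASSES = ("n_alkane", "unsaturated", "branched")


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted amount-vs-area-ratio calibration line for one standard."""

    standard_id: str
    slope: float
    intercept: float
    r: float
    level_range: tuple[float, float]
    n_levels: int

    def predict(self, area_ratio: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(area_ratio, dtype=float) + self.intercept


def _check_peak_table(table: pd.DataFrame) -> None:
    required = {"individual_id", "phase", "compound_id", "area", "is_area"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"peak table missing columns: {sorted(missing)}")
    if (table["area"] < 0).any():
        raise ValueError("peak areas must be >= 0")
    if (table["is_area"] <= 0).any():
        raise ValueError("internal-standard area must be > 0 in every run")
    dup = table.duplicated(["individual_id", "compound_id"])
    if dup.any():
        raise ValueError("one row per (individual, compound) required")


def normalize_relative(table: pd.DataFrame, scope: str = "all") -> pd.DataFrame:
    """Percent-of-total peak areas per individual.

    ``scope="all"`` normalizes over every compound of the individual;
    ``scope="per_class"`` restricts the denominator to each compound's
    class (requires a ``compound_class`` column).  The result carries a
    ``percent`` column summing to 100 per individual (per class).
    """
    _check_peak_table(table)
    if scope not in ("all", "per_class"):
        raise ValueError("scope must be 'all' or 'per_class'")
    out = table.copy()
    keys = ["individual_id"] if scope == "all" else ["individual_id", "compound_class"]
    if scope == "per_class" and "compound_class" not in table.columns:
        raise ValueError("per_class scope requires a compound_class column")
    totals = out.groupby(keys)["area"].transform("sum")
    if (totals == 0).any():
        raise ValueError("individual with all-zero areas cannot be normalized")
    out["percent"] = 100.0 * out["area"] / totals
    return out


def fit_calibration(standards: pd.DataFrame) -> dict[str, CalibrationCurve]:
    """Ordinary least squares of known amount on analyte/IS area ratio.

    ``standards`` needs columns ``standard_id``, ``level_ug_ml``,
    ``area``, ``is_area`` with at least 3 levels per standard.  Returns a
    curve per standard with slope a, intercept b and Pearson R of the
    fit.
    """
    required = {"standard_id", "level_ug_ml", "area", "is_area"}
    missing = required - set(standards.columns)
    if missing:
        raise ValueError(f"standards table missing columns: {sorted(missing)}")
    curves: dict[str, CalibrationCurve] = {}
    for std_id, sub in standards.groupby("standard_id"):
        if len(sub) < 3:
            raise ValueError(f"standard {std_id}: need >= 3 levels")
        ratio = (sub["area"] / sub["is_area"]).to_numpy(dtype=float)
        amount = sub["level_ug_ml"].to_numpy(dtype=float)
        if np.ptp(ratio) == 0:
            raise ValueError(f"standard {std_id}: zero-variance area ratios")
        fit = linregress(ratio, amount)
        curves[str(std_id)] = CalibrationCurve(
            standard_id=str(std_id),
            slope=float(fit.slope),
            intercept=float(fit.intercept),
            r=float(fit.rvalue),
            level_range=(float(amount.min()), float(amount.max())),
            n_levels=len(sub),
        )
    return curves


def assign_curve(carbon_n: int) -> str:
    """Standard curve for a compound's carbon number.

    Compounds up to C24 use the C23 curve, C25 through C29 the C25
    curve, and larger than C29 up to C35 the C32 curve.
    """
    if not 20 <= carbon_n <= 35:
        raise ValueError(
            f"carbon number {carbon_n} outside [20, 35]: no assignable curve"
        )
    if carbon_n <= 24:
        return "C23"
    if carbon_n <= 29:
        return "C25"
    return "C32"


def absolute_quantify(
    table: pd.DataFrame,
    curves: dict[str, CalibrationCurve],
    pool_size: int = 1,
    extract_volume_ul: float = 160.0,
) -> pd.DataFrame:
    """Micrograms per bee per compound via inverse calibration prediction.

    Per row: predicted extract concentration (ug/ml) = a * area ratio + b
    for the curve assigned by carbon number, times the extract volume,
    divided by ``pool_size`` (pooled extracts report per-bee values).
    Negative predictions (area below the calibration blank) are clamped
    to zero with a warning and flagged ``below_quantification``.
    """
    _check_peak_table(table)
    if "carbon_n" not in table.columns:
        raise ValueError("absolute quantification requires a carbon_n column")
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    out = table.copy()
    volume_ml = extract_volume_ul / 1000.0
    ratio = out["area"] / out["is_area"]
    conc = np.empty(len(out), dtype=float)
    for curve_id, idx in out.groupby(out["carbon_n"].map(assign_curve)).groups.items():
        if curve_id not in curves:
            raise KeyError(f"no fitted calibration curve {curve_id!r}")
        conc[out.index.get_indexer(idx)] = curves[curve_id].predict(ratio.loc[idx])
    ug_extract = conc * volume_ml
    below = ug_extract < 0
    if below.any():
        logger.warning(
            "%d peak(s) predicted below the calibration blank; clamped to 0",
            int(below.sum()),
        )
    out["below_quantification"] = below
    out["ug_per_bee"] = np.clip(ug_extract, 0.0, None) / pool_size
    return out


def class_totals(quantified: pd.DataFrame, classes=("n_alkane", "unsaturated")) -> pd.DataFrame:
    """Per-individual class totals of absolute amounts (ug per bee)."""
    if "compound_class" not in quantified.columns:
        raise ValueError("class totals require a compound_class column")
    sub = quantified[quantified["compound_class"].isin(classes)]
    totals = (
        sub.groupby(["individual_id", "phase", "compound_class"])["ug_per_bee"]
        .sum()
        .reset_index()
    )
    return totals


def _letters_by_group(
    frame: pd.DataFrame, value_col: str, alpha: float, phase_order: list[str]
) -> PairwiseLetters:
    groups = [
        frame.loc[frame["phase"] == ph, value_col].to_numpy(dtype=float)
        for ph in phase_order
    ]
    return anova_tukey(groups, alpha=alpha, labels=phase_order)


def per_peak_phase_test(
    relative: pd.DataFrame, alpha: float = 0.05
) -> dict[str, PairwiseLetters]:
    """Tukey's HSD on each compound's percent area across phases."""
    if "percent" not in relative.columns:
        raise ValueError("run normalize_relative first (percent column missing)")
    phase_order = list(dict.fromkeys(relative["phase"]))
    out: dict[str, PairwiseLetters] = {}
    for cid, sub in relative.groupby("compound_id", sort=False):
        out[str(cid)] = _letters_by_group(sub, "percent", alpha, phase_order)
    return out


def per_class_phase_test(
    totals: pd.DataFrame, alpha: float = 0.05
) -> dict[str, PairwiseLetters]:
    """Tukey's HSD on per-class absolute totals across phases."""
    if "ug_per_bee" not in totals.columns:
        raise ValueError("run absolute_quantify / class_totals first")
    phase_order = list(dict.fromkeys(totals["phase"]))
    out: dict[str, PairwiseLetters] = {}
    for cls, sub in totals.groupby("compound_class", sort=False):
        out[str(cls)] = _letters_by_group(sub, "ug_per_bee", alpha, phase_order)
    return out


def percent_matrix(relative: pd.DataFrame) -> pd.DataFrame:
    """Individuals x compounds percent matrix (clustering / PCA input)."""
    return relative.pivot_table(
        index="individual_id", columns="compound_id", values="percent", fill_value=0.0
    )


def pca_loadings(percent_table: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Column-centered PCA of an individuals x compounds percent matrix.

    Returns the loadings (compounds x components, ranked by absolute
    loading within each component in the ``rank_pc1`` column ordering)
    and the explained-variance fractions (non-increasing, summing to 1).
    """
    matrix = percent_table.to_numpy(dtype=float)
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 individuals for PCA")
    n_comp = min(matrix.shape[0] - 1, matrix.shape[1])
    pca = PCA(n_components=n_comp)
    pca.fit(matrix)
    loadings = pd.DataFrame(
        pca.components_.T,
        index=percent_table.columns,
        columns=[f"PC{i + 1}" for i in range(n_comp)],
    )
    loadings["rank_pc1"] = (
        loadings["PC1"].abs().rank(ascending=False, method="first").astype(int)
    )
    return loadings, pca.explained_variance_ratio_
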