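"""Seeded synthetic inputs emulating the comparative study design.

Three generators produce the inputs the pipeline consumes, each with a
ground-truth record so every downstream estimator can be checked against
planted parameters:

* ``generate_expression`` — negative-binomial gene-by-sample count
  matrices for three species (two eusocial, one solitary), 3 developmental
  phases (Pbm, Ne, Fg) x 3 replicates, with genes planted into profile
  classes (shared eusocial-heterochronic shape, all-species shared,
  solitary-shifted, species-specific, flat) and a cross-species ortholog
  map in which a configurable fraction of solitary-species orthologs is
  absent.
* ``generate_chc`` — GC-MS peak tables (per-individual compound peak
  areas with an internal-standard area per run) plus a 6-level n-alkane
  standard series, generated by inverting a true calibration line so the
  quantification stage can round-trip the planted microgram amounts.
* ``generate_thickness`` — per-phase cuticle-thickness samples with
  normal or lognormal noise at requested moments.

All randomness flows through one :class:`numpy.random.Generator` seeded
from the config, so identical config+seed gives byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PHASES",
    "SPECIES",
    "ExpressionSimConfig",
    "ChcSimConfig",
    "GroundTruth",
    "generate_expression",
    "generate_chc",
    "generate_thickness",
    "default_compound_roster",
    "default_chc_amounts",
]

PHASES: tuple[str, ...] = ("Pbm", "Ne", "Fg")
#: species 1 and 2 are the eusocial pair, species 3 the solitary contrast
SPECIES: tuple[str, ...] = ("eusocialA", "eusocialB", "solitary")

DEFAULT_CLASS_FRACTIONS: dict[str, float] = {
    "eusocial_heterochronic": 0.25,
    "all_shared": 0.15,
    "solitary_shifted": 0.15,
    "species_specific": 0.15,
    "flat": 0.30,
}


@dataclass(frozen=True)
class ExpressionSimConfig:
    """Configuration for the expression-count generator.

    ``dispersion`` is the negative-binomial dispersion alpha in the
    mean–dispersion form, variance = mu + alpha * mu^2; alpha = 0 makes
    the counts deterministic (each count equals its class mean, rounded).
    ``fold_change`` is the planted effect multiplier between the low and
    high phases of a non-flat profile.
    """

    n_genes: int = 2000
    species: tuple[str, ...] = SPECIES
    phases: tuple[str, ...] = PHASES
    n_reps: int = 3
    baseline_mean: float = 500.0
    dispersion: float = 0.1
    fold_change: float = 4.0
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS)
    )
    ortholog_absent_fraction: float = 0.05
    heterochronic_solitary_mode: str = "inverted"  # or "flat"
    seed: int = 0

    def validate(self) -> None:
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2 (downstream tests undefined)")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        fracs = np.array(list(self.class_fractions.values()), dtype=float)
        if np.any(fracs < 0):
            raise ValueError("class fractions must be >= 0")
        if abs(fracs.sum() - 1.0) > 1e-9:
            raise ValueError("class fractions must sum to 1 within 1e-9")
        if not 0 <= self.ortholog_absent_fraction <= 1:
            raise ValueError("ortholog_absent_fraction must be in [0, 1]")
        if self.heterochronic_solitary_mode not in ("inverted", "flat"):
            raise ValueError("heterochronic_solitary_mode must be 'inverted' or 'flat'")
        if len(self.species) != 3:
            raise ValueError("the design assumes exactly 3 species")


@dataclass(frozen=True)
class ChcSimConfig:
    """Configuration for the GC-MS peak-table generator.

    ``amounts`` maps (compound_id, phase) to the true per-bee amount in
    micrograms.  Areas are produced by inverting the true calibration
    (amount-as-concentration = a * area_ratio + b for the curve assigned
    to the compound's carbon number) and applying mean-one multiplicative
    lognormal noise at ``peak_cv``.  ``pool_size`` bees contribute to each
    extract (3 emulates the small-bodied eusocial species).
    """

    species: str = "eusocialA"
    phase_n: Mapping[str, int] = field(
        default_factory=lambda: {"Pbm": 15, "Ne": 15, "Fg": 15}
    )
    compounds: tuple[tuple[str, str, int], ...] = ()  # (id, class, carbon_n)
    amounts: Mapping[tuple[str, str], float] = field(default_factory=dict)
    standard_levels: tuple[float, ...] = (1.25, 2.5, 5.0, 10.0, 15.0, 20.0)
    standard_true: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"C23": (2.0, 0.05), "C25": (2.2, 0.05), "C32": (2.5, 0.05)}
    )
    internal_standard_area: float = 100_000.0
    peak_cv: float = 0.10
    standard_cv: float = 0.02
    pool_size: int = 1
    extract_volume_ul: float = 160.0
    seed: int = 0

    def __post_init__(self):
        if not self.compounds:
            object.__setattr__(self, "compounds", default_compound_roster())
        if not self.amounts:
            object.__setattr__(
                self, "amounts", default_chc_amounts(self.compounds)
            )

    def validate(self) -> None:
        levels = np.array(self.standard_levels, dtype=float)
        if np.any(levels <= 0) or np.any(np.diff(levels) <= 0):
            raise ValueError("standard levels must be strictly increasing and positive")
        if self.peak_cv < 0 or self.standard_cv < 0:
            raise ValueError("noise CV must be >= 0")
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        if self.extract_volume_ul <= 0:
            raise ValueError("extract volume must be positive")
        for cid, cls, carbon in self.compounds:
            if cls not in ("n_alkane", "unsaturated", "branched"):
                raise ValueError(f"unknown compound class {cls!r} for {cid}")
            if not 20 <= carbon <= 35:
                raise ValueError(
                    f"compound {cid}: carbon number {carbon} outside [20, 35]; "
                    "no calibration curve is assignable"
                )
        for (cid, phase) in self.amounts:
            if phase not in self.phase_n:
                raise ValueError(f"amount given for unknown phase {phase!r}")


@dataclass
class GroundTruth:
    """Planted parameters: one truth record per generated entity."""

    gene_classes: dict[str, str] = field(default_factory=dict)
    absent_in_solitary: set[str] = field(default_factory=set)
    gene_phase_means: dict[tuple[str, str, str], float] = field(default_factory=dict)
    chc_amounts: dict[tuple[str, str], float] = field(default_factory=dict)
    calibration: dict[str, tuple[float, float]] = field(default_factory=dict)
    thickness: dict[str, tuple[float, float, str]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "gene_classes": self.gene_classes,
            "absent_in_solitary": sorted(self.absent_in_solitary),
            "chc_amounts": {f"{c}|{p}": a for (c, p), a in self.chc_amounts.items()},
            "calibration": {k: list(v) for k, v in self.calibration.items()},
            "thickness": {k: list(v) for k, v in self.thickness.items()},
        }


def default_compound_roster() -> tuple[tuple[str, str, int], ...]:
    """A small realistic CHC roster: n-alkanes C23–C31, three alkenes,
    three methyl-branched alkanes, all within the C20–C35 calibration
    range."""
    roster = [
        ("C23", "n_alkane", 23),
        ("C25", "n_alkane", 25),
        ("C27", "n_alkane", 27),
        ("C29", "n_alkane", 29),
        ("C31", "n_alkane", 31),
        ("C27:1", "unsaturated", 27),
        ("C29:1", "unsaturated", 29),
        ("C31:1", "unsaturated", 31),
        ("3-MeC25", "branched", 26),
        ("11-MeC27", "branched", 28),
        ("13-MeC29", "branched", 30),
    ]
    return tuple(roster)


def default_chc_amounts(
    compounds: Sequence[tuple[str, str, int]],
    pattern: str = "eusocial",
) -> dict[tuple[str, str], float]:
    """Default per-bee microgram amounts per phase.

    ``pattern="eusocial"`` follows the late-maturation profile reported
    for the eusocial species' absolute quantification: n-alkanes roughly
    9/7/18 ug across Pbm/Ne/Fg and unsaturated compounds strongly
    forager-enriched, so the forager composition stands apart while Pbm
    and Ne stay similar.  ``pattern="solitary"`` emulates the
    early-maturing solitary profile: amounts rise between the pharate
    and newly-emerged phases and stay similar from emergence to
    foraging.  Totals are split evenly over the compounds of each class.
    """
    if pattern == "eusocial":
        class_totals = {
            "n_alkane": {"Pbm": 9.0, "Ne": 7.5, "Fg": 18.0},
            "unsaturated": {"Pbm": 0.6, "Ne": 0.9, "Fg": 6.5},
            "branched": {"Pbm": 2.0, "Ne": 2.2, "Fg": 4.0},
        }
    elif pattern == "solitary":
        class_totals = {
            "n_alkane": {"Pbm": 6.5, "Ne": 14.8, "Fg": 13.3},
            "unsaturated": {"Pbm": 9.2, "Ne": 19.2, "Fg": 28.3},
            "branched": {"Pbm": 2.0, "Ne": 3.0, "Fg": 3.2},
        }
    else:
        raise ValueError("pattern must be 'eusocial' or 'solitary'")
    by_class: dict[str, list[str]] = {}
    for cid, cls, _ in compounds:
        by_class.setdefault(cls, []).append(cid)
    amounts: dict[tuple[str, str], float] = {}
    for cls, ids in by_class.items():
        for phase, total in class_totals[cls].items():
            for cid in ids:
                amounts[(cid, phase)] = total / len(ids)
    return amounts


# ---------------------------------------------------------------------------
# expression


def _gene_shapes(
    cls: str, variant: int, config: ExpressionSimConfig
) -> list[np.ndarray]:
    """Per-species phase multiplier vectors (Pbm, Ne, Fg) for one gene.

    Each planted class comes in two mirrored variants (``variant`` 0/1):
    a shape and its elementwise fold-change mirror (genes upregulated in
    the young phases and genes upregulated in foragers both occur), so
    library composition stays balanced across phases and a mirrored
    shape is perfectly anti-correlated with its base shape.
    """
    fc = config.fold_change
    up_young = np.array([fc, 1.0, 1.0])   # high in pharate adults
    up_mid = np.array([1.0, fc, 1.0])     # high at emergence
    up_old = np.array([1.0, 1.0, fc])     # high in foragers
    flat = np.ones(3)

    def pick(shape: np.ndarray) -> np.ndarray:
        return shape if variant == 0 else fc / shape

    if cls == "eusocial_heterochronic":
        shared = pick(up_young)
        if config.heterochronic_solitary_mode == "flat":
            solitary = flat
        else:
            solitary = fc / shared  # anti-correlated with the shared shape
        return [shared, shared, solitary]
    if cls == "all_shared":
        s = pick(up_old)
        return [s, s, s]
    if cls == "solitary_shifted":
        return [flat, flat, pick(up_mid)]
    if cls == "species_specific":
        return [pick(up_young), pick(up_mid), pick(up_old)]
    if cls == "flat":
        return [flat, flat, flat]
    raise ValueError(f"unknown profile class {cls!r}")


def _class_assignment(config: ExpressionSimConfig) -> list[str]:
    """Deterministic per-class gene counts: round(fraction * n_genes),
    with the largest class absorbing the rounding remainder."""
    names = list(config.class_fractions)
    counts = {c: int(round(config.class_fractions[c] * config.n_genes)) for c in names}
    delta = config.n_genes - sum(counts.values())
    largest = max(names, key=lambda c: (config.class_fractions[c], c))
    counts[largest] += delta
    labels: list[str] = []
    for c in names:
        labels.extend([c] * counts[c])
    return labels[: config.n_genes]


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """Negative-binomial counts in the mean–dispersion form.

    variance = mu + alpha * mu^2; alpha = 0 returns the rounded means
    (deterministic degenerate case)."""
    if alpha == 0:
        return np.round(mean).astype(np.int64)
    size_param = 1.0 / alpha
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p).astype(np.int64)


def generate_expression(config: ExpressionSimConfig):
    """Generate per-species expression studies, an ortholog map, and truth.

    Returns ``(studies, ortholog_map, truth)`` where ``studies`` maps
    species name to an :class:`~cuticula.de.ExpressionStudy`,
    ``ortholog_map`` is a DataFrame with one ID column per species (empty
    string marks an ortholog not identified in that species), and
    ``truth`` records each gene's planted class.
    """
    from .de import ExpressionStudy  # local import avoids a cycle

    config.validate()
    rng = np.random.default_rng(config.seed)
    labels = _class_assignment(config)
    # mirrored variants alternate within each class, keeping composition
    # balanced across phases
    class_counter: dict[str, int] = {}
    variants: list[int] = []
    for cls in labels:
        k = class_counter.get(cls, 0)
        variants.append(k % 2)
        class_counter[cls] = k + 1
    shapes = [_gene_shapes(cls, v, config) for cls, v in zip(labels, variants)]
    truth = GroundTruth()

    gene_base = [f"g{i:05d}" for i in range(config.n_genes)]
    for g, cls in zip(gene_base, labels):
        truth.gene_classes[g] = cls

    studies: dict[str, ExpressionStudy] = {}
    for s_idx, sp in enumerate(config.species):
        gene_ids = [f"{sp}_{g}" for g in gene_base]
        sample_ids = [
            f"{sp}_{ph}_{r + 1}"
            for ph in config.phases
            for r in range(config.n_reps)
        ]
        meta = pd.DataFrame(
            {
                "sample_id": sample_ids,
                "species": sp,
                "phase": [ph for ph in config.phases for _ in range(config.n_reps)],
                "replicate": [r + 1 for _ in config.phases for r in range(config.n_reps)],
            }
        )
        mult = np.stack([sh[s_idx] for sh in shapes])  # genes x phases
        means = config.baseline_mean * mult  # genes x phases
        for gi, g in enumerate(gene_base):
            for pi, ph in enumerate(config.phases):
                truth.gene_phase_means[(sp, g, ph)] = float(means[gi, pi])
        mean_matrix = np.repeat(means, config.n_reps, axis=1)  # genes x samples
        counts = _nb_draw(rng, mean_matrix, config.dispersion)
        counts_df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
        studies[sp] = ExpressionStudy.from_counts(sp, counts_df, meta)

    # ortholog map: one row per base gene; solitary member may be absent
    absent = rng.random(config.n_genes) < config.ortholog_absent_fraction
    rows = []
    for gi, g in enumerate(gene_base):
        row = {config.species[0]: f"{config.species[0]}_{g}",
               config.species[1]: f"{config.species[1]}_{g}",
               config.species[2]: "" if absent[gi] else f"{config.species[2]}_{g}"}
        rows.append(row)
        if absent[gi]:
            truth.absent_in_solitary.add(g)
    ortholog_map = pd.DataFrame(rows, columns=list(config.species))
    return studies, ortholog_map, truth


# ---------------------------------------------------------------------------
# CHC


def _lognormal_factor(rng: np.random.Generator, cv: float, size=()) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=size)


def _curve_for_carbon(carbon_n: int) -> str:
    # mirror of chc.assign_curve, duplicated here so the generator does not
    # depend on the quantification stage it is meant to test
    if not 20 <= carbon_n <= 35:
        raise ValueError(f"carbon number {carbon_n} outside [20, 35]")
    if carbon_n <= 24:
        return "C23"
    if carbon_n <= 29:
        return "C25"
    return "C32"


def generate_chc(config: ChcSimConfig):
    """Generate a peak table, a standard series, and the truth record.

    Peak areas are built by exact inversion of the true calibration line
    for each compound's assigned curve: the per-extract concentration
    (true per-bee amount x pool_size / extract volume) is mapped to an
    analyte/internal-standard area ratio and multiplied by lognormal
    noise, so zero-noise data round-trips exactly through the
    quantification stage.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth()
    truth.calibration = {k: tuple(v) for k, v in config.standard_true.items()}

    volume_ml = config.extract_volume_ul / 1000.0
    peak_rows = []
    for phase, n_ind in config.phase_n.items():
        for ind in range(n_ind):
            ind_id = f"{config.species}_{phase}_{ind + 1}"
            for cid, cls, carbon in config.compounds:
                amount = float(config.amounts.get((cid, phase), 0.0))
                truth.chc_amounts[(cid, phase)] = amount
                a, b = config.standard_true[_curve_for_carbon(carbon)]
                conc = amount * config.pool_size / volume_ml  # ug/ml in extract
                ratio = (conc - b) / a
                area = max(ratio, 0.0) * config.internal_standard_area
                area *= float(_lognormal_factor(rng, config.peak_cv))
                peak_rows.append(
                    {
                        "individual_id": ind_id,
                        "species": config.species,
                        "phase": phase,
                        "compound_id": cid,
                        "compound_class": cls,
                        "carbon_n": carbon,
                        "area": area,
                        "is_area": config.internal_standard_area,
                    }
                )
    peaks = pd.DataFrame(peak_rows)

    std_rows = []
    for std_id, (a, b) in config.standard_true.items():
        for level in config.standard_levels:
            ratio = (level - b) / a
            area = ratio * config.internal_standard_area
            area *= float(_lognormal_factor(rng, config.standard_cv))
            std_rows.append(
                {
                    "standard_id": std_id,
                    "level_ug_ml": level,
                    "area": area,
                    "is_area": config.internal_standard_area,
                }
            )
    standards = pd.DataFrame(std_rows)
    return peaks, standards, truth


# ---------------------------------------------------------------------------
# thickness


def generate_thickness(
    phases: Sequence[str],
    means: Sequence[float],
    sds: Sequence[float],
    family: str = "normal",
    n: int = 30,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-phase cuticle-thickness samples (micrometers).

    ``family`` is ``"normal"`` or ``"lognormal"``; the lognormal is
    moment-matched so each phase targets the requested mean and SD.
    """
    if family not in ("normal", "lognormal"):
        raise ValueError("family must be 'normal' or 'lognormal'")
    if n < 2:
        raise ValueError("need n >= 2 measurements per phase")
    if not len(phases) == len(means) == len(sds):
        raise ValueError("phases, means and sds must have equal length")
    rng = np.random.default_rng(seed)
    truth = GroundTruth()
    rows = []
    for phase, mean, sd in zip(phases, means, sds):
        if mean <= 0 or sd < 0:
            raise ValueError("means must be positive and sds non-negative")
        truth.thickness[phase] = (float(mean), float(sd), family)
        if sd == 0:
            values = np.full(n, float(mean))
        elif family == "normal":
            values = rng.normal(mean, sd, size=n)
        else:
            sigma2 = np.log1p((sd / mean) ** 2)
            mu = np.log(mean) - sigma2 / 2
            values = rng.lognormal(mu, np.sqrt(sigma2), size=n)
        for v in values:
            rows.append({"phase": phase, "thickness_um": float(v)})
    return pd.DataFrame(rows), truth
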