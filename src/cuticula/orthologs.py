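"""Cross-species ortholog expression-profile correlation patterns.

Each ortholog trio (two eusocial species, one solitary) is classified by
which species pairs share a positively correlated developmental
expression profile.  A pair "passes positively" iff Pearson r >= 0.6 and
p <= 0.1 (boundary inclusive) over the 9 replicate-level values paired by
(phase, sorted replicate index); "negatively or non-correlated" is the
complement.  The headline pattern is the heterochrony signature: the
eusocial pair passes while both solitary-containing pairs do not.

With n = 9 paired points the two thresholds nearly coincide: p <= 0.1
two-tailed at 7 df corresponds to |r| >= 0.582, so r >= 0.6 is the
slightly stricter filter.  A phase-mean mode (n = 3 points) is available
but makes p <= 0.1 require |r| >= 0.988.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Mapping

import numpy as np
import pandas as pd

from .de import ExpressionStudy
from .stats import CorrelationResult, DegenerateDataError, pearson

__all__ = [
    "PatternLabel",
    "PatternCall",
    "profile_vector",
    "pairwise_profile_correlation",
    "classify_pattern",
    "classify_orthologs",
    "pattern_summary",
]

PAIR_EUSOCIAL = "eusocial_pair"
PAIR_SOLITARY_1 = "eusocialA_solitary"
PAIR_SOLITARY_2 = "eusocialB_solitary"
PAIR_KEYS = (PAIR_EUSOCIAL, PAIR_SOLITARY_1, PAIR_SOLITARY_2)


class PatternLabel(str, Enum):
    EUSOCIAL_SHARED = "EUSOCIAL_SHARED"
    EUSOCIAL_SHARED_SOLITARY_ABSENT = "EUSOCIAL_SHARED_SOLITARY_ABSENT"
    AM_CA_SHARED = "AM_CA_SHARED"
    FV_CA_SHARED = "FV_CA_SHARED"
    ALL_SHARED = "ALL_SHARED"
    NONE = "NONE"


@dataclass
class PatternCall:
    """Per-ortholog pairwise correlations and the pattern label."""

    ids: tuple[str | None, str | None, str | None]
    correlations: Mapping[str, CorrelationResult]
    label: PatternLabel

    def to_row(self) -> dict:
        row: dict = {
            "id_eusocialA": self.ids[0] or "",
            "id_eusocialB": self.ids[1] or "",
            "id_solitary": self.ids[2] or "",
            "label": self.label.value,
        }
        for key in PAIR_KEYS:
            res = self.correlations.get(key)
            row[f"r_{key}"] = res.r if res else np.nan
            row[f"p_{key}"] = res.p if res else np.nan
        return row


def profile_vector(
    study: ExpressionStudy, gene: str, phases: tuple[str, ...] = ("Pbm", "Ne", "Fg"),
    mode: str = "replicates",
) -> np.ndarray:
    """Ordered expression profile for one gene.

    ``replicates`` mode concatenates the normalized abundances phase by
    phase with replicates sorted within each phase (length 9 by default);
    ``phase_means`` collapses each phase to its mean (length 3).  The
    ordering is deterministic, so profiles align across species when
    replicate counts match.
    """
    if gene not in study.norm.index:
        raise KeyError(f"gene {gene!r} not in study {study.species}")
    values: list[float] = []
    n_reps = None
    for ph in phases:
        cols = study.samples_for(ph)
        if not cols:
            raise ValueError(f"phase {ph!r} missing from study {study.species}")
        if n_reps is None:
            n_reps = len(cols)
        elif len(cols) != n_reps:
            raise ValueError(
                f"unequal replicate counts across phases in {study.species}; "
                "profiles must align across species"
            )
        block = study.norm.loc[gene, cols].to_numpy(dtype=float)
        values.append(block.mean() if mode == "phase_means" else block)
    return np.concatenate([np.atleast_1d(v) for v in values])


def pairwise_profile_correlation(
    ids: tuple[str | None, str | None, str | None],
    studies: tuple[ExpressionStudy, ExpressionStudy, ExpressionStudy],
    phases: tuple[str, ...] = ("Pbm", "Ne", "Fg"),
    mode: str = "replicates",
) -> dict[str, CorrelationResult]:
    """Pearson correlation for every species pair with both members present."""
    vectors: list[np.ndarray | None] = []
    for gid, study in zip(ids, studies):
        vectors.append(None if not gid else profile_vector(study, gid, phases, mode))
    pairs = {
        PAIR_EUSOCIAL: (0, 1),
        PAIR_SOLITARY_1: (0, 2),
        PAIR_SOLITARY_2: (1, 2),
    }
    out: dict[str, CorrelationResult] = {}
    for key, (i, j) in pairs.items():
        if vectors[i] is not None and vectors[j] is not None:
            try:
                out[key] = pearson(vectors[i], vectors[j])
            except DegenerateDataError:
                # a constant profile carries no correlation evidence: the
                # pair is present but cannot pass positively
                n = len(vectors[i])
                out[key] = CorrelationResult(r=float("nan"), n=n, p=float("nan"))
    return out


def _pair_state(
    res: CorrelationResult | None, r_min: float, p_max: float
) -> str:
    if res is None:
        return "absent"
    return "pass" if (res.r >= r_min and res.p <= p_max) else "fail"


def label_from_states(es: str, s1: str, s2: str) -> PatternLabel:
    """Pattern label as a pure function of the (pass/fail/absent) triple.

    ``es`` is the eusocial pair, ``s1``/``s2`` the two solitary-containing
    pairs.  A pair that is absent never passes.
    """
    if es == "pass":
        if s1 == "pass" and s2 == "pass":
            return PatternLabel.ALL_SHARED
        if s1 == "absent" and s2 == "absent":
            return PatternLabel.EUSOCIAL_SHARED_SOLITARY_ABSENT
        if s1 != "pass" and s2 != "pass":
            return PatternLabel.EUSOCIAL_SHARED
        return PatternLabel.NONE  # exactly one solitary pair also passes
    # eusocial pair fails or is absent
    if s1 == "pass" and s2 != "pass":
        return PatternLabel.AM_CA_SHARED
    if s2 == "pass" and s1 != "pass":
        return PatternLabel.FV_CA_SHARED
    return PatternLabel.NONE


def classify_pattern(
    correlations: Mapping[str, CorrelationResult],
    r_min: float = 0.6,
    p_max: float = 0.1,
    ids: tuple[str | None, str | None, str | None] = (None, None, None),
) -> PatternCall:
    """Label an ortholog from its per-pair correlation results."""
    if not correlations:
        raise ValueError("no computable species pair for this ortholog")
    states = [
        _pair_state(correlations.get(k), r_min, p_max) for k in PAIR_KEYS
    ]
    return PatternCall(
        ids=ids, correlations=dict(correlations), label=label_from_states(*states)
    )


def classify_orthologs(
    ortholog_map: pd.DataFrame,
    studies: Mapping[str, ExpressionStudy],
    r_min: float = 0.6,
    p_max: float = 0.1,
    phases: tuple[str, ...] = ("Pbm", "Ne", "Fg"),
    mode: str = "replicates",
) -> list[PatternCall]:
    """Classify every row of an ortholog map.

    The map's columns name the species in order (eusocial, eusocial,
    solitary); empty or missing entries mark orthologs not identified in
    that species.
    """
    cols = list(ortholog_map.columns[:3])
    study_trio = tuple(studies[c] for c in cols)
    calls: list[PatternCall] = []
    for _, row in ortholog_map.iterrows():
        ids = tuple(
            (str(row[c]) if isinstance(row[c], str) and row[c] else None) for c in cols
        )
        corr = pairwise_profile_correlation(ids, study_trio, phases, mode)
        if not corr:
            continue
        calls.append(classify_pattern(corr, r_min, p_max, ids=ids))
    return calls


def pattern_summary(calls: list[PatternCall]) -> dict[str, int]:
    """Exhaustive per-label counts; values sum to the number of calls."""
    counts = Counter(call.label.value for call in calls)
    return {label.value: counts.get(label.value, 0) for label in PatternLabel}


def calls_to_table(calls: list[PatternCall]) -> pd.DataFrame:
    return pd.DataFrame([c.to_row() for c in calls])
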