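import numpy as np
import pandas as pd
import pytest

from cuticula.de import ExpressionStudy


def make_study(
    values: np.ndarray,
    species: str = "sp",
    phases=("Pbm", "Ne", "Fg"),
    n_reps: int = 3,
    gene_prefix: str = "g",
) -> ExpressionStudy:
    """Build a study from a gene x sample array with phase-block columns."""
    values = np.asarray(values)
    n_genes, n_samples = values.shape
    assert n_samples == len(phases) * n_reps
    sample_ids = [f"{species}_{ph}_{r + 1}" for ph in phases for r in range(n_reps)]
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "species": species,
            "phase": [ph for ph in phases for _ in range(n_reps)],
            "replicate": [r + 1 for _ in phases for r in range(n_reps)],
        }
    )
    counts = pd.DataFrame(
        values, index=[f"{gene_prefix}{i}" for i in range(n_genes)], columns=sample_ids
    )
    return ExpressionStudy.from_counts(species, counts, meta)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_phase_study(rng):
    """60 genes x (2 phases x 3 reps), Poisson-ish counts around 200."""
    values = rng.poisson(200, size=(60, 6))
    return make_study(values, phases=("Pbm", "Ne"), n_reps=3)
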