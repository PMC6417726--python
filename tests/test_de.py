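"""Tests for normalization, differential-expression calls, and summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cuticula.de import (
    compare_proportions,
    filter_degs,
    normalize,
    upregulation_summary,
)
from cuticula.de import test_de as run_de  # alias: keep pytest from collecting it
from cuticula.simulate import ExpressionSimConfig, generate_expression

from conftest import make_study


class TestNormalize:
    def test_equal_libraries_identity_up_to_constant(self):
        counts = pd.DataFrame([[10, 10], [90, 90]], columns=["s1", "s2"])
        cpm = normalize(counts)
        ratio = cpm / counts
        assert np.allclose(ratio, ratio.iloc[0, 0])

    def test_depth_doubling_leaves_values_unchanged(self):
        counts = pd.DataFrame([[10, 20], [90, 180]], columns=["s1", "s2"])
        cpm = normalize(counts)
        assert np.allclose(cpm["s1"], cpm["s2"])
        mr = normalize(counts, method="median_ratio")
        assert np.allclose(mr["s1"], mr["s2"])

    def test_hand_computed_cpm(self):
        # 2x3 matrix, library sizes 100 / 50 / 10
        counts = pd.DataFrame([[40, 10, 3], [60, 40, 7]], columns=list("abc"))
        cpm = normalize(counts)
        expected = np.array(
            [[40 / 100, 10 / 50, 3 / 10], [60 / 100, 40 / 50, 7 / 10]]
        ) * 1e6
        assert np.allclose(cpm.to_numpy(), expected)

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            normalize(pd.DataFrame([[0, 1], [0, 2]]))

    def test_median_ratio_robust_to_asymmetric_composition(self):
        # 200 null genes plus 40 genes fourfold-up in sample 2: total-count
        # scaling distorts the null genes, size factors do not
        rng = np.random.default_rng(0)
        null = rng.poisson(100, (200, 2)).astype(float)
        up = np.column_stack([rng.poisson(100, 40), rng.poisson(400, 40)])
        counts = pd.DataFrame(np.vstack([null, up]), columns=["s1", "s2"])
        mr = normalize(counts, method="median_ratio")
        null_ratio = (mr.iloc[:200, 1] / mr.iloc[:200, 0]).median()
        assert null_ratio == pytest.approx(1.0, abs=0.05)


class TestTestDe:
    def test_no_effect_zero_dispersion_gives_no_calls(self):
        cfg = ExpressionSimConfig(
            n_genes=100,
            dispersion=0.0,
            class_fractions={"flat": 1.0, "eusocial_heterochronic": 0.0,
                             "all_shared": 0.0, "solitary_shifted": 0.0,
                             "species_specific": 0.0},
            seed=0,
        )
        studies, _, _ = generate_expression(cfg)
        records = run_de(studies["eusocialA"], "Pbm", "Fg")
        assert (records["q"] >= 0.05).all()
        assert len(filter_degs(records)) == 0

    def test_symmetry_flips_sign(self, two_phase_study):
        fwd = run_de(two_phase_study, "Pbm", "Ne")
        rev = run_de(two_phase_study, "Ne", "Pbm")
        assert np.allclose(fwd["log2fc"], -rev["log2fc"])
        assert np.allclose(fwd["p"], rev["p"], atol=1e-12)

    def test_large_sample_matches_normal_approximation_oracle(self, rng):
        # one gene, 2 groups of 100 Poisson samples: the Wald p should match
        # a from-scratch delta-method calculation on the same data
        a = rng.poisson(200, 100)
        b = rng.poisson(260, 100)
        values = np.tile(np.concatenate([a, b]), (5, 1))
        values[1:] = rng.poisson(200, (4, 200))  # filler genes
        study = make_study(values, phases=("P1", "P2"), n_reps=100)
        rec = run_de(study, "P1", "P2").iloc[0]
        norm_vals = study.norm.iloc[0].to_numpy()
        g1, g2 = norm_vals[:100], norm_vals[100:]
        mu1, mu2 = g1.mean(), g2.mean()
        s2 = (g1.var(ddof=1) + g2.var(ddof=1)) / 2
        mu_bar = (mu1 + mu2) / 2
        alpha = max(0.0, (s2 - mu_bar) / mu_bar**2)
        v = lambda m: (m + alpha * m**2) / (100 * m**2)
        z_ref = (np.log(mu2) - np.log(mu1)) / np.sqrt(v(mu1) + v(mu2))
        from scipy.stats import norm as normal

        assert rec["p"] == pytest.approx(2 * normal.sf(abs(z_ref)), rel=1e-6)

    def test_rank_perm_floor_and_null(self, two_phase_study):
        rec = run_de(two_phase_study, "Pbm", "Ne", method="rank_perm")
        assert (rec["p"] >= 1 / 20 - 1e-12).all()

    def test_both_never_more_permissive(self, two_phase_study):
        p_nb = run_de(two_phase_study, "Pbm", "Ne", method="nb_wald")["p"]
        p_perm = run_de(two_phase_study, "Pbm", "Ne", method="rank_perm")["p"]
        p_both = run_de(two_phase_study, "Pbm", "Ne", method="both")["p"]
        assert np.all(p_both >= p_nb - 1e-12)
        assert np.all(p_both >= p_perm - 1e-12)

    def test_all_zero_gene_flagged_untestable(self):
        values = np.vstack([np.zeros(6), np.full((3, 6), 50)])
        study = make_study(values, phases=("P1", "P2"), n_reps=3)
        rec = run_de(study, "P1", "P2")
        assert rec.iloc[0]["untestable"]
        assert rec.iloc[0]["p"] == 1.0

    def test_missing_phase_raises(self, two_phase_study):
        with pytest.raises(ValueError):
            run_de(two_phase_study, "Pbm", "Fg")


def _record(q, lfc, mean_a, mean_b, untestable=False):
    return {
        "gene": "g",
        "comparison": "A_vs_B",
        "log2fc": lfc,
        "p": q / 2,
        "q": q,
        "mean_a": mean_a,
        "mean_b": mean_b,
        "direction": "B" if lfc > 0 else "A",
        "untestable": untestable,
    }


class TestFilterDegs:
    @pytest.mark.parametrize(
        "record,kept",
        [
            (_record(q=0.01, lfc=3.0, mean_a=2.0, mean_b=2.0), False),   # abundance floor
            (_record(q=0.01, lfc=0.8, mean_a=50.0, mean_b=80.0), False), # fold-change floor
            (_record(q=0.04, lfc=-1.0, mean_a=10.0, mean_b=5.0), True),  # boundary |lfc|=1 kept
            (_record(q=0.05, lfc=-2.0, mean_a=10.0, mean_b=5.0), False), # q strictly below
            (_record(q=0.01, lfc=2.0, mean_a=5.0, mean_b=1.0), True),    # max(mean)=5 kept
        ],
    )
    def test_threshold_boundaries(self, record, kept):
        result = filter_degs(pd.DataFrame([record]))
        assert (len(result) == 1) == kept

    def test_direction_consistent_with_sign(self, two_phase_study):
        rec = run_de(two_phase_study, "Pbm", "Ne")
        nonzero = rec[rec["log2fc"] != 0]
        up_b = nonzero["log2fc"] > 0
        assert (nonzero.loc[up_b, "direction"] == "Ne").all()
        assert (nonzero.loc[~up_b, "direction"] == "Pbm").all()


def brute_force_venn(members):
    comps = sorted(members)
    out = {}
    for r in range(1, len(comps) + 1):
        for subset in itertools.combinations(comps, r):
            genes = set.intersection(*(members[c] for c in subset))
            for other in comps:
                if other not in subset:
                    genes = genes - members[other]
            out["&".join(subset)] = len(genes)
    return out


class TestUpregulationSummary:
    def _tables(self, membership):
        tables = {}
        for comp, genes in membership.items():
            rows = [
                {
                    "gene": g,
                    "comparison": comp,
                    "log2fc": 2.0,
                    "p": 0.001,
                    "q": 0.01,
                    "mean_a": 10,
                    "mean_b": 40,
                    "direction": comp.split("_vs_")[1],
                    "untestable": False,
                }
                for g in genes
            ]
            tables[comp] = pd.DataFrame(
                rows,
                columns=["gene", "comparison", "log2fc", "p", "q", "mean_a",
                         "mean_b", "direction", "untestable"],
            )
        return tables

    def test_empty_input_all_zero(self):
        summary = upregulation_summary(self._tables({"Pbm_vs_Ne": []}))
        assert summary["universe_size"] == 0
        assert all(v == 0 for v in summary["venn"].values())

    def test_toy_universe_matches_brute_force_enumeration(self):
        membership = {
            "Pbm_vs_Ne": {"g1", "g2", "g3", "g7"},
            "Ne_vs_Fg": {"g2", "g3", "g4", "g8"},
            "Pbm_vs_Fg": {"g3", "g5", "g6", "g7", "g9", "g10"},
        }
        summary = upregulation_summary(self._tables(membership))
        expected = brute_force_venn({k: set(v) for k, v in membership.items()})
        assert summary["venn"] == expected
        assert summary["universe_size"] == 10
        assert sum(summary["venn"].values()) == 10

    def test_partition_counts_sum_to_universe(self):
        rng = np.random.default_rng(4)
        membership = {
            f"c{i}_vs_c{i+1}": set(rng.choice(50, size=rng.integers(5, 30), replace=False))
            for i in range(3)
        }
        membership = {k: {f"g{v}" for v in vs} for k, vs in membership.items()}
        summary = upregulation_summary(self._tables(membership))
        assert sum(summary["venn"].values()) == summary["universe_size"]
        for d in summary["directions"].values():
            assert 0 <= d["percent"] <= 100

    def test_identical_summaries_give_p_one(self):
        membership = {"Pbm_vs_Fg": {"g1", "g2", "g3"}, "Ne_vs_Fg": {"g4"}}
        s = upregulation_summary(self._tables(membership))
        z, p = compare_proportions(s, s, "Pbm_vs_Fg:Fg_up")
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(1.0)


class TestNullFdr:
    def test_null_simulation_rare_false_calls(self):
        # pure-null negative binomial: almost nothing survives the filter
        cfg = ExpressionSimConfig(
            n_genes=2000,
            class_fractions={"flat": 1.0, "eusocial_heterochronic": 0.0,
                             "all_shared": 0.0, "solitary_shifted": 0.0,
                             "species_specific": 0.0},
            seed=21,
        )
        studies, _, _ = generate_expression(cfg)
        records = run_de(studies["eusocialA"], "Pbm", "Fg")
        assert len(filter_degs(records)) / len(records) <= 0.01
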