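"""End-to-end orchestration of the comparative cuticle-maturation workflow.

``run_all`` executes, on synthetic inputs, the stages in dependency
order: simulate -> differential expression -> bootstrap-supported sample
clustering -> ortholog-profile correlation -> co-expression networks and
intersection -> CHC quantification and Euclidean clustering -> thickness
statistics.  One species' failure in a stage does not abort the others;
the run report (JSON) lists per-stage outputs, counts, warnings and a
checksum for every file written, and the whole run is deterministic
under a fixed seed.
"""

from __future__ import annotations

import hashlib
import itertools
import logging
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chc as chc_mod
from . import io
from .cluster import DistanceSpec, multiscale_bootstrap
from .de import compare_proportions, filter_degs, test_de, upregulation_summary
from .morphometry import compare_phases
from .network import build_network, network_to_sif, shared_interactions_summary
from .orthologs import calls_to_table, classify_orthologs, pattern_summary
from .simulate import (
    SPECIES,
    ChcSimConfig,
    ExpressionSimConfig,
    default_chc_amounts,
    default_compound_roster,
    generate_chc,
    generate_expression,
    generate_thickness,
)

__all__ = ["RunConfig", "run_all"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Thresholds and simulation settings for a full run.

    Defaults are the study's published values: DEG filter q < 0.05,
    |log2FC| >= 1, abundance floor 5; ortholog rule r >= 0.6, p <= 0.1;
    network |r| >= 0.95, p <= 0.05; 10,000 bootstrap replications
    (divided over the 10-scale grid); AU significance cutoff 95; alpha
    0.05 for the group comparisons.
    """

    seed: int = 0
    n_genes: int = 2000
    dispersion: float = 0.1
    fold_change: float = 4.0
    q_max: float = 0.05
    min_abs_log2fc: float = 1.0
    min_abundance: float = 5.0
    r_min: float = 0.6
    p_max: float = 0.1
    net_r_abs_min: float = 0.95
    net_p_max: float = 0.05
    net_genes: int = 40
    boot_total: int = 10_000
    au_cutoff: float = 95.0
    alpha: float = 0.05
    chc_peak_cv: float = 0.10
    chc_standard_cv: float = 0.02

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.boot_total < 1000:
            raise ValueError("boot_total must be >= 1000 (>=100 per scale)")
        for name in ("q_max", "p_max", "net_p_max", "alpha"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if not 0 < self.net_r_abs_min <= 1 or not 0 < self.r_min <= 1:
            raise ValueError("correlation thresholds must be in (0, 1]")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _register(outputs: dict[str, str], path: Path, root: Path) -> None:
    outputs[str(path.relative_to(root))] = _sha256(path)


def run_all(config: RunConfig, outdir: str | Path) -> dict:
    """Run every stage on synthetic inputs; returns the run report."""
    config.validate()
    root = Path(outdir)
    root.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    warnings: list[str] = []
    report: dict = {"seed": config.seed, "stages": {}, "warnings": warnings}
    b_per_scale = config.boot_total // 10

    # ---- stage 1: simulate expression -------------------------------------
    sim_cfg = ExpressionSimConfig(
        n_genes=config.n_genes,
        dispersion=config.dispersion,
        fold_change=config.fold_change,
        seed=config.seed,
    )
    studies, omap, truth = generate_expression(sim_cfg)
    sim_dir = root / "simulated"
    sim_dir.mkdir(exist_ok=True)
    for sp, study in studies.items():
        io.write_matrix(study.counts, sim_dir / f"{sp}_counts.tsv")
        io.write_meta(study.meta, sim_dir / f"{sp}_meta.tsv")
        _register(outputs, sim_dir / f"{sp}_counts.tsv", root)
        _register(outputs, sim_dir / f"{sp}_meta.tsv", root)
    io.write_ortholog_map(omap, sim_dir / "ortholog_map.tsv")
    io.write_json(truth.to_dict(), sim_dir / "truth.json")
    _register(outputs, sim_dir / "ortholog_map.tsv", root)
    _register(outputs, sim_dir / "truth.json", root)
    report["stages"]["simulate"] = {
        "n_genes": config.n_genes,
        "species": list(studies),
    }

    # ---- stage 2: differential expression ---------------------------------
    deg_dir = root / "deg"
    deg_dir.mkdir(exist_ok=True)
    deg_stage: dict = {}
    summaries: dict[str, dict] = {}
    deg_genes: dict[str, list[str]] = {}
    comparisons = [("Pbm", "Ne"), ("Ne", "Fg"), ("Pbm", "Fg")]
    for sp, study in studies.items():
        try:
            filtered_sets = {}
            all_tables = []
            for a, b in comparisons:
                records = test_de(study, a, b, method="nb_wald")
                kept = filter_degs(
                    records, config.q_max, config.min_abs_log2fc, config.min_abundance
                )
                filtered_sets[f"{a}_vs_{b}"] = kept
                all_tables.append(kept)
            deg_table = pd.concat(all_tables, ignore_index=True)
            path = deg_dir / f"{sp}_degs.tsv"
            deg_table.drop(columns=["mean_a", "mean_b"]).to_csv(
                path, sep="\t", index=False
            )
            _register(outputs, path, root)
            summary = upregulation_summary(filtered_sets)
            io.write_json(summary, deg_dir / f"{sp}_venn.json")
            _register(outputs, deg_dir / f"{sp}_venn.json", root)
            summaries[sp] = summary
            deg_genes[sp] = sorted(set(deg_table["gene"]))
            deg_stage[sp] = {
                "n_deg": len(deg_genes[sp]),
                "universe": summary["universe_size"],
            }
        except Exception as exc:  # keep other species running
            warnings.append(f"deg[{sp}] failed: {exc}")
            logger.exception("DEG stage failed for %s", sp)
    # cross-species proportion z-tests on shared upregulation categories
    prop_tests = {}
    for sa, sb in itertools.combinations(summaries, 2):
        shared = set(summaries[sa]["directions"]) & set(summaries[sb]["directions"])
        for cat in sorted(shared):
            try:
                z, p = compare_proportions(summaries[sa], summaries[sb], cat)
                prop_tests[f"{sa}~{sb}:{cat}"] = {"z": z, "p": p}
            except Exception as exc:
                warnings.append(f"proportion[{sa}~{sb}:{cat}]: {exc}")
    io.write_json(prop_tests, deg_dir / "proportion_tests.json")
    _register(outputs, deg_dir / "proportion_tests.json", root)
    deg_stage["proportion_tests"] = len(prop_tests)
    report["stages"]["deg"] = deg_stage

    # ---- stage 3: bootstrap clustering of samples on the DEG subset -------
    clust_dir = root / "clustering"
    clust_dir.mkdir(exist_ok=True)
    clust_stage: dict = {}
    for si, (sp, study) in enumerate(studies.items()):
        try:
            genes = deg_genes.get(sp) or list(study.norm.index)
            matrix = study.norm.loc[genes].T  # samples x genes
            dendro = multiscale_bootstrap(
                matrix,
                DistanceSpec("correlation"),
                b_per_scale=b_per_scale,
                seed=config.seed + 100 + si,
                labels=list(matrix.index),
            )
            (clust_dir / f"{sp}_deg.nwk").write_text(dendro.to_newick() + "\n")
            dendro.to_table().to_csv(clust_dir / f"{sp}_deg_support.tsv", sep="\t", index=False)
            _register(outputs, clust_dir / f"{sp}_deg.nwk", root)
            _register(outputs, clust_dir / f"{sp}_deg_support.tsv", root)
            significant = [
                sorted(dendro.labels[i] for i in node.leaves)
                for node in dendro.nodes
                if node.au is not None and node.au > config.au_cutoff
            ]
            clust_stage[sp] = {"significant_clusters": significant}
        except Exception as exc:
            warnings.append(f"clustering[{sp}] failed: {exc}")
            logger.exception("clustering stage failed for %s", sp)
    report["stages"]["clustering"] = clust_stage

    # ---- stage 4: ortholog-profile correlation ----------------------------
    try:
        calls = classify_orthologs(omap, studies, config.r_min, config.p_max)
        table = calls_to_table(calls)
        table.to_csv(root / "ortholog_patterns.tsv", sep="\t", index=False)
        _register(outputs, root / "ortholog_patterns.tsv", root)
        report["stages"]["orthologs"] = pattern_summary(calls)
    except Exception as exc:
        warnings.append(f"orthologs failed: {exc}")
        logger.exception("ortholog stage failed")

    # ---- stage 5: co-expression networks and intersections ----------------
    net_dir = root / "networks"
    net_dir.mkdir(exist_ok=True)
    nets = {}
    net_stage: dict = {}
    for sp, study in studies.items():
        try:
            genes = deg_genes.get(sp)
            if not genes:
                warnings.append(f"network[{sp}] skipped: no DEGs")
                continue
            subset = genes[: config.net_genes]
            net = build_network(study, subset, config.net_r_abs_min, config.net_p_max)
            nets[sp] = net
            sif, attrs = network_to_sif(net)
            sif.to_csv(net_dir / f"{sp}.sif", sep="\t", index=False, header=False)
            attrs.to_csv(net_dir / f"{sp}_edges.tsv", sep="\t", index=False)
            _register(outputs, net_dir / f"{sp}.sif", root)
            _register(outputs, net_dir / f"{sp}_edges.tsv", root)
            net_stage[sp] = {"nodes": net.number_of_nodes(), "edges": net.number_of_edges()}
        except Exception as exc:
            warnings.append(f"network[{sp}] failed: {exc}")
            logger.exception("network stage failed for %s", sp)
    if len(nets) >= 2 and omap is not None:
        maps = {}
        for sa, sb in itertools.combinations(nets, 2):
            mapping = {
                row[sa]: row[sb]
                for _, row in omap.iterrows()
                if row[sa] and row[sb]
            }
            maps[(sa, sb)] = mapping
        shared = shared_interactions_summary(nets, maps)
        io.write_json(shared, net_dir / "shared_interactions.json")
        _register(outputs, net_dir / "shared_interactions.json", root)
        net_stage["shared"] = shared
    elif omap is None:
        warnings.append("network intersection skipped: no ortholog map")
    report["stages"]["networks"] = net_stage

    # ---- stage 6: CHC quantification and Euclidean clustering -------------
    chc_dir = root / "chc"
    chc_dir.mkdir(exist_ok=True)
    chc_stage: dict = {}
    chc_configs = {
        SPECIES[0]: ChcSimConfig(
            species=SPECIES[0],
            peak_cv=config.chc_peak_cv,
            standard_cv=config.chc_standard_cv,
            seed=config.seed + 200,
        ),
        SPECIES[1]: ChcSimConfig(
            species=SPECIES[1],
            pool_size=3,
            extract_volume_ul=100.0,
            peak_cv=config.chc_peak_cv,
            standard_cv=config.chc_standard_cv,
            seed=config.seed + 201,
        ),
        SPECIES[2]: ChcSimConfig(
            species=SPECIES[2],
            phase_n={"Pbm": 4, "Ne": 7, "Fg": 7},
            amounts=default_chc_amounts(default_compound_roster(), "solitary"),
            peak_cv=config.chc_peak_cv,
            standard_cv=config.chc_standard_cv,
            seed=config.seed + 202,
        ),
    }
    for si, (sp, chc_cfg) in enumerate(chc_configs.items()):
        try:
            peaks, standards, chc_truth = generate_chc(chc_cfg)
            io.write_csv(peaks, chc_dir / f"{sp}_peaks.csv")
            io.write_csv(standards, chc_dir / f"{sp}_standards.csv")
            _register(outputs, chc_dir / f"{sp}_peaks.csv", root)
            _register(outputs, chc_dir / f"{sp}_standards.csv", root)
            curves = chc_mod.fit_calibration(standards)
            relative = chc_mod.normalize_relative(peaks, scope="all")
            quant = chc_mod.absolute_quantify(
                peaks, curves, chc_cfg.pool_size, chc_cfg.extract_volume_ul
            )
            totals = chc_mod.class_totals(quant)
            io.write_csv(quant, chc_dir / f"{sp}_absolute.csv")
            io.write_csv(totals, chc_dir / f"{sp}_class_totals.csv")
            _register(outputs, chc_dir / f"{sp}_absolute.csv", root)
            _register(outputs, chc_dir / f"{sp}_class_totals.csv", root)
            letters = chc_mod.per_class_phase_test(totals, config.alpha)
            io.write_json(
                {cls: pl.to_dict() for cls, pl in letters.items()},
                chc_dir / f"{sp}_class_letters.json",
            )
            _register(outputs, chc_dir / f"{sp}_class_letters.json", root)
            pm = chc_mod.percent_matrix(relative)
            loadings, evr = chc_mod.pca_loadings(pm)
            loadings.to_csv(chc_dir / f"{sp}_pca_loadings.csv")
            _register(outputs, chc_dir / f"{sp}_pca_loadings.csv", root)
            dendro = multiscale_bootstrap(
                pm,
                DistanceSpec("euclidean"),
                b_per_scale=b_per_scale,
                seed=config.seed + 300 + si,
                labels=list(pm.index),
            )
            (chc_dir / f"{sp}_euclidean.nwk").write_text(dendro.to_newick() + "\n")
            dendro.to_table().to_csv(
                chc_dir / f"{sp}_euclidean_support.tsv", sep="\t", index=False
            )
            _register(outputs, chc_dir / f"{sp}_euclidean.nwk", root)
            _register(outputs, chc_dir / f"{sp}_euclidean_support.tsv", root)
            fg_ids = sorted(peaks.loc[peaks["phase"] == "Fg", "individual_id"].unique())
            fg_node = dendro.node_for(fg_ids)
            chc_stage[sp] = {
                "calibration_r": {k: c.r for k, c in curves.items()},
                "fg_cluster_au": None if fg_node is None else fg_node.au,
                "fg_cluster_bp": None if fg_node is None else fg_node.bp,
                "class_letters": {
                    cls: dict(pl.letters) for cls, pl in letters.items()
                },
                "pc1_variance": float(evr[0]),
            }
        except Exception as exc:
            warnings.append(f"chc[{sp}] failed: {exc}")
            logger.exception("CHC stage failed for %s", sp)
    report["stages"]["chc"] = chc_stage

    # ---- stage 7: thickness statistics ------------------------------------
    thick_dir = root / "thickness"
    thick_dir.mkdir(exist_ok=True)
    thick_stage: dict = {}
    thickness_plan = {
        # eusocial A: thickness doubles only after emergence; skewed noise
        SPECIES[0]: (("Pbm", "Ne", "Fg"), (2.0, 2.0, 4.5), (0.6, 0.6, 1.4), "lognormal"),
        # eusocial B: thin cuticle, no change across phases
        SPECIES[1]: (("Pbm", "Ne", "Fg"), (1.0, 1.0, 1.05), (0.25, 0.25, 0.25), "normal"),
        # solitary: thickness triples between the pharate and emerged phases
        SPECIES[2]: (("Pbm", "Ne", "Fg"), (1.5, 4.5, 4.6), (0.4, 0.5, 0.5), "normal"),
    }
    for si, (sp, (phases, means, sds, family)) in enumerate(thickness_plan.items()):
        try:
            data, _ = generate_thickness(
                phases, means, sds, family=family, n=30, seed=config.seed + 400 + si
            )
            io.write_csv(data, thick_dir / f"{sp}_thickness.csv")
            _register(outputs, thick_dir / f"{sp}_thickness.csv", root)
            letters, rep = compare_phases(data, config.alpha)
            io.write_json(rep, thick_dir / f"{sp}_report.json")
            _register(outputs, thick_dir / f"{sp}_report.json", root)
            thick_stage[sp] = {"branch": rep["branch"], "letters": rep["letters"]}
        except Exception as exc:
            warnings.append(f"thickness[{sp}] failed: {exc}")
            logger.exception("thickness stage failed for %s", sp)
    report["stages"]["thickness"] = thick_stage

    import networkx
    import scipy
    import sklearn
    import statsmodels

    report["versions"] = {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "networkx": networkx.__version__,
        "scikit-learn": sklearn.__version__,
        "statsmodels": statsmodels.__version__,
    }
    report["outputs"] = outputs
    io.write_json(report, root / "run_report.json")
    return report
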