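"""End-to-end orchestration of the analysis stages.

``run_pipeline`` executes simulate → filter → DE → structure → diffcoexp →
enrich → coinertia → subtype → phenotype in dependency order, writing every
intermediate artifact as plain TSV/JSON and recording a manifest (config
hash, per-stage outputs with row counts, seeds, version).  Re-running with
an identical config reproduces identical artifact bytes; the manifest's
timestamps are the only run-specific values, so determinism checks compare
everything except ``manifest.json``.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coinertia import coinertia_fit, match_features
from .diffcoexp import condition_correlations, hub_ranking, signflip_edges
from .diffexpr import de_table, protein_de, replicate_filter, rna_de, venn_partition
from .enrichment import enrich, enrichment_table
from .iokit import (GeneSetCollection, OmicsMatrix, read_omics_matrix,
                    write_network, write_omics_matrix)
from .phenotype import fit_ec50, four_pl, growth_rate
from .structure import hcluster_elbow, pca_hotelling
from .subtype import plsda_train, score_subtypes, select_variable_features
from .synthetic_data import (SUBTYPE_CLASSES, SimulationConfig,
                             simulate_growth, simulate_multiomics,
                             simulate_reference_cohort)

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "filter", "de", "structure", "diffcoexp",
              "enrich", "coinertia", "subtype", "phenotype")

DEFAULT_THRESHOLDS = {
    "transcript_fold": 2.0,
    "protein_fold": 1.25,
    "fdr": 0.05,
    "correlation": 0.75,
    "top_k": 60,
}


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: list[dict[str, Any]] = field(default_factory=list)

    def add(self, stage: str, outputs: dict[str, int]) -> None:
        self.stages.append(
            {"stage": stage, "outputs": outputs, "timestamp": time.time()}
        )

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(
            {"config_hash": self.config_hash, "seed": self.seed,
             "version": self.version, "stages": self.stages}, indent=1))


def _config_hash(config: dict) -> str:
    canon = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


def validate_config(config: dict) -> dict:
    """Normalize and validate a pipeline config before any stage runs."""
    cfg = dict(config)
    cfg.setdefault("seed", 0)
    cfg.setdefault("stages", list(ALL_STAGES))
    cfg.setdefault("thresholds", {})
    cfg["thresholds"] = {**DEFAULT_THRESHOLDS, **cfg["thresholds"]}
    cfg.setdefault("simulate", {})
    unknown = set(cfg["stages"]) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    needs_matrices = set(cfg["stages"]) & {"filter", "de", "structure",
                                           "diffcoexp", "enrich", "coinertia",
                                           "subtype"}
    if needs_matrices and "simulate" not in cfg["stages"]:
        inputs = cfg.get("inputs", {})
        required = {"rna", "rna_meta", "protein", "protein_meta"}
        missing = required - set(inputs)
        if missing:
            raise ValueError(
                f"stages {sorted(needs_matrices)} need input paths; "
                f"missing {sorted(missing)} (or enable the simulate stage)"
            )
    return cfg


def _planted_gene_sets(truth, rng: np.random.Generator,
                       universe: list[str]) -> GeneSetCollection:
    """Gene sets derived from planted structure plus random decoys, so the
    enrichment stage has both true and null terms to test."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for cls, feats in truth.signature_features.items():
        sets[f"SIG_{cls.upper()}"] = (f"{cls} signature block", frozenset(feats))
    partners = [b for _, b, _ in truth.hub_edges]
    if partners:
        sets["HUB_PARTNERS"] = ("planted hub partner set", frozenset(partners))
    de_up = [f for f, lfc in truth.de_features.items() if lfc > 0]
    if de_up:
        sets["PLANTED_DE_UP"] = ("planted up-regulated features",
                                 frozenset(de_up[:200]))
    for i in range(10):
        members = rng.choice(universe, size=30, replace=False)
        sets[f"RANDOM_{i + 1:02d}"] = (f"random decoy {i + 1}",
                                       frozenset(map(str, members)))
    return GeneSetCollection(sets=sets)


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> RunManifest:
    """Run the configured stages, writing artifacts and a manifest to ``out_dir``."""
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    cfg = validate_config(config)
    out = Path(out_dir if out_dir is not None else cfg.get("out_dir", "etkras_out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    thr = cfg["thresholds"]
    stages = list(cfg["stages"])
    manifest = RunManifest(config_hash=_config_hash(cfg), seed=seed,
                           version=__version__)

    rna = protein = truth = None
    current_stage = "setup"
    try:
        # ---- simulate -------------------------------------------------
        if "simulate" in stages:
            current_stage = "simulate"
            sim_cfg = SimulationConfig(seed=seed, **cfg["simulate"])
            rna, protein, truth = simulate_multiomics(sim_cfg)
            write_omics_matrix(rna, out / "rna.tsv", out / "rna_samples.tsv")
            write_omics_matrix(protein, out / "protein.tsv",
                               out / "protein_samples.tsv")
            (out / "truth.json").write_text(
                json.dumps(truth.to_dict(), indent=1, sort_keys=True))
            manifest.add("simulate", {
                "rna.tsv": len(rna.values),
                "protein.tsv": len(protein.values),
                "truth.json": len(truth.de_features),
            })
        elif rna is None and "inputs" in cfg:
            inputs = cfg["inputs"]
            rna = read_omics_matrix(inputs["rna"], inputs["rna_meta"],
                                    "rna_counts")
            protein = read_omics_matrix(inputs["protein"],
                                        inputs["protein_meta"], "protein_ratio")

        conds = rna.conditions if rna is not None else []
        focal = conds[-1] if conds else None
        protein_f = None

        # ---- replicate filter -----------------------------------------
        if "filter" in stages:
            current_stage = "filter"
            protein_f = replicate_filter(protein)
            write_omics_matrix(protein_f, out / "protein_filtered.tsv")
            manifest.add("filter", {"protein_filtered.tsv": len(protein_f.values)})
        if protein_f is None and protein is not None:
            protein_f = replicate_filter(protein)

        de_protein_results = None
        # ---- differential expression ----------------------------------
        if "de" in stages:
            current_stage = "de"
            outputs = {}
            contrasts = [(conds[1], conds[0]), (conds[3], conds[2])]
            per_contrast = {}
            for treated, control in contrasts:
                label = f"{treated}_vs_{control}"
                res = rna_de(rna, (treated, control),
                             fold_threshold=thr["transcript_fold"])
                tab = de_table(res)
                tab.to_csv(out / f"de_rna_{label}.tsv", sep="\t",
                           float_format="%.8g")
                outputs[f"de_rna_{label}.tsv"] = len(tab)
                per_contrast[label] = (
                    {r.feature for r in res if r.passed and r.direction == "up"},
                    {r.feature for r in res if r.passed and r.direction == "down"},
                )
            venn = venn_partition(per_contrast)
            (out / "venn_rna.json").write_text(json.dumps(
                {k: sorted(v) for k, v in venn.regions.items()}, indent=1))
            outputs["venn_rna.json"] = len(venn.regions)
            for treated, control in contrasts:
                label = f"{treated}_vs_{control}"
                res = protein_de(protein_f, (treated, control),
                                 fold_threshold=thr["protein_fold"],
                                 alpha=thr["fdr"])
                if (treated, control) == contrasts[-1]:
                    de_protein_results = res
                tab = de_table(res)
                tab.to_csv(out / f"de_protein_{label}.tsv", sep="\t",
                           float_format="%.8g")
                outputs[f"de_protein_{label}.tsv"] = len(tab)
            manifest.add("de", outputs)

        # ---- unsupervised structure -----------------------------------
        if "structure" in stages:
            current_stage = "structure"
            complete = protein_f.with_values(protein_f.values.dropna(axis=0))
            log_prot = complete.with_values(np.log2(complete.values))
            n_clust_feats = min(len(log_prot.values), 500)
            var_feats = select_variable_features(log_prot, n_clust_feats)
            clust = hcluster_elbow(log_prot.subset_features(var_feats))
            pd.Series(clust.assignments, name="cluster").rename_axis(
                "feature").to_csv(out / "clusters.tsv", sep="\t")
            pd.Series(clust.wss_curve, name="wss").rename_axis("k").to_csv(
                out / "wss.tsv", sep="\t", float_format="%.8g")
            pca = pca_hotelling(log_prot)
            pca.scores.rename_axis("sample").to_csv(
                out / "pca_scores.tsv", sep="\t", float_format="%.8g")
            (out / "pca_outliers.txt").write_text(
                "\n".join(sorted(pca.outliers)) + "\n" if pca.outliers else "")
            manifest.add("structure", {
                "clusters.tsv": len(clust.assignments),
                "wss.tsv": len(clust.wss_curve),
                "pca_scores.tsv": len(pca.scores),
                "pca_outliers.txt": len(pca.outliers),
            })

        network = None
        # ---- differential co-expression -------------------------------
        if "diffcoexp" in stages:
            current_stage = "diffcoexp"
            log_protein = protein.with_values(np.log2(protein.values))
            tensor = condition_correlations(log_protein)
            network = signflip_edges(tensor, focal=focal,
                                     threshold=thr["correlation"])
            write_network(network, out / "network.edge.tsv", "edge_tsv")
            write_network(network, out / "network.sif", "sif")
            hubs = hub_ranking(network)
            pd.DataFrame(hubs, columns=["feature", "degree", "positive",
                                        "negative"]).to_csv(
                out / "hubs.tsv", sep="\t", index=False)
            manifest.add("diffcoexp", {
                "network.edge.tsv": len(network.edges),
                "hubs.tsv": len(hubs),
            })

        # ---- enrichment ------------------------------------------------
        if "enrich" in stages:
            current_stage = "enrich"
            if truth is None:
                raise ValueError("enrich stage requires the simulate stage "
                                 "(or run `etkras enrich` directly on a GMT)")
            universe = list(protein_f.feature_ids)
            set_rng = np.random.default_rng(seed + 101)
            collection = _planted_gene_sets(truth, set_rng, universe)
            if de_protein_results is None:
                de_protein_results = protein_de(
                    protein_f, (conds[3], conds[2]),
                    fold_threshold=thr["protein_fold"], alpha=thr["fdr"])
            up = {r.feature for r in de_protein_results
                  if r.passed and r.direction == "up"}
            down = {r.feature for r in de_protein_results
                    if r.passed and r.direction == "down"}
            query = (up | down) & set(universe)
            rows = enrich(query, universe, collection, up=up, down=down)
            enrichment_table(rows).to_csv(out / "enrichment.tsv", sep="\t",
                                          index=False, float_format="%.8g")
            manifest.add("enrich", {"enrichment.tsv": len(rows)})

        # ---- coinertia -------------------------------------------------
        if "coinertia" in stages:
            current_stage = "coinertia"
            tables = match_features(rna, protein)
            coin = coinertia_fit(tables)
            coin.reference_scores.rename_axis("sample").to_csv(
                out / "coinertia_scores.tsv", sep="\t", float_format="%.8g")
            coin.sample_dissimilarity.rename_axis("sample").to_csv(
                out / "coinertia_dissimilarity.tsv", sep="\t",
                float_format="%.8g")
            (out / "coinertia_rv.txt").write_text(f"{coin.rv:.8g}\n")
            manifest.add("coinertia", {
                "coinertia_scores.tsv": len(coin.reference_scores),
                "coinertia_dissimilarity.tsv": len(coin.sample_dissimilarity),
            })

        # ---- subtype ---------------------------------------------------
        if "subtype" in stages:
            current_stage = "subtype"
            sim_cfg = SimulationConfig(seed=seed, **cfg["simulate"])
            ref, ref_labels = simulate_reference_cohort(sim_cfg,
                                                        seed=seed + 211)
            k = min(thr["top_k"], len(ref.values))
            feats = select_variable_features(ref, k)
            n_comp = max(2, len(set(ref_labels.values())) - 1)
            model = plsda_train(ref.subset_features(feats), ref_labels,
                                n_components=n_comp)
            score_subtypes(model, ref.subset_features(feats), ref_labels)
            model.to_json(out / "subtype_model.json")
            scores = score_subtypes(model, protein_f)
            pd.DataFrame(
                [{"sample": s.sample, **s.scores, "top_class": s.top_class}
                 for s in scores]
            ).to_csv(out / "subtype_scores.tsv", sep="\t", index=False,
                     float_format="%.8g")
            pd.Series(model.cutoffs, name="cutoff").rename_axis("class").to_csv(
                out / "subtype_cutoffs.tsv", sep="\t", float_format="%.8g")
            manifest.add("subtype", {
                "subtype_scores.tsv": len(scores),
                "subtype_cutoffs.tsv": len(model.cutoffs),
            })

        # ---- phenotype -------------------------------------------------
        if "phenotype" in stages:
            current_stage = "phenotype"
            times = list(range(0, 193, 48))
            rows = []
            for i, (label, rate) in enumerate(
                    [("WT_control", np.log(2) / 40), ("MUT_treated", np.log(2) / 28)]):
                curve = simulate_growth(rate, 1000, times, noise_cv=0.05,
                                        seed=seed + 300 + i)
                fit = growth_rate(curve)
                rows.append({"line": label, "rate_per_h": fit.rate,
                             "doubling_time_h": fit.doubling_time,
                             "r_squared": fit.r_squared})
            pd.DataFrame(rows).to_csv(out / "growth.tsv", sep="\t",
                                      index=False, float_format="%.8g")
            doses = np.geomspace(0.01, 100, 8)
            rng = np.random.default_rng(seed + 310)
            ec_rows = []
            for drug, true_ec50 in [("gemcitabine", 0.5), ("irinotecan", 5.0),
                                    ("oxaliplatin", 20.0)]:
                resp = four_pl(doses, true_ec50, 1.0, 1.0, 0.05)
                resp = resp * (1 + rng.normal(0, 0.03, size=resp.shape))
                fit = fit_ec50(doses, resp)
                ec_rows.append({"drug": drug, "ec50": fit.ec50,
                                "hill": fit.hill, "top": fit.top,
                                "bottom": fit.bottom, "rss": fit.rss})
            pd.DataFrame(ec_rows).to_csv(out / "ec50.tsv", sep="\t",
                                         index=False, float_format="%.8g")
            manifest.add("phenotype", {"growth.tsv": len(rows),
                                       "ec50.tsv": len(ec_rows)})
    except Exception:
        manifest.write(out / "manifest.json")
        logger.error("pipeline failed in stage %r; partial manifest written",
                     current_stage)
        raise

    manifest.write(out / "manifest.json")
    return manifest
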