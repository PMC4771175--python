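"""File-based pipeline driving the whole analysis on a synthetic study.

Each stage reads its inputs from (and writes its outputs to) a working
directory, so stages can be run separately or chained end to end with
``run_all``.  All randomness flows from the single ``seed`` in the config;
outputs are plain TSV with fixed float formatting, so identical configs
yield byte-identical results.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import consensus as cns
from . import evaluation as ev
from . import io as rio
from .communities import (
    classify_edge_groups,
    cut_consensus_modules,
    detect_communities,
    module_statistics,
)
from .consensus import DiscoverySet
from .genelists import map_interactions, matches_by_module_group
from .inference import MI_METHODS, estimate_mi, rank_edges
from .synth import generate_genelist_hierarchy, generate_ground_truth, sample_cohorts

__all__ = ["Pipeline", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "n_antibodies": 12,
    "density": 0.0929,
    "phospho_fraction": 51 / 187,
    "multi_gene_fraction": 0.15,
    "cohort_sizes": {"C1": 80, "C2": 80, "C3": 80},
    "noise_sd": 0.1,
    "edge_rescale_fraction": 0.3,
    "methods": list(
        (
            "pearsoncor",
            "spearmancor",
            "simpleparcor",
            "genenet",
            "glasso",
            "ridgenet",
            "lassonet",
            "elasticnet",
            "plsnet",
            "aracne_a",
            "aracne_m",
            "clr",
            "mrnet",
        )
    ),
    "recall_max": 0.1,
    "k_neighbors": 3,
    "top_k": 6,
    "threshold_candidates": {"start": 5, "stop": 61, "step": 5},
    "n_edge_groups": 3,
    "n_modules": 4,
    "genelists": {"n_lists": 30, "n_top_level": 6},
}


def _merge(base: dict, override: dict) -> dict:
    # shallow: a dict-valued override (cohort_sizes, grids, ...) replaces the
    # default wholesale rather than unioning keys with it
    out = dict(base)
    out.update(override)
    return out


class Pipeline:
    """Drive the synthetic study through every analysis stage."""

    def __init__(self, config: dict | None = None, outdir: str | Path = "rppanet_out"):
        self.config = _merge(DEFAULT_CONFIG, config or {})
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)

    @classmethod
    def from_yaml(cls, path, outdir=None) -> "Pipeline":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        return cls(config=cfg, outdir=outdir or cfg.get("outdir", "rppanet_out"))

    # -- paths ------------------------------------------------------------
    def path(self, name: str) -> Path:
        return self.outdir / name

    def _log(self, stage: str, params: dict) -> None:
        import rppanet

        with open(self.path("pipeline.log"), "a") as fh:
            fh.write(f"stage={stage}\trppanet={rppanet.__version__}\t{params}\n")

    # -- stages -----------------------------------------------------------
    def simulate(self) -> None:
        """Generate ground truth, cohorts, annotation, gene lists; write all."""
        c = self.config
        gt = generate_ground_truth(
            c["n_antibodies"],
            density=c["density"],
            phospho_fraction=c["phospho_fraction"],
            multi_gene_fraction=c["multi_gene_fraction"],
            seed=c["seed"],
        )
        study = sample_cohorts(
            gt,
            dict(c["cohort_sizes"]),
            noise_sd=c["noise_sd"],
            seed=c["seed"] + 1,
            edge_rescale_fraction=c["edge_rescale_fraction"],
        )
        dataset = study.to_expression_dataset()
        rio.write_expression_tsv(dataset, self.path("expression.tsv"))
        rio.write_annotation_tsv(gt.annotation, self.path("annotation.tsv"))
        rio.write_gold_standard(gt.to_gold_standard(), self.path("gold_standard.tsv"))
        genes = sorted({g for gs in gt.annotation["genes"] for g in gs})
        gl_cfg = c["genelists"]
        collection, hierarchy = generate_genelist_hierarchy(
            genes, n_lists=gl_cfg["n_lists"], n_top_level=gl_cfg["n_top_level"], seed=c["seed"] + 2
        )
        rio.write_gene_lists(collection, hierarchy, self.path("genelists.gmt"), self.path("hierarchy.tsv"))
        self._log("simulate", {"seed": c["seed"], "n_antibodies": c["n_antibodies"]})

    def _load_dataset(self):
        annotation = rio.read_annotation_tsv(self.path("annotation.tsv"))
        return rio.read_expression_tsv(self.path("expression.tsv"), annotation=annotation)

    def infer(self) -> None:
        """Fit every method on every cohort at grid-optimized parameters."""
        c = self.config
        dataset = self._load_dataset()
        gold = rio.read_gold_standard(self.path("gold_standard.tsv"))
        netdir = self.path("networks")
        netdir.mkdir(exist_ok=True)
        rows = []
        for cohort in dataset.cohort_names:
            X = dataset.cohort(cohort)
            mi = (
                estimate_mi(X, k_neighbors=c["k_neighbors"], seed=c["seed"])
                if any(m in MI_METHODS for m in c["methods"])
                else None
            )
            for method in c["methods"]:
                best_params, best_aupr, (net, ranking), _ = ev.optimize_params(
                    method,
                    None,
                    X,
                    gold,
                    recall_max=c["recall_max"],
                    seed=c["seed"],
                    mi_matrix=mi if method in MI_METHODS else None,
                )
                rio.write_network_tsv(net, netdir / f"{cohort}__{method}.tsv", ranking)
                rows.append(
                    {"cohort": cohort, "method": method, "aupr": best_aupr, "params": str(best_params)}
                )
        pd.DataFrame(rows).to_csv(self.path("aupr_table.tsv"), sep="\t", index=False, float_format=rio.FLOAT_FORMAT)
        self._log("infer", {"methods": c["methods"], "recall_max": c["recall_max"]})

    def _aupr_matrix(self) -> pd.DataFrame:
        long = pd.read_csv(self.path("aupr_table.tsv"), sep="\t")
        return long.pivot(index="method", columns="cohort", values="aupr")

    def _load_networks(self):
        c = self.config
        dataset = self._load_dataset()
        nets: dict[str, dict] = {}
        ranks: dict[str, dict] = {}
        for cohort in dataset.cohort_names:
            nets[cohort], ranks[cohort] = {}, {}
            for method in c["methods"]:
                net = rio.read_network_tsv(
                    self.path("networks") / f"{cohort}__{method}.tsv",
                    signed=method not in MI_METHODS,
                    method=method,
                )
                nets[cohort][method] = net
                ranks[cohort][method] = rank_edges(net)
        return nets, ranks

    def evaluate(self) -> None:
        """Cross-cohort method scores and method-similarity structure."""
        aupr = self._aupr_matrix()
        scores = ev.rank_methods(aupr)
        scores.to_csv(self.path("method_scores.tsv"), sep="\t", float_format=rio.FLOAT_FORMAT)
        nets, _ = self._load_networks()
        cohorts = sorted(nets)
        stacked = pd.DataFrame(
            {
                m: np.concatenate([nets[c][m].edge_weights().to_numpy() for c in cohorts])
                for m in self.config["methods"]
            }
        ).T
        spearman, pc_scores, explained, labels = ev.method_similarity(stacked)
        spearman.to_csv(self.path("method_spearman.tsv"), sep="\t", float_format=rio.FLOAT_FORMAT)
        pd.concat([pc_scores, labels], axis=1).to_csv(
            self.path("method_pca.tsv"), sep="\t", float_format=rio.FLOAT_FORMAT
        )
        explained.to_csv(self.path("method_pca_variance.tsv"), sep="\t", float_format=rio.FLOAT_FORMAT)
        self._log("evaluate", {})

    def consensus(self) -> None:
        """Top-k consensus per cohort, rank threshold, discovery set, cohort clustering."""
        c = self.config
        scores = pd.read_csv(self.path("method_scores.tsv"), sep="\t", index_col=0)
        method_set = ev.top_k_methods(scores, k=c["top_k"])
        nets, ranks = self._load_networks()
        per_cohort = {
            cohort: cns.build_consensus(ranks[cohort], nets[cohort], method_set)
            for cohort in sorted(nets)
        }
        tc = c["threshold_candidates"]
        candidates = tuple(range(tc["start"], tc["stop"], tc["step"]))
        threshold, diagnostics = cns.select_rank_threshold(per_cohort, candidates)
        diagnostics.to_csv(self.path("threshold_diagnostics.tsv"), sep="\t", index=False, float_format=rio.FLOAT_FORMAT)
        discovery = cns.build_discovery_set(per_cohort, threshold)

        for cohort, cc in per_cohort.items():
            df = pd.DataFrame({"consensus_rank": cc.rank, "consensus_weight": cc.weight})
            df.index.names = ["antibody1", "antibody2"]
            df.to_csv(self.path(f"consensus__{cohort}.tsv"), sep="\t", float_format=rio.FLOAT_FORMAT)

        disc = discovery.weights.copy()
        disc.columns = [f"weight_{c2}" for c2 in disc.columns]
        sig = discovery.significant.astype(int)
        sig.columns = [f"sig_{c2}" for c2 in sig.columns]
        out = pd.concat([disc, sig], axis=1)
        out["recurrence"] = discovery.recurrence
        out["pan_cancer_weight"] = discovery.pan_cancer_weight
        out.index.names = ["antibody1", "antibody2"]
        out.to_csv(self.path("discovery_set.tsv"), sep="\t", float_format=rio.FLOAT_FORMAT)
        with open(self.path("consensus_meta.tsv"), "w") as fh:
            fh.write("threshold\tmethod_set\n")
            fh.write(f"{threshold}\t{','.join(method_set)}\n")

        jaccard, pc_scores, labels = cns.cohort_similarity(discovery)
        jaccard.to_csv(self.path("cohort_jaccard.tsv"), sep="\t", float_format=rio.FLOAT_FORMAT)
        pd.concat([pc_scores, labels], axis=1).to_csv(
            self.path("cohort_pca.tsv"), sep="\t", float_format=rio.FLOAT_FORMAT
        )
        self._log("consensus", {"method_set": method_set, "threshold": threshold})

    def load_discovery(self) -> DiscoverySet:
        df = pd.read_csv(self.path("discovery_set.tsv"), sep="\t", index_col=[0, 1])
        wcols = [c for c in df.columns if c.startswith("weight_")]
        scols = [c for c in df.columns if c.startswith("sig_")]
        weights = df[wcols].rename(columns=lambda c: c[len("weight_"):])
        significant = df[scols].rename(columns=lambda c: c[len("sig_"):]).astype(bool)
        meta = pd.read_csv(self.path("consensus_meta.tsv"), sep="\t")
        return DiscoverySet(weights=weights, significant=significant, threshold=float(meta["threshold"][0]))

    def modules(self) -> None:
        """Edge groups, five-algorithm module consensus, module statistics."""
        c = self.config
        discovery = self.load_discovery()
        groups = classify_edge_groups(discovery, n_groups=c["n_edge_groups"])
        groups.labels.to_frame().assign(
            recurrence=discovery.recurrence, pan_cancer_weight=discovery.pan_cancer_weight
        ).to_csv(self.path("edge_groups.tsv"), sep="\t", float_format=rio.FLOAT_FORMAT)
        groups.summary.to_csv(self.path("edge_group_summary.tsv"), sep="\t", float_format=rio.FLOAT_FORMAT)

        mc = detect_communities(discovery, seed=c["seed"])
        mc.frequency_frame().to_csv(self.path("module_frequency.tsv"), sep="\t", float_format=rio.FLOAT_FORMAT)
        mc.modularity.to_csv(self.path("module_modularity.tsv"), sep="\t", float_format=rio.FLOAT_FORMAT)
        assignment = cut_consensus_modules(mc, n_modules=min(c["n_modules"], len(mc.antibodies)))
        assignment.to_csv(self.path("module_assignment.tsv"), sep="\t")
        annotation = rio.read_annotation_tsv(self.path("annotation.tsv"))
        stats = module_statistics(assignment, discovery, groups, annotation)
        stats.to_csv(self.path("module_statistics.tsv"), sep="\t", float_format=rio.FLOAT_FORMAT)
        self._log("modules", {"n_modules": c["n_modules"]})

    def map_genelists(self) -> None:
        """Average interaction strengths per gene list and cohort, plus tracks."""
        discovery = self.load_discovery()
        annotation = rio.read_annotation_tsv(self.path("annotation.tsv"))
        collection, hierarchy = rio.read_gene_lists(self.path("genelists.gmt"), self.path("hierarchy.tsv"))
        matrix = map_interactions(discovery, annotation, collection)
        matrix.strength.to_csv(self.path("interaction_strength.tsv"), sep="\t", float_format=rio.FLOAT_FORMAT)
        matrix.counts.to_csv(self.path("interaction_counts.tsv"), sep="\t")

        groups = pd.read_csv(self.path("edge_groups.tsv"), sep="\t", index_col=[0, 1])["group"]
        assignment = pd.read_csv(self.path("module_assignment.tsv"), sep="\t", index_col=0)["module"]
        tracks = matches_by_module_group(
            matrix,
            discovery,
            {tuple(p): g for p, g in groups.items()},
            assignment.to_dict(),
        )
        tracks.to_csv(self.path("genelist_tracks.tsv"), sep="\t", float_format=rio.FLOAT_FORMAT)
        from .genelists import trace_top_level

        roots = {
            lid: ",".join(sorted(trace_top_level(lid, hierarchy))) for lid in collection.ids()
        }
        pd.Series(roots, name="top_level").rename_axis("gene_list").to_csv(
            self.path("genelist_roots.tsv"), sep="\t"
        )
        self._log("map", {})

    def run_all(self) -> None:
        self.simulate()
        self.infer()
        self.evaluate()
        self.consensus()
        self.modules()
        self.map_genelists()
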