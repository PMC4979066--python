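"""Pipeline orchestration: the two analyses end-to-end, plus run manifests.

``run_rrbl`` chains collapse -> filter -> distance -> Fitch-Margoliash ->
rescale -> RRBL -> BM null -> percentile calling -> clade enrichment;
``run_ou_scan`` chains collapse -> filter -> per-gene OU scan -> LRT/FDR ->
per-node counts and outlier flags.  Each run writes TSV outputs, an
annotated Newick, and a JSON manifest (config snapshot, input checksums,
seed, stage timings, version) sufficient to reproduce it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bm_null import build_null, call_significant
from .distance_trees import expression_distance, fitch_margoliash_lengths
from .expression_io import (ExpressionMatrix, SampleMap, collapse_conspecifics,
                            filter_genes, transform)
from .ou_shift import lrt_and_fdr, node_shift_outliers, scan_dataset
from .phylo_core import CladeSpec, PhyloTree, write_newick
from .rrbl import (clade_sign_enrichment, compute_rrbl, lineage_rrbl_summary,
                   rescale_expression_tree)
from .synthetic_data import (ScenarioConfig, gen_expression, gen_sequence_tree,
                             gen_yule_tree)

log = logging.getLogger(__name__)

DEFAULTS = {
    "min_species": 30,       # genes must be observed in this many species
    "transform": "none",
    "min_overlap": 50,       # genes shared per species pair for distances
    "statistic": "sym_ratio",
    "n_reps": 100,           # BM null replicates
    "percentile_lo": 2.5,
    "percentile_hi": 97.5,
    "calling_mode": "pooled",
    "fdr_alpha": 0.05,
    "min_species_per_regime": 3,
    "seed": 0,
}


def merged_config(overrides: dict | None) -> dict:
    cfg = dict(DEFAULTS)
    if overrides:
        unknown = set(overrides) - set(DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update({k: v for k, v in overrides.items() if v is not None})
    return cfg


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


class Manifest:
    """Collects config, input checksums, timings and outputs for one run."""

    def __init__(self, command: str, cfg: dict, inputs: dict):
        self.data = {
            "command": command,
            "version": __version__,
            "config": cfg,
            "config_hash": config_hash(cfg),
            "inputs": {k: _sha256(v) for k, v in inputs.items()},
            "stages": {},
            "outputs": [],
        }
        self._t0 = time.monotonic()

    def stage(self, name: str, **info):
        self.data["stages"][name] = {
            "t_elapsed_s": round(time.monotonic() - self._t0, 3), **info}

    def output(self, path):
        self.data["outputs"].append(str(path))

    def write(self, path):
        with open(path, "w") as fh:
            json.dump(self.data, fh, indent=2, default=str)
        log.info("manifest written to %s", path)


def _prepare_species_matrix(X: ExpressionMatrix, smap: SampleMap,
                            tree: PhyloTree, cfg: dict) -> ExpressionMatrix:
    """collapse conspecifics -> transform -> filter -> align with the tree."""
    smap.validate_against(X)
    Xs = collapse_conspecifics(X, smap)
    Xs = transform(Xs, cfg["transform"])
    tips = set(tree.tip_labels)
    cols = set(Xs.sample_ids)
    if not tips & cols:
        raise ValueError(
            f"no overlap between tree tips and species columns; tree has "
            f"{sorted(tips)[:5]}..., matrix has {sorted(cols)[:5]}...")
    if tips != cols:
        missing_in_matrix = sorted(tips - cols)
        missing_in_tree = sorted(cols - tips)
        raise ValueError(
            "tree/matrix species mismatch: "
            f"absent from matrix {missing_in_matrix[:10]}, "
            f"absent from tree {missing_in_tree[:10]}")
    Xs = ExpressionMatrix(Xs.data[list(tree.tip_labels)])
    return filter_genes(Xs, min_species=min(cfg["min_species"], len(tips)))


def annotated_newick(tree: PhyloTree, values: pd.Series, tag: str) -> str:
    """Newick with per-branch values as NHX-style comments for tree viewers."""

    def render(v: int) -> str:
        ch = tree.children[v]
        nm = tree.names[v]
        core = nm if not ch else "(" + ",".join(render(c) for c in ch) + ")" + nm
        if v == 0:
            return core + ":0"
        comment = f"[&&NHX:{tag}={values[nm]:.6g}]" if nm in values.index else ""
        return f"{core}:{tree.lengths[v]:.12g}{comment}"

    return render(0) + ";"


def run_rrbl(seq_tree: PhyloTree, X: ExpressionMatrix, smap: SampleMap,
             clades: list[CladeSpec] | None = None,
             config: dict | None = None,
             outdir: str | Path | None = None,
             input_paths: dict | None = None) -> dict:
    """The full RRBL analysis; returns tables and writes outputs if asked."""
    cfg = merged_config(config)
    manifest = Manifest("rrbl", cfg, input_paths or {})

    Xs = _prepare_species_matrix(X, smap, seq_tree, cfg)
    manifest.stage("prepare", n_genes=Xs.n_genes, n_species=Xs.n_samples)

    D = expression_distance(Xs, min_overlap=min(cfg["min_overlap"], Xs.n_genes))
    manifest.stage("distance", n_pairs=D.n * (D.n - 1) // 2)

    exp_tree, objective = fitch_margoliash_lengths(seq_tree, D)
    manifest.stage("fitch_margoliash", objective=objective)

    exp_resc = rescale_expression_tree(exp_tree, seq_tree)
    table = compute_rrbl(exp_resc, seq_tree, statistic=cfg["statistic"])
    manifest.stage("rrbl", n_branches=len(table))

    null = build_null(seq_tree, Xs, n_reps=cfg["n_reps"], seed=cfg["seed"],
                      statistic=cfg["statistic"],
                      min_overlap=min(cfg["min_overlap"], Xs.n_genes))
    if null.n_reps < 20:
        log.warning("only %d null replicates: percentile calls are unstable",
                    null.n_reps)
    table = call_significant(table, null, lo=cfg["percentile_lo"],
                             hi=cfg["percentile_hi"], mode=cfg["calling_mode"])
    manifest.stage("null", n_reps=null.n_reps,
                   n_significant=int(table["significant"].sum()))

    enrichment, summary = {}, None
    if clades:
        from .phylo_core import clade_branches
        for c in clades:
            branches = clade_branches(seq_tree, c, include_stem=True)
            enrichment[c.name] = clade_sign_enrichment(table, branches)
        summary = lineage_rrbl_summary(table, seq_tree, clades)
        manifest.stage("enrichment",
                       p_values={k: v["p_value"] for k, v in enrichment.items()})

    result = {"rrbl_table": table, "null": null, "enrichment": enrichment,
              "lineage_summary": summary, "expression_tree": exp_resc,
              "manifest": manifest}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "rrbl_table.tsv", sep="\t", index_label="child")
        manifest.output(outdir / "rrbl_table.tsv")
        null.to_tsv(outdir / "null_distribution.tsv")
        manifest.output(outdir / "null_distribution.tsv")
        (outdir / "rrbl_annotated.nwk").write_text(
            annotated_newick(seq_tree, table["rrbl"], "rrbl") + "\n")
        manifest.output(outdir / "rrbl_annotated.nwk")
        if summary is not None:
            summary.to_csv(outdir / "lineage_summary.tsv", sep="\t")
            manifest.output(outdir / "lineage_summary.tsv")
        if enrichment:
            with open(outdir / "enrichment.json", "w") as fh:
                json.dump(enrichment, fh, indent=2)
            manifest.output(outdir / "enrichment.json")
        manifest.write(outdir / "manifest.json")
    return result


def run_ou_scan(tree: PhyloTree, X: ExpressionMatrix, smap: SampleMap,
                config: dict | None = None,
                outdir: str | Path | None = None,
                input_paths: dict | None = None) -> dict:
    """The genome-wide OU optimum-shift scan; tree must be ultrametric."""
    cfg = merged_config(config)
    if not tree.is_ultrametric(rtol=1e-6):
        raise ValueError("tree is not ultrametric; supply a chronogram or "
                         "apply make_ultrametric_mpl first")
    manifest = Manifest("ou-scan", cfg, input_paths or {})
    Xs = _prepare_species_matrix(X, smap, tree, cfg)
    manifest.stage("prepare", n_genes=Xs.n_genes, n_species=Xs.n_samples)

    scan = scan_dataset(tree, Xs, min_species=cfg["min_species_per_regime"])
    manifest.stage("scan", status_counts=scan["status"].value_counts().to_dict())

    per_gene, counts = lrt_and_fdr(scan, alpha_fdr=cfg["fdr_alpha"])
    from .ou_shift import admissible_nodes
    all_nodes = admissible_nodes(tree, cfg["min_species_per_regime"])
    counts = counts.reindex(all_nodes, fill_value=0)
    node_table = node_shift_outliers(counts) if len(counts) >= 5 else \
        pd.DataFrame({"n_genes_shifted": counts, "outlier": False})
    manifest.stage("lrt", n_tested=int((scan["status"] == "ok").sum()),
                   n_called=int(per_gene["called"].sum()),
                   n_outlier_nodes=int(node_table["outlier"].sum()))

    result = {"per_gene": per_gene, "node_counts": node_table,
              "manifest": manifest}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        per_gene.to_csv(outdir / "ou_per_gene.tsv", sep="\t", index_label="gene")
        manifest.output(outdir / "ou_per_gene.tsv")
        node_table.to_csv(outdir / "ou_node_counts.tsv", sep="\t",
                          index_label="node")
        manifest.output(outdir / "ou_node_counts.tsv")
        (outdir / "ou_annotated.nwk").write_text(
            annotated_newick(tree, node_table["n_genes_shifted"], "shifts") + "\n")
        manifest.output(outdir / "ou_annotated.nwk")
        manifest.write(outdir / "manifest.json")
    return result


def run_simulate(scenario: ScenarioConfig, outdir: str | Path) -> dict:
    """Generate a full synthetic dataset on disk (trees, matrix, map, truth)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree = gen_yule_tree(scenario.n_species, scenario.birth_rate,
                         seed=scenario.seed,
                         normalize_depth=scenario.normalize_depth)
    seq_tree = gen_sequence_tree(tree, scenario.rate_heterogeneity,
                                 seed=scenario.seed)
    X, smap, truth = gen_expression(scenario, tree)

    (outdir / "species_tree.nwk").write_text(write_newick(tree) + "\n")
    (outdir / "sequence_tree.nwk").write_text(write_newick(seq_tree) + "\n")
    X.to_tsv(outdir / "expression.tsv")
    smap.to_tsv(outdir / "sample_map.tsv")
    scenario.to_yaml(outdir / "scenario.yaml")
    truth["per_gene"].to_csv(outdir / "truth_per_gene.tsv", sep="\t",
                             index_label="gene")
    manifest = Manifest("simulate", {"seed": scenario.seed},
                        {"scenario": outdir / "scenario.yaml"})
    for f in ["species_tree.nwk", "sequence_tree.nwk", "expression.tsv",
              "sample_map.tsv", "truth_per_gene.tsv"]:
        manifest.output(outdir / f)
    manifest.data["rng"] = truth["rng"]
    manifest.write(outdir / "manifest.json")
    return {"tree": tree, "seq_tree": seq_tree, "expression": X,
            "sample_map": smap, "truth": truth}
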