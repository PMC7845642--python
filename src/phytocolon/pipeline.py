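"""Configuration-driven end-to-end pipeline.

Runs the full analysis in stages — inputs (synthetic or on-disk) →
quality filters → rarefaction → dissimilarities → PERMANOVA, shared
membership, indicator ASVs, consistency, diversity — writing each
stage's result as a serialized interchange file (TSV/JSON) in the output
directory, plus a run manifest with seeds and parameters.  Every stage
reads only serializable inputs, so any stage can be re-run from its
files alone.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import dissim, diversity, indval, io_tables, overlap, permanova, spatiotemporal
from .synth import SynthConfig, generate_dataset

logger = logging.getLogger("phytocolon")

DEFAULT_CONFIG: dict = {
    "synth": {},  # SynthConfig keyword overrides; None -> read from paths
    "inputs": None,  # {"counts":..., "metadata":..., "taxonomy":..., "tree":...}
    "min_feature_total": 2,
    "min_sample_reads": 10,
    "rarefaction_depth": 1000,
    "dissimilarities": ["raup_crick", "bray_curtis", "unweighted_unifrac"],
    "permanova_formula": "year/stage/tissue + run/plate + site",
    "n_perm": 199,
    "overlap_conditions": ["random", "tissue", "stage", "site", "year"],
    "overlap_n_pairs": 2000,
    "indval_variable": "tissue",
    "indval_n_perm": 499,
    "indval_alpha": 0.01,
    "consistency_axis": "tissue",
    "seed": 0,
    "outdir": "phytocolon_out",
}

_DISSIM_FUNCS = {"raup_crick", "bray_curtis", "unweighted_unifrac", "weighted_unifrac"}


def validate_config(config: dict) -> dict:
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    unknown = set(cfg) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    bad = [m for m in cfg["dissimilarities"] if m not in _DISSIM_FUNCS]
    if bad:
        raise ValueError(f"unknown dissimilarity methods: {bad}")
    if cfg["inputs"] is not None:
        for key, path in cfg["inputs"].items():
            if not Path(path).exists():
                raise FileNotFoundError(f"input {key!r} not found: {path}")
    return cfg


def run_pipeline(config: dict | None = None) -> dict:
    """Run every stage; returns {stage name: output path(s)}."""
    cfg = validate_config(config or {})
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    report: dict = {}
    t0 = time.time()

    def _stage(name):
        logger.info("stage %s (t=%.1fs, seed=%d)", name, time.time() - t0, seed)

    # -- inputs ----------------------------------------------------------
    _stage("inputs")
    if cfg["inputs"] is None:
        synth_cfg = SynthConfig(**{"seed": seed, **cfg["synth"]})
        table, meta, taxonomy, tree, truth = generate_dataset(synth_cfg)
        truth.to_frame().to_csv(outdir / "ground_truth.tsv", sep="\t",
                                index_label="asv_id")
        report["ground_truth"] = str(outdir / "ground_truth.tsv")
    else:
        paths = cfg["inputs"]
        table = io_tables.read_count_table(paths["counts"])
        meta = io_tables.read_metadata(paths["metadata"])
        taxonomy = io_tables.read_taxonomy(paths["taxonomy"])
        tree = io_tables.read_tree(paths["tree"])

    # -- filters and rarefaction ----------------------------------------
    _stage("filter")
    table = io_tables.filter_features(table, cfg["min_feature_total"])
    table = io_tables.filter_samples(table, cfg["min_sample_reads"])
    io_tables.write_count_table(table, outdir / "filtered_counts.tsv")
    report["filtered_counts"] = str(outdir / "filtered_counts.tsv")

    _stage("rarefy")
    rarefied = io_tables.rarefy(table, cfg["rarefaction_depth"], seed=seed + 1)
    if rarefied.n_samples < 4:  # shallow synthetic libraries: analyse unrarefied
        logger.warning("fewer than 4 samples at depth %d; using filtered counts",
                       cfg["rarefaction_depth"])
        rarefied = table
    io_tables.write_count_table(rarefied, outdir / "rarefied_counts.tsv")
    report["rarefied_counts"] = str(outdir / "rarefied_counts.tsv")

    meta = meta.loc[rarefied.sample_ids]
    pa = dissim.presence_absence(rarefied)

    # -- dissimilarities, ordination, PERMANOVA --------------------------
    perm_tables = {}
    for method in cfg["dissimilarities"]:
        _stage(f"dist:{method}")
        if method == "raup_crick":
            dm = dissim.raup_crick(pa)
        elif method == "bray_curtis":
            dm = dissim.bray_curtis(rarefied)
        elif method == "unweighted_unifrac":
            dm = dissim.unweighted_unifrac(pa, tree)
        else:
            dm = dissim.weighted_unifrac(rarefied, tree)
        dm.write_tsv(outdir / f"dist_{method}.tsv")
        report[f"dist_{method}"] = str(outdir / f"dist_{method}.tsv")

        ord_res = dissim.pcoa(dm)
        ord_res.coordinates.to_csv(outdir / f"pcoa_{method}.tsv", sep="\t",
                                   index_label="sample_id")
        report[f"pcoa_{method}"] = str(outdir / f"pcoa_{method}.tsv")

        tab = permanova.permanova(
            dm, meta, cfg["permanova_formula"], n_perm=cfg["n_perm"], seed=seed + 2
        )
        tab.to_csv(outdir / f"permanova_{method}.tsv", sep="\t")
        report[f"permanova_{method}"] = str(outdir / f"permanova_{method}.tsv")
        perm_tables[method] = tab

    # -- shared membership ----------------------------------------------
    _stage("overlap")
    rand = overlap.overlap_distributions(pa, meta, "random",
                                         cfg["overlap_n_pairs"], seed=seed + 3)
    rows = [{"condition": "random", "n_pairs": rand.n_pairs,
             "median": rand.median, "p_vs_random": None}]
    for cond in cfg["overlap_conditions"]:
        if cond == "random":
            continue
        res = overlap.overlap_distributions(pa, meta, cond,
                                            cfg["overlap_n_pairs"], seed=seed + 3)
        rows.append({"condition": cond, "n_pairs": res.n_pairs, "median": res.median,
                     "p_vs_random": overlap.overlap_test(res, rand)})
    pd.DataFrame(rows).to_csv(outdir / "overlap.tsv", sep="\t", index=False)
    report["overlap"] = str(outdir / "overlap.tsv")

    # -- indicator ASVs and consistency ----------------------------------
    _stage("indval")
    iv = indval.indval_permutation_test(
        pa, meta, cfg["indval_variable"], n_perm=cfg["indval_n_perm"],
        alpha=cfg["indval_alpha"], seed=seed + 4,
    )
    iv.to_csv(outdir / "indval.tsv", sep="\t", index=False)
    report["indval"] = str(outdir / "indval.tsv")
    best = indval.select_discriminating(iv, alpha=cfg["indval_alpha"])

    _stage("consistency")
    profile = spatiotemporal.prevalence_by_group(pa, meta, cfg["consistency_axis"])
    records = spatiotemporal.classify_consistency(profile, cfg["consistency_axis"])
    records.to_csv(outdir / "consistency.tsv", sep="\t", index=False)
    report["consistency"] = str(outdir / "consistency.tsv")
    summary = spatiotemporal.consistency_summary(records, best if len(best) else None)
    if len(best):
        breadth, multi_frac = spatiotemporal.habitat_breadth(
            pa, meta, list(best.index), cfg["consistency_axis"]
        )
        summary["multi_habitat_fraction"] = multi_frac
    with open(outdir / "consistency_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    report["consistency_summary"] = str(outdir / "consistency_summary.json")

    # -- diversity --------------------------------------------------------
    _stage("diversity")
    recs = diversity.diversity_records(rarefied, meta, tree=tree)
    recs.to_csv(outdir / "diversity.tsv", sep="\t", index_label="sample_id")
    report["diversity"] = str(outdir / "diversity.tsv")
    stages = [s for s in meta["stage"].cat.categories] \
        if isinstance(meta["stage"].dtype, pd.CategoricalDtype) \
        else sorted(meta["stage"].unique())
    pairs = [(a, b) for a, b in zip(stages[:-1], stages[1:])
             if (recs["stage"] == str(a)).any() and (recs["stage"] == str(b)).any()]
    if pairs:
        tests = diversity.stage_trend_test(recs, "shannon", pairs)
        tests.to_csv(outdir / "stage_tests_shannon.tsv", sep="\t", index=False)
        report["stage_tests_shannon"] = str(outdir / "stage_tests_shannon.tsv")

    # -- manifest ----------------------------------------------------------
    manifest = {
        "seed": seed,
        "config": {k: v for k, v in cfg.items() if k != "inputs"},
        "inputs": cfg["inputs"],
        "n_samples": rarefied.n_samples,
        "n_asvs": rarefied.n_asvs,
        "wall_time_s": round(time.time() - t0, 2),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    report["manifest"] = str(outdir / "manifest.json")
    return report
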