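"""Synthetic plant-microbiome datasets with planted spatiotemporal structure.

The generator emulates a factorial field survey: two sites x two years x
six developmental stages, with the set of harvestable tissues depending
on stage (roots and rosettes during vegetative growth; stems, cauline
leaves, flowers and siliques appearing at flowering; no rosettes or
flowers at senescence).  Community structure follows a two-part
(hurdle) model:

* **occupancy** — ASV presence in a sample is Bernoulli with
  logit P(present) = base + stage_slope * g_asv * stage_index
  + e_tissue[asv, tissue (, site, year)] + e_site[asv] + e_year[asv].
  A positive ``stage_slope`` makes richness (and hence diversity and
  evenness) rise mechanistically with host age.  The per-ASV gain
  ``g_asv`` (mean 1, range [0.5, 1.5]) is graded by the ASV's root-to-tip
  depth on the (non-clock-like) phylogeny: lineages far from the early
  core colonize disproportionately later, so assemblages also become
  more phylogenetically diverse — not just richer — as hosts age.
  With ``stage_slope = 0`` (a soil-like control) the grading vanishes.
* **abundance** — counts for the present ASVs are a multinomial draw of
  a log-normal library size over gamma-distributed relative weights,
  giving negative-binomial-style overdispersion and uneven depth.

A configurable fraction of ASVs is *consistent* (one tissue-preference
vector shared by every site x year cell, so the argmax tissue repeats),
a fraction is *inconsistent* (an independent preference vector per
site x year), and the rest are *neutral* (no tissue preference).  The
drawn effects are returned as ground truth so downstream classifiers can
be scored.
"""

from __future__ import annotations

import io
import random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from skbio import TreeNode

from .containers import CountTable
from .io_tables import RANKS, STAGE_ORDER, UNASSIGNED, write_count_table, \
    write_metadata, write_taxonomy, write_tree

__all__ = ["SynthConfig", "GroundTruth", "generate_tree", "generate_taxonomy",
           "generate_dataset", "write_dataset", "DEFAULT_TISSUE_AVAILABILITY"]

# Mirrors the harvest design of a full factorial field survey: roots and
# rosettes throughout vegetative growth, the full shoot set only at
# flowering, and no rosettes or flowers at senescence.
DEFAULT_TISSUE_AVAILABILITY: dict[str, tuple[str, ...]] = {
    "TwoLeaf": ("Roots", "Rosettes"),
    "FourLeaf": ("Roots", "Rosettes"),
    "SixLeaf": ("Roots", "Rosettes"),
    "EightLeaf": ("Roots", "Rosettes"),
    "Flowering": ("Roots", "Rosettes", "Stems", "CaulineLeaves", "Flowers", "Siliques"),
    "Senescent": ("Roots", "Stems", "Siliques"),
}


@dataclass
class SynthConfig:
    """Parameters of the synthetic survey; defaults are the study conditions."""

    n_asvs: int = 300
    n_sites: int = 2
    n_years: int = 2
    stages: tuple[str, ...] = tuple(STAGE_ORDER)
    tissue_availability: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_AVAILABILITY)
    )
    samples_per_cell: int = 10
    base_occupancy_logit: float = -2.5
    stage_slope: float = 0.3
    effect_sd_tissue: float = 1.5
    effect_sd_site: float = 0.5
    effect_sd_year: float = 0.5
    frac_consistent: float = 0.25
    frac_inconsistent: float = 0.25
    library_size_log_mean: float = 7.6  # exp(7.6) ~ 2,000 reads
    library_size_log_sd: float = 0.6
    abundance_dispersion: float = 1.0
    tree_model: str = "yule"
    seed: int = 0

    def __post_init__(self):
        if self.n_asvs < 2:
            raise ValueError("n_asvs must be >= 2")
        if self.samples_per_cell < 1:
            raise ValueError("samples_per_cell must be >= 1")
        for frac in (self.frac_consistent, self.frac_inconsistent):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("ASV fractions must lie in [0, 1]")
        if self.frac_consistent + self.frac_inconsistent > 1.0 + 1e-12:
            raise ValueError("frac_consistent + frac_inconsistent must be <= 1")
        for stage in self.stages:
            tissues = self.tissue_availability.get(stage, ())
            if not tissues:
                raise ValueError(f"stage {stage!r} has no available tissue")
        known = set(self.tissues)
        for stage, tissues in self.tissue_availability.items():
            unknown = set(tissues) - known
            if unknown:
                raise ValueError(f"unknown tissues {unknown} for stage {stage!r}")

    @property
    def tissues(self) -> list[str]:
        seen: list[str] = []
        for stage in self.stages:
            for t in self.tissue_availability.get(stage, ()):
                if t not in seen:
                    seen.append(t)
        return seen

    @property
    def sites(self) -> list[str]:
        return [f"Site{i + 1}" for i in range(self.n_sites)]

    @property
    def years(self) -> list[str]:
        return [f"Year{i + 1}" for i in range(self.n_years)]


@dataclass
class GroundTruth:
    """What the generator actually planted, for scoring recovery."""

    labels: pd.Series  # asv -> consistent | inconsistent | neutral
    tissues: list[str]
    sites: list[str]
    years: list[str]
    tissue_effects: np.ndarray  # (n_asvs, n_tissues, n_sites, n_years)
    site_effects: np.ndarray  # (n_asvs, n_sites)
    year_effects: np.ndarray  # (n_asvs, n_years)
    stage_gains: pd.Series | None = None  # per-ASV multiplier on stage_slope

    def peak_tissue(self) -> pd.DataFrame:
        """Argmax-tissue of the planted effect per ASV and site x year cell."""
        rows = []
        for i, asv in enumerate(self.labels.index):
            for s, site in enumerate(self.sites):
                for y, year in enumerate(self.years):
                    vec = self.tissue_effects[i, :, s, y]
                    rows.append(
                        {"asv": asv, "site": site, "year": year,
                         "peak_tissue": self.tissues[int(np.argmax(vec))]}
                    )
        return pd.DataFrame(rows)

    def logit_gap(self) -> pd.Series:
        """Top-minus-runner-up tissue effect (first site x year cell).

        For consistent ASVs the vector is shared across cells, so this is
        the planted preference strength in logits.
        """
        gaps = []
        for i in range(len(self.labels)):
            vec = np.sort(self.tissue_effects[i, :, 0, 0])
            gaps.append(vec[-1] - vec[-2] if len(vec) > 1 else 0.0)
        return pd.Series(gaps, index=self.labels.index, name="logit_gap")

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"label": self.labels, "logit_gap": self.logit_gap()})
        if self.stage_gains is not None:
            out["stage_gain"] = self.stage_gains
        peaks = self.peak_tissue()
        for (site, year), sub in peaks.groupby(["site", "year"]):
            out[f"peak_{site}_{year}"] = sub.set_index("asv")["peak_tissue"]
        return out


def generate_tree(n_asvs: int, tree_model: str = "yule", seed: int = 0) -> TreeNode:
    """Simulate a rooted binary phylogeny with ``n_asvs`` ASV tips.

    A Yule (pure-birth) process generates the topology; branch lengths
    are then relaxed with lognormal lineage-rate variation so the tree
    is not clock-like (real 16S gene trees never are, and root-to-tip
    depths must vary for abundance-weighted phylogenetic diversity to be
    informative).  Tips are renamed ASV0001..; non-positive lengths are
    floored at a small epsilon so every branch is informative.
    """
    if n_asvs < 2:
        raise ValueError("n_asvs must be >= 2")
    if tree_model != "yule":
        raise ValueError(f"unknown tree model {tree_model!r}")
    rng = random.Random(int(seed))
    dtree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_asvs,
        rng=rng,
        repeat_until_success=True,
    )
    width = max(4, len(str(n_asvs)))
    for i, leaf in enumerate(dtree.leaf_node_iter()):
        leaf.taxon.label = f"ASV{i + 1:0{width}d}"
    for edge in dtree.preorder_edge_iter():
        if edge.head_node is dtree.seed_node:
            edge.length = None  # root carries no branch
        elif edge.length is None or edge.length <= 0:
            edge.length = 1e-6
        else:
            edge.length *= rng.lognormvariate(0.0, 0.5)  # relaxed clock
    newick = dtree.as_string(schema="newick", suppress_rooting=True)
    return TreeNode.read(io.StringIO(newick), format="newick")


def generate_taxonomy(
    tree: TreeNode,
    ranks: list[str] = RANKS,
    unassigned_rate_per_rank=None,
    seed: int = 0,
) -> pd.DataFrame:
    """Clade-consistent lineages by cutting the tree at increasing depths.

    Rank r's groups are the maximal clades whose root-to-node distance
    first exceeds the rank's depth threshold (thresholds increase from
    coarse to fine), so finer ranks strictly refine coarser ones and any
    two ASVs sharing a genus share every coarser rank.  Unassignment is
    then applied independently per rank at the requested rate (so the
    realised per-rank unassigned fraction is binomial around the rate,
    without propagation to finer ranks).
    """
    ranks = list(ranks)
    if unassigned_rate_per_rank is None:
        rates = [0.0] * len(ranks)
    elif np.isscalar(unassigned_rate_per_rank):
        rates = [float(unassigned_rate_per_rank)] * len(ranks)
    else:
        rates = [float(r) for r in unassigned_rate_per_rank]
    if len(rates) != len(ranks):
        raise ValueError("one unassigned rate per rank required")
    if any(not 0.0 <= r <= 1.0 for r in rates):
        raise ValueError("unassigned rates must lie in [0, 1]")

    tips = [t.name for t in tree.tips()]
    depth = {id(tree): 0.0}
    for node in tree.preorder(include_self=False):
        depth[id(node)] = depth[id(node.parent)] + float(node.length or 0.0)
    max_depth = max(depth[id(t)] for t in tree.tips()) or 1.0

    rng = np.random.default_rng(seed)
    taxonomy = pd.DataFrame(index=pd.Index(tips, name="asv_id"))
    for r_idx, rank in enumerate(ranks):
        threshold = max_depth * r_idx / len(ranks)
        labels: dict[str, str] = {}
        counter = 0
        stack = [tree]
        while stack:
            node = stack.pop()
            if depth[id(node)] >= threshold or node.is_tip():
                counter += 1
                name = f"{rank.lower()[:3]}{counter:03d}"
                for t in ([node] if node.is_tip() else node.tips()):
                    labels[t.name] = name
            else:
                stack.extend(reversed(node.children))
        col = pd.Series(labels).reindex(tips)
        if rates[r_idx] > 0:
            mask = rng.random(len(tips)) < rates[r_idx]
            col[mask] = UNASSIGNED
        taxonomy[rank] = col
    return taxonomy


def _draw_effects(cfg: SynthConfig, rng: np.random.Generator) -> GroundTruth:
    tissues, sites, years = cfg.tissues, cfg.sites, cfg.years
    n, nt, ns, ny = cfg.n_asvs, len(tissues), len(sites), len(years)
    width = max(4, len(str(n)))
    asv_ids = [f"ASV{i + 1:0{width}d}" for i in range(n)]

    n_cons = int(round(cfg.frac_consistent * n))
    n_incons = int(round(cfg.frac_inconsistent * n))
    n_incons = min(n_incons, n - n_cons)
    labels = np.array(
        ["consistent"] * n_cons
        + ["inconsistent"] * n_incons
        + ["neutral"] * (n - n_cons - n_incons)
    )

    tissue_effects = np.zeros((n, nt, ns, ny))
    for i in range(n):
        if labels[i] == "consistent":
            vec = rng.normal(0.0, cfg.effect_sd_tissue, size=nt)
            tissue_effects[i] = vec[:, None, None]
        elif labels[i] == "inconsistent":
            tissue_effects[i] = rng.normal(0.0, cfg.effect_sd_tissue, size=(nt, ns, ny))
    site_effects = rng.normal(0.0, cfg.effect_sd_site, size=(n, ns)) \
        if cfg.effect_sd_site > 0 else np.zeros((n, ns))
    year_effects = rng.normal(0.0, cfg.effect_sd_year, size=(n, ny)) \
        if cfg.effect_sd_year > 0 else np.zeros((n, ny))
    return GroundTruth(
        labels=pd.Series(labels, index=pd.Index(asv_ids, name="asv_id")),
        tissues=tissues, sites=sites, years=years,
        tissue_effects=tissue_effects,
        site_effects=site_effects,
        year_effects=year_effects,
    )


def generate_dataset(
    config: SynthConfig,
) -> tuple[CountTable, pd.DataFrame, pd.DataFrame, TreeNode, GroundTruth]:
    """Generate (counts, metadata, taxonomy, tree, ground truth).

    Deterministic in ``config.seed``: the tree, taxonomy, effects,
    presence draws and counts all derive from it.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    tree = generate_tree(cfg.n_asvs, cfg.tree_model, seed=cfg.seed)
    taxonomy = generate_taxonomy(tree, seed=cfg.seed + 1)
    truth = _draw_effects(cfg, rng)
    asv_ids = truth.labels.index.tolist()
    # the tree's tips carry the same ids by construction
    tissues = cfg.tissues

    # phylogenetically graded stage response: rank ASVs by root-to-tip
    # depth; deeper lineages gain occupancy faster as the host ages
    depths = {t.name: t.accumulate_to_ancestor(tree) for t in tree.tips()}
    depth_rank = pd.Series(depths).reindex(asv_ids).rank(method="average")
    stage_gain = 0.5 + (depth_rank - 0.5) / len(asv_ids)  # in (0.5, 1.5)
    truth.stage_gains = stage_gain.rename("stage_gain")

    sample_rows = []
    logits = []
    inv_logit = lambda x: 1.0 / (1.0 + np.exp(-x))
    for s, site in enumerate(cfg.sites):
        for y, year in enumerate(cfg.years):
            for k, stage in enumerate(cfg.stages):
                for rep in range(cfg.samples_per_cell):
                    plant = f"P.{site}.{year}.{stage}.{rep:03d}"
                    for tissue in cfg.tissue_availability[stage]:
                        t = tissues.index(tissue)
                        sid = f"{site}.{year}.{stage}.{tissue}.{rep:03d}"
                        sample_rows.append(
                            {"sample_id": sid, "tissue": tissue, "stage": stage,
                             "site": site, "year": year, "plant_id": plant,
                             "material": "plant"}
                        )
                        logits.append(
                            cfg.base_occupancy_logit
                            + cfg.stage_slope * stage_gain.to_numpy() * k
                            + truth.tissue_effects[:, t, s, y]
                            + truth.site_effects[:, s]
                            + truth.year_effects[:, y]
                        )
    meta = pd.DataFrame(sample_rows).set_index("sample_id")
    meta["plate"] = [f"Plate{i // 96 + 1:02d}" for i in range(len(meta))]
    meta["run"] = [f"Run{i // 576 + 1}" for i in range(len(meta))]
    meta["stage"] = pd.Categorical(meta["stage"], categories=list(cfg.stages),
                                   ordered=True)

    logit_mat = np.column_stack(logits)  # ASV x sample
    presence = rng.random(logit_mat.shape) < inv_logit(logit_mat)
    libraries = np.maximum(
        1,
        np.round(
            rng.lognormal(cfg.library_size_log_mean, cfg.library_size_log_sd,
                          size=presence.shape[1])
        ).astype(np.int64),
    )
    shape = 1.0 / cfg.abundance_dispersion
    counts = np.zeros(presence.shape, dtype=np.int64)
    for j in range(presence.shape[1]):
        idx = np.flatnonzero(presence[:, j])
        if idx.size == 0:
            continue
        w = rng.gamma(shape, cfg.abundance_dispersion, size=idx.size)
        if w.sum() == 0:
            w = np.ones(idx.size)
        counts[idx, j] = rng.multinomial(libraries[j], w / w.sum())

    table = CountTable(pd.DataFrame(counts, index=asv_ids, columns=meta.index))
    return table, meta, taxonomy, tree, truth


def write_dataset(config: SynthConfig, outdir) -> dict[str, Path]:
    """Generate and write the four pipeline inputs plus the ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, meta, taxonomy, tree, truth = generate_dataset(config)
    paths = {
        "counts": outdir / "counts.tsv",
        "metadata": outdir / "metadata.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
        "tree": outdir / "tree.nwk",
        "ground_truth": outdir / "ground_truth.tsv",
    }
    write_count_table(table, paths["counts"])
    write_metadata(meta, paths["metadata"])
    write_taxonomy(taxonomy, paths["taxonomy"])
    write_tree(tree, paths["tree"])
    truth.to_frame().to_csv(paths["ground_truth"], sep="\t", index_label="asv_id")
    return paths
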