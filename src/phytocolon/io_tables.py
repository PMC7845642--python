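"""Reading, writing, filtering and aggregating ASV count tables.

File conventions (tab-delimited, UTF-8, ``#`` comment lines tolerated):

* counts: first column ASV ids, header row of sample ids, integer cells
* metadata: one row per sample; columns ``tissue``, ``stage``, ``site``,
  ``year``, ``plant_id``, ``plate``, ``run``, ``material``
* taxonomy: one row per ASV; the seven ranks Kingdom..Genus, with the
  literal string ``unassigned`` for missing labels
* trees: Newick, parsed with scikit-bio

Quality-control filters follow the standard amplicon workflow for this
kind of survey: drop ASVs with total frequency below 2, then samples with
fewer than 10 reads; for dissimilarity analyses, additionally prune to
samples with at least 100 counts spread over at least 20 ASVs, and rarefy
to a fixed depth of 1,000 counts.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
from skbio import TreeNode

from .containers import CountTable

RANKS = ["Kingdom", "Phylum", "Class", "Order", "Family", "Genus", "Species"]
UNASSIGNED = "unassigned"

STAGE_ORDER = [
    "TwoLeaf",
    "FourLeaf",
    "SixLeaf",
    "EightLeaf",
    "Flowering",
    "Senescent",
]

__all__ = [
    "RANKS",
    "UNASSIGNED",
    "STAGE_ORDER",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_metadata",
    "read_taxonomy",
    "write_taxonomy",
    "read_tree",
    "write_tree",
    "filter_features",
    "filter_samples",
    "prune_for_dissimilarity",
    "rarefy",
    "aggregate_by_rank",
    "stage_index",
]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_count_table(path) -> CountTable:
    """Read a TSV count table (rows = ASVs, columns = samples).

    Raises
    ------
    ValueError
        On non-integer cells (naming the offending ASV and sample) or
        duplicate identifiers.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    try:
        numeric = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in count table {path}: {exc}") from exc
    frac = numeric != np.floor(numeric)
    if frac.to_numpy().any():
        r, c = np.argwhere(frac.to_numpy())[0]
        raise ValueError(
            f"non-integer count at (asv={df.index[r]!r}, sample={df.columns[c]!r})"
        )
    return CountTable(numeric.astype(np.int64))


def write_count_table(table: CountTable, path) -> None:
    table.data.to_csv(path, sep="\t", index_label="asv_id")


def read_metadata(path, stage_order: Iterable[str] = STAGE_ORDER) -> pd.DataFrame:
    """Read sample metadata; ``stage`` becomes an ordered categorical."""
    meta = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    if meta.index.has_duplicates:
        raise ValueError("duplicate sample ids in metadata")
    if "stage" in meta.columns:
        order = [s for s in stage_order if s in set(meta["stage"].dropna())]
        extra = [s for s in meta["stage"].dropna().unique() if s not in order]
        meta["stage"] = pd.Categorical(meta["stage"], categories=order + extra, ordered=True)
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def read_taxonomy(path) -> pd.DataFrame:
    tax = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    return tax.fillna(UNASSIGNED)


def write_taxonomy(taxonomy: pd.DataFrame, path) -> None:
    taxonomy.to_csv(path, sep="\t", index_label="asv_id")


def read_tree(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def stage_index(meta: pd.DataFrame) -> pd.Series:
    """Integer position of each sample's stage in the ordered stage list."""
    stages = meta["stage"]
    if isinstance(stages.dtype, pd.CategoricalDtype):
        return pd.Series(stages.cat.codes, index=meta.index, name="stage_index")
    order = {s: i for i, s in enumerate(STAGE_ORDER)}
    return stages.map(order).rename("stage_index")


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def filter_features(table: CountTable, min_total: int = 2) -> CountTable:
    """Drop ASVs whose total count over all samples is below ``min_total``."""
    keep = table.asv_totals() >= min_total
    return CountTable(table.data.loc[keep])


def filter_samples(table: CountTable, min_reads: int = 10) -> CountTable:
    """Drop samples with fewer than ``min_reads`` total counts."""
    keep = table.sample_totals() >= min_reads
    return CountTable(table.data.loc[:, keep])


def prune_for_dissimilarity(
    table: CountTable, min_counts: int = 100, min_asvs: int = 20
) -> CountTable:
    """Keep samples with >= min_counts total and >= min_asvs observed ASVs."""
    keep = (table.sample_totals() >= min_counts) & (table.richness() >= min_asvs)
    return CountTable(table.data.loc[:, keep])


def rarefy(table: CountTable, depth: int = 1000, seed: int | None = None) -> CountTable:
    """Subsample each sample to exactly ``depth`` counts without replacement.

    Samples whose total is below ``depth`` are dropped.  Each retained
    sample's counts are drawn from the multivariate hypergeometric law on
    its count multiset, so no rarefied cell can exceed the original cell.
    """
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    kept = [s for s in table.sample_ids if totals[s] >= depth]
    out = np.empty((table.n_asvs, len(kept)), dtype=np.int64)
    for k, s in enumerate(kept):
        col = table.data[s].to_numpy()
        out[:, k] = rng.multivariate_hypergeometric(col, depth)
    return CountTable(pd.DataFrame(out, index=table.asv_ids, columns=kept))


# ---------------------------------------------------------------------------
# taxonomic aggregation
# ---------------------------------------------------------------------------

def aggregate_by_rank(
    table: CountTable,
    taxonomy: pd.DataFrame,
    rank: str,
    unassigned: str = "keep",
) -> tuple[CountTable, float]:
    """Sum counts over ASVs sharing the full lineage down to ``rank``.

    Grouping keys are full lineages (Kingdom..rank), so two genera with
    the same name under different families stay distinct.  ASVs without a
    label at ``rank`` are handled per ``unassigned``:

    * ``"keep"`` (default) — each stays its own singleton group keyed by
      its ASV id, preserving community size without fabricating a pooled
      cosmopolitan taxon;
    * ``"pool"`` — all collapse into one ``unassigned`` group;
    * ``"drop"`` — removed from the table.

    Returns the aggregated table and the fraction of ASVs unassigned at
    ``rank``.  ``rank="ASV"`` is the identity.
    """
    if rank == "ASV":
        return table.copy(), 0.0
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS} or 'ASV'")
    if unassigned not in {"keep", "pool", "drop"}:
        raise ValueError(f"unknown unassigned policy {unassigned!r}")

    tax = taxonomy.reindex(table.asv_ids).fillna(UNASSIGNED)
    upto = RANKS[: RANKS.index(rank) + 1]
    missing = [c for c in upto if c not in tax.columns]
    if missing:
        raise ValueError(f"taxonomy lacks rank columns {missing}")

    is_unassigned = tax[rank] == UNASSIGNED
    unassigned_fraction = float(is_unassigned.mean()) if len(tax) else 0.0

    lineage = tax[upto].agg(";".join, axis=1)
    keys = lineage.copy()
    if unassigned == "keep":
        keys[is_unassigned] = pd.Series(table.asv_ids, index=table.asv_ids)[is_unassigned]
    elif unassigned == "pool":
        keys[is_unassigned] = UNASSIGNED
    else:  # drop
        keep_mask = ~is_unassigned
        sub = CountTable(table.data.loc[keep_mask])
        agg = sub.data.groupby(keys[keep_mask].to_numpy()).sum()
        return CountTable(agg), unassigned_fraction

    agg = table.data.groupby(keys.to_numpy()).sum()
    return CountTable(agg), unassigned_fraction
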