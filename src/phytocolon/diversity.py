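"""Alpha-diversity and evenness measures over host development.

Two per-sample measures track how assemblages change as plants age:

* abundance-weighted phylogenetic diversity, PD_w = sum over branches of
  length(b) * p(b), with p(b) the summed relative abundance of the tips
  descending through b (equals Faith's PD when abundances are uniform on
  a star tree);
* the Shannon-Wiener index H' = -sum p_i ln p_i (natural log by default),
  computed on rarefied counts so depth does not confound evenness.

Stage-pair contrasts use two-sample rank-sum tests with the conventional
significance tiers (ns, *, **, ***, ****).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from skbio import TreeNode

from ._tree import branch_matrix
from .containers import CountTable

__all__ = [
    "weighted_pd",
    "shannon",
    "diversity_records",
    "relabund_distribution",
    "stage_trend_test",
    "significance_tier",
]


def weighted_pd(counts: pd.Series | np.ndarray, tree: TreeNode, asv_ids=None) -> float:
    """Abundance-weighted phylogenetic diversity of one sample.

    ``counts`` is a vector over ASVs (a named Series, or an array with
    ``asv_ids``).  Only ASVs with positive counts need tips in the tree.
    Invariant to rescaling of counts.
    """
    if isinstance(counts, pd.Series):
        asv_ids = counts.index.tolist()
        values = counts.to_numpy(float)
    else:
        values = np.asarray(counts, float)
        asv_ids = list(asv_ids)
    total = values.sum()
    if total <= 0:
        raise ValueError("sample has zero total count")
    present = values > 0
    ids = [a for a, keep in zip(asv_ids, present) if keep]
    lengths, members = branch_matrix(tree, ids)
    p = members.astype(float) @ (values[present] / total)
    return float(lengths @ p)


def shannon(counts, base: float | None = None) -> float:
    """Shannon-Wiener index over nonzero proportions (natural log default)."""
    values = np.asarray(counts, float)
    values = values[values > 0]
    if values.size == 0:
        raise ValueError("sample has zero total count")
    p = values / values.sum()
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def diversity_records(
    table: CountTable,
    metadata: pd.DataFrame,
    tree: TreeNode | None = None,
    base: float | None = None,
) -> pd.DataFrame:
    """Per-sample diversity records (richness, H', and PD_w when a tree is given).

    The table is expected to be rarefied already when comparable H'
    values across samples are wanted.
    """
    meta = metadata.loc[table.sample_ids]
    lengths = members = None
    if tree is not None:
        lengths, members = branch_matrix(tree, table.asv_ids)
    rows = []
    counts = table.counts.astype(float)
    totals = counts.sum(axis=0)
    for k, s in enumerate(table.sample_ids):
        col = counts[:, k]
        if totals[k] <= 0:
            continue
        rec = {
            "sample_id": s,
            "stage": str(meta.loc[s, "stage"]) if "stage" in meta else None,
            "tissue": str(meta.loc[s].get("tissue")),
            "material": str(meta.loc[s].get("material", "plant")),
            "richness": int((col > 0).sum()),
            "shannon": shannon(col, base=base),
        }
        if tree is not None:
            p = members.astype(float) @ (col / totals[k])
            rec["pd_weighted"] = float(lengths @ p)
        rows.append(rec)
    return pd.DataFrame(rows).set_index("sample_id")


def relabund_distribution(
    table: CountTable,
    metadata: pd.DataFrame,
    min_counts: int = 100,
    by: str = "stage",
) -> dict[str, np.ndarray]:
    """Pooled log10 relative abundances of present ASVs, per stage.

    Only samples with at least ``min_counts`` total counts contribute.
    """
    meta = metadata.loc[table.sample_ids]
    totals = table.sample_totals()
    out: dict[str, list] = {}
    for s in table.sample_ids:
        if totals[s] < min_counts:
            continue
        col = table.data[s]
        rel = col[col > 0] / totals[s]
        key = str(meta.loc[s, by])
        out.setdefault(key, []).extend(np.log10(rel.to_numpy()))
    return {k: np.asarray(v) for k, v in out.items()}


def significance_tier(p: float) -> str:
    """Map a p-value to the conventional star tier (strict inequalities)."""
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def stage_trend_test(
    records: pd.DataFrame,
    measure: str,
    stage_pairs: list[tuple[str, str]],
) -> pd.DataFrame:
    """Rank-sum tests of a diversity measure between stage pairs.

    One row per (stage_a, stage_b) with the two-sided Mann-Whitney
    p-value and its star tier.
    """
    if measure not in records.columns:
        raise ValueError(f"measure {measure!r} not in records")
    rows = []
    for sa, sb in stage_pairs:
        va = records.loc[records["stage"] == str(sa), measure].dropna().to_numpy()
        vb = records.loc[records["stage"] == str(sb), measure].dropna().to_numpy()
        if len(va) == 0 or len(vb) == 0:
            raise ValueError(f"no samples for stage pair ({sa}, {sb})")
        if np.ptp(np.concatenate([va, vb])) == 0:
            p = 1.0
        else:
            p = float(mannwhitneyu(va, vb, alternative="two-sided").pvalue)
        rows.append(
            {"stage_a": str(sa), "stage_b": str(sb), "n_a": len(va), "n_b": len(vb),
             "p": p, "tier": significance_tier(p)}
        )
    return pd.DataFrame(rows)
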