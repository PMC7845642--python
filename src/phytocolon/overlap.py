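"""Conditioned shared-membership analysis.

How much of their membership do two plant samples share?  Pairs are drawn
either uniformly at random, or restricted to pairs agreeing on one study
variable (tissue, stage, site, year), or to pairs from different tissues
of the same individual plant.  A right shift of a conditioned
distribution relative to the random one indicates the variable
structures community membership.

Shared proportion defaults to Jaccard similarity |A∩B| / |A∪B|; an
overlap coefficient |A∩B| / min(|A|, |B|) is available as an alternative
denominator.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .containers import CountTable

CONDITIONS = ("random", "tissue", "stage", "site", "year", "same_plant")

__all__ = ["CONDITIONS", "OverlapResult", "shared_proportion",
           "overlap_distributions", "overlap_test"]


@dataclass
class OverlapResult:
    condition: str
    values: np.ndarray
    n_pairs: int
    seed: int | None = None
    denominator: str = "union"
    pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def median(self) -> float:
        return float(np.median(self.values))


def shared_proportion(sample_a: set, sample_b: set, denominator: str = "union") -> float:
    """Proportion of members shared by two presence sets.

    ``denominator="union"`` gives Jaccard similarity |A∩B|/|A∪B|;
    ``"min"`` gives the overlap coefficient |A∩B|/min(|A|,|B|).
    """
    if not sample_a or not sample_b:
        which = "first" if not sample_a else "second"
        raise ValueError(f"{which} sample has an empty presence set")
    inter = len(sample_a & sample_b)
    if denominator == "union":
        return inter / len(sample_a | sample_b)
    if denominator == "min":
        return inter / min(len(sample_a), len(sample_b))
    raise ValueError(f"unknown denominator {denominator!r}")


def _eligible_pairs(meta: pd.DataFrame, condition: str) -> list[tuple[str, str]]:
    ids = meta.index.tolist()
    if condition == "random":
        return list(itertools.combinations(ids, 2))
    if condition == "same_plant":
        pairs = []
        for a, b in itertools.combinations(ids, 2):
            pa, pb = meta.loc[a, "plant_id"], meta.loc[b, "plant_id"]
            if pd.isna(pa) or pd.isna(pb):
                continue
            if pa == pb and meta.loc[a, "tissue"] != meta.loc[b, "tissue"]:
                pairs.append((a, b))
        return pairs
    if condition in ("tissue", "stage", "site", "year"):
        col = meta[condition].astype(str)
        return [
            (a, b)
            for a, b in itertools.combinations(ids, 2)
            if col[a] == col[b]
        ]
    raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")


def overlap_distributions(
    table_pa: CountTable,
    metadata: pd.DataFrame,
    condition: str,
    n_pairs: int = 10000,
    seed: int | None = None,
    denominator: str = "union",
) -> OverlapResult:
    """Distribution of shared-membership proportions for one condition.

    Soil samples (``material != "plant"``) are excluded.  When the
    eligible pair universe holds at most ``n_pairs`` pairs it is used
    exhaustively; otherwise ``n_pairs`` pairs are drawn uniformly without
    replacement (seeded).
    """
    meta = metadata.loc[[s for s in table_pa.sample_ids if s in metadata.index]]
    if "material" in meta.columns:
        meta = meta[meta["material"].astype(str) == "plant"]
    # drop samples with empty presence sets: shared proportion is undefined
    nonempty = table_pa.richness()
    meta = meta[nonempty.reindex(meta.index).fillna(0) > 0]

    pairs = _eligible_pairs(meta, condition)
    if not pairs:
        raise ValueError(f"no eligible sample pair for condition {condition!r}")
    rng = np.random.default_rng(seed)
    if len(pairs) > n_pairs:
        idx = rng.choice(len(pairs), size=n_pairs, replace=False)
        pairs = [pairs[i] for i in sorted(idx)]

    pa = table_pa.data > 0
    sets = {s: set(pa.index[pa[s]]) for s in meta.index}
    values = np.array(
        [shared_proportion(sets[a], sets[b], denominator) for a, b in pairs]
    )
    return OverlapResult(condition, values, len(pairs), seed, denominator, pairs)


def overlap_test(
    conditioned: OverlapResult,
    random: OverlapResult,
    alternative: str = "greater",
) -> float:
    """Mann-Whitney rank-sum p-value for conditioned vs random overlap.

    One-sided ``"greater"`` by default: conditioned pairs share a higher
    proportion of members than random pairs.
    """
    if len(conditioned.values) == 0 or len(random.values) == 0:
        raise ValueError("empty overlap distribution")
    stat = mannwhitneyu(conditioned.values, random.values, alternative=alternative)
    return float(stat.pvalue)
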