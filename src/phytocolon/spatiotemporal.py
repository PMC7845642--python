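"""Prevalence-peak consistency of ASVs across sites and years.

An ASV's prevalence profile is, per (site, year) replicate cell, the
fraction of that cell's samples in which it occurs, broken down along an
axis (tissue or developmental stage).  An ASV behaves *consistently*
when, in every cell where it is present, it peaks in the same habitat —
evidence that deterministic host filtering rather than stochastic
colonisation shapes its distribution.

Habitat-breadth summaries ask the complementary question: are the
discriminating ASVs habitat specialists (seen in a single tissue or at a
single stage) or habitat generalists whose prevalence merely varies?
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import CountTable

__all__ = [
    "prevalence_by_group",
    "classify_consistency",
    "habitat_breadth",
    "consistency_summary",
]

_AXIS_COL = {"tissue": "tissue", "stage": "stage"}


def prevalence_by_group(
    table_pa: CountTable,
    metadata: pd.DataFrame,
    axis: str,
    stratify_by: tuple[str, str] = ("site", "year"),
) -> pd.DataFrame:
    """Per-ASV prevalence within each (site, year, group) cell.

    Returns a long DataFrame with columns ``asv``, the stratifiers, the
    axis column, ``prevalence`` and ``n_samples``.  Cells with zero
    samples do not appear.
    """
    if axis not in _AXIS_COL:
        raise ValueError(f"axis must be 'tissue' or 'stage', got {axis!r}")
    group_col = _AXIS_COL[axis]
    meta = metadata.loc[table_pa.sample_ids]
    keys = [*stratify_by, group_col]
    pa = (table_pa.data > 0)

    records = []
    for cell, sub in meta.groupby(keys, observed=True):
        ids = sub.index.tolist()
        n = len(ids)
        prev = pa[ids].sum(axis=1) / n
        frame = pd.DataFrame({"asv": prev.index, "prevalence": prev.to_numpy()})
        for col, val in zip(keys, cell):
            frame[col] = str(val)
        frame["n_samples"] = n
        records.append(frame)
    out = pd.concat(records, ignore_index=True)
    return out[["asv", *stratify_by, group_col, "prevalence", "n_samples"]]


def classify_consistency(
    profile: pd.DataFrame,
    axis: str,
    min_prevalence: float = 0.0,
    stratify_by: tuple[str, str] = ("site", "year"),
    include_single_cell: bool = False,
) -> pd.DataFrame:
    """Label each ASV by whether its prevalence peak repeats across cells.

    Within each (site, year) cell the peak is the strict argmax of
    prevalence over the axis groups present in that cell; exact ties mark
    the cell ``tied`` and exclude it from the vote.  A cell is evaluable
    when the ASV's maximal prevalence there exceeds ``min_prevalence``
    (is positive when ``min_prevalence`` is 0).

    Labels: ``consistent`` (>= 2 evaluable untied cells, all sharing one
    peak), ``inconsistent`` (>= 2 evaluable cells with differing peaks),
    ``single_cell`` (exactly 1 evaluable cell; counted as consistent
    when ``include_single_cell``), ``ambiguous`` (evaluable cells exist
    but every one is tied), ``absent`` (no evaluable cell).
    """
    group_col = _AXIS_COL.get(axis)
    if group_col is None or group_col not in profile.columns:
        raise ValueError(f"axis {axis!r} not present in profile")
    strat = list(stratify_by)

    records = []
    for asv, sub in profile.groupby("asv", sort=True):
        peaks = []
        n_tied = 0
        for _, cell in sub.groupby(strat):
            top = cell["prevalence"].max()
            if top <= min_prevalence or top <= 0:
                continue  # ASV effectively absent from this cell
            winners = cell.loc[cell["prevalence"] == top, group_col].tolist()
            if len(winners) > 1:
                n_tied += 1
            else:
                peaks.append(winners[0])
        n_eval = len(peaks)
        if n_eval == 0 and n_tied == 0:
            label, peak = "absent", None
        elif n_eval == 0:
            label, peak = "ambiguous", None
        elif n_eval == 1:
            label = "consistent" if include_single_cell else "single_cell"
            peak = peaks[0]
        elif len(set(peaks)) == 1:
            label, peak = "consistent", peaks[0]
        else:
            label, peak = "inconsistent", None
        records.append(
            {
                "asv": asv,
                "axis": axis,
                "label": label,
                "peak_habitat": peak if label == "consistent" else None,
                "n_evaluable_cells": n_eval,
                "n_tied_cells": n_tied,
            }
        )
    return pd.DataFrame(records)


def habitat_breadth(
    table_pa: CountTable,
    metadata: pd.DataFrame,
    discriminating: set[str] | list[str],
    axis: str,
) -> tuple[pd.DataFrame, float]:
    """Breadth of occurrence for discriminating ASVs, and the generalist fraction.

    axis="tissue": an ASV is *multi-habitat* when it occurs in >= 2
    tissues within at least one site x year; axis="stage": when it occurs
    at >= 2 stages within at least one tissue x site x year.  Returns the
    per-ASV table (``max_breadth``, ``multi_habitat``) and the fraction
    of discriminating ASVs that are multi-habitat.
    """
    discriminating = [a for a in discriminating]
    if not discriminating:
        raise ValueError("empty discriminating ASV set")
    missing = [a for a in discriminating if a not in set(table_pa.asv_ids)]
    if missing:
        raise ValueError(f"discriminating ASVs not in table: {missing[:5]}")
    if axis == "tissue":
        strat = ["site", "year"]
        group_col = "tissue"
    elif axis == "stage":
        strat = ["tissue", "site", "year"]
        group_col = "stage"
    else:
        raise ValueError(f"axis must be 'tissue' or 'stage', got {axis!r}")

    meta = metadata.loc[table_pa.sample_ids]
    pa = (table_pa.data.loc[discriminating] > 0)

    breadth = pd.Series(0, index=discriminating, dtype=int)
    for _, sub in meta.groupby(strat, observed=True):
        # per ASV: number of distinct groups occupied within this cell
        occupied = (
            pa[sub.index]
            .T.groupby(sub[group_col].astype(str))
            .any()
        )
        breadth = np.maximum(breadth, occupied.sum(axis=0))
    out = pd.DataFrame(
        {"asv": discriminating, "max_breadth": breadth.to_numpy()}
    )
    out["multi_habitat"] = out["max_breadth"] >= 2
    return out, float(out["multi_habitat"].mean())


def consistency_summary(
    records: pd.DataFrame, indicator_map: pd.Series | None = None
) -> dict:
    """Summarise consistency records, optionally restricted to indicator ASVs.

    Returns the consistent fraction (with numerator and denominator over
    consistent + inconsistent ASVs) and the distribution of peak habitats
    among consistent ASVs (fractions summing to 1 when any exist).
    """
    recs = records
    if indicator_map is not None:
        recs = recs[recs["asv"].isin(set(indicator_map.index))]
    consistent = recs[recs["label"] == "consistent"]
    inconsistent = recs[recs["label"] == "inconsistent"]
    denom = len(consistent) + len(inconsistent)
    frac = len(consistent) / denom if denom else float("nan")
    peaks = consistent["peak_habitat"].value_counts(normalize=True).to_dict()
    return {
        "n_consistent": int(len(consistent)),
        "n_inconsistent": int(len(inconsistent)),
        "n_single_cell": int((recs["label"] == "single_cell").sum()),
        "denominator": int(denom),
        "consistent_fraction": frac,
        "peak_habitat_fractions": peaks,
    }
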