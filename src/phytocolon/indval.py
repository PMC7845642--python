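"""Indicator-value (IndVal) association of ASVs with habitat classes.

For each ASV and each level of a grouping variable (habitat), the index
is the product of two conditional probabilities estimated from the
presence-absence table:

* A (specificity): P(habitat | ASV present) = n(present ∧ habitat) / n(present)
* B (fidelity):    P(ASV present | habitat) = n(present ∧ habitat) / n(habitat)

IndVal = A·B lies in [0, 1] and is 1 only when the ASV occurs in every
sample of the habitat and nowhere else.  Significance comes from
permuting sample-to-habitat assignments, which preserves each ASV's
overall prevalence; the two-tailed p-value flags ASVs observed either
significantly more or significantly less often in a habitat than chance
predicts.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import CountTable

__all__ = ["indval", "indval_permutation_test", "select_discriminating"]


def _presence_and_groups(table_pa: CountTable, metadata: pd.DataFrame, variable: str):
    if variable not in metadata.columns:
        raise ValueError(f"variable {variable!r} not in metadata")
    meta = metadata.loc[table_pa.sample_ids]
    groups = meta[variable].astype(str)
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError(f"variable {variable!r} has fewer than 2 levels")
    presence = (table_pa.counts > 0).astype(float)  # ASV x sample
    habitat = np.stack([(groups == lv).to_numpy(float) for lv in levels], axis=1)
    return presence, habitat, levels


def _indval_matrices(presence: np.ndarray, habitat: np.ndarray):
    """A, B, IndVal matrices (ASV x habitat) from presence and habitat one-hots."""
    joint = presence @ habitat  # n(present ∧ habitat)
    n_present = presence.sum(axis=1)
    n_habitat = habitat.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(n_present[:, None] > 0, joint / n_present[:, None], 0.0)
        b = joint / n_habitat[None, :]
    return a, b, a * b


def indval(
    table_pa: CountTable, metadata: pd.DataFrame, variable: str
) -> pd.DataFrame:
    """Point estimates of A, B and IndVal per ASV x habitat level.

    ASVs absent from every sample are excluded (with a warning via the
    returned frame's ``attrs["excluded"]`` list).
    """
    presence, habitat, levels = _presence_and_groups(table_pa, metadata, variable)
    present_any = presence.sum(axis=1) > 0
    excluded = [a for a, keep in zip(table_pa.asv_ids, present_any) if not keep]
    a, b, iv = _indval_matrices(presence[present_any], habitat)
    asvs = [x for x, keep in zip(table_pa.asv_ids, present_any) if keep]
    out = pd.DataFrame(
        {
            "asv": np.repeat(asvs, len(levels)),
            "habitat": np.tile(levels, len(asvs)),
            "A": a.ravel(),
            "B": b.ravel(),
            "indval": iv.ravel(),
        }
    )
    out.attrs["variable"] = variable
    out.attrs["excluded"] = excluded
    return out


def indval_permutation_test(
    table_pa: CountTable,
    metadata: pd.DataFrame,
    variable: str,
    n_perm: int = 999,
    alpha: float = 0.01,
    seed: int | None = None,
) -> pd.DataFrame:
    """IndVal with permutation two-tailed p-values per ASV x habitat.

    The null permutes sample identities (rows of the habitat coding)
    jointly across habitat levels, leaving every ASV's prevalence
    untouched.  Per cell, p_hi counts permuted IndVals >= observed and
    p_lo counts <= observed (each with the +1 convention);
    p_two_tail = min(1, 2 min(p_hi, p_lo)), flagged at ``alpha``.
    """
    if n_perm < 99 and alpha <= 0.01:
        raise ValueError(
            f"n_perm={n_perm} cannot resolve alpha={alpha}; use n_perm >= 99"
        )
    if 2.0 / (n_perm + 1) >= alpha:
        warnings.warn(
            f"two-tailed floor 2/(n_perm+1)={2.0 / (n_perm + 1):.4g} is not below "
            f"alpha={alpha}; no cell can be flagged significant"
        )
    presence, habitat, levels = _presence_and_groups(table_pa, metadata, variable)
    present_any = presence.sum(axis=1) > 0
    presence = presence[present_any]
    asvs = [x for x, keep in zip(table_pa.asv_ids, present_any) if keep]

    a, b, iv_obs = _indval_matrices(presence, habitat)
    rng = np.random.default_rng(seed)
    n = presence.shape[1]
    ge = np.zeros_like(iv_obs)
    le = np.zeros_like(iv_obs)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        _, _, iv_p = _indval_matrices(presence, habitat[perm])
        ge += iv_p >= iv_obs - 1e-12
        le += iv_p <= iv_obs + 1e-12
    p_hi = (ge + 1) / (n_perm + 1)
    p_lo = (le + 1) / (n_perm + 1)
    p_two = np.minimum(1.0, 2.0 * np.minimum(p_hi, p_lo))

    out = pd.DataFrame(
        {
            "asv": np.repeat(asvs, len(levels)),
            "habitat": np.tile(levels, len(asvs)),
            "A": a.ravel(),
            "B": b.ravel(),
            "indval": iv_obs.ravel(),
            "p_hi": p_hi.ravel(),
            "p_lo": p_lo.ravel(),
            "p_two_tail": p_two.ravel(),
        }
    )
    out["significant"] = out["p_two_tail"] < alpha
    out.attrs.update(
        {"variable": variable, "n_perm": n_perm, "alpha": alpha, "seed": seed}
    )
    return out


def select_discriminating(results: pd.DataFrame, alpha: float = 0.01) -> pd.Series:
    """Map each discriminating ASV to its best habitat.

    An ASV is discriminating when at least one habitat level is
    significant at ``alpha``; it is assigned to the significant level of
    maximal IndVal (ties broken by habitat label order).
    """
    sig = results[results["p_two_tail"] < alpha]
    if sig.empty:
        return pd.Series(dtype=object, name="best_habitat")
    best = (
        sig.sort_values(["asv", "indval", "habitat"], ascending=[True, False, True])
        .groupby("asv", sort=True)
        .first()["habitat"]
    )
    best.name = "best_habitat"
    return best
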