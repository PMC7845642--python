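"""Permutational multivariate ANOVA (PERMANOVA) on distance matrices.

Implements the McArdle-Anderson formulation directly on the Gower-centred
inner-product matrix G = -1/2 J D∘D J: for an ordered sequence of model
terms, sequential (Type I) sums of squares are rank-one-safe trace forms
SS_k = tr((H_k - H_{k-1}) G) with H_k the hat matrix of the cumulative
dummy-coded design.  Significance comes from free permutation of sample
identities (rows and columns of D permuted together).

Nested designs are written with the `/` operator, as in
``"Year/Stage/Tissue + Run/Plate + Site"``: ``A/B`` expands to the main
effect A followed by the interaction A:B, so a factor nested in another
is coded as the full combination of levels.  Degrees of freedom are rank
increments of the cumulative design, which automatically removes
redundancy between overlapping terms.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import DistanceMatrix

__all__ = [
    "ModelTerm",
    "expand_nested_terms",
    "gower_center",
    "permanova",
    "pairwise_tissue_permanova",
]


@dataclass(frozen=True)
class ModelTerm:
    """A model term: a name and the factor columns whose combination codes it."""

    name: str
    factors: tuple[str, ...]


def expand_nested_terms(formula: str) -> list[ModelTerm]:
    """Expand a ``+``/``/`` formula into ordered model terms.

    ``"A/B/C"`` becomes A, A:B, A:B:C; ``+`` concatenates blocks in
    written order.
    """
    terms: list[ModelTerm] = []
    pos = 0
    for block in formula.split("+"):
        stripped = block.strip()
        if not stripped:
            raise ValueError(f"empty term in formula at position {pos}: {formula!r}")
        chain: list[str] = []
        for part in stripped.split("/"):
            name = part.strip()
            if not name:
                raise ValueError(
                    f"malformed nesting in formula at position {pos}: {formula!r}"
                )
            chain.append(name)
            terms.append(ModelTerm(":".join(chain), tuple(chain)))
        pos += len(block) + 1
    return terms


def gower_center(dm: DistanceMatrix | np.ndarray) -> np.ndarray:
    """Gower-centred inner-product matrix G = -1/2 J (D∘D) J.

    trace(G) equals the total sum of squares, sum_{i<j} d_ij^2 / n.
    """
    d = dm.values if isinstance(dm, DistanceMatrix) else np.asarray(dm, float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ (d * d) @ j


def _indicator(metadata: pd.DataFrame, factors: tuple[str, ...]) -> np.ndarray:
    """One-hot matrix of the combined levels of ``factors``."""
    for f in factors:
        if f not in metadata.columns:
            raise ValueError(f"factor {f!r} not in metadata columns")
    combo = metadata[list(factors)].astype(str).agg("\x1f".join, axis=1)
    return pd.get_dummies(combo).to_numpy(float)


def _orth_basis(x: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space (rank-revealing via SVD)."""
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    tol = max(x.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    return u[:, s > tol]


def permanova(
    dm: DistanceMatrix,
    metadata: pd.DataFrame,
    terms: list[ModelTerm] | str,
    n_perm: int = 999,
    seed: int | None = None,
    permutations: str = "free",
) -> pd.DataFrame:
    """Sequential PERMANOVA with permutation p-values.

    Parameters
    ----------
    dm
        Distance matrix over the analysed samples.
    metadata
        Indexed by sample id, covering every sample of ``dm``.
    terms
        Ordered model terms, or a formula string passed through
        :func:`expand_nested_terms`.
    n_perm
        Number of random permutations (p floored at 1/(n_perm+1)).
    permutations
        ``"free"`` (unrestricted random shuffles of sample identity) or
        ``"exhaustive"`` (all n! relabelings; only sensible for tiny n,
        p is then the exact fraction with F_perm >= F_obs).

    Returns
    -------
    DataFrame with one row per retained term plus ``Residual`` and
    ``Total``; columns ``df``, ``SumOfSqs``, ``F``, ``R2``, ``p``.
    ``attrs`` records n_perm, seed and the permutation scheme.
    """
    if isinstance(terms, str):
        terms = expand_nested_terms(terms)
    if n_perm < 1 and permutations == "free":
        raise ValueError("n_perm must be >= 1")
    missing = [s for s in dm.sample_ids if s not in metadata.index]
    if missing:
        raise ValueError(f"samples without metadata: {missing[:5]}")
    meta = metadata.loc[dm.sample_ids]
    n = dm.n_samples

    g = gower_center(dm)
    sst = float(np.trace(g))

    # cumulative orthonormal bases; projector differences P_k
    ones = np.ones((n, 1))
    basis = _orth_basis(ones)
    projs: list[np.ndarray] = []
    dfs: list[int] = []
    kept: list[ModelTerm] = []
    x_cum = ones
    for term in terms:
        x_cum = np.hstack([x_cum, _indicator(meta, term.factors)])
        new_basis = _orth_basis(x_cum)
        df_k = new_basis.shape[1] - basis.shape[1]
        if df_k < 1:
            warnings.warn(
                f"term {term.name!r} adds no rank after redundancy removal; dropped"
            )
            continue
        h_prev = basis @ basis.T
        h_new = new_basis @ new_basis.T
        projs.append(h_new - h_prev)
        dfs.append(df_k)
        kept.append(term)
        basis = new_basis

    rank_full = basis.shape[1]
    df_res = n - rank_full
    h_full = basis @ basis.T
    p_res = np.eye(n) - h_full

    def _stats(gmat: np.ndarray):
        ss = np.array([float(np.sum(p * gmat)) for p in projs])
        ss_res = float(np.sum(p_res * gmat))
        if df_res > 0 and ss_res > 0:
            f = (ss / np.array(dfs)) / (ss_res / df_res)
        else:
            f = np.full(len(ss), np.inf)
        return ss, ss_res, f

    ss_obs, ss_res_obs, f_obs = _stats(g)

    if permutations == "exhaustive":
        exceed = np.zeros(len(kept))
        total = 0
        for perm in itertools.permutations(range(n)):
            gp = g[np.ix_(perm, perm)]
            _, _, fp = _stats(gp)
            exceed += fp >= f_obs - 1e-12
            total += 1
        pvals = exceed / total
        n_perm_used = math.factorial(n)
    elif permutations == "free":
        rng = np.random.default_rng(seed)
        exceed = np.zeros(len(kept))
        for _ in range(n_perm):
            perm = rng.permutation(n)
            gp = g[np.ix_(perm, perm)]
            _, _, fp = _stats(gp)
            exceed += fp >= f_obs - 1e-12
        pvals = (exceed + 1) / (n_perm + 1)
        n_perm_used = n_perm
    else:
        raise ValueError(f"unknown permutation scheme {permutations!r}")

    rows = []
    for term, df_k, ss_k, f_k, p_k in zip(kept, dfs, ss_obs, f_obs, pvals):
        rows.append((term.name, df_k, ss_k, f_k, ss_k / sst if sst else 0.0, p_k))
    rows.append(("Residual", df_res, ss_res_obs, np.nan,
                 ss_res_obs / sst if sst else 0.0, np.nan))
    rows.append(("Total", n - 1, sst, np.nan, 1.0 if sst else 0.0, np.nan))
    out = pd.DataFrame(rows, columns=["term", "df", "SumOfSqs", "F", "R2", "p"])
    out = out.set_index("term")
    out.attrs.update(
        {"n_perm": n_perm_used, "seed": seed, "permutations": permutations,
         "ss_type": "sequential"}
    )
    return out


def pairwise_tissue_permanova(
    dm: DistanceMatrix,
    metadata: pd.DataFrame,
    tissue_pairs: list[tuple[str, str]],
    stage_window: list[str],
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Single-term tissue PERMANOVA on stage-windowed tissue contrasts.

    For each (tissue_a, tissue_b) pair, subsets the samples to those
    tissues within ``stage_window`` stages and partitions variance by
    Tissue alone.  Returns one row per contrast with n, R2, F and p.
    """
    meta = metadata.loc[[s for s in dm.sample_ids if s in metadata.index]]
    rows = []
    for k, (ta, tb) in enumerate(tissue_pairs):
        mask = meta["tissue"].astype(str).isin([ta, tb]) & meta["stage"].astype(str).isin(
            [str(s) for s in stage_window]
        )
        ids = meta.index[mask].tolist()
        sub_meta = meta.loc[ids]
        if sub_meta["tissue"].nunique() < 2:
            raise ValueError(
                f"contrast {ta}~{tb} within stages {stage_window} keeps "
                "fewer than 2 tissues"
            )
        sub_dm = dm.select(ids)
        tab = permanova(
            sub_dm,
            sub_meta,
            [ModelTerm("Tissue", ("tissue",))],
            n_perm=n_perm,
            seed=None if seed is None else seed + k,
        )
        rows.append(
            {
                "tissue_a": ta,
                "tissue_b": tb,
                "stages": ",".join(str(s) for s in stage_window),
                "n_samples": len(ids),
                "df": tab.loc["Tissue", "df"],
                "F": tab.loc["Tissue", "F"],
                "R2": tab.loc["Tissue", "R2"],
                "p": tab.loc["Tissue", "p"],
            }
        )
    return pd.DataFrame(rows)
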