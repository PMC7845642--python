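"""Community dissimilarities and ordination.

Three dissimilarity families capture complementary aspects of community
variation:

* **Raup-Crick** — a null-model probability on presence-absence data:
  the chance that two samples share at least their observed number of
  ASVs when assemblages of the same richness are drawn at random from
  the species pool.  Values near 1 mean the samples share no more than
  expected by chance; values near 0 mean they share improbably many.
* **Bray-Curtis** — normalised L1 difference of abundance vectors.
* **UniFrac** — the fraction of phylogenetic branch length unique to one
  of the two communities (unweighted), or branch-wise absolute
  differences in descending relative abundance (weighted).

Ordination is classical PCoA: Gower-centre the squared distances and
eigendecompose.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import hypergeom
from skbio import TreeNode

from ._tree import branch_matrix
from .containers import CountTable, DistanceMatrix, OrdinationResult

__all__ = [
    "presence_absence",
    "bray_curtis",
    "raup_crick",
    "unweighted_unifrac",
    "weighted_unifrac",
    "pcoa",
    "within_between_distributions",
]


def presence_absence(table: CountTable) -> CountTable:
    """Binarise counts: any positive cell becomes 1."""
    return table.presence_absence()


def bray_curtis(table: CountTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity d = sum|x-y| / sum(x+y)."""
    totals = table.sample_totals()
    empty = totals[totals == 0]
    if len(empty):
        raise ValueError(f"zero-total samples: {empty.index.tolist()}")
    mat = table.counts.T.astype(float)  # samples x ASVs
    d = squareform(pdist(mat, metric="braycurtis"))
    return DistanceMatrix(table.sample_ids, d, "bray_curtis")


def raup_crick(
    table_pa: CountTable,
    pool: str = "all_asvs",
    mode: str = "analytic",
    n_null: int = 999,
    weighted: bool = False,
    seed: int | None = None,
) -> DistanceMatrix:
    """Raup-Crick null-model dissimilarity on a presence-absence table.

    With richnesses a = |A|, b = |B| and shared count j = |A ∩ B| drawn
    against a species pool of N ASVs (all ASVs of the table), the index
    is P(X >= j) for X ~ Hypergeometric(N, a, b): the probability of two
    random assemblages of the observed richnesses sharing at least as
    many ASVs as observed.

    ``mode="analytic"`` evaluates the hypergeometric tail exactly (the
    classic index; deterministic).  ``mode="null_sim"`` instead draws
    ``n_null`` random assemblage pairs preserving the two richnesses —
    ASV inclusion uniform, or proportional to occurrence frequency when
    ``weighted`` — and reports the fraction with shared count >= j.

    The diagonal is P(X >= a) for a sample against itself, not forced to
    0: the index is a probability, and a sample shares all of its own a
    ASVs with itself, which is itself improbable under the null.  Use
    :meth:`DistanceMatrix.zeroed_diagonal` for consumers needing a
    hollow matrix.
    """
    if pool != "all_asvs":
        raise ValueError(f"unknown pool {pool!r}")
    pa = (table_pa.counts > 0).astype(np.int64)
    n_pool = pa.shape[0]
    richness = pa.sum(axis=0)
    if (richness > n_pool).any():
        raise ValueError("sample richness exceeds pool size")
    shared = pa.T @ pa  # j for every pair (diagonal: a)
    n = pa.shape[1]
    a = np.broadcast_to(richness[:, None], (n, n))
    b = np.broadcast_to(richness[None, :], (n, n))

    if mode == "analytic":
        # P(X >= j) = sf(j - 1); hypergeom(M=N, n=a, N=b)
        d = hypergeom.sf(shared - 1, n_pool, a, b)
    elif mode == "null_sim":
        rng = np.random.default_rng(seed)
        freq = pa.sum(axis=1).astype(float)
        if weighted:
            if freq.sum() == 0:
                raise ValueError("cannot frequency-weight an empty table")
            p = freq / freq.sum()
        else:
            p = np.full(n_pool, 1.0 / n_pool)
        d = np.ones((n, n))
        for i in range(n):
            for k in range(i, n):
                ai, bk, j = richness[i], richness[k], shared[i, k]
                hits = 0
                for _ in range(n_null):
                    sa = rng.choice(n_pool, size=ai, replace=False, p=p)
                    sb = rng.choice(n_pool, size=bk, replace=False, p=p)
                    if len(np.intersect1d(sa, sb, assume_unique=True)) >= j:
                        hits += 1
                d[i, k] = d[k, i] = hits / n_null
    else:
        raise ValueError(f"unknown mode {mode!r}")

    return DistanceMatrix(
        table_pa.sample_ids,
        d,
        "raup_crick",
        {"mode": mode, "weighted": weighted, "pool_size": n_pool},
    )


def _branch_presence(table: CountTable, tree: TreeNode):
    lengths, members = branch_matrix(tree, table.asv_ids)
    pa = (table.counts > 0)
    # branch x sample: does any tip of the branch occur in the sample?
    desc = members @ pa > 0
    return lengths, members, desc


def unweighted_unifrac(table_pa: CountTable, tree: TreeNode) -> DistanceMatrix:
    """Unique-over-union branch length between every pair of samples.

    d(A, B) = L_unique / L_union where L_unique sums branches leading to
    tips of exactly one sample and L_union to tips of either.
    """
    lengths, _, desc = _branch_presence(table_pa, tree)
    # u_s = total branch length subtending sample s
    u = lengths @ desc  # (n_samples,)
    m = (desc * lengths[:, None]).T @ desc  # shared branch length, pairwise
    union = u[:, None] + u[None, :] - m
    unique = u[:, None] + u[None, :] - 2 * m
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(union > 0, unique / np.where(union > 0, union, 1.0), 0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(table_pa.sample_ids, d, "unweighted_unifrac")


def weighted_unifrac(
    table: CountTable, tree: TreeNode, normalized: bool = True
) -> DistanceMatrix:
    """Abundance-weighted UniFrac.

    Per branch b, p_S(b) is the relative abundance of sample S descending
    through b; the raw distance sums length(b) * |p_A(b) - p_B(b)|.  The
    normalised variant divides by sum length(b) * (p_A(b) + p_B(b)), the
    maximum attainable for the pair, bounding the result in [0, 1].
    """
    totals = table.sample_totals().to_numpy().astype(float)
    if (totals == 0).any():
        bad = [s for s, t in zip(table.sample_ids, totals) if t == 0]
        raise ValueError(f"zero-total samples: {bad}")
    lengths, members, _ = _branch_presence(table, tree)
    rel = table.counts / totals[None, :]
    p = members.astype(float) @ rel  # branch x sample
    wl = p * lengths[:, None]
    n = table.n_samples
    d = np.zeros((n, n))
    for i, k in itertools.combinations(range(n), 2):
        raw = np.abs(wl[:, i] - wl[:, k]).sum()
        if normalized:
            denom = (wl[:, i] + wl[:, k]).sum()
            raw = raw / denom if denom > 0 else 0.0
        d[i, k] = d[k, i] = raw
    return DistanceMatrix(
        table.sample_ids, d, "weighted_unifrac", {"normalized": normalized}
    )


def pcoa(dm: DistanceMatrix, zero_diagonal: bool = True) -> OrdinationResult:
    """Classical principal-coordinate analysis (metric MDS).

    Gower-centres -1/2 J D^2 J (J = I - 11'/n) and eigendecomposes.
    Coordinates are eigenvectors scaled by sqrt(eigenvalue) for positive
    eigenvalues; negative eigenvalues are reported but excluded from the
    proportion-explained denominator.
    """
    d = dm.values.copy()
    if zero_diagonal:
        np.fill_diagonal(d, 0.0)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d * d) @ j
    vals, vecs = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(1e-12, 1e-12 * abs(vals[0]) if n else 0)
    coords = vecs[:, pos] * np.sqrt(vals[pos])[None, :]
    prop = vals[pos] / vals[pos].sum() if pos.any() else np.array([])
    axes = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=dm.sample_ids, columns=axes),
        eigenvalues=vals,
        proportion_explained=prop,
    )


def within_between_distributions(
    dm: DistanceMatrix,
    metadata: pd.DataFrame,
    group_a,
    group_b,
) -> tuple[np.ndarray, np.ndarray]:
    """Distances within group A and crossing A to B.

    ``group_a``/``group_b`` are boolean selectors over ``metadata`` rows
    (aligned to sample ids) or explicit sample-id lists.  Self-pairs are
    excluded and no pair is double-counted.
    """

    def _ids(sel):
        if isinstance(sel, (list, tuple, set, pd.Index)):
            return [s for s in dm.sample_ids if s in set(sel)]
        mask = pd.Series(sel, index=metadata.index).astype(bool)
        chosen = set(metadata.index[mask])
        return [s for s in dm.sample_ids if s in chosen]

    ids_a, ids_b = _ids(group_a), _ids(group_b)
    ia = [dm.sample_ids.index(s) for s in ids_a]
    ib = [dm.sample_ids.index(s) for s in ids_b]
    within = np.array([dm.values[i, j] for i, j in itertools.combinations(ia, 2)])
    seen = set()
    between = []
    for i in ia:
        for j in ib:
            if i == j:
                continue
            key = (min(i, j), max(i, j))
            if key in seen:
                continue
            seen.add(key)
            between.append(dm.values[i, j])
    return within, np.array(between)
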