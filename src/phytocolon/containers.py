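"""Core in-memory containers shared across the pipeline.

The canonical community object is a :class:`CountTable`: an integer
ASV-by-sample matrix backed by a pandas DataFrame (rows = ASVs, columns =
samples).  Dissimilarity computations return a :class:`DistanceMatrix`
tagged with the method that produced it, and ordination returns an
:class:`OrdinationResult`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd

__all__ = ["CountTable", "DistanceMatrix", "OrdinationResult"]


class CountTable:
    """Integer ASV x sample count matrix with unique identifiers.

    Parameters
    ----------
    data
        DataFrame with ASV identifiers as the index and sample identifiers
        as columns.  Values must be non-negative integers.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate ASV identifiers: {dups[:5]}")
        if data.columns.has_duplicates:
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups[:5]}")
        values = data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                bad = np.argwhere(values != np.round(values))[0]
                raise ValueError(
                    "non-integer count at "
                    f"(asv={data.index[bad[0]]!r}, sample={data.columns[bad[1]]!r})"
                )
            values = np.round(values).astype(np.int64)
        if values.size and values.min() < 0:
            bad = np.argwhere(values < 0)[0]
            raise ValueError(
                "negative count at "
                f"(asv={data.index[bad[0]]!r}, sample={data.columns[bad[1]]!r})"
            )
        self.data = pd.DataFrame(
            values.astype(np.int64, copy=False),
            index=data.index.astype(str),
            columns=data.columns.astype(str),
        )

    # -- identifiers -----------------------------------------------------
    @property
    def asv_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def counts(self) -> np.ndarray:
        """ASV x sample integer matrix."""
        return self.data.to_numpy()

    @property
    def n_asvs(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    # -- summaries -------------------------------------------------------
    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=0)

    def asv_totals(self) -> pd.Series:
        return self.data.sum(axis=1)

    def richness(self) -> pd.Series:
        """Observed ASVs per sample."""
        return (self.data > 0).sum(axis=0)

    def presence_absence(self) -> "CountTable":
        """Binarise: any positive count becomes 1."""
        return CountTable((self.data > 0).astype(np.int64))

    # -- plumbing --------------------------------------------------------
    def select_samples(self, sample_ids) -> "CountTable":
        return CountTable(self.data.loc[:, list(sample_ids)])

    def select_asvs(self, asv_ids) -> "CountTable":
        return CountTable(self.data.loc[list(asv_ids), :])

    def copy(self) -> "CountTable":
        return CountTable(self.data.copy())

    def __eq__(self, other) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return self.data.equals(other.data)

    def __repr__(self) -> str:
        return f"CountTable({self.n_asvs} ASVs x {self.n_samples} samples)"


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarity matrix with a method tag.

    The diagonal is zero for every metric except the Raup-Crick index,
    whose diagonal is the null probability of a sample sharing at least
    its own richness with itself (a probability, not a distance; see the
    methods note).
    """

    sample_ids: list[str]
    values: np.ndarray
    method: str
    parameters: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} sample ids"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("distance matrix is not symmetric")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def between(self, a: str, b: str) -> float:
        i, j = self.sample_ids.index(a), self.sample_ids.index(b)
        return float(self.values[i, j])

    def select(self, sample_ids) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return DistanceMatrix(
            [self.sample_ids[i] for i in idx],
            self.values[np.ix_(idx, idx)],
            self.method,
            dict(self.parameters),
        )

    def zeroed_diagonal(self) -> "DistanceMatrix":
        v = self.values.copy()
        np.fill_diagonal(v, 0.0)
        return DistanceMatrix(list(self.sample_ids), v, self.method, dict(self.parameters))

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def read_tsv(cls, path, method: str = "unknown") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        return cls(df.index.astype(str).tolist(), df.to_numpy(float), method)


@dataclass
class OrdinationResult:
    """Principal-coordinate embedding of a distance matrix.

    Axes are ordered by decreasing eigenvalue; ``proportion_explained``
    is computed over the positive eigenvalues only, so negative
    eigenvalues (reported in ``eigenvalues``) never inflate it.
    """

    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray  # all eigenvalues, descending, may be negative
    proportion_explained: np.ndarray  # per retained (positive) axis
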