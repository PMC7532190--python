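"""Completeness filtering, standardization and missing-aware distances.

Incomplete fossil taxa distort ordinations, so taxa below a completeness
threshold are dropped before analysis.  Distances between the survivors are
Euclidean, rescaled for pairwise-deleted missing cells the way R's ``dist``
does: d(i,j) = sqrt( (P / m_ij) * sum over mutually observed traits of
(x_ik - x_jk)^2 ), with P the total trait count and m_ij the mutually
observed count.  On complete data this is the textbook Euclidean distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import TraitTable

__all__ = [
    "DistanceMatrix",
    "filter_by_completeness",
    "ztransform",
    "euclidean_missing",
    "pairwise_sq_missing",
    "trait_correlations",
]


@dataclass
class DistanceMatrix:
    """Symmetric, zero-diagonal pairwise dissimilarities over named taxa."""

    taxa: list[str]
    D: np.ndarray
    kind: str = "phenotypic"  # phenotypic | cophenetic | patristic | external

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.taxa)
        if self.D.shape != (n, n):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.all(np.isfinite(self.D)):
            raise ValueError("non-finite distances")
        if not np.allclose(self.D, self.D.T, atol=1e-10):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.D), 0.0, atol=1e-10):
            raise ValueError("distance matrix diagonal is not zero")
        self.D = 0.5 * (self.D + self.D.T)
        np.fill_diagonal(self.D, 0.0)

    @property
    def n(self) -> int:
        return len(self.taxa)

    def condensed(self) -> np.ndarray:
        from scipy.spatial.distance import squareform

        return squareform(self.D, checks=False)

    def submatrix(self, taxa: Sequence[str]) -> "DistanceMatrix":
        idx = [self.taxa.index(t) for t in taxa]
        return DistanceMatrix(taxa=list(taxa), D=self.D[np.ix_(idx, idx)],
                              kind=self.kind)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.D, index=self.taxa, columns=self.taxa).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, kind: str = "external") -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(taxa=[str(t) for t in df.index], D=df.to_numpy(dtype=float),
                   kind=kind)


def filter_by_completeness(table: TraitTable, threshold: float,
                           trait_class: str | None = None,
                           ) -> tuple[TraitTable, list[str]]:
    """Retain taxa whose observed fraction is >= threshold (inclusive).

    Completeness is computed over ``trait_class`` columns when given (e.g.
    craniodental only) but the full table rows are returned for survivors.
    Returns (filtered table, dropped taxon list).
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    scored = table if trait_class is None else table.select_traits(trait_class=trait_class)
    comp = scored.completeness()
    keep = [t for t, c in zip(table.taxa, comp) if c >= threshold]
    dropped = [t for t, c in zip(table.taxa, comp) if c < threshold]
    if not keep:
        raise ValueError("completeness filter dropped every taxon")
    return table.select_taxa(keep), dropped


def ztransform(table: TraitTable) -> TraitTable:
    """Standardize each trait over its observed cells: mean 0, sample var 1.

    Missing cells stay missing.  A constant (or singly observed) trait has no
    defined scale and raises.
    """
    X = table.values.copy()
    for j, name in enumerate(table.traits):
        col = X[:, j]
        obs = col[np.isfinite(col)]
        if obs.size < 2:
            raise ValueError(f"trait {name!r} has fewer than 2 observed values")
        sd = obs.std(ddof=1)
        if sd == 0:
            raise ValueError(f"trait {name!r} is constant")
        X[:, j] = (col - obs.mean()) / sd
    return TraitTable(taxa=list(table.taxa), traits=list(table.traits), values=X,
                      trait_class=list(table.trait_class) if table.trait_class else None,
                      trait_kind=list(table.trait_kind) if table.trait_kind else None)


def pairwise_sq_missing(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise sums of squared differences over mutually observed columns.

    Returns (SQ, M): SQ[i, j] = sum_k obs (x_ik - x_jk)^2, M[i, j] = count of
    mutually observed columns.  Vectorized; the workhorse behind both the
    distance and the trait bootstrap.
    """
    X = np.asarray(X, dtype=float)
    mask = np.isfinite(X)
    A = np.where(mask, X, 0.0)
    S = A * A
    M = mask.astype(float)
    # sum_k obs(i) & obs(j): x_i^2 + x_j^2 - 2 x_i x_j
    P1 = S @ M.T
    cross = A @ A.T
    SQ = P1 + P1.T - 2.0 * cross
    SQ = np.maximum(SQ, 0.0)
    return SQ, M @ M.T


def euclidean_missing(table: TraitTable) -> DistanceMatrix:
    """Missing-aware Euclidean distance matrix (pairwise deletion, rescaled)."""
    SQ, m = pairwise_sq_missing(table.values)
    P = table.n_traits
    off = ~np.eye(table.n_taxa, dtype=bool)
    if np.any(m[off] == 0):
        i, j = np.argwhere((m == 0) & off)[0]
        raise ValueError(
            f"taxa {table.taxa[i]!r} and {table.taxa[j]!r} share no observed trait")
    with np.errstate(divide="ignore", invalid="ignore"):
        D = np.sqrt(np.where(m > 0, (P / np.where(m > 0, m, 1.0)) * SQ, 0.0))
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(taxa=list(table.taxa), D=D, kind="phenotypic")


def trait_correlations(table: TraitTable, min_n: int = 3) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations between traits.

    Pairs with fewer than ``min_n`` mutually observed taxa (or zero variance)
    are NaN-flagged, never fatal.
    """
    p = table.n_traits
    R = np.full((p, p), np.nan)
    np.fill_diagonal(R, 1.0)
    X = table.values
    for a in range(p):
        for b in range(a + 1, p):
            obs = np.isfinite(X[:, a]) & np.isfinite(X[:, b])
            if obs.sum() < min_n:
                continue
            xa, xb = X[obs, a], X[obs, b]
            if xa.std() == 0 or xb.std() == 0:
                continue
            R[a, b] = R[b, a] = np.corrcoef(xa, xb)[0, 1]
    return pd.DataFrame(R, index=table.traits, columns=table.traits)
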