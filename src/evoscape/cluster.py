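"""Ward.D2 clustering and multiscale-bootstrap (AU) cluster support.

The dendrogram is built on the *unsquared* missing-aware Euclidean distances
(ward.D2).  Cluster support follows the multiscale bootstrap: the trait set
is resampled at sizes from 0.5x to 10x the original, the recovery frequency
(BP) of each observed node is recorded per scale, and a weighted probit fit
psi(r) = v*sqrt(r) + c/sqrt(r) yields the approximately unbiased p-value
AU = 1 - Phi(v - c).  Resampling acts on traits (features), never taxa: the
taxa are the objects being clustered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import norm

from .core_io import TraitTable
from .traitprep import DistanceMatrix, pairwise_sq_missing

__all__ = ["Dendrogram", "ward_linkage", "cut_k", "au_support", "au_from_bp"]

DEFAULT_SCALES = tuple(np.arange(0.5, 10.01, 0.5))


@dataclass
class Dendrogram:
    """Agglomerative merge sequence over named taxa (scipy linkage format),
    optionally annotated with per-node bootstrap (BP) and AU support."""

    taxa: list[str]
    Z: np.ndarray  # scipy linkage matrix, (n-1, 4)
    support: pd.DataFrame | None = field(default=None)

    @property
    def n(self) -> int:
        return len(self.taxa)

    def heights(self) -> np.ndarray:
        return self.Z[:, 2]

    def node_sets(self) -> list[frozenset[int]]:
        """Member (taxon-index) set of each internal node, in merge order."""
        n = self.n
        sets: list[frozenset[int]] = []
        for a, b in self.Z[:, :2].astype(int):
            sa = frozenset([a]) if a < n else sets[a - n]
            sb = frozenset([b]) if b < n else sets[b - n]
            sets.append(sa | sb)
        return sets

    def cophenetic(self) -> DistanceMatrix:
        coph = squareform(hierarchy.cophenet(self.Z))
        return DistanceMatrix(taxa=list(self.taxa), D=coph, kind="cophenetic")

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.Z)

        def rec(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.taxa[node.id]}:{length:.6f}"
            return (f"({rec(node.left, node.dist)},{rec(node.right, node.dist)})"
                    f":{length:.6f}")

        return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"

    def merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.Z, columns=["child_a", "child_b", "height", "size"])

    def write(self, path_prefix: str | Path) -> None:
        p = Path(path_prefix)
        self.merge_table().to_csv(p.with_suffix(".merges.csv"), index=False)
        p.with_suffix(".nwk").write_text(self.to_newick() + "\n", encoding="utf-8")
        if self.support is not None:
            self.support.to_csv(p.with_suffix(".support.csv"), index=False)


def ward_linkage(D: DistanceMatrix) -> Dendrogram:
    """Ward.D2 agglomeration on unsquared distances (Lance–Williams update
    d(ij,k) = sqrt(((n_i+n_k)d_ik^2 + (n_j+n_k)d_jk^2 - n_k d_ij^2)/(n_i+n_j+n_k)))."""
    if D.n < 2:
        raise ValueError("need at least 2 taxa")
    Z = hierarchy.linkage(D.condensed(), method="ward")
    return Dendrogram(taxa=list(D.taxa), Z=Z)


def cut_k(dend: Dendrogram, k: int) -> dict[str, int]:
    """Cut the merge sequence into exactly k groups.

    Labels are integers numbered by order of first taxon appearance (taxon 0's
    group is 0, the next unseen group is 1, ...)."""
    if not 1 <= k <= dend.n:
        raise ValueError(f"k={k} out of range 1..{dend.n}")
    raw = hierarchy.cut_tree(dend.Z, n_clusters=k).ravel()
    relabel: dict[int, int] = {}
    out: dict[str, int] = {}
    for taxon, g in zip(dend.taxa, raw):
        if g not in relabel:
            relabel[g] = len(relabel)
        out[taxon] = relabel[g]
    return out


def au_from_bp(scales: np.ndarray, bp: np.ndarray, B: np.ndarray | int,
               ) -> tuple[float, float, float]:
    """Fit the multiscale-bootstrap probit curve for one node.

    psi_r = Phi^-1(1 - BP_r) is regressed on (sqrt(r), 1/sqrt(r)) by WLS with
    delta-method weights B*phi(z)^2/(BP(1-BP)); AU = 1 - Phi(v - c).  Scales
    with degenerate BP (0 or 1) carry no curvature information and are
    excluded; with fewer than 2 informative scales the AU falls back to the
    clipped extreme recovery frequency.
    Returns (au, v, c); (nan, nan, nan) when nothing can be estimated."""
    scales = np.asarray(scales, dtype=float)
    bp = np.asarray(bp, dtype=float)
    B = np.broadcast_to(np.asarray(B, dtype=float), bp.shape)
    ok = np.isfinite(bp) & (B > 0)
    if not ok.any():
        return float("nan"), float("nan"), float("nan")
    inner = ok & (bp > 0.0) & (bp < 1.0)
    if inner.sum() < 2:
        mean_bp = float(bp[ok].mean())
        Bm = float(B[ok].mean())
        au = float(np.clip(mean_bp, 1.0 / (Bm + 1.0), 1.0 - 1.0 / (Bm + 1.0)))
        return au, float("nan"), float("nan")
    r, p, b = scales[inner], bp[inner], B[inner]
    p = np.clip(p, 1.0 / (b + 1.0), 1.0 - 1.0 / (b + 1.0))
    z = norm.ppf(p)
    psi = norm.ppf(1.0 - p)
    w = b * norm.pdf(z) ** 2 / (p * (1.0 - p))
    Xd = np.column_stack([np.sqrt(r), 1.0 / np.sqrt(r)])
    W = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(Xd * W[:, None], psi * W, rcond=None)
    v, c = coef
    return float(1.0 - norm.cdf(v - c)), float(v), float(c)


def _node_sets_from_linkage(Z: np.ndarray, n: int) -> set[frozenset[int]]:
    sets: list[frozenset[int]] = []
    for a, b in Z[:, :2].astype(int):
        sa = frozenset([a]) if a < n else sets[a - n]
        sb = frozenset([b]) if b < n else sets[b - n]
        sets.append(sa | sb)
    return set(sets)


def au_support(table: TraitTable, scales=DEFAULT_SCALES, B: int = 1000,
               seed: int | np.random.Generator | None = None) -> Dendrogram:
    """Multiscale bootstrap of the trait set with AU p-values per node.

    For each scale r, B resamples of round(r*P) trait columns (with
    replacement) are drawn, the missing-aware distance and ward.D2 dendrogram
    recomputed, and each observed node's taxon set scored as recovered or not.
    Replicates in which some taxon pair shares no observed trait are skipped
    (the effective B per scale is reported)."""
    if B < 2:
        raise ValueError("B must be >= 2")
    scales = np.asarray(scales, dtype=float)
    if np.any(scales <= 0):
        raise ValueError("scales must be positive")
    rng = np.random.default_rng(seed)
    P = table.n_traits
    if P < 2:
        raise ValueError("need at least 2 traits")
    n = table.n_taxa
    X = table.values

    def dist_condensed(cols: np.ndarray) -> np.ndarray | None:
        SQ, m = pairwise_sq_missing(X[:, cols])
        iu = np.triu_indices(n, 1)
        mm = m[iu]
        if np.any(mm == 0):
            return None
        return np.sqrt(cols.size / mm * SQ[iu])

    base = dist_condensed(np.arange(P))
    if base is None:
        raise ValueError("some taxon pair shares no observed trait")
    Z0 = hierarchy.linkage(base, method="ward")
    dend = Dendrogram(taxa=list(table.taxa), Z=Z0)
    obs_sets = dend.node_sets()

    counts = np.zeros((len(scales), len(obs_sets)), dtype=int)
    eff_B = np.zeros(len(scales), dtype=int)
    for si, r in enumerate(scales):
        m_cols = max(2, int(round(r * P)))
        for _ in range(B):
            cols = rng.integers(0, P, size=m_cols)
            cond = dist_condensed(cols)
            if cond is None:
                continue
            eff_B[si] += 1
            rep_sets = _node_sets_from_linkage(
                hierarchy.linkage(cond, method="ward"), n)
            for ni, s in enumerate(obs_sets):
                if s in rep_sets:
                    counts[si, ni] += 1

    with np.errstate(invalid="ignore"):
        bp = counts / np.where(eff_B[:, None] > 0, eff_B[:, None], np.nan)
    rows = []
    for ni, s in enumerate(obs_sets):
        au, v, c = au_from_bp(scales, bp[:, ni], eff_B)
        rows.append({
            "node": ni,
            "members": "|".join(sorted(table.taxa[i] for i in s)),
            "size": len(s),
            "bp_at_1": float(bp[np.argmin(np.abs(scales - 1.0)), ni]),
            "au": au, "v": v, "c": c,
        })
    support = pd.DataFrame(rows)
    bp_cols = pd.DataFrame(bp.T, columns=[f"bp_r{r:g}" for r in scales])
    dend.support = pd.concat([support, bp_cols], axis=1)
    return dend
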