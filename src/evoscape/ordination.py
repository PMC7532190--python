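"""Morphospace ordination: PCoA with Cailliez correction, and 2-D NMDS.

Missing-aware distances are generally non-Euclidean, so the principal
coordinates analysis applies the Cailliez correction: the smallest constant
added to every off-diagonal distance that makes the matrix Euclidean-
embeddable (the largest eigenvalue of a 2n x 2n companion matrix).  NMDS
minimizes Kruskal stress-1 by SMACOF iterations interleaved with monotone
(pool-adjacent-violators) regression of configuration distances on the rank
order of the input dissimilarities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform

from .traitprep import DistanceMatrix

__all__ = ["Ordination", "pcoa_cailliez", "nmds", "nmds_fit"]


@dataclass
class Ordination:
    """Low-dimensional coordinates plus eigenvalues (PCoA) or stress (NMDS)."""

    taxa: list[str]
    coords: np.ndarray  # (n, k)
    method: str  # "PCoA" | "NMDS"
    eigenvalues: np.ndarray | None = None
    rel_eigenvalues: np.ndarray | None = None
    stress: float | None = None
    cailliez_constant: float = 0.0
    converged: bool = True
    stress_path: list[float] = field(default_factory=list, repr=False)

    @property
    def n_axes(self) -> int:
        return self.coords.shape[1]

    def axes(self, which) -> np.ndarray:
        """Coordinate subset: int k -> first k axes; 'all' -> every axis."""
        if which == "all":
            return self.coords
        return self.coords[:, :int(which)]

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.coords, index=self.taxa,
                          columns=[f"axis{i + 1}" for i in range(self.n_axes)])
        df.index.name = "taxon"
        df.to_csv(path)
        side = {"method": self.method, "cailliez_constant": self.cailliez_constant,
                "stress": self.stress,
                "eigenvalues": None if self.eigenvalues is None else self.eigenvalues.tolist(),
                "rel_eigenvalues": None if self.rel_eigenvalues is None else self.rel_eigenvalues.tolist()}
        Path(path).with_suffix(".json").write_text(json.dumps(side, indent=2),
                                                   encoding="utf-8")


def _gower_center(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * J @ (D ** 2) @ J


def cailliez_constant(D: np.ndarray) -> float:
    """Smallest c such that D + c (off-diagonal) is Euclidean-embeddable:
    the largest real eigenvalue of [[0, 2*Delta1], [-I, -4*Delta2]]."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    d1 = -0.5 * J @ (D ** 2) @ J
    d2 = -0.5 * J @ D @ J
    block = np.block([[np.zeros((n, n)), 2.0 * d1],
                      [-np.eye(n), -4.0 * d2]])
    ev = np.linalg.eigvals(block)
    return float(np.max(ev.real))


def pcoa_cailliez(D: DistanceMatrix, apply_cailliez: bool = True) -> Ordination:
    """Principal coordinates of a distance matrix.

    If the Gower-centred matrix has a meaningfully negative eigenvalue
    (< -1e-8 * max|lambda|) the Cailliez constant is added to all off-diagonal
    distances and the decomposition is redone.  Axes with positive eigenvalues
    are retained, scaled by sqrt(lambda); relative eigenvalues are reported
    against the positive-eigenvalue total."""
    if D.n < 3:
        raise ValueError("PCoA needs at least 3 taxa")
    Dm = D.D.copy()
    c = 0.0
    lam, vec = np.linalg.eigh(_gower_center(Dm))
    tol = 1e-8 * max(np.abs(lam).max(), 1.0)
    if apply_cailliez and lam.min() < -tol:
        c = cailliez_constant(Dm)
        if c > 0:
            off = ~np.eye(D.n, dtype=bool)
            Dm = Dm + c * off
            lam, vec = np.linalg.eigh(_gower_center(Dm))
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    keep = lam > tol
    coords = vec[:, keep] * np.sqrt(lam[keep])
    pos_sum = lam[lam > 0].sum()
    return Ordination(taxa=list(D.taxa), coords=coords, method="PCoA",
                      eigenvalues=lam, rel_eigenvalues=lam / pos_sum,
                      cailliez_constant=c)


def _stress1(dhat: np.ndarray, dtilde: np.ndarray) -> float:
    denom = (dtilde ** 2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((dhat - dtilde) ** 2).sum() / denom))


def _monotone_fit(dtilde: np.ndarray, order: np.ndarray,
                  blocks: np.ndarray) -> np.ndarray:
    """Isotonic regression of configuration distances on dissimilarity rank.

    ``order`` sorts by input dissimilarity; tied dissimilarities (same block
    id) are averaged before the PAV fit and share a fitted value."""
    y = dtilde[order]
    # average within tie blocks, weight by block size
    uniq, inv, cnt = np.unique(blocks, return_inverse=True, return_counts=True)
    sums = np.zeros(uniq.size)
    np.add.at(sums, inv, y)
    means = sums / cnt
    fit = isotonic_regression(means, weights=cnt.astype(float)).x
    dhat = np.empty_like(y)
    dhat = fit[inv]
    out = np.empty_like(dtilde)
    out[order] = dhat
    return out


def _guttman(X: np.ndarray, dhat: np.ndarray, dtilde: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(dtilde > 0, dhat / dtilde, 0.0)
    Bmat = -squareform(ratio)
    np.fill_diagonal(Bmat, -Bmat.sum(axis=1))
    return Bmat @ X / n


def nmds(D: DistanceMatrix, k: int = 2, n_starts: int = 20, maxit: int = 200,
         tol: float = 1e-7, seed: int | np.random.Generator | None = None,
         ) -> Ordination:
    """Non-metric MDS minimizing Kruskal stress-1.

    Best of ``n_starts`` random starts plus one metric (PCoA) start.  Each
    SMACOF step is guarded by a halving line search so stress-1 is
    non-increasing within a start; the final configuration is centred and
    rotated to its principal axes."""
    n = D.n
    if n < k + 1:
        raise ValueError("too few taxa for NMDS")
    diss = D.condensed()
    order = np.argsort(diss, kind="stable")
    # tie blocks: equal dissimilarities share one fitted disparity
    sorted_d = diss[order]
    blocks = np.concatenate([[0], np.cumsum(np.diff(sorted_d) > 1e-12)])
    rng = np.random.default_rng(seed)

    starts: list[np.ndarray] = []
    try:
        pc = pcoa_cailliez(D)
        starts.append(pc.coords[:, :k] if pc.coords.shape[1] >= k else None)
    except Exception:
        starts.append(None)
    scale = max(diss.max(), 1.0)
    for _ in range(n_starts):
        starts.append(rng.normal(scale=scale, size=(n, k)))

    best = None
    best_stress = np.inf
    best_path: list[float] = []
    any_converged = False
    for X0 in starts:
        if X0 is None or X0.shape[1] < k:
            continue
        X = X0.copy()
        dtilde = pdist(X)
        dhat = _monotone_fit(dtilde, order, blocks)
        stress = _stress1(dhat, dtilde)
        path = [stress]
        converged = False
        for _ in range(maxit):
            Xn = _guttman(X, dhat, dtilde)
            # line search guard: stress-1 must not increase
            for _half in range(30):
                dt_n = pdist(Xn)
                dh_n = _monotone_fit(dt_n, order, blocks)
                s_n = _stress1(dh_n, dt_n)
                if s_n <= stress + 1e-15:
                    break
                Xn = 0.5 * (Xn + X)
            else:
                converged = True
                break
            X, dtilde, dhat = Xn, dt_n, dh_n
            path.append(s_n)
            if stress - s_n < tol * max(stress, 1e-12):
                converged = True
                stress = s_n
                break
            stress = s_n
        any_converged |= converged
        if stress < best_stress:
            best_stress, best, best_path = stress, X, path

    # centre and rotate to principal axes
    best = best - best.mean(axis=0)
    _, _, Vt = np.linalg.svd(best, full_matrices=False)
    best = best @ Vt.T
    return Ordination(taxa=list(D.taxa), coords=best, method="NMDS",
                      stress=best_stress, converged=any_converged,
                      stress_path=best_path)


def nmds_fit(D: DistanceMatrix, ordn: Ordination) -> dict[str, float]:
    """Goodness of fit: nonmetric R² = 1 - stress², and the squared Pearson
    correlation between configuration distances and input dissimilarities."""
    if ordn.taxa != D.taxa:
        raise ValueError("ordination and distance matrix taxa mismatch")
    if ordn.stress is None:
        raise ValueError("ordination has no stress (not an NMDS result?)")
    dtilde = pdist(ordn.coords)
    diss = D.condensed()
    r = np.corrcoef(dtilde, diss)[0, 1]
    return {"nonmetric_R2": 1.0 - ordn.stress ** 2, "linear_R2": float(r ** 2)}
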