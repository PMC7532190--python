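"""Tip-based convergence statistics with Brownian-motion nulls.

For a pair of putatively convergent tips, let Dtip be their phenotypic
distance and Dmax the maximum distance between any two post-divergence
ancestors of the two lineages (each lineage's candidate set runs from just
below the MRCA down to, and including, the tip).  Then

    C1 = 1 - Dtip/Dmax          (fraction of maximal divergence closed)
    C2 = Dmax - Dtip            (absolute distance closed)
    C3 = C2 / L_lineages        (scaled by phenotypic path length of the two
                                 MRCA-to-tip lineages)
    C4 = C2 / L_clade           (scaled by total phenotypic evolution in the
                                 clade rooted at the MRCA)

Multi-tip groups average each metric over unordered tip pairs.  Significance
comes from simulating Brownian motion (rate fitted to the data by
independent contrasts) and recomputing the metrics per replicate.

The angle-based test treats each tip's mean-centred ordination vector as a
direction in morphospace: small mean angles between the designated tips —
especially per unit divergence time — indicate convergence relative to
random tip sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .phylo import Chronogram, asr_bm, asr_smoother, bm_rate, patristic, sim_bm

__all__ = ["ConvergenceReport", "stayton_metrics", "stayton_pvalues",
           "angle_state_convergence"]

METRICS = ("C1", "C2", "C3", "C4")


@dataclass
class ConvergenceReport:
    focal: list[str]
    axes: str
    timescaling: str = ""
    metrics: dict = field(default_factory=dict)
    pvalues: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        row = {"focal": "+".join(self.focal), "axes": self.axes,
               "timescaling": self.timescaling}
        row.update(self.metrics)
        row.update({f"p_{k}": v for k, v in self.pvalues.items()})
        return pd.DataFrame([row])


class _PairGeometry:
    """Index arrays for one focal pair, reusable across simulated datasets."""

    def __init__(self, chron: Chronogram, t1: int, t2: int):
        mrca = chron.mrca(t1, t2)
        self.t1, self.t2, self.mrca = t1, t2, mrca

        def path(tip: int) -> list[int]:
            nodes = []
            v = tip
            while v != mrca:
                nodes.append(v)
                v = int(chron.parent[v])
            return nodes  # tip ... just-below-mrca (mrca excluded)

        p1, p2 = path(t1), path(t2)
        cand = [(a, b) for a in p1 for b in p2]
        self.cand_a = np.array([a for a, _ in cand])
        self.cand_b = np.array([b for _, b in cand])
        lineage = p1 + p2
        self.lin_child = np.array(lineage)
        self.lin_parent = chron.parent[self.lin_child]
        clade = [v for v in chron.clade_nodes(mrca) if v != mrca]
        self.clade_child = np.array(clade)
        self.clade_parent = chron.parent[self.clade_child]


def _pair_metrics(V: np.ndarray, g: _PairGeometry) -> dict[str, np.ndarray]:
    """Metrics for one pair from node-value array V of shape (..., nodes, k)."""

    def dist(i, j):
        return np.linalg.norm(V[..., i, :] - V[..., j, :], axis=-1)

    dtip = dist(g.t1, g.t2)
    dmax = dist(g.cand_a, g.cand_b).max(axis=-1)
    l_lin = dist(g.lin_child, g.lin_parent).sum(axis=-1)
    l_clade = dist(g.clade_child, g.clade_parent).sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c1 = 1.0 - dtip / dmax
        c2 = dmax - dtip
        c3 = c2 / l_lin
        c4 = c2 / l_clade
    return {"C1": c1, "C2": c2, "C3": c3, "C4": c4}


def _focal_indices(chron: Chronogram, focal) -> list[int]:
    idx = []
    for t in focal:
        if isinstance(t, str):
            if t not in chron.labels:
                raise ValueError(f"focal tip {t!r} not in tree")
            idx.append(chron.tip_index(t))
        else:
            idx.append(int(t))
    if len(set(idx)) != len(idx) or len(idx) < 2:
        raise ValueError("focal tips must be >= 2 distinct tips")
    return idx


def _group_metrics(V: np.ndarray, geoms: list[_PairGeometry]) -> dict[str, np.ndarray]:
    acc = {m: [] for m in METRICS}
    for g in geoms:
        pm = _pair_metrics(V, g)
        for m in METRICS:
            acc[m].append(pm[m])
    return {m: np.mean(acc[m], axis=0) for m in METRICS}


def stayton_metrics(chron: Chronogram, X: np.ndarray, focal,
                    anc: np.ndarray | None = None) -> dict[str, float]:
    """Observed C1–C4 for a focal tip group on the supplied axes.

    ``X`` is (n_tips, k) tip coordinates; ancestral states come from ML
    Brownian reconstruction unless ``anc`` injects a full (n_nodes, k) array."""
    idx = _focal_indices(chron, focal)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != chron.n_tips:
        X = X.T
    V = asr_bm(chron, X) if anc is None else np.asarray(anc, dtype=float)
    if V.shape != (chron.n_nodes, X.shape[1]):
        raise ValueError("injected node values have wrong shape")
    geoms = [_PairGeometry(chron, a, b) for a, b in combinations(idx, 2)]
    out = _group_metrics(V, geoms)
    if not np.isfinite(out["C1"]):
        raise ValueError("Dmax = 0: no ancestral divergence to reverse")
    return {m: float(v) for m, v in out.items()}


def stayton_pvalues(chron: Chronogram, X: np.ndarray, focal, nsim: int = 1000,
                    seed: int | np.random.Generator | None = None,
                    anc_mode: str = "asr") -> dict[str, float]:
    """Brownian-null p-values for C1–C4.

    The rate matrix is fitted to the data by independent contrasts and the
    root set to the reconstructed ancestral state; ``nsim`` multivariate BM
    replicates are simulated along the chronogram.  ``anc_mode='asr'``
    re-estimates ancestors per replicate with the (precomputed, linear) ML
    smoother, treating simulations exactly like the observed data;
    ``'true'`` uses the simulation's own node values.
    p = (1 + #{sim metric >= observed}) / (1 + nsim)."""
    idx = _focal_indices(chron, focal)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != chron.n_tips:
        X = X.T
    geoms = [_PairGeometry(chron, a, b) for a, b in combinations(idx, 2)]
    V_obs = asr_bm(chron, X)
    obs = _group_metrics(V_obs, geoms)
    R = bm_rate(chron, X)
    root = V_obs[chron.root]
    sims = sim_bm(chron, R, root, nsim, seed)  # (nsim, nodes, k)
    if anc_mode == "asr":
        S = asr_smoother(chron)
        tips = sims[:, : chron.n_tips, :]
        sims = sims.copy()
        sims[:, chron.n_tips:, :] = np.einsum("ij,sjk->sik", S, tips)
    elif anc_mode != "true":
        raise ValueError("anc_mode must be 'asr' or 'true'")
    sim_m = _group_metrics(sims, geoms)
    out: dict[str, float] = {}
    for m in METRICS:
        vals = sim_m[m]
        good = np.isfinite(vals)
        hits = int((vals[good] >= obs[m]).sum())
        out[m] = float(obs[m])
        out[f"p_{m}"] = (1 + hits) / (1 + int(good.sum()))
    return out


def angle_state_convergence(chron: Chronogram, X: np.ndarray, state_tips,
                            nrand: int = 1000,
                            seed: int | np.random.Generator | None = None,
                            ) -> dict[str, float]:
    """Mean angle (degrees) between mean-centred phenotype vectors of a tip
    set, and per-Ma angle using patristic divergence times; randomization p's
    against same-size random tip sets (small values indicate convergence)."""
    idx = _focal_indices(chron, state_tips)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != chron.n_tips:
        X = X.T
    Xc = X - X.mean(axis=0)
    norms = np.linalg.norm(Xc, axis=1)
    if np.any(norms[idx] == 0):
        raise ValueError("a state tip has zero-norm centred coordinates")
    T = patristic(chron).D

    def mean_angles(tipset: list[int]) -> tuple[float, float]:
        angs, angs_t = [], []
        for a, b in combinations(tipset, 2):
            if norms[a] == 0 or norms[b] == 0:
                cosv = 1.0
            else:
                cosv = np.dot(Xc[a], Xc[b]) / (norms[a] * norms[b])
            theta = float(np.degrees(np.arccos(np.clip(cosv, -1.0, 1.0))))
            angs.append(theta)
            t = T[a, b]
            angs_t.append(theta / t if t > 0 else np.nan)
        return float(np.mean(angs)), float(np.nanmean(angs_t))

    ang, ang_t = mean_angles(idx)
    rng = np.random.default_rng(seed)
    obs_set = frozenset(idx)
    all_tips = np.arange(chron.n_tips)
    hits_a = hits_t = 0
    for _ in range(nrand):
        while True:
            draw = rng.choice(all_tips, size=len(idx), replace=False)
            if frozenset(int(d) for d in draw) != obs_set:
                break
        ra, rt = mean_angles([int(d) for d in draw])
        if ra <= ang:
            hits_a += 1
        if rt <= ang_t:
            hits_t += 1
    return {"ang_state": ang, "ang_state_time": ang_t,
            "p_ang_state": (1 + hits_a) / (1 + nrand),
            "p_ang_state_time": (1 + hits_t) / (1 + nrand)}
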