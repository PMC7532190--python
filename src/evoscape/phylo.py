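"""Time-calibrated trees from stratigraphic ranges, and Brownian-motion tools.

A cladogram plus first/last appearance data yields an initial chronogram
(tip age = FAD, node age = oldest descendant) riddled with zero-length
branches; the 'equal' and 'mbl' a-posteriori timescalers then redistribute
time so every branch has positive duration while preserving tip ages and
root-to-tip totals.  On such chronograms the module estimates Brownian
evolutionary rates (independent contrasts), maximum-likelihood ancestral
states, and simulates multivariate Brownian motion — the null model for the
convergence statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import RangeTable, Tree

__all__ = [
    "Chronogram",
    "RateMatrix",
    "timescale_initial",
    "timescale_equal",
    "timescale_mbl",
    "patristic",
    "asr_bm",
    "asr_smoother",
    "bm_rate",
    "sim_bm",
]

_EPS = 1e-12


@dataclass
class Chronogram:
    """Rooted binary tree with node ages in Ma before present.

    Nodes are indexed 0..M-1 with tips first (0..n-1, matching ``labels``);
    ``parent[root] == -1``.  Branch duration of node v is
    ``ages[parent[v]] - ages[v]`` and must be non-negative.
    """

    labels: list[str]
    parent: np.ndarray
    ages: np.ndarray
    _children: list[list[int]] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=int)
        self.ages = np.asarray(self.ages, dtype=float)
        M = self.parent.size
        if self.ages.shape != (M,):
            raise ValueError("ages/parent length mismatch")
        self._children = [[] for _ in range(M)]
        roots = []
        for v, p in enumerate(self.parent):
            if p < 0:
                roots.append(v)
            else:
                self._children[p].append(v)
        if len(roots) != 1:
            raise ValueError("chronogram must have exactly one root")
        self.root = roots[0]

    # -- structure ---------------------------------------------------------
    @property
    def n_tips(self) -> int:
        return len(self.labels)

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    def children(self, v: int) -> list[int]:
        return self._children[v]

    def is_tip(self, v: int) -> bool:
        return v < self.n_tips

    def preorder(self) -> list[int]:
        order, stack = [], [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(reversed(self._children[v]))
        return order

    def postorder(self) -> list[int]:
        return self.preorder()[::-1]

    def durations(self) -> np.ndarray:
        """Branch duration per node (NaN at the root)."""
        dur = np.full(self.n_nodes, np.nan)
        nz = self.parent >= 0
        dur[nz] = self.ages[self.parent[nz]] - self.ages[np.where(nz)[0]]
        return dur

    def validate(self) -> None:
        dur = self.durations()
        bad = np.where(dur < -1e-9)[0]
        if bad.size:
            raise ValueError(f"negative branch duration at node {bad[0]}")

    def copy(self) -> "Chronogram":
        return Chronogram(labels=list(self.labels), parent=self.parent.copy(),
                          ages=self.ages.copy())

    def tip_index(self, label: str) -> int:
        return self.labels.index(label)

    def path_to_root(self, v: int) -> list[int]:
        out = [v]
        while self.parent[out[-1]] >= 0:
            out.append(int(self.parent[out[-1]]))
        return out

    def mrca(self, a: int, b: int) -> int:
        anc = set(self.path_to_root(a))
        for v in self.path_to_root(b):
            if v in anc:
                return v
        raise RuntimeError("disconnected tree")  # pragma: no cover

    def clade_nodes(self, v: int) -> list[int]:
        out, stack = [], [v]
        while stack:
            w = stack.pop()
            out.append(w)
            stack.extend(self._children[w])
        return out

    def prune(self, keep_labels: Sequence[str]) -> "Chronogram":
        """Subtree induced by a tip subset; node ages are preserved and
        unifurcations suppressed."""
        keep = [t for t in self.labels if t in set(keep_labels)]
        if len(keep) < 2:
            raise ValueError("need at least 2 tips after pruning")
        keep_idx = {self.tip_index(t) for t in keep}
        needed = set()
        for v in keep_idx:
            needed.update(self.path_to_root(v))
        # drop internal nodes with a single needed child (unifurcations)
        child_count = {v: sum(1 for c in self._children[v] if c in needed)
                       for v in needed if v not in keep_idx}
        new_parent_of: dict[int, int] = {}
        for v in sorted(needed):
            p = int(self.parent[v])
            while p >= 0 and child_count.get(p, 2) < 2:
                p = int(self.parent[p])
            new_parent_of[v] = p
        kept_nodes = [v for v in needed
                      if v in keep_idx or child_count.get(v, 0) >= 2]
        tips_new = [v for v in kept_nodes if v in keep_idx]
        internal_new = [v for v in kept_nodes if v not in keep_idx]
        order = tips_new + internal_new
        remap = {old: new for new, old in enumerate(order)}
        parent = np.array([remap.get(new_parent_of[v], -1) for v in order])
        ages = self.ages[order]
        labels = [self.labels[v] for v in tips_new]
        return Chronogram(labels=labels, parent=parent, ages=ages)

    # -- construction ------------------------------------------------------
    @classmethod
    def from_tree(cls, tree: Tree, ages: dict[str, float] | None = None,
                  ) -> "Chronogram":
        """Index a (binary) dendropy-backed tree; ages default to branch-length
        depths measured from the deepest tip (0 if no lengths)."""
        from .core_io import normalize_name

        leaves = list(tree.dtree.leaf_node_iter())
        labels = [normalize_name(lf.taxon.label) for lf in leaves]
        n = len(labels)
        index = {id(lf): i for i, lf in enumerate(leaves)}
        nxt = n
        for node in tree.dtree.postorder_node_iter():
            if node.child_nodes():
                index[id(node)] = nxt
                nxt += 1
        M = nxt
        parent = np.full(M, -1, dtype=int)
        age_arr = np.zeros(M)
        # depth from root via branch lengths
        depth = {}
        for node in tree.dtree.preorder_node_iter():
            pn = node.parent_node
            d = 0.0 if pn is None else depth[id(pn)] + (node.edge.length or 0.0)
            depth[id(node)] = d
            if pn is not None:
                parent[index[id(node)]] = index[id(pn)]
        maxd = max(depth.values()) if depth else 0.0
        for node in tree.dtree.preorder_node_iter():
            age_arr[index[id(node)]] = maxd - depth[id(node)]
        chron = cls(labels=labels, parent=parent, ages=age_arr)
        if ages is not None:
            chron = timescale_initial_from_ages(chron, ages)
        return chron

    def to_newick(self) -> str:
        dur = self.durations()

        def rec(v: int) -> str:
            if self.is_tip(v):
                name = self.labels[v]
            else:
                name = ""
            if self._children[v]:
                inner = ",".join(rec(c) for c in self._children[v])
                name = f"({inner}){name}"
            if self.parent[v] >= 0:
                return f"{name}:{dur[v]:.6f}"
            return name

        return rec(self.root) + ";"

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n", encoding="utf-8")

    def node_ages_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "node": np.arange(self.n_nodes),
            "label": [self.labels[v] if v < self.n_tips else "" for v in range(self.n_nodes)],
            "age_Ma": self.ages,
        })


@dataclass
class RateMatrix:
    """Symmetric PSD evolutionary rate matrix (per Ma) over a set of axes."""

    R: np.ndarray

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        if self.R.ndim != 2 or self.R.shape[0] != self.R.shape[1]:
            raise ValueError("rate matrix must be square")
        if not np.allclose(self.R, self.R.T, atol=1e-10):
            raise ValueError("rate matrix must be symmetric")
        ev = np.linalg.eigvalsh(self.R)
        scale = max(abs(ev).max(), 1.0)
        if ev.min() < -1e-10 * scale:
            raise ValueError("rate matrix is not positive semi-definite")

    @property
    def k(self) -> int:
        return self.R.shape[0]

    def sqrt(self) -> np.ndarray:
        s, U = np.linalg.eigh(self.R)
        return U * np.sqrt(np.clip(s, 0.0, None))


# ---------------------------------------------------------------------------
# timescaling


def timescale_initial_from_ages(chron: Chronogram, tip_ages: dict[str, float],
                                root_extension: float = 3.0) -> Chronogram:
    out = chron.copy()
    for i, lab in enumerate(out.labels):
        if lab not in tip_ages:
            raise ValueError(f"no stratigraphic range for tip {lab!r}")
        out.ages[i] = tip_ages[lab]
    for v in out.postorder():
        if not out.is_tip(v):
            out.ages[v] = max(out.ages[c] for c in out.children(v))
    out.ages[out.root] += root_extension
    return out


def timescale_initial(tree: Tree, ranges: RangeTable, root_extension: float = 3.0,
                      tip_age_rule: str = "FAD") -> Chronogram:
    """Initial chronogram: tip age from the range (FAD by default), internal
    node age = oldest descendant tip age, root pushed ``root_extension`` Ma
    older.  Zero-duration branches are expected at this stage."""
    if root_extension < 0:
        raise ValueError("root_extension must be >= 0")
    chron = Chronogram.from_tree(tree)
    tip_ages = {t: ranges.age(t, tip_age_rule) for t in chron.labels
                if t in ranges.taxa}
    return timescale_initial_from_ages(chron, tip_ages, root_extension)


def timescale_equal(chron: Chronogram) -> Chronogram:
    """'equal' timescaler: every maximal root-to-tip run of zero-duration
    branches shares time equally with the nearest positive ancestral branch.

    Intervening node ages slide so a donor branch of duration L followed by k
    zero branches becomes k+1 branches of duration L/(k+1).  Tip ages and
    root-to-tip totals are preserved."""
    out = chron.copy()
    eps = _EPS * max(1.0, abs(out.ages).max())
    dur = out.durations()
    zero = {v for v in range(out.n_nodes)
            if out.parent[v] >= 0 and dur[v] <= eps}
    if not zero:
        return out
    # group zero branches under their nearest positive ancestral branch
    donors: dict[int, list[int]] = {}
    for v in zero:
        u = int(out.parent[v])
        while True:
            if out.parent[u] < 0:
                raise ValueError(
                    "zero-duration run reaches the root; increase root_extension")
            if dur[u] > eps:
                break
            u = int(out.parent[u])
        donors.setdefault(u, []).append(v)
    for donor, members in donors.items():
        comp = set(members)
        p = int(out.parent[donor])
        ap = out.ages[p]
        L = ap - out.ages[donor]
        # depth d(w): edges from p; m(w): edges on the deepest run through w.
        # age(w) = ap - d*L/m divides the donor duration equally along the
        # deepest run; bottom nodes (d == m) keep age ap - L, so tips never
        # move and root-to-tip totals are preserved.
        def depth_below(w: int) -> int:
            kids = [c for c in out.children(w) if c in comp]
            return 1 + max((depth_below(c) for c in kids), default=0) if kids else 0

        def assign(w: int, d: int) -> None:
            m = d + depth_below(w)
            out.ages[w] = ap - d * L / m
            for c in out.children(w):
                if c in comp:
                    assign(c, d + 1)

        assign(donor, 1)
    # clamp: parents at least as old as children (branching runs w/ fixed tips)
    for v in out.postorder():
        if not out.is_tip(v):
            out.ages[v] = max(out.ages[v], max(out.ages[c] for c in out.children(v)))
    out.validate()
    return out


def timescale_mbl(chron: Chronogram, mbl: float = 3.0) -> Chronogram:
    """Minimum-branch-length timescaler: tips-to-root pass pushing parents
    older until every duration >= mbl.  Tip ages unchanged; the root age grows
    if required."""
    if mbl <= 0:
        raise ValueError("mbl must be > 0")
    out = chron.copy()
    for v in out.postorder():
        p = out.parent[v]
        if p >= 0 and out.ages[p] - out.ages[v] < mbl:
            out.ages[p] = out.ages[v] + mbl
    out.validate()
    return out


# ---------------------------------------------------------------------------
# distances, rates, ancestral states, simulation


def patristic(chron: Chronogram):
    """Tip-to-tip path-length (time) distances, as a DistanceMatrix."""
    from .traitprep import DistanceMatrix

    n = chron.n_tips
    mrca_age = np.zeros((n, n))
    tipsets: dict[int, list[int]] = {}
    for v in chron.postorder():
        if chron.is_tip(v):
            tipsets[v] = [v]
        else:
            kids = chron.children(v)
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    for i in tipsets[kids[a]]:
                        for j in tipsets[kids[b]]:
                            mrca_age[i, j] = mrca_age[j, i] = chron.ages[v]
            tipsets[v] = [t for c in kids for t in tipsets[c]]
    D = 2.0 * mrca_age - chron.ages[:n, None] - chron.ages[None, :n]
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(taxa=list(chron.labels), D=np.maximum(D, 0.0),
                          kind="patristic")


def _edge_weights(chron: Chronogram) -> np.ndarray:
    dur = chron.durations()
    pos = dur[np.isfinite(dur) & (dur > 0)]
    floor = 1e-8 * (pos.mean() if pos.size else 1.0)
    w = np.zeros(chron.n_nodes)
    for v in range(chron.n_nodes):
        if chron.parent[v] >= 0:
            w[v] = 1.0 / max(dur[v], floor)
    return w


def asr_smoother(chron: Chronogram) -> np.ndarray:
    """Matrix S with ancestral states = S @ tip_values.

    ML states under Brownian motion minimize sum over branches of
    (Δstate)²/duration — a weighted graph Laplacian solve, linear in the tip
    data, so the smoother can be reused across simulated datasets."""
    n, M = chron.n_tips, chron.n_nodes
    w = _edge_weights(chron)
    L = np.zeros((M, M))
    for v in range(M):
        p = chron.parent[v]
        if p >= 0:
            L[v, v] += w[v]
            L[p, p] += w[v]
            L[v, p] -= w[v]
            L[p, v] -= w[v]
    internal = np.arange(n, M)
    tips = np.arange(n)
    A = L[np.ix_(internal, internal)]
    B = L[np.ix_(internal, tips)]
    return -np.linalg.solve(A, B)


def asr_bm(chron: Chronogram, X: np.ndarray) -> np.ndarray:
    """ML ancestral states under BM for each column of tip matrix X.

    Returns an (n_nodes, k) array with tip rows filled from X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != chron.n_tips:
        X = X.T
    if X.shape[0] != chron.n_tips:
        raise ValueError("tip values shape mismatch")
    if not np.all(np.isfinite(X)):
        raise ValueError("asr_bm requires complete tip values")
    if chron.n_tips == 2:
        dur = chron.durations()
        tips_dur = dur[:2]
        if np.all(tips_dur <= 0) and not np.allclose(X[0], X[1]):
            raise ValueError("zero-duration branches join differing tips: no finite ML")
    S = asr_smoother(chron)
    out = np.empty((chron.n_nodes, X.shape[1]))
    out[: chron.n_tips] = X
    out[chron.n_tips:] = S @ X
    return out


def bm_rate(chron: Chronogram, X: np.ndarray) -> RateMatrix:
    """Evolutionary rate matrix from standardized independent contrasts."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != chron.n_tips:
        X = X.T
    n, k = X.shape
    if n < 3:
        raise ValueError("need >= 3 tips to estimate a rate")
    dur = chron.durations()
    vals = {i: X[i].copy() for i in range(n)}
    blen = {v: (dur[v] if chron.parent[v] >= 0 else 0.0) for v in range(chron.n_nodes)}
    contrasts = []
    for v in chron.postorder():
        kids = chron.children(v)
        if not kids:
            continue
        if len(kids) != 2:
            raise ValueError("contrasts require a binary tree")
        a, b = kids
        ba, bb = blen[a], blen[b]
        if ba + bb <= 0:
            raise ValueError("zero-duration contrast pair")
        contrasts.append((vals[a] - vals[b]) / np.sqrt(ba + bb))
        vals[v] = (bb * vals[a] + ba * vals[b]) / (ba + bb)
        blen[v] += ba * bb / (ba + bb)
    U = np.array(contrasts)
    return RateMatrix(R=(U.T @ U) / (n - 1))


def sim_bm(chron: Chronogram, R: RateMatrix, root: np.ndarray, nsim: int,
           seed: int | np.random.Generator | None = None) -> np.ndarray:
    """Simulate multivariate BM along the chronogram.

    Returns (nsim, n_nodes, k): tip AND internal node values, as the
    convergence nulls need simulated ancestors."""
    rng = np.random.default_rng(seed)
    root = np.asarray(root, dtype=float).ravel()
    k = R.k
    if root.size != k:
        raise ValueError("root vector length must match rate dimension")
    C = R.sqrt()  # (k, k), R = C C'
    dur = chron.durations()
    out = np.empty((nsim, chron.n_nodes, k))
    out[:, chron.root, :] = root
    for v in chron.preorder():
        p = chron.parent[v]
        if p < 0:
            continue
        Z = rng.standard_normal((nsim, k))
        out[:, v, :] = out[:, p, :] + np.sqrt(max(dur[v], 0.0)) * (Z @ C.T)
    return out
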