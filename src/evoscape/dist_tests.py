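"""Permutation tests on distance matrices: one-way PERMANOVA and Mantel.

Both use the (1 + b) / (1 + m) p-value convention (the observed arrangement
counts as one permutation), one-tailed upper.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .traitprep import DistanceMatrix

__all__ = ["PermTestResult", "permanova", "mantel"]


@dataclass
class PermTestResult:
    statistic: float
    p: float
    nperm: int
    seed: int | None
    R2: float | None = None
    method: str = ""

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2), encoding="utf-8")


def _permanova_stats(D2: np.ndarray, groups: np.ndarray, a: int,
                     ) -> tuple[float, float]:
    """(pseudo-F, R²) from squared distances and integer group codes."""
    n = D2.shape[0]
    iu = np.triu_indices(n, 1)
    sst = D2[iu].sum() / n
    ssw = 0.0
    for g in range(a):
        idx = np.where(groups == g)[0]
        if idx.size > 1:
            sub = D2[np.ix_(idx, idx)]
            ssw += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    ssa = sst - ssw
    r2 = ssa / sst if sst > 0 else np.nan
    if ssw <= 0:
        return np.inf if ssa > 0 else np.nan, r2
    f = (ssa / (a - 1)) / (ssw / (n - a))
    return f, r2


def permanova(D: DistanceMatrix, labels: dict[str, int] | np.ndarray,
              nperm: int = 1000, seed: int | np.random.Generator | None = None,
              exhaustive: bool = False) -> PermTestResult:
    """One-way PERMANOVA (pseudo-F on a distance matrix, label permutation).

    ``labels`` maps taxon -> group (any hashable), or is an array aligned with
    ``D.taxa``.  ``exhaustive=True`` enumerates every distinct label
    arrangement (small n only); the p-value is then exact, hits/total."""
    if isinstance(labels, dict):
        lab = np.array([labels[t] for t in D.taxa])
    else:
        lab = np.asarray(labels)
    if lab.shape[0] != D.n:
        raise ValueError("labels do not cover all taxa")
    _, groups = np.unique(lab, return_inverse=True)
    a = groups.max() + 1
    if a < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    counts = np.bincount(groups)
    if (counts >= 2).sum() < 2 and counts.min() < 2:
        raise ValueError("pseudo-F undefined: need >= 2 groups with >= 2 members")
    D2 = D.D ** 2
    f_obs, r2 = _permanova_stats(D2, groups, a)
    if not np.isfinite(f_obs):
        warnings.warn("SSW = 0: pseudo-F infinite; permutation p still defined",
                      stacklevel=2)
    if exhaustive:
        from itertools import permutations

        seen = set()
        hits = total = 0
        for perm in permutations(groups.tolist()):
            if perm in seen:
                continue
            seen.add(perm)
            total += 1
            f_perm, _ = _permanova_stats(D2, np.array(perm), a)
            if f_perm >= f_obs or (np.isinf(f_obs) and np.isinf(f_perm)):
                hits += 1
        return PermTestResult(statistic=float(f_obs), p=hits / total, nperm=total,
                              seed=None, R2=float(r2), method="permanova-exhaustive")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(nperm):
        f_perm, _ = _permanova_stats(D2, rng.permutation(groups), a)
        if f_perm >= f_obs or (np.isinf(f_obs) and np.isinf(f_perm)):
            hits += 1
    p = (1 + hits) / (1 + nperm)
    return PermTestResult(statistic=float(f_obs), p=float(p), nperm=nperm,
                          seed=seed if isinstance(seed, int) else None,
                          R2=float(r2), method="permanova")


def mantel(D1: DistanceMatrix, D2: DistanceMatrix, nperm: int = 1000,
           seed: int | np.random.Generator | None = None,
           exhaustive: bool = False) -> PermTestResult:
    """Mantel test: Pearson r of lower-triangle entries; null by simultaneous
    row/column permutation of the second matrix; one-tailed upper p.

    ``exhaustive=True`` enumerates all n! permutations (exact p, small n)."""
    if D1.taxa != D2.taxa:
        raise ValueError("distance matrices must share the same taxa in order")
    n = D1.n
    il = np.tril_indices(n, -1)
    x = D1.D[il]
    if x.std() == 0 or D2.D[il].std() == 0:
        raise ValueError("zero variance in a distance matrix triangle")

    def corr_with(Dperm: np.ndarray) -> float:
        y = Dperm[il]
        return float(np.corrcoef(x, y)[0, 1])

    r_obs = corr_with(D2.D)
    if exhaustive:
        from itertools import permutations

        hits = total = 0
        for perm in permutations(range(n)):
            total += 1
            if corr_with(D2.D[np.ix_(perm, perm)]) >= r_obs - 1e-12:
                hits += 1
        return PermTestResult(statistic=r_obs, p=hits / total, nperm=total,
                              seed=None, method="mantel-exhaustive")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(nperm):
        perm = rng.permutation(n)
        if corr_with(D2.D[np.ix_(perm, perm)]) >= r_obs:
            hits += 1
    p = (1 + hits) / (1 + nperm)
    return PermTestResult(statistic=r_obs, p=float(p), nperm=nperm,
                          seed=seed if isinstance(seed, int) else None,
                          method="mantel")
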