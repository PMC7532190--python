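"""Sum-of-variance disparity: bootstraps, group comparisons, time bins, and
over/under-dispersion randomization.

Disparity is the sum over axes of the sample variance (n-1 denominator) of a
taxon set's ordination scores.  Uncertainty comes from bootstrapping taxa;
per-time-bin values are compared against random same-size subsets of the
whole dataset to flag over- or under-dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

from .core_io import RangeTable

__all__ = [
    "DisparityReport",
    "JK_BINS",
    "sum_of_variances",
    "sum_of_ranges",
    "bootstrap_disparity",
    "compare_groups",
    "assign_bins",
    "disparity_through_time",
    "dispersion_test",
]

# standard geological stages (Ma), oldest bound first
JK_BINS = {
    "Early Jurassic": (201.4, 174.7),
    "Middle Jurassic": (174.7, 161.5),
    "Late Jurassic": (161.5, 145.0),
    "Early Cretaceous": (145.0, 100.5),
    "Late Cretaceous": (100.5, 66.0),
}


@dataclass
class DisparityReport:
    scope: str
    n_taxa: int
    observed_sov: float
    observed_sor: float | None = None
    boot_median: float | None = None
    q25: float | None = None
    q75: float | None = None
    q025: float | None = None
    q975: float | None = None
    boot_values: np.ndarray | None = field(default=None, repr=False)
    B: int = 0
    seed: int | None = None

    def to_row(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if k != "boot_values"}


def sum_of_variances(X: np.ndarray) -> float:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("need >= 2 taxa for a variance")
    return float(X.var(axis=0, ddof=1).sum())


def sum_of_ranges(X: np.ndarray) -> float:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return float((X.max(axis=0) - X.min(axis=0)).sum())


def bootstrap_disparity(X: np.ndarray, B: int = 1000,
                        seed: int | np.random.Generator | None = None,
                        scope: str = "all") -> DisparityReport:
    """Bootstrap taxa with replacement (same n); median and central 50%/95%
    quantile intervals of the sum of variances."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    obs = sum_of_variances(X)
    rng = np.random.default_rng(seed)
    vals = np.empty(B)
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        vals[b] = X[idx].var(axis=0, ddof=1).sum()
    q = np.quantile(vals, [0.025, 0.25, 0.5, 0.75, 0.975])
    return DisparityReport(scope=scope, n_taxa=n, observed_sov=obs,
                           observed_sor=sum_of_ranges(X),
                           boot_median=float(q[2]), q25=float(q[1]),
                           q75=float(q[3]), q025=float(q[0]), q975=float(q[4]),
                           boot_values=vals, B=B,
                           seed=seed if isinstance(seed, int) else None)


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p with midranks, by full enumeration."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    nx = len(x)
    obs = ranks[:nx].sum()
    mu = nx * (len(pooled) + 1) / 2.0
    obs_dev = abs(obs - mu)
    total = hits = 0
    for comb in combinations(range(len(pooled)), nx):
        total += 1
        if abs(ranks[list(comb)].sum() - mu) >= obs_dev - 1e-12:
            hits += 1
    return hits / total


def compare_groups(boot_a: np.ndarray, boot_b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p comparing two bootstrap distributions.

    Exact enumeration with midranks when both samples have <= 8 values;
    normal approximation with tie correction otherwise."""
    a = np.asarray(boot_a, dtype=float).ravel()
    b = np.asarray(boot_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    if a.size <= 8 and b.size <= 8:
        return float(_exact_ranksum_p(a, b))
    return float(mannwhitneyu(a, b, alternative="two-sided",
                              method="asymptotic").pvalue)


def assign_bins(ranges: RangeTable, bins: dict[str, tuple[float, float]] = None,
                rule: str = "midpoint") -> dict[str, list[str]]:
    """Assign taxa to named age bins (oldest, youngest) in Ma.

    ``rule``: 'midpoint' | 'FAD' (scalar age inside the bin, older bound
    inclusive) or 'any-overlap' (range intersects the bin; a taxon may then
    appear in several bins)."""
    if bins is None:
        bins = JK_BINS
    names = list(bins)
    edges = [bins[n] for n in names]
    for (o1, y1), (o2, y2) in zip(edges, edges[1:]):
        if y1 < o2 - 1e-9 and o2 < o1:
            raise ValueError("bins must be non-overlapping and ordered old->young")
    out: dict[str, list[str]] = {n: [] for n in names}
    unassigned = []
    for i, taxon in enumerate(ranges.taxa):
        if rule == "any-overlap":
            hit = False
            for n in names:
                old, young = bins[n]
                if ranges.lad[i] < old + 1e-9 and ranges.fad[i] > young - 1e-9:
                    out[n].append(taxon)
                    hit = True
            if not hit:
                unassigned.append(taxon)
            continue
        age = ranges.midpoint()[i] if rule == "midpoint" else (
            ranges.fad[i] if rule == "FAD" else ranges.lad[i])
        for n in names:
            old, young = bins[n]
            if young < age <= old:
                out[n].append(taxon)
                break
        else:
            unassigned.append(taxon)
    if unassigned:
        import warnings

        warnings.warn(f"taxa assigned to no bin: {unassigned}", stacklevel=2)
    return out


def disparity_through_time(X: np.ndarray, taxa: list[str], ranges: RangeTable,
                           bins: dict[str, tuple[float, float]] = None,
                           B: int = 1000,
                           seed: int | np.random.Generator | None = None,
                           rule: str = "midpoint") -> dict[str, DisparityReport]:
    """Per-bin bootstrap disparity.  Bins with < 2 taxa are flagged (None)."""
    rng = np.random.default_rng(seed)
    membership = assign_bins(ranges.subset([t for t in taxa if t in ranges.taxa]),
                             bins, rule)
    idx = {t: i for i, t in enumerate(taxa)}
    out: dict[str, DisparityReport | None] = {}
    for name, members in membership.items():
        members = [m for m in members if m in idx]
        if len(members) < 2:
            out[name] = None
            continue
        sub = X[[idx[m] for m in members]]
        out[name] = bootstrap_disparity(sub, B=B, seed=rng, scope=name)
    return out


def dispersion_test(X: np.ndarray, bin_rows: np.ndarray, nrand: int = 1000,
                    seed: int | np.random.Generator | None = None) -> dict:
    """Over/under-dispersion of a bin against random same-size subsets.

    ``bin_rows`` indexes the bin's taxa within X.  nrand subsets of the same
    size are drawn without replacement from all taxa; the quantile q of the
    observed statistic within the null yields the two-tailed
    p = 2*min(q, 1-q), clipped to (0, 1].  Reported for both the sum of
    variances and the sum of ranges."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    rows = np.asarray(bin_rows, dtype=int)
    m = rows.size
    if not 2 <= m <= n:
        raise ValueError("bin size out of range")
    obs_sov = sum_of_variances(X[rows])
    obs_sor = sum_of_ranges(X[rows])
    if m == n:
        return {"sov": obs_sov, "sor": obs_sor, "q_sov": 0.5, "q_sor": 0.5,
                "p_sov": 1.0, "p_sor": 1.0,
                "note": "bin equals the full dataset; every draw identical"}
    rng = np.random.default_rng(seed)
    null_sov = np.empty(nrand)
    null_sor = np.empty(nrand)
    for i in range(nrand):
        draw = rng.choice(n, size=m, replace=False)
        sub = X[draw]
        null_sov[i] = sub.var(axis=0, ddof=1).sum()
        null_sor[i] = (sub.max(axis=0) - sub.min(axis=0)).sum()

    def quant_p(obs: float, null: np.ndarray) -> tuple[float, float]:
        q = float((null < obs).mean() + 0.5 * (null == obs).mean())
        p = 2.0 * min(q, 1.0 - q)
        return q, float(min(max(p, 1.0 / (nrand + 1)), 1.0))

    q_sov, p_sov = quant_p(obs_sov, null_sov)
    q_sor, p_sor = quant_p(obs_sor, null_sor)
    return {"sov": obs_sov, "sor": obs_sor, "q_sov": q_sov, "q_sor": q_sor,
            "p_sov": p_sov, "p_sor": p_sor}


def disparity_table(reports: dict[str, DisparityReport | None]) -> pd.DataFrame:
    rows = []
    for name, rep in reports.items():
        if rep is None:
            rows.append({"scope": name, "n_taxa": 0})
        else:
            rows.append(rep.to_row())
    return pd.DataFrame(rows)
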