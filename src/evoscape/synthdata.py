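"""Synthetic fixtures with the statistical structure the protocol assumes.

The generator emulates a fossil clade with two selective regimes: a
birth–death chronogram whose tips die out through time, traits evolving by
Ornstein–Uhlenbeck pulls toward regime-specific optima (a clade-level regime
divide gives a bimodal morphospace), a minority of branches painted with
regime *transitions* whose tips are true convergents, missing-completely-at-
random cells, and stratigraphic ranges consistent with the node ages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_io import RangeTable, TraitTable
from .phylo import Chronogram

__all__ = ["SynthSpec", "gen_chronogram", "gen_traits", "inject_missing",
           "generate_dataset"]


@dataclass
class SynthSpec:
    """Study conditions for the generator.

    Defaults mirror the scale of the empirical problem: ~30 usable taxa
    scored for 8 craniodental + 3 postcranial traits, ~0.4 missing cells,
    two regimes with distinct craniodental optima, a couple of painted
    regime transitions."""

    n_tips: int = 30
    birth: float = 0.05  # per Ma
    death: float = 0.035  # per Ma
    n_cranio: int = 8
    n_post: int = 3
    delta: float = 3.0  # craniodental optimum separation per trait
    alpha: float = 0.25  # OU pull, per Ma
    sigma2: float = 0.1  # BM diffusion, per Ma
    n_transitions: int = 2
    missing_rate: float = 0.4
    # taxon-level preservation heterogeneity: per-taxon missingness
    # propensities ~ Beta(k*rate, k*(1-rate)).  k = 3 reproduces the empirical
    # pattern this emulates (a 0.42 overall rate collapsing to ~0.23 after a
    # 45% completeness filter drops ~1/4 of the taxa); None = homogeneous MCAR
    missing_concentration: float | None = 3.0
    range_noise: float = 2.0  # Ma, uniform FAD/LAD widening
    tip_span: tuple[float, float] = (195.0, 70.0)  # oldest/youngest tip age, Ma
    seed: int = 0
    max_tries: int = 200

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate <= 0.9:
            raise ValueError("missing rate must be in [0, 0.9]")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")

    @property
    def n_traits(self) -> int:
        return self.n_cranio + self.n_post


def _simulate_bd(spec: SynthSpec, rng: np.random.Generator):
    """Forward birth–death run; returns (parent, t_birth, t_death, tips) or
    None when the clade dies before reaching n_tips tips."""
    # node bookkeeping: each lineage gets an id; splits create internal nodes
    parent: list[int] = [-1]
    born: list[float] = [0.0]
    died: list[float | None] = [None]
    alive = [0]
    finished: list[int] = []
    t = 0.0
    while alive and len(finished) + len(alive) < spec.n_tips:
        rate = len(alive) * (spec.birth + spec.death)
        t += rng.exponential(1.0 / rate)
        lin = alive[int(rng.integers(len(alive)))]
        if rng.random() < spec.birth / (spec.birth + spec.death):
            died[lin] = t
            for _ in range(2):
                parent.append(lin)
                born.append(t)
                died.append(None)
                alive.append(len(parent) - 1)
            alive.remove(lin)
        else:
            died[lin] = t
            alive.remove(lin)
            finished.append(lin)
    if len(finished) + len(alive) < spec.n_tips:
        return None
    # close surviving lineages with independent lifetimes (no more births)
    for lin in alive:
        died[lin] = t + rng.exponential(1.0 / spec.death)
        finished.append(lin)
    return parent, born, died, finished


def gen_chronogram(spec: SynthSpec) -> tuple[Chronogram, RangeTable]:
    """Birth–death chronogram conditioned on n_tips, plus consistent ranges.

    Tip FAD = tip age plus uniform noise, LAD <= FAD; ages in Ma before the
    youngest tip."""
    if spec.n_tips < 4:
        raise ValueError("n_tips must be >= 4")
    rng = np.random.default_rng([spec.seed, 11])
    for _ in range(spec.max_tries):
        sim = _simulate_bd(spec, rng)
        if sim is not None:
            break
    else:
        raise RuntimeError("birth-death simulation failed to reach n_tips; "
                           "death rate too high relative to birth")
    parent, born, died, tips = sim
    # relabel: tips first, then internal nodes (lineages that split)
    internal = [i for i, p in enumerate(parent) if i not in tips]
    order = list(tips) + internal
    remap = {old: new for new, old in enumerate(order)}
    n_all = len(parent)
    new_parent = np.empty(n_all, dtype=int)
    times = np.empty(n_all)
    for old in range(n_all):
        new_parent[remap[old]] = remap[parent[old]] if parent[old] >= 0 else -1
        times[remap[old]] = died[old]
    t_max = times[: len(tips)].max()
    ages = t_max - times  # node age = when the lineage ended (split or died)
    # anchor tip ages inside the target stratigraphic interval
    old, young = spec.tip_span
    tip_ages = ages[: len(tips)]
    span = tip_ages.max() - tip_ages.min()
    if span > 0:
        ages = young + (ages - tip_ages.min()) * (old - young) / span
    else:  # pragma: no cover - degenerate simultaneous extinction
        ages = ages + young
    labels = [f"t{i + 1}" for i in range(len(tips))]
    chron = Chronogram(labels=labels, parent=new_parent, ages=ages)
    chron.validate()
    fad = ages[: len(tips)] + rng.uniform(0, spec.range_noise, len(tips))
    lad = np.maximum(0.0, ages[: len(tips)] - rng.uniform(0, spec.range_noise,
                                                          len(tips)))
    ranges = RangeTable(taxa=labels, fad=fad, lad=lad)
    return chron, ranges


def _paint_regimes(chron: Chronogram, spec: SynthSpec,
                   rng: np.random.Generator) -> tuple[np.ndarray, list[int]]:
    """Regime id per node: a clade-level divide plus painted transitions.

    Returns (regime per node, list of transition branch child-nodes)."""
    n = chron.n_tips
    regime = np.zeros(chron.n_nodes, dtype=int)
    if spec.delta != 0:
        # clade whose size is closest to half the tips becomes regime 1
        sizes = {}
        for v in chron.postorder():
            sizes[v] = 1 if chron.is_tip(v) else sum(sizes[c] for c in chron.children(v))
        candidates = [v for v in range(chron.n_nodes)
                      if not chron.is_tip(v) and v != chron.root]
        divide = min(candidates, key=lambda v: abs(sizes[v] - n / 2))
        for v in chron.clade_nodes(divide):
            regime[v] = 1
    transitions: list[int] = []
    if spec.n_transitions > 0 and spec.delta != 0:
        # flip small subtrees (1-2 tips) so their tips converge on the
        # opposite regime's optimum
        small = [v for v in range(chron.n_nodes)
                 if v != chron.root and
                 sum(1 for w in chron.clade_nodes(v) if chron.is_tip(w)) <= 2]
        small = [int(v) for v in rng.permutation(small)] if small else []
        for v in small:
            if len(transitions) >= spec.n_transitions:
                break
            if any(v in chron.clade_nodes(t) or t in chron.clade_nodes(v)
                   for t in transitions):
                continue
            flip = 1 - regime[v]
            for w in chron.clade_nodes(v):
                regime[w] = flip
            transitions.append(v)
    return regime, transitions


def gen_traits(chron: Chronogram, spec: SynthSpec,
               ) -> tuple[TraitTable, dict]:
    """Complete trait table evolved by per-branch OU steps, plus truth record.

    Each branch applies the exact OU transition toward its regime's optimum:
    mean = theta + (x0 - theta) e^{-alpha t}, var = sigma^2(1-e^{-2 alpha t})
    / (2 alpha); alpha = 0 reduces to Brownian motion.  Craniodental optima
    differ between regimes by ``delta`` per trait; postcranial optima are
    shared (their signal is deliberately blurred)."""
    rng = np.random.default_rng([spec.seed, 23])
    regime, transitions = _paint_regimes(chron, spec, rng)
    p = spec.n_traits
    optima = np.zeros((2, p))
    optima[0, : spec.n_cranio] = -spec.delta / 2.0
    optima[1, : spec.n_cranio] = +spec.delta / 2.0
    vals = np.zeros((chron.n_nodes, p))
    dur = chron.durations()
    root_regime = regime[chron.root]
    vals[chron.root] = optima[root_regime]
    a, s2 = spec.alpha, spec.sigma2
    for v in chron.preorder():
        pnode = chron.parent[v]
        if pnode < 0:
            continue
        t = max(dur[v], 0.0)
        theta = optima[regime[v]]
        if a > 0:
            decay = np.exp(-a * t)
            mean = theta + (vals[pnode] - theta) * decay
            var = s2 * (1.0 - decay ** 2) / (2.0 * a)
        else:
            mean = vals[pnode]
            var = s2 * t
        vals[v] = mean + rng.standard_normal(p) * np.sqrt(var)
    traits = ([f"cranio{i + 1}" for i in range(spec.n_cranio)] +
              [f"post{i + 1}" for i in range(spec.n_post)])
    classes = ["craniodental"] * spec.n_cranio + ["postcranial"] * spec.n_post
    table = TraitTable(taxa=list(chron.labels), traits=traits,
                       values=vals[: chron.n_tips].copy(),
                       trait_class=classes)
    trans_info = [{"node": int(t), "to_regime": int(regime[t]),
                   "tips": sorted(chron.labels[w] for w in chron.clade_nodes(t)
                                  if chron.is_tip(w))}
                  for t in transitions]
    conv_tips = sorted({tip for tr in trans_info for tip in tr["tips"]})
    truth = {
        "regime": {chron.labels[i]: int(regime[i]) for i in range(chron.n_tips)},
        "root_regime": int(root_regime),
        "transitions": trans_info,
        "convergent_tips": conv_tips,
        "node_values": vals,
    }
    return table, truth


def convergent_focal_groups(chron: Chronogram, truth: dict,
                            max_partners: int = 1) -> dict[str, list[str]]:
    """Focal tip groups for the convergence tests, from the generator truth.

    Each painted transition contributes one group: its tips plus the most
    distantly related native tip(s) of the same regime — the pairing whose
    phenotypic similarity can only be explained by convergence."""
    from .phylo import patristic

    T = patristic(chron).D
    regime = truth["regime"]
    painted = set(truth["convergent_tips"])
    groups: dict[str, list[str]] = {}
    for gi, tr in enumerate(truth.get("transitions", [])):
        tips = [t for t in tr["tips"] if t in chron.labels]
        if not tips:
            continue
        natives = [t for t in chron.labels
                   if regime[t] == tr["to_regime"] and t not in painted]
        if not natives:
            continue
        anchor = chron.tip_index(tips[0])
        natives.sort(key=lambda t: -T[anchor, chron.tip_index(t)])
        groups[f"transition{gi + 1}"] = tips + natives[:max_partners]
    return groups


def inject_missing(table: TraitTable, rate: float,
                   seed: int | np.random.Generator | None = None,
                   concentration: float | None = None,
                   ) -> tuple[TraitTable, float]:
    """Missing-at-random mask at the given cell rate, guarding >=1 observed
    cell per taxon and >=2 per trait.  Returns (masked table, realized rate).

    With ``concentration`` k, per-taxon propensities are drawn from
    Beta(k*rate, k*(1-rate)) — preservation quality varies by specimen, so
    missing cells concentrate in poorly preserved taxa; None gives the
    homogeneous cell-wise rate."""
    if not 0.0 <= rate <= 0.9:
        raise ValueError("rate must be in [0, 0.9]")
    rng = np.random.default_rng(seed)
    X = table.values.copy()
    n, p = X.shape
    if rate > 0:
        for _ in range(100):
            if concentration is None:
                probs = np.full((n, 1), rate)
            else:
                probs = np.minimum(
                    rng.beta(concentration * rate, concentration * (1 - rate),
                             size=(n, 1)), 0.9)
            mask = rng.random((n, p)) < probs
            if np.any(mask.all(axis=1)) or np.any((~mask).sum(axis=0) < 2):
                continue
            break
        else:
            raise RuntimeError("could not draw a mask satisfying the guards")
        X[mask] = np.nan
    realized = float(np.isnan(X).mean())
    out = TraitTable(taxa=list(table.taxa), traits=list(table.traits), values=X,
                     trait_class=list(table.trait_class) if table.trait_class else None)
    return out, realized


def _analyzable(masked: TraitTable, threshold: float = 0.45,
                must_keep: list[str] | None = None) -> bool:
    """Every completeness-passing taxon pair must share an observed trait,
    within each trait class the protocol analyses separately; ``must_keep``
    taxa (the designated convergent exemplars) must pass the filter."""
    from .traitprep import pairwise_sq_missing

    for cls in (None, "craniodental"):
        sub = masked if cls is None else masked.select_traits(trait_class=cls)
        comp = sub.completeness()
        rows = comp >= threshold
        if rows.sum() < 4:
            return False
        if must_keep:
            kept = {t for t, ok in zip(sub.taxa, rows) if ok}
            if not set(must_keep) <= kept:
                return False
        _, m = pairwise_sq_missing(sub.values[rows])
        off = ~np.eye(int(rows.sum()), dtype=bool)
        if np.any(m[off] == 0):
            return False
    return True


def generate_dataset(spec: SynthSpec) -> dict:
    """Full fixture: chronogram, ranges, complete and masked tables, truth.

    The MCAR mask is redrawn (seeded substreams) until the masked table
    supports the protocol: completeness-passing taxa must pairwise share at
    least one observed trait, as the empirical data this emulates did."""
    chron, ranges = gen_chronogram(spec)
    table, truth = gen_traits(chron, spec)
    rng = np.random.default_rng([spec.seed, 37])
    for _ in range(100):
        masked, realized = inject_missing(table, spec.missing_rate, rng,
                                          spec.missing_concentration)
        if _analyzable(masked, must_keep=truth["convergent_tips"]):
            break
    else:
        raise RuntimeError("no analyzable missingness mask found; lower the rate")
    return {"chronogram": chron, "ranges": ranges, "table_complete": table,
            "table": masked, "realized_missing": realized, "truth": truth}


def write_dataset(data: dict, outdir: str | Path) -> dict[str, str]:
    """Emit the fixture in the formats the readers accept; truth as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "traits": str(outdir / "traits.csv"),
        "ranges": str(outdir / "ranges.csv"),
        "tree": str(outdir / "tree.nwk"),
        "truth": str(outdir / "truth.json"),
    }
    data["table"].to_csv(paths["traits"])
    data["ranges"].to_csv(paths["ranges"])
    data["chronogram"].write_newick(paths["tree"])
    truth = {k: v for k, v in data["truth"].items() if k != "node_values"}
    Path(paths["truth"]).write_text(json.dumps(truth, indent=2), encoding="utf-8")
    return paths
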