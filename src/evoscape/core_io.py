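"""Data model and readers/writers for trait tables, trees, ranges and run config.

The observational unit is a taxon × trait matrix with explicit missing cells
(fossil datasets are rarely complete), accompanied by biostratigraphic ranges
(first/last appearance data in Ma before present) and a rooted phylogeny whose
tips match the trait table.
"""

from __future__ import annotations

import random
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TraitTable",
    "RangeTable",
    "Tree",
    "RunConfig",
    "normalize_name",
    "load_dataset",
    "load_tree",
]

MISSING_TOKENS = {"", "NA", "NaN", "nan", "na", "N/A"}

TRAIT_CLASSES = ("craniodental", "postcranial")


def normalize_name(name: str) -> str:
    """Canonical taxon name: trim, collapse runs of spaces/underscores to '_'.

    Case-sensitive; Newick files and spreadsheets disagree on separators but
    rarely on case.
    """
    return re.sub(r"[ _]+", "_", name.strip())


@dataclass
class TraitTable:
    """Taxa × traits real matrix with NaN as the missing marker.

    ``trait_class`` optionally tags each trait as craniodental or postcranial;
    ``trait_kind`` optionally tags each trait as ratio or absolute.
    """

    taxa: list[str]
    traits: list[str]
    values: np.ndarray  # (n_taxa, n_traits) float, NaN = missing
    trait_class: list[str] | None = None
    trait_kind: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, p = self.values.shape
        if len(self.taxa) != n or len(self.traits) != p:
            raise ValueError("shape of values does not match taxa/traits")
        if len(set(self.taxa)) != n:
            dup = [t for t in self.taxa if self.taxa.count(t) > 1][0]
            raise ValueError(f"duplicate taxon id: {dup!r}")
        if any(not t for t in self.taxa):
            raise ValueError("empty taxon id")
        if len(set(self.traits)) != p:
            raise ValueError("duplicate trait names")
        if self.trait_class is not None and len(self.trait_class) != p:
            raise ValueError("trait_class length mismatch")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    def completeness(self) -> np.ndarray:
        """Observed fraction per taxon, in [0, 1]."""
        return np.isfinite(self.values).mean(axis=1)

    def select_traits(self, names: Sequence[str] | None = None,
                      trait_class: str | None = None) -> "TraitTable":
        """Subset columns by explicit names or by class tag."""
        if names is None:
            if trait_class is None:
                return self
            if self.trait_class is None:
                raise ValueError("table has no trait class tags")
            names = [t for t, c in zip(self.traits, self.trait_class)
                     if c == trait_class]
        idx = [self.traits.index(t) for t in names]
        return TraitTable(
            taxa=list(self.taxa),
            traits=[self.traits[i] for i in idx],
            values=self.values[:, idx].copy(),
            trait_class=[self.trait_class[i] for i in idx] if self.trait_class else None,
            trait_kind=[self.trait_kind[i] for i in idx] if self.trait_kind else None,
        )

    def select_taxa(self, names: Sequence[str]) -> "TraitTable":
        idx = [self.taxa.index(t) for t in names]
        return TraitTable(
            taxa=[self.taxa[i] for i in idx],
            traits=list(self.traits),
            values=self.values[idx, :].copy(),
            trait_class=list(self.trait_class) if self.trait_class else None,
            trait_kind=list(self.trait_kind) if self.trait_kind else None,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxa, columns=self.traits)

    def to_csv(self, path: str | Path) -> None:
        """Write the table; missing cells as 'NA', class tags as second header row."""
        path = Path(path)
        with path.open("w", encoding="utf-8") as fh:
            fh.write("taxon," + ",".join(self.traits) + "\n")
            if self.trait_class is not None:
                fh.write("class," + ",".join(self.trait_class) + "\n")
            for taxon, row in zip(self.taxa, self.values):
                cells = ["NA" if not np.isfinite(v) else repr(float(v)) for v in row]
                fh.write(taxon + "," + ",".join(cells) + "\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "TraitTable":
        path = Path(path)
        with path.open("r", encoding="utf-8") as fh:
            lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
        if not lines:
            raise ValueError(f"{path}: empty file")
        header = lines[0].split(",")
        if header[0].strip().lower() != "taxon":
            raise ValueError(f"{path}: first column must be 'taxon'")
        traits = [h.strip() for h in header[1:]]
        body = lines[1:]
        trait_class = None
        if body:
            first = [c.strip() for c in body[0].split(",")]
            cells = first[1:]
            if cells and all(c in TRAIT_CLASSES for c in cells if c):
                trait_class = cells
                body = body[1:]
        taxa: list[str] = []
        rows: list[list[float]] = []
        for li, line in enumerate(body, start=2):
            parts = [c.strip() for c in line.split(",")]
            if len(parts) != len(traits) + 1:
                raise ValueError(f"{path}:{li}: expected {len(traits) + 1} fields")
            taxon = normalize_name(parts[0])
            if taxon in taxa:
                raise ValueError(f"duplicate taxon id: {taxon!r}")
            row = []
            for ci, cell in enumerate(parts[1:]):
                if cell in MISSING_TOKENS:
                    row.append(np.nan)
                    continue
                try:
                    row.append(float(cell))
                except ValueError:
                    raise ValueError(
                        f"{path}:{li}: non-numeric value {cell!r} in column "
                        f"{traits[ci]!r}") from None
            taxa.append(taxon)
            rows.append(row)
        return cls(taxa=taxa, traits=traits, values=np.array(rows, dtype=float),
                   trait_class=trait_class)


@dataclass
class RangeTable:
    """Stratigraphic ranges: FAD/LAD per taxon, in Ma before present."""

    taxa: list[str]
    fad: np.ndarray
    lad: np.ndarray

    def __post_init__(self) -> None:
        self.fad = np.asarray(self.fad, dtype=float)
        self.lad = np.asarray(self.lad, dtype=float)
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon id in range table")
        if self.fad.shape != (len(self.taxa),) or self.lad.shape != self.fad.shape:
            raise ValueError("range table shape mismatch")
        bad = np.where((self.fad < self.lad) | (self.lad < 0))[0]
        if bad.size:
            t = self.taxa[bad[0]]
            raise ValueError(
                f"invalid range for {t!r}: FAD={self.fad[bad[0]]} LAD={self.lad[bad[0]]}"
                " (need FAD >= LAD >= 0)")

    def __len__(self) -> int:
        return len(self.taxa)

    def age(self, taxon: str, rule: str = "FAD") -> float:
        """Scalar age for a taxon: 'FAD', 'LAD' or 'midpoint'."""
        i = self.taxa.index(taxon)
        if rule == "FAD":
            return float(self.fad[i])
        if rule == "LAD":
            return float(self.lad[i])
        if rule == "midpoint":
            return float(0.5 * (self.fad[i] + self.lad[i]))
        raise ValueError(f"unknown age rule {rule!r}")

    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.fad + self.lad)

    def subset(self, taxa: Sequence[str]) -> "RangeTable":
        idx = [self.taxa.index(t) for t in taxa]
        return RangeTable(taxa=[self.taxa[i] for i in idx],
                          fad=self.fad[idx], lad=self.lad[idx])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"taxon": self.taxa, "FAD": self.fad, "LAD": self.lad}
                     ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "RangeTable":
        df = pd.read_csv(path)
        cols = {c.lower(): c for c in df.columns}
        for need in ("taxon", "fad", "lad"):
            if need not in cols:
                raise ValueError(f"{path}: missing column {need!r}")
        taxa = [normalize_name(str(t)) for t in df[cols["taxon"]]]
        return cls(taxa=taxa,
                   fad=df[cols["fad"]].to_numpy(dtype=float),
                   lad=df[cols["lad"]].to_numpy(dtype=float))


@dataclass
class Tree:
    """Rooted topology (optionally with branch lengths), wrapping dendropy."""

    dtree: dendropy.Tree

    @property
    def tip_labels(self) -> list[str]:
        return [normalize_name(lf.taxon.label) for lf in self.dtree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.dtree.leaf_node_iter())

    def is_binary(self) -> bool:
        for node in self.dtree.preorder_node_iter():
            if node.child_nodes() and len(node.child_nodes()) != 2:
                return False
        return True

    def newick(self) -> str:
        return self.dtree.as_string(schema="newick").strip()


@dataclass
class RunConfig:
    """Master seed plus tunables; every stochastic step gets a derived seed."""

    seed: int = 0
    settings: dict = field(default_factory=dict)

    def get(self, key: str, default=None):
        return self.settings.get(key, default)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        h = np.random.SeedSequence([self.seed, abs(hash(stage)) % (2**31)])
        return int(h.generate_state(1)[0] % (2**31))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open("r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        seed = int(data.pop("seed", 0))
        return cls(seed=seed, settings=data)


def load_dataset(trait_csv: str | Path, range_csv: str | Path,
                 ) -> tuple[TraitTable, RangeTable]:
    """Read trait table and stratigraphic ranges; cross-check taxon sets.

    Taxa found in only one of the two inputs are reported with a warning; the
    returned objects are *not* pruned (callers choose the intersection).
    """
    table = TraitTable.from_csv(trait_csv)
    ranges = RangeTable.from_csv(range_csv)
    only_traits = sorted(set(table.taxa) - set(ranges.taxa))
    only_ranges = sorted(set(ranges.taxa) - set(table.taxa))
    if only_traits or only_ranges:
        warnings.warn(
            f"taxa only in trait table: {only_traits}; "
            f"taxa only in range table: {only_ranges}", stacklevel=2)
    return table, ranges


def _parse_tree(path_or_string: str | Path) -> dendropy.Tree:
    text = str(path_or_string)
    try:
        p = Path(text)
        if p.exists():
            text = p.read_text(encoding="utf-8")
    except OSError:  # e.g. a newick string too long to be a file name
        pass
    schema = "nexus" if text.lstrip().upper().startswith("#NEXUS") else "newick"
    try:
        return dendropy.Tree.get(data=text, schema=schema)
    except Exception as exc:  # dendropy raises several parse error types
        offset = getattr(exc, "column", None)
        where = f" near character {offset}" if offset is not None else ""
        raise ValueError(f"unparseable {schema} tree{where}: {exc}") from exc


def load_tree(newick: str | Path, tips_expected: Iterable[str],
              resolve: str = "error", seed: int | None = None) -> Tree:
    """Parse a Newick/NEXUS tree, prune to the expected tips, handle polytomies.

    ``resolve`` is 'error' (reject polytomies) or 'random' (randomly resolve
    with zero-length branches, seeded).
    """
    dtree = _parse_tree(newick)
    for taxon in dtree.taxon_namespace:
        taxon.label = normalize_name(taxon.label)
    wanted = {normalize_name(t) for t in tips_expected}
    present = {lf.taxon.label for lf in dtree.leaf_node_iter()}
    missing = sorted(wanted - present)
    if missing:
        warnings.warn(f"tips absent from tree: {missing}", stacklevel=2)
    keep = wanted & present
    if len(keep) < 2:
        raise ValueError(f"fewer than 2 expected tips found in tree (got {len(keep)})")
    dtree.retain_taxa_with_labels(sorted(keep))
    dtree.suppress_unifurcations()
    tree = Tree(dtree=dtree)
    if not tree.is_binary():
        if resolve == "error":
            raise ValueError("tree contains polytomies (resolve='error')")
        if resolve == "random":
            rng = random.Random(seed)
            dtree.resolve_polytomies(rng=rng)
            for edge in dtree.preorder_edge_iter():
                if edge.length is None and edge.head_node.parent_node is not None:
                    edge.length = 0.0
        else:
            raise ValueError(f"unknown polytomy policy {resolve!r}")
    return tree
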