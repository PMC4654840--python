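"""Homolog pairs, relationship classes and molecular-evolution rates.

A :class:`HomologyTable` stores homolog pairs between a species-A and a
species-B gene universe together with per-pair dN and dS substitution rates.
Relationship classes (one2one / one2many / many2many) are decided at the
level of bipartite connected components of the homology graph: a component
in which both species sides carry a multiplied gene is many2many throughout,
a component multiplied on exactly one side is one2many throughout, and an
isolated pair is one2one.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: canonical ordering of relationship classes
CLASS_ORDER = ("one2one", "one2many", "many2many")


@dataclass
class HomologyTable:
    """Homolog pairs with relationship classes and dN/dS rates.

    Parameters
    ----------
    pairs
        List of ``(gene_a, gene_b)`` tuples; gene IDs are opaque strings.
    relationship
        Per-pair class label, one of :data:`CLASS_ORDER`.
    dn, ds
        Per-pair non-negative substitution rates; ``NaN`` marks a missing
        value.  Pairs with ``ds == 0`` are kept but their dN/dS ratio is
        undefined (see :attr:`dnds`).
    universe_a, universe_b
        Full per-species gene universes, including non-homologous genes.
        Default to the genes occurring in ``pairs``.
    """

    pairs: list[tuple[str, str]]
    relationship: list[str]
    dn: np.ndarray
    ds: np.ndarray
    universe_a: set[str] = field(default_factory=set)
    universe_b: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.dn = np.asarray(self.dn, dtype=float)
        self.ds = np.asarray(self.ds, dtype=float)
        n = len(self.pairs)
        if not (len(self.relationship) == len(self.dn) == len(self.ds) == n):
            raise ValueError("pairs, relationship, dn and ds must have equal length")
        bad = set(self.relationship) - set(CLASS_ORDER)
        if bad:
            raise ValueError(f"unknown relationship labels: {sorted(bad)}")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dn, initial=0.0) < 0 or np.nanmin(self.ds, initial=0.0) < 0:
                raise ValueError("dn and ds must be non-negative")
        genes_a = {a for a, _ in self.pairs}
        genes_b = {b for _, b in self.pairs}
        if not self.universe_a:
            self.universe_a = set(genes_a)
        if not self.universe_b:
            self.universe_b = set(genes_b)
        if not genes_a <= self.universe_a:
            raise ValueError("pair genes missing from universe_a")
        if not genes_b <= self.universe_b:
            raise ValueError("pair genes missing from universe_b")

    # -- derived views -------------------------------------------------

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self._pair_set

    @cached_property
    def _pair_set(self) -> set[tuple[str, str]]:
        return set(self.pairs)

    @cached_property
    def ds_zero(self) -> np.ndarray:
        """Boolean flag per pair: dS is exactly zero (ratio undefined)."""
        return np.asarray(self.ds == 0)

    @cached_property
    def rate_missing(self) -> np.ndarray:
        """Boolean flag per pair: dN or dS missing from the source table."""
        return np.isnan(self.dn) | np.isnan(self.ds)

    @cached_property
    def dnds(self) -> np.ndarray:
        """dN/dS per pair; ``NaN`` where dS is zero or a rate is missing."""
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = self.dn / self.ds
        ratio = np.where(self.ds_zero | self.rate_missing, np.nan, ratio)
        return ratio

    @cached_property
    def homologs_of_a(self) -> dict[str, frozenset[str]]:
        """Species-A gene -> set of its species-B homologs."""
        out: dict[str, set[str]] = {}
        for a, b in self.pairs:
            out.setdefault(a, set()).add(b)
        return {a: frozenset(bs) for a, bs in out.items()}

    @cached_property
    def homologs_of_b(self) -> dict[str, frozenset[str]]:
        """Species-B gene -> set of its species-A homologs."""
        out: dict[str, set[str]] = {}
        for a, b in self.pairs:
            out.setdefault(b, set()).add(a)
        return {b: frozenset(a_) for b, a_ in out.items()}

    @cached_property
    def homolog_genes_a(self) -> frozenset[str]:
        return frozenset(a for a, _ in self.pairs)

    @cached_property
    def homolog_genes_b(self) -> frozenset[str]:
        return frozenset(b for _, b in self.pairs)

    @cached_property
    def duplicated_genes_a(self) -> frozenset[str]:
        """Species-A genes involved in at least one non-one2one pair."""
        return frozenset(
            a for (a, _), rel in zip(self.pairs, self.relationship) if rel != "one2one"
        )

    def swapped(self) -> "HomologyTable":
        """Table with species sides exchanged (for symmetry checks)."""
        return HomologyTable(
            pairs=[(b, a) for a, b in self.pairs],
            relationship=list(self.relationship),
            dn=self.dn.copy(),
            ds=self.ds.copy(),
            universe_a=set(self.universe_b),
            universe_b=set(self.universe_a),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_a": [a for a, _ in self.pairs],
                "gene_b": [b for _, b in self.pairs],
                "relationship": self.relationship,
                "dn": self.dn,
                "ds": self.ds,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def classify_relationships(pairs: Sequence[tuple[str, str]]) -> list[str]:
    """Assign relationship classes at the bipartite-component level.

    Within each connected component of the homology graph, if both species
    sides contain a gene occurring in more than one pair the whole component
    is ``many2many``; if exactly one side does, ``one2many``; otherwise
    ``one2one``.  Labels are invariant under row order and species swap
    (up to the side carrying the multiplicity).
    """
    deg_a = Counter(a for a, _ in pairs)
    deg_b = Counter(b for _, b in pairs)

    parent: dict[tuple[str, str], tuple[str, str]] = {}

    def find(x):
        root = x
        while parent.setdefault(root, root) != root:
            root = parent[root]
        while parent[x] != root:  # path compression
            parent[x], x = root, parent[x]
        return root

    for a, b in pairs:
        ra, rb = find(("a", a)), find(("b", b))
        if ra != rb:
            parent[rb] = ra

    multi_a: dict[tuple[str, str], bool] = {}
    multi_b: dict[tuple[str, str], bool] = {}
    for a, b in pairs:
        root = find(("a", a))
        multi_a[root] = multi_a.get(root, False) or deg_a[a] > 1
        multi_b[root] = multi_b.get(root, False) or deg_b[b] > 1

    labels = []
    for a, b in pairs:
        root = find(("a", a))
        ma, mb = multi_a[root], multi_b[root]
        if ma and mb:
            labels.append("many2many")
        elif ma or mb:
            labels.append("one2many")
        else:
            labels.append("one2one")
    return labels


def read_homology_table(
    path,
    universe_a: Iterable[str] | None = None,
    universe_b: Iterable[str] | None = None,
) -> HomologyTable:
    """Read a homology TSV (columns gene_a, gene_b, dn, ds[, relationship]).

    Duplicate ``(gene_a, gene_b)`` rows are collapsed to one pair.  When the
    relationship column is absent, classes are inferred from pair
    multiplicity via :func:`classify_relationships`.  Missing dn/ds values
    are retained as NaN and flagged; malformed numeric fields raise with the
    offending line number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_a", "gene_b", "dn", "ds"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    for col in ("gene_a", "gene_b"):
        bad = df.index[df[col].isna()]
        if len(bad):
            raise ValueError(f"{path}: line {bad[0] + 2}: empty {col}")
    for col in ("dn", "ds"):
        converted = pd.to_numeric(df[col], errors="coerce")
        malformed = df.index[converted.isna() & df[col].notna()]
        if len(malformed):
            # +2: header line plus 1-based numbering
            raise ValueError(
                f"{path}: line {malformed[0] + 2}: malformed {col} value "
                f"{df.loc[malformed[0], col]!r}"
            )
        df[col] = converted
    n_before = len(df)
    df = df.drop_duplicates(subset=["gene_a", "gene_b"], keep="first").reset_index(drop=True)
    if len(df) < n_before:
        logger.info("collapsed %d duplicate homology rows", n_before - len(df))
    pairs = list(zip(df["gene_a"], df["gene_b"]))
    if "relationship" in df.columns:
        relationship = list(df["relationship"])
    else:
        relationship = classify_relationships(pairs)
    return HomologyTable(
        pairs=pairs,
        relationship=relationship,
        dn=df["dn"].to_numpy(float),
        ds=df["ds"].to_numpy(float),
        universe_a=set(universe_a) if universe_a is not None else set(),
        universe_b=set(universe_b) if universe_b is not None else set(),
    )


@dataclass
class DnDsClassComparison:
    """Class-wise dN/dS distributions with omnibus and post-hoc tests."""

    class_values: dict[str, np.ndarray]
    kruskal_stat: float
    kruskal_df: int
    kruskal_p: float
    #: pairwise two-sided Mann-Whitney p-values, Bonferroni-multiplied
    pairwise_p: dict[tuple[str, str], float]


def _mannwhitney_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney p; exact enumeration for small tie-free groups."""
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (max(len(x), len(y)) <= 20 and not has_ties) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def dnds_by_class(table: HomologyTable) -> DnDsClassComparison:
    """Compare dN/dS distributions across relationship classes.

    Runs a Kruskal-Wallis omnibus test over all classes with at least two
    defined ratios, followed by pairwise two-sided Mann-Whitney tests with
    Bonferroni correction (multiply by the number of comparisons, cap at 1).
    Classes with fewer than two defined ratios are excluded with a warning.
    """
    ratio = table.dnds
    rel = np.asarray(table.relationship)
    class_values: dict[str, np.ndarray] = {}
    for cls in CLASS_ORDER:
        vals = ratio[(rel == cls) & np.isfinite(ratio)]
        if len(vals) < 2:
            if (rel == cls).any():
                logger.warning(
                    "class %s has %d defined dN/dS ratios; excluded", cls, len(vals)
                )
            continue
        class_values[cls] = vals
    if len(class_values) < 2:
        raise ValueError("need at least two classes with >= 2 defined dN/dS ratios")
    groups = list(class_values.values())
    kw_stat, kw_p = stats.kruskal(*groups)
    names = list(class_values)
    n_comp = len(names) * (len(names) - 1) // 2
    pairwise: dict[tuple[str, str], float] = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            p = _mannwhitney_p(class_values[names[i]], class_values[names[j]])
            pairwise[(names[i], names[j])] = min(1.0, p * n_comp)
    return DnDsClassComparison(
        class_values=class_values,
        kruskal_stat=float(kw_stat),
        kruskal_df=len(groups) - 1,
        kruskal_p=float(kw_p),
        pairwise_p=pairwise,
    )


def quartile_bins(
    values: Sequence[float], k: int = 4, ids: Sequence[str] | None = None
) -> np.ndarray:
    """Partition values into ``k`` equally sized, value-ordered bins.

    Bin sizes follow the largest-remainder rule (the first ``n mod k`` bins
    get one extra element), so sizes differ by at most one.  Ties straddling
    a boundary are resolved by a stable sort on ``(value, id)``; ``ids``
    default to the element's string index.

    Returns the bin index (0-based, ordered by increasing value) for every
    input element.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    n = len(values)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"cannot split {n} values into {k} bins")
    if ids is None:
        ids = [str(i) for i in range(n)]
    elif len(ids) != n:
        raise ValueError("ids must match values in length")
    order = sorted(range(n), key=lambda i: (values[i], str(ids[i])))
    base, rem = divmod(n, k)
    bins = np.empty(n, dtype=int)
    start = 0
    for b in range(k):
        size = base + (1 if b < rem else 0)
        for i in order[start : start + size]:
            bins[i] = b
        start += size
    return bins
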