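"""Vote-counting co-expression maps and top-percent partner lists.

Per dataset, each gene's expression is discretized against its own
within-dataset median to up / down / neutral.  For every gene pair, pooled
over all datasets, ``C`` counts conditions where both genes move in the same
direction and ``D`` counts conditions where both move but in opposite
directions; the co-expression score is ``C / (C + D)``, a frequency in
``[0, 1]`` (0 when the pair is never jointly non-neutral).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ExpressionDataset:
    """A gene x condition expression matrix from one experiment."""

    genes: list[str]
    conditions: list[str]
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"dataset {self.name!r}: duplicate gene IDs")
        if len(self.conditions) < 2:
            raise ValueError(f"dataset {self.name!r}: need >= 2 conditions")
        if self.values.shape != (len(self.genes), len(self.conditions)):
            raise ValueError(
                f"dataset {self.name!r}: values shape {self.values.shape} does not "
                f"match {len(self.genes)} genes x {len(self.conditions)} conditions"
            )

    @classmethod
    def from_tsv(cls, path, name: str = "") -> "ExpressionDataset":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            genes=[str(g) for g in df.index],
            conditions=[str(c) for c in df.columns],
            values=df.to_numpy(float),
            name=name or str(path),
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.genes, columns=self.conditions).to_csv(
            path, sep="\t", index_label="gene"
        )


def discretize(dataset: ExpressionDataset, neutral_epsilon: float = 0.0) -> np.ndarray:
    """Per-gene median split to an int8 sign matrix (+1 up, -1 down, 0 neutral).

    A value within ``neutral_epsilon`` of the gene's within-dataset median is
    neutral; with the default epsilon of 0 only exact median hits are
    neutral (constant genes are therefore all-neutral).
    """
    med = np.median(dataset.values, axis=1, keepdims=True)
    delta = dataset.values - med
    signs = np.zeros(dataset.values.shape, dtype=np.int8)
    signs[delta > neutral_epsilon] = 1
    signs[delta < -neutral_epsilon] = -1
    return signs


@dataclass
class CoexpressionMap:
    """Symmetric all-pairs co-expression scores over a gene universe.

    ``values`` is an N x N matrix of scores in ``[0, 1]``; the diagonal is
    meaningless and never returned by queries.  Validation samples random
    entries for symmetry and range so that very large (mostly untouched)
    matrices stay cheap to construct.
    """

    species: str
    genes: list[str]
    values: np.ndarray
    validate: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        n = len(self.genes)
        if len(set(self.genes)) != n:
            raise ValueError("duplicate gene IDs in map")
        if self.values.shape != (n, n):
            raise ValueError(f"values shape {self.values.shape} != ({n}, {n})")
        self._index = {g: i for i, g in enumerate(self.genes)}
        self._id_rank_cache: np.ndarray | None = None
        if self.validate and n > 1:
            rng = np.random.default_rng(0)
            k = min(256, n * n)
            ii = rng.integers(0, n, size=k)
            jj = rng.integers(0, n, size=k)
            sub, tsub = self.values[ii, jj], self.values[jj, ii]
            if not np.allclose(sub, tsub, atol=1e-9):
                raise ValueError("co-expression map is not symmetric")
            off = ii != jj
            if off.any() and (
                np.nanmin(sub[off]) < -1e-9 or np.nanmax(sub[off]) > 1 + 1e-9
            ):
                raise ValueError("co-expression scores must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.genes)

    def index_of(self, gene: str) -> int:
        try:
            return self._index[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in {self.species or 'map'} universe") from None

    @property
    def _id_rank(self) -> np.ndarray:
        # rank of each gene under lexicographic ID order; deterministic tie-break
        if self._id_rank_cache is None:
            order = np.argsort(np.asarray(self.genes, dtype=object), kind="stable")
            rank = np.empty(len(self.genes), dtype=np.int64)
            rank[order] = np.arange(len(self.genes))
            self._id_rank_cache = rank
        return self._id_rank_cache

    # -- interchange formats -------------------------------------------

    def to_long_tsv(self, path) -> None:
        """Write the upper triangle as long-form TSV (gene_a, gene_b, score)."""
        n = len(self.genes)
        iu, ju = np.triu_indices(n, k=1)
        genes = np.asarray(self.genes, dtype=object)
        pd.DataFrame(
            {"gene_a": genes[iu], "gene_b": genes[ju], "score": self.values[iu, ju]}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_long_tsv(cls, path, species: str = "") -> "CoexpressionMap":
        df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
        genes = sorted(set(df["gene_a"]) | set(df["gene_b"]))
        idx = {g: i for i, g in enumerate(genes)}
        n = len(genes)
        values = np.zeros((n, n))
        ii = df["gene_a"].map(idx).to_numpy()
        jj = df["gene_b"].map(idx).to_numpy()
        values[ii, jj] = df["score"].to_numpy(float)
        values[jj, ii] = df["score"].to_numpy(float)
        return cls(species=species, genes=genes, values=values)


@dataclass
class TopList:
    """A gene's top-percent co-expressed partner list (ordered, self-free)."""

    gene: str
    percent: float
    partners: list[str]


def _n_top(n_genes: int, percent: float) -> int:
    if not 0 < percent <= 100:
        raise ValueError(f"percent must be in (0, 100], got {percent}")
    return math.floor(n_genes * percent / 100.0)


def _top_indices(cmap: CoexpressionMap, i: int, n_top: int) -> np.ndarray:
    scores = np.asarray(cmap.values[i], dtype=float).copy()
    scores[i] = -np.inf
    # descending score, ties at the cut by ascending gene ID
    order = np.lexsort((cmap._id_rank, -scores))
    return order[:n_top]


def top_percent_list(cmap: CoexpressionMap, gene: str, percent: float = 5.0) -> TopList:
    """The ``floor(percent/100 * N)`` strongest co-expression partners of a gene.

    The focal gene is excluded, ordering is by descending score with
    boundary ties broken by ascending gene ID.  At ``percent == 100`` the
    list is clamped to the ``N - 1`` other genes.
    """
    i = cmap.index_of(gene)
    n_top = min(_n_top(len(cmap), percent), len(cmap) - 1)
    idx = _top_indices(cmap, i, n_top)
    return TopList(gene=gene, percent=percent, partners=[cmap.genes[j] for j in idx])


def all_top_indices(cmap: CoexpressionMap, percent: float) -> tuple[int, np.ndarray]:
    """Top-list member indices for every gene, as an (N, n_top) index array."""
    n = len(cmap)
    n_top = min(_n_top(n, percent), n - 1)
    out = np.empty((n, n_top), dtype=np.int64)
    for i in range(n):
        out[i] = _top_indices(cmap, i, n_top)
    return n_top, out


def build_coexpression_map(
    datasets: Sequence[ExpressionDataset],
    species: str = "",
    neutral_epsilon: float = 0.0,
) -> CoexpressionMap:
    """Build a vote-counting co-expression map from expression datasets.

    The map universe is the sorted union of all dataset genes.  Counts are
    pooled over datasets; gene pairs never co-observed in any dataset score
    0.  The result is invariant to condition order within datasets.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    universe = sorted(set().union(*(set(d.genes) for d in datasets)))
    index = {g: i for i, g in enumerate(universe)}
    n = len(universe)
    c_counts = np.zeros((n, n))
    d_counts = np.zeros((n, n))
    for ds in datasets:
        signs = discretize(ds, neutral_epsilon)
        up = (signs == 1).astype(np.float64)
        down = (signs == -1).astype(np.float64)
        c_local = up @ up.T + down @ down.T
        d_local = up @ down.T + down @ up.T
        idx = np.fromiter((index[g] for g in ds.genes), dtype=np.int64, count=len(ds.genes))
        c_counts[np.ix_(idx, idx)] += c_local
        d_counts[np.ix_(idx, idx)] += d_local
    total = c_counts + d_counts
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(total > 0, c_counts / np.where(total > 0, total, 1.0), 0.0)
    np.fill_diagonal(values, 0.0)
    return CoexpressionMap(species=species, genes=universe, values=values)
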