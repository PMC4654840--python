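"""Directed percentage-threshold networks, connectivity and DiffK.

An arc i -> j exists iff gene i is among the top-percent co-expressed genes
of gene j, so every gene contributes exactly ``floor(percent/100 * m)``
incoming slots and connectivity (the row sum of the adjacency matrix) counts
how many other genes' top lists contain the focal gene.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from coexcons.coexpr import CoexpressionMap, all_top_indices
from coexcons.homology import HomologyTable

logger = logging.getLogger(__name__)

#: pseudocount added to connectivity before the ratio, damping low-count folds
DIFFK_PSEUDOCOUNT = 10.0


@dataclass
class DirectedCoexprNetwork:
    """Boolean adjacency A with A[i, j] = 1 iff arc i -> j, plus the threshold."""

    genes: list[str]
    adjacency: np.ndarray
    percent: float

    def __post_init__(self) -> None:
        m = len(self.genes)
        if self.adjacency.shape != (m, m):
            raise ValueError("adjacency shape does not match gene list")
        if self.adjacency.dtype != bool:
            self.adjacency = self.adjacency.astype(bool)
        if np.diagonal(self.adjacency).any():
            raise ValueError("self-arcs are not allowed")

    @property
    def n_top(self) -> int:
        return math.floor(len(self.genes) * self.percent / 100.0)

    def to_edge_tsv(self, path) -> None:
        ii, jj = np.nonzero(self.adjacency)
        genes = np.asarray(self.genes, dtype=object)
        pd.DataFrame({"source": genes[ii], "target": genes[jj]}).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class ConnectivityVector:
    """Per-gene in-top-list counts (k) for one network."""

    genes: list[str]
    k: np.ndarray

    def as_series(self) -> pd.Series:
        return pd.Series(self.k, index=self.genes, name="k")

    def to_tsv(self, path) -> None:
        self.as_series().rename_axis("gene").to_csv(path, sep="\t")


def build_directed_network(cmap: CoexpressionMap, percent: float = 1.0) -> DirectedCoexprNetwork:
    """Extract the directed top-percent network from a co-expression map."""
    m = len(cmap)
    n_top, top_idx = all_top_indices(cmap, percent)
    if n_top == 0:
        raise ValueError(
            f"percent={percent} yields an empty top list for {m} genes"
        )
    adjacency = np.zeros((m, m), dtype=bool)
    cols = np.repeat(np.arange(m), n_top)
    adjacency[top_idx.ravel(), cols] = True
    return DirectedCoexprNetwork(genes=list(cmap.genes), adjacency=adjacency, percent=percent)


def connectivity(net: DirectedCoexprNetwork) -> ConnectivityVector:
    """k_i = sum_j A[i, j]: how many genes' top lists contain gene i."""
    return ConnectivityVector(genes=list(net.genes), k=net.adjacency.sum(axis=1))


def normalize_connectivity(
    k1: np.ndarray, k2: np.ndarray, m1: int, m2: int, percent: float
) -> tuple[np.ndarray, np.ndarray]:
    """Rescale species-2 connectivity onto the species-1 scale.

    Networks built with a percentage threshold distribute ``m * n_top`` arcs,
    so raw degrees from differently sized universes are made comparable by
    multiplying species-2 degrees with the ratio of top-list lengths.
    Species-1 values are returned unchanged.
    """
    n1 = math.floor(m1 * percent / 100.0)
    n2 = math.floor(m2 * percent / 100.0)
    if n1 == 0 or n2 == 0:
        raise ValueError("percent threshold yields an empty top list")
    factor = n1 / n2
    return np.asarray(k1, dtype=float), np.asarray(k2, dtype=float) * factor


def differential_connectivity(k1n, k2n):
    """Folded DiffK between two (normalized) connectivity values.

    The ratio ``r = (k1n + 10) / (k2n + 10)`` is mapped to its negative
    reciprocal when below 1, then shifted one unit towards zero, giving 0 at
    equality, positive values when species 1 is more connected and negative
    when species 2 is.  Exactly antisymmetric under argument swap.  Accepts
    scalars or arrays.
    """
    k1n = np.asarray(k1n, dtype=float)
    k2n = np.asarray(k2n, dtype=float)
    if (k1n < 0).any() or (k2n < 0).any():
        raise ValueError("connectivity values must be non-negative")
    a = k1n + DIFFK_PSEUDOCOUNT
    b = k2n + DIFFK_PSEUDOCOUNT
    # branch on the comparison (not the computed ratio) so that swapping the
    # arguments flips the sign bit-exactly
    folded = np.where(k1n >= k2n, a / b - 1.0, -(b / a - 1.0))
    return folded if folded.ndim else float(folded)


@dataclass
class DiffKResult:
    """Per-homolog-pair differential connectivity (species 1 vs species 2)."""

    frame: pd.DataFrame  # gene_a, gene_b, relationship, k1, k2, k1_norm, k2_norm, folded
    percent: float

    def gene_level(self, one2one_only: bool = False) -> pd.Series:
        """Mean folded DiffK per species-A gene (optionally one2one pairs only)."""
        df = self.frame
        if one2one_only:
            df = df[df["relationship"] == "one2one"]
        return df.groupby("gene_a")["folded"].mean()

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def differential_connectivity_table(
    table: HomologyTable,
    net_a: DirectedCoexprNetwork,
    net_b: DirectedCoexprNetwork,
) -> DiffKResult:
    """Folded DiffK for every homolog pair present in both networks."""
    if net_a.percent != net_b.percent:
        raise ValueError("networks must be built at the same percent threshold")
    conn_a = connectivity(net_a).as_series()
    conn_b = connectivity(net_b).as_series()
    rows = []
    skipped = 0
    for (a, b), rel in zip(table.pairs, table.relationship):
        if a not in conn_a.index or b not in conn_b.index:
            skipped += 1
            continue
        rows.append((a, b, rel, int(conn_a[a]), int(conn_b[b])))
    if skipped:
        logger.warning("%d homolog pairs absent from the networks; skipped", skipped)
    frame = pd.DataFrame(rows, columns=["gene_a", "gene_b", "relationship", "k1", "k2"])
    k1n, k2n = normalize_connectivity(
        frame["k1"].to_numpy(), frame["k2"].to_numpy(),
        len(net_a.genes), len(net_b.genes), net_a.percent,
    )
    frame["k1_norm"] = k1n
    frame["k2_norm"] = k2n
    frame["folded"] = differential_connectivity(k1n, k2n)
    return DiffKResult(frame=frame, percent=net_a.percent)


@dataclass
class DegreeDistributionFit:
    """Log-log least-squares fit of the degree histogram (diagnostic only)."""

    slope: float
    r_squared: float
    defined: bool
    low_confidence: bool = False


def degree_distribution_fit(k: np.ndarray, min_distinct: int = 20) -> DegreeDistributionFit:
    """Fit log frequency vs log degree over k >= 1 by least squares.

    A power-law degree distribution P(k) ~ k^-y appears as a line of slope
    ``-y``.  With fewer than ``min_distinct`` distinct positive degrees the
    fit is flagged undefined; a near-zero R-squared flags low confidence.
    """
    k = np.asarray(k)
    k = k[k >= 1]
    degrees, counts = np.unique(k, return_counts=True)
    if len(degrees) < min_distinct:
        return DegreeDistributionFit(slope=float("nan"), r_squared=float("nan"), defined=False)
    x = np.log(degrees.astype(float))
    y = np.log(counts / counts.sum())
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    return DegreeDistributionFit(
        slope=float(slope), r_squared=r2, defined=True, low_confidence=r2 < 0.2
    )
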