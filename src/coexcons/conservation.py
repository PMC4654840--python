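"""CCG counting, permutation Spearman association and ranked-extreme exports.

The commonly-co-expressed-genes (CCG) count of a homolog pair is the number
of species-A genes in the pair's species-A top list that have at least one
homolog inside the pair's species-B top list.  Non-homologous list members
can never contribute, and a list member with several matched homologs still
contributes exactly once.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from coexcons.coexpr import CoexpressionMap, TopList, all_top_indices, top_percent_list
from coexcons.homology import HomologyTable

logger = logging.getLogger(__name__)


def ccg_count(
    pair: tuple[str, str],
    top_a: TopList,
    top_b: TopList,
    table: HomologyTable,
) -> int:
    """Count species-A top-list genes with a homolog in the species-B top list."""
    if pair not in table:
        raise KeyError(f"pair {pair} not in homology table")
    if top_a.percent != top_b.percent:
        raise ValueError("top lists must be computed at the same percent")
    homologs = table.homologs_of_a
    members_b = set(top_b.partners)
    count = 0
    for g in top_a.partners:
        hs = homologs.get(g)
        if hs is not None and not hs.isdisjoint(members_b):
            count += 1
    return count


@dataclass
class CCGTable:
    """Per-pair CCG counts with per-gene aggregates and overlap membership.

    ``pairs`` has columns pair_id, gene_a, gene_b, relationship, ccg_count.
    ``gene_level_a`` / ``gene_level_b`` aggregate a gene's pair counts with
    the configured rule (max by default).  ``overlaps`` retains, per pair,
    the actual overlapping species-A genes (needed for the candidate-gene
    association analysis).
    """

    pairs: pd.DataFrame
    gene_level_a: pd.Series
    gene_level_b: pd.Series
    percent: float
    aggregation: str
    overlaps: dict[str, tuple[str, ...]] | None = None

    def to_tsv(self, path) -> None:
        df = self.pairs.copy()
        df["gene_level_a"] = df["gene_a"].map(self.gene_level_a)
        df["gene_level_b"] = df["gene_b"].map(self.gene_level_b)
        df.to_csv(path, sep="\t", index=False)

    def gene_level(self, relationship: str | None = None) -> pd.Series:
        """Species-A gene-level CCG, optionally restricted to one class."""
        df = self.pairs
        if relationship is not None:
            df = df[df["relationship"] == relationship]
        agg = "max" if self.aggregation == "max" else "mean"
        return df.groupby("gene_a")["ccg_count"].agg(agg)


def ccg_all_pairs(
    map_a: CoexpressionMap,
    map_b: CoexpressionMap,
    table: HomologyTable,
    percent: float = 5.0,
    aggregation: str = "max",
    keep_overlaps: bool = True,
) -> CCGTable:
    """CCG counts for every homolog pair resolvable in both maps.

    Pairs whose genes are absent from either map are skipped with a warning.
    Gene-level values aggregate each gene's pair counts (``max`` ranks a
    gene by its best-conserved relationship; ``mean`` is also supported).
    """
    if aggregation not in ("max", "mean"):
        raise ValueError("aggregation must be 'max' or 'mean'")
    _, top_idx_a = all_top_indices(map_a, percent)
    _, top_idx_b = all_top_indices(map_b, percent)
    genes_a = np.asarray(map_a.genes, dtype=object)
    genes_b = np.asarray(map_b.genes, dtype=object)
    homologs = table.homologs_of_a

    top_b_sets: dict[str, set[str]] = {}
    rows = []
    overlaps: dict[str, tuple[str, ...]] = {}
    skipped = 0
    for (a, b), rel in zip(table.pairs, table.relationship):
        if a not in map_a._index or b not in map_b._index:
            skipped += 1
            continue
        if b not in top_b_sets:
            top_b_sets[b] = set(genes_b[top_idx_b[map_b.index_of(b)]])
        members_b = top_b_sets[b]
        hit = []
        for g in genes_a[top_idx_a[map_a.index_of(a)]]:
            hs = homologs.get(g)
            if hs is not None and not hs.isdisjoint(members_b):
                hit.append(g)
        pair_id = f"{a}|{b}"
        rows.append((pair_id, a, b, rel, len(hit)))
        if keep_overlaps:
            overlaps[pair_id] = tuple(hit)
    if skipped:
        logger.warning("%d homolog pairs not resolvable in the maps; skipped", skipped)
    pairs = pd.DataFrame(
        rows, columns=["pair_id", "gene_a", "gene_b", "relationship", "ccg_count"]
    )
    agg = aggregation
    gene_level_a = pairs.groupby("gene_a")["ccg_count"].agg(agg)
    gene_level_b = pairs.groupby("gene_b")["ccg_count"].agg(agg)
    return CCGTable(
        pairs=pairs,
        gene_level_a=gene_level_a,
        gene_level_b=gene_level_b,
        percent=percent,
        aggregation=aggregation,
        overlaps=overlaps if keep_overlaps else None,
    )


@dataclass
class PermutationAssociation:
    """Spearman rho with a permutation-based empirical two-sided p-value."""

    rho: float
    B: int
    p_empirical: float
    seed: int
    n_extreme: int

    @property
    def p_bound(self) -> str | None:
        """Reporting-style bound (e.g. ``"<1e-04"``) when no permutation reached rho."""
        if self.n_extreme == 0:
            return f"<{1.0 / self.B:g}"
        return None


def spearman_permutation(
    x: Sequence[float],
    y: Sequence[float],
    B: int = 10_000,
    seed: int = 0,
) -> PermutationAssociation:
    """Spearman correlation with an empirical permutation p-value.

    The null distribution is built by permuting ``y`` only; the two-sided
    p-value uses the add-one convention
    ``p = (1 + #{|rho_perm| >= |rho_obs|}) / (B + 1)`` so it is never zero
    and is bounded below by ``1 / (B + 1)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
    rho = float(rxc @ ryc) / denom
    rng = np.random.default_rng(seed)
    n_extreme = 0
    abs_obs = abs(rho)
    for _ in range(B):
        perm = rng.permutation(ryc)
        rho_perm = float(rxc @ perm) / denom
        if abs(rho_perm) >= abs_obs - 1e-12:
            n_extreme += 1
    p = (1 + n_extreme) / (B + 1)
    return PermutationAssociation(rho=rho, B=B, p_empirical=p, seed=seed, n_extreme=n_extreme)


def rank_select_extremes(
    values: Mapping[str, float] | pd.Series, percent: float = 5.0
) -> tuple[list[str], list[str]]:
    """Top and bottom ``floor(percent/100 * n)`` genes of a ranked score list.

    Ties at either cut are broken by ascending gene ID.  Intended for export
    to external enrichment tools (one gene per line).
    """
    series = pd.Series(values, dtype=float)
    if not np.isfinite(series.to_numpy()).all():
        raise ValueError("scores must be finite")
    n_sel = math.floor(len(series) * percent / 100.0)
    if n_sel < 1:
        raise ValueError(
            f"{len(series)} genes are too few for a {percent}% extreme selection"
        )
    items = sorted(series.items(), key=lambda kv: (-kv[1], kv[0]))
    top = [g for g, _ in items[:n_sel]]
    items_low = sorted(series.items(), key=lambda kv: (kv[1], kv[0]))
    bottom = [g for g, _ in items_low[:n_sel]]
    return top, bottom


def write_gene_list(path, genes: Sequence[str]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.writelines(f"{g}\n" for g in genes)


@dataclass
class DistributionSummary:
    """Skewness and Shapiro-type normality diagnostics (never gates anything)."""

    skewness: float
    shapiro_w: float
    shapiro_p: float
    normality_defined: bool


def distribution_summary(values: Sequence[float]) -> DistributionSummary:
    """Adjusted Fisher-Pearson skewness plus a Shapiro-Wilk normality test."""
    values = np.asarray(values, dtype=float)
    if len(values) < 8:
        raise ValueError("need at least 8 observations")
    if np.ptp(values) == 0:
        return DistributionSummary(
            skewness=0.0, shapiro_w=float("nan"), shapiro_p=float("nan"),
            normality_defined=False,
        )
    skewness = float(stats.skew(values, bias=False))
    # Shapiro-Wilk p-values are unreliable above n=5000; subsample deterministically
    sample = values
    if len(sample) > 5000:
        sample = np.random.default_rng(0).choice(sample, size=5000, replace=False)
    w, p = stats.shapiro(sample)
    return DistributionSummary(
        skewness=skewness, shapiro_w=float(w), shapiro_p=float(p), normality_defined=True
    )
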