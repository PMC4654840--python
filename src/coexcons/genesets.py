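"""Gene-set collections and the four conservation parameters.

Each gene set is scored with (i) conservation of co-expression (Mann-Whitney
on gene-level CCG, in-set vs remaining genes), (ii) differential
connectivity (Mann-Whitney on folded DiffK), (iii) duplication ratio
(Fisher's exact test on the proportion of duplicated homologs) and (iv)
non-homolog ratio (Fisher's exact test on the proportion of non-homologous
genes).  Benjamini-Hochberg correction is applied across sets separately per
parameter and per homology mode.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _odds_ratio
from statsmodels.stats.multitest import multipletests

from coexcons.conservation import CCGTable
from coexcons.homology import HomologyTable
from coexcons.network import DiffKResult

logger = logging.getLogger(__name__)

PARAMETERS = (
    "ccg_conservation",
    "differential_connectivity",
    "duplication_ratio",
    "nonhomolog_ratio",
)


@dataclass
class GeneSetCollection:
    """Named gene sets over species-A IDs (tissue / pathway / disease style)."""

    sets: dict[str, list[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            # preserve order, drop within-set duplicates
            self.sets[name] = list(dict.fromkeys(members))

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def to_gmt(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for name, members in self.sets.items():
                fh.write("\t".join([name, self.source or "na", *members]) + "\n")


def read_gmt(path, source: str = "") -> GeneSetCollection:
    """Read a standard GMT file (name, description, tab-separated members)."""
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >= 3 tab-separated fields")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}: line {lineno}: duplicate set name {name!r}")
            members = [m for m in fields[2:] if m]
            if not members:
                raise ValueError(f"{path}: line {lineno}: set {name!r} has no members")
            sets[name] = members
    return GeneSetCollection(sets=sets, source=source)


def filter_min_size(
    collection: GeneSetCollection,
    universe: Iterable[str],
    min_genes: int = 10,
    count_in_universe: bool = True,
) -> GeneSetCollection:
    """Drop sets with fewer than ``min_genes`` members (strict "less than").

    Sets are restricted to the analysis universe first; with
    ``count_in_universe=False`` the raw (pre-restriction) size is used for
    the threshold instead, mirroring a filter applied upstream.
    """
    universe = set(universe)
    kept: dict[str, list[str]] = {}
    for name, members in collection.sets.items():
        restricted = [g for g in members if g in universe]
        size = len(restricted) if count_in_universe else len(members)
        if size >= min_genes and restricted:
            kept[name] = restricted
    logger.info("size filter kept %d / %d sets", len(kept), len(collection.sets))
    return GeneSetCollection(sets=kept, source=collection.source)


def eval_set_mannwhitney(
    set_genes: Iterable[str],
    gene_values: Mapping[str, float] | pd.Series,
    one2one_only_values: pd.Series | None = None,
) -> tuple[float, float, float]:
    """Two-sided Mann-Whitney of in-set vs remaining scored genes.

    Returns ``(U, effect, p)`` where effect is the median difference
    ``median(in-set) - median(remaining)``.  When ``one2one_only_values`` is
    given it replaces ``gene_values`` (the one-to-one restricted analysis).
    """
    values = pd.Series(
        one2one_only_values if one2one_only_values is not None else gene_values,
        dtype=float,
    )
    in_mask = values.index.isin(set(set_genes))
    x = values.to_numpy()[in_mask]
    y = values.to_numpy()[~in_mask]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 scored genes inside and outside the set")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    effect = float(np.median(x) - np.median(y))
    return float(res.statistic), effect, float(res.pvalue)


def eval_set_fisher(
    set_genes: Iterable[str],
    gene_labels: pd.Series,
) -> tuple[float, float]:
    """Fisher's exact test of a binary gene attribute, in-set vs out.

    ``gene_labels`` is a boolean series over the relevant universe.  Returns
    the conditional maximum-likelihood odds ratio and the two-sided exact
    p-value.  Degenerate margins (attribute constant, or set covering all or
    none of the universe) give p = 1 with an infinite/zero/NaN odds ratio.
    """
    labels = gene_labels.astype(bool)
    in_mask = labels.index.isin(set(set_genes))
    a = int((in_mask & labels).sum())  # in-set with attribute
    b = int((in_mask & ~labels).sum())
    c = int((~in_mask & labels).sum())
    d = int((~in_mask & ~labels).sum())
    table = np.array([[a, b], [c, d]])
    if min(table.sum(axis=0).min(), table.sum(axis=1).min()) == 0:
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = (a * d) / (b * c) if b * c else float("inf") if a * d else float("nan")
        return float(raw), 1.0
    orr = _odds_ratio(table, kind="conditional").statistic
    p = stats.fisher_exact(table, alternative="two-sided")[1]
    return float(orr), float(p)


@dataclass
class ConservationReport:
    """Per-set conservation parameters with BH-corrected significance.

    ``frame`` columns: set, parameter, homology_mode, statistic, effect, p,
    fdr, significant, direction.
    """

    frame: pd.DataFrame
    alpha: float = 0.05
    warnings_: list[str] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def significant_sets(self, parameter: str, homology_mode: str = "all") -> list[str]:
        df = self.frame
        sel = df[
            (df["parameter"] == parameter)
            & (df["homology_mode"] == homology_mode)
            & df["significant"]
        ]
        return list(sel["set"])


def evaluate_collection(
    collection: GeneSetCollection,
    ccg: CCGTable,
    diffk: DiffKResult,
    table: HomologyTable,
    alpha: float = 0.05,
) -> ConservationReport:
    """Score every set with the four conservation parameters.

    The Mann-Whitney parameters (CCG conservation, differential
    connectivity) run in two homology modes: ``all`` homolog pairs and
    ``one2one`` pairs only.  The Fisher parameters use the homologous-gene
    universe (duplication ratio) and the full species-A universe
    (non-homolog ratio).  BH families are one parameter x one homology mode
    across all sets.  Sets failing a parameter's preconditions are skipped
    for that parameter with a warning; the report is always produced.
    """
    homolog_genes = table.homolog_genes_a
    duplicated = table.duplicated_genes_a
    universe_all = sorted(table.universe_a)
    dup_labels = pd.Series(
        [g in duplicated for g in sorted(homolog_genes)], index=sorted(homolog_genes)
    )
    nonhom_labels = pd.Series(
        [g not in homolog_genes for g in universe_all], index=universe_all
    )
    value_sources: dict[tuple[str, str], pd.Series] = {
        ("ccg_conservation", "all"): ccg.gene_level(),
        ("ccg_conservation", "one2one"): ccg.gene_level("one2one"),
        ("differential_connectivity", "all"): diffk.gene_level(),
        ("differential_connectivity", "one2one"): diffk.gene_level(one2one_only=True),
    }

    rows = []
    notes: list[str] = []
    for name, members in collection:
        for (param, mode), values in value_sources.items():
            try:
                stat, effect, p = eval_set_mannwhitney(members, values)
            except ValueError as exc:
                msg = f"set {name!r}, {param}/{mode}: {exc}"
                notes.append(msg)
                logger.warning(msg)
                continue
            rows.append((name, param, mode, stat, effect, p))
        for param, labels in (
            ("duplication_ratio", dup_labels),
            ("nonhomolog_ratio", nonhom_labels),
        ):
            orr, p = eval_set_fisher(members, labels)
            # effect for Fisher parameters is the odds ratio itself
            rows.append((name, param, "all", orr, orr, p))

    frame = pd.DataFrame(
        rows, columns=["set", "parameter", "homology_mode", "statistic", "effect", "p"]
    )
    frame["fdr"] = np.nan
    for (param, mode), idx in frame.groupby(["parameter", "homology_mode"]).groups.items():
        pvals = frame.loc[idx, "p"].to_numpy()
        frame.loc[idx, "fdr"] = multipletests(pvals, method="fdr_bh")[1]
    frame["significant"] = frame["fdr"] < alpha
    is_fisher = frame["parameter"].isin(["duplication_ratio", "nonhomolog_ratio"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        frame["direction"] = np.select(
            [
                is_fisher & (frame["effect"] > 1),
                is_fisher & (frame["effect"] < 1),
                ~is_fisher & (frame["effect"] > 0),
                ~is_fisher & (frame["effect"] < 0),
            ],
            ["enriched", "depleted", "higher", "lower"],
            default="none",
        )
    # rank sets by CCG-conservation effect within the report
    ccg_effect = (
        frame[(frame["parameter"] == "ccg_conservation") & (frame["homology_mode"] == "all")]
        .set_index("set")["effect"]
    )
    frame["_rank_key"] = frame["set"].map(ccg_effect)
    frame = (
        frame.sort_values(
            ["parameter", "homology_mode", "_rank_key"], ascending=[True, True, False]
        )
        .drop(columns="_rank_key")
        .reset_index(drop=True)
    )
    return ConservationReport(frame=frame, alpha=alpha, warnings_=notes)
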