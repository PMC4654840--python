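"""Candidate genes recurrently co-expressed with a gene set's homologs.

For a gene set, every homolog pair whose species-A gene belongs to the set
contributes its CCG overlap members as candidate associations.  A
candidate's relative frequency is the fraction of set pairs whose overlap
contains it; significance comes from re-running the count on random
homolog-pair subsets of the same size (a one-sided enrichment permutation
test) with Benjamini-Hochberg correction across the set's candidates.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from coexcons.conservation import CCGTable

logger = logging.getLogger(__name__)


def _set_pair_ids(ccg: CCGTable, set_genes: set[str]) -> list[str]:
    pairs = ccg.pairs
    return list(pairs.loc[pairs["gene_a"].isin(set_genes), "pair_id"])


def candidate_frequencies(
    set_genes: Iterable[str],
    ccg: CCGTable,
    exclude_set_members: bool = True,
) -> pd.DataFrame:
    """Count how often each candidate gene appears in the set's CCG overlaps.

    Returns a frame with columns gene, count, rel_freq where ``rel_freq`` is
    count divided by the number of the set's homolog pairs.  Set members are
    excluded from candidacy by default.  A set with no homolog pairs yields
    an empty frame with a warning.
    """
    if ccg.overlaps is None:
        raise ValueError("CCG table was built without overlap membership")
    set_genes = set(set_genes)
    pair_ids = _set_pair_ids(ccg, set_genes)
    if not pair_ids:
        logger.warning("gene set has no homolog pairs in the CCG table")
        return pd.DataFrame(columns=["gene", "count", "rel_freq"])
    counts: dict[str, int] = {}
    for pid in pair_ids:
        for g in ccg.overlaps[pid]:
            if exclude_set_members and g in set_genes:
                continue
            counts[g] = counts.get(g, 0) + 1
    n_pairs = len(pair_ids)
    frame = pd.DataFrame(
        {"gene": list(counts), "count": list(counts.values())}
    ).sort_values("gene", ignore_index=True)
    frame["rel_freq"] = frame["count"] / n_pairs
    return frame


def permutation_significance(
    set_genes: Iterable[str],
    ccg: CCGTable,
    B: int = 1000,
    seed: int = 0,
    exclude_set_members: bool = True,
) -> pd.DataFrame:
    """Permutation p-values for the set's candidate association frequencies.

    Per iteration a uniform random subset of homolog pairs, of the same size
    as the set's pair list, is drawn from the whole table and every observed
    candidate's count is recomputed; ``p = (1 + #{perm >= obs}) / (B + 1)``
    (one-sided, enrichment).  Columns: set-independent gene, count,
    rel_freq, p, fdr; sorted by fdr then descending rel_freq.
    """
    if B < 100:
        logger.warning("B=%d gives a minimum p of %.3g; results are coarse", B, 1 / (B + 1))
    set_genes = set(set_genes)
    observed = candidate_frequencies(set_genes, ccg, exclude_set_members)
    if observed.empty:
        observed["p"] = pd.Series(dtype=float)
        observed["fdr"] = pd.Series(dtype=float)
        return observed
    pair_ids = _set_pair_ids(ccg, set_genes)
    n_set_pairs = len(pair_ids)
    all_pair_ids = list(ccg.pairs["pair_id"])
    candidates = list(observed["gene"])
    cand_index = {g: i for i, g in enumerate(candidates)}
    # pair x candidate membership matrix over the full table
    membership = np.zeros((len(all_pair_ids), len(candidates)), dtype=bool)
    for row, pid in enumerate(all_pair_ids):
        for g in ccg.overlaps[pid]:
            j = cand_index.get(g)
            if j is not None:
                membership[row, j] = True
    obs_counts = observed["count"].to_numpy()
    rng = np.random.default_rng(seed)
    n_extreme = np.zeros(len(candidates), dtype=np.int64)
    for _ in range(B):
        idx = rng.choice(len(all_pair_ids), size=n_set_pairs, replace=False)
        perm_counts = membership[idx].sum(axis=0)
        n_extreme += perm_counts >= obs_counts
    observed = observed.copy()
    observed["p"] = (1 + n_extreme) / (B + 1)
    observed["fdr"] = multipletests(observed["p"].to_numpy(), method="fdr_bh")[1]
    return observed.sort_values(
        ["fdr", "rel_freq"], ascending=[True, False], ignore_index=True
    )
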