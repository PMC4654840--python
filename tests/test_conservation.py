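import numpy as np
import pytest
from scipy import stats

from coexcons.conservation import (
    ccg_all_pairs,
    ccg_count,
    distribution_summary,
    rank_select_extremes,
    spearman_permutation,
)
from coexcons.coexpr import TopList
from coexcons.homology import HomologyTable
from coexcons.synthetic_data import generate_map_pair, random_map

from .conftest import make_identity_homology


def table_from_pairs(pairs, relationship=None):
    n = len(pairs)
    return HomologyTable(
        pairs=pairs,
        relationship=relationship or ["one2one"] * n,
        dn=np.full(n, 0.1),
        ds=np.ones(n),
    )


def toplist(gene, partners, percent=5):
    return TopList(gene=gene, percent=percent, partners=list(partners))


def ccg_oracle(top_a, top_b, homologs_of_a):
    """Brute-force restatement of the counting rule: a species-A top-list
    gene counts once iff any of its homologs is in the species-B top list."""
    members_b = set(top_b)
    return sum(
        1
        for g in top_a
        if any(h in members_b for h in homologs_of_a.get(g, ()))
    )


class TestCcgCount:
    def test_set_intersection_case(self):
        table = table_from_pairs(
            [("x", "y"), ("a", "a'"), ("b", "b'"), ("c", "c'"), ("d", "d'")]
        )
        top_a = toplist("x", ["a", "b", "c"])
        top_b = toplist("y", ["b'", "c'", "d'"])
        assert ccg_count(("x", "y"), top_a, top_b, table) == 2

    def test_disjoint_lists(self):
        table = table_from_pairs([("x", "y"), ("a", "a'"), ("b", "b'")])
        assert ccg_count(("x", "y"), toplist("x", ["a"]), toplist("y", ["b'"]), table) == 0

    def test_identity_self_comparison_is_maximum(self):
        genes = [f"g{i}" for i in range(10)]
        table = make_identity_homology(genes, genes)
        top = toplist("g0", genes[1:6])
        assert ccg_count(("g0", "g0"), top, top, table) == 5

    def test_multi_homolog_contributes_once(self):
        # 'a' has two homologs; both in top_b must still count once
        table = table_from_pairs(
            [("x", "y"), ("a", "a1"), ("a", "a2"), ("b", "b1")],
            relationship=["one2one", "one2many", "one2many", "one2one"],
        )
        top_a = toplist("x", ["a", "b"])
        top_b = toplist("y", ["a1", "a2"])
        assert ccg_count(("x", "y"), top_a, top_b, table) == 1

    def test_nonhomolog_members_never_contribute(self):
        table = table_from_pairs([("x", "y"), ("a", "a'")])
        top_a = toplist("x", ["a", "q1", "q2"])  # q* have no homologs
        top_b = toplist("y", ["a'", "r1", "r2"])
        assert ccg_count(("x", "y"), top_a, top_b, table) == 1

    def test_unknown_pair_error(self):
        table = table_from_pairs([("x", "y")])
        with pytest.raises(KeyError):
            ccg_count(("x", "z"), toplist("x", []), toplist("z", []), table)

    def test_matches_bruteforce_on_random_toys(self, rng):
        for seed in range(30):
            local = np.random.default_rng(seed)
            n = int(local.integers(10, 40))
            genes_a = [f"A{i}" for i in range(n)]
            genes_b = [f"B{i}" for i in range(n)]
            # random many-to-many-ish homology
            pairs = sorted(
                {
                    (genes_a[local.integers(n)], genes_b[local.integers(n)])
                    for _ in range(n)
                }
            )
            table = HomologyTable(
                pairs=pairs,
                relationship=["one2one"] * len(pairs),  # labels irrelevant here
                dn=np.full(len(pairs), 0.1),
                ds=np.ones(len(pairs)),
                universe_a=set(genes_a),
                universe_b=set(genes_b),
            )
            a, b = pairs[0]
            top_a = toplist(a, local.choice(genes_a, 8, replace=False))
            top_b = toplist(b, local.choice(genes_b, 8, replace=False))
            expected = ccg_oracle(top_a.partners, top_b.partners, table.homologs_of_a)
            assert ccg_count((a, b), top_a, top_b, table) == expected


class TestCcgAllPairs:
    def test_perfect_conservation_near_list_length(self):
        map_a, map_b, table = generate_map_pair(n_genes=60, n_modules=3, z=0.0, seed=5)
        result = ccg_all_pairs(map_a, map_b, table, percent=20)
        n_top = int(60 * 0.20)
        module_size = 20
        # both top lists are dominated by the focal gene's (shared) module,
        # so the expected overlap is ~ n_top^2 / module_size, far above the
        # ~ n_top^2 / N chance level
        expected = n_top**2 / module_size
        chance = n_top**2 / 60
        med = result.pairs["ccg_count"].median()
        assert med >= 0.7 * expected
        assert med > 2 * chance

    def test_shuffled_maps_match_hypergeometric_expectation(self):
        # independent maps: P(top-list gene has its homolog in the partner
        # list) = n_top / N, and the list holds ~n_top * H / N homologous
        # genes, so E[CCG] = n_top * (H / N) * (n_top / N)
        n, n_top_pct = 50, 20
        counts = []
        for seed in range(40):
            map_a = random_map(n, seed=2 * seed, species="a")
            map_b = random_map(n, seed=2 * seed + 1, species="b")
            table = make_identity_homology(map_a.genes[:30], map_b.genes[:30])
            table.universe_a, table.universe_b = set(map_a.genes), set(map_b.genes)
            result = ccg_all_pairs(map_a, map_b, table, percent=n_top_pct)
            counts.extend(result.pairs["ccg_count"])
        n_top = n * n_top_pct // 100
        expected = n_top * (30 / n) * (n_top / n)
        observed = np.mean(counts)
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(observed - expected) < 4 * se + 0.15

    def test_gene_level_max_rule(self):
        map_a, map_b, _ = generate_map_pair(n_genes=20, n_modules=2, seed=1)
        pairs = [("hA0000", "mB0000"), ("hA0000", "mB0001"), ("hA0001", "mB0002")]
        table = table_from_pairs(pairs, ["one2many", "one2many", "one2one"])
        table.universe_a = set(map_a.genes)
        table.universe_b = set(map_b.genes)
        result = ccg_all_pairs(map_a, map_b, table, percent=30)
        per_pair = result.pairs.set_index("pair_id")["ccg_count"]
        assert result.gene_level_a["hA0000"] == max(
            per_pair["hA0000|mB0000"], per_pair["hA0000|mB0001"]
        )

    def test_single_pair_gene_level_equals_pair_value(self, toy_map_pair):
        map_a, map_b, table = toy_map_pair
        result = ccg_all_pairs(map_a, map_b, table, percent=20)
        per_pair = result.pairs.set_index("gene_a")["ccg_count"]
        for gene, value in result.gene_level_a.items():
            assert value == per_pair[gene]

    def test_one2one_swap_symmetry(self):
        map_a, map_b, table = generate_map_pair(n_genes=40, n_modules=4, z=0.2, seed=8)
        fwd = ccg_all_pairs(map_a, map_b, table, percent=20)
        rev = ccg_all_pairs(map_b, map_a, table.swapped(), percent=20)
        fwd_counts = fwd.pairs.set_index("gene_a")["ccg_count"]
        rev_counts = rev.pairs.set_index("gene_b")["ccg_count"]
        for gene in fwd_counts.index:
            assert fwd_counts[gene] == rev_counts[gene]

    def test_count_bounded_by_homologous_members(self, toy_map_pair):
        map_a, map_b, table = toy_map_pair
        result = ccg_all_pairs(map_a, map_b, table, percent=20)
        n_top = int(len(map_a.genes) * 0.20)
        homologs = table.homologs_of_a
        for pid, overlap in result.overlaps.items():
            count = result.pairs.set_index("pair_id").loc[pid, "ccg_count"]
            assert count <= n_top
            assert count == len(overlap)
            assert all(g in homologs for g in overlap)

    def test_mean_aggregation_available(self, toy_map_pair):
        map_a, map_b, table = toy_map_pair
        result = ccg_all_pairs(map_a, map_b, table, percent=20, aggregation="mean")
        assert result.aggregation == "mean"


class TestSpearmanPermutation:
    def test_perfect_correlation(self):
        x = np.arange(20.0)
        res = spearman_permutation(x, x, B=200, seed=0)
        assert res.rho == pytest.approx(1.0)
        assert res.p_empirical == pytest.approx(1 / 201)
        assert res.p_bound == "<0.005"

    def test_perfect_anticorrelation(self):
        res = spearman_permutation([1, 2, 3], [3, 2, 1], B=100, seed=0)
        assert res.rho == pytest.approx(-1.0)

    def test_matches_scipy_rho(self, rng):
        x, y = rng.normal(size=50), rng.normal(size=50)
        res = spearman_permutation(x, y, B=10, seed=0)
        assert res.rho == pytest.approx(stats.spearmanr(x, y).statistic, rel=1e-10)

    def test_constant_vector_error(self):
        with pytest.raises(ValueError):
            spearman_permutation([1, 1, 1], [1, 2, 3], B=10, seed=0)

    def test_p_lower_bound(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        res = spearman_permutation(x, y, B=50, seed=1)
        assert res.p_empirical >= 1 / 51

    def test_deterministic_under_seed(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        r1 = spearman_permutation(x, y, B=100, seed=7)
        r2 = spearman_permutation(x, y, B=100, seed=7)
        assert r1 == r2


class TestRankSelectExtremes:
    def test_five_plus_five(self):
        values = {f"g{i:03d}": float(i) for i in range(100)}
        top, bottom = rank_select_extremes(values, percent=5)
        assert len(top) == len(bottom) == 5
        assert top[0] == "g099" and bottom[0] == "g000"

    def test_all_equal_uses_id_order(self):
        values = {f"g{i}": 1.0 for i in range(10)}
        top, bottom = rank_select_extremes(values, percent=20)
        assert top == ["g0", "g1"]
        assert bottom == ["g0", "g1"]

    def test_floor_rule_n41(self):
        values = {f"g{i:02d}": float(i) for i in range(41)}
        top, bottom = rank_select_extremes(values, percent=5)
        assert len(top) == len(bottom) == 2  # floor(0.05 * 41)

    def test_too_few_error(self):
        with pytest.raises(ValueError):
            rank_select_extremes({"a": 1.0, "b": 2.0}, percent=5)


class TestDistributionSummary:
    def test_symmetric_sample_zero_skew(self):
        res = distribution_summary([-2, -1, 0, 1, 2, -2, -1, 0, 1, 2])
        assert res.skewness == pytest.approx(0.0, abs=1e-12)

    def test_exponential_skewness_near_two(self):
        values = np.random.default_rng(0).exponential(size=5000)
        res = distribution_summary(values)
        assert res.skewness == pytest.approx(2.0, abs=0.2)

    def test_normal_sample_calibration(self):
        passes = 0
        for seed in range(20):
            values = np.random.default_rng(seed).normal(size=5000)
            if distribution_summary(values).shapiro_p > 0.01:
                passes += 1
        assert passes >= 17

    def test_constant_vector_flagged(self):
        res = distribution_summary([3.0] * 10)
        assert res.skewness == 0.0
        assert not res.normality_defined

    def test_too_short_error(self):
        with pytest.raises(ValueError):
            distribution_summary([1, 2, 3])
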