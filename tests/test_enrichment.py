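"""Target-set construction, Fisher enrichment, dynamic-tree-cut clustering."""

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from blastohet import (
    ConfigurationError,
    build_target_set,
    correlation_cluster,
    enrichment_test,
)


class TestTargetSet:
    def test_two_of_three_rule(self):
        lists = [["a", "b", "c"], ["b", "c", "d"], ["c", "e"]]
        ts = build_target_set(lists, min_support=2, universe={"a", "b", "c", "d", "e"})
        assert ts.genes == {"b", "c"}

    def test_universe_filters_supported_genes(self):
        lists = [["a", "b"], ["a", "b"]]
        ts = build_target_set(lists, min_support=2, universe={"a"})
        assert ts.genes == {"a"}

    def test_single_list_min_support_one(self):
        ts = build_target_set([["x", "y"]], min_support=1, universe={"x", "z"})
        assert ts.genes == {"x"}

    def test_min_support_exceeding_lists_rejected(self):
        with pytest.raises(ConfigurationError):
            build_target_set([["a"]], min_support=2, universe={"a"})

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_bruteforce_membership_counting(self, seed):
        rng = np.random.default_rng(seed)
        pool = [f"g{i}" for i in range(50)]
        lists = [list(rng.choice(pool, size=20, replace=False)) for _ in range(4)]
        universe = set(rng.choice(pool, size=40, replace=False))
        for support in (1, 2, 3, 4):
            ts = build_target_set(lists, min_support=support, universe=universe)
            oracle = {
                g for g in universe if sum(g in set(l) for l in lists) >= support
            }
            assert ts.genes == oracle


def fisher_two_sided_oracle(a, b, c, d):
    """Exhaustive enumeration over all tables with the observed margins."""
    n = a + b + c + d
    r1 = a + b
    c1 = a + c
    pmf = stats.hypergeom(n, c1, r1).pmf
    p_obs = pmf(a)
    total = 0.0
    for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        pk = pmf(k)
        if pk <= p_obs * (1 + 1e-9):
            total += pk
    return min(total, 1.0)


class TestEnrichment:
    def _result(self, a, b, c, d):
        universe = {f"g{i}" for i in range(a + b + c + d)}
        ordered = sorted(universe)
        variable = set(ordered[: a + b])
        target_genes = set(ordered[:a]) | set(ordered[a + b : a + b + c])
        from blastohet import TargetSet

        ts = TargetSet(genes=target_genes, source_sizes=[len(target_genes)], min_support=1, universe=universe)
        return enrichment_test(variable, ts)

    def test_independence_table(self):
        res = self._result(10, 90, 10, 90)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_against_enumeration_oracle(self):
        res = self._result(30, 70, 100, 800)
        assert res.p_value == pytest.approx(fisher_two_sided_oracle(30, 70, 100, 800), rel=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_small_tables_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = rng.integers(0, 15, size=4)
        if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
            return
        res = self._result(int(a), int(b), int(c), int(d))
        assert res.p_value == pytest.approx(
            fisher_two_sided_oracle(int(a), int(b), int(c), int(d)), rel=1e-9
        )

    def test_infinite_odds_convention(self):
        res = self._result(5, 0, 3, 10)
        assert np.isinf(res.odds_ratio)


def two_module_data(seed, n_per_module=30, n_noise=0, n_cells=50, noise_sd=0.5):
    rng = np.random.default_rng(seed)
    f1, f2 = rng.normal(size=(2, n_cells))
    rows, labels = [], []
    for _ in range(n_per_module):
        rows.append(f1 + noise_sd * rng.normal(size=n_cells))
        labels.append(1)
    for _ in range(n_per_module):
        rows.append(f2 + noise_sd * rng.normal(size=n_cells))
        labels.append(2)
    for _ in range(n_noise):
        rows.append(rng.normal(size=n_cells))
        labels.append(0)
    return np.array(rows), np.array(labels)


class TestCorrelationCluster:
    def test_perfectly_separated_blocks(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=25)
        rows = [base * (1 + 0.01 * i) for i in range(25)] + [
            -base * (1 + 0.01 * i) for i in range(25)
        ]
        assign = correlation_cluster(np.array(rows), min_cluster_size=20)
        labels = assign.labels.to_numpy()
        assert assign.n_clusters == 2
        assert len(set(labels[:25])) == 1 and len(set(labels[25:])) == 1
        assert labels[0] != labels[25]

    def test_fewer_genes_than_min_size_all_unassigned(self):
        X, _ = two_module_data(1, n_per_module=4)
        assign = correlation_cluster(X, min_cluster_size=20)
        assert (assign.labels == 0).all()

    @pytest.mark.parametrize("seed", range(3))
    def test_two_module_recovery(self, seed):
        X, labels = two_module_data(seed)
        assign = correlation_cluster(X, min_cluster_size=20)
        assert adjusted_rand_score(labels, assign.labels.to_numpy()) >= 0.9

    def test_no_structure_rarely_clustered(self):
        fracs = []
        for seed in range(5):
            X = np.random.default_rng(100 + seed).normal(size=(100, 50))
            assign = correlation_cluster(X, min_cluster_size=20)
            fracs.append((assign.labels != 0).mean())
        assert np.mean(fracs) < 0.2

    def test_invariance_to_gene_order_and_monotone_transform(self):
        X, labels = two_module_data(7)
        base = correlation_cluster(X, min_cluster_size=20).labels.to_numpy()
        perm = np.random.default_rng(0).permutation(X.shape[0])
        shuffled = correlation_cluster(X[perm], min_cluster_size=20).labels.to_numpy()
        assert adjusted_rand_score(base[perm], shuffled) == 1.0
        # monotone per-cell transform leaves Spearman, hence labels, unchanged
        transformed = correlation_cluster(np.exp(X / 2), min_cluster_size=20).labels.to_numpy()
        assert adjusted_rand_score(base, transformed) == 1.0

    def test_constant_gene_excluded_with_warning(self):
        X, _ = two_module_data(2)
        X[5, :] = 3.0
        with pytest.warns(UserWarning, match="constant"):
            assign = correlation_cluster(X, min_cluster_size=20)
        assert assign.labels.iloc[5] == 0
        assert len(assign.excluded_constant) == 1
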