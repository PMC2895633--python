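"""Static usage: Wilcoxon statistic, SAM permutation FDR, Fisher enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from subnetusage.expression import ExpressionMatrix
from subnetusage.synthetic import generate_static_experiment
from subnetusage.usage_static import (
    build_static_usage,
    fisher_enrichment,
    sam_call,
    wilcoxon_statistic,
)


def _expr(values: np.ndarray) -> ExpressionMatrix:
    g, s = values.shape
    return ExpressionMatrix(
        pd.DataFrame(values, index=[f"g{i}" for i in range(g)], columns=[f"s{j}" for j in range(s)])
    )


LABELS_8V8 = ["a"] * 8 + ["b"] * 8


class TestWilcoxonStatistic:
    def test_identical_groups_give_zero(self):
        assert wilcoxon_statistic([1, 2, 3], [1, 2, 3]) == 0.0

    def test_separated_groups_attain_enumerated_maximum(self):
        observed = wilcoxon_statistic([4, 5, 6], [1, 2, 3])
        # enumerate all 20 rank assignments of 3 out of 6 ranks
        best = max(
            (sum(c) - 10.5) / math.sqrt(9 * 7 / 12.0)
            for c in itertools.combinations(range(1, 7), 3)
        )
        assert observed == pytest.approx(best)

    def test_fully_tied_data_gives_zero_without_blowup(self):
        assert wilcoxon_statistic([5, 5, 5], [5, 5]) == 0.0

    def test_sign_indicates_direction(self):
        assert wilcoxon_statistic([1, 2], [5, 6]) < 0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_statistic([], [1.0])

    def test_agrees_with_scipy_normal_approximation(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 12), rng.normal(1, 1, 15)
        z = wilcoxon_statistic(a, b)
        # scipy's two-sided normal-approx p (no continuity correction)
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic", use_continuity=False)
        assert 2 * stats.norm.sf(abs(z)) == pytest.approx(res.pvalue, rel=1e-9)


class TestSamCall:
    def test_planted_shift_recovered(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0, 1, (500, 16))
        vals[:50, 8:] += 5.0
        res = sam_call(_expr(vals), LABELS_8V8, q=0.05, n_perm=100, seed=1)
        planted = {f"g{i}" for i in range(50)}
        assert len(res.called & planted) >= 48
        assert len(res.called - planted) <= 5

    def test_null_false_call_fraction_bounded_near_q(self):
        fracs = []
        for s in range(20):
            rng = np.random.default_rng(1000 + s)
            vals = rng.normal(0, 1, (200, 16))
            out = sam_call(_expr(vals), LABELS_8V8, q=0.05, n_perm=50, seed=s)
            fracs.append(len(out.called) / 200)
        assert float(np.mean(fracs)) <= 0.05

    def test_called_sets_nested_in_q(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(0, 1, (300, 16))
        vals[:30, 8:] += 3.0
        expr = _expr(vals)
        c_strict = sam_call(expr, LABELS_8V8, q=0.01, n_perm=100, seed=3).called
        c_loose = sam_call(expr, LABELS_8V8, q=0.10, n_perm=100, seed=3).called
        assert c_strict <= c_loose

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(0, 1, (100, 16))
        vals[:10, 8:] += 4.0
        expr = _expr(vals)
        r1 = sam_call(expr, LABELS_8V8, n_perm=60, seed=9)
        r2 = sam_call(expr, LABELS_8V8, n_perm=60, seed=9)
        assert r1.called == r2.called and r1.delta == r2.delta

    def test_too_few_samples_rejected(self):
        vals = np.zeros((5, 3))
        with pytest.raises(ValueError):
            sam_call(_expr(vals), ["a", "a", "b"])


def _hypergeom_tail_oracle(N, K, n, k):
    """Exhaustive hypergeometric tail by summing point masses."""
    total = 0.0
    for j in range(k, min(K, n) + 1):
        total += math.comb(K, j) * math.comb(N - K, n - j) / math.comb(N, n)
    return total


class TestFisherEnrichment:
    def test_worked_example(self):
        # background of 10 genes, 5 called; subnet of 2, both called
        bg = [f"g{i}" for i in range(10)]
        r = fisher_enrichment(bg[:5], bg[:2], bg)
        assert r.p_value == pytest.approx(10 / 45, abs=1e-12)
        assert r.table == (2, 0, 3, 5)

    def test_no_called_genes_in_subnet_gives_one(self):
        bg = [f"g{i}" for i in range(10)]
        r = fisher_enrichment(bg[:3], bg[5:8], bg)
        assert r.p_value == pytest.approx(1.0)

    def test_subnet_equals_background_gives_one(self):
        bg = [f"g{i}" for i in range(8)]
        assert fisher_enrichment(bg[:4], bg, bg).p_value == pytest.approx(1.0)

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            fisher_enrichment({"a"}, {"a"}, set())

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_exhaustive_oracle_on_small_backgrounds(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(5, 26))
        bg = [f"g{i}" for i in range(N)]
        called = set(rng.choice(bg, size=int(rng.integers(1, N)), replace=False))
        subnet = set(rng.choice(bg, size=int(rng.integers(1, N)), replace=False))
        r = fisher_enrichment(called, subnet, bg)
        k = len(called & subnet)
        assert r.p_value == pytest.approx(
            _hypergeom_tail_oracle(N, len(called), len(subnet), k), abs=1e-12
        )


class TestBuildStaticUsage:
    def test_planted_subnets_recovered(self, flat_trn):
        spec, net, subnets = flat_trn
        used = [s.root for s in subnets if 10 <= s.size <= 40][:5]
        expr, labels, _ = generate_static_experiment(net, used, spec, seed=11)
        res = build_static_usage([(expr, labels)], subnets, net.nodes, n_perm=100, seed=3)
        assert res.usage.shape[1] == 1
        called_rows = set(res.usage.index[res.usage.iloc[:, 0] == 1])
        sens = len(called_rows & set(used)) / len(used)
        fp = len(called_rows - set(used))
        assert sens >= 0.9
        assert 1 - fp / (len(subnets) - len(used)) >= 0.95

    def test_identical_conditions_comparison_skipped(self, flat_trn):
        spec, net, subnets = flat_trn
        rng = np.random.default_rng(0)
        genes = sorted(net.nodes)
        half = rng.normal(0, 1, (len(genes), 8))
        vals = np.concatenate([half, half], axis=1)  # two identical condition blocks
        expr = ExpressionMatrix(
            pd.DataFrame(vals, index=genes, columns=[f"s{j}" for j in range(16)])
        )
        res = build_static_usage([(expr, LABELS_8V8)], subnets, net.nodes, n_perm=50, seed=1)
        assert res.skipped == ["comparison_0"]
        assert res.usage.shape[1] == 0

    def test_no_comparisons_gives_empty_matrix(self, flat_trn):
        _, net, subnets = flat_trn
        res = build_static_usage([], subnets, net.nodes)
        assert res.usage.shape == (len(subnets), 0)

    def test_whole_matrix_deterministic(self, flat_trn):
        spec, net, subnets = flat_trn
        used = [subnets[0].root]
        expr, labels, _ = generate_static_experiment(net, used, spec, seed=5)
        a = build_static_usage([(expr, labels)], subnets, net.nodes, n_perm=50, seed=7)
        b = build_static_usage([(expr, labels)], subnets, net.nodes, n_perm=50, seed=7)
        assert a.usage.equals(b.usage)
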