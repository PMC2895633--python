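"""Time-course usage: SVD entropy, pseudo-subnet z, cutoff calibration."""

import math

import numpy as np
import pandas as pd
import pytest

from subnetusage.expression import ExpressionMatrix
from subnetusage.synthetic import generate_timecourse_experiment
from subnetusage.usage_timecourse import (
    build_timecourse_usage,
    calibrate_cutoff,
    collectivity_z,
    svd_entropy,
)


class TestSvdEntropy:
    def test_rank_one_matrix_gives_zero(self):
        M = np.outer([1.0, 2.0, 3.0], [4.0, 5.0, 6.0, 7.0])
        assert svd_entropy(M) == pytest.approx(0.0, abs=1e-12)

    def test_identity_gives_one(self):
        assert svd_entropy(np.eye(5)) == pytest.approx(1.0)

    def test_diag_sqrt3_one(self):
        assert svd_entropy(np.diag([math.sqrt(3), 1.0])) == pytest.approx(0.8113, abs=1e-4)

    def test_invariance_under_permutation_and_scaling(self):
        rng = np.random.default_rng(0)
        M = rng.normal(size=(6, 9))
        h = svd_entropy(M)
        perm = M[rng.permutation(6)][:, rng.permutation(9)]
        assert svd_entropy(perm) == pytest.approx(h, abs=1e-12)
        assert svd_entropy(-3.7 * M) == pytest.approx(h, abs=1e-12)

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            M = rng.normal(size=(int(rng.integers(2, 8)), int(rng.integers(2, 12))))
            assert 0.0 <= svd_entropy(M) <= 1.0

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            svd_entropy(np.zeros((3, 4)))

    def test_drop_principal_removes_global_mode(self):
        rng = np.random.default_rng(2)
        # strong shared mode plus independent noise
        shared = np.outer(np.ones(6), rng.normal(size=20)) * 10
        M = shared + rng.normal(size=(6, 20))
        assert svd_entropy(M) < 0.3
        assert svd_entropy(M, drop_principal=True) > svd_entropy(M)


class TestCollectivityZ:
    def _noise_expr(self, n_genes=300, T=8, seed=0):
        rng = np.random.default_rng(seed)
        vals = rng.normal(0, 1, (n_genes, T))
        return ExpressionMatrix(
            pd.DataFrame(vals, index=[f"g{i}" for i in range(n_genes)], columns=[f"t{k}" for k in range(T)])
        )

    def test_random_gene_sets_have_near_zero_mean_z(self):
        expr = self._noise_expr()
        rng = np.random.default_rng(3)
        zs = []
        for rep in range(200):
            genes = rng.choice(expr.genes, size=10, replace=False)
            zs.append(collectivity_z(expr, genes, n_pseudo=100, seed=rep).z)
        assert abs(float(np.mean(zs))) <= 0.2

    def test_planted_collective_subnet_strongly_negative(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(0, 1, (300, 8))
        profile = rng.normal(size=8) * 5
        for i in range(15):  # genes 0..14 share one profile, 1% relative noise
            vals[i] = rng.uniform(0.5, 1.5) * profile + rng.normal(0, 0.05, 8)
        expr = ExpressionMatrix(
            pd.DataFrame(vals, index=[f"g{i}" for i in range(300)], columns=[f"t{k}" for k in range(8)])
        )
        res = collectivity_z(expr, [f"g{i}" for i in range(15)], n_pseudo=200, seed=5)
        assert res.z <= -3.0

    def test_fewer_than_three_measured_genes_rejected(self):
        expr = self._noise_expr()
        with pytest.raises(ValueError, match="genes measured"):
            collectivity_z(expr, ["g0", "g1"], n_pseudo=50, seed=0)

    def test_seed_determinism_and_size_matching(self):
        expr = self._noise_expr()
        a = collectivity_z(expr, ["g0", "g1", "g2", "g3"], n_pseudo=100, seed=6)
        b = collectivity_z(expr, ["g0", "g1", "g2", "g3"], n_pseudo=100, seed=6)
        assert a.z == b.z and a.n_genes_measured == 4


class TestCalibrateCutoff:
    def test_constructed_band(self):
        # 25% of rows have min z > −2; the rest have some z < −4
        rng = np.random.default_rng(0)
        rows = []
        for i in range(40):
            if i < 10:
                rows.append(rng.uniform(-1.9, 1.0, 6))
            else:
                r = rng.uniform(-1.0, 1.0, 6)
                r[0] = rng.uniform(-6.0, -4.1)
                rows.append(r)
        Z = pd.DataFrame(rows)
        c = calibrate_cutoff(Z, 0.25)
        # ties break toward the conservative end, so the cutoff sits at the
        # low edge of the zero-error band and never above −1.9
        assert -6.0 <= c <= -1.9
        realized = float((Z.min(axis=1) > c).mean())
        assert realized == pytest.approx(0.25)

    def test_monotone_in_target(self):
        rng = np.random.default_rng(1)
        Z = pd.DataFrame(rng.normal(size=(30, 5)))
        cuts = [calibrate_cutoff(Z, t) for t in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert all(a >= b for a, b in zip(cuts, cuts[1:]))

    def test_target_one_returns_minus_inf_sentinel(self):
        Z = pd.DataFrame(np.zeros((4, 3)))
        assert calibrate_cutoff(Z, 1.0) == -math.inf

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            calibrate_cutoff(pd.DataFrame(), 0.25)


class TestBuildTimecourseUsage:
    def test_planted_recovery(self, flat_trn):
        spec, net, subnets = flat_trn
        rng = np.random.default_rng(5)
        eligible = [s.root for s in subnets if 10 <= s.size <= 60]
        experiments, planted = [], []
        for e in range(4):
            roots = list(rng.choice(eligible, size=4, replace=False))
            expr, _ = generate_timecourse_experiment(net, roots, spec, seed=50 + e)
            experiments.append(expr)
            planted.append(set(roots))
        res = build_timecourse_usage(experiments, subnets, n_pseudo=200, seed=9, cutoff=-3.0)
        tp = fn = fp = tn = 0
        for j, pl in enumerate(planted):
            col = res.usage.iloc[:, j]
            for root in res.usage.index:
                used = col[root] == 1
                if root in pl:
                    tp += used
                    fn += not used
                else:
                    fp += used
                    tn += not used
        assert tp / (tp + fn) >= 0.9
        assert tn / (tn + fp) >= 0.95

    def test_calibrated_null_fraction_near_target(self, flat_trn):
        spec, net, subnets = flat_trn
        noise = [
            generate_timecourse_experiment(net, [], spec, seed=200 + e)[0] for e in range(4)
        ]
        res = build_timecourse_usage(noise, subnets, n_pseudo=150, seed=9, target_null_fraction=0.25)
        realized = float((~(res.z_matrix <= res.cutoff)).all(axis=1).mean())
        assert abs(realized - 0.25) <= 0.05

    def test_no_experiments_gives_empty_matrix(self, flat_trn):
        _, net, subnets = flat_trn
        res = build_timecourse_usage([], subnets, n_pseudo=10, seed=0, cutoff=-3.0)
        assert res.usage.shape == (len(subnets), 0)

    def test_deterministic_under_seed(self, flat_trn):
        spec, net, subnets = flat_trn
        expr, _ = generate_timecourse_experiment(net, [subnets[0].root], spec, seed=77)
        a = build_timecourse_usage([expr], subnets[:10], n_pseudo=50, seed=3, cutoff=-3.0)
        b = build_timecourse_usage([expr], subnets[:10], n_pseudo=50, seed=3, cutoff=-3.0)
        assert a.z_matrix.equals(b.z_matrix)
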