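"""Contact-matrix balancing, O/E, distance-matched nulls, ABC scores."""

import numpy as np
import pytest
from scipy import stats

from semap import hic_targets, synthetic_data
from semap.core_io import ContactMatrix, ValidationError
from semap.enhancer_se import SuperEnhancer
from semap.hic_targets import (
    abc_scores,
    classify_targets,
    distance_matched_null,
    expected_by_distance,
    kr_balance,
    se_gene_oe,
)


def cm(matrix, binsize=10, chrom="chrT"):
    matrix = np.asarray(matrix, dtype=float)
    return ContactMatrix(chrom=chrom, binsize=binsize, matrix=matrix,
                         bin_starts=np.arange(matrix.shape[0]) * binsize)


def sinkhorn_oracle(A, iters=50_000, tol=1e-10):
    """Independent symmetric scaling: alternate x <- sqrt(x / (A x))."""
    x = np.ones(A.shape[0])
    for _ in range(iters):
        v = x * (A @ x)
        if np.abs(v - 1).max() < tol:
            break
        x = np.sqrt(x / (A @ x))
    return x


class TestKrBalance:
    def test_two_by_two_antidiagonal(self):
        out = kr_balance(cm([[0, 2], [2, 0]]))
        np.testing.assert_allclose(out.matrix, [[0, 1], [1, 0]], atol=1e-9)
        np.testing.assert_allclose(out.balancing, [2**-0.5, 2**-0.5], atol=1e-6)

    def test_constant_matrix(self):
        out = kr_balance(cm([[1, 1], [1, 1]]))
        np.testing.assert_allclose(out.matrix, [[0.5, 0.5], [0.5, 0.5]], atol=1e-9)

    def test_random_matrix_rows_sum_to_one_and_matches_oracle(self):
        rng = np.random.default_rng(0)
        A = rng.uniform(0.1, 5.0, size=(50, 50))
        A = (A + A.T) / 2
        out = kr_balance(cm(A))
        row_sums = out.matrix.sum(axis=1)
        assert np.abs(row_sums - 1).max() < 1e-6
        x = sinkhorn_oracle(A)
        oracle = A * np.outer(x, x)
        np.testing.assert_allclose(out.matrix, oracle, atol=1e-4)

    def test_zeros_preserved_and_masked_bins(self):
        A = np.array([[2.0, 1, 0, 0], [1, 0, 3, 0], [0, 3, 1, 0], [0, 0, 0, 0]])
        out = kr_balance(cm(A))
        assert out.mask.tolist() == [False, False, False, True]
        assert (out.matrix[A == 0] == 0).all()
        keep = ~out.mask
        assert np.abs(out.matrix[keep].sum(axis=1) - 1).max() < 1e-6

    def test_fully_zero_matrix_rejected(self):
        with pytest.raises(ValidationError):
            kr_balance(cm(np.zeros((3, 3))))

    def test_simulated_zero_scale_rejected(self):
        contacts, _ = synthetic_data.simulate_contacts(n_bins=20, scale=0.0, seed=0)
        with pytest.raises(ValidationError):
            kr_balance(contacts)


class TestExpectedByDistance:
    def test_exact_distance_function_recovered(self):
        n = 20
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).astype(float)
        A = 1.0 / (1.0 + d)
        out = kr_balance(cm(A))
        exp = expected_by_distance(out)
        # balanced matrix is still a function of |i-j| up to edge effects of
        # balancing; expected(d) must equal the stratum mean exactly
        for dist in range(n):
            i = np.arange(n - dist)
            np.testing.assert_allclose(exp[dist],
                                       out.matrix[i, i + dist].mean(), atol=1e-12)

    def test_single_offdiagonal_stratum_mean(self):
        A = np.zeros((6, 6))
        A[0, 3] = A[3, 0] = 4.0
        A += np.eye(6) * 1.0  # keep rows balanceable
        m = cm(A)
        balanced = kr_balance(m)
        exp = expected_by_distance(balanced)
        i = np.arange(3)
        np.testing.assert_allclose(exp[3], balanced.matrix[i, i + 3].mean())

    def test_unbalanced_matrix_rejected(self):
        with pytest.raises(ValidationError):
            expected_by_distance(cm(np.eye(4)))

    def test_global_oe_mean_is_one(self):
        contacts, _ = synthetic_data.simulate_contacts(n_bins=80, seed=3)
        m = kr_balance(contacts)
        exp = expected_by_distance(m)
        keep = ~m.mask
        vals = []
        for d in range(m.n_bins):
            i = np.arange(m.n_bins - d)
            j = i + d
            ok = keep[i] & keep[j]
            if ok.any() and np.isfinite(exp[d]) and exp[d] > 0:
                vals.extend((m.matrix[i[ok], j[ok]] / exp[d]).tolist())
        assert np.mean(vals) == pytest.approx(1.0, abs=1e-9)

    def test_simulated_decay_follows_power_law(self):
        contacts, _ = synthetic_data.simulate_contacts(
            n_bins=200, decay_exponent=1.0, scale=500.0, seed=5)
        m = kr_balance(contacts)
        exp = expected_by_distance(m)
        d = np.arange(5, 60)
        slope, *_ = stats.linregress(np.log(d), np.log(exp[d]))
        assert slope == pytest.approx(-1.0, abs=0.15)


class TestSeGeneOe:
    def test_null_matrix_oe_near_one(self):
        oes = []
        for seed in range(30):
            contacts, _ = synthetic_data.simulate_contacts(
                n_bins=100, scale=500.0, seed=seed)
            m = kr_balance(contacts)
            exp = expected_by_distance(m)
            oes.append(se_gene_oe(m, exp, 10 * 50_000, 11 * 50_000,
                                  60 * 50_000 + 100))
        assert np.mean(oes) == pytest.approx(1.0, abs=0.1)

    def test_planted_loop_enrichment_recovered(self):
        """Monte-Carlo: O/E at a planted 5x loop averages ~5."""
        oes = []
        for seed in range(100):
            contacts, _ = synthetic_data.simulate_contacts(
                n_bins=100, scale=500.0, loops=[(10, 60, 5.0)], seed=seed)
            m = kr_balance(contacts)
            exp = expected_by_distance(m)
            oes.append(se_gene_oe(m, exp, 10 * 50_000, 11 * 50_000,
                                  60 * 50_000 + 100))
        assert np.mean(oes) == pytest.approx(5.0, rel=0.1)

    def test_self_bin_uses_d0_stratum(self):
        contacts, _ = synthetic_data.simulate_contacts(n_bins=30, seed=1)
        m = kr_balance(contacts)
        exp = expected_by_distance(m)
        oe = se_gene_oe(m, exp, 5 * 50_000, 6 * 50_000, 5 * 50_000 + 100)
        assert np.isfinite(oe)


class TestDistanceMatchedNull:
    def _setup(self, seed=0):
        contacts, _ = synthetic_data.simulate_contacts(n_bins=150, seed=seed)
        m = kr_balance(contacts)
        exp = expected_by_distance(m)
        return m, exp

    def test_self_matching_reproduces_targets(self):
        m, exp = self._setup()
        targets = {f"g{i}": (20 + 7 * i) * 50_000 + 100 for i in range(5)}
        control = distance_matched_null(m, exp, 10 * 50_000, 11 * 50_000,
                                        targets, dict(targets), n_perm=1,
                                        k_near=1, seed=0)
        direct = sorted(se_gene_oe(m, exp, 10 * 50_000, 11 * 50_000, t)
                        for t in targets.values())
        np.testing.assert_allclose(sorted(control), direct)

    def test_pool_smaller_than_targets_rejected(self):
        m, exp = self._setup()
        targets = {f"g{i}": (30 + i) * 50_000 for i in range(4)}
        pool = {"p0": 90 * 50_000}
        with pytest.raises(ValidationError):
            distance_matched_null(m, exp, 0, 50_000, targets, pool)

    def test_deterministic_under_seed(self):
        m, exp = self._setup()
        targets = {f"g{i}": (20 + 9 * i) * 50_000 for i in range(4)}
        pool = {f"p{i}": (15 + 4 * i) * 50_000 for i in range(20)}
        a = distance_matched_null(m, exp, 0, 50_000, targets, pool, seed=5)
        b = distance_matched_null(m, exp, 0, 50_000, targets, pool, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_null_control_matches_target_distribution(self):
        """On a loop-free matrix, targets and distance-matched controls are
        statistically indistinguishable.  A generous pool with a wide
        matching neighbourhood keeps control draws from repeating the same
        few genes, which would overdisperse the two-sample comparison."""
        ks_ps = []
        for seed in range(50):
            contacts, _ = synthetic_data.simulate_contacts(
                n_bins=250, scale=500.0, seed=seed)
            m = kr_balance(contacts)
            exp = expected_by_distance(m)
            rng = np.random.default_rng(seed)
            bins = rng.choice(range(10, 250), size=160, replace=False)
            targets = {f"g{i}": int(b) * 50_000 + 100
                       for i, b in enumerate(bins[:10])}
            pool = {f"p{i}": int(b) * 50_000 + 100
                    for i, b in enumerate(bins[10:])}
            t_oe = [se_gene_oe(m, exp, 0, 50_000, t) for t in targets.values()]
            control = distance_matched_null(m, exp, 0, 50_000, targets, pool,
                                            n_perm=10, k_near=20, seed=seed)
            ks_ps.append(stats.ks_2samp(t_oe, control).pvalue)
        assert np.mean(np.asarray(ks_ps) > 0.05) >= 0.9


class TestClassifyTargets:
    def test_percentile_convention(self):
        control = np.array([1.0, 2.0, 3.0, 4.0])
        calls = classify_targets({"hi": 5.0, "lo": 2.0}, control, "SE1",
                                 {"hi": 1000, "lo": 2000})
        by_gene = {c.gene: c.classification for c in calls}
        assert by_gene == {"hi": "direct", "lo": "indirect"}
        # threshold is 3.25 by linear interpolation: 3.3 is direct, 3.25 not
        calls = classify_targets({"edge": 3.25, "above": 3.3}, control, "SE1", {})
        by_gene = {c.gene: c.classification for c in calls}
        assert by_gene == {"edge": "indirect", "above": "direct"}

    def test_null_direct_rate_quarter(self):
        """Targets drawn from the control distribution go direct ~25 % of the
        time at the default 75th percentile."""
        rng = np.random.default_rng(2)
        control = rng.lognormal(0, 0.5, size=4000)
        targets = {f"g{i}": float(v) for i, v in
                   enumerate(rng.lognormal(0, 0.5, size=2000))}
        calls = classify_targets(targets, control, "SE1", {})
        rate = np.mean([c.classification == "direct" for c in calls])
        se = np.sqrt(0.25 * 0.75 / 2000)
        assert abs(rate - 0.25) < 3 * se + 0.01


class TestRunTargetAnalysis:
    def test_planted_loops_called_direct(self):
        hits = []
        null_rates = []
        binsize = 50_000
        for seed in range(20):
            rng = np.random.default_rng(seed + 1000)
            se_bin = 30
            gene_bins = rng.choice(
                [b for b in range(300) if abs(b - se_bin) >= 3], size=120,
                replace=False)
            de_genes = [f"g{i}" for i in range(20)]
            genes = de_genes + [f"p{i}" for i in range(100)]
            tss = {g: int(gene_bins[i]) * binsize + 25_000
                   for i, g in enumerate(genes)}
            loop_genes = de_genes[:5]
            loops = [(se_bin, int(tss[g] // binsize), 5.0) for g in loop_genes]
            contacts, _ = synthetic_data.simulate_contacts(
                loops=loops, seed=seed)
            m = kr_balance(contacts)
            de = synthetic_data.simulate_de_table(
                genes, {g: -1.5 for g in de_genes}, seed=seed)
            calls = hic_targets.run_target_analysis(
                m, se_bin * binsize, (se_bin + 1) * binsize, "SE1", de, tss,
                seed=seed)
            direct = {c.gene for c in calls if c.classification == "direct"}
            hits.append(all(g in direct for g in loop_genes))
            nonloop = [c for c in calls if c.gene not in loop_genes]
            null_rates.append(np.mean([c.classification == "direct"
                                       for c in nonloop]))
        assert np.mean(hits) >= 0.9
        # non-loop DE genes are exchangeable with the pool: ~25 % direct
        assert abs(np.mean(null_rates) - 0.25) < 0.08

    def test_empty_de_table_empty_output(self):
        contacts, _ = synthetic_data.simulate_contacts(n_bins=50, seed=0)
        m = kr_balance(contacts)
        de = synthetic_data.simulate_de_table(["g0", "g1"], {}, seed=0)
        out = hic_targets.run_target_analysis(m, 0, 50_000, "SE1", de,
                                              {"g0": 10 * 50_000,
                                               "g1": 20 * 50_000})
        assert out == []

    def test_all_trans_genes_empty_output(self):
        contacts, _ = synthetic_data.simulate_contacts(n_bins=50, seed=0)
        m = kr_balance(contacts)
        de = synthetic_data.simulate_de_table(["g0"], {"g0": -1.0}, seed=0)
        out = hic_targets.run_target_analysis(m, 0, 50_000, "SE1", de, {})
        assert out == []

    def test_lfc_filter_restricts_target_set(self):
        contacts, _ = synthetic_data.simulate_contacts(n_bins=100, seed=4)
        m = kr_balance(contacts)
        genes = [f"g{i}" for i in range(10)] + [f"p{i}" for i in range(40)]
        tss = {g: (20 + 2 * i) * 50_000 for i, g in enumerate(genes)}
        planted = {f"g{i}": (-1.0 if i < 5 else -0.2) for i in range(10)}
        de = synthetic_data.simulate_de_table(genes, planted, lfc_noise_sd=0.0,
                                              seed=1)
        all_t = hic_targets.run_target_analysis(m, 0, 50_000, "SE", de, tss,
                                                seed=0)
        down_t = hic_targets.run_target_analysis(m, 0, 50_000, "SE", de, tss,
                                                 lfc_max=-0.5, seed=0)
        assert {c.gene for c in all_t} == {f"g{i}" for i in range(10)}
        assert {c.gene for c in down_t} == {f"g{i}" for i in range(5)}


class TestAbcScores:
    def _ses(self):
        b = 50_000
        return [
            SuperEnhancer("SE1", "chrS", 40 * b + 10_000, 40 * b + 30_000, [],
                          900.0, 1),
            SuperEnhancer("SE2", "chrS", 200 * b + 10_000, 200 * b + 30_000, [],
                          300.0, 2),
        ]

    def test_standardization_exact(self):
        contacts, _ = synthetic_data.simulate_contacts(seed=0)
        m = kr_balance(contacts)
        genes = {f"g{i}": (100 + 3 * i) * 50_000 for i in range(10)}
        recs = abc_scores(self._ses(), genes, m)
        a = np.log2(np.array([r.activity for r in recs]) + 1)
        c = np.log2(np.array([r.contact for r in recs]) + 1)
        a_std = (a - a.mean()) / a.std()
        c_std = (c - c.mean()) / c.std()
        by_pair = {(r.se_id, r.gene): r.score for r in recs}
        for i, r in enumerate(recs):
            assert by_pair[(r.se_id, r.gene)] == pytest.approx(
                a_std[i] * c_std[i])

    def test_identical_pairs_identical_scores(self):
        # Toeplitz (distance-only) matrix is reflection-symmetric, so after
        # balancing the two genes equidistant from the SE1 bin have exactly
        # equal contact, hence exactly equal ABC scores
        n, b = 5, 50_000
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        A = 10.0 / (1.0 + d)
        m = kr_balance(cm(A, binsize=b, chrom="chrS"))
        ses = [
            SuperEnhancer("SE1", "chrS", 2 * b + 1000, 2 * b + 2000, [], 900.0, 1),
            SuperEnhancer("SE2", "chrS", 0 * b + 1000, 0 * b + 2000, [], 300.0, 2),
        ]
        genes = {"gl": 1 * b + 100, "gr": 3 * b + 100}
        recs = abc_scores(ses, genes, m)
        s = {(r.se_id, r.gene): r.score for r in recs}
        assert s[("SE1", "gl")] == pytest.approx(s[("SE1", "gr")], abs=1e-9)

    def test_too_few_pairs_rejected(self):
        contacts, _ = synthetic_data.simulate_contacts(n_bins=50, seed=0)
        m = kr_balance(contacts)
        with pytest.raises(ValidationError):
            abc_scores([self._ses()[0]], {"g": 10 * 50_000}, m)

    def test_planted_loop_gene_ranks_first(self):
        wins = 0
        binsize = 50_000
        for seed in range(20):
            rng = np.random.default_rng(seed)
            ses = self._ses()
            cand = [b for b in range(300)
                    if 60 <= abs(b - 40) <= 120 and abs(b - 200) >= 20]
            gene_bins = rng.choice(cand, size=20, replace=False)
            genes = {f"g{i}": int(b) * binsize + 25_000
                     for i, b in enumerate(gene_bins)}
            loops = [(40, int(genes["g0"] // binsize), 8.0)]
            contacts, _ = synthetic_data.simulate_contacts(loops=loops,
                                                           seed=seed)
            m = kr_balance(contacts)
            recs = [r for r in abc_scores(ses, genes, m) if r.se_id == "SE1"]
            wins += recs[0].gene == "g0"
        assert wins >= 18  # >= 90 % of seeds
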