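"""Scan F-tests, permutation thresholds, stepwise selection, Gibbs estimation
and heritability partitioning."""

import numpy as np
import pytest
from scipy import stats

import rilqts
from rilqts import mapping

from conftest import ENVS, make_genotypes, make_phenotypes, random_ril_codes


def _bundle(codes, values_by_env):
    g = make_genotypes(codes)
    p = make_phenotypes(values_by_env)
    return rilqts.validate_dataset(g, p)


def _additive_bundle(n=120, m=4, a=(1.5,), noise=1.0, seed=0, env_shift=3.0, ae=None):
    rng = np.random.default_rng(seed)
    codes = random_ril_codes(rng, n, m)
    base = sum(ai * codes[:, i] for i, ai in enumerate(a))
    vals = {}
    for k, env in enumerate(ENVS):
        y = base + env_shift * (1 - 2 * k)
        if ae is not None:
            y = y + ae * codes[:, 0] * (1 - 2 * k)
        vals[env] = y + noise * rng.normal(size=n)
    return _bundle(codes, vals)


class TestSingleLocusScan:
    def test_noiseless_causal_marker_saturates(self):
        b = _additive_bundle(a=(2.0,), noise=0.0)
        res = {r.term: r for r in rilqts.scan_single_locus(b, "y", ["m1", "m2"])}
        assert np.isinf(res["m1"].F_statistic)
        assert res["m1"].neg_log10_p == mapping.MAX_NEG_LOG10_P
        assert res["m1"].effect == pytest.approx(2.0, abs=1e-9)

    def test_parent_swap_negates_effect_not_f(self):
        b = _additive_bundle(seed=1)
        swapped = rilqts.DatasetBundle(
            genotypes=rilqts.GenotypeMatrix(
                b.genotypes.line_ids, b.genotypes.map, -b.genotypes.codes
            ),
            phenotypes=b.phenotypes,
        )
        r1 = rilqts.scan_single_locus(b, "y", ["m1"])[0]
        r2 = rilqts.scan_single_locus(swapped, "y", ["m1"])[0]
        assert r2.effect == pytest.approx(-r1.effect)
        assert r2.F_statistic == pytest.approx(r1.F_statistic)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_f_matches_brute_force_least_squares(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        codes = random_ril_codes(rng, n, 2)
        while np.all(codes[:, 0] == codes[0, 0]):
            codes = random_ril_codes(rng, n, 2)
        vals = {e: rng.normal(size=n) for e in ENVS}
        b = _bundle(codes, vals)
        res = rilqts.scan_single_locus(b, "y", ["m1"])[0]
        # independent fit of both nested models by generic least squares
        y = np.concatenate([vals["E1"], vals["E2"]])
        z = np.concatenate([np.ones(n), -np.ones(n)])
        x = np.tile(codes[:, 0], 2)
        D0 = np.column_stack([np.ones(2 * n), z])
        D1 = np.column_stack([D0, x, x * z])
        rss = []
        for D in (D0, D1):
            beta, *_ = np.linalg.lstsq(D, y, rcond=None)
            rss.append(float(((y - D @ beta) ** 2).sum()))
        F = ((rss[0] - rss[1]) / 2) / (rss[1] / (2 * n - 4))
        assert res.F_statistic == pytest.approx(F, rel=1e-8)

    def test_monomorphic_marker_skipped(self):
        codes = np.ones((10, 2))
        codes[:, 1] = np.random.default_rng(3).choice([-1.0, 1.0], 10)
        rng = np.random.default_rng(4)
        b = _bundle(codes, {e: rng.normal(size=10) for e in ENVS})
        res = rilqts.scan_single_locus(b, "y", ["m1", "m2"])
        assert [r.term for r in res] == ["m2"]

    def test_invariant_to_line_and_marker_order(self):
        b = _additive_bundle(seed=5)
        res = {r.term: r.F_statistic for r in rilqts.scan_single_locus(b, "y", ["m1", "m3"])}
        # permuted line order in the phenotype table, reversed candidates
        recs = b.phenotypes.records.sample(frac=1.0, random_state=0)
        b2 = rilqts.validate_dataset(
            b.genotypes, rilqts.PhenotypeTable(recs, b.phenotypes.environments)
        )
        res2 = {r.term: r.F_statistic for r in rilqts.scan_single_locus(b2, "y", ["m3", "m1"])}
        for t in res:
            assert res2[t] == pytest.approx(res[t], rel=1e-10)


class TestEpistasisScan:
    def test_noiseless_pure_epistasis_exact(self):
        rng = np.random.default_rng(6)
        codes = random_ril_codes(rng, 100, 2)
        prod = codes[:, 0] * codes[:, 1]
        b = _bundle(codes, {e: 0.8 * prod for e in ENVS})
        res = rilqts.scan_epistasis(b, "y", [("m1", "m2")])[0]
        assert res.effect == pytest.approx(0.8, abs=1e-9)
        assert np.isinf(res.F_statistic)

    def test_identical_markers_skipped_as_collinear(self):
        rng = np.random.default_rng(7)
        col = rng.choice([-1.0, 1.0], 30)
        codes = np.column_stack([col, col])
        b = _bundle(codes, {e: rng.normal(size=30) for e in ENVS})
        assert rilqts.scan_epistasis(b, "y", [("m1", "m2")]) == []

    def test_null_pair_p_values_uniform(self):
        # additive-only data: nominal epistasis p over replicates is U(0,1)
        pvals = []
        for rep in range(300):
            rng = np.random.default_rng(100 + rep)
            codes = random_ril_codes(rng, 60, 2)
            vals = {
                e: 1.0 * codes[:, 0] - 0.7 * codes[:, 1] + rng.normal(size=60) for e in ENVS
            }
            b = _bundle(codes, vals)
            res = rilqts.scan_epistasis(b, "y", [("m1", "m2")])
            if res:
                pvals.append(10 ** (-res[0].neg_log10_p))
        assert stats.kstest(pvals, "uniform").pvalue > 0.005


class TestPermutationThreshold:
    def test_deterministic_under_seed(self):
        b = _additive_bundle(seed=8)
        kw = dict(n_permutations=120, seed=42)
        t1 = rilqts.permutation_threshold(b, "y", ["m1", "m2", "m3"], **kw)
        t2 = rilqts.permutation_threshold(b, "y", ["m1", "m2", "m3"], **kw)
        assert t1.threshold == t2.threshold
        np.testing.assert_array_equal(t1.max_stats, t2.max_stats)

    def test_alpha_one_gives_minimum_max_stat(self):
        b = _additive_bundle(seed=9)
        t = rilqts.permutation_threshold(b, "y", ["m1", "m2"], alpha=1.0, n_permutations=100, seed=1)
        assert t.threshold == t.max_stats.min()

    def test_threshold_monotone_in_alpha(self):
        b = _additive_bundle(seed=10)
        lo = rilqts.permutation_threshold(b, "y", ["m1"], alpha=0.2, n_permutations=200, seed=2)
        hi = rilqts.permutation_threshold(b, "y", ["m1"], alpha=0.01, n_permutations=200, seed=2)
        assert hi.threshold >= lo.threshold


class TestStepwise:
    def _setup(self, b, candidates, n_perm=150, seed=0, pairs=None):
        thr = rilqts.permutation_threshold(b, "y", candidates, n_permutations=n_perm, seed=seed)
        scan1 = rilqts.scan_single_locus(b, "y", candidates)
        scan2 = rilqts.scan_epistasis(b, "y", pairs) if pairs else None
        return thr, scan1, scan2

    def test_pure_noise_selects_nothing(self):
        rng = np.random.default_rng(11)
        codes = random_ril_codes(rng, 100, 5)
        b = _bundle(codes, {e: rng.normal(size=100) for e in ENVS})
        thr, scan1, _ = self._setup(b, [f"m{i + 1}" for i in range(5)])
        assert rilqts.stepwise_select(b, "y", scan1, None, thr) == []

    def test_duplicated_marker_enters_once(self):
        rng = np.random.default_rng(12)
        col = rng.choice([-1.0, 1.0], 120)
        codes = np.column_stack([col, col, random_ril_codes(rng, 120, 1)])
        vals = {e: 2.0 * col + rng.normal(size=120) for e in ENVS}
        b = _bundle(codes, vals)
        thr, scan1, _ = self._setup(b, ["m1", "m2", "m3"])
        sel = rilqts.stepwise_select(b, "y", scan1, None, thr)
        assert len([t for t in sel if t in ("m1", "m2")]) == 1

    def test_two_planted_qts_power(self):
        # h2 ~ 15% and 10% unlinked loci at n = 138 both selected in >= 80/100
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng(500 + rep)
            codes = random_ril_codes(rng, 138, 10)
            # total variance 1: a1^2 = .15, a2^2 = .10
            y0 = np.sqrt(0.15) * codes[:, 2] + np.sqrt(0.10) * codes[:, 7]
            vals = {e: y0 + np.sqrt(0.75) * rng.normal(size=138) for e in ENVS}
            b = _bundle(codes, vals)
            cands = [f"m{i + 1}" for i in range(10)]
            thr, scan1, _ = self._setup(b, cands, n_perm=150, seed=rep)
            sel = rilqts.stepwise_select(b, "y", scan1, None, thr)
            hits += ("m3" in sel) and ("m8" in sel)
        assert hits >= 80


class TestGibbsEstimation:
    def test_noiseless_recovery_is_exact(self):
        rng = np.random.default_rng(13)
        codes = random_ril_codes(rng, 80, 2)
        mu, a = 20.0, -1.54
        vals = {e: mu + a * codes[:, 0] for e in ENVS}
        b = _bundle(codes, vals)
        model = rilqts.estimate_effects_mcmc(b, "y", ["m1"], n_iter=4000, burn_in=1000, seed=3)
        est = model.terms[0]
        assert est.effect == pytest.approx(a, abs=1e-6)
        assert model.mu_hat == pytest.approx(mu, abs=1e-6)

    def test_posterior_agrees_with_least_squares_at_large_n(self):
        b = _additive_bundle(n=3000, m=3, a=(1.2, -0.8), noise=1.0, seed=14, ae=0.4)
        model = rilqts.estimate_effects_mcmc(
            b, "y", ["m1", "m2"], n_iter=4000, burn_in=1000, seed=4
        )
        # independent estimate: ordinary least squares on the full design
        g, Y = mapping._scan_data(b, "y")
        n = len(Y)
        y = np.concatenate([Y[:, 0], Y[:, 1]])
        z = np.concatenate([np.ones(n), -np.ones(n)])
        x1, x2 = np.tile(g.column("m1"), 2), np.tile(g.column("m2"), 2)
        D = np.column_stack([np.ones(2 * n), z, x1, x2, x1 * z, x2 * z])
        beta, *_ = np.linalg.lstsq(D, y, rcond=None)
        ests = {t.term: t for t in model.terms}
        assert ests["m1"].effect == pytest.approx(beta[2], abs=0.02)
        assert ests["m2"].effect == pytest.approx(beta[3], abs=0.02)
        # ae deviation of m1 in E1 corresponds to the x1*z coefficient
        assert ests["m1"].env_dev["E1"] == pytest.approx(beta[4], abs=0.03)
        assert model.converged

    def test_same_seed_identical_chains(self):
        b = _additive_bundle(seed=15)
        m1 = rilqts.estimate_effects_mcmc(b, "y", ["m1"], n_iter=1500, burn_in=300, seed=5)
        m2 = rilqts.estimate_effects_mcmc(b, "y", ["m1"], n_iter=1500, burn_in=300, seed=5)
        assert m1.terms[0].effect == m2.terms[0].effect
        assert m1.terms[0].se == m2.terms[0].se
        assert m1.residual_variance == m2.residual_variance

    def test_detects_planted_environment_interaction(self):
        b = _additive_bundle(n=300, a=(1.5,), ae=0.8, noise=1.0, seed=16)
        model = rilqts.estimate_effects_mcmc(b, "y", ["m1"], n_iter=3000, burn_in=500, seed=6)
        est = model.terms[0]
        assert "ae" in est.components
        assert est.env_dev["E1"] == pytest.approx(0.8, abs=0.15)
        assert est.env_dev["E1"] == pytest.approx(-est.env_dev["E2"])


class TestHeritability:
    def test_published_gyd_partition_reproduced(self, gyd_preset):
        # effects + the calibrated V_P reproduce every printed component and
        # their printed sum
        printed = {
            "rs8203251": 10.91,
            "rs26662491": 5.02,
            "rs5137246": 6.56,
            "rs26302731": 9.34,
            "rs12354751": 4.01,
            "rs17926420": 5.31,
        }
        for l in gyd_preset.loci:
            assert rilqts.additive_h2(l.a, 1.0, gyd_preset.V_P) == pytest.approx(
                printed[l.qts], abs=0.07
            )
        total = sum(rilqts.additive_h2(l.a, 1.0, gyd_preset.V_P) for l in gyd_preset.loci)
        total += rilqts.interaction_h2((-0.65, 0.64), 1.0, gyd_preset.V_P)
        assert total == pytest.approx(43.06, abs=1e-9)

    def test_published_point_values(self):
        assert rilqts.additive_h2(-1.54, 1.0, 21.74) == pytest.approx(10.91, abs=0.01)
        assert rilqts.interaction_h2((-0.65, 0.64), 1.0, 21.74) == pytest.approx(1.91, abs=0.01)

    def test_zero_effect_zero_h2(self):
        assert rilqts.additive_h2(0.0, 1.0, 5.0) == 0.0
        assert rilqts.interaction_h2((0.0, 0.0), 1.0, 5.0) == 0.0

    def test_invalid_vp_rejected(self):
        with pytest.raises(ValueError):
            rilqts.additive_h2(1.0, 1.0, 0.0)

    def test_model_total_is_sum_of_components(self):
        b = _additive_bundle(n=300, a=(1.5, -1.0), ae=0.6, noise=1.0, seed=17)
        model = rilqts.estimate_effects_mcmc(
            b, "y", ["m1", "m2"], n_iter=2000, burn_in=400, seed=7
        )
        acc = sum(v for t in model.terms for v in t.h2.values())
        assert model.h2_total == pytest.approx(acc, abs=1e-6)
        assert all(v >= 0 for t in model.terms for v in t.h2.values())
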