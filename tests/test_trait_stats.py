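"""Summaries, correlations, genotypic-value shrinkage and conditioning."""

import numpy as np
import pandas as pd
import pytest

import rilqts

from conftest import ENVS, make_phenotypes


def _sample_with(mean, sd, n=2):
    """Two values with exact mean and sample SD (n-1 denominator)."""
    assert n == 2
    half = sd / np.sqrt(2.0)
    return [mean + half, mean - half]


class TestSummaries:
    def test_cv_matches_published_gyd_value(self):
        p = make_phenotypes(
            {"E1": _sample_with(22.86, 6.10), "E2": _sample_with(17.69, 3.47)}, trait="GYD"
        )
        row = rilqts.summarize_traits(p).iloc[0]
        assert row["mean"] == pytest.approx(22.86, abs=1e-9)
        assert row["sd"] == pytest.approx(6.10, abs=1e-9)
        assert round(row["cv_pct"], 2) == 26.68

    def test_environment_difference_d(self):
        p = make_phenotypes(
            {"E1": _sample_with(22.86, 6.10), "E2": _sample_with(17.69, 3.47)}, trait="GYD"
        )
        assert rilqts.summarize_traits(p).iloc[0]["D"] == pytest.approx(5.17, abs=1e-9)

    def test_identical_environments_not_significant(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        p = make_phenotypes({"E1": vals, "E2": vals})
        row = rilqts.summarize_traits(p).iloc[0]
        assert row["D"] == 0.0
        assert row["significance"] == ""

    def test_large_shift_flagged(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, 100)
        p = make_phenotypes({"E1": base, "E2": base + 5.0})
        assert rilqts.summarize_traits(p).iloc[0]["significance"] == "**"


class TestPhenotypicCorrelations:
    def _table(self, y1, y2, env="E1"):
        rows = []
        for trait, vals in (("t1", y1), ("t2", y2)):
            for i, v in enumerate(vals):
                rows.append({"line_id": f"L{i}", "environment": env, "trait": trait, "value": v})
        return rilqts.PhenotypeTable(pd.DataFrame(rows), [env])

    def test_self_correlation_unity(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=20)
        rep = rilqts.phenotypic_correlations(self._table(y, y.copy()))
        r, _ = rep.phenotypic["E1"]
        assert r.loc["t1", "t1"] == 1.0
        assert r.loc["t1", "t2"] == pytest.approx(1.0)

    def test_negated_trait_gives_minus_one(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=20)
        rep = rilqts.phenotypic_correlations(self._table(y, -y))
        r, _ = rep.phenotypic["E1"]
        assert r.loc["t1", "t2"] == pytest.approx(-1.0)

    def test_bivariate_normal_estimate_and_significance(self):
        # rho = 0.6 at n = 138: Fisher-z 95% half-width ~ 0.11 < 0.15
        rng = np.random.default_rng(3)
        z = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]], size=138)
        rep = rilqts.phenotypic_correlations(self._table(z[:, 0], z[:, 1]))
        r, pv = rep.phenotypic["E1"]
        assert r.loc["t1", "t2"] == pytest.approx(0.6, abs=0.15)
        assert pv.loc["t1", "t2"] < 0.005
        assert rilqts.CorrelationReport.stars(pv.loc["t1", "t2"]) == "***"

    def test_constant_trait_reported_missing(self):
        y = np.arange(10.0)
        rep = rilqts.phenotypic_correlations(self._table(y, np.ones(10)))
        r, _ = rep.phenotypic["E1"]
        assert np.isnan(r.loc["t1", "t2"])


class TestGenotypicValues:
    def test_zero_residual_gives_line_means(self):
        g_k = np.array([1.0, 3.0, -2.0, 0.5])
        p = make_phenotypes({"E1": g_k + 1.0, "E2": g_k - 1.0})
        gv = rilqts.predict_genotypic_values(p)["y"]
        np.testing.assert_allclose(gv.to_numpy(), g_k, atol=1e-10)

    def test_zero_genetic_variance_shrinks_to_grand_mean(self):
        rng = np.random.default_rng(4)
        p = make_phenotypes({"E1": rng.normal(size=200), "E2": rng.normal(size=200)})
        gv = rilqts.predict_genotypic_values(p)["y"]
        line_means = p.wide("y").mean(axis=1)
        assert gv.std() < 0.5 * line_means.std()

    def test_shrinkage_factor_matches_closed_form(self):
        rng = np.random.default_rng(5)
        n, s2g, s2e = 4000, 2.0, 1.0
        g_k = rng.normal(0, np.sqrt(s2g), n)
        p = make_phenotypes(
            {
                "E1": g_k + rng.normal(0, np.sqrt(s2e), n) + 3.0,
                "E2": g_k + rng.normal(0, np.sqrt(s2e), n) - 3.0,
            }
        )
        gv = rilqts.predict_genotypic_values(p)["y"]
        line_means = p.wide("y").mean(axis=1)
        grand = line_means.mean()
        lam_hat = np.polyfit(line_means - grand, gv - grand, 1)[0]
        assert lam_hat == pytest.approx(s2g / (s2g + s2e / 2), abs=0.03)

    def test_single_environment_is_an_error(self):
        rows = [
            {"line_id": f"L{i}", "environment": "E1", "trait": "y", "value": float(i)}
            for i in range(5)
        ]
        p = rilqts.PhenotypeTable(pd.DataFrame(rows), ["E1"])
        with pytest.raises(ValueError, match="raw line means"):
            rilqts.predict_genotypic_values(p)

    def test_genotypic_correlations_of_shared_and_disjoint_bases(self):
        rng = np.random.default_rng(6)
        n = 500
        ga = rng.normal(0, 2, n)
        gb = rng.normal(0, 2, n)
        tables = []
        for trait, gen in (("t1", ga), ("t2", ga), ("t3", gb)):
            tables.append(
                make_phenotypes(
                    {
                        "E1": gen + rng.normal(0, 0.3, n),
                        "E2": gen + rng.normal(0, 0.3, n),
                    },
                    trait=trait,
                )
            )
        p = tables[0].add_trait(tables[1]).add_trait(tables[2])
        gv = rilqts.predict_genotypic_values(p)
        r, _ = rilqts.genotypic_correlations(gv)
        assert r.loc["t1", "t2"] > 0.98  # identical genetic basis
        assert abs(r.loc["t1", "t3"]) < 0.15  # disjoint genetic basis


class TestConditioning:
    def _bivariate(self, n=200, seed=7, slope=1.0):
        rng = np.random.default_rng(seed)
        given = {}
        target = {}
        delta = {}
        for env in ENVS:
            x = rng.normal(2.0, 1.0, n)
            d = rng.normal(0.0, 1.0, n)
            given[env] = x
            delta[env] = d
            target[env] = slope * x + d
        p = make_phenotypes(target, trait="T1").add_trait(make_phenotypes(given, trait="T2"))
        return p, delta

    def test_zero_within_environment_covariance(self):
        p, _ = self._bivariate()
        cond = rilqts.conditional_phenotypes(p, "T1", "T2")
        merged = p.add_trait(cond)
        for env in ENVS:
            sub = merged.records[merged.records["environment"] == env]
            w = sub.pivot(index="line_id", columns="trait", values="value")
            assert abs(np.cov(w["T1|T2"], w["T2"])[0, 1]) < 1e-10

    def test_conditioning_on_self_removes_all_variance(self):
        p, _ = self._bivariate()
        cond = rilqts.conditional_phenotypes(p, "T1", "T1")
        for env in ENVS:
            vals = cond.records.loc[cond.records["environment"] == env, "value"]
            assert vals.std() == pytest.approx(0.0, abs=1e-10)

    def test_independent_given_trait_preserves_target(self):
        rng = np.random.default_rng(8)
        n = 5000
        target = {e: rng.normal(size=n) for e in ENVS}
        given = {e: rng.normal(size=n) for e in ENVS}
        p = make_phenotypes(target, trait="T1").add_trait(make_phenotypes(given, trait="T2"))
        cond = rilqts.conditional_phenotypes(p, "T1", "T2")
        for env in ENVS:
            a = p.wide("T1")[env]
            b = cond.wide("T1|T2")[env]
            assert np.corrcoef(a, b.loc[a.index])[0, 1] > 0.99

    def test_conditional_recovers_independent_component(self):
        p, delta = self._bivariate(n=5000, seed=9)
        cond = rilqts.conditional_phenotypes(p, "T1", "T2")
        ids = [f"L{i + 1}" for i in range(5000)]
        for h, env in enumerate(ENVS):
            w = cond.wide("T1|T2")[env].reindex(ids).to_numpy()
            assert np.corrcoef(w, delta[env])[0, 1] > 0.99

    def test_conditioning_is_idempotent(self):
        p, _ = self._bivariate()
        c1 = rilqts.conditional_phenotypes(p, "T1", "T2")
        renamed = rilqts.PhenotypeTable(
            c1.records.assign(trait="T1c"), c1.environments
        )
        c2 = rilqts.conditional_phenotypes(p.add_trait(renamed), "T1c", "T2")
        np.testing.assert_allclose(
            c1.records["value"].to_numpy(), c2.records["value"].to_numpy(), atol=1e-10
        )

    def test_zero_variance_given_is_an_error(self):
        target = {e: np.arange(5.0) for e in ENVS}
        given = {e: np.ones(5) for e in ENVS}
        p = make_phenotypes(target, trait="T1").add_trait(make_phenotypes(given, trait="T2"))
        with pytest.raises(ValueError, match="zero variance"):
            rilqts.conditional_phenotypes(p, "T1", "T2")

    def test_genotypic_mode_runs_and_decorrelates_gv(self):
        p, _ = self._bivariate(n=300, seed=10)
        cond = rilqts.conditional_phenotypes(p, "T1", "T2", mode="genotypic")
        assert set(cond.records["trait"]) == {"T1|T2"}
        assert len(cond.records) == 600
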