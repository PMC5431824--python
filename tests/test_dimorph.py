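"""Model engines, LRT, BIC selection, omega-squared and the trait pipeline."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dioecy import (ModelSpec, SimConfig, TraitSimConfig, factorial_response_test,
                    fit_lm, fit_lmm, lrt, multi_site_battery, omega_squared,
                    select_model_bic, simulate_population, simulate_traits)
from dioecy.dimorph import test_trait as trait_test
from dioecy.errors import ModelError


def _lm_data(n=100, seed=0, beta_lat=0.0, delta_sex=0.0, sigma=1.0):
    rng = np.random.default_rng(seed)
    lat = rng.uniform(44, 60, n)
    male = rng.random(n) < 0.5
    y = beta_lat * lat + delta_sex * male + rng.normal(0, sigma, n)
    return pd.DataFrame({
        "genotype_id": [f"g{i}" for i in range(n)],
        "sex": np.where(male, "M", "F"), "latitude": lat,
        "trait": "t", "value": y})


class TestLM:
    def test_intercept_only_is_mean(self):
        d = pd.DataFrame({"genotype_id": list("abc"), "value": [1.0, 2, 3]})
        f = fit_lm(d, ModelSpec())
        assert f.params["Intercept"] == pytest.approx(2.0)
        assert f.bic == pytest.approx(-2 * f.log_likelihood + 2 * np.log(3))

    def test_slope_recovery(self):
        d = _lm_data(n=100, seed=1, beta_lat=2.0, sigma=0.1)
        f = fit_lm(d, ModelSpec(fixed_terms=("latitude",)))
        resid_se = 0.1 / np.sqrt(np.sum(
            (d["latitude"] - d["latitude"].mean()) ** 2))
        assert abs(f.params["latitude"] - 2.0) < 3 * resid_se

    def test_duplicated_covariate_named_in_error(self):
        d = _lm_data(n=30, seed=2)
        d["PC1"] = d["latitude"]
        with pytest.raises(ModelError, match="PC1"):
            fit_lm(d, ModelSpec(fixed_terms=("latitude", "PC1")))


class TestLMM:
    def _clone_table(self, sigma_g, sigma_e, n_geno=200, n_ramets=4, seed=3):
        cfg = SimConfig(n_individuals=n_geno, n_background_snps=0,
                        n_sdr_snps=1, seed=seed)
        _, samples, _ = simulate_population(cfg)
        tc = TraitSimConfig(sigma_G=sigma_g, sigma_E=sigma_e)
        return simulate_traits(tc, samples, seed=seed + 1, n_ramets=n_ramets)

    def test_degenerate_partition(self):
        """Identical ramets within genotype: residual variance ~ 0 and the
        genotype component carries the between-genotype variance."""
        t = self._clone_table(2.0, 1.0, n_geno=40, seed=5)
        t["value"] = t["genotype_id"].map(
            t.groupby("genotype_id")["value"].mean())
        f = fit_lmm(t, ModelSpec(random_terms=("genotype",)))
        assert f.varcomp["residual"] < 1e-3 * f.varcomp["genotype"]

    def test_ml_variance_recovery(self):
        """sigma_G^2=4, sigma_E^2=1 at 500x4: ML estimates within 15%."""
        t = self._clone_table(2.0, 1.0, n_geno=500, n_ramets=4, seed=7)
        f = fit_lmm(t, ModelSpec(random_terms=("genotype",)))
        assert f.varcomp["genotype"] == pytest.approx(4.0, rel=0.15)
        assert f.varcomp["residual"] == pytest.approx(1.0, rel=0.15)

    def test_boundary_flag_when_no_genotype_variance(self):
        """sigma_G=0 simulations raise the boundary flag in most replicates."""
        flagged = 0
        for seed in range(9, 16):
            t = self._clone_table(0.0, 1.0, n_geno=60, n_ramets=3, seed=seed)
            f = fit_lmm(t, ModelSpec(random_terms=("genotype",)))
            flagged += f.boundary
        assert flagged >= 4


class TestLRT:
    def test_identical_models_p_one(self):
        d = _lm_data(n=50, seed=4)
        spec = ModelSpec(fixed_terms=("latitude",))
        assert lrt(fit_lm(d, spec), fit_lm(d, spec)) == 1.0

    def test_non_nested_rejected(self):
        d = _lm_data(n=50, seed=4)
        d["longitude"] = -d["latitude"] + np.random.default_rng(0).normal(
            0, 5, len(d))
        a = fit_lm(d, ModelSpec(fixed_terms=("latitude",)))
        b = fit_lm(d, ModelSpec(fixed_terms=("longitude",)))
        with pytest.raises(ModelError):
            lrt(a, b)

    def test_differing_rows_rejected(self):
        d = _lm_data(n=50, seed=4)
        a = fit_lm(d, ModelSpec(fixed_terms=("latitude",)))
        b = fit_lm(d.iloc[:40], ModelSpec())
        with pytest.raises(ModelError):
            lrt(a, b)

    def test_null_rejection_rate_nominal(self):
        """Null sex effect, n=200, 500 simulations: rejection rate at 0.05
        inside the binomial 99% CI."""
        n_rep, rej = 500, 0
        for seed in range(n_rep):
            d = _lm_data(n=200, seed=10_000 + seed, beta_lat=0.3)
            full = fit_lm(d, ModelSpec(fixed_terms=("latitude", "sex")))
            red = fit_lm(d, ModelSpec(fixed_terms=("latitude",)))
            rej += lrt(full, red) < 0.05
        lo, hi = stats.binom.ppf([0.005, 0.995], n_rep, 0.05)
        assert lo <= rej <= hi

    def test_rank_agreement_with_f_test(self):
        """Single-coefficient LM: LRT p is monotone with the exact F-test p
        (identical ranks over 100 random datasets)."""
        import statsmodels.api as sm

        lrt_ps, f_ps = [], []
        for seed in range(100):
            d = _lm_data(n=40, seed=seed, delta_sex=0.2)
            full = fit_lm(d, ModelSpec(fixed_terms=("sex",)))
            red = fit_lm(d, ModelSpec())
            lrt_ps.append(lrt(full, red))
            X = sm.add_constant((d["sex"] == "M").astype(float))
            f_ps.append(float(sm.OLS(d["value"], X).fit().f_pvalue))
        assert stats.spearmanr(lrt_ps, f_ps).statistic == pytest.approx(1.0)


class TestBICSelection:
    def test_single_candidate_returned(self):
        d = _lm_data(n=30, seed=6)
        spec = ModelSpec(fixed_terms=("latitude",))
        assert select_model_bic(d, [spec]).spec == spec

    def test_latitude_model_wins_under_strong_effect(self):
        """With a real latitude effect the latitude model has lower BIC in
        >= 95% of replicates."""
        wins = 0
        n_rep = 60
        for seed in range(n_rep):
            d = _lm_data(n=150, seed=500 + seed, beta_lat=0.3)
            best = select_model_bic(
                d, [ModelSpec(), ModelSpec(fixed_terms=("latitude",))])
            wins += best.spec.fixed_terms == ("latitude",)
        assert wins >= int(0.95 * n_rep) - 2

    def test_parsimony_under_pure_noise(self):
        keep = 0
        n_rep = 40
        for seed in range(n_rep):
            d = _lm_data(n=150, seed=900 + seed)
            best = select_model_bic(
                d, [ModelSpec(), ModelSpec(fixed_terms=("sex",))])
            keep += best.spec.fixed_terms == ()
        assert keep > n_rep / 2


class TestOmegaSquared:
    def test_hand_decomposed_toy(self):
        """Two groups of 4 (A=[0,0,1,1], B=[1,1,2,2]): SS decomposition gives
        omega^2 = 5/13 exactly."""
        d = pd.DataFrame({
            "genotype_id": [f"g{i}" for i in range(8)],
            "sex": ["F"] * 4 + ["M"] * 4,
            "value": [0.0, 0, 1, 1, 1, 1, 2, 2], "trait": "t"})
        f = fit_lm(d, ModelSpec(fixed_terms=("sex",)))
        out = omega_squared(f, "sex")
        assert out["raw"] == pytest.approx(5 / 13, abs=1e-12)

    def test_null_effect_clamped_to_zero(self):
        d = pd.DataFrame({
            "genotype_id": [f"g{i}" for i in range(40)],
            "sex": ["F", "M"] * 20,
            "value": np.tile([1.0, 1.0, 2.0, 2.0], 10), "trait": "t"})
        f = fit_lm(d, ModelSpec(fixed_terms=("sex",)))
        out = omega_squared(f, "sex")
        assert out["raw"] <= 0.0 and out["reported"] == 0.0

    def test_quarter_variance_recovered(self):
        """An effect explaining 25% of variance: mean estimate over 200
        replicates at n=2000 within +-0.02 of 0.25."""
        delta = 2.0 / np.sqrt(3.0)   # var share delta^2/4 over delta^2/4 + 1
        ests = []
        rng = np.random.default_rng(123)
        for _ in range(200):
            male = rng.random(2000) < 0.5
            y = delta * male + rng.normal(0, 1, 2000)
            d = pd.DataFrame({"genotype_id": np.arange(2000).astype(str),
                              "sex": np.where(male, "M", "F"),
                              "value": y, "trait": "t"})
            f = fit_lm(d, ModelSpec(fixed_terms=("sex",)))
            ests.append(omega_squared(f, "sex")["raw"])
        assert np.mean(ests) == pytest.approx(0.25, abs=0.02)

    def test_null_estimator_nearly_unbiased(self):
        """Mean raw omega^2 under the null within +-0.005 of zero."""
        rng = np.random.default_rng(321)
        ests = []
        for _ in range(500):
            male = rng.random(500) < 0.5
            d = pd.DataFrame({"genotype_id": np.arange(500).astype(str),
                              "sex": np.where(male, "M", "F"),
                              "value": rng.normal(0, 1, 500), "trait": "t"})
            f = fit_lm(d, ModelSpec(fixed_terms=("sex",)))
            ests.append(omega_squared(f, "sex")["raw"])
        assert abs(np.mean(ests)) < 0.005


@pytest.fixture(scope="module")
def population_samples():
    cfg = SimConfig(n_individuals=400, n_background_snps=0, n_sdr_snps=1,
                    seed=77)
    _, samples, _ = simulate_population(cfg)
    return samples


class TestTraitPipeline:
    def test_insufficient_data_result(self):
        d = _lm_data(n=20, seed=8)
        d["sex"] = "F"
        r = trait_test(d, "t")
        assert r.status == "insufficient_data"

    def test_power_against_real_sex_effect(self, population_samples):
        """delta_sex = 1 sigma_E at 400 genotypes: detected (p < 0.05) in
        >= 90% of replicates."""
        hits, n_rep = 0, 30
        for seed in range(n_rep):
            tc = TraitSimConfig(beta_lat=0.3, delta_sex=1.0, sigma_G=1.0,
                                sigma_E=1.0)
            t = simulate_traits(tc, population_samples, seed=2000 + seed)
            r = trait_test(t, "trait")
            hits += r.p_sex < 0.05
        assert hits >= int(0.90 * n_rep)

    def test_interaction_screen_rarely_retains_null_interaction(
            self, population_samples):
        kept = 0
        n_rep = 40
        for seed in range(n_rep):
            tc = TraitSimConfig(beta_lat=0.3, sigma_G=1.0, sigma_E=1.0)
            t = simulate_traits(tc, population_samples, seed=3000 + seed)
            kept += trait_test(t, "trait").interaction_retained
        # ~5% retention expected; binomial 99.5% upper bound at n=40
        assert kept <= stats.binom.ppf(0.995, n_rep, 0.05) + 1

    def test_confounding_demonstration(self, population_samples):
        """Sex-by-latitude sampling bias with geography omitted inflates the
        sex false-positive rate far above nominal; the latitude covariate
        restores it."""
        n_rep = 60
        fp_naive = fp_corrected = 0
        for seed in range(n_rep):
            tc = TraitSimConfig(beta_lat=0.5, delta_sex=0.0, sigma_G=0.5,
                                sigma_E=1.0, confound_sex_lat=0.3)
            t = simulate_traits(tc, population_samples, seed=4000 + seed)
            naive = trait_test(t, "trait", select_covariates=False,
                               forced_covariates=())
            corr = trait_test(t, "trait", select_covariates=False,
                              forced_covariates=("latitude",))
            fp_naive += naive.p_sex < 0.05
            fp_corrected += corr.p_sex < 0.05
        assert fp_naive / n_rep > 0.15
        lo, hi = stats.binom.ppf([0.005, 0.995], n_rep, 0.05)
        assert fp_corrected <= hi


class TestMultiSite:
    def test_single_stratum_rejected(self, population_samples):
        tc = TraitSimConfig(beta_lat=0.3)
        t = simulate_traits(tc, population_samples, seed=1)
        with pytest.raises(ModelError):
            multi_site_battery({"only": t}, "trait")

    def test_site_specific_effect_not_repeatable(self, population_samples):
        """A sex effect injected at one site only: that site significant,
        verdict not repeatable."""
        tabs = {}
        for i, delta in enumerate((0.0, 0.0, 1.5)):
            tc = TraitSimConfig(beta_lat=0.3, delta_sex=delta, sigma_G=0.5,
                                sigma_E=0.5)
            tabs[f"s{i}"] = simulate_traits(tc, population_samples,
                                            seed=600 + i)
        out = multi_site_battery(tabs, "trait")
        assert out["per_stratum"]["s2"].significant_nominal
        assert not out["repeatable"]


class TestFactorial:
    def test_missing_cell_rejected(self, population_samples):
        tc = TraitSimConfig(design="factorial_warming")
        t = simulate_traits(tc, population_samples, seed=9)
        with pytest.raises(ModelError):
            factorial_response_test(t[t["temperature"] == 10])

    def test_interaction_detected_without_sex_effect(self, population_samples):
        """Strong chilling x temperature interaction, no sex effect: the
        interaction p is tiny while sex stays non-significant."""
        tc = TraitSimConfig(design="factorial_warming", beta_scenario=3.0,
                            beta_temperature=-6.0,
                            beta_scenario_temperature=4.0,
                            sigma_G=1.0, sigma_E=1.0)
        t = simulate_traits(tc, population_samples, seed=10)
        out = factorial_response_test(t)
        assert out["p_scenario_temperature"] < 1e-3
        assert out["p_sex"] > 0.001

    def test_sex_effect_detected_when_injected(self, population_samples):
        tc = TraitSimConfig(design="factorial_warming", delta_sex=1.0,
                            beta_scenario_temperature=2.0,
                            sigma_G=1.0, sigma_E=1.0)
        t = simulate_traits(tc, population_samples, seed=11)
        out = factorial_response_test(t)
        assert out["p_sex"] < 0.001
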