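"""Tests of compositional MANOVA, adjusted means and bootstrap CIs."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from timeuse_coda import (
    COMPONENTS,
    GeneratorConfig,
    adjusted_group_means,
    bootstrap_log_ratio_ci,
    compositional_mean,
    compositional_manova,
    fit_ilr_models,
    generate_compositions,
    impute_augmentation,
    interaction_and_stratify,
    log_ratio_difference,
    make_ilr_basis,
)
from timeuse_coda.simulate import (
    STUDY_ADJUSTED_MEANS_NONE,
    STUDY_ADJUSTED_MEANS_SOME,
)

MODERATE_CFG = GeneratorConfig(
    base_composition=(1 / 3, 1 / 30, 2 / 15, 1 / 3, 1 / 15, 1 / 10),
    group_perturbation=(0.95, 1.3, 0.9, 1.0, 1.4, 1.15),
    noise_covariance=np.eye(5) * 0.1,
)


@pytest.fixture(scope="module")
def imputed_sample():
    comp, truth = generate_compositions(GeneratorConfig(), n=2500, seed=101)
    return impute_augmentation(comp, seed=102), truth


def rotated_basis(seed=0):
    """A different orthonormal ilr basis (random rotation of the pivot one)."""
    rng = np.random.default_rng(seed)
    R, _ = np.linalg.qr(rng.normal(size=(5, 5)))
    return R @ make_ilr_basis(6)


class TestCompositionalManova:
    def test_matches_statsmodels(self, imputed_sample):
        sm_manova = pytest.importorskip("statsmodels.multivariate.manova")
        imp, _ = imputed_sample
        from timeuse_coda.coda import close, ilr

        Z = ilr(close(imp.parts, 1.0))
        df = pd.DataFrame(Z, columns=[f"z{k}" for k in range(1, 6)])
        enc = imp.data
        df["exp"] = enc["active_travel"].astype(float).to_numpy()
        df["age"] = enc["age"].to_numpy()
        df["female"] = (enc["sex"] == "female").astype(float).to_numpy()
        df["working"] = (enc["work_status"] == "working_or_studying").astype(float).to_numpy()
        df["weekend"] = (enc["day_type"] == "weekend").astype(float).to_numpy()
        ref = (
            sm_manova.MANOVA.from_formula(
                "z1+z2+z3+z4+z5 ~ exp+age+female+working+weekend", data=df
            )
            .mv_test()
            .results["exp"]["stat"]
        )
        ours = compositional_manova(imp, stage="full")
        assert ours.f_value == pytest.approx(ref.loc["Wilks' lambda", "F Value"], rel=1e-9)
        assert ours.value == pytest.approx(ref.loc["Wilks' lambda", "Value"], rel=1e-9)
        pil = compositional_manova(imp, stage="full", statistic="pillai")
        assert pil.f_value == pytest.approx(ref.loc["Pillai's trace", "F Value"], rel=1e-9)

    def test_basis_invariance(self, imputed_sample):
        imp, _ = imputed_sample
        a = compositional_manova(imp, basis=make_ilr_basis(6))
        b = compositional_manova(imp, basis=rotated_basis(3))
        assert a.f_value == pytest.approx(b.f_value, abs=1e-9 * max(1, a.f_value))
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)

    def test_detects_group_difference_at_scale(self, imputed_sample):
        imp, _ = imputed_sample
        for stage in ("unadjusted", "age_sex", "full"):
            assert compositional_manova(imp, stage=stage).p_value < 0.001

    def test_null_permutation_is_not_significant_on_average(self):
        # permuting exposure labels breaks the association
        comp, _ = generate_compositions(MODERATE_CFG, n=800, seed=7)
        imp = impute_augmentation(comp, seed=8)
        rng = np.random.default_rng(9)
        ps = []
        for _ in range(20):
            shuffled = imp.data.copy()
            shuffled["active_travel"] = rng.permutation(
                shuffled["active_travel"].to_numpy()
            )
            ps.append(compositional_manova(shuffled).p_value)
        assert np.mean(np.array(ps) < 0.05) < 0.3

    def test_constant_exposure_raises(self, imputed_sample):
        imp, _ = imputed_sample
        bad = imp.data.copy()
        bad["active_travel"] = True
        with pytest.raises(ValueError, match="[Rr]ank"):
            compositional_manova(bad)


class TestFitIlrModels:
    def test_five_models_and_shapes(self, imputed_sample):
        imp, _ = imputed_sample
        fit = fit_ilr_models(imp, stage="full")
        assert len(fit.models) == 5
        assert fit.beta.shape == (6, 5)  # const + exposure + 4 covariates

    def test_statsmodels_agrees_with_fast_path(self, imputed_sample):
        imp, _ = imputed_sample
        fit = fit_ilr_models(imp, stage="age_sex")
        for k, m in enumerate(fit.models):
            assert np.allclose(m.params, fit.beta[:, k], atol=1e-10)

    def test_exposure_coefficients_recover_truth(self):
        # zero covariate effects, large n, little attenuation: coefficients
        # within 3 SEs of the latent ilr-scale contrast
        cfg = replace(MODERATE_CFG, covariate_effects=np.zeros((4, 5)))
        comp, truth = generate_compositions(cfg, n=20_000, seed=31)
        imp = impute_augmentation(comp, seed=32)
        fit = fit_ilr_models(imp, stage="unadjusted")
        est = fit.exposure_coefficients()
        ses = np.array([m.bse[1] for m in fit.models])
        assert (np.abs(est - truth.delta_ilr) < 3 * ses + 0.01).all()

    def test_too_few_rows_raise(self, imputed_sample):
        imp, _ = imputed_sample
        with pytest.raises(ValueError):
            fit_ilr_models(imp.data.iloc[:5], stage="full")


class TestAdjustedMeans:
    def test_sums_and_positivity(self, imputed_sample):
        imp, _ = imputed_sample
        means = adjusted_group_means(fit_ilr_models(imp))
        for comp in (means.composition_some, means.composition_none):
            assert comp.sum() == pytest.approx(1440, abs=1e-6)
            assert (comp > 0).all()

    def test_zero_exposure_coefficient_gives_identical_groups(self, imputed_sample):
        imp, _ = imputed_sample
        fit = fit_ilr_models(imp)
        fit.beta[fit.design_cols.index("exposure")] = 0.0
        means = adjusted_group_means(fit)
        assert np.allclose(means.composition_some, means.composition_none)

    def test_unadjusted_equals_per_group_compositional_means(self, imputed_sample):
        # oracle equivalence: with no covariates the model-adjusted means
        # are exactly the per-group compositional means
        imp, _ = imputed_sample
        means = adjusted_group_means(fit_ilr_models(imp, stage="unadjusted"))
        parts = imp.parts
        exposed = imp.data["active_travel"].to_numpy(dtype=bool)
        cm_some = compositional_mean(parts[exposed], 1440)
        cm_none = compositional_mean(parts[~exposed], 1440)
        assert np.allclose(means.composition_some, cm_some, atol=1e-9)
        assert np.allclose(means.composition_none, cm_none, atol=1e-9)

    def test_basis_invariance(self, imputed_sample):
        imp, _ = imputed_sample
        m1 = adjusted_group_means(fit_ilr_models(imp, basis=make_ilr_basis(6)))
        m2 = adjusted_group_means(fit_ilr_models(imp, basis=rotated_basis(5)))
        assert np.allclose(m1.composition_some, m2.composition_some, atol=1e-9)
        assert np.allclose(m1.composition_none, m2.composition_none, atol=1e-9)

    def test_observed_grid_differs_from_equal_when_unbalanced(self, imputed_sample):
        imp, _ = imputed_sample
        fit = fit_ilr_models(imp)
        eq = adjusted_group_means(fit, grid="equal")
        ob = adjusted_group_means(fit, grid="observed")
        assert not np.allclose(eq.composition_some, ob.composition_some)


class TestLogRatioDifference:
    def test_identical_means_give_zero(self):
        x = np.array([500.0, 20, 150, 500, 60, 210])
        assert np.allclose(log_ratio_difference(x, x), 0)

    def test_survey_scale_values(self):
        d = log_ratio_difference(
            np.array(STUDY_ADJUSTED_MEANS_SOME), np.array(STUDY_ADJUSTED_MEANS_NONE)
        )
        assert d[1] == pytest.approx(np.log(20.8 / 9.5), abs=1e-12)
        assert d[1] == pytest.approx(0.7837, abs=1e-3)
        assert d[0] == pytest.approx(-0.0646, abs=1e-3)

    def test_kappa_invariance(self, rng):
        a = np.abs(rng.normal(size=6)) + 0.1
        b = np.abs(rng.normal(size=6)) + 0.1
        from timeuse_coda.coda import close

        d1 = log_ratio_difference(close(a, 1.0), close(b, 1.0))
        d2 = log_ratio_difference(close(a, 1440.0), close(b, 1440.0))
        assert np.allclose(d1, d2, atol=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            log_ratio_difference(np.array([1.0, 0.0]), np.array([1.0, 1.0]))


class TestBootstrap:
    def test_fixed_seed_reproducible(self, imputed_sample):
        imp, _ = imputed_sample
        a = bootstrap_log_ratio_ci(imp, B=150, seed=5)
        b = bootstrap_log_ratio_ci(imp, B=150, seed=5)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_interval_contains_estimate(self, imputed_sample):
        imp, _ = imputed_sample
        res = bootstrap_log_ratio_ci(imp, B=400, seed=6)
        t = res.table
        assert (t["lower"] <= t["estimate"]).all()
        assert (t["estimate"] <= t["upper"]).all()

    def test_significance_flag_matches_interval(self, imputed_sample):
        imp, _ = imputed_sample
        t = bootstrap_log_ratio_ci(imp, B=150, seed=7).table
        assert (t["significant"] == ((t["lower"] > 0) | (t["upper"] < 0))).all()

    def test_small_b_warns(self, imputed_sample):
        imp, _ = imputed_sample
        with pytest.warns(UserWarning, match="bootstrap"):
            bootstrap_log_ratio_ci(imp, B=50, seed=8)

    def test_single_group_raises(self, imputed_sample):
        imp, _ = imputed_sample
        solo = imp.data[imp.data["active_travel"]]
        with pytest.raises(ValueError, match="non-empty|[Rr]ank"):
            bootstrap_log_ratio_ci(solo, B=150, seed=9)


class TestInteraction:
    def test_injected_interaction_detected_and_stratified(self):
        # boost MVPA for exposed females only: a sex x exposure effect
        comp, _ = generate_compositions(MODERATE_CFG, n=4000, seed=55)
        imp = impute_augmentation(comp, seed=56)
        df = imp.data.copy()
        sel = df["active_travel"] & (df["sex"] == "female")
        parts = df[list(COMPONENTS)].to_numpy()
        parts[sel.to_numpy(), 1] *= np.exp(0.8)
        parts = 1440 * parts / parts.sum(axis=1, keepdims=True)
        df[list(COMPONENTS)] = parts
        res = interaction_and_stratify(df, "sex", B=120, seed=57)
        assert res.manova.p_value < 0.05
        assert set(res.strata) == {"female", "male"}
        for s in res.strata.values():
            assert s.means.composition_some.sum() == pytest.approx(1440, abs=1e-6)
            assert (s.means.composition_some > 0).all()
            assert len(s.log_ratio.table) == 6

    def test_age_group_levels(self, imputed_sample):
        imp, _ = imputed_sample
        res = interaction_and_stratify(imp, "age_group", B=120, seed=58, force_strata=True)
        assert set(res.strata) == {"16-29", "30-59", "60+"}
        assert 0 <= res.manova.p_value <= 1

    def test_unknown_modifier_rejected(self, imputed_sample):
        imp, _ = imputed_sample
        with pytest.raises(ValueError, match="modifier"):
            interaction_and_stratify(imp, "favourite_colour")
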