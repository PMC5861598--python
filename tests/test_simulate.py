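"""Tests of the synthetic diary generator and its ground truth."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from timeuse_coda import (
    COMPONENTS,
    CorruptionRates,
    GeneratorConfig,
    apply_qc,
    build_compositions,
    corrupt_diaries,
    generate_compositions,
    generate_population,
)
from timeuse_coda.simulate import N_SLOTS, implied_prevalence, largest_remainder

TINY_NOISE = np.eye(5) * 1e-8
NO_EFFECTS = np.zeros((4, 5))


class TestGeneratePopulation:
    def test_every_diary_has_144_slots(self, small_population):
        _, _, diaries, _ = small_population
        assert (diaries.groupby("diary_id").size() == N_SLOTS).all()

    def test_seeded_determinism(self):
        cfg = GeneratorConfig(n_participants=50, seed=7)
        p1, d1, _ = generate_population(cfg)
        p2, d2, _ = generate_population(cfg)
        pd.testing.assert_frame_equal(p1, p2)
        pd.testing.assert_frame_equal(d1, d2)

    def test_neutral_perturbation_gives_identical_group_means(self):
        cfg = GeneratorConfig(
            n_participants=10,
            group_perturbation=(1, 1, 1, 1, 1, 1),
            covariate_effects=NO_EFFECTS,
        )
        _, _, truth = generate_population(cfg)
        assert np.allclose(truth.mean_composition_none, truth.mean_composition_some)
        assert np.allclose(truth.log_ratio_difference, 0)

    def test_discretisation_recovers_base_within_one_slot(self):
        # zero noise, zero effects: every rebuilt composition within 10 min
        # of 1440 x base
        base = (1 / 3, 1 / 30, 2 / 15, 1 / 3, 1 / 15, 1 / 10)
        cfg = GeneratorConfig(
            n_participants=4000,
            base_composition=base,
            group_perturbation=(1, 1, 1, 1, 1, 1),
            covariate_effects=NO_EFFECTS,
            noise_covariance=TINY_NOISE,
            seed=5,
        )
        comp, _ = generate_compositions(cfg)
        target = np.array([480, 48, 192, 480, 96, 144], dtype=float)
        M = comp[list(COMPONENTS)].to_numpy()
        assert np.abs(M - target).max() <= 10.0

    def test_uncorrupted_diaries_pass_all_qc(self, small_population):
        _, participants, diaries, _ = small_population
        _, report = apply_qc(diaries, participants)
        assert report.n_removed == 0

    def test_exposure_prevalence_matches_logistic_model(self):
        cfg = GeneratorConfig(n_participants=10_000, seed=11)
        comp, truth = generate_compositions(cfg)
        assert comp["active_travel"].mean() == pytest.approx(
            truth.implied_prevalence, abs=0.02
        )

    def test_monte_carlo_mean_recovery(self):
        # zero covariate effects: the sample compositional mean of rebuilt
        # compositions converges to the configured group mean (< 2 min per
        # part at n = 10k; zeros jittered to mid-slot before taking logs)
        base = (1 / 3, 1 / 30, 2 / 15, 1 / 3, 1 / 15, 1 / 10)
        # moderate dispersion: at survey-scale noise the 10-min rounding
        # itself biases log-scale means of small parts (see docs/methods.md)
        cfg = GeneratorConfig(
            n_participants=10_000,
            base_composition=base,
            group_perturbation=(1, 1, 1, 1, 1, 1),
            covariate_effects=NO_EFFECTS,
            noise_covariance=np.eye(5) * 0.04,
            seed=13,
        )
        comp, truth = generate_compositions(cfg)
        M = comp[list(COMPONENTS)].to_numpy()
        M = np.where(M == 0, 5.0, M)  # non-zero-safe jitter, half a slot
        gm = np.exp(np.log(M).mean(axis=0))
        cm = 1440 * gm / gm.sum()
        assert np.abs(cm - truth.mean_composition_none).max() < 2.0

    def test_truth_record_reports_exact_group_means(self):
        cfg = GeneratorConfig(n_participants=10, seed=1)
        _, _, truth = generate_population(cfg)
        assert truth.mean_composition_none.sum() == pytest.approx(1440)
        assert truth.mean_composition_some.sum() == pytest.approx(1440)
        expected_d = truth.log_ratio_difference
        assert np.allclose(
            expected_d, np.log(truth.mean_composition_some / truth.mean_composition_none)
        )

    def test_sleep_always_present(self, small_population):
        _, participants, diaries, _ = small_population
        comp = build_compositions(diaries, participants)
        assert (comp["sleep"] > 0).all()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            GeneratorConfig(base_composition=(0.5, 0, 0.1, 0.2, 0.1, 0.1)).validate()
        bad_cov = np.eye(5)
        bad_cov[0, 0] = -1.0
        with pytest.raises(ValueError, match="positive definite"):
            GeneratorConfig(noise_covariance=bad_cov).validate()


class TestLargestRemainder:
    def test_rows_sum_to_total(self, rng):
        P = rng.dirichlet(np.ones(6), size=200)
        counts = largest_remainder(P, 144)
        assert (counts.sum(axis=1) == 144).all()
        assert (counts >= 0).all()

    def test_exact_when_divisible(self):
        P = np.array([[0.5, 0.25, 0.25]])
        assert (largest_remainder(P, 144) == [[72, 36, 36]]).all()

    def test_within_one_unit_of_raw(self, rng):
        P = rng.dirichlet(np.ones(6), size=200)
        counts = largest_remainder(P, 144)
        assert np.abs(counts - P * 144).max() < 1.0


class TestImpliedPrevalence:
    def test_matches_monte_carlo(self):
        cfg = GeneratorConfig(active_travel_logit=(0.3, -0.5, 0.2, 0.1))
        analytic = implied_prevalence(cfg)
        rng = np.random.default_rng(0)
        n = 400_000
        mid, sd = cfg.age_standardiser()
        a = (rng.uniform(*cfg.age_range, n) - mid) / sd
        f = rng.random(n) < 0.5
        w = rng.random(n) < 0.5
        eta = 0.3 - 0.5 * a + 0.2 * f + 0.1 * w
        mc = (rng.random(n) < 1 / (1 + np.exp(-eta))).mean()
        assert analytic == pytest.approx(mc, abs=0.005)


class TestCorruptDiaries:
    def test_zero_rates_identity(self, small_population):
        _, _, diaries, _ = small_population
        out, log = corrupt_diaries(diaries, CorruptionRates(0, 0, 0, 0, 0), seed=1)
        pd.testing.assert_frame_equal(
            out.reset_index(drop=True), diaries.reset_index(drop=True)
        )
        assert log.empty

    def test_rate_one_missing_time_hits_every_diary(self):
        cfg = GeneratorConfig(n_participants=5, seed=3)
        _, diaries, _ = generate_population(cfg)
        out, log = corrupt_diaries(diaries, CorruptionRates(1.0, 0, 0, 0, 0), seed=1)
        miss = out.groupby("diary_id")["missing"].sum()
        assert (miss >= 10).all()
        assert len(log) == diaries["diary_id"].nunique()

    def test_qc_removals_match_injected_counts(self):
        # generator bookkeeping as the oracle for QC accounting
        cfg = GeneratorConfig(n_participants=1000, seed=3)
        participants, diaries, _ = generate_population(cfg)
        rates = CorruptionRates(0.05, 0.05, 0.05, 0.05, 0.005)
        corrupted, log = corrupt_diaries(diaries, rates, seed=9)
        _, report = apply_qc(corrupted, participants)
        injected = log["rule"].value_counts()
        general = sum(
            injected.get(r, 0) for r in ("missing_time", "few_episodes", "missing_basic")
        )
        assert report.removed_general == general
        assert report.removed_ineligible == injected.get("ineligible", 0)
        assert report.removed_no_sleep == injected.get("no_sleep", 0)

    def test_removal_counts_near_binomial_expectation(self):
        # sequential first-rule-wins selection: marginal P(rule k) =
        # r_k * prod_{j<k} (1 - r_j); counts within 3 binomial SEs
        cfg = GeneratorConfig(n_participants=1000, seed=17)
        _, diaries, _ = generate_population(cfg)
        r = np.array([0.05, 0.05, 0.05, 0.05, 0.005])
        _, log = corrupt_diaries(diaries, CorruptionRates(*r), seed=21)
        n = diaries["diary_id"].nunique()
        marg = r * np.concatenate([[1], np.cumprod(1 - r)[:-1]])
        counts = log["rule"].value_counts()
        from timeuse_coda.simulate import RULE_NAMES

        for rule, p in zip(RULE_NAMES, marg):
            se = np.sqrt(n * p * (1 - p))
            assert abs(counts.get(rule, 0) - n * p) <= 3 * se


class TestCompositionFastPath:
    def test_matches_full_path_distribution(self):
        # same latent model: moments of the slot-built compositions agree
        cfg = GeneratorConfig(n_participants=4000, seed=29)
        comp_fast, _ = generate_compositions(cfg)
        participants, diaries, _ = generate_population(replace(cfg, seed=31))
        comp_full = build_compositions(diaries, participants)
        a = comp_fast[list(COMPONENTS)].to_numpy()
        b = comp_full[list(COMPONENTS)].to_numpy()
        assert np.abs(a.mean(0) - b.mean(0)).max() < 8.0  # minutes
        assert (a.sum(1) == 1440).all() and (b.sum(1) == 1440).all()
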