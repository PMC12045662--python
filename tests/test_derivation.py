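"""Model derivation: screening, pruning, anchors, fits, EF-band bias."""

import numpy as np
import pandas as pd
import pytest

import heartage as ha
from heartage.derivation import (
    DEFAULT_RELEVANCE_ORDER,
    DerivationConfig,
    ef_recovery_study,
    estimate_ef_correction,
    fit_piecewise,
    interpolate_extremes,
    prune_collinear,
    slope_recovery_study,
    spearman_screen,
)
from heartage.model import DEFAULT_PARAMS, base_age


class TestScreen:
    def test_age_itself_and_transforms(self, rng):
        n = 60
        age = rng.uniform(10, 85, n)
        frame = pd.DataFrame(
            {"age_yr": age, "self_ml": age, "anti_ml": np.exp(-0.05 * age)}
        )
        res = {r.variable: r for r in spearman_screen(frame, ["self_ml", "anti_ml"])}
        assert res["self_ml"].spearman_rho == pytest.approx(1.0)
        assert res["anti_ml"].spearman_rho == pytest.approx(-1.0)

    def test_constant_variable_flagged_not_dropped(self, rng):
        frame = pd.DataFrame(
            {"age_yr": rng.uniform(10, 85, 30), "flat_ml": np.ones(30)}
        )
        (res,) = spearman_screen(frame, ["flat_ml"])
        assert res.constant and np.isnan(res.spearman_rho)

    def test_generator_link_signs(self, healthy_frame):
        res = {
            r.variable: r
            for r in spearman_screen(healthy_frame, ["la_esv_ml", "la_ef_pct"])
        }
        assert res["la_esv_ml"].spearman_rho > 0
        assert res["la_ef_pct"].spearman_rho < 0

    def test_small_cohort_rejected(self):
        frame = pd.DataFrame({"age_yr": np.arange(5.0), "x_ml": np.arange(5.0)})
        with pytest.raises(ValueError):
            spearman_screen(frame, ["x_ml"])


class TestPrune:
    def _screen(self, frame, cols):
        return spearman_screen(frame, cols)

    def test_identical_variables_keep_one(self, rng):
        age = rng.uniform(10, 85, 50)
        frame = pd.DataFrame({"age_yr": age, "a_ml": age * 2, "b_ml": age * 2})
        kept = prune_collinear(
            self._screen(frame, ["a_ml", "b_ml"]), frame,
            relevance_order=["b_ml", "a_ml"],
        )
        assert kept == ["b_ml"]

    def test_uncorrelated_all_retained(self, rng):
        frame = pd.DataFrame(
            {"age_yr": rng.uniform(10, 85, 200),
             "a_ml": rng.normal(size=200), "b_ml": rng.normal(size=200)}
        )
        kept = prune_collinear(self._screen(frame, ["a_ml", "b_ml"]), frame)
        assert sorted(kept) == ["a_ml", "b_ml"]

    def test_relevance_rule_and_order_invariance(self, rng):
        age = rng.uniform(10, 85, 300)
        esv = age + rng.normal(0, 5, 300)
        edv = esv * 2.5 + rng.normal(0, 3, 300)  # collinear with esv
        frame = pd.DataFrame({"age_yr": age, "la_edv_ml": edv, "la_esv_ml": esv})
        for cols in (["la_edv_ml", "la_esv_ml"], ["la_esv_ml", "la_edv_ml"]):
            kept = prune_collinear(
                self._screen(frame, cols), frame,
                relevance_order=["la_esv_ml", "la_edv_ml"],
            )
            assert kept == ["la_esv_ml"]

    def test_clash_without_ranking_is_an_error(self, rng):
        age = rng.uniform(10, 85, 50)
        frame = pd.DataFrame({"age_yr": age, "a_ml": age, "b_ml": age})
        with pytest.raises(ValueError):
            prune_collinear(self._screen(frame, ["a_ml", "b_ml"]), frame)


class TestInterpolateExtremes:
    def _mid_pairs(self):
        esv = np.linspace(15, 50, 40)
        age = -18.0342 + 2.3140 * esv
        return np.column_stack([esv, age])

    def test_zero_anchors_identity(self):
        pairs = self._mid_pairs()
        aug, mask = interpolate_extremes(pairs, 15, 50, n_anchors_per_side=0)
        assert np.array_equal(aug, pairs) and not mask.any()

    def test_blunt_one_continues_mid_slope(self):
        aug, mask = interpolate_extremes(
            self._mid_pairs(), 15, 50, blunt_fraction=1.0
        )
        fit = fit_piecewise(aug, (15, 50), anchor_mask=mask)
        assert fit.segments[2].slope == pytest.approx(2.3140, abs=1e-9)
        assert fit.segments[0].slope == pytest.approx(2.3140, abs=1e-9)

    def test_blunt_quarter_damps_extremes(self):
        aug, mask = interpolate_extremes(
            self._mid_pairs(), 15, 50, blunt_fraction=0.25
        )
        fit = fit_piecewise(aug, (15, 50), anchor_mask=mask)
        assert fit.segments[2].slope == pytest.approx(0.5785, abs=1e-9)
        assert len(fit.augmented_points) == 16

    def test_bad_cuts(self):
        with pytest.raises(ValueError):
            interpolate_extremes(self._mid_pairs(), 50, 15)


class TestFitPiecewise:
    def test_noiseless_recovery(self):
        esv = np.concatenate(
            [np.linspace(1, 14, 10), np.linspace(15, 50, 40), np.linspace(51, 90, 10)]
        )
        age = np.array([base_age(v) for v in esv])
        fit = fit_piecewise(np.column_stack([esv, age]))
        for got, (c, m) in zip(fit.segments, DEFAULT_PARAMS.segments):
            assert got.intercept == pytest.approx(c, abs=1e-9)
            assert got.slope == pytest.approx(m, abs=1e-9)
            assert got.r_squared == pytest.approx(1.0)

    def test_noisy_mid_slope_within_tolerance(self, rng):
        esv = np.concatenate(
            [rng.uniform(2, 14, 10), rng.uniform(15, 50, 150), rng.uniform(51, 80, 10)]
        )
        age = np.array([base_age(v) for v in esv]) + rng.normal(0, 5, len(esv))
        fit = fit_piecewise(np.column_stack([esv, age]))
        assert fit.segments[1].slope == pytest.approx(2.3140, abs=0.15)

    def test_underpopulated_segment_named(self):
        esv = np.array([20.0, 30.0, 40.0, 60.0, 70.0])
        age = np.array([base_age(v) for v in esv])
        with pytest.raises(ValueError, match="segment 0"):
            fit_piecewise(np.column_stack([esv, age]))


class TestEfCorrection:
    def test_exact_recovery_no_noise(self):
        ef = np.linspace(35, 75, 200)
        esv = np.linspace(15, 50, 200)
        base = np.array([base_age(v) for v in esv])
        offsets = {0: 20.0, 1: 15.0, 2: 5.0, 3: 2.0, 4: 0.0}
        band = np.digitize(ef, [55, 58, 60, 62])
        age = base + np.array([offsets[b] for b in band])
        fit = estimate_ef_correction(ef, age, base)
        assert fit.offsets == (20.0, 15.0, 5.0, 2.0)
        assert fit.empty_bands == ()

    def test_noisy_recovery_within_two_years(self):
        study = ef_recovery_study(seed=0)
        assert study["max_abs_error"] < 2.0

    def test_all_high_ef_gives_zero_offsets_with_flags(self):
        ef = np.linspace(63, 75, 50)
        esv = np.linspace(15, 50, 50)
        base = np.array([base_age(v) for v in esv])
        fit = estimate_ef_correction(ef, base, base)
        assert fit.offsets == (0.0, 0.0, 0.0, 0.0)
        assert fit.empty_bands == (0, 1, 2, 3)

    def test_offsets_always_monotone(self, rng):
        for _ in range(20):
            ef = rng.uniform(35, 75, 120)
            base = rng.uniform(20, 80, 120)
            age = base + rng.normal(0, 10, 120)
            fit = estimate_ef_correction(ef, age, base)
            assert all(
                a >= b for a, b in zip(fit.offsets, fit.offsets[1:])
            ) and fit.offsets[-1] >= 0.0


class TestDeriveModel:
    def test_fixed_point_mid_segment(self):
        cfg = ha.CohortConfig(
            n=200, seed=3, noise_sd_years=0.0, ef_jitter_sd=0.0,
            ef_decline=(66.0, 62.0), ef_knee=None, age_range=(17.0, 85.0),
        )
        frame = ha.cohort_frame(ha.generate_healthy(cfg))
        params, report = ha.derive_model(frame)
        c, m = params.segments[1]
        assert c == pytest.approx(-18.0342, abs=1e-6)
        assert m == pytest.approx(2.3140, abs=1e-6)

    def test_fixed_point_blunted_extremes(self):
        cfg = ha.CohortConfig(
            n=300, seed=4, noise_sd_years=0.0, ef_jitter_sd=0.0,
            ef_decline=(66.0, 62.0), ef_knee=None,
        )
        frame = ha.cohort_frame(ha.generate_healthy(cfg))
        params, _ = ha.derive_model(frame)
        assert params.segments[0][1] == pytest.approx(0.25 * 2.3140, abs=1e-6)
        assert params.segments[2][1] == pytest.approx(0.25 * 2.3140, abs=1e-6)

    def test_noisy_derivation_recovers_mid_slope(self):
        cfg = ha.CohortConfig(n=169, seed=9)
        frame = ha.cohort_frame(ha.generate_healthy(cfg))
        params, _ = ha.derive_model(frame)
        assert params.segments[1][1] == pytest.approx(2.3140, rel=0.25)

    def test_refuses_comorbid_cohort(self, unhealthy_frame):
        with pytest.raises(ValueError, match="healthy"):
            ha.derive_model(unhealthy_frame)

    def test_empty_cohort(self):
        with pytest.raises(ValueError):
            ha.derive_model(pd.DataFrame())


class TestRecoveryStudies:
    def test_slope_recovery_under_five_percent(self):
        study = slope_recovery_study(n=169, noise_sd_years=5.0,
                                     n_replicates=100, seed=7)
        assert study["median_abs_relative_error"] < 0.05

    def test_relevance_default_covers_canonical_schema(self, healthy_frame):
        metric_cols = [
            c for c in healthy_frame.columns
            if c.endswith(("_ml", "_pct", "_g", "_ml_per_s", "_ml_per_min"))
        ]
        assert set(metric_cols) <= set(DEFAULT_RELEVANCE_ORDER)
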