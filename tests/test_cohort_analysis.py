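"""Cohort comparison: bias tables, effect sizes, correlations."""

import math
import statistics

import numpy as np
import pytest

from shortsprint import (
    CorrectionMode,
    bias_by_distance,
    bias_table,
    cohens_d,
    correlation_tc_vs_kinetics,
    effect_size_label,
    fit_splits,
)
from shortsprint.fitting import FitResult
from shortsprint.model_core import SprintParameters

from test_fitting import make_splits


def _fake_fit(residuals, mode=CorrectionMode.NONE, mss=7.8, tau=1.1, tc=0.0):
    return FitResult(
        parameters=SprintParameters(mss, tau, tc, mode),
        predicted_times=tuple(0.0 for _ in residuals),
        residuals=tuple(residuals),
        rse=0.0, converged=True, n_iterations=1, mode=mode,
    )


class TestCohensD:
    def test_matches_hand_formula(self, rng):
        """Pooled-SD paired d reproduced by independent arithmetic."""
        x = list(rng.normal(7.2, 0.9, size=40))
        y = list(rng.normal(6.6, 0.8, size=40))
        pooled = math.sqrt((statistics.variance(x) + statistics.variance(y)) / 2)
        expected = (statistics.mean(x) - statistics.mean(y)) / pooled
        d, _ = cohens_d(x, y)
        assert d == pytest.approx(expected, abs=1e-12)

    def test_identical_samples_are_trivial(self):
        x = [1.0, 2.0, 3.0]
        d, label = cohens_d(x, x)
        assert d == 0.0 and label == "trivial"

    def test_shift_by_one_pooled_sd_is_moderate(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        sd = x.std(ddof=1)
        d, label = cohens_d(x + sd, x)
        assert d == pytest.approx(1.0, abs=1e-12)
        assert label == "moderate"

    def test_antisymmetric(self, rng):
        x, y = rng.normal(size=10), rng.normal(size=10)
        assert cohens_d(x, y)[0] == pytest.approx(-cohens_d(y, x)[0], abs=1e-15)

    def test_constant_samples_rejected(self):
        with pytest.raises(ValueError, match="pooled SD"):
            cohens_d([2.0, 2.0, 2.0], [3.0, 3.0, 3.0])

    @pytest.mark.parametrize("d, label", [
        (0.19, "trivial"), (0.2, "trivial"),       # boundary ties -> lower band
        (0.21, "small"), (0.6, "small"),
        (0.61, "moderate"), (1.20, "moderate"),
        (1.21, "large"), (2.0, "large"),
        (2.1, "very large"), (4.0, "very large"),
        (-3.4, "very large"),                       # magnitude-based
    ])
    def test_magnitude_bands(self, d, label):
        assert effect_size_label(d) == label


class TestBiasTable:
    def test_perfect_fits_have_zero_bias(self):
        fits = {CorrectionMode.ESTIMATED: [_fake_fit([0.0] * 5) for _ in range(4)]}
        df = bias_by_distance(fits)
        assert (df["bias"] == 0).all() and (df["n"] == 4).all()

    def test_single_athlete_sd_is_missing_but_bias_defined(self):
        fits = {CorrectionMode.NONE: [_fake_fit([0.02, -0.01, 0.0])]}
        df = bias_by_distance(fits)
        assert df["sd"].isna().all()
        assert list(df["bias"]) == [0.02, -0.01, 0.0]

    def test_mean_matches_independent_aggregation(self, rng):
        resids = rng.normal(0, 0.02, size=(6, 5))
        fits = {CorrectionMode.FIXED: [_fake_fit(r, CorrectionMode.FIXED, tc=0.3)
                                       for r in resids]}
        df = bias_by_distance(fits)
        np.testing.assert_allclose(df["bias"], resids.mean(axis=0), atol=1e-15)
        np.testing.assert_allclose(df["sd"], resids.std(axis=0, ddof=1), atol=1e-15)

    def test_mixed_gate_layouts_rejected(self):
        fits = {CorrectionMode.NONE: [_fake_fit([0.0] * 5), _fake_fit([0.0] * 4)]}
        with pytest.raises(ValueError, match="gate layout"):
            bias_by_distance(fits)

    def test_distance_labels(self):
        fits = {CorrectionMode.NONE: [_fake_fit([0.0, 0.1])]}
        df = bias_table(fits, (5.0, 10.0))
        assert list(df["distance_m"]) == [5.0, 10.0]

    def test_uncorrected_model_biased_at_short_gates(self):
        """Fitting lag-affected splits without a correction leaves larger
        early-gate bias than the estimated-correction fit."""
        splits = [make_splits(7.8 + 0.1 * i, 1.1, tc=0.25, athlete=f"a{i}")
                  for i in range(5)]
        fits = {
            mode: [fit_splits(s, mode) for s in splits]
            for mode in (CorrectionMode.NONE, CorrectionMode.ESTIMATED)
        }
        df = bias_table(fits, (5.0, 10.0, 20.0, 30.0, 35.0)).set_index(["mode", "distance_m"])
        assert abs(df.loc[("none", 5.0), "bias"]) > abs(df.loc[("estimated", 5.0), "bias"])


class TestCorrelations:
    def test_collinear_lag_and_acceleration(self):
        fits = [_fake_fit([0.0], CorrectionMode.ESTIMATED,
                          mss=7.8 + 0.01 * i, tau=1.0 + 0.1 * i, tc=0.1 + 0.05 * i)
                for i in range(5)]
        r = correlation_tc_vs_kinetics(fits)
        # tc rises while mac = mss/tau falls: perfect monotone linear? mac is
        # nonlinear in tau, so only the sign is exact; tc itself is linear in i
        assert r["r_tc_mac"] < -0.99

    def test_hand_computable_four_point_set(self):
        tcs = [0.1, 0.2, 0.3, 0.4]
        macs = [8.0, 7.0, 7.5, 6.0]
        fits = [_fake_fit([0.0], CorrectionMode.ESTIMATED,
                          mss=m * 1.0, tau=1.0, tc=t)  # tau=1 -> mac == mss
                for t, m in zip(tcs, macs)]
        r = correlation_tc_vs_kinetics(fits)
        expected = np.corrcoef(tcs, macs)[0, 1]
        assert r["r_tc_mac"] == pytest.approx(expected, abs=1e-12)
        assert r["r_tc_mss"] == pytest.approx(expected, abs=1e-12)

    def test_independent_draws_uncorrelated(self, rng):
        fits = [_fake_fit([0.0], CorrectionMode.ESTIMATED,
                          mss=rng.uniform(7, 9), tau=1.1, tc=rng.uniform(0.05, 0.5))
                for _ in range(500)]
        r = correlation_tc_vs_kinetics(fits)
        assert abs(r["r_tc_mss"]) < 0.1

    def test_too_few_or_constant_inputs_rejected(self):
        fits = [_fake_fit([0.0], CorrectionMode.ESTIMATED, tc=0.1)] * 2
        with pytest.raises(ValueError, match="at least 3"):
            correlation_tc_vs_kinetics(fits)
        fits = [_fake_fit([0.0], CorrectionMode.ESTIMATED, tc=0.2)] * 5
        with pytest.raises(ValueError, match="constant"):
            correlation_tc_vs_kinetics(fits)
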