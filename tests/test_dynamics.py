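"""Cohort morphometry, lagged cross-covariance, classification, frequency
maps, invasion angles and compartment intensity ratios."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from geltrax import dynamics as dyn
from geltrax import synthetic as syn


def brute_force_ccf(x, y, max_lag):
    """Independent double-loop oracle for the biased 1/n estimator."""
    n = len(x)
    xb, yb = np.mean(x), np.mean(y)
    out = {}
    for k in range(-max_lag, max_lag + 1):
        s = 0.0
        for t in range(n):
            if 0 <= t + k < n:
                s += (x[t] - xb) * (y[t + k] - yb)
        out[k] = s / n
    return out


class TestCrossCovariance:
    def test_autocorrelation_conventions_on_ramp(self):
        x = np.arange(5, dtype=float)
        cc = dyn.cross_covariance(x, x, 1)
        n = 5
        # biased 1/n covariance with ddof-1 SDs: r(0) = (n-1)/n
        assert cc.r[cc.lags == 0][0] == pytest.approx((n - 1) / n, rel=1e-12)
        cc0 = dyn.cross_covariance(x, x, 1, sd_ddof=0)
        assert cc0.r[cc0.lags == 0][0] == pytest.approx(1.0, rel=1e-12)

    def test_constructed_lag_recovered(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=40)
        y = np.roll(x, 2)
        cc = dyn.cross_covariance(x[4:-4], y[4:-4], 3)
        assert cc.peak_lag == 2

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(12, 40))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            max_lag = int(rng.integers(1, (n - 2) // 2))
            cc = dyn.cross_covariance(x, y, max_lag)
            oracle = brute_force_ccf(x, y, max_lag)
            for k, c in oracle.items():
                assert cc.c[cc.lags == k][0] == pytest.approx(c, abs=1e-12)

    def test_white_noise_null_statistics(self):
        rng = np.random.default_rng(4)
        r0 = [dyn.cross_covariance(rng.normal(size=20),
                                   rng.normal(size=20), 1).r[1]
              for _ in range(1000)]
        assert abs(np.mean(r0)) < 0.02
        assert np.std(r0) == pytest.approx(1 / np.sqrt(20), rel=0.2)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            dyn.cross_covariance(np.ones(10), np.arange(10.0), 2)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            dyn.cross_covariance(np.arange(6.0), np.arange(6.0), 3)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_correlation_bounded_and_self_peak_at_zero(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=25)
        cc = dyn.cross_covariance(x, x, 5, sd_ddof=0)
        assert np.all(np.abs(cc.r) <= 1 + 1e-9)
        assert cc.peak_lag == 0

    def test_time_reversal_symmetry(self, rng):
        """Reversing both series swaps the roles of x and y:
        c_{rev(x),rev(y)}(k) = c_yx(k)."""
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        fwd = dyn.cross_covariance(x[::-1], y[::-1], 4)
        rev = dyn.cross_covariance(y, x, 4)
        np.testing.assert_allclose(fwd.c, rev.c, atol=1e-12)


class TestMorphometry:
    def test_absent_cohort_returns_zero_with_warning(self):
        mask = np.zeros((64, 128), bool)
        mask[:, :30] = True
        with pytest.warns(UserWarning, match="no cohort"):
            assert dyn.cohort_length(mask, 30) == 0.0

    def test_rectangular_protrusion_length(self):
        frames = syn.synthesize_cohort_mask_series([40.0], body_cols=30)
        assert dyn.cohort_length(frames[0], 30, pixel_size=0.5) == 20.0

    def test_sawtooth_schedule_recovered_within_one_pixel(self):
        lengths = [5, 15, 25, 10, 20, 30, 15, 25, 35, 20, 30]
        frames = syn.synthesize_cohort_mask_series(lengths, body_cols=30)
        series = dyn.series_from_masks(frames, np.arange(len(lengths)) * 2.0,
                                       body_edge=30)
        np.testing.assert_allclose(series.length, lengths, atol=1.0)

    def test_geodesic_agrees_with_euclidean_for_straight_cohort(self):
        frames = syn.synthesize_cohort_mask_series([40.0], body_cols=30)
        le = dyn.cohort_length(frames[0], 30, method="euclidean")
        lg = dyn.cohort_length(frames[0], 30, method="geodesic")
        assert lg == pytest.approx(le, abs=1.5)

    def test_projected_area_examples(self):
        assert dyn.projected_area(np.zeros((10, 10), bool)) == 0.0
        mask = np.zeros((20, 20), bool)
        mask.ravel()[:100] = True
        assert dyn.projected_area(mask, 0.5) == 25.0

    def test_linear_area_growth_slope_recovered(self):
        rate_px = 2.0  # columns per frame on a 16-row protrusion
        lengths = [rate_px * k for k in range(12)]
        frames = syn.synthesize_cohort_mask_series(lengths, body_cols=20,
                                                   cohort_rows=(24, 40))
        t = np.arange(12.0)
        series = dyn.series_from_masks(frames, t, body_edge=20)
        slope = np.polyfit(t, series.area, 1)[0]
        assert slope == pytest.approx(rate_px * 16, rel=0.05)


class TestClassifyBeads:
    def test_distance_thresholds(self):
        cohort = np.array([[0.0, 0.0, 0.0]])
        pos = np.array([[10.0, 0, 0], [200.0, 0, 0], [50.0, 0, 0]])
        labels = dyn.classify_beads(pos, cohort)
        assert list(labels) == ["near", "far", "far"]  # tie at 50 -> far

    def test_mask_based_classification(self):
        mask = np.zeros((100, 100), bool)
        mask[40:60, 40:60] = True
        pos = np.array([[50.0, 65.0], [50.0, 99.0]])
        labels = dyn.classify_beads(pos, mask, threshold=20.0, pixel_size=1.0)
        assert list(labels) == ["near", "far"]

    def test_generator_coupled_beads_all_near(self, material):
        """Beads from a cavity scene within 50 um of the tissue surface are
        labelled near, beads farther out far, with zero misclassification."""
        rng = np.random.default_rng(8)
        surface_pts = 50.0 * _unit_sphere(rng, 200)
        beads = np.vstack([52.0 * _unit_sphere(rng, 30),
                           90.0 * _unit_sphere(rng, 30),
                           150.0 * _unit_sphere(rng, 30)])
        labels = dyn.classify_beads(beads, surface_pts)
        d = np.linalg.norm(beads, axis=1)
        expected = np.where(d < 98.0, "near", "far")  # 50 um from r=50 shell
        # allow the surface sampling gap: check the unambiguous shells
        assert list(labels[:30]) == ["near"] * 30
        assert list(labels[60:]) == ["far"] * 30


def _unit_sphere(rng, n):
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


class TestNearFarReport:
    def _series(self, seed=0, **kw):
        spec = syn.CoupledSeriesSpec(seed=seed, **kw)
        out = syn.synthesize_coupled_series(spec)
        cohort = dyn.CohortTimeSeries(out["times"], out["length"], out["area"])
        beads = [dyn.BeadSeries(f"n{i}", out["times"], s, "near")
                 for i, s in enumerate(out["near"])]
        beads += [dyn.BeadSeries(f"f{i}", out["times"], s, "far")
                  for i, s in enumerate(out["far"])]
        return cohort, beads

    def test_identical_copies_flagged_degenerate(self):
        t = np.arange(0, 42, 2.0)
        L = 50 + 1.5 * t + 8 * np.sin(2 * np.pi * t / 16)
        cohort = dyn.CohortTimeSeries(t, L)
        beads = [dyn.BeadSeries(f"b{i}", t, L.copy(), "near") for i in range(3)]
        beads += [dyn.BeadSeries(f"f{i}", t, L + i, "far") for i in range(3)]
        rep = dyn.near_far_correlation_report(cohort, beads)
        assert rep["zero_variance"]
        # biased 1/n covariance with ddof-1 SDs on the n=20 differenced
        # series: perfect coupling peaks at (n-1)/n
        assert rep["near_mean_r"] == pytest.approx(19 / 20, abs=1e-9)

    def test_lagged_coupling_recovered(self):
        cohort, beads = self._series(seed=5, lag=2)
        rep = dyn.near_far_correlation_report(cohort, beads)
        lags = [row["peak_lag"] for row in
                rep["per_bead"].to_dict(orient="records")
                if row["class"] == "near"]
        assert int(np.median(lags)) == 2
        assert rep["near_mean_r"] > rep["far_mean_r"]
        assert rep["p_value"] < 0.01

    def test_insufficient_class_rejected(self):
        cohort, beads = self._series(seed=1)
        with pytest.raises(ValueError, match="far"):
            dyn.near_far_correlation_report(
                cohort, [b for b in beads if b.distance_class == "near"]
                + beads[-2:])


class TestFrequencyMap:
    def test_identical_masks_give_binary_map(self):
        base = syn.make_disk_mask((32, 32), 8.0)
        fm = dyn.frequency_map(np.stack([base] * 7))
        np.testing.assert_array_equal(fm.frequency, base.astype(float))

    def test_single_mask_contribution_is_one_over_n(self):
        base = syn.make_disk_mask((32, 32), 8.0)
        stack = np.stack([base] * 50)
        extra = base.copy()
        extra[0, 0] = True
        stack[7] = extra
        fm = dyn.frequency_map(stack)
        assert fm.frequency[0, 0] == pytest.approx(0.02)

    def test_values_are_exact_rationals(self, rng):
        stack = rng.random((10, 16, 16)) > 0.5
        fm = dyn.frequency_map(stack)
        counts = fm.frequency * 10
        np.testing.assert_array_equal(counts, np.round(counts))

    def test_union_dominates_each_mask(self, rng):
        stack = rng.random((8, 16, 16)) > 0.6
        fm = dyn.frequency_map(stack)
        union = dyn.frequency_map(
            np.stack([np.logical_or.reduce(stack, axis=0)] * 8))
        assert np.all(union.frequency >= fm.frequency)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="n_tissues"):
            dyn.frequency_map(np.zeros((4, 4)))


class TestInvasionAngles:
    def test_single_eastward_cohort_is_zero_degrees(self):
        base = syn.make_disk_mask((96, 96), 20.0)
        spec = syn.CohortAngleSpec(distribution="vonmises", mean_deg=0.0,
                                   kappa=1e6)
        stack, _ = syn.synthesize_mask_stack(1, base, spec, seed=0)
        res = dyn.invasion_angles(stack, base_mask=base)
        assert len(res["angles"]) == 1
        assert min(res["angles"][0], 360 - res["angles"][0]) < 5.0

    def test_vonmises_mean_recovered(self):
        base = syn.make_disk_mask((96, 96), 20.0)
        spec = syn.CohortAngleSpec(distribution="vonmises", mean_deg=90.0,
                                   kappa=4.0)
        stack, _ = syn.synthesize_mask_stack(83, base, spec, seed=2)
        res = dyn.invasion_angles(stack, base_mask=base)
        d = abs((res["circular_mean"] - 90.0 + 180.0) % 360.0 - 180.0)
        assert d <= 10.0
        assert res["rayleigh_p"] < 0.01

    def test_no_cohorts_warns(self):
        base = syn.make_disk_mask((64, 64), 12.0)
        stack = np.stack([base] * 4)
        with pytest.warns(UserWarning, match="no cohorts"):
            res = dyn.invasion_angles(stack, base_mask=base)
        assert res["angles"].size == 0


class TestNuclearCytoplasmicRatio:
    def _masks(self):
        cell = syn.make_disk_mask((64, 64), 20.0)
        nuc = syn.make_disk_mask((64, 64), 8.0)
        return nuc, cell

    def test_uniform_image_ratio_one(self):
        nuc, cell = self._masks()
        img = np.full((64, 64), 100.0)
        assert dyn.nuclear_cytoplasmic_ratio(img, nuc, cell, background=0.0) \
            == pytest.approx(1.0)

    def test_constructed_two_to_one(self):
        nuc, cell = self._masks()
        img = np.zeros((64, 64))
        img[cell] = 100.0
        img[nuc] = 200.0
        assert dyn.nuclear_cytoplasmic_ratio(img, nuc, cell) == \
            pytest.approx(2.0)

    def test_poisson_noise_recovery_over_cells(self):
        """50 synthetic cells with true ratio 1.8 under Poisson counting
        noise: the mean recovered ratio is within +/- 0.1."""
        nuc, cell = self._masks()
        rng = np.random.default_rng(6)
        ratios = []
        for _ in range(50):
            img = np.full((64, 64), 5.0)
            img[cell] = 100.0
            img[nuc] = 180.0
            noisy = rng.poisson(img).astype(float)
            ratios.append(dyn.nuclear_cytoplasmic_ratio(noisy, nuc, cell))
        # background 5 is subtracted: (180-5)/(100-5) ~ 1.84
        assert np.mean(ratios) == pytest.approx(1.84, abs=0.1)

    def test_nuclear_outside_cell_rejected(self):
        nuc = syn.make_disk_mask((64, 64), 30.0)
        cell = syn.make_disk_mask((64, 64), 20.0)
        with pytest.raises(ValueError, match="within"):
            dyn.nuclear_cytoplasmic_ratio(np.ones((64, 64)), nuc, cell)

    def test_empty_cytoplasm_rejected(self):
        cell = syn.make_disk_mask((64, 64), 20.0)
        with pytest.raises(ValueError, match="empty"):
            dyn.nuclear_cytoplasmic_ratio(np.ones((64, 64)), cell, cell)
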