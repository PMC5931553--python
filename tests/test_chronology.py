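"""Chronology: excess 210Pb, CRS dating, tie points, age-depth fitting."""

import numpy as np
import pandas as pd
import pytest

import arclake.chronology as ch
from arclake.synthetic import SedimentScenario, gen_core, synthetic_bomb_curve


def make_profile(pb, ra, cs=None, pb_sd=None, ra_sd=None, mass=0.1):
    n = len(pb)
    z = np.zeros(n)
    cs = np.zeros(n) if cs is None else np.asarray(cs, float)
    return ch.IsotopeProfile(
        depth_top=np.arange(n, dtype=float),
        depth_bottom=np.arange(1, n + 1, dtype=float),
        dry_mass=np.full(n, mass),
        pb210=pb,
        pb210_sigma=z if pb_sd is None else np.asarray(pb_sd, float),
        ra226=ra,
        ra226_sigma=z if ra_sd is None else np.asarray(ra_sd, float),
        cs137=cs,
        cs137_sigma=z,
    )


class TestExcessPb:
    def test_subtraction_and_quadrature(self):
        prof = make_profile(
            pb=[150.0, 120, 90], ra=[50.0, 50, 50], pb_sd=[4.0, 4, 4], ra_sd=[3.0, 3, 3]
        )
        ex = ch.excess_pb210(prof, tail="none")
        assert ex.excess[0] == pytest.approx(100.0)
        assert ex.excess_sigma[0] == pytest.approx(5.0)  # sqrt(16+9)

    def test_constant_excess_inventory_linear(self):
        n = 6
        prof = make_profile(pb=[140.0] * n, ra=[40.0] * n)
        ex = ch.excess_pb210(prof, tail="none")
        # inventory below slice k proportional to remaining slice count
        expect = np.arange(n - 1, -1, -1, dtype=float)
        assert np.allclose(ex.inventory_below / ex.inventory_below[0], expect / expect[0])

    def test_negative_excess_clamped_with_warning(self):
        prof = make_profile(pb=[100.0, 30, 90], ra=[50.0, 50, 50])
        with pytest.warns(UserWarning, match="clamped"):
            ex = ch.excess_pb210(prof, tail="none")
        assert ex.excess[1] == 0.0
        assert ex.clamped[1] and not ex.clamped[0]

    def test_missing_slices_interpolated(self):
        pb = [150.0, np.nan, 90, 70, 60]
        ra = [50.0, np.nan, 50, 50, 50]
        ex = ch.excess_pb210(make_profile(pb, ra), tail="none")
        assert ex.interpolated[1] and not ex.interpolated[0]
        assert ex.excess[1] == pytest.approx(70.0)  # midway between 100 and 40

    def test_inventory_matches_analytic_integral(self, constant_rate_core):
        profile, truth = constant_rate_core
        ex = ch.excess_pb210(profile)
        z = ex.depth_bottom[:-2]
        expect = truth.excess_inventory_below(z)
        assert np.allclose(ex.inventory_below[:-2], expect, rtol=0.01)

    def test_requires_three_measured_slices(self):
        prof = make_profile(pb=[100.0, np.nan, np.nan, np.nan], ra=[50.0, np.nan, np.nan, np.nan])
        with pytest.raises(ValueError):
            ch.excess_pb210(prof)


class TestCrs:
    def test_surface_age_zero(self):
        assert ch.crs_age(1.0, 1.0) == pytest.approx(0.0)

    def test_half_inventory_is_one_half_life(self):
        assert ch.crs_age(1.0, 0.5) == pytest.approx(ch.PB210_HALF_LIFE_YR)

    def test_zero_inventory_is_an_error(self):
        with pytest.raises(ValueError):
            ch.crs_age(1.0, 0.0)

    def test_constant_rate_recovery_under_one_year(self, constant_rate_core):
        profile, truth = constant_rate_core
        ex = ch.excess_pb210(profile)
        ties = ch.crs_ages(ex, collection_year=2015.0, n_monte_carlo=0)
        errs = [abs(t.age - truth.age_at_depth(t.depth)) for t in ties
                if t.age > 1915.0]
        assert max(errs) < 1.0

    def test_two_epoch_recovery_within_one_percent(self, two_epoch_core):
        profile, truth = two_epoch_core
        ex = ch.excess_pb210(profile)
        ties = ch.crs_ages(ex, collection_year=2015.0, n_monte_carlo=0)
        for t in ties:
            t_true = 2015.0 - truth.age_at_depth(t.depth)
            if t_true > 1.0:
                assert abs((2015.0 - t.age) - t_true) / t_true < 0.01

    def test_rescaling_invariance(self, constant_rate_core):
        profile, _ = constant_rate_core
        ex = ch.excess_pb210(profile)
        scaled = ch.ExcessPbProfile(
            **{**ex.__dict__,
               "excess": 3.7 * ex.excess,
               "excess_sigma": 3.7 * ex.excess_sigma,
               "slice_inventory": 3.7 * ex.slice_inventory,
               "inventory_below": 3.7 * ex.inventory_below,
               "total_inventory": 3.7 * ex.total_inventory,
               "tail_inventory": 3.7 * ex.tail_inventory}
        )
        a = ch.crs_ages(ex, 2015.0, n_monte_carlo=0)
        b = ch.crs_ages(scaled, 2015.0, n_monte_carlo=0)
        assert np.allclose([t.age for t in a], [t.age for t in b])

    def test_monte_carlo_sigma_scales_with_activity_sigma(self, constant_rate_core):
        profile, _ = constant_rate_core
        ex = ch.excess_pb210(profile)
        base = ex.__dict__
        sig_small = ch.ExcessPbProfile(**{**base, "excess_sigma": 0.02 * ex.excess})
        sig_large = ch.ExcessPbProfile(**{**base, "excess_sigma": 0.04 * ex.excess})
        a = ch.crs_ages(sig_small, 2015.0, n_monte_carlo=400, seed=5)
        b = ch.crs_ages(sig_large, 2015.0, n_monte_carlo=400, seed=5)
        ratio = np.array([tb.age_sigma for tb in b]) / np.array([ta.age_sigma for ta in a])
        assert np.median(ratio) == pytest.approx(2.0, rel=0.25)

    def test_zero_measurement_sigma_gives_zero_age_sigma(self, constant_rate_core):
        profile, _ = constant_rate_core
        ex = ch.excess_pb210(profile)
        ties = ch.crs_ages(ex, 2015.0, n_monte_carlo=500, seed=1)
        assert all(t.age_sigma == 0.0 for t in ties)

    def test_reference_date_crs_fixes_varying_rate_bias(self, default_core):
        # the multi-epoch core defeats activity extrapolation of the deep
        # inventory; a 1963 reference horizon must restore accurate ages
        profile, truth = default_core
        ex = ch.excess_pb210(profile)
        ref = (truth.cs_peak_depth, 1963.0)
        ties = ch.crs_ages(ex, 2015.0, n_monte_carlo=0, reference=ref)
        errs = [abs(t.age - truth.age_at_depth(t.depth)) for t in ties]
        # sub-slice interpolation granularity leaves ~1 yr at the very base
        assert max(errs) < 2.0
        assert np.median(errs) < 0.5
        # without the reference, the deep-inventory extrapolation is biased
        ties_plain = ch.crs_ages(ex, 2015.0, n_monte_carlo=0)
        errs_plain = [abs(t.age - truth.age_at_depth(t.depth)) for t in ties_plain]
        assert max(errs_plain) > max(errs)

    def test_parameter_recovery_on_random_noisy_scenarios(self):
        """Median CRS age error < 5 yr post-1950 across 20 random histories."""
        rng = np.random.default_rng(2024)
        medians = []
        for k in range(20):
            n_ep = int(rng.integers(2, 5))
            bounds = np.sort(rng.uniform(1915, 2005, n_ep - 1))
            years = np.concatenate([[1900.0], bounds, [2015.0]])
            rates = np.sort(rng.uniform(0.005, 0.02, n_ep))
            epochs = tuple((years[i], years[i + 1], rates[i]) for i in range(n_ep))
            sc = SedimentScenario(epochs=epochs, noise_cv=0.05,
                                  seed=int(rng.integers(2**31)))
            profile, truth = gen_core(sc)
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ex = ch.excess_pb210(profile)
                cs = ch.detect_cs137_peak(profile)
                ties = ch.crs_ages(ex, 2015.0, n_monte_carlo=0, reference=cs.tie)
            errs = [abs(t.age - truth.age_at_depth(t.depth))
                    for t in ties if truth.age_at_depth(t.depth) > 1950.0]
            medians.append(np.median(errs))
        assert np.median(medians) < 5.0


class TestCs137Peak:
    def test_synthetic_pulse_located(self, default_core):
        profile, truth = default_core
        peak = ch.detect_cs137_peak(profile)
        assert peak.interior_peak
        assert peak.tie.depth == pytest.approx(truth.cs_peak_depth, abs=0.5)
        assert peak.tie.age == 1962.5 and peak.tie.age_sigma == 1.0
        assert peak.window_top <= truth.cs_peak_depth <= peak.window_bottom

    def test_monotone_profile_flags_boundary_maximum(self):
        prof = make_profile(pb=[100.0] * 4, ra=[50.0] * 4, cs=[40.0, 30, 20, 10])
        peak = ch.detect_cs137_peak(prof)
        assert peak.tie.depth == 0.5
        assert not peak.interior_peak

    def test_ties_break_shallow(self):
        prof = make_profile(pb=[100.0] * 4, ra=[50.0] * 4, cs=[10.0, 30, 30, 10])
        assert ch.detect_cs137_peak(prof).tie.depth == 1.5

    def test_no_signal_raises(self):
        prof = make_profile(pb=[100.0] * 4, ra=[50.0] * 4, cs=[0.0, 0, 0, 0])
        with pytest.raises(ValueError, match="signal"):
            ch.detect_cs137_peak(prof)


class TestBombCalibration:
    def test_unique_crossing_on_monotone_curve(self):
        curve = pd.DataFrame({
            "year_ad": np.arange(1955, 1965),
            "f14c_percent": np.linspace(101, 190, 10),
            "f14c_sd": 1e-9,
        })
        sample = ch.RadiocarbonSample(curve["f14c_percent"].iloc[4], 1e-9, -28.0, 5.0)
        assert ch.calibrate_bomb_14c(sample, curve) == [(1959, 1959)]

    def test_triangular_curve_two_symmetric_intervals(self):
        years = np.arange(1955, 1974)
        f = 190.0 - 10.0 * np.abs(years - 1964)
        curve = pd.DataFrame({"year_ad": years, "f14c_percent": f, "f14c_sd": 0.5})
        sample = ch.RadiocarbonSample(150.0, 4.0, -28.0, 5.0)
        got = ch.calibrate_bomb_14c(sample, curve)
        # brute-force oracle over the same grid
        tol = np.sqrt(16.0 + 0.25)
        ok = np.abs(150.0 - f) <= tol
        runs = []
        start = None
        for y, flag in zip(years, ok):
            if flag and start is None:
                start = y
            if not flag and start is not None:
                runs.append((start, y - 1))
                start = None
        if start is not None:
            runs.append((start, years[-1]))
        assert got == runs and len(got) == 2
        lo, hi = got
        assert (1964 - lo[1]) == (hi[0] - 1964)  # symmetric about the peak

    def test_two_limb_intervals_on_synthetic_bomb_curve(self):
        curve = synthetic_bomb_curve()
        sample = ch.RadiocarbonSample(144.62, 4.4, -33.73, 5.0)
        intervals = ch.calibrate_bomb_14c(sample, curve)
        assert len(intervals) == 2
        assert intervals[0][1] < 1964 < intervals[1][0]

    def test_no_intersection_raises(self):
        curve = synthetic_bomb_curve()
        with pytest.raises(ValueError, match="envelope"):
            ch.calibrate_bomb_14c(ch.RadiocarbonSample(400.0, 0.1, -28.0, 5.0), curve)

    def test_pre_bomb_sample_rejected(self):
        with pytest.raises(ValueError, match="post-bomb"):
            ch.calibrate_bomb_14c(
                ch.RadiocarbonSample(95.0, 1.0, -28.0, 5.0), synthetic_bomb_curve()
            )


class TestAgeDepthFit:
    def test_collinear_points_give_degenerate_quadratic(self):
        pts = [ch.TiePoint(d, 2015.0 - 2.0 * d, 1.0, "crs") for d in (2.0, 5.0, 9.0)]
        m = ch.fit_age_depth(pts, 2015.0, add_surface=False)
        assert abs(m.a) < 1e-9
        for p in pts:
            assert m.age_at(p.depth) == pytest.approx(p.age, abs=1e-6)

    def test_exact_quadratic_recovered(self):
        truth = lambda d: 2015.0 - 0.5 * d - 0.05 * d**2
        pts = [ch.TiePoint(d, truth(d), 1.0, "crs") for d in (3.0, 11.0, 20.0)]
        m = ch.fit_age_depth(pts, 2015.0, add_surface=False)
        assert m.a == pytest.approx(-0.05, abs=1e-6)
        assert m.b == pytest.approx(-0.5, abs=1e-6)
        assert m.c == pytest.approx(2015.0, abs=1e-6)
        assert m.sedimentation_rate(0.0) == pytest.approx(2.0)

    def test_non_monotone_points_raise(self):
        pts = [
            ch.TiePoint(2.0, 1990.0, 0.1, "crs"),
            ch.TiePoint(5.0, 2010.0, 0.1, "crs"),
            ch.TiePoint(9.0, 1950.0, 0.1, "crs"),
        ]
        with pytest.raises(ch.NonMonotoneAgeModelError):
            ch.fit_age_depth(pts, 2015.0)

    def test_surface_point_is_honoured(self):
        pts = [ch.TiePoint(d, 2015.0 - 3.0 * d, 2.0, "crs") for d in (2.0, 5.0, 8.0)]
        m = ch.fit_age_depth(pts, 2015.0)
        assert abs(m.age_at(0.0) - 2015.0) <= 1.0

    def test_evaluation_outside_range_raises(self):
        pts = [ch.TiePoint(d, 2015.0 - 2.0 * d, 1.0, "crs") for d in (2.0, 5.0, 9.0)]
        m = ch.fit_age_depth(pts, 2015.0)
        with pytest.raises(ValueError):
            m.age_at(12.0)

    def test_linear_model_constant_rate(self):
        pts = [ch.TiePoint(d, 2015.0 - 10.0 * d, 0.0, "crs") for d in (1.0, 4.0, 7.0)]
        m = ch.fit_age_depth(pts, 2015.0)
        assert ch.sedimentation_rate(m, 3.0) == pytest.approx(0.1)
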