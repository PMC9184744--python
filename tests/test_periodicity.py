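"""Correlation statistics: oracles, closed-form cosine cases, and recovery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mpskit.errors import AnalysisError
from mpskit.io import SegmentROI
from mpskit.periodicity import (
    CorrelationCurve,
    Profile1D,
    align_and_average,
    autocorrelation,
    average_curves,
    bin_profile,
    compare_conditions,
    cross_correlation,
    estimate_phase,
    periodicity_metrics,
    project_to_axis,
)


def brute_force_autocorrelation(counts, n_lags):
    """Independent double-loop estimator: mean-subtracted, overlap-normalized."""
    c = np.asarray(counts, float)
    n = c.size
    mean, var = c.mean(), c.var()
    out = []
    for lag in range(n_lags):
        acc = 0.0
        for i in range(n - lag):
            acc += (c[i] - mean) * (c[i + lag] - mean)
        out.append(acc / (n - lag) / var)
    return np.array(out)


def brute_force_cross_correlation(a, b, n_lags):
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n = a.size
    da, db = a - a.mean(), b - b.mean()
    norm = math.sqrt(a.var() * b.var())
    out = []
    for lag in range(-n_lags, n_lags + 1):
        acc = 0.0
        cnt = 0
        for i in range(n):
            j = i + lag
            if 0 <= j < n:
                acc += da[i] * db[j]
                cnt += 1
        out.append(acc / cnt / norm)
    return np.array(out)


def cosine_profile(period=190.0, bin_size=10.0, length=2000.0, phase_nm=0.0, offset=2.0):
    n = int(length / bin_size)
    x = (np.arange(n) + 0.5) * bin_size
    return Profile1D(bin_size, 0.0, offset + np.cos(2 * np.pi * (x - phase_nm) / period))


class TestProjectToAxis:
    def _frame(self, xy):
        import pandas as pd

        xy = np.asarray(xy, float)
        return pd.DataFrame({"x_nm": xy[:, 0], "y_nm": xy[:, 1]})

    def test_collinear_points_project_to_distances(self):
        pos = project_to_axis(self._frame([(0, 0), (100, 0), (200, 0)]), "auto")
        assert np.allclose(np.sort(pos), [0, 100, 200])

    def test_rotation_invariance(self):
        c, s = math.cos(math.pi / 4), math.sin(math.pi / 4)
        pts = np.array([(0, 0), (100, 0), (200, 0)]) @ np.array([[c, -s], [s, c]]).T
        pos = project_to_axis(self._frame(pts), "auto")
        assert np.allclose(np.sort(pos), [0, 100, 200], atol=1e-6)

    def test_axis_matches_closed_form_eigenvector(self):
        """Compare the fitted axis with an explicit 2x2 eigen-solution."""
        rng = np.random.default_rng(0)
        xy = np.column_stack([rng.normal(0, 100, 10), rng.normal(0, 10, 10)])
        theta = 0.6
        rot = np.array([[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]])
        xy = xy @ rot.T
        pos = project_to_axis(self._frame(xy), "auto")
        # closed-form principal eigenvector of [[a, b], [b, c]]
        centered = xy - xy.mean(axis=0)
        a, b, c = (
            (centered[:, 0] ** 2).mean(),
            (centered[:, 0] * centered[:, 1]).mean(),
            (centered[:, 1] ** 2).mean(),
        )
        lam = 0.5 * (a + c + math.sqrt((a - c) ** 2 + 4 * b * b))
        v = np.array([b, lam - a])
        v = v / np.linalg.norm(v)
        expected = centered @ v
        expected -= expected.min()
        assert np.allclose(np.sort(pos), np.sort(expected), atol=1e-9) or np.allclose(
            np.sort(pos), np.sort(expected.max() - expected), atol=1e-9
        )

    def test_single_point_rejected(self):
        with pytest.raises(AnalysisError):
            project_to_axis(self._frame([(0, 0)]), "auto")

    def test_explicit_roi_gives_axial_coordinate(self):
        roi = SegmentROI((100.0, 0.0), (100.0, 1000.0), 50.0)
        pos = project_to_axis(self._frame([(100, 0), (100, 250)]), roi)
        assert np.allclose(pos, [0, 250])


class TestBinProfile:
    def test_two_positions_two_bins(self):
        p = bin_profile(np.array([5.0, 15.0]), 10.0, (0.0, 20.0))
        assert list(p.counts) == [1.0, 1.0]

    def test_interior_edge_goes_to_upper_bin(self):
        p = bin_profile(np.array([10.0]), 10.0, (0.0, 20.0))
        assert list(p.counts) == [0.0, 1.0]

    def test_positions_outside_range_dropped(self):
        p = bin_profile(np.array([-1.0, 5.0, 20.0]), 10.0, (0.0, 20.0))
        assert p.counts.sum() == 1

    def test_uniform_positions_pass_chi_square(self):
        rng = np.random.default_rng(1)
        p = bin_profile(rng.uniform(0, 1000, 1000), 10.0, (0.0, 1000.0))
        stat, pval = stats.chisquare(p.counts)
        assert pval > 0.01

    def test_empty_range_rejected(self):
        with pytest.raises(AnalysisError):
            bin_profile(np.array([1.0]), 10.0, (5.0, 5.0))


class TestAutocorrelation:
    def test_constant_profile_degenerate(self):
        g = autocorrelation(Profile1D(10.0, 0.0, np.full(100, 3.0)), 300.0)
        assert g.degenerate
        assert np.allclose(g.values, 0.0)

    def test_cosine_autocorrelation_is_cosine(self):
        g = autocorrelation(cosine_profile(), 400.0)
        assert g.value_at(190.0) == pytest.approx(1.0, abs=0.05)
        assert g.value_at(95.0) == pytest.approx(-1.0, abs=0.05)

    def test_small_profile_matches_double_loop_oracle(self):
        g = autocorrelation(Profile1D(1.0, 0.0, np.array([1.0, 2, 3, 4])), 2.0)
        assert np.allclose(g.values, brute_force_autocorrelation([1, 2, 3, 4], 3), atol=1e-12)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_oracle_equivalence_on_random_profiles(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(4.0, size=rng.integers(10, 50)).astype(float)
        if counts.var() == 0:
            return
        n_lags = counts.size // 2
        g = autocorrelation(Profile1D(1.0, 0.0, counts), float(n_lags - 1))
        assert np.allclose(g.values, brute_force_autocorrelation(counts, n_lags), atol=1e-10)

    def test_normalization_at_zero_lag(self):
        rng = np.random.default_rng(2)
        g = autocorrelation(Profile1D(10.0, 0.0, rng.poisson(5, 100).astype(float)), 300.0)
        assert g.values[0] == pytest.approx(1.0)

    def test_too_short_profile_rejected(self):
        with pytest.raises(AnalysisError):
            autocorrelation(Profile1D(10.0, 0.0, np.arange(10.0)), 600.0)


class TestCrossCorrelation:
    def test_identical_profiles_peak_one_at_zero(self):
        p = cosine_profile()
        cc = cross_correlation(p, p, 400.0)
        assert cc.value_at(0.0) == pytest.approx(1.0)
        # overlap normalization can nudge repeat peaks a hair above 1
        assert cc.values.max() == pytest.approx(1.0, abs=0.01)

    def test_forward_shift_moves_extremum_to_positive_lag(self):
        """b = a circularly shifted forward 3 bins -> extremum at +3 bins."""
        p = cosine_profile(period=200.0, bin_size=10.0)
        b = Profile1D(10.0, 0.0, np.roll(p.counts, 3))
        cc = cross_correlation(p, b, 400.0)
        # restrict to within half a period of zero: the curve repeats every period
        near = np.abs(cc.lags) <= 100.0
        peak_lag = cc.lags[near][np.argmax(cc.values[near])]
        assert peak_lag == pytest.approx(30.0)

    def test_half_period_cosines(self):
        a = cosine_profile(period=190.0)
        b = cosine_profile(period=190.0, phase_nm=95.0)
        cc = cross_correlation(a, b, 400.0)
        assert cc.value_at(0.0) == pytest.approx(-1.0, abs=0.05)
        positive = cc.lags > 0
        first_max_lag = cc.lags[positive][np.argmax(cc.values[positive][:19])]
        assert abs(first_max_lag - 95.0) <= 10.0

    def test_symmetry_between_argument_order(self):
        rng = np.random.default_rng(3)
        a = Profile1D(10.0, 0.0, rng.poisson(5, 80).astype(float))
        b = Profile1D(10.0, 0.0, rng.poisson(5, 80).astype(float))
        ab = cross_correlation(a, b, 300.0)
        ba = cross_correlation(b, a, 300.0)
        assert np.allclose(ab.values, ba.values[::-1], atol=1e-12)

    def test_self_cross_correlation_equals_autocorrelation(self):
        rng = np.random.default_rng(4)
        p = Profile1D(10.0, 0.0, rng.poisson(5, 80).astype(float))
        cc = cross_correlation(p, p, 300.0)
        g = autocorrelation(p, 300.0)
        assert np.allclose(cc.values[cc.lags >= 0], g.values, atol=1e-12)

    def test_oracle_equivalence(self):
        rng = np.random.default_rng(5)
        a = rng.poisson(4, 40).astype(float)
        b = rng.poisson(4, 40).astype(float)
        cc = cross_correlation(Profile1D(1.0, 0.0, a), Profile1D(1.0, 0.0, b), 15.0)
        assert np.allclose(cc.values, brute_force_cross_correlation(a, b, 15), atol=1e-10)

    def test_mismatched_binning_rejected(self):
        a = Profile1D(10.0, 0.0, np.arange(50.0))
        b = Profile1D(5.0, 0.0, np.arange(50.0))
        with pytest.raises(AnalysisError):
            cross_correlation(a, b, 100.0)


class TestAverageCurves:
    def _curve(self, values):
        values = np.asarray(values, float)
        return CorrelationCurve(np.arange(values.size) * 10.0, values)

    def test_average_of_identical_curves_is_that_curve(self):
        c = self._curve([1.0, 0.5, -0.2])
        avg = average_curves([c, c, c])
        assert np.allclose(avg.values, c.values)
        assert avg.n_segments_averaged == 3

    def test_average_of_curve_and_negation_is_zero(self):
        c = self._curve([1.0, 0.5, -0.2])
        neg = self._curve([-1.0, -0.5, 0.2])
        assert np.allclose(average_curves([c, neg]).values, 0.0)

    def test_degenerate_curves_excluded(self):
        c = self._curve([1.0, 0.5])
        d = CorrelationCurve(c.lags, np.zeros(2), degenerate=True)
        avg = average_curves([c, d])
        assert np.allclose(avg.values, c.values)
        assert avg.n_segments_averaged == 1

    def test_all_degenerate_rejected(self):
        d = CorrelationCurve(np.array([0.0]), np.array([0.0]), degenerate=True)
        with pytest.raises(AnalysisError):
            average_curves([d])


class TestPeriodicityMetrics:
    def test_sampled_cosine_period_and_amplitude(self):
        g = autocorrelation(cosine_profile(), 400.0)
        result = periodicity_metrics(g)
        assert abs(result.period - 190.0) <= 10.0
        assert result.amplitude == pytest.approx(2.0, abs=0.1)

    def test_hand_built_curve_arithmetic(self):
        lags = np.arange(0, 400.0, 10.0)
        values = np.zeros_like(lags)
        values[lags == 180.0] = 0.2
        values[lags == 90.0] = -0.3
        values[lags == 280.0] = -0.1
        result = periodicity_metrics(CorrelationCurve(lags, values))
        assert result.amplitude == pytest.approx(0.4)
        assert result.period == pytest.approx(180.0)

    def test_degenerate_curve_flagged(self):
        d = CorrelationCurve(np.arange(0, 400.0, 10.0), np.zeros(40), degenerate=True)
        result = periodicity_metrics(d)
        assert result.degenerate and result.amplitude == 0.0 and result.period is None

    def test_short_curve_rejected(self):
        c = CorrelationCurve(np.arange(0, 100.0, 10.0), np.zeros(10))
        with pytest.raises(AnalysisError):
            periodicity_metrics(c)


class TestEstimatePhase:
    def test_cosine_crest_at_origin_has_zero_phase(self):
        est = estimate_phase(cosine_profile(), 190.0)
        assert min(est.phase, 2 * np.pi - est.phase) < 0.05
        assert est.strength > 0.5

    def test_half_period_shift_gives_pi(self):
        est = estimate_phase(cosine_profile(phase_nm=95.0), 190.0)
        assert est.phase == pytest.approx(np.pi, abs=0.05)

    def test_flat_profile_returns_zero_strength(self):
        est = estimate_phase(Profile1D(10.0, 0.0, np.full(100, 2.0)), 190.0)
        assert est.strength == 0.0 and est.phase == 0.0

    def test_recovers_generator_phase_on_noisy_segment(self):
        """Phase of a simulated noisy segment matches the generator ground truth."""
        from mpskit.pipeline import segment_profiles
        from mpskit.simulate import MPSSimConfig, simulate_mps_localizations

        cfg = MPSSimConfig(n_segments=6, seed=17)
        table, rois, truth = simulate_mps_localizations(cfg)
        profiles = segment_profiles(table, rois)
        d = cfg.ring_spacing
        tol = 2 * np.pi * (10.0 / d)
        for profile, phi_nm in zip(profiles, truth.phases):
            est = estimate_phase(profile, d)
            expected = 2 * np.pi * phi_nm / d
            delta = abs((est.phase - expected + np.pi) % (2 * np.pi) - np.pi)
            assert delta < tol


class TestAlignAndAverage:
    def test_zero_phases_give_plain_average(self):
        # an integer number of periods makes the phase estimate exactly zero
        profiles = [cosine_profile(phase_nm=0.0, length=1900.0) for _ in range(4)]
        ref_avg, par_avg = align_and_average(profiles, profiles, 190.0)
        n = ref_avg.counts.size
        assert np.allclose(ref_avg.counts, profiles[0].counts[:n], atol=1e-9)

    def test_alignment_rescues_random_phase_average(self):
        rng = np.random.default_rng(6)
        phases = rng.uniform(0, 190, 30)
        profiles = [cosine_profile(phase_nm=p) for p in phases]
        ref_avg, _ = align_and_average(profiles, profiles, 190.0)
        aligned_amp = ref_avg.counts.max() - ref_avg.counts.min()
        unaligned = np.mean([p.counts[: ref_avg.counts.size] for p in profiles], axis=0)
        unaligned_amp = unaligned.max() - unaligned.min()
        single_amp = profiles[0].counts.max() - profiles[0].counts.min()
        assert aligned_amp > 0.9 * single_amp
        assert unaligned_amp < 0.3 * single_amp

    def test_partner_offset_preserved_midway(self):
        """Partners a half period from references average midway between crests."""
        rng = np.random.default_rng(7)
        phases = rng.uniform(0, 190, 20)
        refs = [cosine_profile(phase_nm=p) for p in phases]
        partners = [cosine_profile(phase_nm=p + 95.0) for p in phases]
        ref_avg, par_avg = align_and_average(refs, partners, 190.0)
        ref_peak = ref_avg.bin_centers[np.argmax(ref_avg.counts[:19])]
        par_peak = par_avg.bin_centers[np.argmax(par_avg.counts[:19])]
        assert abs(abs(par_peak - ref_peak) - 95.0) <= 10.0

    def test_length_mismatch_rejected(self):
        p = cosine_profile()
        with pytest.raises(AnalysisError):
            align_and_average([p, p], [p], 190.0)


class TestCompareConditions:
    def test_identical_groups_null_result(self):
        r = compare_conditions([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == pytest.approx(0.0) and r.p == pytest.approx(1.0)

    def test_matches_pooled_variance_textbook_formula(self):
        a, b = np.array([1.0, 2, 3]), np.array([2.0, 3, 4])
        r = compare_conditions(a, b)
        sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (a.size + b.size - 2)
        t_expected = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / a.size + 1 / b.size))
        p_expected = 2 * stats.t.sf(abs(t_expected), a.size + b.size - 2)
        assert r.t == pytest.approx(t_expected)
        assert r.p == pytest.approx(p_expected)
        assert r.sem_a == pytest.approx(a.std(ddof=1) / math.sqrt(3))

    def test_zero_variance_groups_handled(self):
        r = compare_conditions([1.0, 1.0], [2.0, 2.0])
        assert r.p == 0.0 and math.isinf(r.t)

    def test_single_value_group_rejected(self):
        with pytest.raises(AnalysisError):
            compare_conditions([1.0], [1.0, 2.0])
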