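"""Linear MF fit, SMFDR calibration, and the N-level fatigue quantizer."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import emgfatigue as ef
from emgfatigue.errors import (
    InputError,
    InsufficientDataError,
    NoFatigueRangeError,
    ParameterError,
)


def _series(times, mf):
    return ef.MFSeries(np.asarray(times, float), np.asarray(mf, float), 10240.0, 2560.0)


def ols_oracle(x, y):
    """Closed-form normal-equations least squares, coded independently."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx, sxy = sum(v * v for v in x), sum(a * b for a, b in zip(x, y))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept


def quantizer_oracle(y, mf0, mfs, n_levels):
    """Brute-force interval scan: (lo, hi] membership, then clamp."""
    delta = (mf0 - mfs) / (n_levels - 1)
    for k in range(n_levels):
        lo = mf0 - (2 * k + 1) * delta / 2.0
        hi = mf0 - (2 * k - 1) * delta / 2.0
        if lo < y <= hi:
            return k
    return 0 if y > mf0 else n_levels - 1


class TestFitMFLine:
    def test_perfect_line(self):
        t = np.arange(10.0)
        fit = ef.fit_mf_line(_series(t, -0.1 * t + 135.0))
        assert fit.slope_A == pytest.approx(-0.1, abs=1e-12)
        assert fit.intercept_b == pytest.approx(135.0, abs=1e-10)
        assert fit.R == pytest.approx(1.0, abs=1e-12)
        assert fit.mf_S == pytest.approx(fit.slope_A * fit.t_end + fit.intercept_b)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            t = np.sort(rng.uniform(0, 160, size=rng.integers(3, 60)))
            t += np.arange(t.size) * 1e-6  # ensure strictly increasing
            y = 130 + rng.normal(0, 5, size=t.size)
            fit = ef.fit_mf_line(_series(t, y))
            slope, intercept = ols_oracle(list(t), list(y))
            assert fit.slope_A == pytest.approx(slope, abs=1e-9)
            assert fit.intercept_b == pytest.approx(intercept, abs=1e-9)

    def test_constant_series_is_degenerate(self):
        fit = ef.fit_mf_line(_series([0, 1, 2], [130.0, 130.0, 130.0]))
        assert fit.slope_A == 0.0
        assert fit.R == 0.0
        assert fit.degenerate

    def test_two_windows_insufficient(self):
        with pytest.raises(InsufficientDataError):
            ef.fit_mf_line(_series([0, 1], [130.0, 129.0]))


def _fit(mf0, mfs, t_end=150.0):
    slope = (mfs - mf0) / t_end
    return ef.LinearFit(slope, mf0, mfs, 0.9, t_end, 59)


class TestSMFDR:
    def test_mean_of_three(self):
        fits = [_fit(m, m - 13.0) for m in (135.6, 135.8, 136.0)]
        sm = ef.build_smfdr(fits)
        assert sm.mf0_bar == pytest.approx(135.8)
        assert sm.n_train == 3

    def test_single_fit_passthrough(self):
        sm = ef.build_smfdr([_fit(130.0, 120.0)])
        assert sm.mf0_bar == pytest.approx(130.0)
        assert sm.mfs_bar == pytest.approx(120.0)

    def test_random_lists_match_mean_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            fits = [_fit(rng.uniform(120, 140), rng.uniform(90, 125))
                    for _ in range(rng.integers(1, 8))]
            sm = ef.build_smfdr(fits)
            assert sm.mf0_bar == pytest.approx(sum(f.intercept_b for f in fits) / len(fits))
            assert sm.mfs_bar == pytest.approx(sum(f.mf_S for f in fits) / len(fits))

    def test_empty_training_set_rejected(self):
        with pytest.raises(InsufficientDataError):
            ef.build_smfdr([])

    def test_inverted_range_flagged_and_refused(self):
        sm = ef.build_smfdr([_fit(120.0, 130.0)])
        assert not sm.usable
        with pytest.raises(NoFatigueRangeError):
            ef.estimate_level(125.0, sm, 3)


SUBJECT_A = ef.SMFDR(mf0_bar=135.8, mfs_bar=122.4, n_train=3)


class TestLevelBoundaries:
    def test_subject_range_n5(self):
        bounds = ef.level_boundaries(SUBJECT_A, 5)
        delta = (135.8 - 122.4) / 4
        assert ef.level_width(SUBJECT_A, 5) == pytest.approx(delta)
        for lo, hi, k in bounds:
            center = 135.8 - k * delta
            assert (lo + hi) / 2 == pytest.approx(center)
            assert hi - lo == pytest.approx(delta)

    def test_two_levels_span_whole_range(self):
        bounds = ef.level_boundaries(SUBJECT_A, 2)
        assert len(bounds) == 2
        assert ef.level_width(SUBJECT_A, 2) == pytest.approx(135.8 - 122.4)

    def test_intervals_tile_without_gaps(self):
        for n_levels in (2, 3, 5, 7):
            bounds = ef.level_boundaries(SUBJECT_A, n_levels)
            for (lo, _, _), (_, hi_next, _) in zip(bounds[:-1], bounds[1:]):
                assert lo == pytest.approx(hi_next, abs=1e-12)

    def test_single_level_rejected(self):
        with pytest.raises(ParameterError):
            ef.level_boundaries(SUBJECT_A, 1)


class TestEstimateLevel:
    def test_range_endpoints(self):
        top = ef.estimate_level(135.8, SUBJECT_A, 5)
        bottom = ef.estimate_level(122.4, SUBJECT_A, 5)
        assert (top.level_index_k, top.LF) == (0, 0.0)
        assert (bottom.level_index_k, bottom.LF) == (4, 1.0)

    def test_interior_value_matches_oracle(self):
        est = ef.estimate_level(130.0, SUBJECT_A, 5)
        assert est.level_index_k == quantizer_oracle(130.0, 135.8, 122.4, 5)

    def test_out_of_range_clamps(self):
        assert ef.estimate_level(150.0, SUBJECT_A, 5).level_index_k == 0
        assert ef.estimate_level(100.0, SUBJECT_A, 5).level_index_k == 4

    def test_printed_clamp_inverts_out_of_range_branches(self):
        # audit mode: below MF̄0 → 0, above MF̄s → N−1
        assert ef.estimate_level(150.0, SUBJECT_A, 5, printed_clamp=True).level_index_k == 4
        assert ef.estimate_level(100.0, SUBJECT_A, 5, printed_clamp=True).level_index_k == 0

    def test_edge_ties_go_to_more_fatigued_level(self):
        delta = ef.level_width(SUBJECT_A, 5)
        edge = 135.8 - delta / 2.0  # boundary between k=0 and k=1
        assert ef.estimate_level(edge, SUBJECT_A, 5).level_index_k == 1

    def test_nonfinite_value_rejected(self):
        with pytest.raises(InputError):
            ef.estimate_level(math.nan, SUBJECT_A, 5)

    @settings(derandomize=True, deadline=None, max_examples=300)
    @given(
        y=st.floats(min_value=80.0, max_value=160.0),
        mf0=st.floats(min_value=125.0, max_value=140.0),
        span=st.floats(min_value=1.0, max_value=40.0),
        n_levels=st.integers(min_value=2, max_value=6),
    )
    def test_quantizer_matches_brute_force(self, y, mf0, span, n_levels):
        sm = ef.SMFDR(mf0_bar=mf0, mfs_bar=mf0 - span, n_train=1)
        est = ef.estimate_level(y, sm, n_levels)
        assert est.level_index_k == quantizer_oracle(y, mf0, mf0 - span, n_levels)
        assert est.LF == pytest.approx(est.level_index_k / (n_levels - 1))


class TestTrajectory:
    def test_flat_line_at_mf0_stays_unfatigued(self):
        fit = ef.LinearFit(0.0, 135.8, 135.8, 0.0, 150.0, 59)
        traj = ef.fatigue_trajectory(fit, SUBJECT_A, 3, np.linspace(0, 150, 30))
        assert all(e.LF == 0.0 for e in traj)

    def test_full_span_visits_all_levels_in_order(self):
        t_end = 150.0
        fit = _fit(135.8, 122.4, t_end)
        times = np.linspace(0.0, t_end, 601)
        traj = ef.fatigue_trajectory(fit, SUBJECT_A, 3, times)
        lf = [e.LF for e in traj]
        assert lf[0] == 0.0 and lf[-1] == 1.0
        seen = sorted(set(lf))
        assert seen == [0.0, 0.5, 1.0]
        # boundary-crossing times computed analytically from the line
        delta = ef.level_width(SUBJECT_A, 3)
        for k_target in (1, 2):
            y_edge = 135.8 - (2 * k_target - 1) * delta / 2.0
            t_cross = (y_edge - fit.intercept_b) / fit.slope_A
            before = traj[int(np.searchsorted(times, t_cross) - 1)]
            after = traj[min(int(np.searchsorted(times, t_cross) + 1), len(traj) - 1)]
            assert before.level_index_k <= k_target <= after.level_index_k

    def test_monotone_for_any_negative_slope(self):
        rng = np.random.default_rng(30)
        for _ in range(20):
            fit = _fit(rng.uniform(130, 140), rng.uniform(110, 129))
            lf = [e.LF for e in
                  ef.fatigue_trajectory(fit, SUBJECT_A, 4, np.linspace(0, 150, 50))]
            assert all(a <= b for a, b in zip(lf, lf[1:]))

    def test_coarsening_preserves_fatigue_ordering(self):
        """N=5 → N=2 nesting: a 2-step strict ordering never reverses."""
        rng = np.random.default_rng(31)
        for _ in range(200):
            a, b = rng.uniform(118, 140, size=2)
            k5a = ef.estimate_level(a, SUBJECT_A, 5).level_index_k
            k5b = ef.estimate_level(b, SUBJECT_A, 5).level_index_k
            if k5a <= k5b - 2:
                lf2a = ef.estimate_level(a, SUBJECT_A, 2).LF
                lf2b = ef.estimate_level(b, SUBJECT_A, 2).LF
                assert lf2a <= lf2b
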