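"""Tests of the trace-analysis operations against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from quorumclock.analysis import (detect_sync_time, estimate_period,
                                  extract_phase, order_parameter,
                                  order_parameter_series, phase_clusters,
                                  weighted_mean_trace, windowed_sd)
from quorumclock.errors import InvalidArgumentError, NoOscillationError


def sinusoid(period, dt, t_end, phase=0.0, amp=1.0, offset=2.0):
    t = np.arange(0.0, t_end, dt)
    return t, offset + amp * np.cos(2 * np.pi * t / period - phase)


def autocorr_period(trace, dt):
    """Independent oracle: first nonzero-lag peak of the autocorrelation."""
    x = trace - trace.mean()
    ac = np.correlate(x, x, mode="full")[len(x) - 1:]
    # first local maximum after the initial decay
    k = 1
    while k + 1 < len(ac) and ac[k + 1] <= ac[k]:
        k += 1
    while k + 1 < len(ac) and ac[k + 1] >= ac[k]:
        k += 1
    return k * dt


class TestEstimatePeriod:
    def test_pure_sinusoid_recovered_within_one_sample(self):
        t, y = sinusoid(300.0, 20.0, 3000.0)
        period, intervals = estimate_period(y, 20.0)
        assert abs(period - 300.0) <= 20.0
        assert np.all(np.abs(intervals - 300.0) <= 20.0)

    @pytest.mark.parametrize("period", [120.0, 270.0, 400.0])
    def test_various_periods(self, period):
        t, y = sinusoid(period, 10.0, 12 * period)
        est, _ = estimate_period(y, 10.0)
        assert abs(est - period) <= 10.0

    def test_constant_trace_is_no_oscillation(self):
        with pytest.raises(NoOscillationError):
            estimate_period(np.full(200, 3.0), 20.0)

    def test_too_few_peaks_is_no_oscillation(self):
        t, y = sinusoid(300.0, 20.0, 500.0)  # < 2 full cycles
        with pytest.raises(NoOscillationError):
            estimate_period(y, 20.0)

    def test_noisy_sinusoid_matches_autocorrelation_oracle(self, rng):
        t, y = sinusoid(300.0, 20.0, 6000.0)
        noisy = y + 0.2 * rng.standard_normal(len(y))  # SNR ~ 5 on the swing
        est, _ = estimate_period(noisy, 20.0)
        oracle = autocorr_period(noisy, 20.0)
        assert abs(est - oracle) <= 20.0

    def test_invalid_dt_rejected(self):
        with pytest.raises(InvalidArgumentError):
            estimate_period(np.arange(10.0), 0.0)


class TestWeightedMean:
    def test_two_cells_direct_value(self):
        g = np.array([[1.0, 3.0]])
        assert weighted_mean_trace(g)[0] == pytest.approx(2.5)
        assert g.mean(axis=1)[0] == pytest.approx(2.0)

    def test_identical_cells_equal_arithmetic(self):
        g = np.full((7, 4), 3.7)
        assert weighted_mean_trace(g) == pytest.approx(np.full(7, 3.7))

    def test_single_bright_cell_dominates(self):
        g = np.array([[0.0, 0.0, 5.0]])
        assert weighted_mean_trace(g)[0] == pytest.approx(5.0)

    def test_all_zero_slice_reported_nan(self):
        g = np.array([[1.0, 1.0], [0.0, 0.0]])
        with pytest.warns(UserWarning):
            wm = weighted_mean_trace(g)
        assert np.isnan(wm[1]) and wm[0] == pytest.approx(1.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_weighted_never_below_arithmetic(self, seed):
        g = np.random.default_rng(seed).uniform(0, 10, size=(5, 8))
        wm = weighted_mean_trace(g)
        am = g.mean(axis=1)
        assert np.all(wm >= am - 1e-12)

    def test_negative_values_rejected(self):
        with pytest.raises(InvalidArgumentError):
            weighted_mean_trace(np.array([[1.0, -0.1]]))


class TestWindowedSD:
    def test_constant_equal_cells_zero_sd(self):
        g = np.full((60, 5), 2.0)
        mids, sds = windowed_sd(g, dt=20.0, window=300.0)
        assert np.all(sds == 0.0)
        assert mids[0] == pytest.approx(150.0)

    def test_two_constant_cells_population_convention(self):
        g = np.tile([0.0, 2.0], (60, 1))
        _, sds = windowed_sd(g, dt=20.0, window=300.0)
        assert sds == pytest.approx(np.ones(len(sds)))

    def test_window_shorter_than_two_samples_rejected(self):
        with pytest.raises(InvalidArgumentError):
            windowed_sd(np.zeros((50, 2)), dt=20.0, window=20.0)


class TestPhase:
    def test_sinusoid_phase_matches_analytic(self):
        t, y = sinusoid(300.0, 5.0, 3000.0)
        ph = extract_phase(y, 5.0)
        ok = np.isfinite(ph)
        analytic = (t % 300.0) / 300.0 * 2 * np.pi  # 0 at each cosine peak
        err = np.angle(np.exp(1j * (ph[ok] - analytic[ok])))
        assert np.sqrt(np.mean(err ** 2)) < 0.2

    def test_identical_traces_zero_phase_difference(self):
        t, y = sinusoid(300.0, 10.0, 3000.0)
        d = extract_phase(y, 10.0) - extract_phase(y, 10.0)
        assert np.nanmax(np.abs(d)) == 0.0

    def test_half_period_shift_gives_pi(self):
        t, a = sinusoid(300.0, 5.0, 3000.0)
        _, b = sinusoid(300.0, 5.0, 3000.0, phase=np.pi)
        pa, pb = extract_phase(a, 5.0), extract_phase(b, 5.0)
        ok = np.isfinite(pa) & np.isfinite(pb)
        diff = np.abs(np.angle(np.exp(1j * (pa[ok] - pb[ok]))))
        assert np.median(np.abs(diff - np.pi)) < 0.2

    def test_flat_trace_has_no_phase(self):
        with pytest.raises(NoOscillationError):
            extract_phase(np.ones(100), 10.0)


class TestOrderParameter:
    def test_unison_is_one(self):
        assert order_parameter(np.full(30, 1.3)) == pytest.approx(1.0)

    @pytest.mark.parametrize("n", [2, 3, 8])
    def test_uniformly_spaced_is_zero(self, n):
        ph = 2 * np.pi * np.arange(n) / n
        assert order_parameter(ph) == pytest.approx(0.0, abs=1e-12)

    def test_quarter_turn_pair(self):
        assert order_parameter([0.0, np.pi / 2]) == pytest.approx(np.sqrt(2) / 2)

    @given(st.floats(-10, 10), st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_rotation_invariance(self, rot, seed):
        ph = np.random.default_rng(seed).uniform(0, 2 * np.pi, size=12)
        r0, r1 = order_parameter(ph), order_parameter(ph + rot)
        assert r1 == pytest.approx(r0, abs=1e-9)

    def test_bounds(self, rng):
        for _ in range(20):
            ph = rng.uniform(-7, 7, size=rng.integers(1, 40))
            assert 0.0 <= order_parameter(ph) <= 1.0 + 1e-12

    def test_undefined_phases_give_nan(self):
        assert np.isnan(order_parameter([np.nan, np.nan]))


def brute_force_clusters(phases, gap):
    """Exhaustive oracle: transitive closure of 'circular distance <= gap'
    between consecutive points on the sorted circle, scanning every point."""
    ph = np.mod(np.asarray(phases, dtype=float), 2 * np.pi)
    order = np.argsort(ph, kind="stable")
    m = len(ph)
    # adjacency between circular neighbours
    linked = np.zeros(m, dtype=bool)  # linked[j]: sorted j joined to j+1 (mod m)
    for j in range(m):
        a, b = ph[order[j]], ph[order[(j + 1) % m]]
        d = (b - a) % (2 * np.pi)
        linked[j] = d <= gap
    if linked.all():
        return np.zeros(m, dtype=int)[np.argsort(order)]
    # start labelling after some broken link
    start = int(np.where(~linked)[0][0]) + 1
    labels_sorted = np.empty(m, dtype=int)
    lab = 0
    for k in range(m):
        j = (start + k) % m
        labels_sorted[j] = lab
        if not linked[j]:
            lab += 1
    labels = np.empty(m, dtype=int)
    labels[order] = labels_sorted
    return labels


class TestPhaseClusters:
    def test_all_equal_single_cluster(self):
        labels, sizes = phase_clusters(np.full(10, 0.7))
        assert np.all(labels == 0) and sizes.tolist() == [10]

    def test_two_tight_groups(self):
        ph = np.array([0.0, 0.05, -0.03, np.pi, np.pi + 0.04])
        labels, sizes = phase_clusters(ph, gap=0.5)
        assert len(sizes) == 2
        assert labels[0] == labels[1] == labels[2]
        assert labels[3] == labels[4] != labels[0]

    @given(st.integers(0, 2**31 - 1), st.floats(0.2, 1.5))
    @settings(max_examples=40, deadline=None)
    def test_matches_brute_force_oracle(self, seed, gap):
        ph = np.random.default_rng(seed).uniform(0, 2 * np.pi,
                                                 size=np.random.default_rng(seed).integers(2, 25))
        labels, sizes = phase_clusters(ph, gap=gap)
        oracle = brute_force_clusters(ph, gap)
        # same partition up to label names
        for a in range(len(ph)):
            for b in range(a + 1, len(ph)):
                assert (labels[a] == labels[b]) == (oracle[a] == oracle[b])
        assert sizes.sum() == len(ph)

    def test_wraparound_group_is_one_cluster(self):
        ph = np.array([0.05, 2 * np.pi - 0.05, 0.1])
        labels, sizes = phase_clusters(ph, gap=0.5)
        assert len(sizes) == 1

    def test_undefined_phases_labelled_minus_one(self):
        labels, sizes = phase_clusters([0.0, np.nan, 0.1], gap=0.5)
        assert labels[1] == -1 and labels[0] == labels[2] == 0


class TestDetectSyncTime:
    def test_identical_cells_sync_from_first_window(self):
        t, y = sinusoid(300.0, 20.0, 4000.0)
        g = np.tile(y[:, None], (1, 6))
        st_ = detect_sync_time(g, dt=20.0)
        mids, _ = windowed_sd(g, dt=20.0, window=300.0)
        assert st_ == pytest.approx(mids[0])

    def test_permanent_random_phases_never_sync(self, rng):
        t = np.arange(0.0, 6000.0, 20.0)
        phases = rng.uniform(0, 2 * np.pi, size=20)
        g = 2 + np.cos(2 * np.pi * t[:, None] / 300.0 - phases[None, :])
        assert detect_sync_time(g, dt=20.0) is None

    def test_short_trajectory_rejected(self):
        with pytest.raises(InvalidArgumentError):
            detect_sync_time(np.zeros((10, 3)), dt=20.0)

    def test_sd_plateau_criterion_on_converging_traces(self):
        t = np.arange(0.0, 8000.0, 20.0)
        spread = 0.05 + np.exp(-t / 800.0)  # spread decays to a noise floor
        phases = np.linspace(0, np.pi, 8)
        g = 2 + np.cos(2 * np.pi * t[:, None] / 300.0 - spread[:, None] * phases[None, :])
        st_ = detect_sync_time(g, dt=20.0, criterion="sd_plateau")
        assert st_ is not None and st_ < 6000.0


class TestOrderParameterSeries:
    def test_synchronous_population_near_one(self):
        t, y = sinusoid(300.0, 20.0, 4000.0)
        g = np.tile(y[:, None], (1, 5))
        r = order_parameter_series(g, dt=20.0)
        ok = np.isfinite(r)
        assert np.nanmin(r[ok]) > 0.99

    def test_scattered_phases_low_coherence(self, rng):
        t = np.arange(0.0, 6000.0, 20.0)
        phases = 2 * np.pi * np.arange(16) / 16
        g = 2 + np.cos(2 * np.pi * t[:, None] / 300.0 - phases[None, :])
        r = order_parameter_series(g, dt=20.0)
        mid = r[np.isfinite(r)]
        assert np.median(mid) < 0.3
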