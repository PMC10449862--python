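"""Baseline correction, condition averaging, deceleration-window means and
peak-anchored FRN/P3 extraction."""

import numpy as np
import pytest

from dynexpect import erp
from dynexpect.erp import (
    ConditionAverage,
    Epoch,
    EpochSet,
    average_by_condition,
    baseline_correct,
    component_mean,
    eeg_window_means,
    peak_window,
)
from dynexpect.outcomes import CONDITION_ORDER, OutcomeClass

SFREQ = 200.0
CHANNELS = ["Fz", "FCz", "Cz", "CPz", "Pz", "POz", "Oz"]


def make_epoch(data=None, outcome=OutcomeClass.MATCH, spin_onset=-4.5, fill=0.0):
    times = -5.0 + np.arange(int(6.0 * SFREQ) + 1) / SFREQ  # [-5, 1]
    if data is None:
        data = np.full((len(CHANNELS), times.size), fill)
    return Epoch(data=data, times=times, outcome=outcome, spin_onset=spin_onset)


def corrected_set(epochs):
    return EpochSet(
        subject="S01",
        epochs=[baseline_correct(ep) for ep in epochs],
        sfreq=SFREQ,
        channels=CHANNELS,
    )


class TestBaseline:
    def test_constant_channel_becomes_zero(self):
        ep = baseline_correct(make_epoch(fill=5.0))
        assert np.allclose(ep.data, 0.0)

    def test_zero_baseline_mean_is_identity(self, rng):
        ep = make_epoch()
        ep.data[:] = rng.normal(size=ep.data.shape)
        mask = (ep.times >= ep.spin_onset - 0.2) & (ep.times < ep.spin_onset)
        ep.data -= ep.data[:, mask].mean(axis=1, keepdims=True)
        before = ep.data.copy()
        assert np.allclose(baseline_correct(ep).data, before, atol=1e-12)

    def test_corrected_baseline_mean_is_zero(self, rng):
        ep = make_epoch()
        ep.data[:] = rng.normal(3.0, 2.0, size=ep.data.shape)
        out = baseline_correct(ep)
        mask = (out.times >= out.spin_onset - 0.2) & (out.times < out.spin_onset)
        assert np.allclose(out.data[:, mask].mean(axis=1), 0.0, atol=1e-12)

    def test_idempotence(self, rng):
        ep = make_epoch()
        ep.data[:] = rng.normal(size=ep.data.shape)
        once = baseline_correct(ep)
        twice = baseline_correct(once)
        assert np.allclose(once.data, twice.data, atol=1e-10)

    def test_uncovered_baseline_raises(self):
        ep = make_epoch(spin_onset=-5.5)  # baseline would start at -5.7
        with pytest.raises(ValueError, match="baseline"):
            baseline_correct(ep)


class TestAveraging:
    def test_two_identical_epochs(self, rng):
        data = rng.normal(size=(len(CHANNELS), int(6.0 * SFREQ) + 1))
        es = corrected_set([make_epoch(data.copy()), make_epoch(data.copy())])
        avg = average_by_condition(es)
        # baseline correction removes the same offsets from both
        assert np.allclose(avg.averages[OutcomeClass.MATCH], es.epochs[0].data)

    def test_opposite_epochs_cancel(self, rng):
        data = rng.normal(size=(len(CHANNELS), int(6.0 * SFREQ) + 1))
        data -= data.mean(axis=1, keepdims=True)  # zero-mean so baselines agree
        es = corrected_set([make_epoch(data.copy()), make_epoch(-data.copy())])
        avg = average_by_condition(es)
        assert np.allclose(avg.averages[OutcomeClass.MATCH], 0.0, atol=1e-10)

    def test_smoothing_preserves_dc(self):
        es = corrected_set([make_epoch(fill=4.0)])
        avg = average_by_condition(es, smooth=True)
        # constant after baseline correction is 0; add a nonzero constant path
        avg2_data = avg.averages[OutcomeClass.MATCH] + 3.0
        from dynexpect.erp import _lowpass

        assert np.allclose(_lowpass(avg2_data, SFREQ), avg2_data, atol=1e-6)

    def test_missing_class_warns_and_omits(self):
        es = corrected_set([make_epoch(outcome=OutcomeClass.MATCH)])
        with pytest.warns(UserWarning, match="omitted"):
            avg = average_by_condition(es)
        assert OutcomeClass.FULL_AWAY not in avg.averages


class TestWindowMeans:
    def _avg_with_cz(self, cz_fn):
        times = -5.0 + np.arange(int(6.0 * SFREQ) + 1) / SFREQ
        mat = np.zeros((len(CHANNELS), times.size))
        mat[CHANNELS.index("Cz")] = cz_fn(times)
        return ConditionAverage(times=times, channels=CHANNELS,
                                averages={OutcomeClass.MATCH: mat})

    def test_constant_trace(self):
        avg = self._avg_with_cz(lambda t: np.full_like(t, -5.0))
        means = eeg_window_means(avg, "Cz")
        assert np.allclose(means[OutcomeClass.MATCH], -5.0)

    def test_linear_ramp_closed_form(self):
        # 0 -> -6 uV over [-3, 0]: the [-0.5, 0] window mean is -5.5
        avg = self._avg_with_cz(
            lambda t: np.where((t >= -3) & (t <= 0), -2.0 * (t + 3.0), 0.0)
        )
        means = eeg_window_means(avg, "Cz")
        assert means[OutcomeClass.MATCH][-1] == pytest.approx(-5.5, abs=0.01)

    def test_brute_force_oracle(self, rng):
        avg = self._avg_with_cz(lambda t: rng.normal(size=t.size))
        cz = avg.averages[OutcomeClass.MATCH][CHANNELS.index("Cz")]
        means = eeg_window_means(avg, "Cz")
        from dynexpect.behavior import DECEL_WINDOWS

        for wi, (a, b) in enumerate(DECEL_WINDOWS):
            if wi == len(DECEL_WINDOWS) - 1:
                sel = cz[(avg.times >= a - 1e-9) & (avg.times <= b + 1e-9)]
            else:
                sel = cz[(avg.times >= a - 1e-9) & (avg.times < b - 1e-9)]
            assert means[OutcomeClass.MATCH][wi] == pytest.approx(sel.mean(), rel=1e-12)

    def test_unknown_channel_error_lists_channels(self):
        avg = self._avg_with_cz(lambda t: np.zeros_like(t))
        with pytest.raises(KeyError, match="Cz"):
            eeg_window_means(avg, "T7")

    def test_linearity_of_scaling(self, rng):
        avg = self._avg_with_cz(lambda t: rng.normal(size=t.size))
        m1 = eeg_window_means(avg, "Cz")[OutcomeClass.MATCH]
        avg.averages[OutcomeClass.MATCH] *= 2.5
        m2 = eeg_window_means(avg, "Cz")[OutcomeClass.MATCH]
        assert np.allclose(m2, 2.5 * m1)


def grand_with_bump(center, amp, cluster_channels):
    """Grand average with a single Gaussian bump on the given channels."""
    times = -5.0 + np.arange(int(6.0 * SFREQ) + 1) / SFREQ
    mats = {}
    for oc in CONDITION_ORDER:
        mat = np.zeros((len(CHANNELS), times.size))
        bump = amp * np.exp(-0.5 * ((times - center) / 0.02) ** 2)
        for ch in cluster_channels:
            mat[CHANNELS.index(ch)] = bump
        mats[oc] = mat
    return ConditionAverage(times=times, channels=CHANNELS, averages=mats)


class TestPeakWindow:
    def test_frn_peak_at_251ms_gives_printed_window(self):
        # minimum at 251 ms (on-grid at 200 Hz: 0.250... use 1000 Hz grid)
        times = np.arange(0.0, 0.6, 0.001)
        mats = {}
        for oc in CONDITION_ORDER:
            mat = np.zeros((len(CHANNELS), times.size))
            mat[:3] = 5 * ((times - 0.251) ** 2)[None, :] - 3.0  # min at 0.251
            mats[oc] = mat
        grand = ConditionAverage(times=times, channels=CHANNELS, averages=mats)
        win = peak_window(grand, "FRN")
        assert win.peak == pytest.approx(0.251, abs=1e-9)
        assert win.measure_window == (pytest.approx(0.210), pytest.approx(0.290))

    def test_p3_peak_at_400ms(self):
        grand = grand_with_bump(0.400, +6.0, ["Cz", "CPz", "Pz", "POz", "Oz"])
        win = peak_window(grand, "P3")
        assert win.peak == pytest.approx(0.400, abs=1 / SFREQ)
        assert win.measure_window[0] == pytest.approx(0.360, abs=0.011)
        assert win.measure_window[1] == pytest.approx(0.440, abs=0.011)

    def test_two_equal_minima_earlier_selected(self):
        times = np.arange(0.0, 0.6, 0.001)
        trace = np.zeros(times.size)
        for c in (0.25, 0.32):
            trace -= 2.0 * np.exp(-0.5 * ((times - c) / 0.01) ** 2)
        mats = {}
        for oc in CONDITION_ORDER:
            mat = np.zeros((len(CHANNELS), times.size))
            mat[:3] = trace
            mats[oc] = mat
        grand = ConditionAverage(times=times, channels=CHANNELS, averages=mats)
        win = peak_window(grand, "FRN")
        assert win.peak == pytest.approx(0.25, abs=2e-3)

    def test_flat_signal_warns(self):
        times = np.arange(0.0, 0.6, 0.001)
        mats = {
            oc: np.zeros((len(CHANNELS), times.size)) for oc in CONDITION_ORDER
        }
        grand = ConditionAverage(times=times, channels=CHANNELS, averages=mats)
        with pytest.warns(UserWarning, match="flat"):
            peak_window(grand, "FRN")


class TestComponentMean:
    def test_constant_amplitude(self):
        grand = grand_with_bump(0.25, -3.0, ["Fz", "FCz", "Cz"])
        win = peak_window(grand, "FRN")
        avg = grand_with_bump(0.25, 0.0, ["Fz"])
        for oc in CONDITION_ORDER:
            avg.averages[oc] += 3.0
        amps = component_mean(avg, win)
        for oc in CONDITION_ORDER:
            assert amps[oc] == pytest.approx(3.0)

    def test_additivity_of_constant_offset(self, rng):
        grand = grand_with_bump(0.25, -3.0, ["Fz", "FCz", "Cz"])
        win = peak_window(grand, "FRN")
        avg = grand_with_bump(0.25, -2.0, ["Fz", "FCz", "Cz"])
        base = component_mean(avg, win)
        for oc in CONDITION_ORDER:
            avg.averages[oc] += 1.7
        shifted = component_mean(avg, win)
        for oc in CONDITION_ORDER:
            assert shifted[oc] == pytest.approx(base[oc] + 1.7)

    def test_brute_force_oracle(self, rng):
        grand = grand_with_bump(0.25, -3.0, ["Fz", "FCz", "Cz"])
        win = peak_window(grand, "FRN")
        avg = grand_with_bump(0.25, -1.0, ["Fz", "FCz", "Cz"])
        avg.averages[OutcomeClass.MATCH] += rng.normal(
            size=avg.averages[OutcomeClass.MATCH].shape
        )
        amps = component_mean(avg, win)
        lo, hi = win.measure_window
        mask = (avg.times >= lo - 1e-9) & (avg.times <= hi + 1e-9)
        idxs = [CHANNELS.index(c) for c in win.cluster]
        expected = avg.averages[OutcomeClass.MATCH][np.ix_(idxs, np.flatnonzero(mask))].mean()
        assert amps[OutcomeClass.MATCH] == pytest.approx(expected, rel=1e-12)
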