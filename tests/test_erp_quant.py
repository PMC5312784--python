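"""ERP preprocessing contracts and component measures, checked against
closed-form constructions and brute-force window scans."""

import numpy as np
import pandas as pd
import pytest

from revlearn import erp_quant as eq


def _epochs(data, sfreq=250.0, tmin=-500.0, ch_names=None, time_zero="feedback",
            info=None):
    if ch_names is None:
        ch_names = eq.SCALP_CHANNELS[:data.shape[0]]
    return eq.EpochSet(data=np.asarray(data, dtype=float), sfreq=sfreq,
                       ch_names=tuple(ch_names), tmin_ms=tmin,
                       time_zero=time_zero,
                       trial_info=info if info is not None else pd.DataFrame())


def _raised_cosine(times, latency, width, amp):
    x = times - latency
    out = np.where(np.abs(x) <= width / 2,
                   0.5 * (1 + np.cos(2 * np.pi * x / width)), 0.0)
    return amp * out


class TestPreprocess:
    def test_large_step_trial_rejected(self, rng):
        t = np.arange(-0.5, 1.5, 1 / 250)
        data = rng.standard_normal((32, len(t), 10)) * 3
        data[:, :, 4] += np.where(t > 0.2, 150.0, 0.0)[None, :]
        clean, n_rejected = eq.preprocess(_epochs(data))
        assert n_rejected == 1 and clean.n_trials == 9

    def test_clean_epochs_keep_all_trials(self, rng):
        data = rng.standard_normal((32, 500, 6)) * 3
        clean, n_rejected = eq.preprocess(_epochs(data))
        assert n_rejected == 0 and clean.n_trials == 6

    def test_all_rejected_raises(self):
        data = np.zeros((32, 500, 2))
        data[0, 100, :] = 200.0
        with pytest.raises(eq.EpochError, match="rejected"):
            eq.preprocess(_epochs(data))

    def test_50hz_attenuated_below_one_percent(self):
        sf = 1000.0
        t = np.arange(-0.5, 1.5, 1 / sf)
        data = np.zeros((1, len(t), 1))
        data[0, :, 0] = 30 * np.sin(2 * np.pi * 50 * t)
        clean, _ = eq.preprocess(_epochs(data, sfreq=sf, ch_names=("CZ",)))
        assert clean.sfreq == 250.0
        interior = clean.data[0, 170:-170, 0]       # skip filter transients
        assert np.abs(interior).max() < 0.01 * 30

    def test_downsampling_to_canonical_rate(self, rng):
        data = rng.standard_normal((4, 2000, 3))
        clean, _ = eq.preprocess(_epochs(data, sfreq=1000.0))
        assert clean.sfreq == 250.0 and clean.data.shape[1] == 500


class TestBaseline:
    def test_constant_offset_removed(self):
        data = np.full((2, 500, 3), 7.5)
        out = eq.baseline_correct(_epochs(data), (-200.0, -100.0))
        assert np.allclose(out.data, 0.0)

    def test_ramp_closed_form(self):
        ep = _epochs(np.zeros((1, 500, 1)))
        times = ep.times_ms
        ramp = 0.01 * times
        ep.data[0, :, 0] = ramp
        out = eq.baseline_correct(ep, (-200.0, -100.0))
        window = (times >= -200) & (times <= -100)
        assert np.allclose(out.data[0, :, 0], ramp - ramp[window].mean())

    def test_idempotent(self, rng):
        ep = _epochs(rng.standard_normal((3, 500, 4)))
        once = eq.baseline_correct(ep, (-200.0, -100.0))
        twice = eq.baseline_correct(once, (-200.0, -100.0))
        assert np.allclose(once.data, twice.data)

    def test_window_outside_epoch_raises(self, rng):
        ep = _epochs(rng.standard_normal((1, 500, 1)))
        with pytest.raises(eq.EpochError, match="outside"):
            eq.baseline_correct(ep, (-900.0, -800.0))


class TestClusterWaveform:
    def test_hand_computed_mean(self):
        data = np.arange(2 * 4 * 2, dtype=float).reshape(2, 4, 2)
        ep = _epochs(data, ch_names=("F3", "FZ"))
        wave = eq.cluster_waveform(ep, ("F3", "FZ"))
        assert np.allclose(wave, data.mean(axis=0).mean(axis=1))

    def test_single_channel_cluster(self, rng):
        data = rng.standard_normal((3, 10, 5))
        ep = _epochs(data, ch_names=("F3", "FZ", "F4"))
        assert np.allclose(eq.cluster_waveform(ep, ("FZ",)),
                           data[1].mean(axis=1))

    def test_invariant_to_channels_outside_cluster(self, rng):
        data = rng.standard_normal((5, 10, 4))
        ep_small = _epochs(data[:3], ch_names=("F3", "FZ", "F4"))
        ep_big = _epochs(data, ch_names=("F3", "FZ", "F4", "CZ", "PZ"))
        assert np.allclose(eq.cluster_waveform(ep_small, ("F3", "FZ")),
                           eq.cluster_waveform(ep_big, ("F3", "FZ")))

    def test_invariant_to_trial_order(self, rng):
        data = rng.standard_normal((2, 10, 6))
        ep = _epochs(data, ch_names=("F3", "FZ"))
        perm = rng.permutation(6)
        assert np.allclose(eq.cluster_waveform(ep, ("F3",)),
                           eq.cluster_waveform(ep.select_trials(perm), ("F3",)))

    def test_unknown_channel_raises(self, rng):
        ep = _epochs(rng.standard_normal((1, 10, 1)), ch_names=("CZ",))
        with pytest.raises(eq.EpochError, match="not in montage"):
            eq.cluster_waveform(ep, ("XX",))


class TestFrn:
    times = np.arange(-500.0, 1500.0, 4.0)

    def test_flat_waveform_zero(self):
        amp = eq.frn_amplitude(np.zeros_like(self.times), self.times)
        assert amp.value == 0.0
        assert amp.windows_used["trough"] == eq.FRN_TROUGH_WINDOW

    def test_cosine_bump_construction(self):
        # analytic extrema +5 uV @192 ms, -4 uV @260 ms, +6 uV @352 ms
        wave = (_raised_cosine(self.times, 192.0, 60.0, 5.0)
                + _raised_cosine(self.times, 260.0, 40.0, -4.0)
                + _raised_cosine(self.times, 352.0, 60.0, 6.0))
        amp = eq.frn_amplitude(wave, self.times)
        assert amp.value == pytest.approx(0.5 * (5 + 6) + 4, abs=1e-12)

    def test_simple_base_to_peak_variant(self):
        wave = (_raised_cosine(self.times, 192.0, 60.0, 5.0)
                + _raised_cosine(self.times, 260.0, 40.0, -4.0)
                + _raised_cosine(self.times, 352.0, 60.0, 6.0))
        amp = eq.frn_amplitude(wave, self.times, mode="preceding_peak")
        assert amp.value == pytest.approx(9.0, abs=1e-12)

    def test_ramp_widens_to_hard_bound_and_is_deterministic(self):
        wave = 0.01 * self.times
        first = eq.frn_amplitude(wave, self.times)
        second = eq.frn_amplitude(wave, self.times)
        assert first.windows_used == second.windows_used
        # second peak widens rightward to the 800 ms cap
        assert first.windows_used["peak2"][1] == 800.0
        # first peak widens rightward but never into the trough window
        assert first.windows_used["peak1"][1] == eq.FRN_TROUGH_WINDOW[0]
        # value matches a brute-force evaluation on the capped windows
        w1 = first.windows_used["peak1"]
        w2 = first.windows_used["peak2"]
        sel = lambda w: wave[(self.times >= w[0]) & (self.times <= w[1])]
        expected = 0.5 * (sel(w1).max() + sel(w2).max()) \
            - sel(eq.FRN_TROUGH_WINDOW).min()
        assert first.value == pytest.approx(expected, abs=1e-12)

    def test_widening_stops_when_peak_interior(self):
        # peak just outside the nominal second window: widening must find it
        wave = _raised_cosine(self.times, 440.0, 60.0, 5.0) \
            + _raised_cosine(self.times, 192.0, 60.0, 3.0) \
            + _raised_cosine(self.times, 260.0, 40.0, -4.0)
        amp = eq.frn_amplitude(wave, self.times)
        assert amp.windows_used["peak2"][1] >= 444.0
        assert amp.value == pytest.approx(0.5 * (3 + 5) + 4, abs=1e-12)


class TestSpn:
    def _spn_epochs(self, fill):
        interval = 1200.0
        times = np.arange(-500.0, interval + 500.0 + 1e-9, 4.0)
        chans = sum(eq.SPN_CLUSTERS.values(), ())
        data = np.tile(fill(times)[None, :, None], (len(chans), 1, 2))
        info = pd.DataFrame({"interval_ms": [interval, interval]})
        return _epochs(data, tmin=-500.0, ch_names=chans,
                       time_zero="response", info=info)

    def test_flat_epoch_zero_everywhere(self):
        out = eq.spn_amplitude(self._spn_epochs(lambda t: 0.0 * t))
        assert np.allclose(out.to_numpy(), 0.0)

    def test_linear_negativity_decreasing_window_means(self):
        out = eq.spn_amplitude(self._spn_epochs(lambda t: -0.005 * t))
        central = out["central"].to_numpy()
        assert central[0] > central[1] > central[2]

    def test_symmetric_input_no_laterality_effect(self):
        out = eq.spn_amplitude(self._spn_epochs(lambda t: -0.005 * t))
        assert np.allclose(out["left"], out["right"])

    def test_feedback_locked_epochs_rejected(self, rng):
        ep = _epochs(rng.standard_normal((9, 500, 2)),
                     ch_names=sum(eq.SPN_CLUSTERS.values(), ()))
        with pytest.raises(eq.EpochError, match="response-locked"):
            eq.spn_amplitude(ep)

    def test_interval_too_short_raises(self):
        times = np.arange(-500.0, 900.0, 4.0)
        chans = sum(eq.SPN_CLUSTERS.values(), ())
        data = np.zeros((len(chans), len(times), 1))
        ep = _epochs(data, ch_names=chans, time_zero="response")
        with pytest.raises(eq.EpochError, match="too short"):
            eq.spn_amplitude(ep, interval_ms=400.0)


class TestWindowExtrema:
    times = np.arange(-500.0, 1500.0, 4.0)

    def test_flat_zero(self):
        flat = np.zeros_like(self.times)
        assert eq.p3_amplitude(flat, self.times).value == 0.0
        assert eq.p1_amplitude(flat, self.times).value == 0.0
        assert eq.n1_amplitude(flat, self.times).value == 0.0

    def test_gaussian_bump_at_360ms_gives_p3(self):
        wave = 8.0 * np.exp(-0.5 * ((self.times - 360.0) / 30.0) ** 2)
        assert eq.p3_amplitude(wave, self.times).value == pytest.approx(8.0)

    def test_bump_outside_window_gives_edge_value(self):
        # component peaking past the window: the measure reports the
        # brute-force window maximum (an edge value), not the bump peak
        wave = 8.0 * np.exp(-0.5 * ((self.times - 500.0) / 30.0) ** 2)
        window = (self.times >= 300) & (self.times <= 420)
        assert eq.p3_amplitude(wave, self.times).value \
            == pytest.approx(wave[window].max())
        assert eq.p3_amplitude(wave, self.times).value < 8.0

    def test_n1_minimum(self):
        wave = _raised_cosine(self.times, 168.0, 40.0, -4.0)
        assert eq.n1_amplitude(wave, self.times).value == pytest.approx(-4.0)

    def test_p1_maximum(self):
        wave = _raised_cosine(self.times, 80.0, 40.0, 3.0)
        assert eq.p1_amplitude(wave, self.times).value == pytest.approx(3.0)


class TestEpochSetIO:
    def test_save_load_round_trip(self, rng, tmp_path):
        info = pd.DataFrame({"instruction": ["volatility", "stability"],
                             "feedback": ["negative", "positive"]})
        ep = _epochs(rng.standard_normal((3, 20, 2)),
                     ch_names=("F3", "FZ", "F4"), info=info)
        ep.save(tmp_path / "epochs")
        back = eq.EpochSet.load(tmp_path / "epochs")
        assert np.array_equal(back.data, ep.data)
        assert back.ch_names == ep.ch_names
        assert back.sfreq == ep.sfreq and back.tmin_ms == ep.tmin_ms
        pd.testing.assert_frame_equal(back.trial_info, ep.trial_info)
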