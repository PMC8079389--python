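"""Stimulus protocol arithmetic, trial averaging, and threshold calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icband import evoked, synthetic
from icband.core import MovieStack


@pytest.fixture(scope="module")
def protocol():
    return evoked.build_stimulus_protocol(seed=0)


class TestProtocol:
    def test_combination_count_is_cross_product(self, protocol):
        assert protocol.n_combinations == \
            len(protocol.frequencies) * len(protocol.levels)
        assert len(set(protocol.combinations)) == protocol.n_combinations

    def test_half_octave_frequencies_and_level_ladder(self, protocol):
        assert protocol.frequencies[0] == 4.0
        assert protocol.frequencies[-1] == 32.0
        assert np.allclose(np.diff(np.log2(protocol.frequencies)), 0.5)
        assert protocol.levels[0] == 96 and protocol.levels[-1] == 8
        assert set(np.diff(protocol.levels)) == {-8}

    def test_trial_frame_layout(self, protocol):
        assert protocol.frames_per_trial == 50
        assert protocol.pre_frames == 10
        assert protocol.frames_per_session == protocol.n_combinations * 50

    def test_session_order_is_seeded_permutation(self, protocol):
        o1 = protocol.session_order(0)
        o2 = protocol.session_order(0)
        o3 = protocol.session_order(1)
        assert o1 == o2
        assert sorted(o1) == sorted(protocol.combinations)
        assert o1 != o3


def _toy_sessions(protocol, n_sessions, response, noise, rng):
    """Tiny sessions where every trial is ``response`` plus noise."""
    fov = (6, 8)
    fpt = protocol.frames_per_trial
    sessions = []
    for s in range(n_sessions):
        order = protocol.session_order(s)
        data = np.empty((fpt * len(order), *fov))
        logs = []
        for i, (f, l) in enumerate(order):
            clip = response((f, l)) + noise * rng.standard_normal((fpt, *fov))
            data[i * fpt:(i + 1) * fpt] = clip
            logs.append(dict(session=s, trial=i, frequency_kHz=f, SPL_dB=l,
                             start_frame=i * fpt))
        sessions.append((MovieStack(data), pd.DataFrame(logs)))
    return sessions


class TestAverageTrials:
    def test_identical_trials_average_to_single_trial(self, protocol):
        rng = np.random.default_rng(0)
        base = {k: 100 + rng.random((protocol.frames_per_trial, 6, 8))
                for k in protocol.combinations}
        sessions = _toy_sessions(protocol, 3, lambda k: base[k], 0.0, rng)
        tensor = evoked.average_trials(sessions, protocol)
        assert len(tensor.entries) == protocol.n_combinations
        key = protocol.combinations[5]
        assert np.allclose(tensor.entries[key], base[key])
        assert tensor.counts[key] == 3

    def test_noise_shrinks_as_sqrt_trials(self, protocol):
        rng = np.random.default_rng(1)
        sigma = 1.0
        sessions = _toy_sessions(protocol, 10, lambda k: np.full((50, 6, 8), 100.0),
                                 sigma, rng)
        tensor = evoked.average_trials(sessions, protocol)
        resid = np.concatenate([(v - 100.0).ravel() for v in tensor.entries.values()])
        assert resid.std() == pytest.approx(sigma / np.sqrt(10), rel=0.2)

    def test_missing_combination_named(self, protocol):
        rng = np.random.default_rng(2)
        sessions = _toy_sessions(protocol, 1, lambda k: np.full((50, 6, 8), 1.0),
                                 0.0, rng)
        movie, log = sessions[0]
        sessions = [(movie, log[log.SPL_dB != 8])]
        with pytest.raises(ValueError, match="no trials for combination"):
            evoked.average_trials(sessions, protocol)


class TestEvokedDff:
    def _tensor(self, entry, protocol):
        return evoked.ResponseTensor({protocol.combinations[0]: entry},
                                     {protocol.combinations[0]: 1}, 10.0)

    def test_flat_entry_maps_to_zero(self, protocol):
        t = evoked.evoked_dff(self._tensor(np.full((50, 4, 4), 7.0), protocol))
        assert np.allclose(next(iter(t.entries.values())), 0.0)

    def test_step_after_baseline_equals_relative_change(self, protocol):
        entry = np.full((50, 4, 4), 100.0)
        entry[10:] = 110.0   # 10% step at frame 11 (1-based)
        t = evoked.evoked_dff(self._tensor(entry, protocol))
        out = next(iter(t.entries.values()))
        assert np.allclose(out[:10], 0.0)
        assert np.allclose(out[10:], 0.10)

    def test_nonpositive_baseline_rejected(self, protocol):
        entry = np.zeros((50, 4, 4))
        with pytest.raises(ValueError, match="baseline"):
            evoked.evoked_dff(self._tensor(entry, protocol))


class TestPooledCurve:
    def test_single_pixel_region_returns_seed_trace(self):
        rng = np.random.default_rng(3)
        entry = 0.001 * rng.standard_normal((50, 8, 8))
        entry[10:15, 3, 4] = 0.2      # lone responder
        curve, seed, region = evoked.pooled_response_curve(entry)
        assert seed == (3, 4)
        assert region[seed]
        if region.sum() == 1:
            assert np.allclose(curve, entry[:, 3, 4])

    def test_pooling_reduces_noise_of_coherent_region(self):
        rng = np.random.default_rng(4)
        sig = np.zeros(50)
        sig[10:15] = 0.2
        entry = 0.01 * rng.standard_normal((50, 10, 10))
        coherent = sig[:, None] + 0.001 * rng.standard_normal((50, 25))
        entry[:, 2:7, 2:7] = coherent.reshape(50, 5, 5)
        curve, seed, region = evoked.pooled_response_curve(entry, corr_threshold=0.99)
        assert region.sum() > 10
        single = entry[:, seed[0], seed[1]]
        assert curve[:10].std() < single[:10].std()

    def test_seed_search_window_is_stimulus_frames_only(self):
        entry = np.zeros((50, 6, 6))
        entry[11, 2, 2] = 0.1     # in-window responder
        entry[30, 4, 4] = 5.0     # larger artifact outside frames 11-15
        _, seed, _ = evoked.pooled_response_curve(entry)
        assert seed == (2, 2)


class TestDetermineThreshold:
    def _curves(self, peak_by_level):
        out = {}
        for level, peak in peak_by_level.items():
            c = np.zeros(50)
            c[12] = peak
            out[level] = c
        return out

    def test_no_response_below_criterion(self):
        thr, _ = evoked.determine_threshold(self._curves({96: 0.01, 88: 0.01}))
        assert np.isnan(thr)

    def test_lowest_responding_level_wins(self):
        thr, peaks = evoked.determine_threshold(
            self._curves({96: 0.05, 88: 0.03, 80: 0.01}))
        assert thr == 88
        assert peaks[80] == pytest.approx(0.01)

    def test_non_monotone_pattern_keeps_literal_rule(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="icband.evoked"):
            thr, _ = evoked.determine_threshold(
                self._curves({96: 0.05, 88: 0.01, 80: 0.03}))
        assert thr == 80
        assert "non-monotone" in caplog.text

    def test_crossing_outside_window_ignored(self):
        c = np.zeros(50)
        c[25] = 0.5               # after frame 20
        thr, _ = evoked.determine_threshold({96: c})
        assert np.isnan(thr)

    @given(st.floats(min_value=0.005, max_value=0.1))
    @settings(max_examples=25, deadline=None)
    def test_threshold_monotone_in_criterion(self, crit):
        curves = self._curves({96: 0.06, 88: 0.04, 80: 0.02, 72: 0.008})
        lo, _ = evoked.determine_threshold(curves, criterion=0.02)
        hi, _ = evoked.determine_threshold(curves, criterion=max(crit, 0.02))
        if not np.isnan(hi):
            assert hi >= lo


class TestResponseImage:
    def test_flat_entry_zero_image(self):
        assert np.allclose(evoked.response_image(np.zeros((50, 4, 4))), 0.0)

    def test_matches_hand_mean_on_fixture(self):
        rng = np.random.default_rng(5)
        entry = rng.standard_normal((50, 3, 3))
        img = evoked.response_image(entry)
        assert np.allclose(img, entry[10:15].mean(axis=0), atol=1e-12)
        assert img.shape == (3, 3)


class TestThresholdRecovery:
    def test_tonotopic_ordering_recovered_at_low_noise(self):
        """Called thresholds and response-band positions preserve the
        generator's tonotopic ordering."""
        protocol = evoked.build_stimulus_protocol(seed=1)
        freqs = protocol.frequencies
        centers = {f: 0.1 + 0.8 * i / (len(freqs) - 1) for i, f in enumerate(freqs)}
        truths = {f: 24.0 + 8.0 * i for i, f in enumerate(freqs)}
        tuning = synthetic.ToneTuning(centers=centers, thresholds=truths)
        sessions = []
        for s in range(3):
            movie, _, log = synthetic.generate_evoked_session(
                protocol, tuning, fov=(24, 36), noise_sigma=0.0, session=s, seed=2)
            sessions.append((movie, log))
        tensor = evoked.evoked_dff(evoked.average_trials(sessions, protocol))
        table = evoked.threshold_table(tensor, protocol)
        called = [table.threshold(f) for f in freqs]
        # thresholds follow the generator's ordering (ties possible on the
        # discrete 8-dB ladder)
        assert np.all(np.diff(called) >= 0)
        assert called[-1] > called[0]
        # response image band position advances laterally with frequency
        img_cols = []
        for f in freqs:
            img = evoked.response_image(tensor.entries[(f, 96)])
            left = img[:, :img.shape[1] // 2]
            img_cols.append(np.argmax(left.max(axis=0)))
        # left hemisphere: larger p (higher frequency) = smaller column
        from scipy.stats import spearmanr
        rho, _ = spearmanr(np.arange(len(freqs)), img_cols)
        assert rho == pytest.approx(-1.0)
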