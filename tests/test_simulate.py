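"""Generator behaviour: determinism, protocol structure, separation semantics."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import signal as sps
from scipy import stats

from eegauth import (
    build_schedule,
    inject_blinks,
    make_cohort,
    session_params,
    simulate_ec,
    simulate_vs,
)
from eegauth.exceptions import EmptyInputError
from eegauth.simulate import CHANNELS, FRONTAL_CHANNELS, N_CHANNELS


class TestCohort:
    def test_rejects_single_subject(self):
        with pytest.raises(ValueError):
            make_cohort(1, seed=0)

    def test_seed_determinism(self):
        a = make_cohort(8, seed=1, separation=1.0)
        b = make_cohort(8, seed=1, separation=1.0)
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.mixing_matrix, pb.mixing_matrix)
            assert pa.alpha_peak_hz == pb.alpha_peak_hz
            assert pa.rng_seed == pb.rng_seed

    def test_high_separation_gives_distinct_fingerprints(self):
        cohort = make_cohort(8, seed=1, separation=1.0)
        for i in range(len(cohort)):
            for j in range(i + 1, len(cohort)):
                assert not np.allclose(
                    cohort[i].mixing_matrix, cohort[j].mixing_matrix
                )

    def test_zero_separation_gives_identical_generative_params(self):
        a, b = make_cohort(2, seed=1, separation=0.0)
        ga, gb = a.generative_fields(), b.generative_fields()
        assert np.array_equal(ga["mixing_matrix"], gb["mixing_matrix"])
        assert ga["alpha_peak_hz"] == gb["alpha_peak_hz"]
        for ca, cb in zip(ga["erp_components"], gb["erp_components"]):
            assert ca.latency_ms == cb.latency_ms
            assert np.array_equal(ca.topography, cb.topography)
        # identities and noise streams still differ
        assert a.subject_id != b.subject_id
        assert a.rng_seed != b.rng_seed

    def test_mixing_matrices_have_full_column_rank(self, cohort):
        for p in cohort:
            m = p.mixing_matrix
            assert np.linalg.matrix_rank(m) == m.shape[1]


class TestSchedule:
    def test_120_words_take_four_minutes(self):
        schedule = build_schedule(120)
        assert schedule.n_stimuli == 120
        assert schedule.total_duration_s == 240.0  # 4 min

    def test_single_stimulus(self):
        schedule = build_schedule(1)
        assert schedule.total_duration_s == 2.0
        assert schedule.onsets_s.tolist() == [0.0]

    def test_onset_spacing(self):
        schedule = build_schedule(10)
        assert schedule.onsets_s.tolist() == [float(2 * k) for k in range(10)]

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            build_schedule(0)


class TestEyesClosed:
    def test_shape_30s_at_256hz(self, ec_recording):
        assert ec_recording.signal.shape == (14, 30 * 256)
        assert ec_recording.protocol == "EC"
        assert ec_recording.events.size == 0

    def test_bit_identical_on_repeat(self, params):
        a = simulate_ec(params, 10.0, 256.0)
        b = simulate_ec(params, 10.0, 256.0)
        assert np.array_equal(a.signal, b.signal)

    def test_all_sources_off_gives_zero_signal(self, params):
        silent = replace(
            params,
            alpha_amplitude_uv=0.0,
            background_amplitude_uv=0.0,
            sensor_noise_uv=0.0,
        )
        rec = simulate_ec(silent, 5.0, 256.0)
        assert np.all(rec.signal == 0.0)

    def test_alpha_band_power_dominates_neighbouring_band(self, ec_recording, params):
        freqs, psd = sps.welch(ec_recording.signal, fs=256.0, nperseg=1024)
        f0 = params.alpha_peak_hz
        in_band = psd[:, (freqs >= f0 - 2) & (freqs <= f0 + 2)].mean(axis=1)
        neighbour = psd[:, (freqs >= f0 + 5) & (freqs <= f0 + 9)].mean(axis=1)
        assert np.any(in_band > neighbour)

    def test_rejects_nonpositive_duration(self, params):
        with pytest.raises(ValueError):
            simulate_ec(params, 0.0, 256.0)
        with pytest.raises(ValueError):
            simulate_ec(params, 10.0, -1.0)


class TestVisualStimulation:
    def test_full_session_covers_schedule(self, params):
        rec = simulate_vs(params, build_schedule(120), 256.0)
        assert rec.events.size == 120
        assert rec.duration_s >= 240.0
        assert rec.protocol == "VS"
        # every default epoch window fits
        assert rec.events[0] - int(0.5 * 256) >= 0
        assert rec.events[-1] + int(1.5 * 256) <= rec.n_samples

    def test_time_locked_average_recovers_erp(self, params):
        """Averaging onset-locked epochs recovers the injected deflection.

        The evoked response is projected onto the component's scalp map (a
        matched spatial filter, after per-channel demeaning to discard
        electrode offsets); its residual against the ground-truth waveform
        shrinks with more stimuli, and the recovered peak latency is within
        one sample of the injected latency.
        """
        fs = 256.0
        component = params.erp_components[1]  # the late, wide component
        w = component.topography / (component.topography @ component.topography)

        residuals = {}
        for n_stim in (30, 120):
            rec = simulate_vs(params, build_schedule(n_stim), fs)
            signal = rec.signal - rec.signal.mean(axis=1, keepdims=True)
            post = int(0.6 * fs)
            epochs = np.stack([signal[:, e : e + post] for e in rec.events])
            evoked = w @ epochs.mean(axis=0)

            t = np.arange(post) / fs
            expected = np.zeros(post)
            for c in params.erp_components:
                expected += (
                    c.amplitude_uv
                    * (w @ c.topography)
                    * np.exp(
                        -0.5
                        * ((t - c.latency_ms / 1000.0) / (c.width_ms / 1000.0)) ** 2
                    )
                )
            residuals[n_stim] = np.sqrt(np.mean((evoked - expected) ** 2))

            # the late component dominates its own spatial projection there;
            # sample-level latency recovery needs the full stimulus count
            if n_stim == 120:
                peak_window = slice(int(0.25 * fs), post)
                peak = np.argmax(evoked[peak_window]) + peak_window.start
                true_peak = np.argmax(expected)
                assert abs(peak - true_peak) <= 1

        assert residuals[120] < residuals[30]

    def test_zero_amplitude_erp_leaves_background(self, params):
        mute = replace(
            params,
            erp_components=tuple(
                replace(c, amplitude_uv=0.0) for c in params.erp_components
            ),
        )
        rec = simulate_vs(mute, build_schedule(60), 256.0)
        signal = rec.signal - rec.signal.mean(axis=1, keepdims=True)
        post = int(0.6 * 256)
        evoked = np.stack(
            [signal[:, e : e + post] for e in rec.events]
        ).mean(axis=0)
        # the evoked mean is residual background, well below the 5 uV bumps
        assert np.sqrt(np.mean(evoked**2)) < 2.5

    def test_rejects_empty_schedule(self):
        with pytest.raises(EmptyInputError):
            build_schedule(1).__class__(onsets_s=np.array([]))


class TestSessions:
    def test_session_params_deterministic_and_fresh(self, params):
        s1a = session_params(params, 1)
        s1b = session_params(params, 1)
        s2 = session_params(params, 2)
        assert s1a.rng_seed == s1b.rng_seed
        assert s1a.rng_seed != s2.rng_seed
        # traits unchanged: only the realization seed moves
        assert np.array_equal(s1a.mixing_matrix, params.mixing_matrix)
        assert s1a.alpha_amplitude_uv == params.alpha_amplitude_uv


class TestBlinks:
    def test_zero_rate_is_identity(self, vs_recording, params):
        quiet = replace(params, blink_rate_hz=0.0)
        out = inject_blinks(vs_recording, quiet)
        assert np.array_equal(out.signal, vs_recording.signal)
        assert out.meta["blink_onsets"].size == 0

    def test_blink_count_is_poisson(self, params):
        """Total blink count over 100 parameter draws lands in the Poisson
        99% interval (rate 0.2 Hz x 30 s x 100 = 600 expected)."""
        total = 0
        for k in range(100):
            p = replace(params, rng_seed=100_000 + k)
            rec = simulate_ec(p, 30.0, 256.0)
            total += inject_blinks(rec, p).meta["blink_onsets"].size
        lo, hi = stats.poisson.ppf([0.005, 0.995], 100 * 0.2 * 30.0)
        assert lo <= total <= hi

    def test_blinks_raise_frontal_peak_amplitude(self, vs_recording, params):
        out = inject_blinks(vs_recording, params)
        assert out.meta["blink_onsets"].size > 0
        frontal = [CHANNELS.index(c) for c in FRONTAL_CHANNELS]
        assert (
            np.abs(out.signal[frontal]).max()
            > np.abs(vs_recording.signal[frontal]).max()
        )

    def test_ground_truth_onsets_recorded(self, vs_with_blinks):
        onsets = vs_with_blinks.meta["blink_onsets"]
        width = vs_with_blinks.meta["blink_duration_samples"]
        assert np.all(onsets >= 0)
        assert np.all(onsets + width <= vs_with_blinks.n_samples)


def test_recording_validates_events(params):
    rec = simulate_vs(params, build_schedule(3), 256.0)
    with pytest.raises(ValueError):
        rec.__class__(
            signal=rec.signal,
            fs=rec.fs,
            channel_labels=rec.channel_labels,
            protocol="VS",
            events=np.array([5, 5, 6]),  # not strictly increasing
            subject_id="X",
            session_id="S1",
        )


def test_channel_count_matches_montage(ec_recording):
    assert len(ec_recording.channel_labels) == N_CHANNELS == 14
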