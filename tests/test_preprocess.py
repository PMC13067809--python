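import numpy as np
import pytest

from epibench import preprocess as pp
from epibench.synthetic import (BeatTemplate, ElectrodeModel, NoiseSpec,
                                Recording, sample_cohort_templates,
                                synthesize_ecg)

FS = 200.0


def _rec(x, fs=FS, leads=None):
    x = np.atleast_2d(x)
    leads = leads or [f"L{i + 1}" for i in range(x.shape[0])]
    return Recording(samples=x, fs=fs, lead_labels=leads, participant_id="t")


def _rms(x):
    return float(np.sqrt(np.mean(np.square(x))))


class TestEcgChainSteps:
    def test_baseline_step_cancels_constant(self):
        rec = _rec(np.ones(int(10 * FS)))
        out, _ = pp.ecg_chain(rec, mode="single_step:baseline_ma")
        assert np.max(np.abs(out.samples[0, int(FS):])) < 1e-6

    def test_notch_suppresses_50hz(self):
        t = np.arange(int(30 * FS)) / FS
        rec = _rec(np.sin(2 * np.pi * 50 * t))
        out, _ = pp.ecg_chain(rec, mode="single_step:notch")
        steady = slice(int(5 * FS), int(25 * FS))
        assert _rms(out.samples[0, steady]) <= 0.1 * _rms(rec.samples[0, steady])

    def test_lowpass_passes_5hz(self):
        t = np.arange(int(30 * FS)) / FS
        rec = _rec(np.sin(2 * np.pi * 5 * t))
        out, _ = pp.ecg_chain(rec, mode="single_step:lowpass")
        steady = slice(int(5 * FS), int(25 * FS))
        assert _rms(out.samples[0, steady]) == pytest.approx(
            _rms(rec.samples[0, steady]), rel=0.02)

    def test_cutoff_above_nyquist_rejected(self):
        rec = _rec(np.zeros(int(10 * 181)), fs=181.0)
        with pytest.raises(ValueError):
            pp.lowpass(rec.samples, 181.0, 95.0)

    def test_low_sampling_rate_rejected(self):
        rec = _rec(np.zeros(1000), fs=100.0)
        with pytest.raises(ValueError):
            pp.ecg_chain(rec)

    def test_full_chain_equals_composed_steps(self, rng):
        """Filter-isolation consistency: full mode composes the single steps."""
        x = rng.standard_normal(int(30 * FS))
        rec = _rec(x)
        full, mask = pp.ecg_chain(rec, mode="full")
        step = rec
        for name in ("lowpass", "notch", "baseline_ma"):
            step, _ = pp.ecg_chain(step, mode=f"single_step:{name}")
        assert np.allclose(full.samples[:, mask.keep], step.samples[:, mask.keep])

    def test_chain_preserves_length(self, small_cohort):
        rec = small_cohort[0]
        out, mask = pp.ecg_chain(rec)
        assert out.samples.shape == rec.samples.shape
        assert mask.keep.size == rec.n_samples


class TestSegmentRejection:
    def test_burst_window_rejected(self, rng):
        x = rng.standard_normal(int(60 * FS))
        burst = slice(int(30 * FS), int(32 * FS))
        x[burst] *= 10.0
        mask = pp.reject_bad_segments(_rec(x), variance_win=2.0, variance_z=5.0)
        assert not mask.keep[burst].any()
        assert mask.keep[: int(28 * FS)].all()
        assert set(mask.reasons[~mask.keep]) == {"variance"}

    def test_homogeneous_noise_untouched(self, rng):
        x = rng.standard_normal(int(60 * FS))
        mask = pp.reject_bad_segments(_rec(x), variance_z=8.0)
        assert mask.n_rejected == 0

    def test_all_zero_signal_untouched(self):
        mask = pp.reject_bad_segments(_rec(np.zeros(int(20 * FS))))
        assert mask.n_rejected == 0

    def test_empty_signal_empty_mask(self):
        rec = Recording(samples=np.zeros((1, 0)), fs=FS, lead_labels=["I"],
                        participant_id="t")
        assert pp.reject_bad_segments(rec).keep.size == 0


class TestEogChain:
    def test_dc_offset_removed(self, rng):
        x = 5.0 + 0.01 * rng.standard_normal(int(30 * FS))
        out = pp.eog_chain(_rec(x))
        assert abs(out.samples.mean()) < 1e-3

    def test_gaze_square_wave_preserved(self):
        t = np.arange(int(60 * FS)) / FS
        x = 0.5 * np.sign(np.sin(2 * np.pi * 0.3 * t))
        out = pp.eog_chain(_rec(x))
        # plateau-to-plateau swing retained within 20%
        mid = out.samples[0, int(10 * FS):int(50 * FS)]
        swing = np.percentile(mid, 98) - np.percentile(mid, 2)
        assert swing == pytest.approx(1.0, rel=0.2)

    def test_50hz_attenuated_20db(self):
        t = np.arange(int(60 * FS)) / FS
        x = np.sin(2 * np.pi * 50 * t)
        out = pp.eog_chain(_rec(x))
        steady = slice(int(10 * FS), int(50 * FS))
        assert _rms(out.samples[0, steady]) <= 0.1 * _rms(x[steady])

    def test_too_short_record_rejected(self):
        with pytest.raises(ValueError):
            pp.eog_chain(_rec(np.zeros(16)))


class TestEmgChain:
    def test_cardiac_template_subtraction(self):
        """A pure repeated cardiac artifact is mostly removed at the R windows."""
        tpl = sample_cohort_templates(1, seed=5)[0]
        tpl = BeatTemplate(wave_params=tpl.wave_params, rr_mean=1.0, rr_sd=0.0)
        rec = synthesize_ecg(tpl, leads=1, duration=30.0, noise=NoiseSpec.none(),
                             electrode=ElectrodeModel.ideal(), seed=0)
        r = rec.truth["r_times"]
        bp_only = pp.apply_step(rec, pp.FilterStep("bandpass", {"lo": 20.0, "hi": 90.0}))
        out = pp.emg_chain(rec, r_times=r)
        w = int(0.05 * FS)
        idx = np.concatenate([np.arange(int(t * FS) - w, int(t * FS) + w)
                              for t in r[2:-2]])
        assert _rms(out.samples[0, idx]) <= 0.2 * _rms(bp_only.samples[0, idx])

    def test_no_r_times_skips_template(self, rng):
        x = rng.standard_normal(int(20 * FS))
        rec = _rec(x)
        out = pp.emg_chain(rec, r_times=[])
        ref = pp.apply_step(rec, pp.FilterStep("bandpass", {"lo": 20.0, "hi": 90.0}))
        ref = pp.apply_step(ref, pp.FilterStep("notch", {"freq": 50.0}))
        ref = pp.apply_step(ref, pp.FilterStep("wavelet_denoise"))
        assert np.allclose(out.samples, ref.samples)

    def test_10hz_attenuated_20db(self):
        t = np.arange(int(30 * FS)) / FS
        x = np.sin(2 * np.pi * 10 * t)
        out = pp.emg_chain(_rec(x), r_times=[])
        steady = slice(int(5 * FS), int(25 * FS))
        assert _rms(out.samples[0, steady]) <= 0.1 * _rms(x[steady])


class TestEegChain:
    def test_linear_ramp_removed(self):
        t = np.arange(int(30 * FS)) / FS
        out = pp.eeg_chain(_rec(2.5 * t))
        slope = np.polyfit(t, out.samples[0], 1)[0]
        assert abs(slope) < 1e-6

    def test_alpha_band_preserved(self):
        t = np.arange(int(30 * FS)) / FS
        x = np.sin(2 * np.pi * 10 * t)
        out = pp.eeg_chain(_rec(x))
        steady = slice(int(5 * FS), int(25 * FS))
        assert _rms(out.samples[0, steady]) == pytest.approx(_rms(x[steady]), rel=0.05)

    def test_60hz_attenuated_15db(self):
        t = np.arange(int(30 * FS)) / FS
        x = np.sin(2 * np.pi * 60 * t)
        out = pp.eeg_chain(_rec(x))
        steady = slice(int(5 * FS), int(25 * FS))
        assert _rms(out.samples[0, steady]) <= 10 ** (-15 / 20) * _rms(x[steady])


class TestDenoisingEnergy:
    @pytest.mark.parametrize("step", ["wavelet_denoise", "median"])
    def test_denoising_never_increases_energy(self, rng, step):
        for _ in range(5):
            x = rng.standard_normal(2048)
            x -= x.mean()
            y = pp._STEP_FUNCS[step](x, FS, {})
            assert np.sum(y ** 2) <= np.sum(x ** 2) * (1 + 1e-9)


def test_clean_signal_survives_ecg_chain():
    """Noiseless ideal-electrode ECG passes the chain nearly unchanged."""
    tpl = sample_cohort_templates(1, seed=3)[0]
    tpl = BeatTemplate(wave_params=tpl.wave_params, rr_mean=1.0, rr_sd=0.0)
    rec = synthesize_ecg(tpl, leads=1, duration=30.0, noise=NoiseSpec.none(),
                         electrode=ElectrodeModel.ideal(), seed=0)
    out, _ = pp.ecg_chain(rec)
    r_amp = tpl.wave_params["R"].amplitude
    core = slice(int(2 * FS), int(28 * FS))  # away from filter warm-up
    dev = np.max(np.abs(out.samples[0, core] - rec.samples[0, core]))
    assert dev < 0.01 * r_amp
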