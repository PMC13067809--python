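"""Synthetic multi-participant biosignal cohort with known ground truth.

Real benchmarking cohorts for skin-electrode comparisons are rarely
released, so every downstream stage in this package is exercised against a
generator that emulates their statistical structure: 3-lead chest ECG at
200 Hz with per-participant beat morphology, RR variability, baseline
wander, 50 Hz mains plus an 80 Hz component, broadband noise, motion
artifact bursts, and an electrode-dependent low-pass transfer.  Ground
truth (clean waveform and R-peak times) is carried along for oracle-style
evaluation of detectors, SNR estimators and clustering.

Beats are modelled as a sum of five Gaussians (P, Q, R, S, T), the
standard dynamical-ECG parameterization; leads differ by a per-lead,
per-wave diagonal amplitude gain, which reproduces inter-lead information
structure without a torso model.  The front end is AC-coupled: the clean
beat train is mean-subtracted so the record carries no DC offset.

The generator also synthesizes single-time-constant equivalent-circuit
impedance spectra, Z(ω) = R_s + R_ct/(1 + jω R_ct C_dl), whose analytic
relaxation frequency 1/(2π R_ct C_dl) serves as the oracle for the
dielectric analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .dielectric import ImpedanceSpectrum

WAVE_NAMES = ("P", "Q", "R", "S", "T")

#: Cohort priors for per-participant template parameters, as truncated
#: normals (mean, sd, lo, hi).  Amplitudes in mV, centers/widths in s
#: relative to the R peak.  Values are chosen to emulate a resting adult
#: chest ECG; they are configuration, not claims about any dataset.
COHORT_PRIORS: dict[str, tuple[float, float, float, float]] = {
    "p_amp": (0.15, 0.03, 0.08, 0.24),
    "q_amp": (-0.10, 0.04, -0.22, -0.02),
    "r_amp": (1.10, 0.10, 0.85, 1.35),
    "s_amp": (-0.25, 0.05, -0.38, -0.12),
    "t_amp": (0.30, 0.05, 0.20, 0.42),
    "p_center": (-0.160, 0.018, -0.200, -0.120),
    "q_center": (-0.040, 0.006, -0.058, -0.024),
    "s_center": (0.040, 0.006, 0.024, 0.058),
    "t_center": (0.200, 0.025, 0.140, 0.250),
    "p_width": (0.040, 0.008, 0.022, 0.060),
    "q_width": (0.015, 0.003, 0.008, 0.022),
    "r_width": (0.022, 0.004, 0.012, 0.032),
    "s_width": (0.015, 0.003, 0.008, 0.022),
    "t_width": (0.065, 0.012, 0.040, 0.095),
    "rr_mean": (0.95, 0.08, 0.91, 1.20),
    "rr_sd": (0.035, 0.010, 0.010, 0.060),
}

#: Per-lead diagonal gains on wave amplitudes.  The three gain vectors
#: are deliberately non-proportional — lead II is R-dominant, lead I
#: P/T-accented with a small QRS, lead III has a deep S and inverted T —
#: so the leads carry genuinely different projections of the same beat
#: (different waveform shape, not just overall scale), which is the
#: inter-lead information structure the identification analysis exploits.
DEFAULT_LEAD_GAINS: dict[str, dict[str, float]] = {
    "I": {"P": 1.20, "Q": 0.50, "R": 0.45, "S": 0.45, "T": 1.25},
    "II": {"P": 1.0, "Q": 1.0, "R": 1.0, "S": 1.0, "T": 0.55},
    "III": {"P": 0.45, "Q": 0.90, "R": 0.55, "S": 1.35, "T": -0.55},
}

LEAD_LABELS = ("I", "II", "III")


@dataclass(frozen=True)
class Wave:
    """One Gaussian component: amplitude (mV), center (s, R at 0), width (s)."""

    amplitude: float
    center: float
    width: float


@dataclass(frozen=True)
class BeatTemplate:
    """Per-participant beat morphology and rhythm parameters."""

    wave_params: dict[str, Wave]
    rr_mean: float
    rr_sd: float

    def __post_init__(self) -> None:
        missing = set(WAVE_NAMES) - set(self.wave_params)
        if missing:
            raise ValueError(f"missing wave components: {sorted(missing)}")
        centers = [self.wave_params[w].center for w in WAVE_NAMES]
        if any(np.diff(centers) <= 0):
            raise ValueError("wave centers must be strictly ordered P < Q < R < S < T")
        if any(self.wave_params[w].width <= 0 for w in WAVE_NAMES):
            raise ValueError("wave widths must be positive")
        span = self.wave_params["T"].center - self.wave_params["P"].center
        if self.rr_mean <= 2.0 * span:
            raise ValueError("rr_mean must exceed twice the P-to-T span")
        if self.rr_sd < 0:
            raise ValueError("rr_sd must be nonnegative")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise model for a synthetic recording.

    Amplitudes in mV; ``artifact_rate`` in events per minute.  The
    defaults emulate a seated resting recording with moderate mains
    pickup; ``NoiseSpec.none()`` disables everything.
    """

    baseline_amp: float = 0.15
    baseline_freq: float = 0.25
    powerline_50: float = 0.05
    powerline_80: float = 0.02
    broadband_sd: float = 0.03
    artifact_rate: float = 2.0
    artifact_amp: float = 0.5
    artifact_dur: float = 1.0

    def __post_init__(self) -> None:
        for name in ("baseline_amp", "powerline_50", "powerline_80",
                     "broadband_sd", "artifact_rate", "artifact_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.artifact_dur <= 0:
            raise ValueError("artifact_dur must be positive")
        if self.baseline_freq >= 1.0:
            raise ValueError("baseline wander is sub-1 Hz by definition")

    @classmethod
    def none(cls) -> "NoiseSpec":
        return cls(baseline_amp=0.0, baseline_freq=0.25, powerline_50=0.0,
                   powerline_80=0.0, broadband_sd=0.0, artifact_rate=0.0,
                   artifact_amp=0.0, artifact_dur=1.0)


@dataclass(frozen=True)
class ElectrodeModel:
    """Minimal electrode transfer model.

    A single-pole low-pass at ``lp_cutoff`` stands in for the interfacial
    capacitive filtering; ``noise_gain`` scales broadband/mains pickup and
    ``drift_gain`` scales baseline wander and motion artifacts.  The
    hydrogel (PPHG) defaults encode the qualitative contrast reported for
    capacitive hydrogel interfaces — lower cutoff, less pickup, less
    drift — relative to faradaic Ag/AgCl.  They are configuration, not
    measured device parameters.
    """

    kind: str
    lp_cutoff: float
    noise_gain: float
    drift_gain: float

    def __post_init__(self) -> None:
        if self.kind not in ("PPHG", "AgCl", "ideal"):
            raise ValueError("electrode kind must be 'PPHG', 'AgCl' or 'ideal'")
        if self.lp_cutoff <= 0:
            raise ValueError("lp_cutoff must be positive")
        if self.noise_gain < 0 or self.drift_gain < 0:
            raise ValueError("gains must be >= 0")
        if self.kind == "ideal" and (self.noise_gain != 0 or self.drift_gain != 0):
            raise ValueError("ideal electrode must have zero noise/drift gains")

    @classmethod
    def pphg(cls) -> "ElectrodeModel":
        return cls(kind="PPHG", lp_cutoff=45.0, noise_gain=0.6, drift_gain=0.5)

    @classmethod
    def agcl(cls) -> "ElectrodeModel":
        return cls(kind="AgCl", lp_cutoff=95.0, noise_gain=1.0, drift_gain=1.0)

    @classmethod
    def ideal(cls) -> "ElectrodeModel":
        return cls(kind="ideal", lp_cutoff=1e9, noise_gain=0.0, drift_gain=0.0)


@dataclass
class Recording:
    """Uniformly sampled multichannel recording in mV.

    ``truth`` optionally carries generator ground truth: R-peak times
    (``r_times``, s) and the clean pre-noise signal (``clean``, mV).
    """

    samples: np.ndarray  # (n_channels, n_samples)
    fs: float
    lead_labels: list[str]
    participant_id: str
    electrode: str = "ideal"
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.lead_labels) != self.samples.shape[0]:
            raise ValueError("one lead label per channel required")
        if len(set(self.lead_labels)) != len(self.lead_labels):
            raise ValueError("lead labels must be unique")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def channel(self, lead: str) -> np.ndarray:
        return self.samples[self.lead_labels.index(lead)]

    def with_samples(self, samples: np.ndarray) -> "Recording":
        return Recording(samples=samples, fs=self.fs,
                         lead_labels=list(self.lead_labels),
                         participant_id=self.participant_id,
                         electrode=self.electrode,
                         truth=self.truth)


def _draw(rng: np.random.Generator, prior: tuple[float, float, float, float]) -> float:
    mean, sd, lo, hi = prior
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def truncated_prior_mean(name: str) -> float:
    """Analytic mean of a configured truncated-normal prior (test oracle)."""
    mean, sd, lo, hi = COHORT_PRIORS[name]
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.mean(a, b, loc=mean, scale=sd))


def sample_cohort_templates(n_participants: int, seed: int) -> list[BeatTemplate]:
    """Draw per-participant beat templates from the cohort priors.

    Deterministic for a fixed seed; each participant gets an independent
    draw of amplitudes, timings, widths and rhythm parameters.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    rng = np.random.default_rng(seed)
    templates = []
    for _ in range(n_participants):
        waves = {}
        for w in WAVE_NAMES:
            amp = _draw(rng, COHORT_PRIORS[f"{w.lower()}_amp"]) if w != "R" \
                else _draw(rng, COHORT_PRIORS["r_amp"])
            center = 0.0 if w == "R" else _draw(rng, COHORT_PRIORS[f"{w.lower()}_center"])
            width = _draw(rng, COHORT_PRIORS[f"{w.lower()}_width"])
            waves[w] = Wave(amplitude=amp, center=center, width=width)
        rr_mean = _draw(rng, COHORT_PRIORS["rr_mean"])
        rr_sd = _draw(rng, COHORT_PRIORS["rr_sd"])
        templates.append(BeatTemplate(wave_params=waves, rr_mean=rr_mean, rr_sd=rr_sd))
    return templates


def _beat_train(template: BeatTemplate, gains: dict[str, float],
                r_times: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Sum-of-Gaussians train for one lead, evaluated in local windows."""
    fs = 1.0 / (t[1] - t[0])
    x = np.zeros_like(t)
    half = max(abs(template.wave_params["P"].center) + 4 * template.wave_params["P"].width,
               template.wave_params["T"].center + 4 * template.wave_params["T"].width) + 0.05
    for r in r_times:
        i0 = max(0, int((r - half) * fs))
        i1 = min(t.size, int((r + half) * fs) + 1)
        tw = t[i0:i1]
        for name in WAVE_NAMES:
            w = template.wave_params[name]
            amp = w.amplitude * gains.get(name, 1.0)
            x[i0:i1] += amp * np.exp(-0.5 * ((tw - r - w.center) / w.width) ** 2)
    return x


def synthesize_ecg(template: BeatTemplate,
                   leads: int = 3,
                   duration: float = 420.0,
                   fs: float = 200.0,
                   noise: NoiseSpec | None = None,
                   electrode: ElectrodeModel | None = None,
                   seed: int = 0,
                   participant_id: str = "p1",
                   lead_gains: dict[str, dict[str, float]] | None = None) -> Recording:
    """Synthesize a multi-lead ECG recording with ground truth.

    The clean train is AC-coupled (mean-subtracted) per lead, then
    environmental noise scaled by the electrode's gains is added and the
    sum is passed through the electrode's first-order low-pass transfer.
    An ``ideal`` electrode returns the clean train exactly.

    RR intervals are i.i.d. Gaussian around ``template.rr_mean``
    truncated at ±3 SD; the first R lands at ``rr_mean/2``.
    """
    if noise is None:
        noise = NoiseSpec()
    if electrode is None:
        electrode = ElectrodeModel.ideal()
    if duration < 5.0 * template.rr_mean:
        raise ValueError("duration must cover at least five mean RR intervals")
    if fs < 100:
        raise ValueError("fs must be >= 100 Hz")
    if leads < 1:
        raise ValueError("need at least one lead")

    rng = np.random.default_rng(seed)
    labels = [LEAD_LABELS[i] if i < len(LEAD_LABELS) else f"L{i + 1}"
              for i in range(leads)]
    gains_map = lead_gains if lead_gains is not None else DEFAULT_LEAD_GAINS

    # R-peak schedule
    r_times = []
    r = template.rr_mean / 2.0
    while r < duration:
        r_times.append(r)
        jitter = rng.standard_normal()
        jitter = float(np.clip(jitter, -3.0, 3.0))
        r += template.rr_mean + template.rr_sd * jitter
    r_times = np.asarray(r_times)

    n = int(round(duration * fs))
    t = np.arange(n) / fs
    clean = np.zeros((leads, n))
    for i, lab in enumerate(labels):
        gains = gains_map.get(lab, {w: 1.0 for w in WAVE_NAMES})
        clean[i] = _beat_train(template, gains, r_times, t)
        clean[i] -= clean[i].mean()  # AC-coupled front end

    # environmental noise, shared phase structure per lead but independent draws
    out = np.empty_like(clean)
    for i in range(leads):
        wander = noise.baseline_amp * np.sin(
            2 * np.pi * noise.baseline_freq * t + rng.uniform(0, 2 * np.pi))
        mains = (noise.powerline_50 * np.sin(2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi))
                 + noise.powerline_80 * np.sin(2 * np.pi * 80.0 * t + rng.uniform(0, 2 * np.pi)))
        broadband = noise.broadband_sd * rng.standard_normal(n)
        bursts = np.zeros(n)
        n_events = rng.poisson(noise.artifact_rate * duration / 60.0)
        w = int(round(noise.artifact_dur * fs))
        if w >= 2:
            lump = signal.windows.hann(w)
            for _ in range(n_events):
                start = rng.integers(0, max(1, n - w))
                bursts[start:start + w] += noise.artifact_amp * rng.choice([-1.0, 1.0]) * lump
        x = (clean[i]
             + electrode.noise_gain * (mains + broadband)
             + electrode.drift_gain * (wander + bursts))
        if electrode.kind == "ideal":
            out[i] = x
        else:
            b, a = signal.butter(1, electrode.lp_cutoff / (fs / 2.0), btype="low")
            out[i] = signal.lfilter(b, a, x)

    return Recording(samples=out, fs=fs, lead_labels=labels,
                     participant_id=participant_id, electrode=electrode.kind,
                     truth={"r_times": r_times, "clean": clean})


def synthesize_eis(r_s: float, r_ct: float, c_dl: float,
                   freqs: np.ndarray) -> ImpedanceSpectrum:
    """Single-time-constant equivalent circuit Z(ω) = R_s + R_ct/(1 + jωR_ctC_dl).

    The −Z″ semicircle peaks at f = 1/(2π R_ct C_dl), which makes this
    the analytic oracle for relaxation-time recovery.
    """
    if r_s < 0:
        raise ValueError("r_s must be >= 0")
    if r_ct <= 0 or c_dl <= 0:
        raise ValueError("r_ct and c_dl must be positive")
    freqs = np.asarray(freqs, dtype=float)
    if freqs.ndim != 1 or freqs.size == 0 or np.any(freqs <= 0):
        raise ValueError("freqs must be positive")
    if np.any(np.diff(freqs) <= 0):
        raise ValueError("freqs must be strictly ascending")
    omega = 2 * np.pi * freqs
    z = r_s + r_ct / (1.0 + 1j * omega * r_ct * c_dl)
    return ImpedanceSpectrum(freq=freqs, z_real=z.real, z_imag=z.imag)
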