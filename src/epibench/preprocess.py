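"""Modality-specific preprocessing chains for ECG, EOG, EMG and EEG.

Each chain composes reusable single filters so that any step can also be
applied in isolation (needed for processed-to-raw band-power analyses).
All IIR filters are applied forward-backward (zero phase): morphology
measurements downstream would be biased by group delay, so the stated
passband/stopband figures refer to the squared magnitude response.

Chains (in order):

* ECG:  order-4 Butterworth low-pass at 90 Hz → order-2 band-stop
  notches at 50 and 80 Hz (±1 Hz) → subtraction of a trailing 1-s
  moving-average baseline → variance-based bad-segment rejection.
* EOG:  order-4 band-pass 0.1–15 Hz → mean subtraction → linear detrend
  → db4 level-3 wavelet denoising → 50 ms median filter.
* EMG:  band-pass 20–90 Hz → 50 Hz notch → amplitude-scaled cardiac
  template subtraction at supplied R times → db4 wavelet denoising.
* EEG:  linear detrend → order-4 low-pass at 49 Hz.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal

from .synthetic import Recording

logger = logging.getLogger(__name__)

NOTCH_HALF_BANDWIDTH = 1.0  # Hz; realizes a "narrow-band" order-2 band-stop


@dataclass
class FilterStep:
    """One named filter with its parameter map (cutoffs in Hz, windows in s)."""

    name: str
    params: dict = field(default_factory=dict)

    _VALID = {"lowpass", "bandpass", "notch", "baseline_ma", "wavelet_denoise",
              "median", "detrend", "mean_subtract"}

    def __post_init__(self) -> None:
        if self.name not in self._VALID:
            raise ValueError(f"unknown filter step '{self.name}'")


@dataclass
class SegmentMask:
    """Per-sample keep/reject mask with reason codes on rejected samples."""

    keep: np.ndarray                 # bool, per sample
    reasons: np.ndarray              # str codes, '' on kept samples

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)
        self.reasons = np.asarray(self.reasons, dtype=object)
        if self.keep.shape != self.reasons.shape:
            raise ValueError("keep and reasons must have equal length")
        if any(r != "" for r in self.reasons[self.keep]):
            raise ValueError("reason codes are only allowed on rejected samples")

    @classmethod
    def all_keep(cls, n: int) -> "SegmentMask":
        return cls(keep=np.ones(n, dtype=bool),
                   reasons=np.full(n, "", dtype=object))

    @property
    def n_rejected(self) -> int:
        return int((~self.keep).sum())


# --- primitive filters (arrays in, arrays out, length preserving) -----------

def _check_cutoff(cutoff: float, fs: float) -> None:
    if cutoff >= fs / 2.0:
        raise ValueError(f"cutoff {cutoff} Hz is at or above Nyquist ({fs / 2} Hz)")


def lowpass(x: np.ndarray, fs: float, cutoff: float, order: int = 4) -> np.ndarray:
    _check_cutoff(cutoff, fs)
    sos = signal.butter(order, cutoff / (fs / 2.0), btype="low", output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


def bandpass(x: np.ndarray, fs: float, lo: float, hi: float, order: int = 4) -> np.ndarray:
    _check_cutoff(hi, fs)
    if lo <= 0 or lo >= hi:
        raise ValueError("need 0 < lo < hi")
    sos = signal.butter(order, [lo / (fs / 2.0), hi / (fs / 2.0)],
                        btype="band", output="sos")
    # a sub-1 Hz high-pass edge rings for seconds; pad accordingly so the
    # edge transient stays out of the record
    n = np.shape(x)[-1]
    padlen = int(min(n - 1, max(3 * fs / lo, 3 * (2 * len(sos) + 1))))
    return signal.sosfiltfilt(sos, x, axis=-1, padlen=padlen)


def notch(x: np.ndarray, fs: float, freq: float, order: int = 2,
          half_bw: float = NOTCH_HALF_BANDWIDTH) -> np.ndarray:
    _check_cutoff(freq + half_bw, fs)
    sos = signal.butter(order, [(freq - half_bw) / (fs / 2.0),
                                (freq + half_bw) / (fs / 2.0)],
                        btype="bandstop", output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


def baseline_ma(x: np.ndarray, fs: float, window: float = 1.0) -> np.ndarray:
    """Subtract a trailing ("lookback") moving-average baseline estimate."""
    if window <= 0:
        raise ValueError("window must be positive")
    w = max(1, int(round(window * fs)))
    kernel = np.ones(w) / w
    baseline = signal.lfilter(kernel, [1.0], x, axis=-1)
    return x - baseline


def mean_subtract(x: np.ndarray) -> np.ndarray:
    return x - np.mean(x, axis=-1, keepdims=True)


def detrend(x: np.ndarray) -> np.ndarray:
    return signal.detrend(x, axis=-1, type="linear")


def median_filter(x: np.ndarray, fs: float, window: float = 0.05) -> np.ndarray:
    k = int(round(window * fs))
    if k % 2 == 0:
        k += 1
    k = max(k, 1)
    x2 = np.atleast_2d(x)
    out = np.stack([signal.medfilt(row, kernel_size=k) for row in x2])
    return out.reshape(np.shape(x))


def wavelet_denoise(x: np.ndarray, wavelet: str = "db4", level: int = 3) -> np.ndarray:
    """Soft-threshold wavelet denoising, universal rule per detail level.

    The noise scale of each detail band is estimated with the MAD rule
    sigma = median(|d|)/0.6745 and thresholded at sigma*sqrt(2 ln n).
    """
    x2 = np.atleast_2d(x)
    n = x2.shape[-1]
    if n < 2 ** level * 8:
        raise ValueError("record too short for the requested decomposition level")
    out = np.empty_like(x2)
    for i, row in enumerate(x2):
        coeffs = pywt.wavedec(row, wavelet, level=level)
        denoised = [coeffs[0]]
        for d in coeffs[1:]:
            sigma = np.median(np.abs(d)) / 0.6745
            thr = sigma * np.sqrt(2.0 * np.log(max(n, 2)))
            denoised.append(pywt.threshold(d, thr, mode="soft"))
        rec = pywt.waverec(denoised, wavelet)
        out[i] = rec[:n]
    return out.reshape(np.shape(x))


_STEP_FUNCS = {
    "lowpass": lambda x, fs, p: lowpass(x, fs, p.get("cutoff", 90.0), p.get("order", 4)),
    "bandpass": lambda x, fs, p: bandpass(x, fs, p["lo"], p["hi"], p.get("order", 4)),
    "notch": lambda x, fs, p: notch(x, fs, p["freq"], p.get("order", 2),
                                    p.get("half_bw", NOTCH_HALF_BANDWIDTH)),
    "baseline_ma": lambda x, fs, p: baseline_ma(x, fs, p.get("window", 1.0)),
    "mean_subtract": lambda x, fs, p: mean_subtract(x),
    "detrend": lambda x, fs, p: detrend(x),
    "median": lambda x, fs, p: median_filter(x, fs, p.get("window", 0.05)),
    "wavelet_denoise": lambda x, fs, p: wavelet_denoise(
        x, p.get("wavelet", "db4"), p.get("level", 3)),
}


def apply_step(rec: Recording, step: FilterStep) -> Recording:
    """Apply a single named filter step to every channel of a recording."""
    out = _STEP_FUNCS[step.name](rec.samples, rec.fs, step.params)
    logger.info("applied %s (%s) on %s", step.name, step.params, rec.participant_id)
    return rec.with_samples(out)


ECG_STEPS = [
    FilterStep("lowpass", {"cutoff": 90.0, "order": 4}),
    FilterStep("notch", {"freq": 50.0, "order": 2}),
    FilterStep("notch", {"freq": 80.0, "order": 2}),
    FilterStep("baseline_ma", {"window": 1.0}),
]

EOG_STEPS = [
    FilterStep("bandpass", {"lo": 0.1, "hi": 15.0, "order": 4}),
    FilterStep("mean_subtract"),
    FilterStep("detrend"),
    FilterStep("wavelet_denoise", {"wavelet": "db4", "level": 3}),
    FilterStep("median", {"window": 0.05}),
]

EEG_STEPS = [
    FilterStep("detrend"),
    FilterStep("lowpass", {"cutoff": 49.0, "order": 4}),
]


def reject_bad_segments(rec: Recording,
                        variance_win: float = 2.0,
                        variance_z: float = 5.0,
                        impedance_series: np.ndarray | None = None,
                        impedance_threshold: float | None = None) -> SegmentMask:
    """Variance (and optionally impedance) based bad-segment rejection.

    The record is cut into non-overlapping windows of ``variance_win``
    seconds; windows whose log-variance robust z-score (median/MAD)
    exceeds ``variance_z`` on any channel are rejected with reason code
    ``"variance"``.  If an impedance series is supplied, samples whose
    impedance exceeds the threshold are rejected with reason
    ``"impedance"``; otherwise that rule is skipped and logged.
    """
    if variance_win <= 0:
        raise ValueError("variance_win must be positive")
    n = rec.n_samples
    mask = SegmentMask.all_keep(n)
    if n == 0:
        return mask
    w = max(1, int(round(variance_win * rec.fs)))
    n_win = n // w
    if n_win >= 3:
        for ch in rec.samples:
            variances = np.array([ch[k * w:(k + 1) * w].var() for k in range(n_win)])
            if np.all(variances == 0):
                continue
            logv = np.log(np.maximum(variances, np.finfo(float).tiny))
            med = np.median(logv)
            mad = np.median(np.abs(logv - med))
            if mad == 0:
                continue
            z = (logv - med) / (1.4826 * mad)
            for k in np.nonzero(z > variance_z)[0]:
                mask.keep[k * w:(k + 1) * w] = False
                mask.reasons[k * w:(k + 1) * w] = "variance"
    if impedance_series is not None and impedance_threshold is not None:
        bad = np.asarray(impedance_series) > impedance_threshold
        mask.keep[bad] = False
        mask.reasons[bad] = "impedance"
    else:
        logger.info("impedance series unavailable; impedance rule skipped")
    logger.info("segment rejection: %d of %d samples rejected", mask.n_rejected, n)
    return mask


def ecg_chain(rec: Recording, mode: str = "full",
              variance_win: float = 2.0,
              variance_z: float = 5.0) -> tuple[Recording, SegmentMask]:
    """ECG preprocessing chain (or one step of it).

    ``mode="full"`` applies low-pass → 50/80 Hz notches → baseline
    removal → segment rejection.  ``mode="single_step:<name>"`` applies
    exactly one named step and returns an all-keep mask, as required for
    per-filter band-power ratio analyses.
    """
    if rec.fs <= 180:
        raise ValueError("ECG chain needs fs > 180 Hz for the 90 Hz cutoff")
    if mode == "full":
        out = rec
        for step in ECG_STEPS:
            out = apply_step(out, step)
        mask = reject_bad_segments(out, variance_win=variance_win, variance_z=variance_z)
        return out, mask
    if mode.startswith("single_step:"):
        name = mode.split(":", 1)[1]
        matching = [s for s in ECG_STEPS if s.name == name]
        if name == "notch" and not matching:
            raise ValueError("no notch step configured")
        if not matching:
            raise ValueError(f"step '{name}' is not part of the ECG chain")
        out = rec
        for step in matching:  # both notches count as the notch step
            out = apply_step(out, step)
        return out, SegmentMask.all_keep(rec.n_samples)
    raise ValueError(f"unknown mode '{mode}'")


def eog_chain(rec: Recording) -> Recording:
    out = rec
    for step in EOG_STEPS:
        out = apply_step(out, step)
    return out


def emg_chain(rec: Recording, r_times: np.ndarray | list | None = None,
              template_halfwidth: float = 0.15) -> Recording:
    """EMG chain with amplitude-scaled cardiac template subtraction.

    The cardiac template is the mean of windows (±``template_halfwidth``
    s) around the supplied R times on the band-passed signal; each beat
    window gets a least-squares scale before subtraction.  With fewer
    than three R times the template step is skipped with a warning.
    """
    out = apply_step(rec, FilterStep("bandpass", {"lo": 20.0, "hi": 90.0, "order": 4}))
    out = apply_step(out, FilterStep("notch", {"freq": 50.0, "order": 2}))
    r_times = np.asarray(r_times, dtype=float) if r_times is not None else np.array([])
    if np.any(np.diff(r_times) <= 0):
        raise ValueError("r_times must be sorted and strictly increasing")
    if r_times.size >= 3:
        half = int(round(template_halfwidth * rec.fs))
        x = out.samples.copy()
        for ch in range(x.shape[0]):
            idx = np.round(r_times * rec.fs).astype(int)
            windows = [x[ch, i - half:i + half + 1] for i in idx
                       if i - half >= 0 and i + half + 1 <= x.shape[1]]
            if len(windows) < 3:
                warnings.warn("too few complete R windows; template step skipped")
                break
            template = np.mean(windows, axis=0)
            energy = float(template @ template)
            if energy == 0:
                continue
            for i in idx:
                if i - half < 0 or i + half + 1 > x.shape[1]:
                    continue
                seg = x[ch, i - half:i + half + 1]
                scale = float(seg @ template) / energy
                x[ch, i - half:i + half + 1] = seg - scale * template
        out = out.with_samples(x)
    elif r_times.size:
        warnings.warn("fewer than 3 R times; cardiac template step skipped")
    out = apply_step(out, FilterStep("wavelet_denoise", {"wavelet": "db4", "level": 3}))
    return out


def eeg_chain(rec: Recording) -> Recording:
    out = rec
    for step in EEG_STEPS:
        out = apply_step(out, step)
    return out


CHAINS = {"ecg": ECG_STEPS, "eog": EOG_STEPS, "eeg": EEG_STEPS}
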