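"""Variance-based SNR estimation and spectral quality analyses.

SNR is defined as the variance ratio between an activity segment and a
baseline noise segment, in decibels:

    SNR_dB = 10 log10( sigma^2_signal / sigma^2_noise )

For ECG the noise segments are 100 ms windows placed halfway between
successive QRS complexes, which samples the baseline while avoiding
physiological waveforms.  Spectral analyses use Welch's method (2-s
Hamming windows, 50% overlap) for PSDs, trapezoidal band-power
integration, a sliding-window time-resolved delta (0.5–4 Hz) power
profile, and a Morlet continuous-wavelet scalogram for visualization.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal as sps

from .synthetic import Recording

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.lo < self.hi):
            raise ValueError("need 0 <= lo < hi")


#: Default band edges for processed-to-raw power-ratio analyses.  The
#: band names follow the noise/ECG-content split (motion artifacts at
#: the bottom, mains region at the top); edges are configuration.
DEFAULT_BANDS = [
    BandDefinition("motion", 0.05, 0.5),
    BandDefinition("LF", 0.5, 4.0),
    BandDefinition("MF", 4.0, 15.0),
    BandDefinition("HF", 15.0, 40.0),
    BandDefinition("UHF1", 40.0, 60.0),
    BandDefinition("UHF2", 60.0, 90.0),
]

DELTA_BAND = BandDefinition("delta", 0.5, 4.0)


def snr_variance(signal_seg: np.ndarray, noise_seg: np.ndarray) -> float:
    """10·log10 of the activity-to-noise variance ratio, in dB."""
    s = np.asarray(signal_seg, dtype=float)
    n = np.asarray(noise_seg, dtype=float)
    if s.size == 0 or n.size == 0:
        raise ValueError("segments must be nonempty")
    var_n = float(n.var())
    if var_n == 0:
        raise ValueError("noise segment has zero variance")
    return float(10.0 * np.log10(s.var() / var_n))


def ecg_noise_windows(r_times: np.ndarray, width: float = 0.1,
                      duration: float | None = None) -> list[tuple[float, float]]:
    """100 ms noise windows centered halfway between successive R peaks.

    Windows extending past the record bounds (when ``duration`` is
    given) are dropped.  Fewer than two peaks yields an empty list with
    a warning.
    """
    r_times = np.asarray(r_times, dtype=float)
    if r_times.size < 2:
        warnings.warn("fewer than 2 R peaks: no noise windows")
        return []
    mids = (r_times[:-1] + r_times[1:]) / 2.0
    windows = []
    for m in mids:
        t0, t1 = m - width / 2.0, m + width / 2.0
        if t0 < 0 or (duration is not None and t1 > duration):
            continue
        windows.append((t0, t1))
    return windows


def ecg_snr(rec: Recording, r_times: np.ndarray, channel: int = 0,
            width: float = 0.1) -> dict:
    """Variance SNR of an ECG channel with QRS-anchored noise windows.

    The signal variance is taken over the whole channel; the noise
    variance pools the inter-beat windows.
    """
    x = rec.samples[channel]
    windows = ecg_noise_windows(r_times, width=width, duration=rec.duration)
    if not windows:
        raise ValueError("no usable noise windows")
    segs = [x[int(round(t0 * rec.fs)):int(round(t1 * rec.fs))] for t0, t1 in windows]
    noise = np.concatenate(segs)
    var_signal, var_noise = float(x.var()), float(noise.var())
    return {"snr_db": 10.0 * np.log10(var_signal / var_noise),
            "var_signal": var_signal, "var_noise": var_noise,
            "n_noise_windows": len(windows)}


def welch_psd(x: np.ndarray | Recording, fs: float | None = None,
              win: float = 2.0, overlap: float = 0.5,
              channel: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch PSD with Hamming windows (defaults: 2 s, 50%)."""
    if isinstance(x, Recording):
        fs = x.fs
        x = x.samples[channel]
    x = np.asarray(x, dtype=float)
    if fs is None:
        raise ValueError("fs required for array input")
    nperseg = int(round(win * fs))
    if x.size < nperseg:
        raise ValueError("record shorter than one Welch window")
    freqs, psd = sps.welch(x, fs=fs, window="hamming", nperseg=nperseg,
                           noverlap=int(round(nperseg * overlap)))
    return freqs, psd


def band_power(freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal integral of the PSD over [lo, hi]."""
    if lo >= hi:
        raise ValueError("empty band")
    m = (freqs >= lo) & (freqs <= hi)
    if m.sum() < 2:
        raise ValueError("band contains fewer than two frequency bins")
    return float(np.trapezoid(psd[m], freqs[m]))


def band_power_ratio(raw: Recording, processed: Recording,
                     bands: list[BandDefinition] | None = None,
                     channel: int = 0, win: float = 20.0) -> dict[str, float]:
    """Processed-to-raw band power ratio per band (Welch integration).

    The default 20-s Welch window gives 0.05 Hz resolution so the lowest
    (motion-artifact) band is resolvable.  A band with (numerically)
    zero raw power yields NaN with a warning rather than an arbitrary
    ratio.
    """
    if bands is None:
        bands = DEFAULT_BANDS
    if raw.fs != processed.fs or raw.n_samples != processed.n_samples:
        raise ValueError("raw and processed recordings must share fs and length")
    f_raw, p_raw = welch_psd(raw, win=win, channel=channel)
    f_proc, p_proc = welch_psd(processed, win=win, channel=channel)
    out = {}
    for band in bands:
        pr = band_power(f_raw, p_raw, band.lo, band.hi)
        pp = band_power(f_proc, p_proc, band.lo, band.hi)
        if pr <= 0:
            warnings.warn(f"zero raw power in band {band.name}; ratio undefined")
            out[band.name] = float("nan")
        else:
            out[band.name] = pp / pr
    return out


def delta_power_timeseries(x: np.ndarray | Recording, fs: float | None = None,
                           win: float = 2.0, step: float = 0.5,
                           band: BandDefinition = DELTA_BAND,
                           channel: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window delta band power, timestamped at window centers."""
    if isinstance(x, Recording):
        fs = x.fs
        x = x.samples[channel]
    x = np.asarray(x, dtype=float)
    w = int(round(win * fs))
    s = max(1, int(round(step * fs)))
    if x.size < w:
        raise ValueError("record shorter than one window")
    starts = np.arange(0, x.size - w + 1, s)
    times = (starts + w / 2.0) / fs
    powers = np.empty(starts.size)
    for i, st in enumerate(starts):
        seg = x[st:st + w]
        freqs, psd = sps.periodogram(seg, fs=fs, window="hamming")
        m = (freqs >= band.lo) & (freqs <= band.hi)
        powers[i] = np.trapezoid(psd[m], freqs[m])
    return times, powers


def scalogram(x: np.ndarray | Recording, fs: float | None = None,
              fmin: float = 0.5, fmax: float = 49.0,
              voices_per_octave: int = 12,
              channel: int = 0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Morlet CWT magnitude map over [fmin, fmax] (visualization output).

    Returns (times, freqs, magnitude) with freqs descending from fmax.
    """
    if isinstance(x, Recording):
        fs = x.fs
        x = x.samples[channel]
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty record")
    n_octaves = np.log2(fmax / fmin)
    n_freqs = max(2, int(np.ceil(voices_per_octave * n_octaves)) + 1)
    freqs = fmax * 2.0 ** (-np.arange(n_freqs) / voices_per_octave)
    wavelet = "cmor1.5-1.0"
    center = pywt.central_frequency(wavelet)
    scales = center * fs / freqs
    coeffs, _ = pywt.cwt(x, scales, wavelet, sampling_period=1.0 / fs)
    times = np.arange(x.size) / fs
    return times, freqs, np.abs(coeffs)
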