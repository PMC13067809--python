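"""Landmark amplitudes and similarity statistics on aligned heartbeats.

Amplitudes are read relative to the Q-point value: the P-wave amplitude
is the magnitude of the largest deflection from the Q level in the
pre-Q segment, and the T-wave amplitude the same in the post-S segment,
so inverted waves yield positive amplitudes.  Peak-to-peak amplitude is
simply max − min over the beat.

Similarity between two aligned beats uses (a) the maximum over all lags
of the energy-normalized cross-correlation (scale invariant, in
[−1, 1]) and (b) the RMS error normalized by the combined range of both
beats (NRMSE).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class BeatLandmarks:
    """Landmark indices and amplitudes for one beat (amplitudes in mV)."""

    p_idx: int
    q_idx: int
    r_idx: int
    s_idx: int
    t_idx: int
    a_pp: float
    p_amp: float
    t_amp: float


def peak_to_peak(beat: np.ndarray) -> float:
    """A_pp = max(beat) − min(beat)."""
    beat = np.asarray(beat, dtype=float)
    if beat.size == 0:
        raise ValueError("empty beat")
    return float(beat.max() - beat.min())


def locate_qs(beat: np.ndarray, r_idx: int, fs: float) -> tuple[int, int]:
    """Locate Q and S as the minima within 60 ms before/after the R sample.

    Used on centroid beats, which carry no detector annotations.
    """
    beat = np.asarray(beat, dtype=float)
    w = max(1, int(round(0.060 * fs)))
    lo = max(0, r_idx - w)
    hi = min(beat.size, r_idx + w + 1)
    if lo == r_idx or r_idx + 1 == hi:
        raise ValueError("R index too close to the window edge to locate Q/S")
    q_idx = lo + int(np.argmin(beat[lo:r_idx]))
    s_idx = r_idx + 1 + int(np.argmin(beat[r_idx + 1:hi]))
    return q_idx, s_idx


def landmark_amplitudes(beat: np.ndarray, q_idx: int, s_idx: int) -> tuple[float, float]:
    """P- and T-wave amplitudes as deflections from the Q-point value.

    p_amp is taken over [0, q_idx), t_amp over (s_idx, end]; both are
    magnitudes of the extremum's distance from ``beat[q_idx]``.  An
    empty segment raises rather than silently reporting zero.
    """
    beat = np.asarray(beat, dtype=float)
    if not (0 <= q_idx < s_idx < beat.size):
        raise ValueError("need 0 <= q_idx < s_idx within the beat window")
    pre = beat[:q_idx]
    post = beat[s_idx + 1:]
    if pre.size == 0:
        raise ValueError("pre-Q segment empty: P amplitude undefined")
    if post.size == 0:
        raise ValueError("post-S segment empty: T amplitude undefined")
    q_level = beat[q_idx]
    p_amp = float(np.max(np.abs(pre - q_level)))
    t_amp = float(np.max(np.abs(post - q_level)))
    return p_amp, t_amp


def beat_landmarks(beat: np.ndarray, r_idx: int, fs: float) -> BeatLandmarks:
    """Full landmark set for a centroid beat (Q/S located automatically)."""
    q_idx, s_idx = locate_qs(beat, r_idx, fs)
    p_amp, t_amp = landmark_amplitudes(beat, q_idx, s_idx)
    q_level = beat[q_idx]
    p_idx = int(np.argmax(np.abs(beat[:q_idx] - q_level)))
    t_idx = s_idx + 1 + int(np.argmax(np.abs(beat[s_idx + 1:] - q_level)))
    return BeatLandmarks(p_idx=p_idx, q_idx=q_idx, r_idx=r_idx, s_idx=s_idx,
                         t_idx=t_idx, a_pp=peak_to_peak(beat),
                         p_amp=p_amp, t_amp=t_amp)


def xcorr_max(beat1: np.ndarray, beat2: np.ndarray) -> tuple[float, int]:
    """Maximum normalized cross-correlation over all lags, with its lag.

    The cross-correlation at each lag is divided by the square root of
    the product of the two beats' total energies, so the result is
    invariant to positive rescaling of either beat.
    """
    b1 = np.asarray(beat1, dtype=float)
    b2 = np.asarray(beat2, dtype=float)
    if b1.shape != b2.shape or b1.ndim != 1:
        raise ValueError("beats must be equal-length 1-D vectors")
    e1, e2 = float(b1 @ b1), float(b2 @ b2)
    if e1 == 0 or e2 == 0:
        raise ValueError("zero-energy beat: normalized cross-correlation undefined")
    r = np.correlate(b1, b2, mode="full") / np.sqrt(e1 * e2)
    lags = np.arange(-(b1.size - 1), b1.size)
    best = int(np.argmax(r))
    return float(r[best]), int(lags[best])


def nrmse(beat1: np.ndarray, beat2: np.ndarray) -> float:
    """RMS error between aligned beats, normalized by their combined range."""
    b1 = np.asarray(beat1, dtype=float)
    b2 = np.asarray(beat2, dtype=float)
    if b1.shape != b2.shape or b1.ndim != 1:
        raise ValueError("beats must be equal-length 1-D vectors")
    combined_range = float(max(b1.max(), b2.max()) - min(b1.min(), b2.min()))
    rmse = float(np.sqrt(np.mean((b1 - b2) ** 2)))
    if combined_range == 0:
        warnings.warn("both beats constant and equal; NRMSE defined as 0")
        return 0.0
    return rmse / combined_range
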