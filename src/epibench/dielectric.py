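"""Impedance-spectrum handling and dielectric relaxation analysis.

An electrode–skin interface measured by electrochemical impedance
spectroscopy (EIS) yields a complex impedance Z*(ω) = Z′ + jZ″ on a
frequency grid.  A single interfacial relaxation process shows up as a
semicircle in the Nyquist plane (Z′ vs −Z″); the apex frequency f_max of
the −Z″ peak defines the interfacial relaxation time

    τ = 1 / (2π f_max)

Slower relaxation (larger τ) indicates stronger low-frequency capacitive
coupling, the property that lets a hydrogel electrode act as a
material-level low-pass filter.

The same spectrum can be re-expressed as a complex relative permittivity
using the parallel-plate geometry of the electrode,

    ε*(ω) = 1 / (jω C₀ Z*(ω)),   C₀ = ε₀ A / d,

from which the loss tangent tan δ = ε″/ε′ and the electric modulus
M* = 1/ε* follow.  The imaginary-modulus peak M″(ω) is the dielectric-side
marker of the same relaxation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

VACUUM_PERMITTIVITY = 8.8541878128e-12  # F/m

#: Default electrode geometry: 1.7 cm diameter disc, 1.5 mm thick.
DEFAULT_AREA_M2 = np.pi * (0.017 / 2.0) ** 2
DEFAULT_THICKNESS_M = 1.5e-3


@dataclass
class ImpedanceSpectrum:
    """Complex impedance vs frequency with optional cell geometry.

    Parameters
    ----------
    freq : ndarray
        Frequencies in Hz, strictly ascending and positive.
    z_real, z_imag : ndarray
        Real and imaginary parts of Z* in ohm (capacitive systems have
        ``z_imag < 0``).
    area : float, optional
        Electrode face area in m².
    thickness : float, optional
        Dielectric thickness in m.
    """

    freq: np.ndarray
    z_real: np.ndarray
    z_imag: np.ndarray
    area: float | None = None
    thickness: float | None = None

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        self.z_real = np.asarray(self.z_real, dtype=float)
        self.z_imag = np.asarray(self.z_imag, dtype=float)
        if self.freq.ndim != 1 or self.freq.size == 0:
            raise ValueError("frequency grid must be a nonempty 1-D array")
        if np.any(self.freq <= 0):
            raise ValueError("frequencies must be strictly positive")
        if np.any(np.diff(self.freq) <= 0):
            raise ValueError("frequency grid must be strictly ascending")
        if self.z_real.shape != self.freq.shape or self.z_imag.shape != self.freq.shape:
            raise ValueError("z_real/z_imag must match the frequency grid")

    @property
    def z(self) -> np.ndarray:
        """Complex impedance Z′ + jZ″."""
        return self.z_real + 1j * self.z_imag


@dataclass
class DielectricSpectrum:
    """Permittivity, loss tangent and electric modulus derived from EIS."""

    freq: np.ndarray
    eps_real: np.ndarray
    eps_imag: np.ndarray
    tan_delta: np.ndarray
    mod_real: np.ndarray
    mod_imag: np.ndarray
    tau: float | None = field(default=None)


def relaxation_time(spectrum: ImpedanceSpectrum, refine: bool = False) -> tuple[float, float]:
    """Relaxation time from the −Z″ peak of a Nyquist semicircle.

    Parameters
    ----------
    spectrum : ImpedanceSpectrum
    refine : bool
        If True, refine f_max by a quadratic fit through the peak and its
        neighbours.  Off by default: f_max is read off the raw grid.

    Returns
    -------
    tau, f_max : float
        τ = 1/(2π f_max) in seconds and the peak frequency in Hz.

    Raises
    ------
    ValueError
        If −Z″ has no interior maximum (monotone spectrum: the grid does
        not bracket the relaxation).
    """
    neg_zim = -spectrum.z_imag
    idx = int(np.argmax(neg_zim))
    if idx == 0 or idx == neg_zim.size - 1:
        raise ValueError(
            "-Z'' has no interior maximum on this grid; relaxation time undefined"
        )
    f_max = float(spectrum.freq[idx])
    if refine:
        # quadratic through (log f, -Z'') around the apex
        x = np.log10(spectrum.freq[idx - 1 : idx + 2])
        y = neg_zim[idx - 1 : idx + 2]
        a, b, _ = np.polyfit(x, y, 2)
        if a < 0:
            f_max = float(10 ** (-b / (2 * a)))
    tau = 1.0 / (2.0 * np.pi * f_max)
    return tau, f_max


def _cell_capacitance(spectrum: ImpedanceSpectrum,
                      area: float | None, thickness: float | None) -> float:
    if area is None:
        area = spectrum.area
    if thickness is None:
        thickness = spectrum.thickness
    if area is None or thickness is None:
        warnings.warn(
            "electrode geometry not set; using defaults (1.7 cm diameter, 1.5 mm thick)",
            stacklevel=3,
        )
        area = DEFAULT_AREA_M2 if area is None else area
        thickness = DEFAULT_THICKNESS_M if thickness is None else thickness
    if area <= 0 or thickness <= 0:
        raise ValueError("electrode area and thickness must be positive")
    return VACUUM_PERMITTIVITY * area / thickness


def to_dielectric(spectrum: ImpedanceSpectrum,
                  area: float | None = None,
                  thickness: float | None = None) -> DielectricSpectrum:
    """Convert an impedance spectrum to dielectric quantities.

    Uses the parallel-plate conversion ε*(ω) = 1/(jω C₀ Z*) with
    C₀ = ε₀·A/d, under the convention ε* = ε′ − jε″ and M* = 1/ε* =
    M′ + jM″.  The relaxation time is taken from the −Z″ peak when the
    grid brackets one, otherwise left as None.
    """
    c0 = _cell_capacitance(spectrum, area, thickness)
    omega = 2.0 * np.pi * spectrum.freq
    eps_star = 1.0 / (1j * omega * c0 * spectrum.z)  # = eps' - j eps''
    eps_real = eps_star.real
    eps_imag = -eps_star.imag
    with np.errstate(divide="ignore", invalid="ignore"):
        tan_delta = np.where(eps_real != 0, eps_imag / eps_real, np.nan)
    mod_star = 1j * omega * c0 * spectrum.z  # 1/eps* as M' + jM''
    try:
        tau, _ = relaxation_time(spectrum)
    except ValueError:
        tau = None
    return DielectricSpectrum(
        freq=spectrum.freq.copy(),
        eps_real=eps_real,
        eps_imag=eps_imag,
        tan_delta=tan_delta,
        mod_real=mod_star.real,
        mod_imag=mod_star.imag,
        tau=tau,
    )


def modulus_peak_frequency(diel: DielectricSpectrum) -> float:
    """Frequency of the M″ peak, the dielectric-side relaxation marker.

    For a single-time-constant interface this agrees with the −Z″ apex;
    the pair is a useful internal consistency check on measured spectra.
    """
    idx = int(np.argmax(diel.mod_imag))
    if idx == 0 or idx == diel.freq.size - 1:
        raise ValueError("M'' has no interior maximum on this grid")
    return float(diel.freq[idx])


def nyquist_curve(spectra: list[ImpedanceSpectrum],
                  smooth_window: int = 1) -> dict[str, np.ndarray]:
    """Pointwise mean ± SD Nyquist curve over replicate spectra.

    Replicates must share a frequency grid (triplicate EIS measurements
    are the typical input).  The mean curve is smoothed with a centered
    moving average of ``smooth_window`` points; the SD is reported
    unsmoothed.
    """
    if not spectra:
        raise ValueError("need at least one spectrum")
    if smooth_window < 1:
        raise ValueError("smooth_window must be >= 1")
    f0 = spectra[0].freq
    for s in spectra[1:]:
        if s.freq.shape != f0.shape or not np.allclose(s.freq, f0):
            raise ValueError("replicate spectra must share a frequency grid")
    zr = np.stack([s.z_real for s in spectra])
    nzi = np.stack([-s.z_imag for s in spectra])
    mean_re, mean_im = zr.mean(axis=0), nzi.mean(axis=0)
    sd_re, sd_im = zr.std(axis=0, ddof=0), nzi.std(axis=0, ddof=0)
    if smooth_window > 1:
        kernel = np.ones(smooth_window)
        norm = np.convolve(np.ones_like(mean_re), kernel, mode="same")
        mean_re = np.convolve(mean_re, kernel, mode="same") / norm
        mean_im = np.convolve(mean_im, kernel, mode="same") / norm
    return {
        "freq": f0.copy(),
        "z_real_mean": mean_re,
        "neg_z_imag_mean": mean_im,
        "z_real_sd": sd_re,
        "neg_z_imag_sd": sd_im,
    }
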