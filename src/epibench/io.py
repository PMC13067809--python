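"""Plain-text readers/writers and pipeline configuration.

Recordings travel as CSV (time column plus one column per lead, mV)
with a JSON metadata sidecar; beat matrices as CSV with 121 value
columns plus provenance columns; EIS spectra as three-column CSV.  All
round-trips are identity up to float formatting.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dielectric import ImpedanceSpectrum
from .heartbeats import BEAT_WINDOW, BeatMatrix
from .synthetic import Recording

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All protocol parameters in one serializable place."""

    fs: float = 200.0
    beat_window: int = 121
    variance_target: float = 0.99
    kmeans_restarts: int = 5
    kmeans_iters: int = 1000
    tsne_perplexity: float = 30.0
    k_lead: int = 3
    seed: int = 0
    variance_win: float = 2.0
    variance_z: float = 5.0
    bands: dict = field(default_factory=lambda: {
        "motion": [0.05, 0.5], "LF": [0.5, 4.0], "MF": [4.0, 15.0],
        "HF": [15.0, 40.0], "UHF1": [40.0, 60.0], "UHF2": [60.0, 90.0]})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording(rec: Recording, path: str | Path, seed: int | None = None) -> None:
    path = Path(path)
    df = pd.DataFrame({"time_s": rec.times})
    for lab, row in zip(rec.lead_labels, rec.samples):
        df[f"lead_{lab}_mv"] = row
    df.to_csv(path, index=False)
    meta = {
        "fs": rec.fs,
        "lead_labels": list(rec.lead_labels),
        "participant_id": rec.participant_id,
        "electrode": rec.electrode,
        "seed": seed,
        "truth_r_times": (None if rec.truth is None
                          else [float(t) for t in rec.truth["r_times"]]),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_recording(path: str | Path) -> Recording:
    path = Path(path)
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    diffs = np.diff(t)
    bad = np.nonzero(diffs <= 0)[0]
    if bad.size:
        raise ValueError(f"{path}: non-monotone time column at row {int(bad[0]) + 2}")
    meta = json.loads(_sidecar(path).read_text())
    samples = np.vstack([df[f"lead_{lab}_mv"].to_numpy()
                         for lab in meta["lead_labels"]])
    truth = None
    if meta.get("truth_r_times") is not None:
        truth = {"r_times": np.asarray(meta["truth_r_times"], dtype=float)}
    return Recording(samples=samples, fs=meta["fs"],
                     lead_labels=list(meta["lead_labels"]),
                     participant_id=meta["participant_id"],
                     electrode=meta["electrode"], truth=truth)


def write_beats(beats: BeatMatrix, path: str | Path) -> None:
    df = pd.DataFrame(beats.beats, columns=[f"s{i}" for i in range(BEAT_WINDOW)])
    df["participant"] = beats.participant_ids
    df["lead"] = beats.lead_ids
    df["electrode"] = beats.electrode
    df.attrs["fs"] = beats.fs
    df.insert(0, "fs", beats.fs)
    df.insert(1, "r_index", beats.r_index)
    df.to_csv(Path(path), index=False)


def read_beats(path: str | Path) -> BeatMatrix:
    df = pd.read_csv(Path(path))
    cols = [f"s{i}" for i in range(BEAT_WINDOW)]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing beat sample columns (first: {missing[0]})")
    electrode = df["electrode"].iloc[0] if len(df) else "unknown"
    return BeatMatrix(beats=df[cols].to_numpy(), fs=float(df["fs"].iloc[0]),
                      r_index=int(df["r_index"].iloc[0]),
                      participant_ids=df["participant"].to_numpy(dtype=object),
                      lead_ids=df["lead"].to_numpy(dtype=object),
                      electrode=electrode)


def write_eis(spec: ImpedanceSpectrum, path: str | Path) -> None:
    pd.DataFrame({"freq_hz": spec.freq, "z_real_ohm": spec.z_real,
                  "z_imag_ohm": spec.z_imag}).to_csv(Path(path), index=False)


def read_eis(path: str | Path, area: float | None = None,
             thickness: float | None = None) -> ImpedanceSpectrum:
    df = pd.read_csv(Path(path))
    for col in ("freq_hz", "z_real_ohm", "z_imag_ohm"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column '{col}'")
    if not df["freq_hz"].is_monotonic_increasing:
        logger.warning("%s: frequencies not ascending; sorting", path)
        df = df.sort_values("freq_hz")
    return ImpedanceSpectrum(freq=df["freq_hz"].to_numpy(),
                             z_real=df["z_real_ohm"].to_numpy(),
                             z_imag=df["z_imag_ohm"].to_numpy(),
                             area=area, thickness=thickness)


def write_report(report: dict, path: str | Path) -> None:
    """Deterministic JSON report (sorted keys, fixed float formatting)."""
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not serializable: {type(o)}")
    Path(path).write_text(json.dumps(report, indent=1, sort_keys=True,
                                     default=default))
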