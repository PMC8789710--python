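"""Containers and text I/O for conductance-catheter-style PV recordings.

A recording is a pair of uniformly sampled left-ventricular signals —
pressure in mmHg and volume in ml — plus the per-acquisition metadata
(body surface area, invasive systolic arterial pressure, mean
transvalvular gradient) needed to index the derived hemodynamic
quantities.  Units are fixed package-wide: mmHg, ml, s.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["RecordingMeta", "PVRecording", "read_recording", "write_recording"]


@dataclass
class RecordingMeta:
    """Per-recording clinical metadata.

    bsa            body surface area, m^2 (divisor for SVI / CI)
    sap            invasive systolic arterial pressure, mmHg
    mean_gradient  mean transvalvular gradient, mmHg
    labels         free-form subgroup labels, e.g. {"af": True}
    """

    bsa: float | None = None
    sap: float | None = None
    mean_gradient: float | None = None
    labels: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RecordingMeta":
        return cls(
            bsa=d.get("bsa"),
            sap=d.get("sap"),
            mean_gradient=d.get("mean_gradient"),
            labels=dict(d.get("labels", {})),
        )


class PVRecording:
    """Uniformly sampled LV pressure and volume trace.

    Sample ``k`` is taken at time ``k / fs`` seconds (0-based).  Arrays are
    validated to be finite and of equal length on construction.
    """

    def __init__(
        self,
        pressure: np.ndarray,
        volume: np.ndarray,
        fs: float,
        meta: RecordingMeta | None = None,
    ):
        pressure = np.asarray(pressure, dtype=float)
        volume = np.asarray(volume, dtype=float)
        if pressure.ndim != 1 or volume.ndim != 1:
            raise ValueError("pressure and volume must be 1-D arrays")
        if pressure.shape != volume.shape:
            raise ValueError(
                f"length mismatch: {pressure.size} pressure vs {volume.size} volume samples"
            )
        if not np.isfinite(pressure).all() or not np.isfinite(volume).all():
            raise ValueError("pressure and volume must be finite")
        if not fs > 0:
            raise ValueError("sampling rate must be positive")
        self.pressure = pressure
        self.volume = volume
        self.fs = float(fs)
        self.meta = meta if meta is not None else RecordingMeta()

    @property
    def n_samples(self) -> int:
        return self.pressure.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def __len__(self) -> int:
        return self.n_samples

    def __repr__(self) -> str:
        return (
            f"PVRecording({self.n_samples} samples @ {self.fs:g} Hz, "
            f"{self.duration:.1f} s)"
        )


def write_recording(rec: PVRecording, path: str | Path, sidecar: dict | None = None) -> None:
    """Write ``time_s,pressure_mmHg,volume_ml`` delimited text plus a JSON sidecar.

    The sidecar (``<path>.json``) carries the metadata and, optionally, any
    extra dict the caller supplies (e.g. simulator ground truth).
    """
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_s": rec.time,
            "pressure_mmHg": rec.pressure,
            "volume_ml": rec.volume,
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")
    payload = {"fs": rec.fs, "meta": rec.meta.to_dict()}
    if sidecar:
        payload.update(sidecar)
    Path(str(path) + ".json").write_text(json.dumps(payload, indent=1, default=_jsonable))


def read_recording(path: str | Path) -> PVRecording:
    """Read a recording written by :func:`write_recording`.

    The sampling rate is taken from the sidecar when present, otherwise
    inferred from the time column (which must be uniform).
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("time_s", "pressure_mmHg", "volume_ml"):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} in {path}")
    t = df["time_s"].to_numpy()
    meta = RecordingMeta()
    fs = None
    side = Path(str(path) + ".json")
    if side.exists():
        payload = json.loads(side.read_text())
        fs = payload.get("fs")
        if "meta" in payload:
            meta = RecordingMeta.from_dict(payload["meta"])
    if fs is None:
        dt = np.diff(t)
        if dt.size == 0 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("non-uniform time column and no sidecar sampling rate")
        fs = 1.0 / dt[0]
    return PVRecording(df["pressure_mmHg"].to_numpy(), df["volume_ml"].to_numpy(), fs, meta)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
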