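"""Canonical 40-point PV-loop representation and loop averaging.

A closed PV loop is decomposed into its four physiological limbs —
isovolumic contraction, ejection, isovolumic relaxation, filling — and
each limb is resampled to 10 points equally spaced by arc length, giving
exactly 40 points per loop.  Corresponding points of canonical loops can
then be averaged pointwise to draw a mean loop for a group of beats or
patients, the numerization one would otherwise perform by digitizing a
plotted loop figure point by point.

Corner conventions: end-diastole is the maximum-volume vertex (lowest
pressure among ties); end-systole is the vertex maximizing P/V; the
onset-of-ejection corner is the highest-pressure vertex still within 5% of
EDV on the contraction arc, and the onset-of-filling corner the
lowest-pressure vertex within 5% of ESV on the relaxation arc.  Each limb
owns its starting corner and excludes its ending corner, so 4 x 10 = 40
points without duplicates.  Arc length is measured in the raw
(ml, mmHg) coordinates, as a digitizer operator would on a plotted figure.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .indices import shoelace_area

__all__ = [
    "LoopPolyline",
    "CanonicalLoop",
    "LIMB_NAMES",
    "POINTS_PER_LIMB",
    "canonicalize",
    "mean_loop",
    "loop_from_beat",
    "read_loop",
    "write_canonical_loop",
]

LIMB_NAMES = ("isovolumic-contraction", "ejection", "isovolumic-relaxation", "filling")
POINTS_PER_LIMB = 10
CORNER_VOLUME_FRACTION = 0.05  # "still isovolumic" band as fraction of EDV-ESV


@dataclass
class LoopPolyline:
    """Ordered closed-cycle vertices (volume ml, pressure mmHg); closure implicit."""

    volume: np.ndarray
    pressure: np.ndarray

    def __post_init__(self):
        self.volume = np.asarray(self.volume, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        if self.volume.ndim != 1 or self.volume.shape != self.pressure.shape:
            raise ValueError("volume and pressure must be equal-length 1-D arrays")
        if self.volume.size < 8:
            raise ValueError(f"loop needs >= 8 vertices, got {self.volume.size}")
        if not (np.isfinite(self.volume).all() and np.isfinite(self.pressure).all()):
            raise ValueError("loop vertices must be finite")
        # drop an explicit duplicate closing vertex
        if (self.volume[0] == self.volume[-1]) and (self.pressure[0] == self.pressure[-1]):
            self.volume = self.volume[:-1]
            self.pressure = self.pressure[:-1]

    @property
    def counterclockwise(self) -> bool:
        return shoelace_area(self.volume, self.pressure) > 0

    @property
    def area(self) -> float:
        return abs(shoelace_area(self.volume, self.pressure))


@dataclass
class CanonicalLoop:
    """Exactly 40 (V, P) points: 4 limbs x 10, in limb order starting at ED."""

    volume: np.ndarray
    pressure: np.ndarray

    def __post_init__(self):
        self.volume = np.asarray(self.volume, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        if self.volume.shape != (40,) or self.pressure.shape != (40,):
            raise ValueError("canonical loop must have exactly 40 points")

    @property
    def limbs(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        out = {}
        for i, name in enumerate(LIMB_NAMES):
            s = slice(i * POINTS_PER_LIMB, (i + 1) * POINTS_PER_LIMB)
            out[name] = (self.volume[s], self.pressure[s])
        return out

    @property
    def area(self) -> float:
        return abs(shoelace_area(self.volume, self.pressure))

    @property
    def edv(self) -> float:
        return float(self.volume[0])

    @property
    def edp(self) -> float:
        return float(self.pressure[0])


def loop_from_beat(rec, beat) -> LoopPolyline:
    """Extract the closed loop polyline of one segmented beat.

    The denoised traces are used: a digitized loop figure is a clean curve,
    and corner detection on raw catheter noise is not meaningful.
    """
    from .beatseg import smoothed_signals

    p, v = smoothed_signals(rec)
    seg = slice(beat.start, beat.end)
    return LoopPolyline(v[seg].copy(), p[seg].copy())


def _find_corners(v: np.ndarray, p: np.ndarray) -> tuple[int, int, int, int]:
    """Indices of (ED, onset-ejection, ES, onset-filling) on a CCW loop."""
    n = v.size
    # ED: the lowest-pressure vertex on the end-diastolic volume plateau
    # (within 2% of the volume excursion of the true maximum); picking the
    # strict volume maximum would land on noise-displaced vertices after
    # pressure has begun to rise
    v_band = 0.02 * max(float(np.ptp(v)), 1e-9)
    plateau = np.nonzero(v >= v.max() - v_band)[0]
    i_ed = int(plateau[np.argmin(p[plateau])])
    rolled_v = np.roll(v, -i_ed)
    rolled_p = np.roll(p, -i_ed)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(rolled_v > 1e-9, rolled_p / np.maximum(rolled_v, 1e-9), -np.inf)
    j_es = int(np.argmax(ratio))
    if j_es == 0:
        raise ValueError("degenerate loop: end-systole coincides with end-diastole")
    edv = rolled_v[0]
    esv = rolled_v[j_es]
    band = CORNER_VOLUME_FRACTION * max(edv - esv, 1e-9)
    # onset of ejection: highest pressure on the ED..ES arc with V within band of EDV
    arc1 = np.arange(0, j_es + 1)
    cand1 = arc1[rolled_v[arc1] >= edv - band]
    j_oe = int(cand1[np.argmax(rolled_p[cand1])])
    # onset of filling: lowest pressure on the ES..ED arc with V within band of ESV
    arc2 = np.arange(j_es, n)
    cand2 = arc2[rolled_v[arc2] <= esv + band]
    j_of = int(cand2[np.argmin(rolled_p[cand2])])
    if not (0 <= j_oe <= j_es <= j_of < n):
        raise ValueError("corner detection failed: corners out of cyclic order")
    # nudge coincident corners apart when the vertex budget allows it
    if j_oe == 0 and j_es >= 2:
        j_oe = 1
    if j_oe == j_es and j_oe > 1:
        j_oe -= 1
    if j_of == j_es and j_of < n - 1:
        j_of += 1
    if len({0, j_oe, j_es, j_of}) < 4:
        raise ValueError("corner detection failed: coincident corners (degenerate loop)")
    return i_ed, j_oe, j_es, j_of


def _resample_arc(v: np.ndarray, p: np.ndarray, n_pts: int) -> tuple[np.ndarray, np.ndarray]:
    """Resample an open polyline to n_pts points equally spaced by arc length,
    including the first vertex and excluding the last."""
    d = np.hypot(np.diff(v), np.diff(p))
    s = np.concatenate([[0.0], np.cumsum(d)])
    total = s[-1]
    if total <= 0:
        # zero-length limb (e.g. perfectly isovolumic segment collapsed):
        # repeat the corner
        return np.full(n_pts, v[0]), np.full(n_pts, p[0])
    targets = np.arange(n_pts) * total / n_pts
    return np.interp(targets, s, v), np.interp(targets, s, p)


def canonicalize(loop: LoopPolyline) -> CanonicalLoop:
    """Reduce a closed PV loop to the canonical 4 x 10 = 40-point form.

    The loop is first oriented counterclockwise (ejection at high pressure);
    raises ``ValueError`` when the four corners cannot be located.
    """
    v, p = loop.volume, loop.pressure
    if not loop.counterclockwise:
        v, p = v[::-1].copy(), p[::-1].copy()
    i_ed, j_oe, j_es, j_of = _find_corners(v, p)
    rv = np.roll(v, -i_ed)
    rp = np.roll(p, -i_ed)
    # close the cycle for the final limb
    rv = np.concatenate([rv, rv[:1]])
    rp = np.concatenate([rp, rp[:1]])
    bounds = [0, j_oe, j_es, j_of, rv.size - 1]
    vs, ps = [], []
    for a, b in zip(bounds[:-1], bounds[1:]):
        lv, lp = _resample_arc(rv[a:b + 1], rp[a:b + 1], POINTS_PER_LIMB)
        vs.append(lv)
        ps.append(lp)
    return CanonicalLoop(np.concatenate(vs), np.concatenate(ps))


def mean_loop(loops: list[CanonicalLoop]) -> CanonicalLoop:
    """Pointwise arithmetic mean of corresponding points; limb structure kept."""
    if not loops:
        raise ValueError("need at least one canonical loop")
    v = np.mean([lo.volume for lo in loops], axis=0)
    p = np.mean([lo.pressure for lo in loops], axis=0)
    return CanonicalLoop(v, p)


def mean_loop_of_recording(rec, n_beats: int = 10, rr_tol="auto") -> CanonicalLoop:
    """Canonical mean loop of a recording's steady-state beats.

    Segments the recording, drops extrasystoles, selects the steady-state
    window, canonicalizes each beat's loop and averages them pointwise —
    the per-acquisition "mean loop" a digitizing operator would produce.
    """
    from .beatseg import flag_extrasystoles, segment_beats, select_steady_state, smoothed_signals

    beats = segment_beats(rec)
    if rr_tol == "auto":
        rr = np.array([b.rr for b in beats])
        med = float(np.median(rr))
        cv = 1.4826 * float(np.median(np.abs(rr - med))) / med
        rr_tol = min(max(0.20, 3.0 * cv), 0.35)
    beats = flag_extrasystoles(beats, rr_tol=float(rr_tol))
    _, v_s = smoothed_signals(rec)
    try:
        window = select_steady_state(beats, v_s, n_beats=n_beats)
    except ValueError:
        window = [b for b in beats if not b.ectopic][:n_beats]
    return mean_loop([canonicalize(loop_from_beat(rec, b)) for b in window])


def read_loop(path: str | Path) -> LoopPolyline:
    """Read loop vertices from ``volume_ml,pressure_mmHg`` delimited text."""
    df = pd.read_csv(path)
    for col in ("volume_ml", "pressure_mmHg"):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} in {path}")
    return LoopPolyline(df["volume_ml"].to_numpy(), df["pressure_mmHg"].to_numpy())


def write_canonical_loop(loop: CanonicalLoop, path: str | Path) -> None:
    """Write the 40-point loop with a limb-label column."""
    labels = [name for name in LIMB_NAMES for _ in range(POINTS_PER_LIMB)]
    pd.DataFrame(
        {"volume_ml": loop.volume, "pressure_mmHg": loop.pressure, "limb": labels}
    ).to_csv(path, index=False)
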