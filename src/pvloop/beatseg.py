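"""Beat segmentation, landmark detection and extrasystole exclusion.

Cardiac cycles are delimited at end-diastole.  Upstrokes are found by
peak-picking the smoothed pressure derivative (prominence >= 200 mmHg/s);
end-diastole is the volume maximum in the 250 ms window preceding each
upstroke, and the beat span starts one sample before it so the half-open
[start, end) intervals tile the analyzed stretch.  Within each beat,
end-systole is the sample maximizing P/V (the maximal-elastance point with
an assumed zero volume intercept) between the dP/dt extremes.

Extrasystoles are flagged by an RR rule — a beat whose RR deviates more
than ``rr_tol`` (default 20%) from the running median is ectopic, and the
post-extrasystolic beat is excluded with it, since its loading is aberrant
too.  Steady-state analysis then takes the contiguous run of clean beats
with the most stable end-diastolic volume.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .recording import PVRecording

__all__ = [
    "Beat",
    "segment_beats",
    "flag_extrasystoles",
    "select_steady_state",
    "smoothed_derivative",
    "write_beat_table",
]

DPDT_PROMINENCE = 200.0  # mmHg/s, upstroke detection threshold
ED_SEARCH_MS = 250.0     # window before each upstroke searched for the volume max
ED_PLATEAU_TOL_ML = 1.0  # tolerance defining the end-diastolic volume plateau
SMOOTH_MS = 20.0         # moving-average width for the derivative


@dataclass(frozen=True)
class Beat:
    """One cardiac cycle as half-open sample span [start, end).

    Landmarks are sample indices into the parent recording:
    i_ed end-diastole, i_es end-systole, i_dpdt_max / i_dpdt_min the
    pressure-derivative extremes.  rr = (end - start) / fs seconds.
    """

    start: int
    end: int
    i_ed: int
    i_es: int
    i_dpdt_max: int
    i_dpdt_min: int
    rr: float
    ectopic: bool = False

    def __post_init__(self):
        if not (self.start < self.i_ed <= self.i_dpdt_max < self.i_es
                <= self.i_dpdt_min < self.end):
            raise ValueError(
                "landmark ordering violated: require start < i_ed <= i_dpdt_max"
                " < i_es <= i_dpdt_min < end "
                f"(got {self.start}, {self.i_ed}, {self.i_dpdt_max}, "
                f"{self.i_es}, {self.i_dpdt_min}, {self.end})"
            )


def _moving_average(x: np.ndarray, fs: float, width_ms: float) -> np.ndarray:
    w = max(int(round(width_ms * 1e-3 * fs)), 1)
    if w <= 1:
        return x
    kernel = np.ones(w) / w
    return np.convolve(x, kernel, mode="same")


def smoothed_derivative(pressure: np.ndarray, fs: float, smooth_ms: float = SMOOTH_MS) -> np.ndarray:
    """Central-difference dP/dt (mmHg/s) after a moving-average smoothing."""
    return np.gradient(_moving_average(pressure, fs, smooth_ms)) * fs


def smoothed_signals(rec: PVRecording, smooth_ms: float = SMOOTH_MS) -> tuple[np.ndarray, np.ndarray]:
    """Denoised (pressure, volume) used for landmark values; cached on the
    recording.  Pressure gets the standard smoothing window, volume twice
    that (conductance volume is the noisier channel)."""
    key = ("_pvloop_smooth", smooth_ms)
    cached = getattr(rec, "_smooth_cache", None)
    if cached and cached[0] == key:
        return cached[1]
    out = (
        _moving_average(rec.pressure, rec.fs, smooth_ms),
        _moving_average(rec.volume, rec.fs, 2 * smooth_ms),
    )
    rec._smooth_cache = (key, out)
    return out


def segment_beats(rec: PVRecording, smooth_ms: float = SMOOTH_MS) -> list[Beat]:
    """Decompose a recording into beats with hemodynamic landmarks.

    Raises ``ValueError`` if fewer than 3 cycles are detected.
    """
    p, v, fs = rec.pressure, rec.volume, rec.fs
    # landmarks located on smoothed signals for noise robustness
    p_s, v_s = smoothed_signals(rec, smooth_ms)
    dpdt = smoothed_derivative(p, fs, smooth_ms)
    min_dist = max(int(0.3 * fs), 1)  # refractory: no two upstrokes within 300 ms
    # absolute height floor scaled to a robust upper quantile of dP/dt
    # rejects low-amplitude diastolic bumps whose prominence is inflated by
    # noise, without letting a single spike raise the floor above real
    # upstrokes
    height = max(DPDT_PROMINENCE, 0.3 * float(np.percentile(dpdt, 99.0)))
    peaks, _ = find_peaks(dpdt, prominence=DPDT_PROMINENCE, height=height, distance=min_dist)
    if peaks.size < 3:
        raise ValueError(f"no cycles detected (found {peaks.size} upstrokes, need >= 3)")

    w_ed = max(int(round(ED_SEARCH_MS * 1e-3 * fs)), 2)
    ed_idx = []
    for pk in peaks:
        # cap the search at the upstroke onset (last sample before the peak
        # with dP/dt below 10% of the peak value) so a noisy volume maximum
        # cannot land after pressure has started rising
        onset = pk
        j_lo = max(pk - int(0.15 * fs), 0)
        below = np.nonzero(dpdt[j_lo:pk] <= 0.1 * dpdt[pk])[0]
        if below.size:
            onset = j_lo + int(below[-1]) + 1
        lo = max(onset - w_ed, 0)
        if onset - lo < 2:
            continue
        win = v_s[lo:onset]
        # earliest sample on the end-diastolic volume plateau: argmax alone
        # lands arbitrarily late on a flat, noisy plateau
        near_max = np.nonzero(win >= win.max() - ED_PLATEAU_TOL_ML)[0]
        ed_idx.append(lo + int(near_max[0]))
    ed_idx = np.asarray(sorted(set(ed_idx)), dtype=int)
    if ed_idx.size < 3:
        raise ValueError(f"no cycles detected (found {ed_idx.size} end-diastoles)")

    beats: list[Beat] = []
    for a, b in zip(ed_idx[:-1], ed_idx[1:]):
        start, end = int(a) - 1, int(b) - 1
        if start < 0 or end - start < int(0.2 * fs):
            continue
        seg = slice(a, end)
        d = dpdt[seg]
        i_max = int(a + np.argmax(d))
        i_min = int(a + np.argmin(d))
        if not (i_max < i_min):
            continue
        pv_seg = slice(i_max, i_min + 1)
        ratio = p_s[pv_seg] / np.maximum(v_s[pv_seg], 1e-9)
        i_es = int(i_max + np.argmax(ratio))
        i_es = min(max(i_es, i_max + 1), i_min)
        try:
            beats.append(
                Beat(
                    start=start,
                    end=end,
                    i_ed=int(a),
                    i_es=i_es,
                    i_dpdt_max=i_max,
                    i_dpdt_min=i_min,
                    rr=(end - start) / fs,
                )
            )
        except ValueError:
            continue  # malformed cycle (e.g. truncated at the edges)
    if len(beats) < 3:
        raise ValueError(f"no cycles detected (only {len(beats)} well-formed beats)")
    return beats


def flag_extrasystoles(beats: list[Beat], rr_tol: float = 0.20, window: int = 7) -> list[Beat]:
    """Flag ectopic beats by RR deviation from the running median.

    A beat is ectopic iff its RR deviates more than ``rr_tol`` (fractional)
    from the median RR of the ``window`` beats centered on it; the beat
    immediately following an ectopic is flagged as well (post-extrasystolic
    potentiation makes it unrepresentative).  Existing flags are never
    cleared.
    """
    if len(beats) < 3:
        raise ValueError("need >= 3 beats to establish an RR baseline")
    rr = np.array([b.rr for b in beats])
    half = window // 2
    flags = [b.ectopic for b in beats]
    for i in range(len(beats)):
        lo, hi = max(0, i - half), min(len(beats), i + half + 1)
        ref = np.median(np.concatenate([rr[lo:i], rr[i + 1:hi]])) if hi - lo > 1 else rr[i]
        if ref > 0 and abs(rr[i] - ref) / ref > rr_tol:
            flags[i] = True
            if i + 1 < len(beats):
                flags[i + 1] = True
    return [replace(b, ectopic=f) for b, f in zip(beats, flags)]


def select_steady_state(
    beats: list[Beat],
    volume: np.ndarray,
    n_beats: int = 10,
) -> list[Beat]:
    """Pick the contiguous run of ``n_beats`` clean beats with the most
    stable end-diastolic volume (minimal variance of V at end-diastole).

    ``volume`` is the recording's volume trace the beats index into.
    """
    clean_runs: list[list[Beat]] = []
    run: list[Beat] = []
    for b in beats:
        if b.ectopic:
            if run:
                clean_runs.append(run)
            run = []
        else:
            run.append(b)
    if run:
        clean_runs.append(run)

    n_clean = sum(len(r) for r in clean_runs)
    candidates = []
    for r in clean_runs:
        for i in range(len(r) - n_beats + 1):
            w = r[i:i + n_beats]
            edv = volume[[b.i_ed for b in w]]
            candidates.append((float(np.var(edv)), i, w))
    if not candidates:
        raise ValueError(
            f"insufficient unflagged beats: need a contiguous run of {n_beats}, "
            f"have {n_clean} clean beats in runs of "
            f"{[len(r) for r in clean_runs]}"
        )
    candidates.sort(key=lambda c: (c[0], c[1]))
    return candidates[0][2]


def write_beat_table(beats: list[Beat], path: str | Path) -> None:
    """Export one row per beat: sample span, landmarks, RR, ectopic flag."""
    df = pd.DataFrame(
        [
            {
                "start": b.start,
                "end": b.end,
                "i_ed": b.i_ed,
                "i_es": b.i_es,
                "i_dpdt_max": b.i_dpdt_max,
                "i_dpdt_min": b.i_dpdt_min,
                "rr_s": b.rr,
                "ectopic": int(b.ectopic),
            }
            for b in beats
        ]
    )
    df.to_csv(path, index=False)
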