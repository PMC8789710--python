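"""The invasive PV-loop hemodynamic index battery.

Per-beat quantities: end-diastolic / end-systolic volume and pressure
(EDV, ESV, EDP, ESP), stroke volume SV = EDV - ESV, ejection fraction
EF = SV/EDV, stroke work SW = area of the closed P-V loop (shoelace),
dP/dt extremes, the isovolumic relaxation constant Tau (both as the
half-decay time of pressure from dP/dt_min — the headline definition —
and as a zero-asymptote exponential fit), the Starling contractile index
SCI = dP/dt_max / EDV, and effective arterial elastance Ea = ESP/SV.

Multi-beat quantities exploit natural beat-to-beat preload variability in
the steady-state window: preload recruitable stroke work PRSW is the OLS
slope of SW on EDV; the end-systolic and end-diastolic pressure-volume
relations (ESPVR -> Ees, EDPVR -> Eed) are OLS slopes of ESP on ESV and
EDP on EDV, with per-beat ratio variants (mean ESP/ESV, mean EDP/EDV)
reported separately.  The recording-level report adds HR, CO, CI, SVI,
valvulo-arterial impedance Zva = (SAP + mean gradient)/SVI, and
ventricular-arterial coupling in both orientations (Ea/Ees and Ees/Ea).

The three-element Windkessel closed form for arterial elastance,
Ea = R_T / [t_s + tau (1 - exp(-t_d / tau))], is provided for comparison
of the measured ESP/SV with the arterial-model prediction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict, field

import numpy as np
from scipy import stats

from .beatseg import (
    Beat,
    flag_extrasystoles,
    segment_beats,
    select_steady_state,
    smoothed_derivative,
    smoothed_signals,
)
from .recording import PVRecording

__all__ = [
    "BeatIndices",
    "IndexReport",
    "WindkesselInputs",
    "beat_indices",
    "tau_half",
    "tau_exp",
    "prsw",
    "espvr_slope",
    "edpvr_slope",
    "windkessel_ea",
    "global_report",
    "analyze_recording",
    "shoelace_area",
]


@dataclass(frozen=True)
class BeatIndices:
    """All per-beat indices, units as in the clinical tables."""

    edv: float          # ml
    esv: float          # ml
    edp: float          # mmHg
    esp: float          # mmHg
    sv: float           # ml
    ef: float           # fraction
    sw: float           # mmHg.ml
    dpdt_max: float     # mmHg/s
    dpdt_min: float     # mmHg/s
    tau_half_ms: float  # ms (nan if truncated)
    tau_exp_ms: float   # ms (nan if fit impossible)
    sci: float          # mmHg/(ml.s)
    ea: float           # mmHg/ml


@dataclass
class IndexReport:
    """Per-recording summary: means over analyzed beats plus composed indices."""

    hr: float                      # beats/min
    n_beats: int
    edv: float
    esv: float
    edp: float
    esp: float
    sv: float
    ef: float
    sw: float
    dpdt_max: float
    dpdt_min: float
    tau_half_ms: float
    tau_exp_ms: float
    sci: float
    ea: float                      # mmHg/ml, mean of per-beat ESP/SV
    co: float                      # l/min
    prsw: float                    # mmHg
    ees: float                     # mmHg/ml, ESPVR regression slope
    ees_ratio: float               # mmHg/ml, mean per-beat ESP/ESV
    eed: float                     # mmHg/ml, EDPVR regression slope
    eed_ratio: float               # mmHg/ml, mean per-beat EDP/EDV
    vac_ea_over_ees: float         # dimensionless (conventional orientation)
    vac_ees_over_ea: float         # dimensionless
    svi: float | None = None       # ml/m^2
    ci: float | None = None        # l/min/m^2
    zva: float | None = None       # mmHg.m^2/ml
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class WindkesselInputs:
    """Inputs to the Windkessel arterial-elastance closed form.

    r_t : total mean vascular resistance Zc + Rp, mmHg.s/ml
    t_s, t_d : systolic and diastolic periods, s (t_s + t_d = cycle length)
    tau : diastolic arterial pressure decay constant Rp*C, s
    """

    r_t: float
    t_s: float
    t_d: float
    tau: float

    def __post_init__(self):
        if self.r_t <= 0 or self.t_s <= 0 or self.t_d < 0 or self.tau < 0:
            raise ValueError("Windkessel inputs must be positive (t_d, tau >= 0)")


def shoelace_area(v: np.ndarray, p: np.ndarray) -> float:
    """Signed area of the closed polygon (v, p), positive counterclockwise."""
    v = np.asarray(v, dtype=float)
    p = np.asarray(p, dtype=float)
    return 0.5 * float(np.dot(v, np.roll(p, -1)) - np.dot(p, np.roll(v, -1)))


def _loop_is_simple(v: np.ndarray, p: np.ndarray) -> bool:
    """Cheap self-intersection screen via shapely when available."""
    try:
        from shapely.geometry import LinearRing

        return LinearRing(np.column_stack([v, p])).is_simple
    except Exception:
        return True


def beat_indices(rec: PVRecording, beat: Beat, check_simple: bool = False) -> BeatIndices:
    """Compute all per-beat indices for one (non-ectopic) beat.

    Stroke work is the shoelace area of the sampled P-V trajectory over
    the beat, closed last-to-first; a counterclockwise loop (ejection at
    high pressure) gives positive area, and the magnitude is reported.
    Raises ``ValueError`` for a non-ejecting beat (SV <= 0).
    """
    if beat.ectopic:
        raise ValueError("refusing to index a beat flagged ectopic")
    p, v = smoothed_signals(rec)
    edv = float(v[beat.i_ed])
    esv = float(v[beat.i_es])
    edp = float(p[beat.i_ed])
    esp = float(p[beat.i_es])
    sv = edv - esv
    if sv <= 0:
        raise ValueError(f"non-ejecting beat: SV = {sv:.2f} ml <= 0")
    ef = sv / edv

    seg = slice(beat.start, beat.end)
    area = shoelace_area(v[seg], p[seg])
    if area < 0 or (check_simple and not _loop_is_simple(v[seg], p[seg])):
        warnings.warn(
            "PV loop clockwise or self-intersecting; reporting |signed area|",
            RuntimeWarning,
            stacklevel=2,
        )
    sw = abs(area)

    dpdt = smoothed_derivative(p[seg], rec.fs)
    # landmarks are recording-indexed; evaluate on the beat-local derivative
    dpdt_max = float(dpdt[beat.i_dpdt_max - beat.start])
    dpdt_min = float(dpdt[beat.i_dpdt_min - beat.start])

    try:
        t_half = tau_half(rec, beat)
    except ValueError:
        t_half = math.nan
    try:
        t_exp = tau_exp(rec, beat)
    except ValueError:
        t_exp = math.nan

    return BeatIndices(
        edv=edv, esv=esv, edp=edp, esp=esp, sv=sv, ef=ef, sw=sw,
        dpdt_max=dpdt_max, dpdt_min=dpdt_min,
        tau_half_ms=t_half, tau_exp_ms=t_exp,
        sci=dpdt_max / edv, ea=esp / sv,
    )


def tau_half(rec: PVRecording, beat: Beat) -> float:
    """Isovolumic relaxation constant as a half-decay time, ms.

    Time from dP/dt_min until pressure first falls to half its value at
    dP/dt_min, linearly interpolated between samples.  Raises
    ``ValueError`` if the crossing is not reached before beat end.
    """
    p, _ = smoothed_signals(rec)
    i0 = beat.i_dpdt_min
    p0 = p[i0]
    target = p0 / 2.0
    seg = p[i0:beat.end]
    below = np.nonzero(seg <= target)[0]
    if below.size == 0:
        raise ValueError("relaxation window truncated: pressure never halves before beat end")
    j = int(below[0])
    if j == 0:
        return 0.0
    frac = (seg[j - 1] - target) / (seg[j - 1] - seg[j])
    return (j - 1 + frac) / rec.fs * 1e3


def tau_exp(rec: PVRecording, beat: Beat, min_samples: int = 8) -> float:
    """Isovolumic relaxation constant from a zero-asymptote exponential fit, ms.

    Least-squares slope of ln P versus t from dP/dt_min until pressure
    falls to (next end-diastolic pressure + 5 mmHg); returns -1/slope.
    """
    p, _ = smoothed_signals(rec)
    i0 = beat.i_dpdt_min
    edp_floor = p[beat.end] if beat.end < p.size else p[beat.i_ed]
    stop_level = edp_floor + 5.0
    seg = p[i0:beat.end]
    below = np.nonzero(seg <= stop_level)[0]
    i1 = int(below[0]) if below.size else seg.size
    window = seg[:max(i1, 0)]
    if window.size < min_samples:
        raise ValueError(
            f"fit window too short: {window.size} samples < {min_samples}"
        )
    if np.any(window <= 0):
        raise ValueError("non-positive pressure in relaxation window; zero-asymptote fit invalid")
    t = np.arange(window.size) / rec.fs
    slope, _ = np.polyfit(t, np.log(window), 1)
    if slope >= 0:
        raise ValueError("pressure not decaying in relaxation window")
    return -1.0 / slope * 1e3


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    slope, _intercept = np.polyfit(x, y, 1)
    return float(slope)


def prsw(beats_indices: list[BeatIndices], min_spread: float = 2.0) -> float:
    """Preload recruitable stroke work: OLS slope of SW on EDV, mmHg."""
    if len(beats_indices) < 5:
        raise ValueError("need >= 5 beats for the SW-EDV regression")
    edv = np.array([b.edv for b in beats_indices])
    sw = np.array([b.sw for b in beats_indices])
    if edv.max() - edv.min() <= min_spread:
        raise ValueError(
            f"EDV spread {edv.max() - edv.min():.2f} ml too small for PRSW; "
            "acquire with preload variability"
        )
    return _ols_slope(edv, sw)


def espvr_slope(beats_indices: list[BeatIndices], min_spread: float = 1.0) -> tuple[float, float]:
    """ESPVR: (OLS slope of ESP on ESV, mean per-beat ESP/ESV), both mmHg/ml."""
    if len(beats_indices) < 5:
        raise ValueError("need >= 5 beats for the ESPVR regression")
    esv = np.array([b.esv for b in beats_indices])
    esp = np.array([b.esp for b in beats_indices])
    if esv.max() - esv.min() <= min_spread:
        raise ValueError(f"ESV spread {esv.max() - esv.min():.2f} ml too small for ESPVR")
    return _ols_slope(esv, esp), float(np.mean(esp / esv))


def edpvr_slope(beats_indices: list[BeatIndices], min_spread: float = 1.0) -> tuple[float, float]:
    """EDPVR: (OLS slope of EDP on EDV, mean per-beat EDP/EDV), both mmHg/ml."""
    if len(beats_indices) < 5:
        raise ValueError("need >= 5 beats for the EDPVR regression")
    edv = np.array([b.edv for b in beats_indices])
    edp = np.array([b.edp for b in beats_indices])
    if edv.max() - edv.min() <= min_spread:
        raise ValueError(f"EDV spread {edv.max() - edv.min():.2f} ml too small for EDPVR")
    return _ols_slope(edv, edp), float(np.mean(edp / edv))


def windkessel_ea(w: WindkesselInputs) -> float:
    """Arterial elastance from the three-element Windkessel closed form.

    Ea = R_T / [t_s + tau (1 - exp(-t_d / tau))], mmHg/ml.  The tau -> 0
    limit (instant diastolic decay) gives R_T / t_s.
    """
    if w.tau == 0.0:
        return w.r_t / w.t_s
    return w.r_t / (w.t_s + w.tau * (1.0 - math.exp(-w.t_d / w.tau)))


def global_report(
    rec: PVRecording,
    beats: list[Beat],
    beats_indices: list[BeatIndices] | None = None,
) -> IndexReport:
    """Compose the per-recording index report from analyzed beats.

    ``beats`` are the analyzed (clean, steady-state) beats; per-beat fields
    are averaged, HR = 60 / mean RR, CO = HR x mean SV / 1000 l/min, and
    the BSA- and pressure-dependent indices (SVI, CI, Zva) are added when
    the metadata carries the needed fields — otherwise they are omitted
    with a recorded warning rather than silently zeroed.
    """
    if not beats:
        raise ValueError("no analyzed beats")
    if beats_indices is None:
        beats_indices = [beat_indices(rec, b) for b in beats]
    notes: list[str] = []

    def nanmean(vals):
        vals = np.asarray(vals, dtype=float)
        ok = np.isfinite(vals)
        return float(vals[ok].mean()) if ok.any() else math.nan

    hr = 60.0 / float(np.mean([b.rr for b in beats]))
    mean = {f: nanmean([getattr(b, f) for b in beats_indices])
            for f in ("edv", "esv", "edp", "esp", "sv", "ef", "sw",
                      "dpdt_max", "dpdt_min", "tau_half_ms", "tau_exp_ms",
                      "sci", "ea")}
    co = hr * mean["sv"] / 1000.0

    try:
        prsw_val = prsw(beats_indices)
    except ValueError as e:
        notes.append(f"PRSW unavailable: {e}")
        prsw_val = math.nan
    try:
        ees, ees_ratio = espvr_slope(beats_indices)
    except ValueError as e:
        notes.append(f"ESPVR unavailable: {e}")
        ees = math.nan
        ees_ratio = nanmean([b.esp / b.esv for b in beats_indices])
    try:
        eed, eed_ratio = edpvr_slope(beats_indices)
    except ValueError as e:
        notes.append(f"EDPVR unavailable: {e}")
        eed = math.nan
        eed_ratio = nanmean([b.edp / b.edv for b in beats_indices])

    vac_ea_ees = mean["ea"] / ees if ees and math.isfinite(ees) and ees != 0 else math.nan
    vac_ees_ea = ees / mean["ea"] if mean["ea"] else math.nan

    svi = ci = zva = None
    bsa = rec.meta.bsa
    if bsa:
        svi = mean["sv"] / bsa
        ci = co / bsa
    else:
        notes.append("BSA missing: SVI and CI omitted")
    if svi is not None and rec.meta.sap is not None and rec.meta.mean_gradient is not None:
        zva = (rec.meta.sap + rec.meta.mean_gradient) / svi
    else:
        notes.append("SAP/mean gradient missing: Zva omitted")

    return IndexReport(
        hr=hr, n_beats=len(beats),
        co=co, prsw=prsw_val,
        ees=ees, ees_ratio=ees_ratio, eed=eed, eed_ratio=eed_ratio,
        vac_ea_over_ees=vac_ea_ees, vac_ees_over_ea=vac_ees_ea,
        svi=svi, ci=ci, zva=zva, warnings=notes,
        **mean,
    )


def analyze_recording(
    rec: PVRecording,
    n_beats: int = 10,
    rr_tol: float | str = 0.20,
    min_beats: int | None = None,
) -> IndexReport:
    """Full single-recording pipeline: segment, exclude extrasystoles,
    select the steady-state window, and report all indices.

    ``rr_tol="auto"`` widens the extrasystole RR tolerance to three robust
    RR coefficients of variation (capped at 35%) so that AF-type baseline
    irregularity is not mistaken for ectopy, while the 40% RR shortening
    of an extrasystole still trips the rule.  ``min_beats`` allows falling
    back to a shorter steady-state window when fewer than ``n_beats``
    clean consecutive beats exist (the shortfall is recorded in the
    report's warnings).
    """
    beats = segment_beats(rec)
    if rr_tol == "auto":
        rr = np.array([b.rr for b in beats])
        med = float(np.median(rr))
        cv_robust = 1.4826 * float(np.median(np.abs(rr - med))) / med
        rr_tol = min(max(0.20, 3.0 * cv_robust), 0.35)
    beats = flag_extrasystoles(beats, rr_tol=float(rr_tol))
    _, v_s = smoothed_signals(rec)
    used = n_beats
    while True:
        try:
            window = select_steady_state(beats, v_s, n_beats=used)
            break
        except ValueError:
            if min_beats is None or used <= min_beats:
                raise
            used -= 1
    report = global_report(rec, window)
    if used < n_beats:
        report.warnings.append(
            f"steady-state window shortened to {used} beats (requested {n_beats})"
        )
    return report
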