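"""Lumped-parameter cardiovascular simulator with known ground truth.

The left ventricle is a time-varying elastance: P_lv(t) = E(t) (V - V0),
with E(t) sweeping between a diastolic floor Emin and a systolic peak Emax
along a normalized double-Hill activation waveform.  The arterial system is
a three-element Windkessel (characteristic impedance Zc, peripheral
resistance Rp, compliance C).  The aortic valve obeys a quadratic
(Gorlin-type) orifice law, dP = (q / (K * EOA))^2, so a small effective
orifice area produces the transvalvular gradient of aortic stenosis;
"valve replacement" is modelled by enlarging the orifice and applying
configurable multiplicative changes to contractility and relaxation
timing.  Filling is resistive inflow from a constant-pressure venous
reservoir through the mitral valve.

Beat-to-beat variability (RR irregularity up to AF-like levels, AR(1)
preload fluctuation, ectopic beats with compensatory pauses) and additive
measurement noise turn the deterministic model into a generator of
realistic conductance-catheter-like recordings whose true parameters are
known exactly, so every downstream index estimator can be validated by
parameter recovery.

State is integrated with fixed-step RK4 at a 1 ms internal step and
resampled to the requested output rate; the first beats from the arbitrary
initial condition are discarded so emitted samples are in periodic steady
state.  Units throughout: mmHg, ml, s (ml/s for flow).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace, asdict

import numpy as np

from .recording import PVRecording, RecordingMeta

__all__ = [
    "ElastanceParams",
    "AfterloadParams",
    "ValveParams",
    "VariabilityParams",
    "TaviIntervention",
    "SimTruth",
    "SimulationError",
    "simulate_recording",
    "apply_tavi",
    "generate_cohort",
    "CohortPatient",
    "CohortRanges",
]

_DT = 1e-3          # internal integrator step, s
_WARMUP_BEATS = 10  # beats discarded before emission
_V_MAX_EXCURSION = 400.0  # ml above V0 considered non-physiological


class SimulationError(RuntimeError):
    """Integration left physiological bounds; message names the suspect parameter."""


@dataclass(frozen=True)
class ElastanceParams:
    """Time-varying elastance of the left ventricle.

    emax, emin : mmHg/ml — systolic / diastolic elastance bounds.
    v0         : ml — unstressed volume.
    t_act      : activation-rise time scale, fraction of the cycle.
    t_rel      : relaxation time scale (center of the decay), fraction of cycle.
    n_rise, n_decay : double-Hill exponents shaping rise and decay.
    """

    emax: float = 3.5
    emin: float = 0.145
    v0: float = 5.0
    t_act: float = 0.269
    t_rel: float = 0.452
    n_rise: float = 1.32
    n_decay: float = 14.0

    def __post_init__(self):
        if not (self.emax > self.emin > 0):
            raise ValueError("require emax > emin > 0")
        if self.v0 < 0:
            raise ValueError("require v0 >= 0")
        if not (0 < self.t_act < self.t_rel < 1):
            raise ValueError("require 0 < t_act < t_rel < 1")


@dataclass(frozen=True)
class AfterloadParams:
    """Three-element Windkessel plus venous filling.

    zc  : characteristic impedance, mmHg.s/ml
    rp  : peripheral resistance, mmHg.s/ml
    c   : arterial compliance, ml/mmHg
    pven: venous/atrial filling pressure, mmHg
    rmv : mitral inflow resistance, mmHg.s/ml
    """

    zc: float = 0.07
    rp: float = 1.8
    c: float = 1.3
    pven: float = 15.0
    rmv: float = 0.025

    def __post_init__(self):
        for name in ("zc", "rp", "c", "pven", "rmv"):
            if not getattr(self, name) > 0:
                raise ValueError(f"require {name} > 0")

    @property
    def total_resistance(self) -> float:
        """R_T = Zc + Rp, the total mean vascular resistance."""
        return self.zc + self.rp

    @property
    def decay_tau(self) -> float:
        """Diastolic arterial pressure decay constant Rp*C, s."""
        return self.rp * self.c


@dataclass(frozen=True)
class ValveParams:
    """Quadratic orifice law: dP = (q / (k * eoa))^2 for forward flow q (ml/s).

    eoa : effective orifice area, cm^2 (0.7 is severe stenosis; >= 1.8 post
          valve replacement).
    k   : Gorlin-type orifice constant, ml/(s.cm^2.mmHg^0.5).
    """

    eoa: float = 0.7
    k: float = 51.6

    def __post_init__(self):
        if not self.eoa > 0:
            raise ValueError("require eoa > 0")
        if not self.k > 0:
            raise ValueError("require k > 0")

    def gradient(self, q: float) -> float:
        """Instantaneous transvalvular gradient for forward flow q >= 0, mmHg."""
        if q <= 0:
            return 0.0
        return (q / (self.k * self.eoa)) ** 2


@dataclass(frozen=True)
class VariabilityParams:
    """Stochastic terms layered on the deterministic model.

    rr_mean     : mean RR interval, s.
    rr_cv       : coefficient of variation of RR; ~0.03 sinus, >= 0.1 AF-like.
    preload_sd  : SD of AR(1) beat-to-beat fluctuation of pven, mmHg.
    ectopic_rate: probability per beat of an extrasystole (RR x 0.6,
                  Emax x 0.7, followed by a compensatory pause).
    noise_p_sd, noise_v_sd : additive white Gaussian measurement noise on
                  pressure (mmHg) and volume (ml), applied after dynamics.
    seed        : RNG seed; only stochastic terms consume it.
    """

    rr_mean: float = 0.92
    rr_cv: float = 0.03
    preload_sd: float = 0.8
    ectopic_rate: float = 0.0
    noise_p_sd: float = 1.0
    noise_v_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if not self.rr_mean > 0:
            raise ValueError("require rr_mean > 0")
        for name in ("rr_cv", "preload_sd", "noise_p_sd", "noise_v_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"require {name} >= 0")
        if not (0 <= self.ectopic_rate < 0.5):
            raise ValueError("require 0 <= ectopic_rate < 0.5")

    @classmethod
    def quiet(cls, rr_mean: float = 0.92, seed: int = 0) -> "VariabilityParams":
        """All stochastic terms off: strictly periodic, noise-free."""
        return cls(rr_mean=rr_mean, rr_cv=0.0, preload_sd=0.0,
                   ectopic_rate=0.0, noise_p_sd=0.0, noise_v_sd=0.0, seed=seed)


@dataclass(frozen=True)
class SimTruth:
    """Ground truth accompanying a simulated recording.

    Derived values are measured on the emitted (steady-state, noise-free)
    trajectory, not asserted: the mean transvalvular gradient is the
    time-average of the orifice-law gradient during ejection; the
    Windkessel arterial elastance evaluates
    R_T / [t_s + tau (1 - exp(-t_d/tau))] with the measured systolic
    period t_s, diastolic period t_d and tau = Rp*C; the pressure-decay
    constant is the half-decay time of the isovolumic pressure implied by
    the elastance waveform.
    """

    elastance: ElastanceParams
    afterload: AfterloadParams
    valve: ValveParams
    variability: VariabilityParams
    true_mean_gradient: float       # mmHg, ejection-phase time average
    true_ea_windkessel: float       # mmHg/ml
    true_emax: float                # mmHg/ml
    true_tau_ms: float              # ms
    t_systole: float                # s, mean ejection duration
    beat_onsets: np.ndarray = field(repr=False)          # s, activation starts in emitted frame
    ectopic_beats: np.ndarray = field(repr=False)        # indices into beat_onsets

    def to_dict(self) -> dict:
        d = {
            "elastance": asdict(self.elastance),
            "afterload": asdict(self.afterload),
            "valve": asdict(self.valve),
            "variability": asdict(self.variability),
            "true_mean_gradient": self.true_mean_gradient,
            "true_ea_windkessel": self.true_ea_windkessel,
            "true_emax": self.true_emax,
            "true_tau_ms": self.true_tau_ms,
            "t_systole": self.t_systole,
            "beat_onsets": self.beat_onsets.tolist(),
            "ectopic_beats": self.ectopic_beats.tolist(),
        }
        return d


# ---------------------------------------------------------------------------
# activation waveform


_ACT_HORIZON = 1.6  # activation table horizon in units of rr: the decay tail
                    # extends past the nominal cycle so a premature next beat
                    # does not truncate relaxation discontinuously


def _activation_curve(el: ElastanceParams, rr: float, n: int = 512):
    """Normalized double-Hill activation sampled on [0, 1.6*rr); peak = 1."""
    t = np.linspace(0.0, _ACT_HORIZON * rr, n, endpoint=False)
    a1 = el.t_act * rr
    a2 = el.t_rel * rr
    x1 = (t / a1) ** el.n_rise
    rise = x1 / (1.0 + x1)
    decay = 1.0 / (1.0 + (t / a2) ** el.n_decay)
    g = rise * decay
    peak = g.max()
    if peak <= 0:
        raise SimulationError("activation waveform degenerate (t_act/t_rel)")
    return t, g / peak


def true_relaxation_half_time(el: ElastanceParams, rr: float) -> float:
    """Half-decay time (ms) of isovolumic pressure implied by the elastance fall.

    At constant volume, P(t) is proportional to E(t); the generative analog
    of the clinical Tau(half) is the time from the steepest pressure fall to
    the point where pressure has halved.
    """
    t = np.linspace(0.0, rr, 20001)
    x1 = (t / (el.t_act * rr)) ** el.n_rise
    with np.errstate(divide="ignore"):
        g = (x1 / (1.0 + x1)) / (1.0 + (t / (el.t_rel * rr)) ** el.n_decay)
    g = np.nan_to_num(g / g.max())
    e = el.emin + (el.emax - el.emin) * g
    de = np.gradient(e, t)
    i0 = int(np.argmin(de))  # steepest fall
    target = e[i0] / 2.0
    for j in range(i0, t.size - 1):
        if e[j + 1] <= target:
            # linear interpolation between samples
            frac = (e[j] - target) / (e[j] - e[j + 1])
            return ((t[j] + frac * (t[j + 1] - t[j])) - t[i0]) * 1e3
    return math.nan


# ---------------------------------------------------------------------------
# beat schedule


@dataclass
class _BeatPlan:
    onset: float       # s from integration start
    rr: float          # s
    emax_factor: float
    pven: float        # mmHg, effective filling pressure this beat
    ectopic: bool


def _schedule_beats(
    var: VariabilityParams,
    total_time: float,
    rng: np.random.Generator,
    base_pven: float,
) -> list[_BeatPlan]:
    """Draw the beat sequence covering [0, total_time] plus one spare beat."""
    plans: list[_BeatPlan] = []
    t = 0.0
    pven = base_pven
    phi = 0.7  # AR(1) persistence of the preload fluctuation
    pending_pause = False
    while t <= total_time:
        rr = var.rr_mean
        if var.rr_cv > 0:
            rr = var.rr_mean * (1.0 + var.rr_cv * rng.standard_normal())
            rr = max(rr, 0.35 * var.rr_mean)
        emax_f = 1.0
        ectopic = False
        if pending_pause:
            rr = 1.4 * var.rr_mean  # compensatory pause
            pending_pause = False
        elif var.ectopic_rate > 0 and rng.random() < var.ectopic_rate:
            rr = 0.6 * var.rr_mean
            emax_f = 0.7
            ectopic = True
            pending_pause = True
        if var.preload_sd > 0:
            innov = var.preload_sd * math.sqrt(1.0 - phi * phi) * rng.standard_normal()
            pven = base_pven + phi * (pven - base_pven) + innov
            pven = max(pven, 2.0)
        else:
            pven = base_pven
        plans.append(_BeatPlan(onset=t, rr=rr, emax_factor=emax_f, pven=pven, ectopic=ectopic))
        t += rr
    return plans


# ---------------------------------------------------------------------------
# core integration


def simulate_recording(
    elastance: ElastanceParams = ElastanceParams(),
    afterload: AfterloadParams = AfterloadParams(),
    valve: ValveParams = ValveParams(),
    variability: VariabilityParams = VariabilityParams(),
    duration: float = 30.0,
    fs: float = 250.0,
    bsa: float = 1.9,
) -> tuple[PVRecording, SimTruth]:
    """Simulate a steady-state LV pressure-volume recording.

    Parameters
    ----------
    duration : emitted length in seconds (>= 10); ten additional warm-up
        beats are integrated and discarded first.
    fs : output sampling rate, Hz (>= 100).
    bsa : body surface area stored in the recording metadata, m^2.

    Returns the recording (with measurement noise, if configured) and the
    ground truth measured on the noise-free trajectory.
    """
    if duration < 10.0:
        raise ValueError("duration must be >= 10 s")
    if fs < 100.0:
        raise ValueError("fs must be >= 100 Hz")

    rng = np.random.default_rng(variability.seed)
    warmup_time_est = _WARMUP_BEATS * variability.rr_mean
    total = warmup_time_est + duration + 2.0 * variability.rr_mean
    plans = _schedule_beats(variability, total, rng, afterload.pven)
    # emission starts a quarter second before the first post-warm-up beat so
    # that its end-diastolic plateau is present in the emitted samples
    t_emit = max(plans[_WARMUP_BEATS].onset - 0.25, 0.0)

    n_steps = int(math.ceil((t_emit + duration) / _DT)) + 1
    el, af, vv = elastance, afterload, valve
    kq = vv.k * vv.eoa
    a_q = 1.0 / (kq * kq)        # quadratic coefficient of the orifice law
    zc, rp, cc, rmv = af.zc, af.rp, af.c, af.rmv
    emin, v0 = el.emin, el.v0

    # per-beat activation lookup tables (cached by rr, emax_factor)
    act_cache: dict[tuple[float, float], tuple[np.ndarray, float]] = {}

    def activation(rr: float) -> tuple[np.ndarray, float]:
        key = (round(rr, 9), 0.0)
        if key not in act_cache:
            tgrid, g = _activation_curve(el, rr, n=2048)
            act_cache[key] = (g, _ACT_HORIZON * rr / g.size)
        return act_cache[key]

    # state
    v = v0 + 0.85 * (afterload.pven / emin)   # start near diastolic equilibrium
    pwk = 70.0
    beat_idx = 0
    n_plans = len(plans)

    times = np.empty(n_steps)
    p_out = np.empty(n_steps)
    v_out = np.empty(n_steps)
    pao_out = np.empty(n_steps)
    qav_out = np.empty(n_steps)
    grad_out = np.empty(n_steps)
    # cumulative inflow/outflow integrated as RK4 states so the volume
    # conservation identity holds to floating-point precision
    cin = 0.0
    cout = 0.0
    cin_trace = np.empty(n_steps)
    cout_trace = np.empty(n_steps)

    def _act_of(plan: _BeatPlan, t_abs: float) -> float:
        tb = t_abs - plan.onset
        if tb <= 0.0:
            return 0.0
        g, dtg = activation(plan.rr)
        x = tb / dtg
        i = int(x)
        if i >= g.size - 1:
            return 0.0
        a = g[i] + (x - i) * (g[i + 1] - g[i])
        return (el.emax * plan.emax_factor - emin) * a

    def elast(t_abs: float, bi: int) -> float:
        # the previous beat's relaxation tail may still be decaying when the
        # next activation starts (short RR); take the envelope of both
        stress = _act_of(plans[bi], t_abs)
        if bi > 0:
            stress = max(stress, _act_of(plans[bi - 1], t_abs))
        return emin + stress

    def rhs(t_abs: float, v_: float, pwk_: float, bi: int):
        e = elast(t_abs, bi)
        plv = e * (v_ - v0)
        dp = plv - pwk_
        if dp > 0.0:
            qav = (-zc + math.sqrt(zc * zc + 4.0 * a_q * dp)) / (2.0 * a_q)
        else:
            qav = 0.0
        pven_b = plans[bi].pven
        qmv = (pven_b - plv) / rmv
        if qmv < 0.0:
            qmv = 0.0
        dv = qmv - qav
        dpwk = (qav - pwk_ / rp) / cc
        return dv, dpwk, qmv, qav, plv, e

    t = 0.0
    for k in range(n_steps):
        # advance beat pointer
        while beat_idx + 1 < n_plans and t >= plans[beat_idx + 1].onset:
            beat_idx += 1
        dv1, dw1, qmv1, qav1, plv, e_now = rhs(t, v, pwk, beat_idx)
        times[k] = t
        p_out[k] = plv
        v_out[k] = v
        pao_out[k] = pwk + zc * qav1
        qav_out[k] = qav1
        grad_out[k] = vv.gradient(qav1)
        cin_trace[k] = cin
        cout_trace[k] = cout

        if not (v0 - 1e-6 < v < v0 + _V_MAX_EXCURSION):
            raise SimulationError(
                f"volume {v:.1f} ml left bounds at t={t:.3f} s; "
                "check pven/emin (filling) or valve eoa (ejection)"
            )
        if not (-20.0 < plv < 400.0):
            raise SimulationError(
                f"LV pressure {plv:.1f} mmHg left bounds at t={t:.3f} s; check emax"
            )

        # RK4 step (beat index held over the step; onset error <= 1 ms)
        h = _DT
        dv2, dw2, qmv2, qav2, *_ = rhs(t + 0.5 * h, v + 0.5 * h * dv1, pwk + 0.5 * h * dw1, beat_idx)
        dv3, dw3, qmv3, qav3, *_ = rhs(t + 0.5 * h, v + 0.5 * h * dv2, pwk + 0.5 * h * dw2, beat_idx)
        dv4, dw4, qmv4, qav4, *_ = rhs(t + h, v + h * dv3, pwk + h * dw3, beat_idx)
        v += h / 6.0 * (dv1 + 2 * dv2 + 2 * dv3 + dv4)
        pwk += h / 6.0 * (dw1 + 2 * dw2 + 2 * dw3 + dw4)
        cin += h / 6.0 * (qmv1 + 2 * qmv2 + 2 * qmv3 + qmv4)
        cout += h / 6.0 * (qav1 + 2 * qav2 + 2 * qav3 + qav4)
        t += h

    # ------------------------------------------------------------------
    # emitted span and truth measurements
    i0 = int(round(t_emit / _DT))
    sel = slice(i0, n_steps)
    t_rel_grid = times[sel] - t_emit

    # resample to fs on [0, duration)
    n_out = int(math.floor(duration * fs))
    t_out = np.arange(n_out) / fs
    p_sig = np.interp(t_out, t_rel_grid, p_out[sel])
    v_sig = np.interp(t_out, t_rel_grid, v_out[sel])

    # mean transvalvular gradient: ejection-phase time average over emitted span
    ej = qav_out[sel] > 1e-9
    if ej.any():
        mean_grad = float(grad_out[sel][ej].mean())
        # mean ejection duration per beat
        edges = np.diff(ej.astype(int))
        n_open = max(int((edges == 1).sum()), 1)
        t_systole = float(ej.sum() * _DT / n_open)
    else:
        mean_grad = 0.0
        t_systole = math.nan

    # systolic arterial pressure (mean of per-step aortic maxima is close to
    # the beat-wise mean; use global percentile for robustness)
    sap = float(np.percentile(pao_out[sel], 99.0))

    emitted_plans = [p for p in plans if t_emit <= p.onset < t_emit + duration]
    beat_onsets = np.array([p.onset - t_emit for p in emitted_plans])
    ectopics = np.array(
        [i for i, p in enumerate(emitted_plans) if p.ectopic], dtype=int
    )
    rr_mean_emitted = float(np.mean([p.rr for p in emitted_plans])) if emitted_plans else variability.rr_mean

    tau_wk = af.decay_tau
    t_d = max(rr_mean_emitted - t_systole, 1e-6)
    ea_wk = af.total_resistance / (t_systole + tau_wk * (1.0 - math.exp(-t_d / tau_wk)))

    truth = SimTruth(
        elastance=el,
        afterload=af,
        valve=vv,
        variability=variability,
        true_mean_gradient=mean_grad,
        true_ea_windkessel=float(ea_wk),
        true_emax=el.emax,
        true_tau_ms=true_relaxation_half_time(el, rr_mean_emitted),
        t_systole=t_systole,
        beat_onsets=beat_onsets,
        ectopic_beats=ectopics,
    )

    # measurement noise (post-dynamics)
    if variability.noise_p_sd > 0:
        p_sig = p_sig + variability.noise_p_sd * rng.standard_normal(p_sig.size)
    if variability.noise_v_sd > 0:
        v_sig = v_sig + variability.noise_v_sd * rng.standard_normal(v_sig.size)

    meta = RecordingMeta(bsa=bsa, sap=sap, mean_gradient=mean_grad, labels={})
    rec = PVRecording(p_sig, v_sig, fs, meta)

    # volume conservation audit: integral of (q_in - q_out) must equal the
    # volume change; both sides integrated by the same RK4, so the residual
    # is pure floating-point error
    net = (cin_trace - cout_trace) - (v_out - v_out[0])
    rec.conservation_residual = float(np.max(np.abs(net)))

    return rec, truth


# ---------------------------------------------------------------------------
# TAVI intervention


@dataclass(frozen=True)
class TaviIntervention:
    """Configurable pre-to-post contrast of valve replacement.

    eoa_post    : cm^2, orifice area of the implanted valve (> pre eoa).
    emax_factor : multiplicative change of contractility (early post-TAVI
                  depression when < 1).
    trel_factor : multiplicative slowing of the relaxation time scale.
    ndecay_factor : multiplicative change of the relaxation Hill exponent;
                  < 1 flattens the elastance fall-off, lengthening Tau
                  independently of cycle length (activation timing is a
                  fraction of the cycle, so a faster post rate would
                  otherwise shorten the measured relaxation).
    pven_factor : multiplicative change of filling pressure (periprocedural
                  volume state; drives the EDP shift).
    rr_factor   : multiplicative change of the mean RR interval.
    """

    eoa_post: float = 1.8
    emax_factor: float = 0.6
    trel_factor: float = 1.10
    ndecay_factor: float = 0.85
    pven_factor: float = 1.35
    rr_factor: float = 0.87


def apply_tavi(
    valve: ValveParams,
    elastance: ElastanceParams,
    intervention: TaviIntervention = TaviIntervention(),
    afterload: AfterloadParams | None = None,
):
    """Return post-intervention parameter blocks.

    The orifice area must strictly increase.  When ``afterload`` is given a
    third, adjusted block (filling pressure scaled by ``pven_factor``) is
    returned as well.
    """
    if not intervention.eoa_post > valve.eoa:
        raise ValueError(
            f"post eoa ({intervention.eoa_post}) must exceed pre eoa ({valve.eoa})"
        )
    valve_post = replace(valve, eoa=intervention.eoa_post)
    t_rel_post = min(elastance.t_rel * intervention.trel_factor, 0.95)
    el_post = replace(
        elastance,
        emax=elastance.emax * intervention.emax_factor,
        t_rel=t_rel_post,
        n_decay=elastance.n_decay * intervention.ndecay_factor,
    )
    if afterload is None:
        return valve_post, el_post
    af_post = replace(afterload, pven=afterload.pven * intervention.pven_factor)
    return valve_post, el_post, af_post


# ---------------------------------------------------------------------------
# cohort generation


@dataclass(frozen=True)
class CohortRanges:
    """Sampling ranges for per-patient pre-TAVI parameters.

    Centers reflect a severe-aortic-stenosis population: orifice ~0.7 cm^2,
    end-diastolic volume ~94 ml, filling pressure ~13-16 mmHg, HR 60-75.
    Gaussian entries are (mean, sd); uniform entries are (lo, hi).
    """

    emax: tuple[float, float] = (3.5, 0.8)          # gaussian, mmHg/ml
    emin: tuple[float, float] = (0.12, 0.17)        # uniform, mmHg/ml
    edv_target: tuple[float, float] = (94.0, 12.0)  # gaussian, ml
    eoa: tuple[float, float] = (0.5, 0.9)           # uniform, cm^2
    rr_mean: tuple[float, float] = (0.80, 1.00)     # uniform, s
    bsa: tuple[float, float] = (1.7, 2.1)           # uniform, m^2
    af_fraction: float = 0.6
    rr_cv_sinus: float = 0.03
    rr_cv_af: float = 0.15
    preload_sd: float = 0.8
    ectopic_rate: float = 0.02
    low_ef_emax_threshold: float = 3.0              # drawn emax below -> low-EF label
    severe_mi_fraction: float = 0.375

    def validate(self) -> None:
        for name in ("emin", "eoa", "rr_mean", "bsa"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"degenerate range for {name}: min > max")
        for name in ("emax", "edv_target"):
            if getattr(self, name)[1] < 0:
                raise ValueError(f"negative sd for {name}")


@dataclass
class CohortPatient:
    """One synthetic patient: paired pre/post recordings with ground truth."""

    patient_id: str
    pre: PVRecording
    post: PVRecording
    truth_pre: SimTruth
    truth_post: SimTruth
    labels: dict
    covariates: dict


def draw_cohort_params(
    n_patients: int,
    ranges: CohortRanges,
    rng: np.random.Generator,
) -> list[dict]:
    """Draw per-patient parameter blocks (no simulation)."""
    out = []
    for i in range(n_patients):
        emax = max(rng.normal(*ranges.emax), 1.2)
        emin = rng.uniform(*ranges.emin)
        edv_t = max(rng.normal(*ranges.edv_target), 55.0)
        v0 = 5.0
        # set pven so the diastolic equilibrium sits at the drawn EDV target
        pven = emin * (edv_t - v0) * 1.02
        eoa = rng.uniform(*ranges.eoa)
        rr = rng.uniform(*ranges.rr_mean)
        af = bool(rng.random() < ranges.af_fraction)
        out.append(
            {
                "elastance": ElastanceParams(emax=emax, emin=emin, v0=v0),
                "afterload": AfterloadParams(pven=pven),
                "valve": ValveParams(eoa=eoa),
                "rr_mean": rr,
                "rr_cv": ranges.rr_cv_af if af else ranges.rr_cv_sinus,
                "bsa": rng.uniform(*ranges.bsa),
                "af": af,
                "low_ef": emax < ranges.low_ef_emax_threshold,
                "severe_mi": bool(rng.random() < ranges.severe_mi_fraction),
                "edv_target": edv_t,
                "rvp_count": int(rng.integers(0, 4)),
                "contrast_ml": float(rng.uniform(40.0, 200.0)),
            }
        )
    return out


def generate_cohort(
    n_patients: int = 8,
    ranges: CohortRanges = CohortRanges(),
    intervention: TaviIntervention = TaviIntervention(),
    seed: int = 7,
    duration: float = 25.0,
    fs: float = 250.0,
    noise: bool = True,
) -> list[CohortPatient]:
    """Simulate a paired pre/post valve-replacement cohort.

    Each patient's pre parameters are drawn from ``ranges``; the post state
    applies ``intervention`` to the same patient.  Fully reproducible under
    a fixed seed.  Use :func:`pvloop.cohortstats.cohort_table` to turn the
    result into index reports and statistics.
    """
    if n_patients < 2:
        raise ValueError("n_patients must be >= 2")
    ranges.validate()
    rng = np.random.default_rng(seed)
    draws = draw_cohort_params(n_patients, ranges, rng)
    patients = []
    for i, d in enumerate(draws):
        noise_p = 1.0 if noise else 0.0
        noise_v = 2.0 if noise else 0.0
        var_pre = VariabilityParams(
            rr_mean=d["rr_mean"],
            rr_cv=d["rr_cv"],
            preload_sd=ranges.preload_sd,
            ectopic_rate=ranges.ectopic_rate,
            noise_p_sd=noise_p,
            noise_v_sd=noise_v,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        rec_pre, truth_pre = simulate_recording(
            d["elastance"], d["afterload"], d["valve"], var_pre,
            duration=duration, fs=fs, bsa=d["bsa"],
        )
        valve_post, el_post, af_post = apply_tavi(
            d["valve"], d["elastance"], intervention, d["afterload"]
        )
        var_post = replace(
            var_pre,
            rr_mean=d["rr_mean"] * intervention.rr_factor,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        rec_post, truth_post = simulate_recording(
            el_post, af_post, valve_post, var_post,
            duration=duration, fs=fs, bsa=d["bsa"],
        )
        labels = {"low_ef": d["low_ef"], "af": d["af"], "severe_mi": d["severe_mi"]}
        rec_pre.meta.labels.update(labels)
        rec_post.meta.labels.update(labels)
        patients.append(
            CohortPatient(
                patient_id=f"P{i + 1:02d}",
                pre=rec_pre,
                post=rec_post,
                truth_pre=truth_pre,
                truth_post=truth_post,
                labels=labels,
                covariates={"rvp_count": d["rvp_count"], "contrast_ml": d["contrast_ml"]},
            )
        )
    return patients
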