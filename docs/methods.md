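# Methods

## The measurement problem

Invasive PV-loop analysis around transcatheter valve replacement asks a
simple question of a difficult signal: given continuous LV pressure and
volume before and immediately after the intervention, how do contractility,
relaxation and ventricular–arterial interaction change?  The raw signal is
a few tens of cardiac cycles at a few hundred Hz, contaminated by catheter
noise, RR irregularity (most of these patients are in atrial fibrillation),
and occasional extrasystoles whose loading is unrepresentative.  Every
index must therefore be defined beat-wise, on a cleaned steady-state
window, and averaged.

## Simulator

The ventricle is a time-varying elastance, `P_lv(t) = E(t)·(V − V0)`, with

```
E(t) = Emin + (Emax − Emin) · e(t/T),
e(s) ∝ [ (s/a1)^n1 / (1 + (s/a1)^n1) ] · [ 1 / (1 + (s/a2)^n2) ]
```

a double-Hill activation normalized to unit peak: a smooth waveform whose
rise (`a1 = t_act`, exponent `n1`) and decay (`a2 = t_rel`, exponent `n2`)
are separately controllable, which is exactly what is needed to emulate
systole and an isovolumic relaxation of tunable speed.  The decay tail is
evaluated out to 1.6 cycle lengths so a premature next beat (short RR in
AF, extrasystoles) overlaps the previous relaxation instead of truncating
it discontinuously; instantaneous elastance is the envelope of the two.

Afterload is a three-element Windkessel (characteristic impedance `Zc`,
peripheral resistance `Rp`, compliance `C`).  The aortic valve follows a
quadratic orifice law `ΔP = (q / (K·EOA))²` with the Gorlin-type constant
`K = 51.6 ml·s⁻¹·cm⁻²·mmHg^(−1/2)`: an effective orifice area of 0.7 cm²
yields a mean systolic gradient around 30 mmHg at normal flows, a
wide-open orifice a negligible one.  Filling is resistive inflow from a
constant-pressure venous reservoir (`Pven`, `Rmv`); there is no atrial
chamber, baroreflex, or regurgitant flow.

State (LV volume, Windkessel pressure, and the cumulative trans-mitral and
trans-aortic flow integrals) is advanced by fixed-step RK4 at 1 ms and
linearly resampled to the output rate.  Integrating the flow integrals
with the same RK4 stages makes volume conservation,
∫(q_in − q_out) dt = ΔV, an identity up to floating-point error (~1e−11 ml
over 30 s), which the tests assert.  Ten warm-up beats from the arbitrary
initial condition are discarded; emission starts 0.25 s before a beat
onset so the first end-diastolic plateau is in frame.  Out-of-bounds state
(volume outside (V0, V0+400 ml), pressure outside (−20, 400) mmHg) raises
an error naming the likely offending parameter.

Stochastic layers, all seeded: RR intervals `rr_mean·(1 + rr_cv·ε)`
(cv ≈ 0.03 for sinus rhythm, ≥ 0.1 AF-like); an AR(1) fluctuation of the
filling pressure (φ = 0.7, configurable SD, default 0.8 mmHg) which
produces the natural beat-to-beat preload spread the PRSW/ESPVR/EDPVR
regressions need; extrasystoles (RR shortened to 60%, contractility ×0.7,
followed by a 1.4·RR compensatory pause); and additive white measurement
noise after the dynamics (defaults 1 mmHg and 2 ml — conductance-catheter
scale).

### Default operating point

Defaults were chosen once to put the simulated patient in the severe-
aortic-stenosis regime of the intended population: `Emax` 3.5 mmHg/ml,
`Emin` 0.145 mmHg/ml, `V0` 5 ml, `Zc` 0.07, `Rp` 1.8, `C` 1.3, `Pven`
15 mmHg, `Rmv` 0.025, EOA 0.7 cm², HR ≈ 65/min.  This yields EDV ≈ 99 ml,
EDP ≈ 13.6 mmHg, EF ≈ 0.52, ESP ≈ 146 mmHg, mean gradient ≈ 30 mmHg,
Tau ≈ 39 ms.  The default "TAVI" intervention enlarges the orifice to
1.8 cm², scales `Emax` ×0.6 (early contractile depression), slows
relaxation (`t_rel` ×1.1 and decay exponent ×0.85 — the exponent change is
needed because activation timing scales with the cycle, and the faster
post-procedural rate would otherwise cancel the slowing), raises `Pven`
×1.35 (periprocedural filling state, which carries the EDP rise), and
shortens RR ×0.87.  These effect sizes are configuration, not asserted
physiology; they produce the qualitative post-procedural signature (EF↓,
PRSW↓, Ees↓, Tau↑, EDP↑, ESV↑, loop shifted right/up) that the acceptance
suite checks as inequalities on cohort means.

Cohort generation draws per-patient parameters independently: `Emax`
~ N(3.5, 0.8²) (floored), `Emin` ~ U(0.12, 0.17), an EDV target
~ N(94, 12²) ml realized by setting `Pven` to the implied diastolic
equilibrium, EOA ~ U(0.5, 0.9) cm², RR ~ U(0.8, 1.0) s, BSA ~ U(1.7, 2.1)
m², AF in 60% of patients, and placeholder low-EF / severe-MI labels.
Rapid-pacing count and contrast volume are recorded as covariates with no
generative link to any index, so correlation analyses on synthetic cohorts
have a true null.

## Beat segmentation

Upstrokes are peaks of the smoothed pressure derivative (20 ms moving
average, central differences) with prominence ≥ 200 mmHg/s, a height floor
of 30% of the 99th-percentile derivative (robust to isolated spikes), and
a 300 ms refractory distance.  End-diastole is located in the 250 ms
window before each upstroke, capped at the upstroke onset (derivative
< 10% of peak): the earliest sample on the end-diastolic volume plateau
(within 1 ml of the window maximum, on a 40 ms-smoothed volume).  Without
the onset cap, volume noise can place the "maximum" after pressure has
started rising and corrupt EDP by tens of mmHg.  Beats are half-open
spans `[ED−1, nextED−1)`, so they tile the record.  End-systole is the
sample maximizing P/V (zero volume-intercept assumption) between the
derivative extremes, which are the within-beat argmax/argmin of the
smoothed derivative.  Landmark *values* (EDV, ESV, EDP, ESP, and the
relaxation fits) are read from the smoothed traces; without this, the
2 ml volume noise swamps the few-ml natural ESV spread and biases the
ESPVR slope toward zero.

Extrasystole exclusion: a beat whose RR deviates more than 20% from the
running median (7-beat neighborhood) is flagged, as is the following
(post-extrasystolic) beat.  In AF the 20% rule misfires on normal beats,
so the pipeline-level entry point can widen the tolerance to three robust
RR coefficients of variation, capped at 35% — still below the 40%
shortening of a simulated extrasystole.  The steady-state window is the
contiguous run of n clean beats (default 10; the cohort pipeline falls
back as low as 6, recording the shortfall) with minimal variance of
end-diastolic volume.

## Indices

Per beat: SW is the shoelace area of the sampled loop (counterclockwise
positive; magnitude reported and a warning raised for clockwise or
self-intersecting loops); Tau(half) is the interpolated time for pressure
to fall to half its value at dP/dt_min; Tau(exp) is −1/slope of ln P
versus t from dP/dt_min down to (next EDP + 5 mmHg), a zero-asymptote
model (on a true exponential, Tau(half)/Tau(exp) = ln 2, which the tests
verify to 1%).  Multi-beat: PRSW, Ees and Eed are OLS slopes over the
analyzed beats, guarded by minimum-spread checks (2 ml EDV for PRSW, 1 ml
for the PV relations) so that degenerate windows error out instead of
returning noise; per-beat ratio variants (mean ESP/ESV, mean EDP/EDV) are
reported alongside and labeled distinctly, since a slope and a ratio only
agree when the relation passes through the origin.  VA coupling is
reported in both orientations because the field (and the source setting)
uses both; Ea/Ees is the headline.  CO = HR·SV/1000 l/min; SVI, CI and
Zva require BSA / arterial pressures and are omitted with an explicit
warning when metadata is missing.

The Windkessel closed form `E_A = R_T/[t_s + τ(1 − e^(−t_d/τ))]` is
implemented exactly, with the τ→0 limit `R_T/t_s` and the τ→∞ limit
`R_T/(t_s + t_d)` (the e-term tends to t_d, not 0).  Agreement of the
measured ESP/SV with this form is validated at a non-stenotic orifice
(EOA 10 cm²), where it holds to ~5%; with a 0.7 cm² valve the LV-side ESP
deliberately includes the transvalvular gradient, which is precisely the
extra load Zva exists to capture, so the arterial-side closed form is not
the right reference there.

## Loop canonicalization

A loop polyline is oriented counterclockwise, its four corners located
(ED: lowest-pressure vertex within 2% of the volume maximum; ES: max P/V;
onset of ejection / filling: the highest-/lowest-pressure vertex within
5% of the iso-volumic band), and each limb resampled to 10 points equally
spaced by arc length in raw (ml, mmHg) coordinates, the starting corner
included and the ending corner excluded — 40 points, no duplicates.  On
an axis-aligned rectangle this reproduces the vertices and the exact area;
on simulated beats at ≥ 200 Hz the 40-point polygon's area is within 3%
of the dense polyline's.  Mean loops are pointwise arithmetic means, which
commute with rigid translation and are idempotent on copies.

## Statistics

Paired contrasts use the Wilcoxon signed-rank test with zero differences
discarded (count reported) and the null distribution enumerated exactly
over all 2^n sign assignments on midranks for n ≤ 15; subgroup contrasts
of per-patient deltas use Mann–Whitney U with the null enumerated over all
C(n, n₁) group assignments for combined n ≤ 20.  Beyond those sizes both
fall back to tie-corrected normal approximations.  Two-sided p values
count both tails symmetric about the null mean.  Kendall tau-b and
Pearson r come from scipy; constant-input tau-b is reported as undefined
with an explicit flag rather than coerced to a number.  Cohort tables
aggregate per-patient indices (mean of ratios, not ratio of means), report
mean ± SD pre and post with the exact paired p, and mark significance at
p < 0.05 with no multiplicity correction by default (Holm available),
matching exploratory-pilot practice.  The exact paired test's empirical
type-I error at n = 8 is ≤ 0.05 by construction (discreteness makes it
conservative, ~0.04 at nominal 0.05), verified by simulation.

## What the synthetic data does and does not show

The simulator reproduces the features the pipeline must survive — beat-to-
beat preload variation, AF-like RR irregularity, ectopy with compensatory
pauses, measurement noise, stenotic gradients, and a configurable
pre/post contrast — with exactly known ground truth.  It does not model
atrial transport, reflex control, regurgitation, catheter drift/recalibration,
or respiratory modulation; passing recovery tests therefore demonstrates
estimator correctness under the stated model, not robustness to every
clinical artifact.  Absolute magnitudes of regression-based indices
(e.g. PRSW ≈ 150 mmHg here versus ~70 in clinical reports) depend on the
source of preload variation — natural fluctuation here, not caval
occlusion — so cross-study comparison of magnitudes is not the goal;
directional contrasts and parameter recovery are.

## Problem sizes and tolerances

Default study sizes: 20–30 s recordings at 250 Hz (internal 1 ms step),
10-beat analysis windows, 20-run recovery studies, 8-patient cohorts,
10,000-replicate calibration — sizes at which every reported quantity is
stable to well within its acceptance tolerance (Ees recovery median error
~2% against a 20% bound; Ea agreement ~5% against 15%).  Numerical
tie-breaks: first-minimum window selection, earliest-plateau end-diastole,
midranks for ties, |signed area| for degenerate loops.
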