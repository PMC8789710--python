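"""Parameter-recovery and calibration studies used to validate the pipeline.

These run the full simulate -> segment -> index pipeline with known ground
truth and measure how well the estimators recover it:

* end-systolic elastance (ESPVR slope) against the simulator's Emax,
* measured arterial elastance (ESP/SV) against the three-element
  Windkessel closed form, evaluated at a non-stenotic orifice because the
  closed form models the arterial side only — with a stenotic valve the
  LV-side ESP deliberately includes the transvalvular gradient,
* the empirical type-I error of the exact paired signed-rank test under
  a continuous symmetric null.
"""

from __future__ import annotations

import numpy as np

from .cohortstats import paired_wilcoxon
from .hemosim import (
    AfterloadParams,
    ElastanceParams,
    ValveParams,
    VariabilityParams,
    simulate_recording,
)
from .indices import analyze_recording

__all__ = [
    "ees_recovery_study",
    "ea_windkessel_study",
    "type_one_error_study",
]


def ees_recovery_study(n_runs: int = 20, seed: int = 0, duration: float = 25.0):
    """Relative errors of the recovered ESPVR slope vs the true Emax.

    Noise-free recordings with beat-to-beat preload variability; Emax is
    drawn per run from a physiological range so recovery is not tested at
    a single operating point.  Returns the array of relative errors; a run
    whose regression is refused (insufficient natural spread) counts as an
    infinite error rather than being dropped.
    """
    rng = np.random.default_rng(seed)
    errs = []
    for i in range(n_runs):
        emax = float(rng.uniform(2.0, 4.5))
        el = ElastanceParams(emax=emax)
        var = VariabilityParams(
            rr_cv=0.03, preload_sd=0.8, noise_p_sd=0.0, noise_v_sd=0.0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        rec, truth = simulate_recording(el, variability=var, duration=duration)
        rep = analyze_recording(rec)
        err = abs(rep.ees - truth.true_emax) / truth.true_emax
        errs.append(err if np.isfinite(err) else np.inf)
    return np.asarray(errs)


def ea_windkessel_study(n_runs: int = 20, seed: int = 0, duration: float = 20.0):
    """Relative deviation of measured Ea (ESP/SV) from the Windkessel form.

    Run at a wide-open orifice (EOA 10 cm^2) so no valvular gradient
    separates the ventricular from the arterial side.  Returns the array
    of relative deviations.
    """
    rng = np.random.default_rng(seed)
    devs = []
    for i in range(n_runs):
        rp = float(rng.uniform(1.4, 2.2))
        af = AfterloadParams(rp=rp)
        var = VariabilityParams(
            rr_cv=0.03, preload_sd=0.8, noise_p_sd=0.0, noise_v_sd=0.0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        rec, truth = simulate_recording(
            afterload=af, valve=ValveParams(eoa=10.0), variability=var,
            duration=duration,
        )
        rep = analyze_recording(rec)
        devs.append(abs(rep.ea - truth.true_ea_windkessel) / truth.true_ea_windkessel)
    return np.asarray(devs)


def type_one_error_study(reps: int = 10000, n: int = 8, alpha: float = 0.05,
                         seed: int = 0) -> float:
    """Empirical rejection rate of the exact paired test under the null.

    Differences are drawn from a continuous symmetric distribution, the
    permutation (sign-flip) null of the signed-rank test.
    """
    rng = np.random.default_rng(seed)
    zeros = np.zeros(n)
    rej = 0
    for _ in range(reps):
        if paired_wilcoxon(zeros, rng.standard_normal(n)).p < alpha:
            rej += 1
    return rej / reps
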