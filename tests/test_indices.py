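"""Per-beat and per-recording hemodynamic indices."""

import math

import numpy as np
import pytest

from pvloop import PVRecording, RecordingMeta, VariabilityParams, simulate_recording
from pvloop.beatseg import Beat, flag_extrasystoles, segment_beats, smoothed_signals
from pvloop.indices import (
    BeatIndices,
    WindkesselInputs,
    analyze_recording,
    beat_indices,
    edpvr_slope,
    espvr_slope,
    global_report,
    prsw,
    shoelace_area,
    tau_exp,
    tau_half,
    windkessel_ea,
)


def _mk_indices(**kw):
    base = dict(edv=100.0, esv=50.0, edp=12.0, esp=120.0, sv=50.0, ef=0.5,
                sw=5000.0, dpdt_max=1200.0, dpdt_min=-1100.0,
                tau_half_ms=35.0, tau_exp_ms=50.0, sci=12.0, ea=2.4)
    base.update(kw)
    return BeatIndices(**base)


def _decay_recording(tau_s=0.025, fs=1000.0, p0=80.0):
    """Trace whose tail is a pure exponential decay from dP/dt-min onward."""
    n = 1000
    t = np.arange(n) / fs
    p = np.empty(n)
    p[:130] = np.linspace(5.0, p0, 130)
    p[130:] = p0 * np.exp(-(t[130:] - t[130]) / tau_s)
    rec = PVRecording(p, np.full(n, 50.0), fs)
    beat = Beat(start=0, end=900, i_ed=10, i_es=100, i_dpdt_max=50,
                i_dpdt_min=150, rr=0.9)
    return rec, beat


class TestBeatIndices:
    def test_rectangular_loop_stroke_work(self):
        # V: 50<->100 ml, P: 10<->110 mmHg traversed counterclockwise
        v = np.array([100.0, 100.0, 50.0, 50.0])
        p = np.array([10.0, 110.0, 110.0, 10.0])
        assert shoelace_area(v, p) == pytest.approx(5000.0)

    def test_ef_formula(self):
        bi = _mk_indices(edv=100.0, esv=50.0)
        assert (bi.edv - bi.esv) / bi.edv == pytest.approx(0.50)

    def test_simulated_beat_esp_close_to_truth(self, quiet_sim):
        rec, truth = quiet_sim
        beats = flag_extrasystoles(segment_beats(rec))
        b = [x for x in beats if not x.ectopic][5]
        bi = beat_indices(rec, b)
        # true end-systolic pressure at maximal elastance
        esp_true = truth.true_emax * (bi.esv - truth.elastance.v0)
        assert bi.esp == pytest.approx(esp_true, rel=0.05)

    def test_identity_suite(self, preload_sim):
        rec, _ = preload_sim
        beats = flag_extrasystoles(segment_beats(rec))
        for b in beats:
            if b.ectopic:
                continue
            bi = beat_indices(rec, b)
            assert bi.sv == pytest.approx(bi.edv - bi.esv, rel=1e-9)
            assert bi.ea * bi.sv == pytest.approx(bi.esp, rel=1e-9)
            assert bi.ef * bi.edv == pytest.approx(bi.sv, rel=1e-9)
            assert bi.dpdt_min < 0 < bi.dpdt_max
            assert bi.sw > 0

    def test_non_ejecting_beat_rejected(self):
        n = 2000
        p = 50 + 40 * np.sin(2 * np.pi * np.arange(n) / 250)
        v = np.full(n, 80.0)
        rec = PVRecording(p, v, 250.0)
        beat = Beat(start=0, end=500, i_ed=10, i_dpdt_max=30, i_es=100,
                    i_dpdt_min=180, rr=2.0)
        with pytest.raises(ValueError, match="non-ejecting"):
            beat_indices(rec, beat)

    def test_ectopic_beat_refused(self, quiet_sim):
        rec, _ = quiet_sim
        b = segment_beats(rec)[3]
        from dataclasses import replace

        with pytest.raises(ValueError, match="ectopic"):
            beat_indices(rec, replace(b, ectopic=True))


class TestTau:
    def test_half_decay_closed_form(self):
        rec, beat = _decay_recording(tau_s=0.025)
        assert tau_half(rec, beat) == pytest.approx(25.0 * math.log(2), abs=0.05)

    def test_plateau_never_halves(self):
        n = 1000
        p = np.empty(n)
        p[:150] = np.linspace(20, 80, 150)
        p[150:] = 48.0 + 32.0 * np.exp(-np.arange(n - 150) / 50.0)  # floor at 60%
        rec = PVRecording(p, np.full(n, 50.0), 1000.0)
        beat = Beat(start=0, end=900, i_ed=10, i_es=100, i_dpdt_max=50,
                    i_dpdt_min=155, rr=0.9)
        with pytest.raises(ValueError, match="truncated"):
            tau_half(rec, beat)

    def test_sampling_rate_convergence(self):
        vals = []
        for fs in (1000.0, 2000.0):
            n = int(fs)
            t = np.arange(n) / fs
            i0 = int(0.15 * fs)
            p = np.empty(n)
            p[:i0] = np.linspace(5, 80, i0)
            p[i0:] = 80 * np.exp(-(t[i0:] - t[i0]) / 0.025)
            rec = PVRecording(p, np.full(n, 50.0), fs)
            # dP/dt-min placed past the smoothing half-window of the
            # ramp/decay junction so the smoothed tail is purely exponential
            beat = Beat(start=0, end=int(0.9 * fs), i_ed=10, i_es=int(0.1 * fs),
                        i_dpdt_max=50, i_dpdt_min=i0 + int(0.025 * fs), rr=0.9)
            vals.append(tau_half(rec, beat))
        assert abs(vals[1] - vals[0]) < 0.5

    def test_exponential_fit_recovers_constant(self):
        rec, beat = _decay_recording(tau_s=0.025)
        assert tau_exp(rec, beat) == pytest.approx(25.0, abs=0.1)

    def test_half_over_exp_is_ln2_on_exponentials(self):
        rec, beat = _decay_recording(tau_s=0.030)
        ratio = tau_half(rec, beat) / tau_exp(rec, beat)
        assert ratio == pytest.approx(math.log(2), rel=0.01)

    def test_noise_robustness_within_15pct(self):
        base = None
        for noise in (0.0, 1.0):
            var = VariabilityParams(rr_cv=0.0, preload_sd=0.0,
                                    noise_p_sd=noise, noise_v_sd=2 * noise, seed=4)
            rec, _ = simulate_recording(variability=var, duration=15.0)
            rep = analyze_recording(rec, n_beats=8)
            if base is None:
                base = rep.tau_exp_ms
            else:
                assert rep.tau_exp_ms == pytest.approx(base, rel=0.15)


class TestRegressions:
    def test_prsw_exact_linear_data(self):
        beats = [_mk_indices(edv=e, sw=70.0 * e - 1000.0) for e in
                 (80.0, 90.0, 100.0, 110.0, 120.0)]
        assert prsw(beats) == pytest.approx(70.0)

    def test_prsw_requires_spread(self):
        beats = [_mk_indices(edv=100.0, sw=5000.0)] * 6
        with pytest.raises(ValueError, match="spread"):
            prsw(beats)

    def test_prsw_reproducible_across_seeds(self):
        slopes = []
        for seed in (21, 22, 23):
            var = VariabilityParams(rr_cv=0.03, preload_sd=0.8, noise_p_sd=0.0,
                                    noise_v_sd=0.0, seed=seed)
            rec, _ = simulate_recording(variability=var, duration=25.0)
            slopes.append(analyze_recording(rec).prsw)
        assert all(s > 0 for s in slopes)
        assert np.ptp(slopes) / np.mean(slopes) < 0.3

    def test_espvr_exact_line(self):
        beats = [_mk_indices(esv=s, esp=2.5 * s + 10.0) for s in
                 (30.0, 40.0, 50.0, 60.0, 70.0)]
        slope, ratio = espvr_slope(beats)
        assert slope == pytest.approx(2.5)
        assert ratio == pytest.approx(np.mean([(2.5 * s + 10) / s for s in
                                               (30, 40, 50, 60, 70)]))

    def test_espvr_needs_five_beats(self):
        beats = [_mk_indices(esv=40.0), _mk_indices(esv=60.0)]
        with pytest.raises(ValueError):
            espvr_slope(beats)

    def test_edpvr_exact_line(self):
        beats = [_mk_indices(edv=e, edp=0.15 * e - 2.0) for e in
                 (85.0, 92.0, 100.0, 108.0, 115.0)]
        slope, _ = edpvr_slope(beats)
        assert slope == pytest.approx(0.15)

    def test_espvr_recovers_simulator_emax(self, preload_sim):
        rec, truth = preload_sim
        rep = analyze_recording(rec)
        assert rep.ees == pytest.approx(truth.true_emax, rel=0.2)


class TestWindkesselEa:
    def test_printed_formula_hand_evaluation(self):
        w = WindkesselInputs(r_t=1.2, t_s=0.3, t_d=0.5, tau=0.5)
        expected = 1.2 / (0.3 + 0.5 * (1 - math.exp(-1.0)))
        assert windkessel_ea(w) == pytest.approx(expected)
        assert windkessel_ea(w) == pytest.approx(1.948, abs=5e-4)

    def test_no_diastole_limit(self):
        w = WindkesselInputs(r_t=1.2, t_s=0.3, t_d=1e-12, tau=0.5)
        assert windkessel_ea(w) == pytest.approx(1.2 / 0.3, rel=1e-6)

    def test_zero_tau_limit(self):
        w = WindkesselInputs(r_t=1.2, t_s=0.3, t_d=0.5, tau=0.0)
        assert windkessel_ea(w) == pytest.approx(1.2 / 0.3)

    def test_infinite_tau_limit(self):
        # tau (1 - exp(-t_d/tau)) -> t_d as tau -> inf, so Ea -> R_T/(t_s + t_d)
        w = WindkesselInputs(r_t=1.2, t_s=0.3, t_d=0.5, tau=1e9)
        assert windkessel_ea(w) == pytest.approx(1.2 / 0.8, rel=1e-6)


class TestGlobalReport:
    def test_cardiac_output_formula(self, quiet_sim):
        rec, _ = quiet_sim
        rep = analyze_recording(rec)
        assert rep.co == pytest.approx(rep.hr * rep.sv / 1000.0, rel=1e-12)
        assert rep.ci == pytest.approx(rep.co / rec.meta.bsa, rel=1e-12)
        assert rep.svi == pytest.approx(rep.sv / rec.meta.bsa, rel=1e-12)

    def test_zva_direct_formula(self):
        # SAP 130, mean gradient 25, SVI 24.2 -> 155/24.2
        rec, _ = simulate_recording(
            variability=VariabilityParams.quiet(), duration=10.0
        )
        rec.meta.sap = 130.0
        rec.meta.mean_gradient = 25.0
        rep = analyze_recording(rec, n_beats=5)
        assert rep.zva == pytest.approx(155.0 / rep.svi, rel=1e-12)
        svi = 24.2
        assert (130.0 + 25.0) / svi == pytest.approx(6.405, abs=5e-4)

    def test_vac_orientations_reciprocal(self, preload_sim):
        rec, _ = preload_sim
        rep = analyze_recording(rec)
        assert rep.vac_ea_over_ees == pytest.approx(1.0 / rep.vac_ees_over_ea, rel=1e-9)
        assert rep.vac_ea_over_ees == pytest.approx(rep.ea / rep.ees, rel=1e-9)

    def test_missing_bsa_omits_indexed_values_with_warning(self, quiet_sim):
        rec, _ = quiet_sim
        stripped = PVRecording(rec.pressure, rec.volume, rec.fs, RecordingMeta())
        rep = analyze_recording(stripped)
        assert rep.svi is None and rep.ci is None and rep.zva is None
        assert any("BSA" in w for w in rep.warnings)
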