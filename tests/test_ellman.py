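"""Ellman-assay analysis chain and inhibition-plate simulator."""

import numpy as np
import pytest

from eiipkit.ellman import (
    AssayConditions,
    PlateAssay,
    ProgressCurve,
    SimulationSpec,
    analyze_plate,
    blank_correct,
    fit_ic50,
    inhibited_velocity_mM_per_min,
    initial_rate,
    percent_inhibition,
    simulate_plate,
)
from eiipkit.errors import DataError, NoTransitionError, PlateError


def _curve(times, absorbance, **kw):
    kw.setdefault("well", "A1")
    return ProgressCurve(times_s=np.asarray(times), absorbance=np.asarray(absorbance), **kw)


class TestInitialRate:
    def test_exact_linear_trace(self):
        t = np.arange(0, 301, 15.0)
        a = 0.10 + 0.02 * t / 60.0  # 0.02 AU/min
        assert initial_rate(_curve(t, a)) == pytest.approx(0.0200, abs=1e-12)

    def test_constant_trace_is_zero(self):
        t = np.arange(0, 301, 15.0)
        assert initial_rate(_curve(t, np.full_like(t, 0.3))) == pytest.approx(0.0, abs=1e-12)

    def test_decreasing_trace_warns_negative(self):
        t = np.arange(0, 301, 15.0)
        with pytest.warns(UserWarning, match="decreasing"):
            rate = initial_rate(_curve(t, 0.5 - 0.01 * t / 60.0))
        assert rate == pytest.approx(-0.01, abs=1e-12)

    def test_window_too_small(self):
        t = np.arange(0, 301, 15.0)
        with pytest.raises(PlateError):
            initial_rate(_curve(t, t * 0.0), window_s=20.0)

    def test_recovers_beer_lambert_forward_model(self):
        """Slope of a noiseless simulated control equals epsilon*l*v."""
        cond = AssayConditions()
        spec = SimulationSpec(ic50_uM=300.0, noise_sd_AU=0.0, seed=0, conditions=cond)
        plate = simulate_plate(spec)
        ctrl = next(c for c in plate.curves if c.role == "negative-control")
        v0 = inhibited_velocity_mM_per_min(0.0, spec.true_ki_uM, spec.mode, cond)
        assert initial_rate(ctrl) == pytest.approx(cond.rate_to_AU_per_min(v0), rel=1e-9)


class TestPercentInhibition:
    @pytest.mark.parametrize("test, ctrl, expected", [(1.0, 1.0, 0.0), (0.0, 1.0, 100.0), (0.5, 1.0, 50.0)])
    def test_scale(self, test, ctrl, expected):
        assert percent_inhibition(test, ctrl) == expected

    def test_nonpositive_control_is_assay_failure(self):
        with pytest.raises(DataError):
            percent_inhibition(0.1, 0.0)


class TestFitIC50:
    def test_exact_hyperbolic_data(self):
        c = np.array([10.0, 30.0, 100.0, 300.0, 1000.0])
        inh = 100.0 * c / (c + 100.0)
        res = fit_ic50(c, inh)
        assert res.converged
        assert res.ic50_uM == pytest.approx(100.0, rel=1e-6)
        assert res.hill == pytest.approx(1.0, rel=1e-6)
        assert res.rmse == pytest.approx(0.0, abs=1e-8)

    def test_symmetric_crossing_recovers_midpoint(self):
        c = np.array([1.0, 10.0, 100.0, 1000.0, 10000.0])
        inh = 100.0 / (1.0 + (100.0 / c) ** 0.7)  # 50% exactly at c* = 100
        res = fit_ic50(c, inh)
        assert res.ic50_uM == pytest.approx(100.0, rel=1e-6)

    def test_low_inhibition_everywhere_is_censored(self):
        c = np.array([1.0, 10.0, 100.0, 500.0])
        res = fit_ic50(c, np.array([0.0, 2.0, 10.0, 30.0]))
        assert not res.converged
        assert res.ic50_uM is None
        assert res.censored == "gt:500"

    def test_high_inhibition_everywhere_is_no_transition(self):
        c = np.array([1.0, 10.0, 100.0, 500.0])
        with pytest.raises(NoTransitionError):
            fit_ic50(c, np.array([80.0, 90.0, 95.0, 99.0]))

    def test_needs_four_distinct_concentrations(self):
        with pytest.raises(DataError):
            fit_ic50(np.array([1.0, 10.0, 10.0]), np.array([10.0, 60.0, 62.0]))

    def test_se_scales_with_scatter(self):
        rng = np.random.default_rng(7)
        c = np.array([10.0, 30.0, 100.0, 300.0, 1000.0, 3000.0])
        clean = 100.0 * c / (c + 300.0)
        noisy = clean + rng.normal(0, 3.0, c.size)
        res = fit_ic50(c, noisy)
        assert res.converged and res.ic50_se_uM > 0
        assert res.ic50_uM == pytest.approx(300.0, rel=0.3)


class TestSimulator:
    def test_seed_reproducibility_byte_identical(self, tmp_path):
        spec = SimulationSpec(ic50_uM=300.0, seed=11)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        simulate_plate(spec).write_csv(p1)
        simulate_plate(spec).write_csv(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_noise_free_curves_perfectly_linear(self):
        plate = simulate_plate(SimulationSpec(ic50_uM=300.0, noise_sd_AU=0.0, seed=0))
        for curve in plate.curves:
            resid = np.polyval(np.polyfit(curve.times_s, curve.absorbance, 1), curve.times_s) - curve.absorbance
            assert np.max(np.abs(resid)) < 1e-12

    def test_inhibition_monotone_in_concentration_noise_free(self):
        plate = simulate_plate(SimulationSpec(ic50_uM=150.0, noise_sd_AU=0.0, seed=0))
        ctrl = np.mean([initial_rate(c) for c in plate.curves if c.role == "negative-control"])
        by_conc = {}
        for c in plate.curves:
            if c.role == "test":
                by_conc.setdefault(c.conc_uM, []).append(initial_rate(c))
        concs = sorted(by_conc)
        inh = [percent_inhibition(float(np.mean(by_conc[c])), ctrl) for c in concs]
        assert all(b >= a for a, b in zip(inh, inh[1:]))

    def test_depletion_warning(self):
        cond = AssayConditions(enzyme_U_per_mL=0.05)  # fast enzyme depletes substrate
        with pytest.warns(UserWarning, match="depletion"):
            plate = simulate_plate(SimulationSpec(ic50_uM=300.0, noise_sd_AU=0.0, seed=0, conditions=cond))
        assert plate.warnings

    def test_spec_validation(self):
        with pytest.raises(DataError):
            SimulationSpec()  # neither ic50 nor ki
        with pytest.raises(DataError):
            SimulationSpec(ic50_uM=1.0, ki_uM=1.0)
        with pytest.raises(DataError):
            SimulationSpec(ic50_uM=1.0, mode="uncompetitive")


class TestAnalyzePlate:
    def test_noise_free_recovery_is_exact(self):
        plate = simulate_plate(SimulationSpec(ic50_uM=300.0, noise_sd_AU=0.0, seed=5))
        res = analyze_plate(plate)
        assert res.converged
        assert res.ic50_uM == pytest.approx(300.0, rel=1e-3)

    def test_noisy_recovery_within_fit_se(self):
        plate = simulate_plate(SimulationSpec(ic50_uM=300.0, noise_sd_AU=0.005, seed=12))
        res = analyze_plate(plate)
        assert res.converged
        assert abs(res.ic50_uM - 300.0) <= 3 * res.ic50_se_uM

    def test_row_order_independence(self):
        plate = simulate_plate(SimulationSpec(ic50_uM=200.0, noise_sd_AU=0.003, seed=3))
        frame = plate.to_frame()
        shuffled = frame.sample(frac=1.0, random_state=0)
        r1 = analyze_plate(PlateAssay.from_frame(frame))
        r2 = analyze_plate(PlateAssay.from_frame(shuffled))
        assert r1.ic50_uM == pytest.approx(r2.ic50_uM, rel=1e-12)

    def test_missing_blanks_or_controls_rejected(self):
        plate = simulate_plate(SimulationSpec(ic50_uM=300.0, noise_sd_AU=0.0, seed=0))
        no_blanks = PlateAssay([c for c in plate.curves if c.role != "blank"])
        with pytest.raises(PlateError, match="blank"):
            analyze_plate(no_blanks)
        no_ctrl = PlateAssay([c for c in plate.curves if c.role != "negative-control"])
        with pytest.raises(PlateError, match="control"):
            analyze_plate(no_ctrl)

    def test_inactive_compound_reported_as_censored(self):
        """Test wells behaving like the uninhibited control -> IC50 > c_max."""
        t = np.arange(0, 301, 15.0)
        slope = 0.01 / 60.0  # AU/s
        curves = [_curve(t, np.full_like(t, 0.05), well=f"B{r}", role="blank") for r in range(3)]
        curves += [_curve(t, 0.05 + slope * t, well=f"N{r}", role="negative-control") for r in range(3)]
        for i, conc in enumerate([62.5, 125.0, 250.0, 500.0]):
            curves.append(_curve(t, 0.05 + slope * t, well=f"T{i}", conc_uM=conc, role="test"))
        res = analyze_plate(PlateAssay(curves))
        assert res.ic50_uM is None
        assert res.censored == "gt:500"

    def test_result_json_shape(self):
        plate = simulate_plate(SimulationSpec(ic50_uM=300.0, noise_sd_AU=0.0, seed=0))
        payload = analyze_plate(plate).to_json_dict()
        assert set(payload) == {
            "conc_uM", "inhibition_pct", "ic50_uM", "ic50_se_uM",
            "hill", "rmse", "n_points", "converged", "censored",
        }
        assert payload["n_points"] == 8


class TestBlankCorrection:
    def test_removes_background_trend(self):
        t = np.arange(0, 301, 15.0)
        bg = 0.04 + 2e-5 * t  # chromogen drift
        curves = [
            _curve(t, bg, well="B1", role="blank"),
            _curve(t, bg + (0.012 / 60.0) * t, well="N1", role="negative-control"),
        ]
        corrected = blank_correct(PlateAssay(curves))
        blank, ctrl = corrected.curves
        assert np.max(np.abs(blank.absorbance)) < 1e-12
        assert initial_rate(ctrl) == pytest.approx(0.012, rel=1e-9)

    def test_idempotent_on_noise_free_plate(self):
        plate = simulate_plate(SimulationSpec(ic50_uM=300.0, noise_sd_AU=0.0, seed=0))
        once = blank_correct(plate)
        twice = blank_correct(once)
        for a, b in zip(once.curves, twice.curves):
            assert np.allclose(a.absorbance, b.absorbance, atol=1e-12)


class TestChengPrusoff:
    def test_competitive_ic50_tracks_substrate(self):
        """IC50/Ki = 1 + [S]/Km for competitive inhibition at sigma = 0."""
        for s_mM in (0.2, 0.5, 1.0):
            cond = AssayConditions(substrate_mM=s_mM)
            spec = SimulationSpec(
                ki_uM=100.0, mode="competitive", noise_sd_AU=0.0, seed=0,
                conditions=cond, concentrations_uM=tuple(3000.0 / 2**k for k in range(8)),
            )
            res = analyze_plate(simulate_plate(spec))
            assert res.ic50_uM / 100.0 == pytest.approx(1.0 + s_mM / cond.km_mM, rel=0.01)

    def test_noncompetitive_ic50_equals_ki(self):
        for s_mM in (0.2, 1.0):
            cond = AssayConditions(substrate_mM=s_mM)
            spec = SimulationSpec(ki_uM=100.0, mode="noncompetitive", noise_sd_AU=0.0, seed=0, conditions=cond)
            res = analyze_plate(simulate_plate(spec))
            assert res.ic50_uM == pytest.approx(100.0, rel=0.01)
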