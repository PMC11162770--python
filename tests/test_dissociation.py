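"""Dissociation-kinetics tests: closed form vs ODE oracle, Gillespie
recovery, photobleaching correction, footprint coverage."""

import warnings

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from ssbdyn import simulate
from ssbdyn.dissociation import (
    CoverageModel,
    DissocTrace,
    TwoStateFit,
    correct_photobleaching,
    coverage_fraction,
    estimate_bleach_rate,
    fit_two_state,
    intensity_to_count,
    monomers_to_tetramers,
    two_state_solution,
)
from ssbdyn.errors import (
    AlreadyCorrectedError,
    ControlShapeWarning,
    FitFailureError,
    FloorWarning,
    SaturationWarning,
)


def ode_oracle(t, w0, b0, kw, kb):
    """Independent numerical integration of the two-state ODE system."""
    sol = solve_ivp(
        lambda _, y: [-kw * y[0], kw * y[0] - kb * y[1]],
        (0.0, float(np.max(t))), [w0, b0], t_eval=np.atleast_1d(t),
        method="RK45", rtol=1e-12, atol=1e-12,
    )
    return sol.y.sum(axis=0)


class TestTwoStateSolution:
    def test_initial_condition(self):
        assert two_state_solution(0.0, 300, 150, 0.004, 0.03) == pytest.approx(450)

    def test_degenerate_rates_frozen_value(self):
        # w0=100, b0=0, kw=kb=0.1, t=10 -> w=36.79, b=36.79 (RK4-verified)
        n = two_state_solution(np.array([10.0]), 100, 0, 0.1, 0.1)[0]
        assert n == pytest.approx(73.58, abs=0.01)
        assert n == pytest.approx(ode_oracle(10.0, 100, 0, 0.1, 0.1)[0], rel=1e-8)

    def test_frozen_wrapped_pool(self):
        t = np.linspace(0, 100, 11)
        n = two_state_solution(t, 200, 100, 0.0, 0.05)
        assert np.allclose(n, 200 + 100 * np.exp(-0.05 * t))

    @pytest.mark.parametrize("kw,kb", [
        (0.004, 0.03), (0.03, 0.004), (0.01, 0.01), (0.01, 0.010000001),
        (0.0, 0.02), (0.5, 0.5), (1e-5, 2.0),
    ])
    def test_matches_ode_integration(self, kw, kb):
        t = np.linspace(0, 500, 60)
        ours = two_state_solution(t, 300, 150, kw, kb)
        ref = ode_oracle(t, 300, 150, kw, kb)
        # error relative to the initial pool size (the solver's atol floor
        # dominates once n has decayed to ~1e-10 of n0)
        assert np.max(np.abs(ours - ref)) / 450.0 < 1e-8

    def test_continuity_across_degenerate_diagonal(self):
        t = np.linspace(0, 300, 31)
        at = two_state_solution(t, 100, 50, 0.02, 0.02)
        near = two_state_solution(t, 100, 50, 0.02, 0.02 * (1 + 1e-7))
        assert np.max(np.abs(at - near)) < 1e-4

    def test_non_increasing_and_vanishing(self):
        t = np.linspace(0, 5000, 500)
        n = two_state_solution(t, 300, 150, 0.004, 0.03)
        assert np.all(np.diff(n) <= 1e-12)
        assert n[-1] < 1e-3 * n[0]


class TestIntensityConversion:
    def test_division(self):
        assert intensity_to_count(5000, 10) == pytest.approx(500)
        assert intensity_to_count(0, 10) == 0
        assert intensity_to_count(900, 10, labeling_efficiency=0.9) == pytest.approx(100)

    def test_bad_calibration(self):
        with pytest.raises(ValueError):
            intensity_to_count(100, 0)
        with pytest.raises(ValueError):
            intensity_to_count(100, 10, labeling_efficiency=1.5)

    def test_tetramer_conversion(self):
        assert monomers_to_tetramers(2200) == pytest.approx(550)


class TestFitTwoState:
    def test_noiseless_recovery(self):
        t = np.arange(0, 900, 5.0)
        y = two_state_solution(t, 300, 150, 0.004, 0.03)
        res = fit_two_state(DissocTrace("m", t, y))
        f = res.fit
        for got, want in [(f.w0, 300), (f.b0, 150), (f.k_unwrap, 0.004),
                          (f.k_unbind, 0.03)]:
            assert got == pytest.approx(want, rel=5e-3)
        assert res.aic_two_state < res.aic_single_exp

    @pytest.mark.parametrize("preset", ["WT-like", "R107Q-like"])
    def test_gillespie_ensemble_recovery(self, preset):
        traces, truth = simulate.gen_dissociation_ensemble(
            n_molecules=50, preset=preset, seed=11, k_bleach=0.0)
        counts = np.mean([tr.count for tr in traces], axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_two_state(DissocTrace("mean", traces[0].time_s, counts))
        assert res.fit.k_unwrap == pytest.approx(truth["k_unwrap_per_s"], rel=0.10)
        assert res.fit.k_unbind == pytest.approx(truth["k_unbind_per_s"], rel=0.10)

    def test_non_decaying_refused(self):
        t = np.arange(0, 100, 5.0)
        with pytest.raises(FitFailureError):
            fit_two_state(DissocTrace("m", t, np.full(t.size, 50.0)))

    def test_near_degenerate_flagged(self):
        t = np.arange(0, 600, 5.0)
        y = two_state_solution(t, 200, 100, 0.01, 0.012)
        with pytest.warns(UserWarning):
            res = fit_two_state(DissocTrace("m", t, y))
        assert res.near_degenerate


class TestPhotobleachCorrection:
    def test_subtraction(self):
        fit = TwoStateFit(300, 150, 0.004, 0.0300)
        out = correct_photobleaching(fit, 0.0059)
        assert out.k_unbind == pytest.approx(0.0241)
        assert out.corrected

    def test_zero_bleach_identity(self):
        fit = TwoStateFit(300, 150, 0.004, 0.03)
        out = correct_photobleaching(fit, 0.0)
        assert (out.k_unwrap, out.k_unbind) == (0.004, 0.03)

    def test_floor_with_warning(self):
        fit = TwoStateFit(300, 150, 0.004, 0.03)
        with pytest.warns(FloorWarning):
            out = correct_photobleaching(fit, 0.0059)
        assert out.k_unwrap == 0.0

    def test_no_double_correction(self):
        fit = TwoStateFit(300, 150, 0.01, 0.03)
        out = correct_photobleaching(fit, 0.001)
        with pytest.raises(AlreadyCorrectedError):
            correct_photobleaching(out, 0.001)

    def test_correction_recovers_true_rates_from_bleached_ensemble(self):
        # bleaching simulated at the measured 5.9e-3 /s, then subtracted.
        # Bleaching multiplies each pool by e^(-k_bleach t), so the apparent
        # rates are exactly true + k_bleach; a large ensemble isolates that
        # systematic from sampling noise: residual bias < 5%.
        traces, truth = simulate.gen_dissociation_ensemble(
            n_molecules=400, preset="WT-like", seed=21)
        counts = np.mean([tr.count for tr in traces], axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_two_state(DissocTrace("mean", traces[0].time_s, counts))
        corr = correct_photobleaching(res.fit, truth["k_bleach_per_s"])
        assert corr.k_unwrap == pytest.approx(truth["k_unwrap_per_s"], rel=0.05)
        assert corr.k_unbind == pytest.approx(truth["k_unbind_per_s"], rel=0.05)


class TestBleachRateEstimation:
    def test_recovers_generated_rate(self):
        t = np.arange(0, 900, 5.0)
        y = 450 * np.exp(-5.9e-3 * t)
        assert estimate_bleach_rate(DissocTrace("c", t, y)) == pytest.approx(
            5.9e-3, rel=0.02)

    def test_constant_trace_zero(self):
        t = np.arange(0, 100, 5.0)
        assert estimate_bleach_rate(DissocTrace("c", t, np.full(t.size, 450.0))) == 0.0

    def test_rising_trace_rejected(self):
        t = np.arange(0, 100, 5.0)
        with pytest.raises(ValueError):
            estimate_bleach_rate(DissocTrace("c", t, 10 + t))

    def test_two_regime_trace_warns(self):
        t = np.arange(0, 900, 5.0)
        y = 300 * np.exp(-0.002 * t) + 150 * np.exp(-0.08 * t)
        with pytest.warns(ControlShapeWarning):
            estimate_bleach_rate(DissocTrace("c", t, y))


class TestCoverage:
    def test_wt_printed_tetramer_counts(self):
        # 25 binding-mode + 70 wrapping-mode tetramers on 48,502 nt -> ~10%
        model = CoverageModel.from_tetramers(25, 70)
        assert 100 * coverage_fraction(model) == pytest.approx(10.2, abs=0.1)

    def test_r107q_monomer_split(self):
        # 2200 monomers, 50/50 modes -> ~50%
        model = CoverageModel(2200, 0.5)
        assert 100 * coverage_fraction(model) == pytest.approx(51.0, abs=0.1)

    def test_zero_monomers(self):
        assert coverage_fraction(CoverageModel(0, 0.5)) == 0.0

    def test_linear_below_saturation(self):
        c1 = coverage_fraction(CoverageModel(400, 0.3))
        c2 = coverage_fraction(CoverageModel(800, 0.3))
        assert c2 == pytest.approx(2 * c1, rel=1e-12)

    def test_saturation_capped(self):
        with pytest.warns(SaturationWarning):
            assert coverage_fraction(CoverageModel(8000, 0.0)) == 1.0


class TestGillespieGenerator:
    def test_all_rates_zero_constant(self):
        tr, _ = simulate.gen_dissociation_gillespie(
            n_tetramers=30, k_unwrap=0.0, k_unbind=0.0, k_bleach=0.0, seed=0)
        assert np.all(tr.count == 120)

    def test_bleach_only_decays_at_bleach_rate(self):
        tr, truth = simulate.gen_dissociation_gillespie(
            n_tetramers=400, frac_wrapped=1.0, k_unwrap=0.0, k_unbind=0.03,
            k_bleach=5.9e-3, T_total_s=600.0, seed=1)
        # wrapped pool never leaves, so all loss is bleaching
        k = estimate_bleach_rate(tr)
        assert k == pytest.approx(5.9e-3, rel=0.1)

    def test_ensemble_mean_matches_ode_at_1000(self):
        traces, truth = simulate.gen_dissociation_ensemble(
            n_molecules=1000, preset="WT-like", seed=33, k_bleach=0.0,
            n_tetramers=25, T_total_s=600.0)
        arr = np.vstack([tr.count for tr in traces])
        mean = arr.mean(axis=0)
        se = arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])
        t = traces[0].time_s
        expected = two_state_solution(
            t, truth["w0_monomers"], truth["b0_monomers"],
            truth["k_unwrap_per_s"], truth["k_unbind_per_s"])
        # checkpoints thin the grid so the 3-SE band is a fair simultaneous test
        idx = np.arange(0, t.size, 10)
        assert np.all(np.abs(mean[idx] - expected[idx]) <= 3 * se[idx] + 0.05)

    def test_convergence_rate_with_ensemble_size(self):
        def rmse(n, seed):
            traces, truth = simulate.gen_dissociation_ensemble(
                n_molecules=n, preset="WT-like", seed=seed, k_bleach=0.0,
                n_tetramers=25, T_total_s=300.0)
            arr = np.vstack([tr.count for tr in traces])
            t = traces[0].time_s
            expected = two_state_solution(
                t, truth["w0_monomers"], truth["b0_monomers"],
                truth["k_unwrap_per_s"], truth["k_unbind_per_s"])
            return np.sqrt(np.mean((arr.mean(axis=0) - expected) ** 2))

        # ~1/sqrt(n): a 10x ensemble should cut the error at least ~2x
        assert rmse(1000, 7) < rmse(100, 8) / 2.0
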