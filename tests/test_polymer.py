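"""Polymer-mechanics tests: eFJC evaluation, fitting, energy integration."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ssbdyn import simulate
from ssbdyn.errors import EmptyOverlapError, InsufficientDataError, RampMismatchWarning
from ssbdyn.polymer import (
    EFJCParams,
    ForceExtensionCurve,
    curve_energy,
    ddE,
    efjc_extension,
    fit_efjc,
    hysteresis_energy,
    kBT_to_pNnm,
    pNnm_to_kBT,
    theoretical_contour_length,
)

BARE = EFJCParams(Lc_um=4.8, Lp_nm=1.9)
WT = EFJCParams(Lc_um=1.3, Lp_nm=9.3)


def efjc_oracle(F, Lc, Lp, S, kBT):
    """Independent per-point evaluation with python math functions."""
    x = 2.0 * F * Lp / kBT
    coth = math.cosh(x) / math.sinh(x)
    return Lc * (coth - 1.0 / x) * (1.0 + F / S)


class TestEFJCExtension:
    def test_matches_independent_evaluation(self):
        forces = np.geomspace(0.05, 50.0, 200)
        L = efjc_extension(forces, BARE)
        oracle = np.array([efjc_oracle(f, 4.8, 1.9, 800.0, 4.11) for f in forces])
        assert np.max(np.abs(L - oracle) / oracle) < 1e-10

    def test_worked_value_10pN(self):
        # x = 9.245, bracket = 0.8918, enthalpy factor 1.0125 -> ~4.33 um
        assert efjc_extension(10.0, BARE) == pytest.approx(4.334, abs=5e-3)

    def test_small_force_limit(self):
        # bracket ~ x/3 as F -> 0, so extension -> 0
        tiny = efjc_extension(1e-9, BARE)
        x = 2 * 1e-9 * 1.9 / 4.11
        assert tiny == pytest.approx(4.8 * x / 3, rel=1e-6)

    def test_rigid_backbone_saturation(self):
        stiff = EFJCParams(Lc_um=4.8, Lp_nm=1.9, S_pN=1e12)
        assert efjc_extension(1e4, stiff) == pytest.approx(4.8, rel=1e-3)

    def test_domain_error_at_zero_force(self):
        with pytest.raises(ValueError):
            efjc_extension(0.0, BARE)
        with pytest.raises(ValueError):
            efjc_extension(-1.0, BARE)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        f=st.floats(0.01, 40.0),
        scale=st.floats(1.01, 3.0),
    )
    def test_monotone_in_force_and_lc_decreasing_in_stiffness(self, f, scale):
        base = efjc_extension(f, BARE)
        assert efjc_extension(f * scale, BARE) > base  # increasing in F
        longer = EFJCParams(Lc_um=4.8 * scale, Lp_nm=1.9)
        assert efjc_extension(f, longer) > base  # increasing in Lc
        floppier = EFJCParams(Lc_um=4.8, Lp_nm=1.9 / scale)
        assert efjc_extension(f, floppier) < base  # decreasing Lp decreases L


class TestFitEFJC:
    def test_noiseless_self_consistency(self):
        _, ret, _ = simulate.gen_efjc_curve(BARE)
        fit = fit_efjc(ret, (0.1, 15.0))
        assert fit.params.Lc_um == pytest.approx(4.8, rel=1e-3)
        assert fit.params.Lp_nm == pytest.approx(1.9, rel=1e-3)
        assert fit.residual_norm_um < 1e-8
        assert not fit.window_clipped

    def test_noisy_recovery_coated_regime(self):
        # WT-coated regime, 2% multiplicative noise, window 0.1-2 pN
        errs_lc, errs_lp = [], []
        for seed in range(20):
            _, ret, _ = simulate.gen_efjc_curve(
                WT, F_grid=np.linspace(0.1, 2.0, 200), noise_frac=0.02, seed=seed
            )
            fit = fit_efjc(ret, (0.1, 2.0))
            errs_lc.append(abs(fit.params.Lc_um / 1.3 - 1))
            errs_lp.append(abs(fit.params.Lp_nm / 9.3 - 1))
        assert np.median(errs_lc) < 0.05
        assert np.median(errs_lp) < 0.05

    def test_window_clipping_reported(self):
        _, ret, _ = simulate.gen_efjc_curve(BARE, F_grid=np.linspace(0.5, 15.0, 100))
        fit = fit_efjc(ret, (0.1, 2.0))
        assert fit.window_clipped
        assert fit.window_effective_pN[0] == pytest.approx(0.5)
        assert fit.window_effective_pN[1] == pytest.approx(2.0)

    def test_insufficient_in_window_samples(self):
        _, ret, _ = simulate.gen_efjc_curve(BARE, F_grid=np.linspace(5.0, 15.0, 50))
        with pytest.raises(InsufficientDataError):
            fit_efjc(ret, (0.1, 2.0))


class TestCurveEnergy:
    def _flat(self, force, n=100, d0=0.0, d1=1.0, **kw):
        return ForceExtensionCurve(np.linspace(d0, d1, n), np.full(n, force), **kw)

    def test_identity_zero(self):
        a = self._flat(2.0)
        assert curve_energy(a, a).delta_E_pNnm == 0.0

    def test_rectangle_area(self):
        e = curve_energy(self._flat(2.0), self._flat(1.0))
        assert e.delta_E_pNnm == pytest.approx(1000.0)
        assert e.delta_E_kBT == pytest.approx(1000.0 / 4.11, rel=1e-6)
        assert e.delta_E_kBT == pytest.approx(244, abs=2)

    def test_antisymmetry(self):
        _, bare_ret, _ = simulate.gen_efjc_curve(BARE)
        _, wt_ret, _ = simulate.gen_efjc_curve(WT)
        ab = curve_energy(wt_ret, bare_ret).delta_E_pNnm
        ba = curve_energy(bare_ret, wt_ret).delta_E_pNnm
        assert ab == pytest.approx(-ba, rel=1e-12)

    def test_coated_above_bare(self):
        # shorter/stiffer (coated) chain sits at higher force for a given
        # distance, so the area (coated minus bare) is positive
        _, bare_ret, _ = simulate.gen_efjc_curve(BARE)
        _, wt_ret, _ = simulate.gen_efjc_curve(WT)
        assert curve_energy(wt_ret, bare_ret).delta_E_pNnm > 0

    def test_additive_over_adjacent_intervals(self):
        grid = np.linspace(0.1, 15.0, 400)
        _, a, _ = simulate.gen_efjc_curve(WT, F_grid=grid)
        _, b, _ = simulate.gen_efjc_curve(BARE, F_grid=grid)
        full = curve_energy(a, b)
        lo, hi = full.integration_range_um
        mid = (lo + hi) / 2

        def clip(c, d0, d1):
            d, f = c.sorted_by_distance()
            # keep endpoints exact by interpolating at the cut
            dd = np.unique(np.concatenate([d[(d >= d0) & (d <= d1)], [d0, d1]]))
            return ForceExtensionCurve(dd, np.interp(dd, d, f), phase=c.phase)

        left = curve_energy(clip(a, lo, mid), clip(b, lo, mid)).delta_E_pNnm
        right = curve_energy(clip(a, mid, hi), clip(b, mid, hi)).delta_E_pNnm
        assert left + right == pytest.approx(full.delta_E_pNnm, rel=1e-9)

    def test_trapezoid_matches_quadrature(self):
        from scipy.integrate import quad

        grid = np.linspace(0.1, 15.0, 250)
        _, a, _ = simulate.gen_efjc_curve(WT, F_grid=grid)
        _, b, _ = simulate.gen_efjc_curve(BARE, F_grid=grid)
        e = curve_energy(a, b)
        da, fa = a.sorted_by_distance()
        db, fb = b.sorted_by_distance()
        lo, hi = e.integration_range_um
        val, _ = quad(
            lambda d: np.interp(d, da, fa) - np.interp(d, db, fb), lo, hi, limit=500
        )
        assert e.delta_E_pNnm == pytest.approx(val * 1000, rel=5e-3)

    def test_empty_overlap(self):
        a = self._flat(1.0, d0=0.0, d1=1.0)
        b = self._flat(1.0, d0=2.0, d1=3.0)
        with pytest.raises(EmptyOverlapError):
            curve_energy(a, b)


class TestHysteresis:
    def test_identical_phases_zero(self):
        ext, ret, _ = simulate.gen_efjc_curve(WT)
        assert hysteresis_energy(ext, ret).delta_E_pNnm == pytest.approx(0.0, abs=1e-9)

    def test_unbinding_creates_positive_hysteresis(self):
        ext, ret, _ = simulate.gen_efjc_curve(
            WT, unbind_fraction=0.3, bare_params=BARE
        )
        assert hysteresis_energy(ext, ret).delta_E_pNnm > 0

    def test_ddE_zero_for_identical_ramps(self):
        ext, ret, _ = simulate.gen_efjc_curve(WT, unbind_fraction=0.3, bare_params=BARE)
        e = hysteresis_energy(ext, ret)
        d = ddE(e, e)
        assert d.delta_E_pNnm == 0.0

    def test_ddE_positive_when_second_ramp_loses_less_protein(self):
        # fewer proteins remain at R2, so 30% less unbinds during the ramp
        # and the dissipated area shrinks: ddE = dE(R1) - dE(R2) > 0
        e1 = hysteresis_energy(*simulate.gen_efjc_curve(
            WT, unbind_fraction=0.3, bare_params=BARE, ramp_id="R1")[:2])
        e2 = hysteresis_energy(*simulate.gen_efjc_curve(
            WT, unbind_fraction=0.3 * 0.7, bare_params=BARE, ramp_id="R2")[:2])
        d = ddE(e1, e2)
        assert d.delta_E_pNnm > 0
        assert d.delta_E_pNnm == pytest.approx(
            e1.delta_E_pNnm - e2.delta_E_pNnm, rel=1e-12)

    def test_mismatched_ramp_labels_warn(self):
        ext, _, _ = simulate.gen_efjc_curve(WT, ramp_id="R1")
        _, ret, _ = simulate.gen_efjc_curve(WT, ramp_id="R2")
        with pytest.warns(RampMismatchWarning):
            hysteresis_energy(ext, ret)


class TestUnitsAndArithmetic:
    def test_kbt_at_25C(self):
        # 4.1 pN nm is ~1 kBT at 25 C
        assert float(pNnm_to_kBT(4.1, 25.0)) == pytest.approx(1.0, abs=0.01)
        assert float(pNnm_to_kBT(0.0)) == 0.0
        assert float(pNnm_to_kBT(41.0, 25.0)) == pytest.approx(10.0, abs=0.05)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(e=st.floats(-1e4, 1e4), t=st.floats(0.0, 100.0))
    def test_linear_and_roundtrip(self, e, t):
        assert float(pNnm_to_kBT(2 * e, t)) == pytest.approx(
            2 * float(pNnm_to_kBT(e, t)), rel=1e-12, abs=1e-12)
        assert float(kBT_to_pNnm(pNnm_to_kBT(e, t), t)) == pytest.approx(
            e, rel=1e-12, abs=1e-12)

    def test_temperature_range(self):
        with pytest.raises(ValueError):
            pNnm_to_kBT(1.0, -10.0)

    def test_theoretical_contour_length(self):
        assert theoretical_contour_length(48502) == pytest.approx(16.0, abs=0.05)
        assert theoretical_contour_length(1) == pytest.approx(0.33e-3)
        assert theoretical_contour_length(9000) == pytest.approx(2.97)
        with pytest.raises(ValueError):
            theoretical_contour_length(0)
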