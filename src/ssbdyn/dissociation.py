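"""Two-state dissociation kinetics of SSB from ssDNA, and footprint coverage.

The number of labelled SSB monomers on a tethered ssDNA, followed over time
after a salt jump, decays in two regimes: a fast loss followed by a slow
one. This is captured by a two-state scheme

    W (wrapped) --k_w--> B (bound) --k_b--> free

where dissociation happens only from the low-affinity bound state:

    dw/dt = -k_w w
    db/dt =  k_w w - k_b b

with closed-form solution

    w(t) = w0 e^(-k_w t)
    b(t) = b0 e^(-k_b t) + w0 k_w/(k_b - k_w) (e^(-k_w t) - e^(-k_b t))

(and b(t) = (b0 + w0 k t) e^(-k t) in the degenerate k_w = k_b limit). The
observed count n(t) = w(t) + b(t) also loses fluorophores to photobleaching,
which multiplies each pool by e^(-k_bleach t); the fitted rates are
corrected by subtracting k_bleach.

Footprint arithmetic: a tetramer occludes ~30 nt in the binding mode and
~60 nt in the wrapping mode, so the fitted pool sizes translate directly
into the fraction of the template covered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares, curve_fit

from .errors import (
    AlreadyCorrectedError,
    ControlShapeWarning,
    FitFailureError,
    FloorWarning,
    IdentifiabilityWarning,
    InsufficientDataError,
    SaturationWarning,
)

#: Photobleaching rate of the label under the intermittent 5-s imaging
#: protocol, s^-1 (measured on no-dissociation controls).
K_BLEACH_DEFAULT = 5.9e-3

#: Nucleotides occluded per tetramer in each binding mode.
FOOTPRINT_BINDING_NT = 30.0
FOOTPRINT_WRAPPING_NT = 60.0

#: Length of the ssDNA template derived from lambda-phage DNA, nt.
LAMBDA_SSDNA_NT = 48502


@dataclass
class DissocTrace:
    """Molecule-count time series for one ssDNA during salt-induced
    dissociation (counts are real-valued, intensity-derived monomers)."""

    molecule_id: str
    time_s: np.ndarray
    count: np.ndarray
    salt_mM: float | None = None
    protein: str | None = None

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.count = np.asarray(self.count, dtype=float)
        if self.time_s.shape != self.count.shape:
            raise ValueError("time and count series must have equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.count < 0):
            raise ValueError("counts must be >= 0")


@dataclass
class TwoStateFit:
    """Fitted parameters of the W->B->free scheme."""

    w0: float
    b0: float
    k_unwrap: float
    k_unbind: float
    k_bleach: float = 0.0
    corrected: bool = False

    def to_dict(self) -> dict:
        return {
            "w0": self.w0, "b0": self.b0,
            "k_unwrap_per_s": self.k_unwrap, "k_unbind_per_s": self.k_unbind,
            "k_bleach_per_s": self.k_bleach, "corrected": self.corrected,
        }


@dataclass
class TwoStateFitResult:
    """TwoStateFit plus fit diagnostics and model comparison."""

    fit: TwoStateFit
    stderr: dict[str, float]
    residual_norm: float
    aic_two_state: float
    aic_single_exp: float
    single_exp_rate: float
    near_degenerate: bool


@dataclass
class CoverageModel:
    """Monomer counts and mode fractions mapped to template coverage."""

    n_monomers: float
    frac_binding_mode: float
    footprint_binding_nt: float = FOOTPRINT_BINDING_NT
    footprint_wrapping_nt: float = FOOTPRINT_WRAPPING_NT
    template_nt: float = LAMBDA_SSDNA_NT

    def __post_init__(self):
        if not 0.0 <= self.frac_binding_mode <= 1.0:
            raise ValueError("frac_binding_mode must lie in [0, 1]")
        if not self.template_nt > 0:
            raise ValueError("template_nt must be > 0")
        if self.n_monomers < 0:
            raise ValueError("n_monomers must be >= 0")

    @classmethod
    def from_tetramers(
        cls,
        n_binding_tetramers: float,
        n_wrapping_tetramers: float,
        template_nt: float = LAMBDA_SSDNA_NT,
        footprint_binding_nt: float = FOOTPRINT_BINDING_NT,
        footprint_wrapping_nt: float = FOOTPRINT_WRAPPING_NT,
    ) -> "CoverageModel":
        total = n_binding_tetramers + n_wrapping_tetramers
        frac = n_binding_tetramers / total if total else 0.0
        return cls(
            n_monomers=4.0 * total,
            frac_binding_mode=frac,
            footprint_binding_nt=footprint_binding_nt,
            footprint_wrapping_nt=footprint_wrapping_nt,
            template_nt=template_nt,
        )


def intensity_to_count(
    I_total: float, I_single_fluorophore: float, labeling_efficiency: float = 1.0
) -> float:
    """Convert integrated fluorescence to a (real-valued) monomer count."""
    if not I_single_fluorophore > 0:
        raise ValueError("single-fluorophore intensity must be > 0")
    if not 0.0 < labeling_efficiency <= 1.0:
        raise ValueError("labeling efficiency must lie in (0, 1]")
    return np.asarray(I_total, dtype=float) / I_single_fluorophore / labeling_efficiency


def monomers_to_tetramers(n_monomers: float) -> float:
    """SSB is a homotetramer: four monomers per bound unit."""
    return np.asarray(n_monomers, dtype=float) / 4.0


def two_state_solution(t, w0: float, b0: float, k_unwrap: float, k_unbind: float):
    """Total count n(t) = w(t) + b(t) of the W->B->free scheme (closed form).

    Continuous across the degenerate k_unwrap = k_unbind limit, where the
    transfer term becomes w0 * k * t * e^(-k t).
    """
    if k_unwrap < 0 or k_unbind < 0:
        raise ValueError("rates must be >= 0")
    t = np.asarray(t, dtype=float)
    kw, kb = k_unwrap, k_unbind
    w = w0 * np.exp(-kw * t)
    scale = max(kw, kb, 1e-300)
    if abs(kb - kw) < 1e-9 * scale:
        b = (b0 + w0 * kw * t) * np.exp(-kw * t)
    else:
        b = b0 * np.exp(-kb * t) + w0 * kw / (kb - kw) * (np.exp(-kw * t) - np.exp(-kb * t))
    return w + b


def _single_exp(t, a, k):
    return a * np.exp(-k * t)


def _aic(n, ssr, p):
    return n * np.log(max(ssr, 1e-300) / n) + 2 * p


def fit_two_state(
    trace: DissocTrace,
    poisson_weights: bool = False,
) -> TwoStateFitResult:
    """Fit (w0, b0, k_unwrap, k_unbind) to a decaying count trace.

    Unweighted least squares on counts against the closed form (Poisson
    1/sqrt(n) weighting optional). Multi-start over rate guesses derived
    from the fast and slow decay segments. Reports a single-exponential
    comparison fit (AIC) and flags near-degenerate rate pairs
    (k_unwrap/k_unbind in [0.5, 2]) where the two pools are weakly
    identifiable.
    """
    t = trace.time_s - trace.time_s[0]
    y = trace.count
    n = t.size
    if n < 10:
        raise InsufficientDataError("need >= 10 points for a two-state fit")
    n_dec = max(1, n // 10)
    if not np.mean(y[-n_dec:]) < np.mean(y[:n_dec]):
        raise FitFailureError("trace does not decay; two-state fit refused")

    w = 1.0 / np.sqrt(np.clip(y, 1.0, None)) if poisson_weights else np.ones(n)
    n0 = float(np.mean(y[:n_dec]))

    # rate scales from the head and tail of the log-trace
    def seg_rate(sl):
        yy = np.clip(y[sl], 1e-9, None)
        tt = t[sl]
        if tt.size < 2 or tt[-1] == tt[0]:
            return 1.0 / max(t[-1], 1.0)
        slope = np.polyfit(tt, np.log(yy), 1)[0]
        return max(-slope, 1e-6)
    k_fast = seg_rate(slice(0, max(3, n // 4)))
    k_slow = seg_rate(slice(3 * n // 4, n))

    def resid(x):
        w0, b0, kw, kb = x
        return (two_state_solution(t, w0, b0, kw, kb) - y) * w

    starts = [
        (2 * n0 / 3, n0 / 3, k_slow, k_fast),
        (n0 / 2, n0 / 2, k_slow, k_fast),
        (n0 / 3, 2 * n0 / 3, k_fast, k_slow),
        (2 * n0 / 3, n0 / 3, k_fast / 10, k_fast),
    ]
    best = None
    for x0 in starts:
        sol = least_squares(
            resid, np.clip(x0, 1e-9, None),
            bounds=([0, 0, 0, 0], [np.inf] * 4),
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise FitFailureError("two-state fit did not converge from any start")

    w0, b0, kw, kb = best.x
    ssr = float(2 * best.cost)
    dof = max(n - 4, 1)
    try:
        cov = (ssr / dof) * np.linalg.inv(best.jac.T @ best.jac)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(4, np.nan)

    # single-exponential comparison
    try:
        popt, _ = curve_fit(_single_exp, t, y, p0=[n0, k_fast], maxfev=10000)
        ssr1 = float(np.sum((_single_exp(t, *popt) - y) ** 2))
        k1 = float(popt[1])
    except RuntimeError:
        ssr1, k1 = np.inf, np.nan

    near_deg = kb > 0 and 0.5 <= kw / kb <= 2.0
    if near_deg:
        warnings.warn(
            f"unwrap/unbind rates nearly degenerate (ratio {kw / kb:.2f}); "
            "pool assignment weakly identified",
            IdentifiabilityWarning,
            stacklevel=2,
        )
    return TwoStateFitResult(
        fit=TwoStateFit(float(w0), float(b0), float(kw), float(kb)),
        stderr=dict(zip(("w0", "b0", "k_unwrap", "k_unbind"), se.tolist())),
        residual_norm=float(np.sqrt(ssr)),
        aic_two_state=_aic(n, ssr, 4),
        aic_single_exp=_aic(n, ssr1, 2),
        single_exp_rate=k1,
        near_degenerate=bool(near_deg),
    )


def correct_photobleaching(fit: TwoStateFit, k_bleach: float = K_BLEACH_DEFAULT) -> TwoStateFit:
    """Subtract the photobleaching rate from both fitted rates.

    Bleaching multiplies the observed intensity of either pool by
    e^(-k_bleach t), so each apparent rate is the true rate plus k_bleach.
    Rates are floored at 0 (with a warning); re-correcting raises.
    """
    if k_bleach < 0:
        raise ValueError("k_bleach must be >= 0")
    if fit.corrected:
        raise AlreadyCorrectedError("fit already photobleach-corrected")
    kw = fit.k_unwrap - k_bleach
    kb = fit.k_unbind - k_bleach
    if kw < 0 or kb < 0:
        warnings.warn(
            "corrected rate fell below 0 and was floored", FloorWarning, stacklevel=2
        )
    return replace(
        fit,
        k_unwrap=max(kw, 0.0),
        k_unbind=max(kb, 0.0),
        k_bleach=k_bleach,
        corrected=True,
    )


def estimate_bleach_rate(control_trace: DissocTrace) -> float:
    """Photobleaching rate from a no-dissociation control (10 mM salt).

    Fits a single exponential to the control count trace. Rejects rising
    traces; warns when the trace is visibly not single-exponential (rates
    fitted on the two halves differ more than 3-fold), as expected when a
    dissociating trace is passed by mistake.
    """
    t = control_trace.time_s - control_trace.time_s[0]
    y = control_trace.count
    if y.size < 4:
        raise InsufficientDataError("control trace too short")
    n_dec = max(1, y.size // 10)
    head, tail = np.mean(y[:n_dec]), np.mean(y[-n_dec:])
    if tail > head * (1 + 1e-9):
        raise ValueError("control trace rises; not a bleaching control")
    if np.allclose(y, y[0]):
        return 0.0
    popt, _ = curve_fit(_single_exp, t, y, p0=[float(head), 1e-3], maxfev=10000)
    k = float(max(popt[1], 0.0))

    # a fast second phase dies early: compare the endpoint rate over the
    # first decile with the fitted tail rate
    decile = max(y.size // 10, 3)
    rates = []
    if y[0] > 0 and y[decile - 1] > 0 and t[decile - 1] > t[0]:
        rates.append(max(np.log(y[0] / y[decile - 1]) / (t[decile - 1] - t[0]), 1e-12))
    yy, tt = y[y.size // 2:], t[y.size // 2:]
    if np.all(yy > 0) and tt.size > 2:
        rates.append(max(-np.polyfit(tt, np.log(yy), 1)[0], 1e-12))
    if len(rates) == 2 and max(rates) / min(rates) > 3.0:
        warnings.warn(
            "control decays with two regimes; a bleaching control should be "
            "single-exponential",
            ControlShapeWarning,
            stacklevel=2,
        )
    return k


def coverage_fraction(model: CoverageModel) -> float:
    """Fraction of the template occluded by bound tetramers.

    coverage = (tet_binding * 30 + tet_wrapping * 60) / template_nt with
    tet_mode = n_monomers * frac_mode / 4. Linear in n_monomers below
    saturation; capped at 1 with a warning above.
    """
    tet_b = model.n_monomers * model.frac_binding_mode / 4.0
    tet_w = model.n_monomers * (1.0 - model.frac_binding_mode) / 4.0
    cov = (tet_b * model.footprint_binding_nt + tet_w * model.footprint_wrapping_nt) / model.template_nt
    if cov > 1.0:
        warnings.warn(
            f"coverage {cov:.3f} exceeds 1; capped (over-saturation)",
            SaturationWarning,
            stacklevel=2,
        )
        cov = 1.0
    return float(cov)
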