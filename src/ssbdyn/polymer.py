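"""Polymer mechanics of ssDNA under force: the extensible freely jointed chain.

Force spectroscopy (AFS) stretches a surface-tethered ssDNA molecule with a
calibrated force ramp while tracking the bead-surface distance.  The
force-extension response of ssDNA (and of SSB-coated ssDNA, which stays
flexible between bound tetramers) is described by the extensible freely
jointed chain (eFJC):

    L(F) = Lc * [coth(x) - 1/x] * (1 + F/S),   x = 2 F Lp / kBT

with contour length Lc (um), persistence length Lp (nm), stretch modulus S
(pN, fixed at 800 pN for ssDNA) and thermal energy kBT (4.11 pN nm at 25 C).
Protein binding compacts and stiffens the chain, which shows up as a smaller
apparent Lc and a larger apparent Lp.  Areas between force-distance curves
measure the mechanical work stored by protein binding (Delta-E) and, between
successive ramps, its force-induced loss (Delta-Delta-E).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import medfilt

from .errors import (
    EmptyOverlapError,
    FitFailureError,
    InsufficientDataError,
    MonotonicityWarning,
    RampMismatchWarning,
)

#: Boltzmann constant in pN nm / K.
KB_PN_NM = 1.380649e-2

#: Thermal energy at 25 C in pN nm.
KBT_25C = 4.11

#: Stretch modulus of ssDNA in pN.
S_SSDNA = 800.0

#: Helical rise per nucleotide of ssDNA at full extension, nm.
RISE_PER_NT_NM = 0.33


@dataclass(frozen=True)
class EFJCParams:
    """eFJC parameters. Lengths mix units on purpose: Lc in um (the scale of
    whole-molecule extension), Lp in nm (the scale of chain flexibility)."""

    Lc_um: float
    Lp_nm: float
    S_pN: float = S_SSDNA
    kBT_pNnm: float = KBT_25C

    def __post_init__(self):
        for name in ("Lc_um", "Lp_nm", "S_pN", "kBT_pNnm"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")


@dataclass
class ForceExtensionCurve:
    """One phase of one AFS force ramp."""

    distance_um: np.ndarray
    force_pN: np.ndarray
    phase: str = "extension"  # "extension" | "retraction"
    ramp_id: str = "R1"
    condition: str = "bare"

    def __post_init__(self):
        self.distance_um = np.asarray(self.distance_um, dtype=float)
        self.force_pN = np.asarray(self.force_pN, dtype=float)
        if self.distance_um.shape != self.force_pN.shape:
            raise ValueError("distance and force series must have equal length")
        if self.distance_um.size < 2:
            raise ValueError("a curve needs at least 2 samples")
        if np.any(self.force_pN < 0):
            raise ValueError("forces must be >= 0")
        if self.phase not in ("extension", "retraction"):
            raise ValueError(f"unknown phase {self.phase!r}")
        self._check_monotonicity()

    def _check_monotonicity(self):
        # Noise-tolerant check: monotonicity judged on a 5-sample median filter.
        f = self.force_pN
        if f.size >= 5:
            f = medfilt(f, kernel_size=5)
        d = np.diff(f)
        ok = np.all(d >= -1e-9) if self.phase == "extension" else np.all(d <= 1e-9)
        if not ok:
            warnings.warn(
                f"force not monotone for phase {self.phase!r} (median-filtered)",
                MonotonicityWarning,
                stacklevel=3,
            )

    def sorted_by_distance(self) -> tuple[np.ndarray, np.ndarray]:
        order = np.argsort(self.distance_um)
        return self.distance_um[order], self.force_pN[order]


@dataclass
class EnergyResult:
    """Energy difference between two force-distance curves."""

    delta_E_pNnm: float
    delta_E_kBT: float
    integration_range_um: tuple[float, float]


@dataclass
class EFJCFit:
    """Result of an eFJC least-squares fit (residuals in distance)."""

    params: EFJCParams
    stderr: dict[str, float]
    residual_norm_um: float
    n_points: int
    window_requested_pN: tuple[float, float]
    window_effective_pN: tuple[float, float]
    window_clipped: bool
    free_names: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "Lc_um": self.params.Lc_um,
            "Lp_nm": self.params.Lp_nm,
            "S_pN": self.params.S_pN,
            "kBT_pNnm": self.params.kBT_pNnm,
            "stderr": self.stderr,
            "residual_norm_um": self.residual_norm_um,
            "n_points": self.n_points,
            "window_requested_pN": list(self.window_requested_pN),
            "window_effective_pN": list(self.window_effective_pN),
            "window_clipped": self.window_clipped,
            "free_parameters": list(self.free_names),
        }


def efjc_extension(F, params: EFJCParams):
    """Extension L(F) of the eFJC at force F (pN; scalar or array), in um.

    Strictly increasing in F; L -> Lc (1 + F/S) at high force. F <= 0 is a
    domain error (the Langevin bracket is undefined at 0; its limit is 0).
    """
    F = np.asarray(F, dtype=float)
    if np.any(F <= 0):
        raise ValueError("efjc_extension requires F > 0 (the F->0 limit is L=0)")
    x = 2.0 * F * params.Lp_nm / params.kBT_pNnm
    # coth(x) - 1/x, numerically stable near 0 via the series x/3 - x^3/45.
    small = x < 1e-4
    with np.errstate(over="ignore"):
        bracket = np.where(small, x / 3.0 - x**3 / 45.0, 1.0 / np.tanh(np.where(small, 1.0, x)) - 1.0 / np.where(small, 1.0, x))
    L = params.Lc_um * bracket * (1.0 + F / params.S_pN)
    return L if L.shape else float(L)


def fit_efjc(
    curve: ForceExtensionCurve,
    force_window: tuple[float, float] = (0.1, 15.0),
    fixed: dict | None = None,
    p0: dict | None = None,
) -> EFJCFit:
    """Fit the eFJC to a force-distance curve inside a force window.

    Residuals are in distance (L predicted from F): force is the controlled
    variable in an AFS ramp. S is fixed at 800 pN unless it appears as a free
    parameter via ``fixed={"S_pN": None}``-style omission; by default free
    parameters are Lc and Lp. The window is clipped to the data's force
    support and the effective window reported.
    """
    fixed = dict(fixed) if fixed else {"S_pN": S_SSDNA}
    fixed.setdefault("kBT_pNnm", KBT_25C)
    fmin_req, fmax_req = map(float, force_window)
    f_data = curve.force_pN
    pos = f_data > 0
    fmin_eff = max(fmin_req, float(f_data[pos].min()) if pos.any() else fmin_req)
    fmax_eff = min(fmax_req, float(f_data.max()))
    clipped = (fmin_eff > fmin_req + 1e-12) or (fmax_eff < fmax_req - 1e-12)
    mask = (f_data >= fmin_eff) & (f_data <= fmax_eff) & pos
    if mask.sum() < 5:
        raise InsufficientDataError(
            f"only {int(mask.sum())} samples inside force window "
            f"[{fmin_eff:g}, {fmax_eff:g}] pN; need >= 5"
        )
    F = f_data[mask]
    L = curve.distance_um[mask]

    all_names = ("Lc_um", "Lp_nm", "S_pN", "kBT_pNnm")
    free_names = tuple(n for n in all_names if n not in fixed)
    if not free_names:
        raise ValueError("no free parameters to fit")

    defaults = {
        "Lc_um": float(np.max(curve.distance_um)),
        "Lp_nm": 1.0,
        "S_pN": S_SSDNA,
        "kBT_pNnm": KBT_25C,
    }
    if p0:
        defaults.update(p0)
    x0 = np.array([defaults[n] for n in free_names])
    bounds_lo = {"Lc_um": 1e-6, "Lp_nm": 1e-3, "S_pN": 1.0, "kBT_pNnm": 0.1}
    bounds_hi = {"Lc_um": 100.0, "Lp_nm": 100.0, "S_pN": 1e5, "kBT_pNnm": 100.0}
    lo = np.array([bounds_lo[n] for n in free_names])
    hi = np.array([bounds_hi[n] for n in free_names])
    x0 = np.clip(x0, lo, hi)

    def make_params(x):
        kw = dict(fixed)
        kw.update(dict(zip(free_names, x)))
        return EFJCParams(**kw)

    def resid(x):
        return efjc_extension(F, make_params(x)) - L

    sol = least_squares(resid, x0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not sol.success:
        raise FitFailureError(
            "eFJC fit did not converge", diagnostics={"message": sol.message, "x": sol.x.tolist()}
        )
    n, p = F.size, len(free_names)
    dof = max(n - p, 1)
    s2 = 2.0 * sol.cost / dof
    try:
        cov = s2 * np.linalg.inv(sol.jac.T @ sol.jac)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return EFJCFit(
        params=make_params(sol.x),
        stderr=dict(zip(free_names, se.tolist())),
        residual_norm_um=float(np.sqrt(2.0 * sol.cost)),
        n_points=int(n),
        window_requested_pN=(fmin_req, fmax_req),
        window_effective_pN=(fmin_eff, fmax_eff),
        window_clipped=bool(clipped),
        free_names=free_names,
    )


def _overlap_grid(curve_a: ForceExtensionCurve, curve_b: ForceExtensionCurve):
    da, fa = curve_a.sorted_by_distance()
    db, fb = curve_b.sorted_by_distance()
    lo = max(da[0], db[0])
    hi = min(da[-1], db[-1])
    if not hi > lo:
        raise EmptyOverlapError(
            f"no overlapping distance support: [{da[0]:g},{da[-1]:g}] vs [{db[0]:g},{db[-1]:g}] um"
        )
    grid = np.union1d(da, db)
    grid = grid[(grid >= lo) & (grid <= hi)]
    if grid[0] > lo:
        grid = np.insert(grid, 0, lo)
    if grid[-1] < hi:
        grid = np.append(grid, hi)
    return grid, np.interp(grid, da, fa), np.interp(grid, db, fb), (lo, hi)


def curve_energy(
    curve_a: ForceExtensionCurve,
    curve_b: ForceExtensionCurve,
    kBT_pNnm: float = KBT_25C,
) -> EnergyResult:
    """Area between two force-distance curves over their overlapping support.

    Delta-E = integral of (F_a - F_b) dd by the trapezoid rule on the union
    grid (linear interpolation), reported in pN nm and kBT. Antisymmetric in
    its arguments. Used with curve_a = protein-coated retraction and curve_b
    = bare retraction this is the work stored by protein binding.
    """
    grid, fa, fb, rng = _overlap_grid(curve_a, curve_b)
    e_pN_um = float(np.trapezoid(fa - fb, grid))
    e_pNnm = e_pN_um * 1000.0  # um -> nm
    return EnergyResult(e_pNnm, e_pNnm / kBT_pNnm, rng)


def hysteresis_energy(
    extension: ForceExtensionCurve,
    retraction: ForceExtensionCurve,
    kBT_pNnm: float = KBT_25C,
) -> EnergyResult:
    """Area between the extension and retraction curves of one force ramp.

    Positive hysteresis means work was dissipated during the ramp (protein
    unbinding at mild tension). Warns if the two phases carry different ramp
    labels but still computes.
    """
    if extension.ramp_id != retraction.ramp_id:
        warnings.warn(
            f"ramp labels differ: {extension.ramp_id!r} vs {retraction.ramp_id!r}",
            RampMismatchWarning,
            stacklevel=2,
        )
    return curve_energy(extension, retraction, kBT_pNnm=kBT_pNnm)


def ddE(ramp1: EnergyResult, ramp2: EnergyResult) -> EnergyResult:
    """Delta-Delta-E = Delta-E(R1) - Delta-E(R2) between two successive ramps.

    A positive value means less work is stored in the second ramp, i.e.
    protein was lost between ramps.
    """
    kbt = ramp1.delta_E_pNnm / ramp1.delta_E_kBT if ramp1.delta_E_kBT else KBT_25C
    d = ramp1.delta_E_pNnm - ramp2.delta_E_pNnm
    return EnergyResult(d, d / kbt, ramp1.integration_range_um)


def pNnm_to_kBT(E_pNnm, T_celsius: float = 25.0):
    """Convert an energy from pN nm to units of kBT at temperature T."""
    if not 0.0 <= T_celsius <= 100.0:
        raise ValueError("temperature out of physical range 0-100 C")
    return np.asarray(E_pNnm, dtype=float) / (KB_PN_NM * (T_celsius + 273.15))


def kBT_to_pNnm(E_kBT, T_celsius: float = 25.0):
    """Inverse of :func:`pNnm_to_kBT`."""
    if not 0.0 <= T_celsius <= 100.0:
        raise ValueError("temperature out of physical range 0-100 C")
    return np.asarray(E_kBT, dtype=float) * (KB_PN_NM * (T_celsius + 273.15))


def theoretical_contour_length(n_nt: int, rise_per_nt_nm: float = RISE_PER_NT_NM) -> float:
    """Theoretical contour length of an n-nucleotide ssDNA in um.

    At 0.33 nm/nt a 48,502-nt molecule gives 16.0 um.
    """
    if not n_nt > 0:
        raise ValueError("nucleotide count must be > 0")
    return n_nt * rise_per_nt_nm / 1000.0
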