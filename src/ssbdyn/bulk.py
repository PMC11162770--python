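"""Bulk binding assays: BLI 1:1 Langmuir kinetics and mass-photometry fits.

Biolayer interferometry (BLI) follows the optical-thickness response of a
DNA-functionalized sensor during association (analyte at concentration C)
and dissociation (buffer only). The 1:1 Langmuir model is

    association:  R(t) = R_eq (1 - e^(-(k_on C + k_off) t)),
                  R_eq = R_max C / (C + K_d),  K_d = k_off / k_on
    dissociation: R(t) = R_end e^(-k_off t)

fitted globally (shared k_on, k_off, R_max) across a concentration panel.

Mass photometry yields one molecular mass per landing event; the
distribution of an oligomer population is fitted with a Gaussian (mixture
of Gaussians for multiple species).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import FitFailureError, IdentifiabilityWarning, InsufficientDataError


@dataclass
class BLITrace:
    """One phase of one sensorgram at a fixed analyte concentration.

    Time is phase-local (0 at the start of the phase); dissociation traces
    are paired with their association phase through the concentration label.
    """

    time_s: np.ndarray
    response_nm: np.ndarray
    concentration_M: float
    phase: str = "association"  # "association" | "dissociation"

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.response_nm = np.asarray(self.response_nm, dtype=float)
        if self.time_s.shape != self.response_nm.shape:
            raise ValueError("time and response must have equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.phase not in ("association", "dissociation"):
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.concentration_M < 0:
            raise ValueError("concentration must be >= 0")


@dataclass
class BindingFit1to1:
    """Global 1:1 Langmuir parameters."""

    k_on_per_M_s: float
    k_off_per_s: float
    R_max_nm: float

    @property
    def K_d_M(self) -> float:
        return self.k_off_per_s / self.k_on_per_M_s

    @property
    def K_d_nM(self) -> float:
        return self.K_d_M * 1e9

    def to_dict(self) -> dict:
        return {
            "k_on_per_M_s": self.k_on_per_M_s,
            "k_off_per_s": self.k_off_per_s,
            "R_max_nm": self.R_max_nm,
            "K_d_nM": self.K_d_nM,
        }


@dataclass
class GaussianFit:
    """Gaussian (mixture) fit of a mass-event distribution."""

    means_kDa: np.ndarray
    sds_kDa: np.ndarray
    weights: np.ndarray

    @property
    def mean_kDa(self) -> float:
        """Mean of the dominant component."""
        return float(self.means_kDa[int(np.argmax(self.weights))])

    @property
    def sd_kDa(self) -> float:
        return float(self.sds_kDa[int(np.argmax(self.weights))])


def bli_1to1_model(
    t,
    phase: str,
    C_M: float,
    fit: BindingFit1to1,
    t_assoc_s: float = 300.0,
):
    """Model response of the 1:1 Langmuir scheme for one phase.

    For the dissociation phase, t is phase-local and the starting response
    R_end is the association model evaluated at t_assoc_s for the same
    concentration (vendor-software convention for paired phases).
    """
    t = np.asarray(t, dtype=float)
    if C_M < 0:
        raise ValueError("concentration must be >= 0")
    kon, koff, rmax = fit.k_on_per_M_s, fit.k_off_per_s, fit.R_max_nm
    kd = koff / kon

    def assoc(tt, C):
        if C == 0:
            return np.zeros_like(tt)
        req = rmax * C / (C + kd)
        return req * (1.0 - np.exp(-(kon * C + koff) * tt))

    if phase == "association":
        return assoc(t, C_M)
    if phase == "dissociation":
        r_end = assoc(np.asarray([t_assoc_s]), C_M)[0]
        return r_end * np.exp(-koff * t)
    raise ValueError(f"unknown phase {phase!r}")


def fit_bli_global(
    traces: list[BLITrace],
    t_assoc_s: float = 300.0,
    p0: dict | None = None,
) -> BindingFit1to1:
    """Global least-squares fit of k_on, k_off, R_max across all traces.

    All phases and concentrations share the three parameters; fitting is in
    log-parameter space (rates span decades and must stay positive).
    Mismatched time bases need no resampling: the model is evaluated on each
    trace's own time grid. A single-concentration panel is fitted but warned
    about (k_on and K_d are then only weakly identified).
    """
    if not traces:
        raise ValueError("no traces")
    concs = {tr.concentration_M for tr in traces if tr.concentration_M > 0}
    if len(concs) < 2:
        warnings.warn(
            "fewer than 2 analyte concentrations: k_on / K_d weakly identifiable",
            IdentifiabilityWarning,
            stacklevel=2,
        )
    rmax0 = max(float(np.max(tr.response_nm)) for tr in traces)
    defaults = {"k_on_per_M_s": 1e6, "k_off_per_s": 1e-3, "R_max_nm": max(rmax0, 1e-6)}
    if p0:
        defaults.update(p0)
    x0 = np.log([defaults["k_on_per_M_s"], defaults["k_off_per_s"], defaults["R_max_nm"]])

    def resid(x):
        fit = BindingFit1to1(*np.exp(x))
        out = []
        for tr in traces:
            out.append(
                bli_1to1_model(tr.time_s, tr.phase, tr.concentration_M, fit, t_assoc_s)
                - tr.response_nm
            )
        return np.concatenate(out)

    sol = least_squares(resid, x0, xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=20000)
    if not sol.success:
        raise FitFailureError("global BLI fit did not converge",
                              diagnostics={"message": sol.message})
    kon, koff, rmax = np.exp(sol.x)
    return BindingFit1to1(float(kon), float(koff), float(rmax))


def fit_mass_gaussian(
    masses_kDa,
    n_components: int = 1,
    bin_width_kDa: float = 2.0,
    random_state: int = 0,
) -> GaussianFit:
    """Gaussian fit of a mass-photometry event list (histogram-free MLE).

    The single-component MLE is the sample mean and SD. For several species
    (e.g. tetramer plus dimer) a Gaussian mixture is fitted by EM. Requires
    >= 30 events; a degenerate (zero-spread) sample gets the bin-limited SD
    floor bin_width/sqrt(12) with a warning.
    """
    m = np.asarray(masses_kDa, dtype=float)
    if m.size < 30:
        raise InsufficientDataError(f"need >= 30 events, got {m.size}")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    floor = bin_width_kDa / np.sqrt(12.0)
    if n_components == 1:
        mu = float(np.mean(m))
        sd = float(np.std(m, ddof=1))
        if sd < floor:
            warnings.warn("sample spread below bin resolution; SD floored", stacklevel=2)
            sd = floor
        return GaussianFit(np.array([mu]), np.array([sd]), np.array([1.0]))
    from sklearn.mixture import GaussianMixture

    gm = GaussianMixture(
        n_components=n_components, n_init=5, random_state=random_state,
        covariance_type="full",
    ).fit(m.reshape(-1, 1))
    order = np.argsort(gm.means_.ravel())
    sds = np.sqrt(gm.covariances_.ravel()[order])
    return GaussianFit(gm.means_.ravel()[order], np.maximum(sds, floor), gm.weights_[order])


def oligomer_mass(monomer_kDa: float, n_subunits: int) -> float:
    """Mass of an n-subunit oligomer from the monomer mass."""
    if n_subunits < 1:
        raise ValueError("n_subunits must be >= 1")
    return monomer_kDa * n_subunits
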