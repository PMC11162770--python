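"""Synthetic-data generators for every assay in the pipeline.

Each generator draws data with the statistical structure its analysis stage
assumes, under the experimental regimes of the study (sample sizes, pool
sizes, rates, concentration panels), and returns a machine-readable
ground-truth sidecar so recovery tests compare only generated data against
generated truth. A fixed seed gives bit-identical output.

Regime presets (monomer counts from the dissociation experiments, polymer
parameters from the force spectroscopy fits):

* WT-like dissociation: ~500 monomers, twice as many wrapped as bound
  (w0 ~ 2 b0 ~ 300), slow unwrapping.
* R107Q-like dissociation: ~2200 monomers split evenly between modes
  (b0 ~ w0 ~ 1100), ~3x faster unwrapping.
* eFJC: bare ssDNA Lc 4.8 um / Lp 1.9 nm; WT-coated 1.3 um / 9.3 nm;
  R107Q-coated 2.5 um / 3.3 nm.
* Compaction amplitude beta = 0.63 (100 mM salt) or 0.80 (400 mM salt).
* Two-color 1:1 mixing: 24% WT-only, 76% co-coated, 0% mutant-only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .bulk import BindingFit1to1, BLITrace
from .compaction import MoleculeTrace
from .dissociation import DissocTrace, K_BLEACH_DEFAULT
from .polymer import EFJCParams, ForceExtensionCurve, efjc_extension
from .tirf import FrameStack

EFJC_PRESETS: dict[str, EFJCParams] = {
    "bare": EFJCParams(Lc_um=4.8, Lp_nm=1.9),
    "wt_coated": EFJCParams(Lc_um=1.3, Lp_nm=9.3),
    "r107q_coated": EFJCParams(Lc_um=2.5, Lp_nm=3.3),
}

#: Dissociation regime presets: tetramer counts and initial mode split chosen
#: so the monomer pools match the fitted w0/b0 scales (WT: w0~300, b0~150;
#: R107Q: w0~b0~1100 monomers).
DISSOC_PRESETS: dict[str, dict] = {
    "WT-like": dict(n_tetramers=112, frac_wrapped=2.0 / 3.0,
                    k_unwrap=0.004, k_unbind=0.03),
    "R107Q-like": dict(n_tetramers=550, frac_wrapped=0.5,
                       k_unwrap=0.012, k_unbind=0.03),
}

#: Compaction regime presets (amplitude by salt; rate ~2x faster at high salt
#: and ~2x faster for WT than for R107Q).
COMPACTION_PRESETS: dict[str, dict] = {
    "WT-100mM": dict(beta=0.63, kc=0.010, L0_um=2.56),
    "WT-400mM": dict(beta=0.80, kc=0.020, L0_um=2.56),
    "R107Q-100mM": dict(beta=0.63, kc=0.005, L0_um=4.14),
    "R107Q-400mM": dict(beta=0.80, kc=0.010, L0_um=4.14),
}

#: Two-color class probabilities (A-only, both, B-only) per mixing ratio
#: (mutant:WT); channel A is the WT label.
TWO_COLOR_PRESETS: dict[str, tuple[float, float, float]] = {
    "1:2": (1.0, 0.0, 0.0),
    "1:1": (0.24, 0.76, 0.0),
    "1:0.1": (0.0, 0.90, 0.10),
    "1:0.01": (0.0, 0.0, 1.0),
}

#: Channel-A composition of co-coated molecules per mixing ratio.
TWO_COLOR_COMPOSITION: dict[str, float] = {"1:1": 0.73, "1:0.1": 0.06}

#: BLI concentration panel, molar.
BLI_PANEL_M: tuple[float, ...] = (0.625e-9, 1.5e-9, 2.5e-9, 5e-9)


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# force spectroscopy


def gen_efjc_curve(
    params: EFJCParams,
    F_grid=None,
    noise_frac: float = 0.0,
    unbind_fraction: float = 0.0,
    bare_params: EFJCParams | None = None,
    ramp_id: str = "R1",
    condition: str = "synthetic",
    seed=0,
) -> tuple[ForceExtensionCurve, ForceExtensionCurve, dict]:
    """One extension/retraction force-ramp pair from the eFJC forward model.

    ``noise_frac`` applies multiplicative Gaussian noise to the distances.
    With ``unbind_fraction`` > 0 the retraction phase is generated with
    parameters interpolated that fraction of the way toward ``bare_params``
    (protein lost during the ramp), which creates hysteresis.
    Returns (extension, retraction, truth).
    """
    if F_grid is None:
        F_grid = np.linspace(0.1, 15.0, 300)
    F_grid = np.asarray(F_grid, dtype=float)
    if np.any(F_grid <= 0) or np.any(np.diff(F_grid) <= 0):
        raise ValueError("F_grid must be positive and sorted")
    rng = _rng(seed)

    if unbind_fraction:
        if bare_params is None:
            raise ValueError("unbind_fraction needs bare_params to interpolate toward")
        f = unbind_fraction
        ret_params = EFJCParams(
            Lc_um=params.Lc_um + f * (bare_params.Lc_um - params.Lc_um),
            Lp_nm=params.Lp_nm + f * (bare_params.Lp_nm - params.Lp_nm),
            S_pN=params.S_pN,
            kBT_pNnm=params.kBT_pNnm,
        )
    else:
        ret_params = params

    def make(phase, p):
        L = efjc_extension(F_grid, p)
        if noise_frac:
            L = L * (1.0 + noise_frac * rng.standard_normal(L.shape))
        order = slice(None) if phase == "extension" else slice(None, None, -1)
        return ForceExtensionCurve(
            distance_um=L[order], force_pN=F_grid[order],
            phase=phase, ramp_id=ramp_id, condition=condition,
        )

    truth = {
        "extension_params": vars(params).copy(),
        "retraction_params": vars(ret_params).copy(),
        "unbind_fraction": unbind_fraction,
        "noise_frac": noise_frac,
    }
    return make("extension", params), make("retraction", ret_params), truth


# ---------------------------------------------------------------------------
# compaction


def gen_compaction_ensemble(
    beta: float = 0.80,
    kc: float = 0.020,
    Lf_frac: float | None = None,
    n_molecules: int = 60,
    L0_um: float = 2.56,
    L0_cv: float = 0.15,
    onset_frame: int = 10,
    onset_jitter_frames: int = 3,
    n_frames: int = 80,
    dt_s: float = 5.0,
    noise_sd: float = 0.05,
    seed=0,
) -> tuple[list[MoleculeTrace], dict]:
    """Ensemble of plateau-then-exponential-decay length traces.

    Per molecule, L0 is lognormal around ``L0_um`` (CV ``L0_cv``), the
    plateau lasts ``onset_frame`` frames plus integer jitter, and after
    onset L(t*)/L0 = beta e^(-kc t*) + Lf/L0 with additive Gaussian noise of
    SD ``noise_sd`` (normalized units). Lf defaults to (1 - beta) * L0 so the
    curve starts at 1. Defaults are the high-salt regime (beta = 0.80) with
    the ensemble size of the published decay curves (60 molecules).
    """
    if Lf_frac is None:
        Lf_frac = 1.0 - beta
    rng = _rng(seed)
    traces, truth_rows = [], []
    for i in range(n_molecules):
        L0 = L0_um * rng.lognormal(mean=0.0, sigma=L0_cv)
        onset = onset_frame + int(rng.integers(0, onset_jitter_frames + 1))
        t = np.arange(n_frames) * dt_s
        tstar = np.clip(t - onset * dt_s, 0.0, None)
        norm = np.where(t < onset * dt_s, 1.0, beta * np.exp(-kc * tstar) + Lf_frac)
        if noise_sd:
            norm = norm + noise_sd * rng.standard_normal(n_frames)
        traces.append(
            MoleculeTrace(
                molecule_id=f"mol{i:03d}", time_s=t,
                length_um=np.clip(norm, 0.0, None) * L0,
            )
        )
        truth_rows.append({"molecule_id": f"mol{i:03d}", "L0_um": L0,
                           "onset_frame": onset, "t0_star_s": onset * dt_s})
    truth = {
        "beta": beta, "kc_per_s": kc, "Lf_over_L0": Lf_frac,
        "dt_s": dt_s, "noise_sd": noise_sd, "molecules": truth_rows,
    }
    return traces, truth


# ---------------------------------------------------------------------------
# dissociation (Gillespie)


def gen_dissociation_gillespie(
    n_tetramers: int = 112,
    frac_wrapped: float = 2.0 / 3.0,
    k_unwrap: float = 0.004,
    k_unbind: float = 0.03,
    k_bleach: float = K_BLEACH_DEFAULT,
    labeling_efficiency: float = 1.0,
    dt_s: float = 5.0,
    T_total_s: float = 900.0,
    I_single_au: float = 10.0,
    molecule_id: str = "mol000",
    seed=0,
) -> tuple[DissocTrace, dict]:
    """Stochastic W->B->free trajectory of one SSB-coated ssDNA.

    Continuous-time Markov simulation: each tetramer starting wrapped waits
    Exp(k_unwrap) before entering the bound state, then Exp(k_unbind) before
    detaching (exact for the scheme; sampling at dt mimics camera
    integration). Each of the 4 subunit fluorophores is present with
    probability ``labeling_efficiency`` and bleaches independently at
    ``k_bleach`` while the tetramer is attached - bleached-but-attached
    tetramers stay attached and invisible, reproducing the confound that the
    rate-subtraction correction removes. The trace counts unbleached
    fluorophores (= observed monomers) at each sample time.
    """
    rng = _rng(seed)
    n_wrapped = int(round(n_tetramers * frac_wrapped))
    t_sample = np.arange(0.0, T_total_s + dt_s / 2, dt_s)
    counts = np.zeros_like(t_sample)
    for i in range(n_tetramers):
        wrapped = i < n_wrapped
        t_unwrap = rng.exponential(1.0 / k_unwrap) if (wrapped and k_unwrap > 0) else (
            np.inf if wrapped else 0.0)
        t_detach = t_unwrap + (rng.exponential(1.0 / k_unbind) if k_unbind > 0 else np.inf)
        n_fluor = int(rng.binomial(4, labeling_efficiency))
        if n_fluor == 0:
            continue
        t_bleach = (rng.exponential(1.0 / k_bleach, size=n_fluor)
                    if k_bleach > 0 else np.full(n_fluor, np.inf))
        attached = t_sample < t_detach
        visible = (t_sample[None, :] < t_bleach[:, None]).sum(axis=0)
        counts += attached * visible
    truth = {
        "n_tetramers": n_tetramers, "frac_wrapped": frac_wrapped,
        "w0_monomers": 4.0 * n_wrapped * labeling_efficiency,
        "b0_monomers": 4.0 * (n_tetramers - n_wrapped) * labeling_efficiency,
        "k_unwrap_per_s": k_unwrap, "k_unbind_per_s": k_unbind,
        "k_bleach_per_s": k_bleach, "labeling_efficiency": labeling_efficiency,
        "I_single_au": I_single_au,
    }
    return DissocTrace(molecule_id, t_sample, counts), truth


def gen_dissociation_ensemble(
    n_molecules: int = 50, preset: str = "WT-like", seed=0, **overrides
) -> tuple[list[DissocTrace], dict]:
    """Ensemble of Gillespie traces at a named regime preset."""
    kw = dict(DISSOC_PRESETS[preset])
    kw.update(overrides)
    seeds = np.random.SeedSequence(seed).spawn(n_molecules)
    traces, truth = [], None
    for i, s in enumerate(seeds):
        tr, truth = gen_dissociation_gillespie(
            molecule_id=f"mol{i:03d}", seed=s, **kw
        )
        traces.append(tr)
    return traces, truth


# ---------------------------------------------------------------------------
# two-color competition


def gen_two_color_table(
    n_molecules: int = 300,
    class_probabilities: tuple[float, float, float] = (0.24, 0.76, 0.0),
    composition_A: float = 0.73,
    mean_monomers: float = 500.0,
    count_cv: float = 0.3,
    I_single_A: float = 10.0,
    I_single_B: float = 10.0,
    intensity_noise_frac: float = 0.02,
    ratio_condition: str = "1:1",
    seed=0,
) -> tuple["np.ndarray", dict]:
    """Two-color intensity table with known class labels.

    Molecules are multinomial over (A-only, both, B-only); monomer counts
    per molecule are lognormal around ``mean_monomers``; co-coated molecules
    split their monomers ``composition_A`` : 1-``composition_A`` between
    channels. Returns (records DataFrame-ready structured rows, truth).
    """
    import pandas as pd

    p = np.asarray(class_probabilities, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9 or np.any(p < 0):
        raise ValueError("class probabilities must be non-negative and sum to 1")
    rng = _rng(seed)
    labels = rng.choice(["A_only", "both", "B_only"], size=n_molecules, p=p)
    sigma = np.sqrt(np.log(1 + count_cv**2))
    rows = []
    for i, lab in enumerate(labels):
        n = mean_monomers * rng.lognormal(-sigma**2 / 2, sigma)
        if lab == "A_only":
            nA, nB = n, 0.0
        elif lab == "B_only":
            nA, nB = 0.0, n
        else:
            nA, nB = n * composition_A, n * (1 - composition_A)
        IA = nA * I_single_A
        IB = nB * I_single_B
        if intensity_noise_frac:
            IA *= max(1.0 + intensity_noise_frac * rng.standard_normal(), 0.0)
            IB *= max(1.0 + intensity_noise_frac * rng.standard_normal(), 0.0)
        rows.append({"molecule_id": f"mol{i:03d}", "I_A_au": IA, "I_B_au": IB,
                     "ratio_condition": ratio_condition, "true_class": lab})
    df = pd.DataFrame(rows)
    truth = {
        "class_probabilities": p.tolist(), "composition_A": composition_A,
        "I_single_A": I_single_A, "I_single_B": I_single_B,
        "labels": df["true_class"].tolist(),
    }
    return df, truth


def gen_exchange_traces(
    n_molecules: int = 10,
    k_off_A: float = 0.01,
    k_on_B: float = 0.01,
    I0_A: float = 1000.0,
    I_inf_B: float = 800.0,
    dt_s: float = 5.0,
    T_total_s: float = 600.0,
    noise_frac: float = 0.02,
    seed=0,
) -> tuple[list[MoleculeTrace], list[MoleculeTrace], dict]:
    """Real-time exchange preset: channel A decays while channel B rises."""
    rng = _rng(seed)
    t = np.arange(0.0, T_total_s + dt_s / 2, dt_s)
    A, B = [], []
    for i in range(n_molecules):
        ia = I0_A * np.exp(-k_off_A * t)
        ib = I_inf_B * (1 - np.exp(-k_on_B * t))
        if noise_frac:
            ia = ia * (1 + noise_frac * rng.standard_normal(t.shape))
            ib = ib * (1 + noise_frac * rng.standard_normal(t.shape))
        common = dict(time_s=t, length_um=np.full_like(t, 2.5))
        A.append(MoleculeTrace(f"A{i:03d}", intensity_au=np.clip(ia, 0, None),
                               channel="A", **common))
        B.append(MoleculeTrace(f"B{i:03d}", intensity_au=np.clip(ib, 0, None),
                               channel="B", **common))
    truth = {"k_off_A": k_off_A, "k_on_B": k_on_B, "I0_A": I0_A, "I_inf_B": I_inf_B}
    return A, B, truth


# ---------------------------------------------------------------------------
# bulk assays


def gen_bli_traces(
    fit: BindingFit1to1,
    concentrations_M=BLI_PANEL_M,
    t_assoc_s: float = 300.0,
    t_dissoc_s: float = 600.0,
    dt_s: float = 1.0,
    noise_sd_nm: float = 0.0,
    seed=0,
) -> tuple[list[BLITrace], dict]:
    """Sensorgram panel (association + dissociation per concentration)."""
    from .bulk import bli_1to1_model

    rng = _rng(seed)
    traces = []
    for C in concentrations_M:
        ta = np.arange(dt_s, t_assoc_s + dt_s / 2, dt_s)
        td = np.arange(dt_s, t_dissoc_s + dt_s / 2, dt_s)
        ra = bli_1to1_model(ta, "association", C, fit, t_assoc_s)
        rd = bli_1to1_model(td, "dissociation", C, fit, t_assoc_s)
        if noise_sd_nm:
            ra = ra + noise_sd_nm * rng.standard_normal(ra.shape)
            rd = rd + noise_sd_nm * rng.standard_normal(rd.shape)
        traces.append(BLITrace(ta, ra, C, "association"))
        traces.append(BLITrace(td, rd, C, "dissociation"))
    truth = fit.to_dict() | {"noise_sd_nm": noise_sd_nm,
                             "concentrations_M": list(concentrations_M)}
    return traces, truth


def gen_mass_events(
    mean_kDa: float = 67.0, sd_kDa: float = 2.0, n: int = 5000, seed=0
) -> tuple[np.ndarray, dict]:
    """Mass-photometry event list drawn from N(mean, sd^2)."""
    if sd_kDa < 0:
        raise ValueError("sd must be >= 0")
    rng = _rng(seed)
    events = mean_kDa + sd_kDa * rng.standard_normal(n)
    return events, {"mean_kDa": mean_kDa, "sd_kDa": sd_kDa, "n": n}


# ---------------------------------------------------------------------------
# TIRF movies


@dataclass
class FilamentSpec:
    """Ground-truth description of one synthetic filament."""

    anchor: tuple[int, int]  # (row, col), tether point; filament extends +col
    lengths_um: np.ndarray  # per-frame length
    intensities_au: np.ndarray  # per-frame total emitted intensity


def gen_tirf_movie(
    filaments: list[FilamentSpec],
    n_frames: int | None = None,
    shape: tuple[int, int] = (64, 128),
    pixel_size_um: float = 0.1,
    frame_interval_s: float = 5.0,
    psf_sigma_px: float = 0.8,
    background: float = 10.0,
    noise_sd: float = 0.5,
    seed=0,
) -> tuple[FrameStack, dict]:
    """Synthetic TIRF movie of flow-stretched filaments.

    Each filament deposits its per-frame intensity uniformly along a
    horizontal line of pixels starting at its anchor, blurred with an
    isotropic Gaussian PSF, on a constant background with Gaussian read
    noise. The truth sidecar echoes the specs.
    """
    rng = _rng(seed)
    if n_frames is None:
        n_frames = max(len(f.lengths_um) for f in filaments) if filaments else 1
    frames = np.zeros((n_frames, *shape))
    for fi in range(n_frames):
        img = np.zeros(shape)
        for f in filaments:
            if fi >= len(f.lengths_um):
                continue
            npx = max(int(round(f.lengths_um[fi] / pixel_size_um)), 1)
            r, c = f.anchor
            c1 = min(c + npx, shape[1])
            img[r, c:c1] += f.intensities_au[fi] / (c1 - c)
        if psf_sigma_px > 0:
            img = ndimage.gaussian_filter(img, psf_sigma_px)
        img += background
        if noise_sd:
            img += noise_sd * rng.standard_normal(shape)
        frames[fi] = img
    truth = {
        "filaments": [
            {"anchor": list(f.anchor),
             "lengths_um": np.asarray(f.lengths_um, dtype=float).tolist(),
             "intensities_au": np.asarray(f.intensities_au, dtype=float).tolist()}
            for f in filaments
        ],
        "pixel_size_um": pixel_size_um, "frame_interval_s": frame_interval_s,
        "psf_sigma_px": psf_sigma_px, "background": background, "noise_sd": noise_sd,
    }
    return FrameStack(frames, pixel_size_um, frame_interval_s), truth


def gen_compaction_movie(
    n_frames: int = 30,
    onset_frame: int = 10,
    kc: float = 0.05,
    beta: float = 0.7,
    L0_um: float = 4.0,
    intensity_au: float = 5000.0,
    seed=0,
    **movie_kwargs,
) -> tuple[FrameStack, dict]:
    """Movie preset: one filament shrinking exponentially after an onset."""
    dt = movie_kwargs.get("frame_interval_s", 5.0)
    t = np.arange(n_frames) * dt
    tstar = np.clip(t - onset_frame * dt, 0.0, None)
    norm = np.where(t < onset_frame * dt, 1.0, beta * np.exp(-kc * tstar) + (1 - beta))
    spec = FilamentSpec(
        anchor=(32, 10),
        lengths_um=norm * L0_um,
        intensities_au=np.full(n_frames, intensity_au),
    )
    stack, truth = gen_tirf_movie([spec], n_frames=n_frames, seed=seed, **movie_kwargs)
    truth["compaction"] = {"beta": beta, "kc_per_s": kc, "onset_frame": onset_frame,
                           "L0_um": L0_um}
    return stack, truth
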