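"""End-to-end pipeline runs: simulate -> (quantify) -> fit -> report.

A run is described by a validated configuration (assay, seed, per-stage
parameters). All randomness derives from the single top-level seed through
``numpy.random.SeedSequence(seed).spawn`` in stage order, so a rerun with
the same config and seed reproduces every artifact bit-for-bit. Each run
directory holds the per-stage JSON results, a combined summary CSV, and a
run log echoing the config, its hash, and package versions.
"""

from __future__ import annotations

import hashlib
import json
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, bulk, compaction, competition, dissociation, io, polymer, simulate, tirf
from .errors import ConfigError

log = logging.getLogger("ssbdyn")

KNOWN_ASSAYS = ("efjc", "compaction", "dissociation", "competition", "bli", "mp", "tirf")
KNOWN_KEYS = {"assay", "seed", "out_dir", "simulate", "fit", "log_level"}


@dataclass
class RunConfig:
    """Validated run configuration."""

    assay: str
    seed: int = 0
    out_dir: str = "run"
    simulate: dict = field(default_factory=dict)
    fit: dict = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "assay" not in d:
            raise ConfigError("config must name an assay")
        if d["assay"] not in KNOWN_ASSAYS:
            raise ConfigError(f"unknown assay {d['assay']!r}; known: {KNOWN_ASSAYS}")
        for k in ("simulate", "fit"):
            if k in d and not isinstance(d[k], dict):
                raise ConfigError(f"{k} section must be a mapping")
        if "seed" in d and not isinstance(d["seed"], int):
            raise ConfigError("seed must be an integer")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def canonical(self) -> str:
        return json.dumps(
            {"assay": self.assay, "seed": self.seed, "simulate": self.simulate,
             "fit": self.fit}, sort_keys=True)

    def hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


def _stage_seeds(seed: int, n: int = 4) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n)


def _run_efjc(cfg, out, seeds):
    params = simulate.EFJC_PRESETS[cfg.simulate.get("preset", "bare")]
    ext, ret, truth = simulate.gen_efjc_curve(
        params, noise_frac=cfg.simulate.get("noise_frac", 0.0), seed=seeds[0])
    io.write_curves([ext, ret], out / "curves.csv")
    io.write_json(truth, out / "truth.json")
    window = tuple(cfg.fit.get("window", (0.1, 15.0)))
    fit = polymer.fit_efjc(ret, window)
    io.write_json(fit.to_dict(), out / "fit.json")
    return {"Lc_um": fit.params.Lc_um, "Lp_nm": fit.params.Lp_nm,
            "truth_Lc_um": params.Lc_um, "truth_Lp_nm": params.Lp_nm}


def _run_compaction(cfg, out, seeds):
    preset = cfg.simulate.get("preset")
    kw = dict(simulate.COMPACTION_PRESETS[preset]) if preset else {}
    kw.update({k: v for k, v in cfg.simulate.items() if k != "preset"})
    traces, truth = simulate.gen_compaction_ensemble(seed=seeds[0], **kw)
    io.write_traces(traces, out / "traces.csv", out / "conditions.json")
    io.write_json(truth, out / "truth.json")
    ens = compaction.normalize_and_align(traces, delta=cfg.fit.get("delta", 0.05))
    fit = compaction.fit_compaction_decay(ens)
    io.write_json(fit.to_dict(), out / "fit.json")
    return {"beta": fit.beta, "kc_per_s": fit.kc, "truth_beta": truth["beta"],
            "truth_kc_per_s": truth["kc_per_s"]}


def _run_dissociation(cfg, out, seeds):
    preset = cfg.simulate.get("preset", "WT-like")
    n_mol = cfg.simulate.get("n_molecules", 10)
    overrides = {k: v for k, v in cfg.simulate.items()
                 if k not in ("preset", "n_molecules")}
    traces, truth = simulate.gen_dissociation_ensemble(
        n_molecules=n_mol, preset=preset, seed=seeds[0], **overrides)
    # ensemble mean trace is the fitting target by default
    counts = np.mean([tr.count for tr in traces], axis=0)
    mean_trace = dissociation.DissocTrace("ensemble_mean", traces[0].time_s, counts)
    io.write_json(truth, out / "truth.json")
    res = dissociation.fit_two_state(mean_trace)
    corrected = dissociation.correct_photobleaching(
        res.fit, truth["k_bleach_per_s"]) if cfg.fit.get("correct_bleach", True) \
        else res.fit
    io.write_json({"raw": res.fit.to_dict(), "corrected": corrected.to_dict()},
                  out / "fit.json")
    return {"k_unwrap_per_s": corrected.k_unwrap, "k_unbind_per_s": corrected.k_unbind,
            "truth_k_unwrap_per_s": truth["k_unwrap_per_s"],
            "truth_k_unbind_per_s": truth["k_unbind_per_s"]}


def _run_competition(cfg, out, seeds):
    preset = cfg.simulate.get("preset", "1:1")
    probs = simulate.TWO_COLOR_PRESETS[preset]
    df, truth = simulate.gen_two_color_table(
        n_molecules=cfg.simulate.get("n_molecules", 300),
        class_probabilities=probs, ratio_condition=preset, seed=seeds[0])
    io.write_two_color(df.drop(columns=["true_class"]), out / "twocolor.csv")
    io.write_json(truth, out / "truth.json")
    records = [competition.TwoColorRecord(r.molecule_id, r.I_A_au, r.I_B_au, preset)
               for r in df.itertuples(index=False)]
    summary = competition.classify_molecules(records, threshold_A=1.0, threshold_B=1.0)
    io.write_json(summary.to_dict(), out / "fit.json")
    return summary.to_dict()


def _run_bli(cfg, out, seeds):
    truth_fit = bulk.BindingFit1to1(
        k_on_per_M_s=cfg.simulate.get("k_on_per_M_s", 1e6),
        k_off_per_s=cfg.simulate.get("k_off_per_s", 1.17e-3),
        R_max_nm=cfg.simulate.get("R_max_nm", 1.0))
    traces, truth = simulate.gen_bli_traces(
        truth_fit, noise_sd_nm=cfg.simulate.get("noise_sd_nm", 0.0), seed=seeds[0])
    io.write_bli(traces, out / "sensorgrams.csv")
    io.write_json(truth, out / "truth.json")
    fit = bulk.fit_bli_global(traces)
    io.write_json(fit.to_dict(), out / "fit.json")
    return {"K_d_nM": fit.K_d_nM, "truth_K_d_nM": truth_fit.K_d_nM}


def _run_mp(cfg, out, seeds):
    events, truth = simulate.gen_mass_events(
        mean_kDa=cfg.simulate.get("mean_kDa", 67.0),
        sd_kDa=cfg.simulate.get("sd_kDa", 2.0),
        n=cfg.simulate.get("n", 5000), seed=seeds[0])
    io.write_masses(events, out / "masses.csv")
    io.write_json(truth, out / "truth.json")
    fit = bulk.fit_mass_gaussian(events, n_components=cfg.fit.get("components", 1))
    result = {"mean_kDa": fit.mean_kDa, "sd_kDa": fit.sd_kDa,
              "truth_mean_kDa": truth["mean_kDa"]}
    io.write_json(result, out / "fit.json")
    return result


def _run_tirf(cfg, out, seeds):
    stack, truth = simulate.gen_compaction_movie(seed=seeds[0])
    try:
        import tifffile

        tifffile.imwrite(out / "movie.tif", stack.frames.astype(np.float32))
    except Exception:  # TIFF write is best-effort; traces are the contract
        pass
    io.write_json(truth, out / "truth.json")
    traces = tirf.quantify_stack(stack)
    io.write_traces(traces, out / "traces.csv")
    return {"n_tracks": len(traces),
            "n_filaments_true": len(truth["filaments"])}


_RUNNERS = {
    "efjc": _run_efjc, "compaction": _run_compaction,
    "dissociation": _run_dissociation, "competition": _run_competition,
    "bli": _run_bli, "mp": _run_mp, "tirf": _run_tirf,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute one configured run; return the summary dict.

    Writes per-stage artifacts, summary.csv and run.log under the run
    directory. On stage failure, partial outputs are kept under a failed/
    marker and the exception re-raised with the stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    seeds = _stage_seeds(config.seed)
    log.info("run %s assay=%s seed=%d", config.hash(), config.assay, config.seed)
    try:
        summary = _RUNNERS[config.assay](config, out, seeds)
    except Exception as exc:
        (out / "failed").mkdir(exist_ok=True)
        (out / "failed" / "error.txt").write_text(
            f"stage {config.assay!r} failed: {exc}\n\n{traceback.format_exc()}")
        raise
    summary = {"config_hash": config.hash(), "assay": config.assay,
               "seed": config.seed, **summary}
    import pandas as pd

    pd.DataFrame([summary]).to_csv(out / "summary.csv", index=False)
    (out / "run.log").write_text(
        f"ssbdyn {__version__}\nconfig_hash {config.hash()}\n"
        f"config {config.canonical()}\n")
    return summary
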