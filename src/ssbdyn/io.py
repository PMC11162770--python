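"""File-format contracts: CSV/JSON readers and writers for every stage.

Formats are deliberately plain and diff-able:

* force curves: CSV with ramp_id, phase, distance_um, force_pN, condition
* molecule traces: long CSV with molecule_id, frame, time_s, length_um,
  intensity_au (+ a JSON conditions sidecar keyed by molecule_id)
* two-color tables: CSV with molecule_id, I_A_au, I_B_au, ratio_condition
* BLI sensorgrams: CSV with time_s, response_nm, conc_M, phase
* mass photometry: CSV with a single mass_kDa column
* fit results: JSON
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .bulk import BLITrace
from .compaction import MoleculeTrace
from .competition import TwoColorRecord
from .dissociation import DissocTrace
from .polymer import ForceExtensionCurve

CURVE_COLUMNS = ["ramp_id", "phase", "distance_um", "force_pN", "condition"]
TRACE_COLUMNS = ["molecule_id", "frame", "time_s", "length_um", "intensity_au"]


def write_curves(curves: list[ForceExtensionCurve], path) -> None:
    rows = []
    for c in curves:
        for d, f in zip(c.distance_um, c.force_pN):
            rows.append({"ramp_id": c.ramp_id, "phase": c.phase,
                         "distance_um": d, "force_pN": f, "condition": c.condition})
    pd.DataFrame(rows, columns=CURVE_COLUMNS).to_csv(path, index=False)


def read_curves(path) -> list[ForceExtensionCurve]:
    df = pd.read_csv(path)
    missing = set(CURVE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"curve file missing columns: {sorted(missing)}")
    curves = []
    for (ramp, phase, cond), g in df.groupby(["ramp_id", "phase", "condition"], sort=False):
        curves.append(ForceExtensionCurve(
            distance_um=g["distance_um"].to_numpy(),
            force_pN=g["force_pN"].to_numpy(),
            phase=str(phase), ramp_id=str(ramp), condition=str(cond),
        ))
    return curves


def write_traces(traces: list[MoleculeTrace], path, conditions_path=None) -> None:
    rows = []
    cond = {}
    for tr in traces:
        inten = tr.intensity_au if tr.intensity_au is not None else np.full_like(tr.time_s, np.nan)
        for i, (t, l, a) in enumerate(zip(tr.time_s, tr.length_um, inten)):
            rows.append({"molecule_id": tr.molecule_id, "frame": i, "time_s": t,
                         "length_um": l, "intensity_au": a})
        cond[tr.molecule_id] = {"protein": tr.protein, "salt_mM": tr.salt_mM,
                                "channel": tr.channel}
    pd.DataFrame(rows, columns=TRACE_COLUMNS).to_csv(path, index=False)
    if conditions_path is not None:
        Path(conditions_path).write_text(json.dumps(cond, indent=1))


def read_traces(path, conditions_path=None) -> list[MoleculeTrace]:
    df = pd.read_csv(path)
    cond = {}
    if conditions_path is not None and Path(conditions_path).exists():
        cond = json.loads(Path(conditions_path).read_text())
    traces = []
    for mid, g in df.groupby("molecule_id", sort=False):
        g = g.sort_values("time_s")
        inten = g["intensity_au"].to_numpy() if "intensity_au" in g else None
        if inten is not None and np.all(np.isnan(inten)):
            inten = None
        meta = cond.get(str(mid), {})
        traces.append(MoleculeTrace(
            molecule_id=str(mid), time_s=g["time_s"].to_numpy(),
            length_um=g["length_um"].to_numpy(), intensity_au=inten,
            protein=meta.get("protein"), salt_mM=meta.get("salt_mM"),
            channel=meta.get("channel"),
        ))
    return traces


def traces_to_dissoc(
    traces: list[MoleculeTrace], I_single_au: float, labeling_efficiency: float = 1.0
) -> list[DissocTrace]:
    """Convert intensity traces to monomer-count traces via calibration."""
    from .dissociation import intensity_to_count

    out = []
    for tr in traces:
        if tr.intensity_au is None:
            raise ValueError(f"trace {tr.molecule_id} has no intensity")
        out.append(DissocTrace(
            molecule_id=tr.molecule_id, time_s=tr.time_s,
            count=intensity_to_count(tr.intensity_au, I_single_au, labeling_efficiency),
            salt_mM=tr.salt_mM, protein=tr.protein,
        ))
    return out


def write_two_color(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_two_color(path) -> list[TwoColorRecord]:
    df = pd.read_csv(path)
    return [
        TwoColorRecord(str(r.molecule_id), float(r.I_A_au), float(r.I_B_au),
                       str(getattr(r, "ratio_condition", "")))
        for r in df.itertuples(index=False)
    ]


def write_bli(traces: list[BLITrace], path) -> None:
    rows = []
    for tr in traces:
        for t, r in zip(tr.time_s, tr.response_nm):
            rows.append({"time_s": t, "response_nm": r,
                         "conc_M": tr.concentration_M, "phase": tr.phase})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_bli(path) -> list[BLITrace]:
    df = pd.read_csv(path)
    traces = []
    for (c, phase), g in df.groupby(["conc_M", "phase"], sort=False):
        g = g.sort_values("time_s")
        traces.append(BLITrace(g["time_s"].to_numpy(), g["response_nm"].to_numpy(),
                               float(c), str(phase)))
    return traces


def write_masses(masses, path) -> None:
    pd.DataFrame({"mass_kDa": np.asarray(masses, dtype=float)}).to_csv(path, index=False)


def read_masses(path) -> np.ndarray:
    return pd.read_csv(path)["mass_kDa"].to_numpy()


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, cls=_NumpyEncoder) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
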