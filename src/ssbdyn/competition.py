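"""Two-color competition for ssDNA binding between two SSB variants.

Molecules carrying two differently labelled proteins (channel A = WT,
channel B = mutant in the original experiment) are classified from their
per-channel integrated intensities as A-only, co-coated or B-only.
Molecules below both detection thresholds are invisible to fluorescence and
are excluded from the percentage base (their count is reported). On
co-coated molecules, single-fluorophore calibration converts intensities to
monomer counts and hence to a per-molecule channel-A composition fraction.
Real-time exchange experiments are summarized as per-channel ensemble mean
intensity versus time with the sign of the fitted linear trend.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compaction import MoleculeTrace


@dataclass
class TwoColorRecord:
    """Per-molecule integrated intensity in the two spectral channels."""

    molecule_id: str
    I_A: float
    I_B: float
    ratio_condition: str = ""

    def __post_init__(self):
        if self.I_A < 0 or self.I_B < 0:
            raise ValueError("intensities must be >= 0")


@dataclass
class CompetitionSummary:
    """Classification percentages over the visible-molecule base."""

    n_total: int
    n_excluded: int
    pct_A_only: float
    pct_both: float
    pct_B_only: float
    classes: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_excluded": self.n_excluded,
            "pct_A_only": self.pct_A_only,
            "pct_both": self.pct_both,
            "pct_B_only": self.pct_B_only,
        }


def default_threshold(background_sd: float, k: float = 3.0) -> float:
    """Detection threshold as k times the background intensity SD."""
    if background_sd < 0:
        raise ValueError("background SD must be >= 0")
    return k * background_sd


def classify_molecules(
    records: list[TwoColorRecord],
    threshold_A: float,
    threshold_B: float,
) -> CompetitionSummary:
    """Classify each molecule as A-only / both / B-only by channel thresholds.

    Percentages are over the molecules visible in at least one channel;
    molecules below both thresholds are excluded from the base and counted
    separately (fluorescence cannot count uncoated DNA).
    """
    if not records:
        raise ValueError("empty record list")
    if not (threshold_A > 0 and threshold_B > 0):
        raise ValueError("thresholds must be > 0")
    rows = []
    for r in records:
        a = r.I_A >= threshold_A
        b = r.I_B >= threshold_B
        cls = "A_only" if a and not b else "both" if a and b else "B_only" if b else "uncoated"
        rows.append({"molecule_id": r.molecule_id, "I_A": r.I_A, "I_B": r.I_B, "class": cls})
    df = pd.DataFrame(rows)
    included = df[df["class"] != "uncoated"]
    n_inc = len(included)
    n_exc = len(df) - n_inc
    if n_inc == 0:
        raise ValueError("all molecules below both thresholds; nothing to classify")
    counts = included["class"].value_counts()
    pct = lambda c: 100.0 * counts.get(c, 0) / n_inc
    return CompetitionSummary(
        n_total=n_inc,
        n_excluded=n_exc,
        pct_A_only=pct("A_only"),
        pct_both=pct("both"),
        pct_B_only=pct("B_only"),
        classes=df,
    )


def composition_fractions(
    co_records: list[TwoColorRecord],
    I_single_A: float,
    I_single_B: float,
) -> tuple[pd.DataFrame, float, float]:
    """Channel-A monomer fraction on co-coated molecules.

    fraction_A = (I_A/I_single_A) / (I_A/I_single_A + I_B/I_single_B); the
    ratio is invariant to a common rescaling of both calibrations. Records
    dark in both channels are skipped with a warning. Returns the
    per-molecule table plus the ensemble mean and SD.
    """
    if not (I_single_A > 0 and I_single_B > 0):
        raise ValueError("single-fluorophore intensities must be > 0")
    rows = []
    for r in co_records:
        nA = r.I_A / I_single_A
        nB = r.I_B / I_single_B
        if nA + nB == 0:
            warnings.warn(f"record {r.molecule_id} dark in both channels; skipped", stacklevel=2)
            continue
        rows.append({"molecule_id": r.molecule_id, "n_A": nA, "n_B": nB,
                     "fraction_A": nA / (nA + nB)})
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no usable co-coated records")
    fr = df["fraction_A"].to_numpy()
    return df, float(np.mean(fr)), float(np.std(fr, ddof=1)) if fr.size > 1 else 0.0


def _channel_summary(traces: list[MoleculeTrace]) -> pd.DataFrame:
    base = traces[0].time_s
    stack = []
    for tr in traces:
        if tr.intensity_au is None:
            raise ValueError("realtime traces need intensity series")
        stack.append(np.interp(base, tr.time_s, tr.intensity_au))
    arr = np.vstack(stack)
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else np.zeros_like(mean)
    slope = float(np.polyfit(base, mean, 1)[0])
    df = pd.DataFrame({"time_s": base, "mean": mean, "sd": sd})
    df.attrs["slope"] = slope
    df.attrs["trend"] = "rising" if slope > 0 else "falling" if slope < 0 else "flat"
    return df


def realtime_exchange(
    traces_A: list[MoleculeTrace],
    traces_B: list[MoleculeTrace],
) -> dict[str, pd.DataFrame]:
    """Ensemble mean intensity vs time per channel, with linear-trend sign.

    Channels are summarized independently on the first trace's time base
    (other traces interpolated). An empty channel is omitted with a warning.
    In an exchange experiment the resident protein's channel falls while the
    invading protein's channel rises.
    """
    out: dict[str, pd.DataFrame] = {}
    for name, traces in (("A", traces_A), ("B", traces_B)):
        if not traces:
            warnings.warn(f"channel {name} empty; omitted", stacklevel=2)
            continue
        out[name] = _channel_summary(traces)
    return out
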