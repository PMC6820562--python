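"""Unit classification and trial/unit inclusion filters.

Units are split into putative pyramidal cells and putative interneurons
from two session-wide scalars: a unit is pyramidal iff its mean discharge
rate is below 8.92 Hz AND its filtered spike-waveform width is at least
254 us; everything else is an interneuron. Cluster-quality screening
requires no inter-spike interval under 2 ms and, when an L-ratio is
supplied by the spike sorter, L-ratio < 0.10.

Delay-period analyses include a pyramidal unit only when its mean firing
rate is >= 0.5 Hz both during the entire fixed 4-s delay and during the
initial 4 s of the random delay (delay >= 4 s trials, correct only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_core import AnalysisWindow, UnitSpikeSet, window_spikes

__all__ = [
    "PYRAMIDAL_MAX_RATE_HZ",
    "PYRAMIDAL_MIN_WIDTH_US",
    "RateMatrix",
    "InclusionReport",
    "classify_unit",
    "screen_unit_quality",
    "select_trials",
    "rate_matrix",
    "apply_inclusion",
]

PYRAMIDAL_MAX_RATE_HZ = 8.92   # strict: rate < 8.92
PYRAMIDAL_MIN_WIDTH_US = 254.0  # inclusive: width >= 254
MIN_ISI_MS = 2.0
MAX_L_RATIO = 0.10
DEFAULT_RATE_THRESHOLD_HZ = 0.5

TRIAL_RULES = ("correct_only", "correct_and_delay_ge4", "correct_iti_gt2")


def classify_unit(mean_rate: float, spike_width: float) -> str:
    """Classify a unit as ``pyramidal`` or ``interneuron``.

    Pyramidal iff mean_rate < 8.92 Hz and spike_width >= 254 us.
    """
    if not (math.isfinite(mean_rate) and math.isfinite(spike_width)):
        raise ValueError("mean_rate and spike_width must be finite")
    if mean_rate < PYRAMIDAL_MAX_RATE_HZ and spike_width >= PYRAMIDAL_MIN_WIDTH_US:
        return "pyramidal"
    return "interneuron"


def screen_unit_quality(unit: UnitSpikeSet) -> bool:
    """Cluster quality screen: min ISI >= 2 ms; L-ratio < 0.10 when present."""
    if unit.min_isi < MIN_ISI_MS:
        return False
    if unit.l_ratio is not None and not unit.l_ratio < MAX_L_RATIO:
        return False
    return True


def select_trials(trials: pd.DataFrame, condition: str | None, rule: str) -> pd.DataFrame:
    """Deterministic trial subset, preserving original order.

    rules: ``correct_only``; ``correct_and_delay_ge4`` additionally keeps
    only delays >= 4 s (used whenever random-delay activity is cut at 4 s);
    ``correct_iti_gt2`` keeps correct trials preceded by an inter-trial
    interval longer than 2 s (pre-stimulus control).
    """
    if rule not in TRIAL_RULES:
        raise ValueError(f"unknown trial rule {rule!r}; expected one of {TRIAL_RULES}")
    out = trials
    if condition is not None:
        out = out[out["condition"] == condition]
    out = out[out["correct"]]
    if rule == "correct_and_delay_ge4":
        out = out[out["delay_duration"] >= 4.0]
    elif rule == "correct_iti_gt2":
        out = out[out["iti_before"] > 2.0]
    return out


@dataclass
class RateMatrix:
    """Units x trials firing rates (Hz) for one analysis window."""

    unit_ids: List[str]
    trial_ids: List[int]
    rates: np.ndarray  # shape (n_units, n_trials)
    window: AnalysisWindow

    def mean_rates(self) -> np.ndarray:
        """Per-unit mean over trials, Hz."""
        return self.rates.mean(axis=1)

    def unit_row(self, unit_id: str) -> np.ndarray:
        return self.rates[self.unit_ids.index(unit_id)]


def rate_matrix(
    units: Mapping[str, UnitSpikeSet], trials: pd.DataFrame, window: AnalysisWindow
) -> RateMatrix:
    """Spike count / window length in Hz for every unit x trial."""
    if len(trials) == 0:
        raise ValueError("rate_matrix requires a non-empty trial table")
    unit_ids = sorted(units)
    trial_records = trials.to_dict("records")
    rates = np.zeros((len(unit_ids), len(trial_records)))
    for i, uid in enumerate(unit_ids):
        for j, trial in enumerate(trial_records):
            ws = window_spikes(units[uid], trial, window)
            rates[i, j] = ws.count / window.duration
    return RateMatrix(
        unit_ids=unit_ids,
        trial_ids=[int(t["trial_id"]) for t in trial_records],
        rates=rates,
        window=window,
    )


@dataclass
class InclusionReport:
    """Audit record of every filter applied to one unit."""

    unit_id: str
    cell_class: str
    passed_isi: bool
    passed_lratio: bool
    mean_rate_fixed_delay: float
    mean_rate_random_initial4: float
    included: bool
    reasons: List[str] = field(default_factory=list)


def apply_inclusion(
    units: Mapping[str, UnitSpikeSet],
    rate_fixed: RateMatrix,
    rate_random: RateMatrix,
    threshold: float = DEFAULT_RATE_THRESHOLD_HZ,
) -> tuple[List[str], List[InclusionReport]]:
    """Delay-period inclusion filter.

    A unit is included iff it is a putative pyramidal cell, passes the
    quality screen, and its mean delay-period rate is >= ``threshold`` in
    BOTH the fixed-delay matrix and the initial-4-s random-delay matrix.
    """
    if set(rate_fixed.unit_ids) != set(rate_random.unit_ids):
        only = set(rate_fixed.unit_ids) ^ set(rate_random.unit_ids)
        raise ValueError(f"rate matrices cover different units: {sorted(only)}")
    mean_fixed = dict(zip(rate_fixed.unit_ids, rate_fixed.mean_rates()))
    mean_random = dict(zip(rate_random.unit_ids, rate_random.mean_rates()))

    included: List[str] = []
    reports: List[InclusionReport] = []
    for uid in rate_fixed.unit_ids:
        unit = units[uid]
        cell_class = classify_unit(unit.mean_rate, unit.spike_width)
        passed_isi = unit.min_isi >= MIN_ISI_MS
        passed_lratio = unit.l_ratio is None or unit.l_ratio < MAX_L_RATIO
        reasons = []
        if cell_class != "pyramidal":
            reasons.append("not_pyramidal")
        if not passed_isi:
            reasons.append("isi_violation")
        if not passed_lratio:
            reasons.append("l_ratio")
        if not mean_fixed[uid] >= threshold:
            reasons.append("rate_fixed_below_threshold")
        if not mean_random[uid] >= threshold:
            reasons.append("rate_random_below_threshold")
        ok = not reasons
        if ok:
            included.append(uid)
        reports.append(
            InclusionReport(
                unit_id=uid,
                cell_class=cell_class,
                passed_isi=passed_isi,
                passed_lratio=passed_lratio,
                mean_rate_fixed_delay=float(mean_fixed[uid]),
                mean_rate_random_initial4=float(mean_random[uid]),
                included=ok,
                reasons=reasons,
            )
        )
    return included, reports


def inclusion_report_frame(reports: Sequence[InclusionReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        d = r.__dict__.copy()
        d["reasons"] = ";".join(d["reasons"])
        rows.append(d)
    return pd.DataFrame(rows)
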