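"""Shared data model and tabular I/O for delayed match-to-sample sessions.

The on-disk representation is three UTF-8 CSV files:

``trials.csv``
    One row per trial with behavioral metadata and event times on a
    trial-relative clock (sample-cue onset at t = 0, delay onset at 2 s).
``spikes.csv``
    Long format, one row per spike: ``unit_id, trial_id, spike_time_s``.
    Spike times are on the same trial clock and may be negative (spikes
    emitted during the preceding inter-trial interval).
``units.csv``
    One row per unit with session-wide scalars used for classification
    and quality screening.

All analysis windows are half-open ``[start, end)`` so that windows tiling
an interval partition its spikes exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "AnalysisWindow",
    "UnitSpikeSet",
    "ValidationError",
    "SchemaError",
    "WindowedSpikes",
    "TRIAL_COLUMNS",
    "UNIT_COLUMNS",
    "SPIKE_COLUMNS",
    "validate_trials",
    "load_dataset",
    "write_dataset",
    "window_spikes",
]

#: Sample phase duration in seconds; delay onset on the trial clock.
SAMPLE_PHASE_S = 2.0

TRIAL_COLUMNS = [
    "session_id",
    "trial_id",
    "condition",
    "sample",
    "choice",
    "correct",
    "delay_duration",
    "t_cue_on",
    "t_delay_on",
    "t_delay_off",
    "iti_before",
]

UNIT_COLUMNS = ["unit_id", "session_id", "mean_rate", "spike_width", "l_ratio", "min_isi"]

SPIKE_COLUMNS = ["unit_id", "trial_id", "spike_time_s"]

CONDITIONS = ("fixed", "random")
SIDES = ("L", "R")


class SchemaError(ValueError):
    """A file is missing required columns or has an unreadable layout."""


class ValidationError(ValueError):
    """Loaded data violate a declared invariant; message names the row/unit."""


@dataclass(frozen=True)
class AnalysisWindow:
    """Half-open time window ``[start, end)`` relative to an alignment event.

    alignment is one of ``cue_on`` (t = 0 on the trial clock), ``delay_on``
    or ``delay_off``.
    """

    alignment: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.alignment not in ("cue_on", "delay_on", "delay_off"):
            raise ValueError(f"unknown alignment {self.alignment!r}")
        if not self.end > self.start:
            raise ValueError(f"window end must exceed start: [{self.start}, {self.end})")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class UnitSpikeSet:
    """Per-unit spike timestamps (trial clock) plus waveform summary scalars."""

    unit_id: str
    session_id: str
    spikes: Dict[int, np.ndarray] = field(default_factory=dict)
    mean_rate: float = 0.0          # Hz, session-wide
    spike_width: float = 300.0      # microseconds
    l_ratio: Optional[float] = None # dimensionless, pass-through from sorting
    min_isi: float = np.inf         # milliseconds, over all trials

    def trial_spikes(self, trial_id: int) -> np.ndarray:
        return self.spikes.get(trial_id, np.empty(0))

    def validate(self) -> None:
        if not self.mean_rate >= 0:
            raise ValidationError(f"unit {self.unit_id}: mean_rate must be >= 0")
        if not self.spike_width > 0:
            raise ValidationError(f"unit {self.unit_id}: spike_width must be > 0")
        for trial_id, times in self.spikes.items():
            if times.size > 1 and not np.all(np.diff(times) > 0):
                raise ValidationError(
                    f"unit {self.unit_id}, trial {trial_id}: spike times not strictly increasing"
                )

    @staticmethod
    def compute_min_isi_ms(spikes: Mapping[int, np.ndarray]) -> float:
        """Smallest inter-spike interval across trials, in milliseconds."""
        best = np.inf
        for times in spikes.values():
            if times.size > 1:
                best = min(best, float(np.min(np.diff(times))) * 1000.0)
        return best


@dataclass(frozen=True)
class WindowedSpikes:
    """Aligned spikes of one unit in one trial's analysis window."""

    count: int
    times: np.ndarray
    valid: bool = True  # False when the window falls outside the trial record


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Check TrialTable invariants; raise ValidationError naming offending rows."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise SchemaError(f"trials table missing columns: {missing}")
    for row_label, row in trials.iterrows():
        where = f"trials row {row_label} (trial_id={row['trial_id']})"
        if row["condition"] not in CONDITIONS:
            raise ValidationError(f"{where}: unknown condition {row['condition']!r}")
        if row["sample"] not in SIDES or row["choice"] not in SIDES:
            raise ValidationError(f"{where}: sample/choice must be L or R")
        if abs(row["t_cue_on"]) > 1e-9:
            raise ValidationError(f"{where}: t_cue_on must be 0 on the trial clock")
        if abs(row["t_delay_on"] - SAMPLE_PHASE_S) > 1e-9:
            raise ValidationError(f"{where}: t_delay_on must equal {SAMPLE_PHASE_S}")
        if abs(row["t_delay_off"] - (row["t_delay_on"] + row["delay_duration"])) > 1e-6:
            raise ValidationError(f"{where}: t_delay_off != t_delay_on + delay_duration")
        d = row["delay_duration"]
        if row["condition"] == "fixed" and abs(d - 4.0) > 1e-9:
            raise ValidationError(f"{where}: fixed condition requires delay_duration = 4.0")
        if row["condition"] == "random" and not (1.0 <= d <= 7.0):
            raise ValidationError(f"{where}: random delay_duration {d} outside [1, 7]")
        if bool(row["correct"]) != (row["sample"] == row["choice"]):
            raise ValidationError(f"{where}: correct flag inconsistent with sample/choice")
    out = trials.copy()
    out["correct"] = out["correct"].astype(bool)
    out["trial_id"] = out["trial_id"].astype(int)
    return out


def _read_csv(path: Path, required: List[str], label: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{label} file {path}: missing columns {missing}")
    return df


def load_dataset(
    spikes_path, trials_path, units_path
) -> tuple[Dict[str, UnitSpikeSet], pd.DataFrame]:
    """Load and validate a session from the three CSV files.

    Returns ``(units, trials)`` where ``units`` maps unit_id to
    :class:`UnitSpikeSet` and ``trials`` is the validated TrialTable.
    """
    trials = validate_trials(_read_csv(Path(trials_path), TRIAL_COLUMNS, "trials"))
    units_df = _read_csv(Path(units_path), UNIT_COLUMNS, "units")
    spikes_df = _read_csv(Path(spikes_path), SPIKE_COLUMNS, "spikes")

    units: Dict[str, UnitSpikeSet] = {}
    for _, row in units_df.iterrows():
        l_ratio = row["l_ratio"]
        units[str(row["unit_id"])] = UnitSpikeSet(
            unit_id=str(row["unit_id"]),
            session_id=str(row["session_id"]),
            mean_rate=float(row["mean_rate"]),
            spike_width=float(row["spike_width"]),
            l_ratio=None if pd.isna(l_ratio) else float(l_ratio),
            min_isi=float(row["min_isi"]),
        )
    known_trials = set(trials["trial_id"].tolist())
    for (unit_id, trial_id), group in spikes_df.groupby(["unit_id", "trial_id"], sort=True):
        unit_id = str(unit_id)
        if unit_id not in units:
            raise ValidationError(f"spikes file references unknown unit {unit_id!r}")
        if int(trial_id) not in known_trials:
            raise ValidationError(
                f"spikes file references unknown trial {trial_id} (unit {unit_id})"
            )
        units[unit_id].spikes[int(trial_id)] = np.sort(
            group["spike_time_s"].to_numpy(dtype=float)
        )
    for unit in units.values():
        unit.validate()
    return units, trials


def write_dataset(units: Mapping[str, UnitSpikeSet], trials: pd.DataFrame, out_dir) -> Dict[str, Path]:
    """Write the three CSVs; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "trials": out / "trials.csv",
        "units": out / "units.csv",
        "spikes": out / "spikes.csv",
    }
    trials[TRIAL_COLUMNS].to_csv(paths["trials"], index=False)

    unit_rows = []
    spike_rows = []
    for unit_id in sorted(units):
        u = units[unit_id]
        unit_rows.append(
            {
                "unit_id": u.unit_id,
                "session_id": u.session_id,
                "mean_rate": u.mean_rate,
                "spike_width": u.spike_width,
                "l_ratio": u.l_ratio if u.l_ratio is not None else np.nan,
                "min_isi": u.min_isi,
            }
        )
        for trial_id in sorted(u.spikes):
            for t in u.spikes[trial_id]:
                spike_rows.append((u.unit_id, trial_id, t))
    pd.DataFrame(unit_rows, columns=UNIT_COLUMNS).to_csv(paths["units"], index=False)
    pd.DataFrame(spike_rows, columns=SPIKE_COLUMNS).to_csv(paths["spikes"], index=False)
    return paths


def alignment_time(trial: Mapping, alignment: str) -> float:
    """Trial-clock time of the window alignment event."""
    if alignment == "cue_on":
        return float(trial["t_cue_on"])
    if alignment == "delay_on":
        return float(trial["t_delay_on"])
    if alignment == "delay_off":
        return float(trial["t_delay_off"])
    raise ValueError(f"unknown alignment {alignment!r}")


def window_spikes(unit: UnitSpikeSet, trial: Mapping, window: AnalysisWindow) -> WindowedSpikes:
    """Aligned spike times of ``unit`` in ``trial`` restricted to ``window``.

    Returned times are ``t_spike - t_event`` filtered to the half-open
    interval ``[start, end)``. When the window reaches before the recorded
    trial span (offset alignment on delays shorter than the window) the
    result is empty and flagged ``valid=False``.
    """
    t_event = alignment_time(trial, window.alignment)
    # trial record spans [-iti_before, t_delay_off + choice]; only the left
    # edge can truncate an offset-aligned window on short delays
    if t_event + window.start < -float(trial.get("iti_before", 0.0)) - 1e-9:
        return WindowedSpikes(count=0, times=np.empty(0), valid=False)
    times = unit.trial_spikes(int(trial["trial_id"])) - t_event
    sel = times[(times >= window.start) & (times < window.end)]
    return WindowedSpikes(count=int(sel.size), times=sel, valid=True)
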