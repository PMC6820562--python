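"""Synthetic delayed match-to-sample sessions with ground-truth tuning.

Emulates the structure of head-fixed mouse recordings in the task: a 2-s
sample phase, a delay that is either fixed at 4 s or drawn uniformly from
1-7 s, a choice phase, and an inter-trial interval drawn uniformly from
0-10 s. Single units fire as inhomogeneous Poisson processes whose rate
functions carry one of three delay-period codes:

``sequential``
    A Gaussian bump in time at ``tuning_center`` seconds after delay onset
    with width ``tuning_width`` (std), riding on the baseline.
``persistent``
    A constant rate elevation throughout the delay.
``untuned``
    Constant baseline rate.

Sample selectivity (``selectivity_gain`` on preferred-sample trials) and
delay-condition modulation (``condition_gain`` on random-delay trials) are
multiplicative, so downstream scale-invariant statistics are exercised.
Ground truth is returned for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from ._rng import substream as _substream
from .io_core import (
    SAMPLE_PHASE_S,
    TRIAL_COLUMNS,
    UnitSpikeSet,
    validate_trials,
    write_dataset,
)

__all__ = [
    "NeuronSpec",
    "SimConfig",
    "rate_function",
    "sample_spikes",
    "generate_trials",
    "generate_session",
    "write_session",
]

CHOICE_PHASE_S = 2.0
REFRACTORY_S = 0.002  # absolute refractory period imposed on generated trains


@dataclass(frozen=True)
class NeuronSpec:
    """Ground-truth tuning of one simulated unit."""

    unit_id: str
    cell_class: str = "pyramidal"       # pyramidal | interneuron
    code_type: str = "untuned"          # sequential | persistent | untuned
    baseline_rate: float = 2.0          # Hz
    peak_gain: float = 0.0              # dimensionless >= 0
    tuning_center: Optional[float] = None  # s after delay onset (sequential)
    tuning_width: Optional[float] = None   # s, std of the bump (sequential)
    preferred_sample: str = "none"      # L | R | none
    selectivity_gain: float = 1.0       # rate multiplier on preferred trials
    condition_gain: float = 1.0         # rate multiplier on random-delay trials
    spike_width: float = 300.0          # microseconds

    def __post_init__(self) -> None:
        if self.baseline_rate <= 0:
            raise ValueError(f"{self.unit_id}: baseline_rate must be > 0")
        if self.code_type == "sequential":
            if self.tuning_center is None or not (0.0 <= self.tuning_center <= 7.0):
                raise ValueError(f"{self.unit_id}: tuning_center must lie in [0, 7] s")
            if self.tuning_width is None or self.tuning_width <= 0:
                raise ValueError(f"{self.unit_id}: tuning_width must be > 0")


@dataclass
class SimConfig:
    """Session layout and population composition.

    Trial counts default to the task's ~83 trials per delay condition per
    day; choice accuracy defaults to the trained-animal range (85%).
    """

    n_sequential: int = 20
    n_persistent: int = 5
    n_untuned: int = 5
    n_interneurons: int = 5
    n_trials_per_condition: int = 83
    p_correct: float = 0.85
    delay_range: Tuple[float, float] = (1.0, 7.0)
    iti_range: Tuple[float, float] = (0.0, 10.0)
    seed: int = 0
    session_id: str = "sim-000"
    # population parameter ranges (drawn per unit)
    baseline_range: Tuple[float, float] = (0.5, 2.0)
    peak_gain_range: Tuple[float, float] = (2.0, 6.0)
    persistent_gain_range: Tuple[float, float] = (0.5, 1.5)
    tuning_width_range: Tuple[float, float] = (0.2, 0.6)
    selectivity_gain_range: Tuple[float, float] = (1.0, 1.6)
    condition_gain_range: Tuple[float, float] = (0.8, 1.3)
    frac_selective: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_correct <= 1.0:
            raise ValueError("p_correct must be in [0, 1]")
        if self.n_trials_per_condition < 1:
            raise ValueError("n_trials_per_condition must be >= 1")


def rate_function(spec: NeuronSpec, trial: Mapping) -> Callable[[np.ndarray], np.ndarray]:
    """Firing rate (Hz) as a function of trial-clock time for one trial.

    Gains compose multiplicatively: the condition gain applies on
    random-delay trials, the selectivity gain when the trial's sample
    matches the preferred one. The sequential bump is anchored to delay
    onset; the persistent elevation spans exactly the delay period.
    """
    g = spec.baseline_rate
    if trial["condition"] == "random":
        g *= spec.condition_gain
    g_sel = 1.0
    if spec.preferred_sample != "none" and trial["sample"] == spec.preferred_sample:
        g_sel = spec.selectivity_gain
    t_on = float(trial["t_delay_on"])
    t_off = float(trial["t_delay_off"])

    if spec.code_type == "sequential":
        c, w = spec.tuning_center, spec.tuning_width

        def rate(t: np.ndarray) -> np.ndarray:
            bump = spec.peak_gain * np.exp(-((np.asarray(t, float) - t_on - c) ** 2) / (2 * w**2))
            return g * g_sel * (1.0 + bump)

    elif spec.code_type == "persistent":

        def rate(t: np.ndarray) -> np.ndarray:
            t = np.asarray(t, float)
            in_delay = (t >= t_on) & (t < t_off)
            return np.where(in_delay, g * g_sel * (1.0 + spec.peak_gain), g)

    elif spec.code_type == "untuned":
        # untuned units carry no task modulation at all: constant baseline
        def rate(t: np.ndarray) -> np.ndarray:
            return np.full_like(np.asarray(t, float), spec.baseline_rate)

    else:
        raise ValueError(f"unknown code_type {spec.code_type!r}")
    return rate


def rate_max(spec: NeuronSpec) -> float:
    """Upper bound on the rate function over any trial (thinning envelope)."""
    top = spec.baseline_rate * max(spec.condition_gain, 1.0) * max(spec.selectivity_gain, 1.0)
    if spec.code_type in ("sequential", "persistent"):
        top *= 1.0 + spec.peak_gain
    return top


def sample_spikes(
    rate_fn: Callable[[np.ndarray], np.ndarray],
    duration: float,
    rng: np.random.Generator,
    r_max: float,
    t_start: float = 0.0,
) -> np.ndarray:
    """Inhomogeneous Poisson spike train on [t_start, t_start + duration).

    Thinning: draw a homogeneous Poisson process at ``r_max`` and keep each
    event with probability ``rate(t) / r_max``. Returns sorted times.
    """
    if r_max <= 0 or duration <= 0:
        return np.empty(0)
    n = rng.poisson(r_max * duration)
    if n == 0:
        return np.empty(0)
    candidates = np.sort(rng.uniform(t_start, t_start + duration, size=n))
    accept = rng.uniform(0.0, 1.0, size=n) < np.asarray(rate_fn(candidates)) / r_max
    return candidates[accept]


def enforce_refractory(spikes: np.ndarray, refractory: float = REFRACTORY_S) -> np.ndarray:
    """Drop spikes closer than ``refractory`` to their predecessor.

    Real neurons cannot fire twice within the absolute refractory period,
    and the cluster-quality screen rejects units with any inter-spike
    interval under 2 ms, so generated trains respect it. The dead-time
    bias on rates is r * refractory (under 1% below ~5 Hz).
    """
    if spikes.size < 2:
        return spikes
    keep = [0]
    last = spikes[0]
    for i in range(1, spikes.size):
        if spikes[i] - last >= refractory:
            keep.append(i)
            last = spikes[i]
    return spikes[keep]


def generate_trials(cfg: SimConfig) -> pd.DataFrame:
    """Trial table for one simulated day: one fixed and one random block."""
    rng = _substream(cfg.seed, "trials")
    rows = []
    trial_id = 0
    for condition in ("fixed", "random"):
        for _ in range(cfg.n_trials_per_condition):
            if condition == "fixed":
                delay = 4.0
            else:
                delay = float(rng.uniform(*cfg.delay_range))
            sample = "L" if rng.uniform() < 0.5 else "R"
            if rng.uniform() < cfg.p_correct:
                choice = sample
            else:
                choice = "R" if sample == "L" else "L"
            rows.append(
                {
                    "session_id": cfg.session_id,
                    "trial_id": trial_id,
                    "condition": condition,
                    "sample": sample,
                    "choice": choice,
                    "correct": sample == choice,
                    "delay_duration": delay,
                    "t_cue_on": 0.0,
                    "t_delay_on": SAMPLE_PHASE_S,
                    "t_delay_off": SAMPLE_PHASE_S + delay,
                    "iti_before": float(rng.uniform(*cfg.iti_range)),
                }
            )
            trial_id += 1
    return validate_trials(pd.DataFrame(rows, columns=TRIAL_COLUMNS))


def _draw_specs(cfg: SimConfig) -> List[NeuronSpec]:
    specs: List[NeuronSpec] = []
    counts = [
        ("sequential", cfg.n_sequential),
        ("persistent", cfg.n_persistent),
        ("untuned", cfg.n_untuned),
    ]
    idx = 0
    for code_type, n in counts:
        for _ in range(n):
            unit_id = f"u{idx:04d}"
            rng = _substream(cfg.seed, "spec", unit_id)
            selective = code_type != "untuned" and rng.uniform() < cfg.frac_selective
            specs.append(
                NeuronSpec(
                    unit_id=unit_id,
                    cell_class="pyramidal",
                    code_type=code_type,
                    baseline_rate=float(rng.uniform(*cfg.baseline_range)),
                    peak_gain=float(
                        rng.uniform(*cfg.peak_gain_range)
                        if code_type == "sequential"
                        else rng.uniform(*cfg.persistent_gain_range)
                        if code_type == "persistent"
                        else 0.0
                    ),
                    tuning_center=float(rng.uniform(0.2, 3.8))
                    if code_type == "sequential"
                    else None,
                    tuning_width=float(rng.uniform(*cfg.tuning_width_range))
                    if code_type == "sequential"
                    else None,
                    preferred_sample=("L" if rng.uniform() < 0.5 else "R")
                    if selective
                    else "none",
                    selectivity_gain=float(rng.uniform(*cfg.selectivity_gain_range))
                    if selective
                    else 1.0,
                    condition_gain=float(rng.uniform(*cfg.condition_gain_range)),
                    # pyramidal: broad waveforms, clear of the 254 us boundary
                    spike_width=float(np.clip(rng.normal(297.1, 32.6), 262.0, 420.0)),
                )
            )
            idx += 1
    for _ in range(cfg.n_interneurons):
        unit_id = f"u{idx:04d}"
        rng = _substream(cfg.seed, "spec", unit_id)
        specs.append(
            NeuronSpec(
                unit_id=unit_id,
                cell_class="interneuron",
                code_type="untuned",
                # fast-spiking: high rate, narrow waveform well below 254 us
                baseline_rate=float(rng.uniform(9.5, 18.0)),
                condition_gain=1.0,
                spike_width=float(np.clip(rng.normal(240.0, 10.0), 200.0, 248.0)),
            )
        )
        idx += 1
    return specs


def generate_session(
    cfg: SimConfig, specs: Optional[List[NeuronSpec]] = None
) -> Tuple[Dict[str, UnitSpikeSet], pd.DataFrame, List[NeuronSpec]]:
    """Simulate a full session: trials, spikes for every unit, ground truth.

    Spikes are generated from ``-iti_before`` (preceding inter-trial
    interval, used by the pre-stimulus control) through the choice phase.
    """
    trials = generate_trials(cfg)
    if specs is None:
        specs = _draw_specs(cfg)
    units: Dict[str, UnitSpikeSet] = {}
    for spec in specs:
        r_max = rate_max(spec)
        spikes: Dict[int, np.ndarray] = {}
        for trial in trials.to_dict("records"):
            rng = _substream(cfg.seed, "spikes", spec.unit_id, trial["trial_id"])
            t0 = -float(trial["iti_before"])
            t1 = float(trial["t_delay_off"]) + CHOICE_PHASE_S
            fn = rate_function(spec, trial)
            spikes[int(trial["trial_id"])] = enforce_refractory(
                sample_spikes(fn, t1 - t0, rng, r_max, t_start=t0)
            )
        total_time = float(
            np.sum(trials["iti_before"] + trials["t_delay_off"] + CHOICE_PHASE_S)
        )
        n_spikes = sum(s.size for s in spikes.values())
        units[spec.unit_id] = UnitSpikeSet(
            unit_id=spec.unit_id,
            session_id=cfg.session_id,
            spikes=spikes,
            mean_rate=n_spikes / total_time,
            spike_width=spec.spike_width,
            l_ratio=float(_substream(cfg.seed, "lratio", spec.unit_id).uniform(0.005, 0.05)),
            min_isi=UnitSpikeSet.compute_min_isi_ms(spikes),
        )
    return units, trials, specs


def merge_sessions(
    sessions: List[Tuple[Dict[str, UnitSpikeSet], pd.DataFrame]]
) -> Tuple[Dict[str, UnitSpikeSet], pd.DataFrame]:
    """Combine independently simulated sessions into one dataset.

    Trial ids are reindexed to be globally unique; each unit keeps its own
    session_id, so session-aware analyses (decoding eligibility) treat the
    result as a pseudo-population pooled across recording days. Unit ids
    and session ids must be unique across the inputs.
    """
    all_units: Dict[str, UnitSpikeSet] = {}
    frames = []
    offset = 0
    seen_sessions = set()
    for units, trials in sessions:
        sids = set(trials["session_id"])
        if sids & seen_sessions:
            raise ValueError(f"duplicate session ids: {sorted(sids & seen_sessions)}")
        seen_sessions |= sids
        t = trials.copy()
        t["trial_id"] = t["trial_id"] + offset
        frames.append(t)
        for uid, u in units.items():
            if uid in all_units:
                raise ValueError(f"duplicate unit id {uid!r} across sessions")
            all_units[uid] = UnitSpikeSet(
                unit_id=u.unit_id,
                session_id=u.session_id,
                spikes={tid + offset: s for tid, s in u.spikes.items()},
                mean_rate=u.mean_rate,
                spike_width=u.spike_width,
                l_ratio=u.l_ratio,
                min_isi=u.min_isi,
            )
        offset += int(trials["trial_id"].max()) + 1
    merged = pd.concat(frames, ignore_index=True)
    return all_units, merged


def write_session(cfg: SimConfig, out_dir) -> Dict[str, Path]:
    """Generate a session and write the three data CSVs plus ground_truth.csv."""
    units, trials, specs = generate_session(cfg)
    paths = write_dataset(units, trials, out_dir)
    gt = pd.DataFrame([asdict(s) for s in specs])
    paths["ground_truth"] = Path(out_dir) / "ground_truth.csv"
    gt.to_csv(paths["ground_truth"], index=False)
    return paths
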