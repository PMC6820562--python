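"""Pseudo-population decoding of sample identity.

Neurons recorded in different sessions are pooled into a pseudo-population:
for each neuron, 15 left-sample and 15 right-sample correct trials are
drawn at random without replacement, and pseudo-trial j of a class stacks
each neuron's j-th draw as if recorded simultaneously. Sample identity is
then decoded with linear discriminant analysis under a shared diagonal
covariance (neurons treated as independent, equal priors) and scored by
leave-one-out cross-validation over the 30 pseudo-trials. The whole
procedure (neuron draw + trial draw + LOOCV) is repeated ``n_repeats``
times; accuracy is reported as mean +/- SEM across repeats.

Eligibility of a neuron for decoding requires:

1. its session has >= 15 correct trials of each sample class (after any
   delay-length filtering the analysis window implies);
2. mean firing rate >= 0.5 Hz over the full 4-s delay window under the
   relevant alignment;
3. for sliding-window analyses, fewer than 15 zero-spike trials per class
   in every 2-s window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._rng import substream
from .io_core import AnalysisWindow, UnitSpikeSet, window_spikes
from .unit_selection import select_trials

__all__ = [
    "PseudoPopulation",
    "DecodingResult",
    "DECODE_MODES",
    "select_decoding_units",
    "build_pseudopopulation",
    "diag_lda_loocv",
    "decode_sweep",
    "sweep_windows",
]

N_PER_CLASS = 15
VARIANCE_FLOOR = 1e-6  # Hz^2, applied when a training fold has zero pooled variance
MIN_RATE_HZ = 0.5
CLASSES = ("L", "R")

DECODE_MODES = (
    "sliding_2s_step0.1_onset",
    "sliding_2s_step0.1_offset",
    "nonoverlap_2s",
    "full_4s_ensemble_curve",
    "prestim_1s",
)


def sweep_windows(mode: str) -> List[AnalysisWindow]:
    """Analysis windows for each decoding mode.

    Onset-aligned sliding windows advance a 2-s window in 0.1-s steps from
    2 s before delay onset (covering the sample phase) to the end of the
    4-s delay; offset-aligned windows cover the last 4 s of the delay.
    """
    if mode == "sliding_2s_step0.1_onset":
        starts = np.round(np.arange(-2.0, 2.0 + 1e-9, 0.1), 10)
        return [AnalysisWindow("delay_on", s, s + 2.0) for s in starts]
    if mode == "sliding_2s_step0.1_offset":
        starts = np.round(np.arange(-4.0, -2.0 + 1e-9, 0.1), 10)
        return [AnalysisWindow("delay_off", s, s + 2.0) for s in starts]
    if mode == "nonoverlap_2s":
        return [AnalysisWindow("delay_on", 0.0, 2.0), AnalysisWindow("delay_on", 2.0, 4.0)]
    if mode == "full_4s_ensemble_curve":
        return [AnalysisWindow("delay_on", 0.0, 4.0)]
    if mode == "prestim_1s":
        return [AnalysisWindow("cue_on", -1.0, 0.0)]
    raise ValueError(f"unknown decoding mode {mode!r}; expected one of {DECODE_MODES}")


def _mode_trial_rule(mode: str) -> str:
    return "correct_iti_gt2" if mode == "prestim_1s" else "correct_and_delay_ge4"


def _full_window(mode: str) -> AnalysisWindow:
    """Window used for the 0.5-Hz rate criterion under the mode's alignment."""
    if mode == "sliding_2s_step0.1_offset":
        return AnalysisWindow("delay_off", -4.0, 0.0)
    return AnalysisWindow("delay_on", 0.0, 4.0)


@dataclass
class EligibleUnit:
    unit_id: str
    trials_L: List[int]  # candidate trial ids per class, original order
    trials_R: List[int]


def select_decoding_units(
    units: Mapping[str, UnitSpikeSet],
    trials: pd.DataFrame,
    condition: str,
    mode: str,
    included_unit_ids: Optional[Sequence[str]] = None,
    n_per_class: int = N_PER_CLASS,
) -> List[EligibleUnit]:
    """Units eligible for decoding under ``mode`` in one delay condition.

    The dataset may pool several recording sessions; every criterion is
    evaluated on the trials of the unit's own session.
    """
    rule = _mode_trial_rule(mode)
    sub = select_trials(trials, condition, rule)
    by_session = {
        str(sid): grp.to_dict("records") for sid, grp in sub.groupby("session_id")
    }
    candidates = sorted(included_unit_ids) if included_unit_ids is not None else sorted(units)

    sliding = mode.startswith("sliding")
    windows = sweep_windows(mode) if sliding else []
    full_win = _full_window(mode)

    out: List[EligibleUnit] = []
    for uid in candidates:
        unit = units[uid]
        records = by_session.get(unit.session_id, [])
        by_class = {c: [t for t in records if t["sample"] == c] for c in CLASSES}
        # criterion 1: enough correct trials of each class in the session
        if any(len(by_class[c]) < n_per_class for c in CLASSES):
            continue
        # criterion 2: mean rate over the full 4-s delay window
        counts = [window_spikes(unit, t, full_win).count for t in records]
        if not np.mean(counts) / full_win.duration >= MIN_RATE_HZ:
            continue
        # criterion 3: sliding analyses require < 15 zero-spike trials per
        # class in every window
        if sliding:
            ok = True
            for win in windows:
                for c in CLASSES:
                    zeros = sum(
                        window_spikes(unit, t, win).count == 0 for t in by_class[c]
                    )
                    if zeros >= n_per_class:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                continue
        out.append(
            EligibleUnit(
                unit_id=uid,
                trials_L=[int(t["trial_id"]) for t in by_class["L"]],
                trials_R=[int(t["trial_id"]) for t in by_class["R"]],
            )
        )
    return out


@dataclass
class PseudoPopulation:
    """Feature tensor (units x 2*n_per_class pseudo-trials x windows, Hz)."""

    unit_ids: List[str]
    features: np.ndarray
    labels: np.ndarray  # "L"/"R" per pseudo-trial
    seed: int


def build_pseudopopulation(
    units: Mapping[str, UnitSpikeSet],
    trials: pd.DataFrame,
    eligible: Sequence[EligibleUnit],
    windows: Sequence[AnalysisWindow],
    seed: int,
    n_per_class: int = N_PER_CLASS,
) -> PseudoPopulation:
    """Draw trials independently per unit and assemble the feature tensor.

    Pseudo-trial j of class c concatenates each unit's j-th drawn trial of
    that class. Reproducible under ``seed``.
    """
    trial_map = {int(t["trial_id"]): t for t in trials.to_dict("records")}
    n_units = len(eligible)
    features = np.zeros((n_units, 2 * n_per_class, len(windows)))
    for i, eu in enumerate(eligible):
        rng = substream(seed, "pseudotrials", eu.unit_id)
        for c_idx, (cls, pool) in enumerate((("L", eu.trials_L), ("R", eu.trials_R))):
            if len(pool) < n_per_class:
                raise ValueError(
                    f"unit {eu.unit_id}: only {len(pool)} correct {cls} trials, "
                    f"need {n_per_class}"
                )
            chosen = rng.choice(len(pool), size=n_per_class, replace=False)
            for j, k in enumerate(chosen):
                trial = trial_map[pool[int(k)]]
                row = c_idx * n_per_class + j
                for w_idx, win in enumerate(windows):
                    ws = window_spikes(units[eu.unit_id], trial, win)
                    features[i, row, w_idx] = ws.count / win.duration
    labels = np.array(["L"] * n_per_class + ["R"] * n_per_class)
    return PseudoPopulation(
        unit_ids=[eu.unit_id for eu in eligible], features=features, labels=labels, seed=seed
    )


def diag_lda_loocv(features: np.ndarray, labels: Sequence[str]) -> float:
    """Leave-one-out accuracy (%) of diagonal-covariance LDA.

    ``features`` is units x pseudo-trials. Each held-out pseudo-trial is
    classified from per-class means and a pooled per-unit variance
    (diagonal covariance shared between classes) fit on the remaining
    trials, with equal priors. Ties break toward class L.
    """
    X = np.asarray(features, float)
    labels = np.asarray(labels)
    n_trials = X.shape[1]
    correct = 0
    for test in range(n_trials):
        train = np.arange(n_trials) != test
        Xtr, ytr = X[:, train], labels[train]
        mus = {}
        pooled_num = np.zeros(X.shape[0])
        pooled_den = 0
        for cls in CLASSES:
            Xc = Xtr[:, ytr == cls]
            mus[cls] = Xc.mean(axis=1)
            pooled_num += ((Xc - mus[cls][:, None]) ** 2).sum(axis=1)
            pooled_den += Xc.shape[1] - 1
        var = pooled_num / max(pooled_den, 1)
        var = np.maximum(var, VARIANCE_FLOOR)
        x = X[:, test]
        scores = {
            cls: float(-0.5 * np.sum((x - mus[cls]) ** 2 / var)) for cls in CLASSES
        }
        pred = "L" if scores["L"] >= scores["R"] else "R"
        if pred == labels[test]:
            correct += 1
    return 100.0 * correct / n_trials


@dataclass
class DecodingResult:
    mode: str
    condition: str
    window_label: str
    window: AnalysisWindow
    ensemble_size: int
    mean_accuracy: float  # %
    sem: float            # % across repeats
    n_repeats: int
    seed: int
    accuracies: np.ndarray  # per-repeat, %


def _window_label(win: AnalysisWindow) -> str:
    return f"{win.alignment}[{win.start:+.1f},{win.end:+.1f})"


def _precompute_rates(
    units: Mapping[str, UnitSpikeSet],
    trials: pd.DataFrame,
    eligible: Sequence[EligibleUnit],
    windows: Sequence[AnalysisWindow],
) -> Dict[str, Dict[str, np.ndarray]]:
    """rates[unit_id][class] -> (n_candidate_trials, n_windows) Hz."""
    trial_map = {int(t["trial_id"]): t for t in trials.to_dict("records")}
    out: Dict[str, Dict[str, np.ndarray]] = {}
    for eu in eligible:
        per_class = {}
        for cls, pool in (("L", eu.trials_L), ("R", eu.trials_R)):
            arr = np.zeros((len(pool), len(windows)))
            for j, tid in enumerate(pool):
                trial = trial_map[tid]
                for w_idx, win in enumerate(windows):
                    arr[j, w_idx] = window_spikes(units[eu.unit_id], trial, win).count / win.duration
            per_class[cls] = arr
        out[eu.unit_id] = per_class
    return out


def decode_sweep(
    units: Mapping[str, UnitSpikeSet],
    trials: pd.DataFrame,
    condition: str,
    mode: str,
    n_repeats: int = 100,
    ensemble_size: int = 90,
    seed: int = 0,
    ensemble_sizes: Optional[Sequence[int]] = None,
    included_unit_ids: Optional[Sequence[str]] = None,
    n_per_class: int = N_PER_CLASS,
) -> List[DecodingResult]:
    """Repeated pseudo-population decoding for one delay condition.

    Per repeat: draw ``ensemble_size`` eligible units without replacement,
    redraw each unit's 15+15 trials, and run diagonal-LDA LOOCV in every
    window of the mode. In ``full_4s_ensemble_curve`` mode the ensemble
    size is swept over ``ensemble_sizes`` instead (one result per size).
    """
    windows = sweep_windows(mode)
    eligible = select_decoding_units(
        units, trials, condition, mode, included_unit_ids, n_per_class
    )
    sizes = list(ensemble_sizes) if ensemble_sizes is not None else [ensemble_size]
    if mode == "prestim_1s" and ensemble_sizes is None:
        sizes = [ensemble_size]
    for size in sizes:
        if size > len(eligible):
            raise ValueError(
                f"ensemble size {size} exceeds {len(eligible)} eligible units"
            )
    rates = _precompute_rates(units, trials, eligible, windows)

    results: List[DecodingResult] = []
    for size in sizes:
        acc = np.zeros((n_repeats, len(windows)))
        for rep in range(n_repeats):
            rng = substream(seed, "ensemble", condition, size, rep)
            chosen = rng.choice(len(eligible), size=size, replace=False)
            feats = np.zeros((size, 2 * n_per_class, len(windows)))
            for i, idx in enumerate(chosen):
                eu = eligible[int(idx)]
                trng = substream(seed, "trials", condition, size, rep, eu.unit_id)
                for c_idx, cls in enumerate(CLASSES):
                    pool = rates[eu.unit_id][cls]
                    pick = trng.choice(pool.shape[0], size=n_per_class, replace=False)
                    feats[i, c_idx * n_per_class : (c_idx + 1) * n_per_class, :] = pool[pick]
            labels = ["L"] * n_per_class + ["R"] * n_per_class
            for w_idx in range(len(windows)):
                acc[rep, w_idx] = diag_lda_loocv(feats[:, :, w_idx], labels)
        for w_idx, win in enumerate(windows):
            a = acc[:, w_idx]
            results.append(
                DecodingResult(
                    mode=mode,
                    condition=condition,
                    window_label=_window_label(win),
                    window=win,
                    ensemble_size=size,
                    mean_accuracy=float(a.mean()),
                    sem=float(a.std(ddof=1) / np.sqrt(len(a))) if len(a) > 1 else 0.0,
                    n_repeats=n_repeats,
                    seed=seed,
                    accuracies=a,
                )
            )
    return results


def results_frame(results: Sequence[DecodingResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mode": r.mode,
                "condition": r.condition,
                "window": r.window_label,
                "alignment": r.window.alignment,
                "start": r.window.start,
                "end": r.window.end,
                "ensemble_size": r.ensemble_size,
                "mean_accuracy_pct": r.mean_accuracy,
                "sem_pct": r.sem,
                "n_repeats": r.n_repeats,
                "seed": r.seed,
            }
            for r in results
        ]
    )
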