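"""End-to-end orchestration: simulate -> classify -> metrics -> decode.

Every stage reads and writes files under the run directory; ``run_all``
records a manifest with the config hash, per-stage output checksums and
timestamps. Output files contain no timestamps, so re-running with the
same config and seed reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .config import DEFAULTS, merge_config
from .io_core import AnalysisWindow, load_dataset
from .sdf_metrics import FlatSDFError, half_duration, normalize_sdf, sdf_for_unit, spike_density
from .selectivity import (
    behavior_summary,
    proportion_chisq,
    responsive_proportions,
    two_way_anova,
    wm_duration,
    wm_duration_summary,
)
from .sequentiality import sequentiality_index
from .synthetic import SimConfig, write_session
from .unit_selection import (
    apply_inclusion,
    inclusion_report_frame,
    rate_matrix,
    select_trials,
)
from .decoding import decode_sweep, results_frame

__all__ = ["RunManifest", "run_all"]

DELAY_WINDOW = AnalysisWindow("delay_on", 0.0, 4.0)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: List[Dict[str, Any]] = field(default_factory=list)

    def record(self, name: str, status: str, outputs: Dict[str, str]) -> None:
        self.stages.append(
            {
                "stage": name,
                "status": status,
                "outputs": outputs,
                "finished_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
            }
        )

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, default=str)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def _condition_trials(trials: pd.DataFrame, condition: str) -> pd.DataFrame:
    """Correct trials of one condition, delay cut to 4 s for random."""
    rule = "correct_and_delay_ge4" if condition == "random" else "correct_only"
    return select_trials(trials, condition, rule)


def run_all(config: Optional[Dict[str, Any]] = None, out_dir=".", log=print) -> RunManifest:
    """Run every stage in dependency order; write summary.json + manifest."""
    cfg = merge_config(DEFAULTS, config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    config_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    manifest = RunManifest(config_hash=config_hash, seed=seed, version=__version__)
    summary: Dict[str, Any] = {"seed": seed, "config_hash": config_hash}
    t_start = time.time()

    def stage(name):
        def wrap(fn):
            if any(s["status"] in ("failed", "skipped") for s in manifest.stages):
                manifest.record(name, "skipped", {})
                return None
            t0 = time.time()
            try:
                outputs = fn() or {}
                manifest.record(
                    name, "ok", {k: _sha256(Path(v)) for k, v in outputs.items()}
                )
                log(f"[delaycode] {name}: ok ({time.time() - t0:.1f}s)")
            except Exception as exc:  # stage failure skips downstream stages
                manifest.record(name, "failed", {"error": str(exc)})
                log(f"[delaycode] {name}: FAILED ({exc})")
            return None

        return wrap

    data_dir = out / "data"
    state: Dict[str, Any] = {}

    @stage("simulate")
    def _simulate():
        sim = SimConfig(seed=seed, **cfg["simulate"])
        paths = write_session(sim, data_dir)
        return {k: str(p) for k, p in paths.items()}

    @stage("load")
    def _load():
        units, trials = load_dataset(
            data_dir / "spikes.csv", data_dir / "trials.csv", data_dir / "units.csv"
        )
        state["units"], state["trials"] = units, trials
        summary["behavior"] = behavior_summary(trials)
        return {}

    @stage("classify")
    def _classify():
        units, trials = state["units"], state["trials"]
        rm_fixed = rate_matrix(units, _condition_trials(trials, "fixed"), DELAY_WINDOW)
        rm_random = rate_matrix(units, _condition_trials(trials, "random"), DELAY_WINDOW)
        included, reports = apply_inclusion(
            units, rm_fixed, rm_random, threshold=cfg["classification"]["rate_threshold_hz"]
        )
        state["included"] = included
        path = out / "inclusion_report.csv"
        inclusion_report_frame(reports).to_csv(path, index=False)
        summary["inclusion"] = {
            "n_units": len(reports),
            "n_pyramidal": sum(r.cell_class == "pyramidal" for r in reports),
            "n_included": len(included),
        }
        return {"inclusion_report": str(path)}

    @stage("sdf_metrics")
    def _sdf():
        units, trials = state["units"], state["trials"]
        sigma, dt = cfg["sdf"]["sigma_s"], cfg["sdf"]["dt_s"]
        rows = []
        means = {}
        for condition in ("fixed", "random"):
            sub = _condition_trials(trials, condition)
            values = []
            for uid in state["included"]:
                try:
                    sdf = normalize_sdf(
                        sdf_for_unit(units[uid], sub, DELAY_WINDOW, sigma=sigma, dt=dt)
                    )
                except FlatSDFError:
                    rows.append(
                        {"unit_id": uid, "condition": condition, "half_duration_s": np.nan,
                         "peak_time_s": np.nan, "censored": True, "note": "flat SDF"}
                    )
                    continue
                hd = half_duration(sdf)
                values.append(hd.value)
                rows.append(
                    {"unit_id": uid, "condition": condition,
                     "half_duration_s": hd.value, "peak_time_s": hd.peak_time,
                     "censored": hd.censored, "note": ""}
                )
            values = np.asarray(values)
            means[condition] = {
                "mean_ms": float(values.mean() * 1000) if values.size else None,
                "sem_ms": float(values.std(ddof=1) / np.sqrt(values.size) * 1000)
                if values.size > 1
                else None,
                "n": int(values.size),
            }
        path = out / "sdf_metrics.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        summary["half_duration"] = means
        return {"sdf_metrics": str(path)}

    @stage("selectivity")
    def _selectivity():
        units, trials = state["units"], state["trials"]
        fixed = _condition_trials(trials, "fixed")
        random_ = _condition_trials(trials, "random")
        both = pd.concat([fixed, random_])
        rm = rate_matrix(units, both, DELAY_WINDOW)
        cond_labels = both["condition"].tolist()
        sample_labels = both["sample"].tolist()
        results = []
        for uid in state["included"]:
            results.append(
                two_way_anova(rm.unit_row(uid), cond_labels, sample_labels, unit_id=uid)
            )
        props = responsive_proportions(results)
        chi2, p = proportion_chisq(props.n_condition, props.n_sample, props.n_testable)
        path = out / "selectivity.csv"
        pd.DataFrame(
            [
                {k: getattr(r, k) for k in (
                    "unit_id", "F_condition", "F_sample", "F_interaction",
                    "p_condition", "p_sample", "p_interaction", "testable")}
                for r in results
            ]
        ).to_csv(path, index=False)
        summary["selectivity"] = {
            "n_testable": props.n_testable,
            "n_condition": props.n_condition,
            "n_sample": props.n_sample,
            "n_interaction": props.n_interaction,
            "frac_condition": props.frac_condition,
            "frac_sample": props.frac_sample,
            "chi2_condition_vs_sample": chi2,
            "chi2_p": p,
            "mean_F_vector": list(props.mean_vector),
        }
        return {"selectivity": str(path)}

    @stage("wm_duration")
    def _wm():
        units, trials = state["units"], state["trials"]
        n_bins = cfg["wm_bins"]["n_bins"]
        bin_s = cfg["wm_bins"]["bin_s"]
        windows = [
            AnalysisWindow("delay_on", i * bin_s, (i + 1) * bin_s) for i in range(n_bins)
        ]
        out_summary = {}
        rows = []
        for condition in ("fixed", "random"):
            sub = _condition_trials(trials, condition)
            labels = sub["sample"].tolist()
            results = []
            for uid in state["included"]:
                bins = np.column_stack(
                    [rate_matrix({uid: units[uid]}, sub, w).rates[0] for w in windows]
                )
                r = wm_duration(bins, labels, unit_id=uid)
                results.append(r)
                rows.append(
                    {"unit_id": uid, "condition": condition,
                     "n_significant_bins": r.n_significant_bins}
                )
            out_summary[condition] = wm_duration_summary(results)
        path = out / "wm_bins.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        summary["wm_duration"] = out_summary
        return {"wm_bins": str(path)}

    @stage("sequentiality")
    def _si():
        units, trials = state["units"], state["trials"]
        si_cfg = cfg["sequentiality"]
        sigma, dt = cfg["sdf"]["sigma_s"], cfg["sdf"]["dt_s"]
        rows = []
        for condition in ("fixed", "random"):
            sub = _condition_trials(trials, condition)
            for trial in sub.to_dict("records"):
                one = sub[sub["trial_id"] == trial["trial_id"]]
                sdfs = {
                    uid: sdf_for_unit(units[uid], one, DELAY_WINDOW, sigma=sigma, dt=dt)
                    for uid in state["included"]
                }
                res = sequentiality_index(
                    sdfs,
                    trial_id=int(trial["trial_id"]),
                    condition=condition,
                    ridge_halfwidth=si_cfg["ridge_halfwidth_s"],
                    n_entropy_bins=si_cfg["n_entropy_bins"],
                )
                if res is not None:
                    rows.append(res.__dict__)
        df = pd.DataFrame(rows)
        path = out / "si.csv"
        df.to_csv(path, index=False)
        summary["sequentiality"] = {
            cond: {
                "mean_si": float(df[df["condition"] == cond]["si"].mean()),
                "n_trials": int((df["condition"] == cond).sum()),
            }
            for cond in ("fixed", "random")
            if (df["condition"] == cond).any()
        }
        return {"si": str(path)}

    if cfg["decoding"]["enabled"]:

        @stage("decoding")
        def _decode():
            units, trials = state["units"], state["trials"]
            dcfg = cfg["decoding"]
            all_results = []
            for condition in ("fixed", "random"):
                all_results += decode_sweep(
                    units,
                    trials,
                    condition,
                    dcfg["mode"],
                    n_repeats=dcfg["n_repeats"],
                    ensemble_size=dcfg["ensemble_size"],
                    seed=seed,
                    included_unit_ids=state["included"],
                    n_per_class=dcfg["n_per_class"],
                )
                if dcfg["prestim"]:
                    all_results += decode_sweep(
                        units,
                        trials,
                        condition,
                        "prestim_1s",
                        n_repeats=dcfg["n_repeats"],
                        ensemble_size=dcfg["prestim_ensemble_size"],
                        seed=seed,
                        included_unit_ids=state["included"],
                        n_per_class=dcfg["n_per_class"],
                    )
            path = out / "decode.csv"
            results_frame(all_results).to_csv(path, index=False)
            summary["decoding"] = [
                {
                    "mode": r.mode,
                    "condition": r.condition,
                    "window": r.window_label,
                    "ensemble_size": r.ensemble_size,
                    "mean_accuracy_pct": r.mean_accuracy,
                    "sem_pct": r.sem,
                }
                for r in all_results
            ]
            return {"decode": str(path)}

    else:
        manifest.record("decoding", "disabled", {})

    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(_jsonable(summary), indent=2, sort_keys=True))
    manifest.record("summary", "ok", {"summary": _sha256(summary_path)})
    manifest_path = out / "manifest.json"
    manifest_path.write_text(manifest.to_json())
    log(f"[delaycode] run complete in {time.time() - t_start:.1f}s -> {summary_path}")
    return manifest
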