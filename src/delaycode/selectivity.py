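"""Per-neuron selectivity statistics and population proportions.

Each analyzed unit gets a two-factor ANOVA on its per-trial delay-period
firing rates with factors delay condition (fixed vs random) and sample
identity (left vs right), including the interaction. Type II sums of
squares are used so unbalanced trial counts across the 2x2 cells do not
privilege either main effect. Population summaries count units with
p < 0.05 per effect; proportions of responsive units are compared with a
Pearson chi-square test (no continuity correction).

Working-memory duration is measured per unit by splitting the 4-s delay
into eight 0.5-s bins and t-testing left vs right sample rates per bin;
the per-unit statistic is the number of significant bins (0-8).

No correction for multiple comparisons is applied across neurons or bins:
the population summaries report raw p < 0.05 proportions, so expect a 5%
false-positive floor on null data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.formula.api import ols

from .io_core import AnalysisWindow, UnitSpikeSet, window_spikes
from .unit_selection import RateMatrix

__all__ = [
    "SelectivityResult",
    "WMDurationResult",
    "two_way_anova",
    "responsive_proportions",
    "proportion_chisq",
    "wm_duration",
    "behavior_summary",
]

ALPHA = 0.05
N_WM_BINS = 8
WM_BIN_S = 0.5


@dataclass
class SelectivityResult:
    unit_id: str
    window_label: str
    F_condition: float
    F_sample: float
    F_interaction: float
    p_condition: float
    p_sample: float
    p_interaction: float
    testable: bool = True

    @property
    def sig_condition(self) -> bool:
        return self.testable and self.p_condition < ALPHA

    @property
    def sig_sample(self) -> bool:
        return self.testable and self.p_sample < ALPHA

    @property
    def sig_interaction(self) -> bool:
        return self.testable and self.p_interaction < ALPHA


def _clean_F_p(ss_effect: float, F: float, p: float) -> tuple[float, float]:
    # statsmodels yields NaN when the residual variance is exactly zero
    if np.isnan(F):
        if ss_effect <= 1e-12:
            return 0.0, 1.0
        return np.inf, 0.0
    return float(F), float(p)


def two_way_anova(
    rates: np.ndarray,
    factor_condition: Sequence[str],
    factor_sample: Sequence[str],
    unit_id: str = "",
    window_label: str = "full_4s",
) -> SelectivityResult:
    """Fixed-effects two-way ANOVA (Type II SS) with interaction.

    One observation per trial. Requires at least two trials in each of the
    four condition x sample cells; otherwise the result is flagged
    untestable and excluded from population proportions.
    """
    df = pd.DataFrame(
        {
            "rate": np.asarray(rates, float),
            "condition": list(factor_condition),
            "sample": list(factor_sample),
        }
    )
    cell_counts = df.groupby(["condition", "sample"], observed=True).size()
    if len(cell_counts) < 4 or cell_counts.min() < 2:
        return SelectivityResult(
            unit_id, window_label, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
            testable=False,
        )
    # identical responses: every sum of squares is 0, so F = 0 by convention
    if np.var(df["rate"].to_numpy()) <= 1e-12 * (1.0 + df["rate"].mean() ** 2):
        return SelectivityResult(unit_id, window_label, 0.0, 0.0, 0.0, 1.0, 1.0, 1.0)
    model = ols("rate ~ C(condition) * C(sample)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    Fc, pc = _clean_F_p(
        table.loc["C(condition)", "sum_sq"],
        table.loc["C(condition)", "F"],
        table.loc["C(condition)", "PR(>F)"],
    )
    Fs, ps = _clean_F_p(
        table.loc["C(sample)", "sum_sq"],
        table.loc["C(sample)", "F"],
        table.loc["C(sample)", "PR(>F)"],
    )
    Fi, pi = _clean_F_p(
        table.loc["C(condition):C(sample)", "sum_sq"],
        table.loc["C(condition):C(sample)", "F"],
        table.loc["C(condition):C(sample)", "PR(>F)"],
    )
    return SelectivityResult(unit_id, window_label, Fc, Fs, Fi, pc, ps, pi)


@dataclass
class ResponsiveProportions:
    n_testable: int
    n_condition: int
    n_sample: int
    n_interaction: int
    frac_condition: float
    frac_sample: float
    frac_interaction: float
    f_pairs: pd.DataFrame          # per-unit (F_condition, F_sample)
    mean_vector: tuple[float, float]  # sample mean of the F pairs


def responsive_proportions(results: Sequence[SelectivityResult]) -> ResponsiveProportions:
    """Counts and fractions of significantly responsive units per effect."""
    testable = [r for r in results if r.testable]
    if not testable:
        raise ValueError("no testable units")
    n = len(testable)
    n_cond = sum(r.sig_condition for r in testable)
    n_samp = sum(r.sig_sample for r in testable)
    n_int = sum(r.sig_interaction for r in testable)
    finite = [r for r in testable if np.isfinite(r.F_condition) and np.isfinite(r.F_sample)]
    f_pairs = pd.DataFrame(
        {
            "unit_id": [r.unit_id for r in finite],
            "F_condition": [r.F_condition for r in finite],
            "F_sample": [r.F_sample for r in finite],
        }
    )
    mean_vec = (
        float(f_pairs["F_condition"].mean()) if len(f_pairs) else np.nan,
        float(f_pairs["F_sample"].mean()) if len(f_pairs) else np.nan,
    )
    return ResponsiveProportions(
        n_testable=n,
        n_condition=n_cond,
        n_sample=n_samp,
        n_interaction=n_int,
        frac_condition=n_cond / n,
        frac_sample=n_samp / n,
        frac_interaction=n_int / n,
        f_pairs=f_pairs,
        mean_vector=mean_vec,
    )


def proportion_chisq(k1: int, k2: int, n: int) -> tuple[float, float]:
    """Pearson chi-square (df=1, no continuity correction) comparing two
    proportions k1/n vs k2/n."""
    if not (0 <= k1 <= n and 0 <= k2 <= n):
        raise ValueError("counts must satisfy 0 <= k <= n")
    table = np.array([[k1, n - k1], [k2, n - k2]], float)
    if np.any(table.sum(axis=0) == 0):
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


@dataclass
class WMDurationResult:
    unit_id: str
    n_significant_bins: int
    bin_p_values: List[float]


def _bin_ttest(a: np.ndarray, b: np.ndarray) -> float:
    """Two-tailed Student t-test; degenerate zero-variance bins resolved by
    comparing means (equal -> p=1, different -> p=0)."""
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(p) if np.isfinite(p) else 1.0


def wm_duration(
    bin_rates: np.ndarray, sample_labels: Sequence[str], unit_id: str = ""
) -> WMDurationResult:
    """Count delay bins with sample-dependent firing for one unit.

    ``bin_rates`` is trials x 8 (0.5-s bins over the 4-s delay window).
    """
    bin_rates = np.asarray(bin_rates, float)
    if bin_rates.shape[1] != N_WM_BINS:
        raise ValueError(f"expected {N_WM_BINS} bins, got {bin_rates.shape[1]}")
    labels = np.asarray(sample_labels)
    left = bin_rates[labels == "L"]
    right = bin_rates[labels == "R"]
    if len(left) < 2 or len(right) < 2:
        raise ValueError("need >= 2 trials per sample for the bin t-tests")
    ps = [_bin_ttest(left[:, b], right[:, b]) for b in range(N_WM_BINS)]
    return WMDurationResult(
        unit_id=unit_id,
        n_significant_bins=int(sum(p < ALPHA for p in ps)),
        bin_p_values=ps,
    )


def wm_duration_summary(results: Sequence[WMDurationResult]) -> Dict[str, object]:
    """Population histogram of significant-bin counts and the fraction of
    units sample-selective in every bin."""
    counts = np.array([r.n_significant_bins for r in results])
    hist = {k: int(np.sum(counts == k)) for k in range(N_WM_BINS + 1)}
    n = len(results)
    n_full = hist[N_WM_BINS]
    any_sig = counts[counts > 0]
    return {
        "histogram": hist,
        "n_units": n,
        "n_all_bins": n_full,
        "pct_all_bins": round(100.0 * n_full / n, 1) if n else np.nan,
        "frac_le3_of_selective": float(np.mean(any_sig <= 3)) if any_sig.size else np.nan,
    }


def behavior_summary(trials: pd.DataFrame) -> Dict[str, object]:
    """% correct per condition and per 1-s delay bin in the random condition.

    Empty strata are reported as missing (NaN), never as 0%.
    """
    out: Dict[str, object] = {}
    for condition in ("fixed", "random"):
        sub = trials[trials["condition"] == condition]
        out[f"pct_correct_{condition}"] = (
            100.0 * sub["correct"].mean() if len(sub) else np.nan
        )
    random_trials = trials[trials["condition"] == "random"]
    per_bin = {}
    for lo in range(1, 7):
        sub = random_trials[
            (random_trials["delay_duration"] >= lo)
            & (random_trials["delay_duration"] < lo + 1)
        ]
        per_bin[f"{lo}-{lo + 1}s"] = 100.0 * sub["correct"].mean() if len(sub) else np.nan
    out["pct_correct_random_by_delay"] = per_bin
    return out
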