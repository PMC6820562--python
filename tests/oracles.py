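"""Independent reference implementations used only by the tests.

These deliberately avoid the code paths they check: the ANOVA oracle works
from explicit design/projection matrices via least squares, and the LDA
oracle evaluates Gaussian class posteriors term by term with scipy.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def glm_two_way_typ2(rates, condition, sample):
    """Type II two-way ANOVA with interaction by explicit model comparison.

    Builds least-squares fits of the nested models {B}, {A}, {A+B},
    {A+B+AB} and converts residual-sum-of-squares differences into F and p
    values against the full-model residual. Sum-to-zero coding.
    """
    y = np.asarray(rates, float)
    a = (np.asarray(condition) == np.asarray(condition)[0]).astype(float) * 2 - 1
    b = (np.asarray(sample) == "L").astype(float) * 2 - 1
    one = np.ones_like(y)

    def rss(*cols):
        X = np.column_stack([one, *cols]) if cols else one[:, None]
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    rss_a = rss(a)
    rss_b = rss(b)
    rss_ab = rss(a, b)
    rss_full = rss(a, b, a * b)
    df_resid = len(y) - 4
    ms_resid = rss_full / df_resid

    out = {}
    for name, ss in (
        ("condition", rss_b - rss_ab),
        ("sample", rss_a - rss_ab),
        ("interaction", rss_ab - rss_full),
    ):
        F = ss / ms_resid
        out[name] = (F, float(stats.f.sf(F, 1, df_resid)))
    return out


def gaussian_posterior_loocv(features, labels):
    """LOOCV accuracy (%) by explicit per-unit Gaussian likelihood products.

    Pooled per-unit variance shared between classes, equal priors, ties to
    class L — the same probabilistic model as diagonal LDA, evaluated
    through scipy's normal pdf instead of discriminant algebra.
    """
    X = np.asarray(features, float)
    labels = np.asarray(labels)
    n = X.shape[1]
    correct = 0
    for test in range(n):
        keep = np.arange(n) != test
        Xtr, ytr = X[:, keep], labels[keep]
        post = {}
        for cls in ("L", "R"):
            Xc = Xtr[:, ytr == cls]
            mu = Xc.mean(axis=1)
            resid = np.concatenate(
                [
                    (Xtr[:, ytr == c] - Xtr[:, ytr == c].mean(axis=1)[:, None])
                    for c in ("L", "R")
                ],
                axis=1,
            )
            var = (resid**2).sum(axis=1) / (Xtr.shape[1] - 2)
            var = np.maximum(var, 1e-6)
            logpdf = stats.norm.logpdf(X[:, test], loc=mu, scale=np.sqrt(var))
            post[cls] = logpdf.sum()
        pred = "L" if post["L"] >= post["R"] else "R"
        correct += pred == labels[test]
    return 100.0 * correct / n


def chisq_by_hand(k1, k2, n):
    """Pearson chi-square on the 2x2 table by direct sum over cells."""
    obs = np.array([[k1, n - k1], [k2, n - k2]], float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    exp = row @ col / obs.sum()
    return float(((obs - exp) ** 2 / exp).sum())
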