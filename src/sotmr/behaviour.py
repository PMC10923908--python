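"""Behavioural summaries, chance-level tests, and brain-behaviour correlation.

The chance-level test picks Student's one-sample t or the Wilcoxon
signed-rank depending on a Shapiro normality gate; the decoding-behaviour
link is a Pearson correlation with a BCa bootstrap confidence interval,
a permutation null for the p value, and Holm correction across the
declared family of tested classifier/metric x behaviour combinations.
Heavier factorial machinery (robust trimmed-means RM-ANOVA) is deliberately
left to established statistical routines; :func:`sotmr.task.score_behaviour`
exports tidy tables shaped for them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


def _pearson_vectorised(a, b, axis=-1):
    am = a - a.mean(axis=axis, keepdims=True)
    bm = b - b.mean(axis=axis, keepdims=True)
    num = (am * bm).sum(axis=axis)
    den = np.sqrt((am**2).sum(axis=axis) * (bm**2).sum(axis=axis))
    return num / den


@dataclass
class ChanceTestResult:
    statistic: float
    p: float
    test: str                  # "t" or "wilcoxon"
    normality_p: float
    degenerate: bool = False


def chance_level_test(accuracies, chance: float = 0.5) -> ChanceTestResult:
    """Test one cell's per-subject accuracies against chance level.

    Shapiro-Wilk at alpha = 0.05 gates the choice between the one-sample
    t-test and the Wilcoxon signed-rank test (two-sided).  A sample sitting
    exactly at chance for every subject is degenerate: flagged, p = 1.
    """
    x = np.asarray(accuracies, dtype=float)
    if x.size < 3:
        raise ValueError("chance-level test needs at least 3 subjects")
    if np.all(x == chance):
        return ChanceTestResult(statistic=0.0, p=1.0, test="degenerate",
                                normality_p=np.nan, degenerate=True)
    if np.ptp(x) == 0:
        # constant but off chance: normality is untestable, fall back to Wilcoxon
        stat, p = stats.wilcoxon(x - chance)
        return ChanceTestResult(float(stat), float(p), "wilcoxon", np.nan)
    norm_p = float(stats.shapiro(x).pvalue)
    if norm_p >= 0.05:
        res = stats.ttest_1samp(x, chance)
        logger.debug("normality ok (p=%.3f): Student t", norm_p)
        return ChanceTestResult(float(res.statistic), float(res.pvalue), "t", norm_p)
    stat, p = stats.wilcoxon(x - chance)
    logger.debug("normality rejected (p=%.3f): Wilcoxon signed-rank", norm_p)
    return ChanceTestResult(float(stat), float(p), "wilcoxon", norm_p)


def holm_correct(p_values) -> np.ndarray:
    """Holm step-down correction; monotone, p_corrected >= p_raw."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted


@dataclass
class CorrelationResult:
    r: float
    ci: tuple[float, float]
    p_raw: float
    p_corrected: float
    n: int
    n_boot: int
    family_size: int
    method: str = "pearson, BCa bootstrap CI, permutation p, Holm family bound"


def correlate_decoding_behaviour(scores, accuracies, n_boot: int = 2000,
                                 seed: int | None = 0, family_size: int = 1) -> CorrelationResult:
    """Pearson correlation between per-subject decoding scores and behaviour.

    CI: bias-corrected accelerated (BCa) bootstrap over paired subject
    resampling — percentile intervals for correlations undercover at
    follow-up-sized cohorts (n~17), BCa restores nominal coverage; when the
    BCa correction is degenerate (e.g. perfectly collinear data) the
    percentile interval of the same bootstrap distribution is used.
    p: permutation null that breaks the pairing by index permutation
    (two-sided on |r|).  ``family_size`` applies the first (most
    conservative) Holm step for the declared family of tested combinations;
    with a single test it is the identity.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(accuracies, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("scores and accuracies must be paired 1-D vectors")
    if x.size < 5:
        raise ValueError("correlation needs at least 5 subjects")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise ValueError("inputs contain NaN/inf")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input; correlation undefined")
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    n = x.size
    r = float(np.corrcoef(x, y)[0, 1])

    rng = np.random.default_rng(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.bootstrap((x, y), _pearson_vectorised, paired=True,
                              n_resamples=n_boot, confidence_level=0.95,
                              method="BCa", random_state=np.random.default_rng(seed))
    lo, hi = res.confidence_interval
    if not (np.isfinite(lo) and np.isfinite(hi)):
        boot = res.bootstrap_distribution
        boot = boot[np.isfinite(boot)]
        lo, hi = np.percentile(boot, [2.5, 97.5])
        logger.info("BCa correction degenerate; reporting percentile interval")
    ci = (float(lo), float(hi))

    count = 0
    for _ in range(n_boot):
        r_perm = np.corrcoef(x, y[rng.permutation(n)])[0, 1]
        if abs(r_perm) >= abs(r):
            count += 1
    p_raw = (1 + count) / (n_boot + 1)
    p_corrected = min(1.0, family_size * p_raw)
    return CorrelationResult(r=r, ci=ci, p_raw=float(p_raw), p_corrected=float(p_corrected),
                             n=n, n_boot=n_boot, family_size=family_size)
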