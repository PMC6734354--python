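"""Paired non-parametric statistics across protocol phases.

The study design is within-subject: every subject contributes one pre-RIC
value (mean of the two baseline segments) and one post-RIC value (mean of
the last reperfusion segment and the post-rest segment) per feature, and
those pairs go into a Wilcoxon signed-rank test at alpha = 0.05.  A second
comparison pairs the per-subject mean over the four occlusion segments with
the mean over the four non-occlusion segments.  Per-subject changes
(post - pre) of two features are correlated with Spearman's rho.

The Wilcoxon implementation drops zero differences, ranks |d| with average
ranks for ties, and reports W = min(W+, W-).  For n <= 25 nonzero pairs the
two-sided p-value is exact — computed from the full null distribution of W+
over all 2^n sign assignments (a rank-sum convolution, valid with tied
ranks) — otherwise a normal approximation with tie and continuity
correction is used.  No multiple-testing correction is applied by default
(``holm=True`` turns it on).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .types import CorrelationResult, TestResult

__all__ = [
    "wilcoxon_signed_rank",
    "exact_wilcoxon_pvalue",
    "compare_pre_post",
    "compare_occlusion",
    "correlate_deltas",
    "assign_subsets",
    "PRE_PHASES",
    "POST_PHASES",
    "OCCLUSION_PHASES",
    "NON_OCCLUSION_PHASES",
    "ANALYSIS_FEATURES",
]

logger = logging.getLogger("richrv")

PRE_PHASES = ("baseline_1", "baseline_2")
POST_PHASES = ("non_occlusion_4", "post_rest")
OCCLUSION_PHASES = tuple(f"occlusion_{k}" for k in range(1, 5))
NON_OCCLUSION_PHASES = tuple(f"non_occlusion_{k}" for k in range(1, 5))

#: the ten features the protocol analysis reports on
ANALYSIS_FEATURES = [
    "mean_rr_ms",
    "median_rr_ms",
    "pnn50",
    "rmssd_ms",
    "nu_lf",
    "nu_hf",
    "lf_hf",
    "sd1_ms",
    "sd2_ms",
    "sd1_sd2",
]

EXACT_N_MAX = 25


def _signed_rank_distribution(ranks2: np.ndarray) -> np.ndarray:
    """Counts of each value of 2*W+ over all sign assignments.

    ``ranks2`` holds the doubled ranks (integers even with average-rank
    ties).  Entry j of the result is the number of sign patterns with
    2*W+ = j; the total is 2^n.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        nxt = counts.copy()
        nxt[r:] += counts[: total + 1 - r]
        counts = nxt
    return counts


def exact_wilcoxon_pvalue(d: np.ndarray) -> tuple[float, float]:
    """Exact two-sided signed-rank p for nonzero differences ``d``.

    Returns (W = min(W+, W-), p).  p = P(W+ <= w or W+ >= T - w) under the
    null of random signs, with w the observed min and T the total rank sum.
    """
    d = np.asarray(d, dtype=float)
    ranks = sp_stats.rankdata(np.abs(d))
    ranks2 = np.rint(2.0 * ranks).astype(np.int64)
    w_plus2 = int(np.rint(2.0 * ranks[d > 0].sum()))
    total2 = int(ranks2.sum())
    w2 = min(w_plus2, total2 - w_plus2)
    counts = _signed_rank_distribution(ranks2)
    n_patterns = 2.0 ** d.size
    p = (counts[: w2 + 1].sum() + counts[total2 - w2 :].sum()) / n_patterns
    return w2 / 2.0, float(min(p, 1.0))


def _approx_wilcoxon_pvalue(d: np.ndarray) -> tuple[float, float]:
    """Normal approximation with tie and continuity correction."""
    n = d.size
    ranks = sp_stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    total = n * (n + 1) / 2.0
    w = min(w_plus, total - w_plus)
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    z = (w - mu + 0.5) / np.sqrt(var)
    return w, float(min(1.0, 2.0 * sp_stats.norm.cdf(z)))


def wilcoxon_signed_rank(
    x: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.05,
    feature: str = "",
    comparison: str = "",
    subset: str = "all",
) -> TestResult:
    """Two-sided paired Wilcoxon signed-rank test on (x, y).

    Zero differences are dropped (Wilcoxon's original treatment); an
    all-zero difference vector raises ``degenerate: no nonzero pairs``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise ValueError("x and y must be 1-d arrays of equal length >= 1")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("degenerate: no nonzero pairs")
    if d.size <= EXACT_N_MAX:
        w, p = exact_wilcoxon_pvalue(d)
    else:
        w, p = _approx_wilcoxon_pvalue(d)
    direction = int(np.sign(np.median(d)))
    return TestResult(
        feature=feature,
        comparison=comparison,
        subset=subset,
        n_pairs=int(d.size),
        statistic=w,
        p_value=p,
        direction=direction,
        significant=bool(p < alpha),
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Cohort-level comparisons


def _subset_frame(cohort: pd.DataFrame, subset: str) -> pd.DataFrame:
    if subset == "all":
        return cohort
    if subset not in ("young", "senior"):
        raise ValueError("subset must be 'all', 'young' or 'senior'")
    return cohort[cohort["subset"] == subset]


def _phase_means(
    cohort: pd.DataFrame, phases: tuple[str, ...], features: list[str]
) -> pd.DataFrame:
    """Per-subject mean of each feature over the given phases.

    Subjects missing any of the phases are excluded (logged), mirroring the
    protocol rule that a subject lacking one time interval leaves the
    paired analysis.
    """
    sub = cohort[cohort["phase"].isin(phases)]
    counts = sub.groupby("subject_id")["phase"].nunique()
    complete = counts[counts == len(phases)].index
    dropped = sorted(set(cohort["subject_id"]) - set(complete))
    if dropped:
        logger.info(
            "excluding %d subject(s) missing phases %s: %s", len(dropped), phases, dropped
        )
    return sub[sub["subject_id"].isin(complete)].groupby("subject_id")[features].mean()


def _paired_tests(
    a: pd.DataFrame,
    b: pd.DataFrame,
    features: list[str],
    comparison: str,
    subset: str,
    alpha: float,
    holm: bool,
) -> list[TestResult]:
    common = a.index.intersection(b.index)
    if len(common) < 2:
        raise ValueError(f"fewer than 2 complete subjects for {comparison!r} ({subset})")
    results: list[TestResult] = []
    for feat in features:
        xa = a.loc[common, feat].to_numpy()
        xb = b.loc[common, feat].to_numpy()
        ok = np.isfinite(xa) & np.isfinite(xb)
        try:
            if ok.sum() < 2:
                raise ValueError("fewer than 2 finite pairs")
            res = wilcoxon_signed_rank(
                xa[ok], xb[ok], alpha=alpha, feature=feat, comparison=comparison, subset=subset
            )
        except ValueError as exc:
            res = TestResult(
                feature=feat,
                comparison=comparison,
                subset=subset,
                n_pairs=int(ok.sum()),
                statistic=float("nan"),
                p_value=float("nan"),
                direction=0,
                significant=False,
                alpha=alpha,
                note=str(exc),
            )
        results.append(res)
    if holm:
        results = _holm_adjust(results, alpha)
    return results


def _holm_adjust(results: list[TestResult], alpha: float) -> list[TestResult]:
    """Holm step-down correction of the significance calls (p left raw)."""
    import dataclasses

    order = sorted(
        (i for i, r in enumerate(results) if np.isfinite(r.p_value)),
        key=lambda i: results[i].p_value,
    )
    m = len(order)
    adjusted = list(results)
    still = True
    for rank, i in enumerate(order):
        thresh = alpha / (m - rank)
        sig = still and results[i].p_value < thresh
        if not sig:
            still = False
        adjusted[i] = dataclasses.replace(results[i], significant=sig)
    return adjusted


def compare_pre_post(
    cohort: pd.DataFrame,
    subset: str = "all",
    features: list[str] | None = None,
    alpha: float = 0.05,
    pre_phases: tuple[str, ...] = PRE_PHASES,
    post_phases: tuple[str, ...] = POST_PHASES,
    holm: bool = False,
) -> list[TestResult]:
    """Wilcoxon pre/post comparison per feature.

    Pre = per-subject mean over the two baseline segments; post = mean over
    the last reperfusion segment and the post-rest segment (both windows are
    10 min realized as two 5-min segments).
    """
    frame = _subset_frame(cohort, subset)
    feats = features if features is not None else ANALYSIS_FEATURES
    post = _phase_means(frame, post_phases, feats)
    pre = _phase_means(frame, pre_phases, feats)
    return _paired_tests(post, pre, feats, "pre_vs_post", subset, alpha, holm)


def compare_occlusion(
    cohort: pd.DataFrame,
    subset: str = "all",
    features: list[str] | None = None,
    alpha: float = 0.05,
    holm: bool = False,
) -> list[TestResult]:
    """Wilcoxon occlusion vs non-occlusion comparison per feature.

    Each subject contributes the mean over its four occlusion segments
    paired with the mean over its four non-occlusion segments.
    """
    frame = _subset_frame(cohort, subset)
    feats = features if features is not None else ANALYSIS_FEATURES
    occ = _phase_means(frame, OCCLUSION_PHASES, feats)
    non = _phase_means(frame, NON_OCCLUSION_PHASES, feats)
    return _paired_tests(occ, non, feats, "occlusion_vs_non_occlusion", subset, alpha, holm)


def correlate_deltas(
    cohort: pd.DataFrame,
    feature_a: str,
    feature_b: str,
    method: str = "spearman",
    pre_phases: tuple[str, ...] = PRE_PHASES,
    post_phases: tuple[str, ...] = POST_PHASES,
) -> CorrelationResult:
    """Correlation between per-subject changes of two features.

    Delta = post - pre with the same aggregation as :func:`compare_pre_post`.
    Spearman's rho by default (the standard non-parametric choice);
    ``method="pearson"`` is available.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    feats = [feature_a, feature_b]
    pre = _phase_means(cohort, pre_phases, feats)
    post = _phase_means(cohort, post_phases, feats)
    common = pre.index.intersection(post.index)
    delta = post.loc[common, feats] - pre.loc[common, feats]
    delta = delta.dropna()
    if len(delta) < 4:
        raise ValueError("need at least 4 subjects with complete pre and post values")
    da = delta[feature_a].to_numpy()
    db = delta[feature_b].to_numpy()
    if np.ptp(da) == 0 or np.ptp(db) == 0:
        raise ValueError("zero variance in the delta vector")
    if method == "spearman":
        rho, p = sp_stats.spearmanr(da, db)
    else:
        rho, p = sp_stats.pearsonr(da, db)
    return CorrelationResult(feature_a, feature_b, len(delta), float(rho), float(p), method)


def assign_subsets(cohort: pd.DataFrame, cutoff_years: float = 60.0) -> pd.DataFrame:
    """Label every row young/senior by strict age cutoff (senior: age > 60)."""
    if cohort["age"].isna().any():
        raise ValueError("every subject needs an age to assign subsets")
    out = cohort.copy()
    out["subset"] = np.where(out["age"] > cutoff_years, "senior", "young")
    return out


def results_frame(results: list[TestResult]) -> pd.DataFrame:
    """Flatten TestResults into the tabular layout used by the reports."""
    return pd.DataFrame(
        [
            {
                "feature": r.feature,
                "comparison": r.comparison,
                "subset": r.subset,
                "n_pairs": r.n_pairs,
                "W": r.statistic,
                "p_value": r.p_value,
                "direction": r.direction,
                "significant": r.significant,
                "note": r.note,
            }
            for r in results
        ]
    )
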