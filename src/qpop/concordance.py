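"""Outcome-level concordance statistics for ex vivo drug-sensitivity screens.

Links per-therapy mean NCV predictions to clinical outcomes (RECIST
PR/SD/PD): ROC discrimination with a Youden-J cutoff, responder 2x2
contingency analysis (odds ratio, Fisher exact, total predictive value),
cohort-level aggregation of top-ranked combinations, one- vs two-drug
correlation, plus the xenograft tumor volume and growth-rate formulas
used for in vivo validation.

Conventions: a clinical *responder* is PR or SD; a predicted (screen-
defined) responder is a case whose therapy mean NCV falls below the NCV
cutoff — lower viability predicts response.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ranking import CombinationRanking

__all__ = [
    "ROCResult",
    "ContingencyResult",
    "CohortAggregate",
    "TTestResult",
    "roc_analysis",
    "contingency_analysis",
    "outcome_proportions",
    "top_combo_frequencies",
    "one_vs_two_drug_correlation",
    "group_mean_comparison",
    "tumor_volume",
    "growth_rate",
]

RESPONDER_CLASSES = frozenset({"PR", "SD"})
RECIST_CLASSES = ("PR", "SD", "PD")


@dataclass(frozen=True)
class ROCResult:
    thresholds: np.ndarray  # candidate NCV cutoffs (midpoints)
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    p_value: float  # two-sided Wilcoxon-Mann-Whitney
    cutoff: float  # NCV maximizing Youden's J
    youden_j: float


@dataclass(frozen=True)
class ContingencyResult:
    """2x2 responder table: rows predicted R/NR, columns clinical PR+SD / PD."""

    a: int  # predicted responder, clinical responder
    b: int  # predicted responder, clinical non-responder
    c: int  # predicted non-responder, clinical responder
    d: int  # predicted non-responder, clinical non-responder
    odds_ratio: float
    or_ci: tuple[float, float]
    fisher_p: float
    tpv: float  # overall accuracy (a + d) / N
    sensitivity: float  # a / (a + c): clinical responders correctly predicted
    specificity: float  # d / (b + d)


def _validate_outcomes(outcomes: pd.DataFrame) -> pd.DataFrame:
    required = {"mean_ncv", "recist"}
    missing = required - set(outcomes.columns)
    if missing:
        raise ValueError(f"outcomes table missing columns: {sorted(missing)}")
    bad = set(outcomes["recist"].unique()) - set(RECIST_CLASSES)
    if bad:
        raise ValueError(f"unknown RECIST classes: {sorted(bad)}; expected {RECIST_CLASSES}")
    if not np.isfinite(outcomes["mean_ncv"].to_numpy(dtype=float)).all():
        raise ValueError("mean_ncv contains non-finite values")
    return outcomes


def roc_analysis(outcomes: pd.DataFrame) -> ROCResult:
    """ROC of mean NCV against clinical response (positive = PR or SD).

    AUC comes from the rank (Mann-Whitney) formulation with midrank tie
    correction; its 95% CI from the Hanley-McNeil normal approximation;
    the p-value from the two-sided Wilcoxon-Mann-Whitney test comparing
    NCV between responders and non-responders.  The operating cutoff is
    the midpoint threshold between adjacent distinct NCVs that
    maximizes Youden's J (ties broken toward the smaller cutoff).
    """
    outcomes = _validate_outcomes(outcomes)
    ncv = outcomes["mean_ncv"].to_numpy(dtype=float)
    is_resp = outcomes["recist"].isin(RESPONDER_CLASSES).to_numpy()
    n_pos, n_neg = int(is_resp.sum()), int((~is_resp).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both responder and non-responder outcomes are required")
    # low NCV predicts response: score = -NCV
    ranks = stats.rankdata(-ncv)
    auc = (ranks[is_resp].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (
        auc * (1 - auc) + (n_pos - 1) * (q1 - auc**2) + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    se = math.sqrt(max(var, 0.0))
    ci = (max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se))
    mw = stats.mannwhitneyu(ncv[is_resp], ncv[~is_resp], alternative="two-sided")
    distinct = np.unique(ncv)
    mids = (distinct[:-1] + distinct[1:]) / 2
    thresholds = np.concatenate([[distinct[0] - 1e-9], mids, [distinct[-1] + 1e-9]])
    sens = np.array([(ncv[is_resp] < t).mean() for t in thresholds])
    spc = np.array([(ncv[~is_resp] >= t).mean() for t in thresholds])
    j = sens + spc - 1.0
    best = int(np.argmax(j))  # argmax takes the first (smallest cutoff) on ties
    return ROCResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spc,
        auc=float(auc),
        auc_ci=ci,
        p_value=float(mw.pvalue),
        cutoff=float(thresholds[best]),
        youden_j=float(j[best]),
    )


def _fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric point probabilities
    not exceeding that of the observed table (with relative slack for
    floating-point ties), at fixed margins."""
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    rv = stats.hypergeom(n, col1, row1)
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


def contingency_analysis(
    a: int, b: int, c: int, d: int, or_ci_method: str = "woolf"
) -> ContingencyResult:
    """Responder contingency analysis of a 2x2 table.

    Odds ratio ad/bc (infinite when bc = 0 with ad > 0); two-sided
    Fisher exact p by hypergeometric summation; OR 95% CI by the Woolf
    logit interval with Haldane +0.5 correction on zero cells, or the
    conditional-MLE interval (``or_ci_method="conditional"``).  TPV is
    the overall accuracy (a + d) / N.
    """
    cells = (a, b, c, d)
    if any(not float(x).is_integer() or x < 0 for x in cells):
        raise ValueError(f"cell counts must be nonnegative integers, got {cells}")
    a, b, c, d = (int(x) for x in cells)
    n = a + b + c + d
    if n == 0:
        raise ValueError("contingency table is empty")
    if b * c == 0:
        odds_ratio = math.inf if a * d > 0 else math.nan
    else:
        odds_ratio = (a * d) / (b * c)
    if or_ci_method == "woolf":
        aa, bb, cc, dd = (x + 0.5 if 0 in cells else x for x in cells)
        log_or = math.log((aa * dd) / (bb * cc))
        se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
        or_ci = (math.exp(log_or - 1.96 * se), math.exp(log_or + 1.96 * se))
    elif or_ci_method == "conditional":
        res = stats.contingency.odds_ratio([[a, b], [c, d]], kind="conditional")
        interval = res.confidence_interval(0.95)
        or_ci = (float(interval.low), float(interval.high))
    else:
        raise ValueError(f"unknown or_ci_method {or_ci_method!r}")
    return ContingencyResult(
        a=a, b=b, c=c, d=d,
        odds_ratio=odds_ratio,
        or_ci=or_ci,
        fisher_p=_fisher_exact_two_sided(a, b, c, d),
        tpv=(a + d) / n,
        sensitivity=a / (a + c) if a + c else math.nan,
        specificity=d / (b + d) if b + d else math.nan,
    )


def outcome_proportions(recist: Sequence[str]) -> pd.DataFrame:
    """Counts and percentages (one decimal) of PR/SD/PD outcome classes."""
    labels = list(recist)
    bad = set(labels) - set(RECIST_CLASSES)
    if bad:
        raise ValueError(f"unknown RECIST classes: {sorted(bad)}")
    n = len(labels)
    rows = []
    for cls in RECIST_CLASSES:
        count = labels.count(cls)
        rows.append(
            {
                "recist": cls,
                "count": count,
                "pct": round(100.0 * count / n, 1) if n else math.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CohortAggregate:
    """Cohort-level frequency of top-ranked pairs (upset-plot-ready).

    ``pair_counts``: drug-index pair, count of samples whose top-k
    unique two-drug list contains it, sorted descending.
    ``single_counts``: per drug, total appearances within any top-k
    pair, summed over samples.
    """

    n_samples: int
    top_k: int
    pair_counts: pd.DataFrame
    single_counts: pd.DataFrame


def top_combo_frequencies(
    rankings: Sequence[CombinationRanking], top_k: int = 10
) -> CohortAggregate:
    """Aggregate each sample's top-k unique two-drug list across the cohort."""
    if not rankings:
        raise ValueError("need at least one per-sample ranking")
    pair_counts: dict[tuple[int, int], int] = {}
    single_counts: dict[int, int] = {}
    for ranking in rankings:
        if ranking.order != 2:
            raise ValueError("cohort aggregation expects order-2 (pair) rankings")
        for therapy in ranking.top(top_k)["therapy"]:
            key = tuple(sorted(therapy))
            pair_counts[key] = pair_counts.get(key, 0) + 1
            for drug in key:
                single_counts[drug] = single_counts.get(drug, 0) + 1
    pairs = pd.DataFrame(
        [{"pair": k, "count": v} for k, v in pair_counts.items()]
    ).sort_values(["count", "pair"], ascending=[False, True], ignore_index=True)
    singles = pd.DataFrame(
        [{"drug": k, "count": v} for k, v in single_counts.items()]
    ).sort_values(["count", "drug"], ascending=[False, True], ignore_index=True)
    return CohortAggregate(
        n_samples=len(rankings), top_k=top_k, pair_counts=pairs, single_counts=singles
    )


def one_vs_two_drug_correlation(
    single_rankings: Sequence[CombinationRanking],
    pair_rankings: Sequence[CombinationRanking],
    top_k: int = 20,
) -> pd.DataFrame:
    """Per-drug Pearson correlation of one-drug vs two-drug mean NCV.

    For every sample and every pair in its top-k two-drug list, each
    member drug contributes the point (its one-drug mean NCV in that
    sample, the pair's mean NCV).  Points pool across samples and pair
    appearances; drugs with fewer than 3 points are skipped with a
    warning.  Returns a tidy table (drug, r, p, n).
    """
    if len(single_rankings) != len(pair_rankings):
        raise ValueError("need matching single and pair rankings per sample")
    points: dict[int, list[tuple[float, float]]] = {}
    for singles, pairs in zip(single_rankings, pair_rankings):
        one_drug = {t[0]: m for t, m in zip(singles.summary["therapy"], singles.summary["mean_ncv"])}
        for _, row in pairs.top(top_k).iterrows():
            for drug in row["therapy"]:
                points.setdefault(drug, []).append((one_drug[drug], row["mean_ncv"]))
    rows = []
    for drug in sorted(points):
        pts = points[drug]
        if len(pts) < 3:
            warnings.warn(
                f"drug index {drug} has only {len(pts)} point(s); skipped", stacklevel=2
            )
            continue
        x, y = np.array(pts).T
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            warnings.warn(
                f"drug index {drug} has constant coordinates; r undefined, skipped",
                stacklevel=2,
            )
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"drug": drug, "r": float(r), "p": float(p), "n": len(pts)})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    degenerate: bool = False


def group_mean_comparison(
    values_a: Sequence[float],
    values_b: Sequence[float],
    paired: bool = False,
    welch: bool = False,
) -> TTestResult:
    """Two-tailed Student's t comparison of two groups.

    Equal-variance pooled t by default (Welch behind a flag); paired t
    when ``paired``.  Degenerate zero-variance inputs resolve by
    convention: equal means give t = 0, p = 1; a constant nonzero
    difference gives p = 0 with the degenerate flag set.
    """
    x = np.asarray(values_a, dtype=float)
    y = np.asarray(values_b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need >= 2 values per group")
    if paired:
        if x.size != y.size:
            raise ValueError("paired comparison requires equal-length groups")
        diff = x - y
        if diff.std(ddof=1) == 0:
            if diff.mean() == 0:
                return TTestResult(t=0.0, p=1.0, degenerate=True)
            return TTestResult(t=math.copysign(math.inf, diff.mean()), p=0.0, degenerate=True)
        res = stats.ttest_rel(x, y)
    else:
        if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
            if x.mean() == y.mean():
                return TTestResult(t=0.0, p=1.0, degenerate=True)
            return TTestResult(
                t=math.copysign(math.inf, x.mean() - y.mean()), p=0.0, degenerate=True
            )
        res = stats.ttest_ind(x, y, equal_var=not welch)
    return TTestResult(t=float(res.statistic), p=float(res.pvalue))


def tumor_volume(a: float, b: float) -> float:
    """Xenograft tumor volume V = pi/6 * A^2 * B from superficial diameters.

    ``a`` is the smallest and ``b`` the largest superficial diameter;
    the result carries the cube of the input unit (cm -> cm^3).
    """
    if a <= 0 or b <= 0:
        raise ValueError("diameters must be positive")
    if a > b:
        raise ValueError(f"smallest diameter A={a} exceeds largest B={b}")
    return math.pi / 6.0 * a**2 * b


def growth_rate(v_first: float, v_last: float, days: float) -> float:
    """Tumor growth rate: (last - first volume) / days of treatment."""
    if days <= 0:
        raise ValueError("days of treatment must be positive")
    return (v_last - v_first) / days
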