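"""Cumulative-index diagnostic statistics: ROC, optimal cutoff, likelihood
ratios and Fagan post-test probabilities.

The cumulative index of a feature set is the plain arithmetic sum of the raw
feature values (mixed units summed deliberately); disease or worse stage is
called when the index falls at or below the cutoff.  The optimal cutoff
maximizes sensitivity + specificity (Youden); likelihood ratios are
LR+ = Se/(1-Sp) and LR- = (1-Se)/Sp; post-test probabilities follow the
Fagan nomogram, post-odds = pretest-odds x LR, with the pretest probability
taken as the group-size prevalence of the comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DiagnosticReport",
    "cumulative_index",
    "roc_analysis",
    "optimal_cutoff",
    "likelihood_ratios",
    "post_test_probability",
    "group_stats",
    "diagnostic_report",
]


def cumulative_index(table: pd.DataFrame, features: list[str]) -> np.ndarray:
    """Per-subject cumulative index: arithmetic sum of the raw features."""
    if not features:
        raise ValueError("empty feature list")
    missing = [f for f in features if f not in table.columns]
    if missing:
        raise KeyError(f"missing feature(s): {missing}")
    return table[list(features)].to_numpy(dtype=float).sum(axis=1)


@dataclass
class ROCCurve:
    """Empirical ROC with 'index <= threshold => positive' direction."""

    thresholds: np.ndarray  # candidate cutoffs (ascending)
    sensitivity: np.ndarray  # fraction, per threshold
    specificity: np.ndarray
    auc: float


def roc_analysis(values: np.ndarray, positive: np.ndarray) -> ROCCurve:
    """Empirical ROC of a cumulative index, positives at low index values.

    Thresholds scan the midpoints between consecutive sorted unique values
    plus sentinels below/above the data range; AUC by the trapezoidal rule
    over (1-Sp, Se).
    """
    values = np.asarray(values, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    if positive.all() or (~positive).all():
        raise ValueError("both classes must be present")
    uniq = np.unique(values)
    mids = (uniq[:-1] + uniq[1:]) / 2
    thresholds = np.concatenate([[uniq[0] - 1.0], uniq, mids, [uniq[-1] + 1.0]])
    thresholds = np.unique(thresholds)
    n_pos = positive.sum()
    n_neg = (~positive).sum()
    calls = values[None, :] <= thresholds[:, None]
    se = (calls & positive[None, :]).sum(axis=1) / n_pos
    sp = ((~calls) & (~positive)[None, :]).sum(axis=1) / n_neg
    fpr = 1.0 - sp
    order = np.argsort(fpr, kind="stable")
    auc = float(np.trapezoid(se[order], fpr[order]))
    return ROCCurve(thresholds=thresholds, sensitivity=se, specificity=sp, auc=auc)


def optimal_cutoff(roc: ROCCurve) -> tuple[float, float, float]:
    """Cutoff maximizing Se + Sp (Youden), ties broken toward higher Se.

    Returns (cutoff, Se, Sp) with Se/Sp as fractions.
    """
    youden = roc.sensitivity + roc.specificity
    best = np.max(youden)
    cand = np.nonzero(np.isclose(youden, best))[0]
    cand = cand[np.argsort(-roc.sensitivity[cand], kind="stable")]
    i = cand[0]
    return float(roc.thresholds[i]), float(roc.sensitivity[i]), float(roc.specificity[i])


def likelihood_ratios(se: float, sp: float) -> tuple[float, float]:
    """LR+ = Se/(1-Sp) and LR- = (1-Se)/Sp from fractional Se/Sp.

    Division by zero yields +inf with a warning.
    """
    if not (0 <= se <= 1 and 0 <= sp <= 1):
        raise ValueError("Se and Sp must be fractions in [0, 1]")
    if sp == 1.0:
        warnings.warn("Sp = 1: LR+ is infinite", stacklevel=2)
        lr_pos = np.inf if se > 0 else np.nan
    else:
        lr_pos = se / (1.0 - sp)
    if sp == 0.0:
        warnings.warn("Sp = 0: LR- is infinite", stacklevel=2)
        lr_neg = np.inf if se < 1 else np.nan
    else:
        lr_neg = (1.0 - se) / sp
    return float(lr_pos), float(lr_neg)


def post_test_probability(pretest: float, lr: float) -> float:
    """Fagan nomogram: pretest odds x LR back-converted to a probability."""
    if not 0 < pretest < 1:
        raise ValueError("pretest probability must be in (0, 1)")
    if lr < 0:
        raise ValueError("likelihood ratio must be >= 0")
    if np.isinf(lr):
        return 1.0
    odds = pretest / (1.0 - pretest) * lr
    return odds / (1.0 + odds)


@dataclass
class DiagnosticReport:
    """Table-style diagnostic accuracy summary for one pairwise comparison."""

    comparison: str
    features: tuple[str, ...]
    auc: float
    ocp: float  # index units; index <= OCP calls the positive class
    se_pct: float
    sp_pct: float
    lr_pos: float
    lr_neg: float
    pretest: float
    ptp_pos_pct: float
    ptp_neg_pct: float

    def as_row(self) -> dict:
        return {
            "comparison": self.comparison,
            "features": "+".join(self.features),
            "AUC": round(self.auc, 2),
            "OCP": round(self.ocp, 2),
            "Se_pct": round(self.se_pct, 2),
            "Sp_pct": round(self.sp_pct, 2),
            "LR+": round(self.lr_pos, 2),
            "LR-": round(self.lr_neg, 2),
            "+PTP_pct": round(self.ptp_pos_pct),
            "-PTP_pct": round(self.ptp_neg_pct),
        }


def diagnostic_report(
    table: pd.DataFrame,
    features: list[str],
    positive_label: str,
    negative_label: str,
    label_col: str = "label",
    comparison: str | None = None,
) -> DiagnosticReport:
    """Cumulative-index ROC report for one pairwise group comparison.

    The positive (diseased / worse-stage) group is called at low index
    values; the pretest probability is the prevalence of the positive group
    within the two compared groups.
    """
    mask = table[label_col].isin([positive_label, negative_label])
    sub = table[mask]
    idx = cumulative_index(sub, features)
    pos = (sub[label_col] == positive_label).to_numpy()
    if pos.sum() == 0 or (~pos).sum() == 0:
        raise ValueError("both comparison groups must be non-empty")
    roc = roc_analysis(idx, pos)
    ocp, se, sp = optimal_cutoff(roc)
    lr_pos, lr_neg = likelihood_ratios(se, sp)
    pretest = pos.mean()
    return DiagnosticReport(
        comparison=comparison or f"{negative_label} vs {positive_label}",
        features=tuple(features),
        auc=roc.auc,
        ocp=ocp,
        se_pct=100 * se,
        sp_pct=100 * sp,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        pretest=pretest,
        ptp_pos_pct=100 * post_test_probability(pretest, lr_pos),
        ptp_neg_pct=100 * post_test_probability(pretest, lr_neg),
    )


@dataclass
class GroupTestReport:
    test: str  # 't' | 'mann-whitney' | 'anova'
    statistic: float
    p_value: float
    normal: tuple[bool, ...]
    posthoc: pd.DataFrame | None = None


def group_stats(
    groups: list[np.ndarray], alpha_normal: float = 0.05
) -> GroupTestReport:
    """Normality-gated between-group test.

    Two groups: Shapiro-Wilk on each; if both pass at ``alpha_normal`` an
    unpaired two-sample t-test is used, otherwise a two-tailed Mann-Whitney
    test.  More than two groups: one-way ANOVA with Bonferroni-corrected
    pairwise t-tests as post-hoc.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if g.size < 3:
            raise ValueError("each group needs n >= 3")
    normal = tuple(bool(stats.shapiro(g).pvalue > alpha_normal) for g in groups)
    if len(groups) == 2:
        a, b = groups
        if all(normal):
            res = stats.ttest_ind(a, b)
            return GroupTestReport("t", float(res.statistic), float(res.pvalue), normal)
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        return GroupTestReport(
            "mann-whitney", float(res.statistic), float(res.pvalue), normal
        )
    f, p = stats.f_oneway(*groups)
    pairs = [
        (i, j) for i in range(len(groups)) for j in range(i + 1, len(groups))
    ]
    rows = []
    for i, j in pairs:
        t, praw = stats.ttest_ind(groups[i], groups[j])
        rows.append(
            {
                "group_a": i,
                "group_b": j,
                "t": float(t),
                "p_bonferroni": min(1.0, float(praw) * len(pairs)),
            }
        )
    return GroupTestReport(
        "anova", float(f), float(p), normal, posthoc=pd.DataFrame(rows)
    )
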