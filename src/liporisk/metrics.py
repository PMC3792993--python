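"""ROC/AUC machinery, operating-point metrics, NRI, and cohort statistics.

AUC is computed exactly from midranks — the probability that a random event
outscores a random non-event, counting ties as one half — which equals the
trapezoidal area under the empirical ROC curve with tie-grouped thresholds
(the Mann-Whitney identity).  The net reclassification improvement (NRI)
follows the standard two-category definition: the net fraction of events
reclassified upward plus the net fraction of non-events reclassified
downward when one model's binary calls replace another's.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

import pandas as pd

from .cohort import AT_RISK_GROUPS, GROUPS, CohortTable


def _as_binary(truth) -> np.ndarray:
    t = np.asarray(truth).astype(int)
    if not set(np.unique(t)) <= {0, 1}:
        raise ValueError("truth must be binary 0/1")
    return t


def auc(scores, truth) -> float:
    """Exact AUC via midranks: P(score_event > score_nonevent) + 0.5 P(tie)."""
    s = np.asarray(scores, dtype=float)
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    t = _as_binary(truth)
    n1 = int(t.sum())
    n0 = len(t) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: only one outcome class present")
    ranks = stats.rankdata(s)
    u = ranks[t == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


@dataclass
class ROCCurve:
    thresholds: np.ndarray  # descending
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_curve(scores, truth) -> ROCCurve:
    """Empirical ROC over tie-grouped thresholds, endpoints (0,0) and (1,1).

    The ``auc`` field is the trapezoidal area; it matches :func:`auc` to
    machine precision.
    """
    s = np.asarray(scores, dtype=float)
    t = _as_binary(truth)
    n1 = int(t.sum())
    n0 = len(t) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: only one outcome class present")
    order = np.argsort(-s, kind="stable")
    s_sorted, t_sorted = s[order], t[order]
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), len(s) - 1]
    tp = np.cumsum(t_sorted)[distinct]
    fp = np.cumsum(1 - t_sorted)[distinct]
    tpr = np.r_[0.0, tp / n1]
    fpr = np.r_[0.0, fp / n0]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    area = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=area)


def confusion_metrics(scores, truth, threshold: float, groups=None) -> dict:
    """Sensitivity, specificity, and per-group accuracy at a score cutoff.

    The prediction rule is ``score >= threshold -> at-risk``.  Per-group
    accuracy is the fraction of T2D (resp. IGT) subjects called at-risk and
    the fraction of NGT subjects called not-at-risk; an absent group reports
    NaN rather than zero.
    """
    s = np.asarray(scores, dtype=float)
    t = _as_binary(truth)
    pred = s >= threshold
    tp = int(np.sum(pred & (t == 1)))
    fn = int(np.sum(~pred & (t == 1)))
    tn = int(np.sum(~pred & (t == 0)))
    fp = int(np.sum(pred & (t == 0)))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    out = {"sensitivity": sens, "specificity": spec}
    if groups is not None:
        g = np.asarray(groups)
        acc = {}
        for grp in GROUPS:
            mask = g == grp
            if not mask.any():
                acc[grp] = float("nan")
            elif grp in AT_RISK_GROUPS:
                acc[grp] = float(np.mean(pred[mask]))
            else:
                acc[grp] = float(np.mean(~pred[mask]))
        out["per_group_accuracy"] = acc
    return out


@dataclass
class NRIResult:
    """Two-category net reclassification improvement between two models."""

    n_events: int
    n_nonevents: int
    up_events: int
    down_events: int
    up_nonevents: int
    down_nonevents: int

    @property
    def event_component(self) -> float:
        return (self.up_events - self.down_events) / self.n_events

    @property
    def nonevent_component(self) -> float:
        return (self.down_nonevents - self.up_nonevents) / self.n_nonevents

    @property
    def nri(self) -> float:
        return self.event_component + self.nonevent_component


def nri(old_predictions, new_predictions, truth) -> NRIResult:
    """NRI of replacing ``old`` binary calls with ``new`` ones.

    "Up" means reclassified from not-at-risk to at-risk.  Antisymmetric:
    swapping the two models negates the statistic.
    """
    old = np.asarray(old_predictions).astype(bool)
    new = np.asarray(new_predictions).astype(bool)
    t = _as_binary(truth)
    if not (len(old) == len(new) == len(t)):
        raise ValueError("old_predictions, new_predictions and truth must align")
    n1 = int(t.sum())
    n0 = len(t) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("NRI undefined: only one outcome class present")
    ev, nv = t == 1, t == 0
    up = new & ~old
    down = old & ~new
    return NRIResult(
        n_events=n1,
        n_nonevents=n0,
        up_events=int(np.sum(up & ev)),
        down_events=int(np.sum(down & ev)),
        up_nonevents=int(np.sum(up & nv)),
        down_nonevents=int(np.sum(down & nv)),
    )


def auc_gain_test(auc_samples_a, auc_samples_b, method: str = "t") -> dict:
    """Gain in mean AUC of model B over model A with a paired two-sided test.

    Samples are per-iteration AUCs over the same cross-validation iterations.
    ``method`` is ``"t"`` (paired t-test, default) or ``"wilcoxon"`` (paired
    signed-rank).
    """
    a = np.asarray(auc_samples_a, dtype=float)
    b = np.asarray(auc_samples_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired AUC samples must have equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 iterations for a paired test")
    diff = b - a
    gain = float(diff.mean())
    if np.ptp(diff) == 0:  # constant differences: the test statistic degenerates
        return {"gain": gain, "p_value": 1.0 if diff[0] == 0 else 0.0}
    if method == "t":
        p = float(stats.ttest_rel(b, a).pvalue)
    elif method == "wilcoxon":
        p = float(stats.wilcoxon(b, a, zero_method="zsplit").pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return {"gain": gain, "p_value": p}


def mann_whitney_p(x, y) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact by exhaustive enumeration of all group assignments (doubled
    smaller tail, midranks for ties) when n + m <= 8; tie-corrected normal
    approximation otherwise.  Identical samples yield p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    if n + m <= 8:
        ranks = stats.rankdata(pooled)
        u_obs = ranks[:n].sum() - n * (n + 1) / 2.0
        us = []
        for comb in combinations(range(n + m), n):
            us.append(ranks[list(comb)].sum() - n * (n + 1) / 2.0)
        us = np.asarray(us)
        tol = 1e-9
        p_low = np.mean(us <= u_obs + tol)
        p_high = np.mean(us >= u_obs - tol)
        return float(min(1.0, 2.0 * min(p_low, p_high)))
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue)


def chi2_proportions_p(x_binary, y_binary) -> float:
    """Chi-square test (no continuity correction) that two groups share a
    binary proportion.  Degenerate tables (constant variable) report p = 1."""
    x = np.asarray(x_binary)
    y = np.asarray(y_binary)
    table = np.array(
        [
            [np.sum(x == 0), np.sum(x == 1)],
            [np.sum(y == 0), np.sum(y == 1)],
        ]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.chi2_contingency(table, correction=False).pvalue)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def _median_iqr(v: np.ndarray) -> str:
    q25, med, q75 = np.percentile(v, [25, 50, 75])
    return f"{med:.2f} ({q25:.2f}-{q75:.2f})"


def cohort_characteristics(table: CohortTable, binary_variables=("sex",)) -> pd.DataFrame:
    """Per-variable group summary comparing at-risk (T2D + IGT) with NGT.

    Continuous risk factors report median (IQR) per group and a two-sided
    Mann-Whitney U p-value; binary variables use the chi-square test of
    proportions.  All p-values are Benjamini-Hochberg adjusted jointly.
    """
    at_risk = table.at_risk.astype(bool)
    if at_risk.all() or not at_risk.any():
        raise ValueError("both at-risk and NGT subjects are required")
    rows = []
    raw_p = []
    for var in table.risk_factor_names:
        v = table.data[var].to_numpy(dtype=float)
        v1, v0 = v[at_risk], v[~at_risk]
        if var in binary_variables:
            summary1 = f"{100 * np.mean(v1):.1f}% positive"
            summary0 = f"{100 * np.mean(v0):.1f}% positive"
            p = chi2_proportions_p(v1, v0)
        else:
            summary1, summary0 = _median_iqr(v1), _median_iqr(v0)
            p = mann_whitney_p(v1, v0)
        rows.append({"variable": var, "at_risk": summary1, "ngt": summary0})
        raw_p.append(p)
    adj = benjamini_hochberg(raw_p)
    out = pd.DataFrame(rows)
    out["p_value"] = raw_p
    out["p_adjusted"] = adj
    return out
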