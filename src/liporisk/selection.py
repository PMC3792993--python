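"""Repeated stratified k-fold CV with AUC-ordered forward feature inclusion.

This is the core procedure.  Each repeat partitions the cohort into k
stratified folds (approximately equal three-way label proportions per fold).
Each fold in turn is held out; on the remaining training two-thirds the
candidate features are ranked by their univariate AUC (folded above 0.5, so
inversely associated features such as protective lipids rank by
discrimination, not direction), and the classifier is retrained as features
are included one at a time in that order.  AUC, sensitivity and specificity
on the held-out fold are recorded at every feature count.  Nothing from the
held-out fold touches the ranking or the training — the no-leakage property
is structural and is asserted by tests.

With k = 3 and 200 repeats this yields 600 iterations; performance is
averaged per feature count over iterations with empirical percentile 95%
confidence bands.  The operating point is the feature count maximizing mean
AUC (smallest count on ties), and the incorporation frequency of a feature
is the percentage of iterations in which it appears among the first
operating-point features selected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classifier import ClassifierParams, fit_oriented
from .metrics import auc


@dataclass
class CVConfig:
    k_folds: int = 3
    n_repeats: int = 200
    max_features: int | None = None  # None: all candidates, capped at 30
    seed: int = 0

    def validate(self) -> None:
        if self.k_folds < 2:
            raise ValueError(f"k_folds must be >= 2, got {self.k_folds}")
        if self.n_repeats < 1:
            raise ValueError(f"n_repeats must be >= 1, got {self.n_repeats}")
        if self.max_features is not None and self.max_features < 1:
            raise ValueError("max_features must be >= 1")


DEFAULT_MAX_FEATURES = 30


def resolve_max_features(config: CVConfig, n_candidates: int) -> int:
    if config.max_features is not None:
        return min(config.max_features, n_candidates)
    return min(DEFAULT_MAX_FEATURES, n_candidates)


def stratified_folds(labels, config: CVConfig, repeat: int) -> np.ndarray:
    """Assign each subject a fold id in ``{0..k-1}``, stratified by label.

    Within every fold each label's count is within 1 of ``n_label / k``.
    Deterministic given ``(labels, config.seed, repeat)``; different repeats
    shuffle differently.
    """
    config.validate()
    labels = np.asarray(labels)
    k = config.k_folds
    rng = np.random.default_rng([config.seed, repeat])
    fold = np.full(len(labels), -1, dtype=int)
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if len(idx) < k:
            raise ValueError(
                f"label {lab!r} has {len(idx)} subjects, fewer than k_folds={k}"
            )
        idx = rng.permutation(idx)
        base, rem = divmod(len(idx), k)
        sizes = np.full(k, base)
        sizes[rng.permutation(k)[:rem]] += 1
        stops = np.cumsum(sizes)
        starts = np.r_[0, stops[:-1]]
        for f in range(k):
            fold[idx[starts[f] : stops[f]]] = f
    return fold


def univariate_auc(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Column-wise AUC of each feature's raw value as the score."""
    y = np.asarray(y).astype(int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: only one outcome class present")
    ranks = stats.rankdata(X, axis=0)
    u = ranks[y == 1].sum(axis=0) - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)


def rank_features_by_auc(
    X: pd.DataFrame, y, candidates: Sequence[str] | None = None, fold_auc: bool = True
) -> list[str]:
    """Order features by descending univariate AUC on the given (training) set.

    With ``fold_auc`` (default) each AUC is folded above 0.5 as
    ``max(a, 1 - a)`` so inversely associated features rank by their
    discrimination.  Ties break alphabetically by feature name.
    """
    if candidates is None:
        candidates = list(X.columns)
    if len(candidates) == 0:
        raise ValueError("empty candidate feature list")
    a = univariate_auc(X[list(candidates)].to_numpy(dtype=float), y)
    key = np.maximum(a, 1.0 - a) if fold_auc else a
    return [name for _, name in sorted(zip(-key, candidates), key=lambda t: (t[0], t[1]))]


@dataclass
class IterationTrace:
    """One (repeat, held-out fold) iteration of the forward-selection CV."""

    repeat: int
    test_fold: int
    test_index: np.ndarray  # positional subject indices of the held-out fold
    ordered_features: list[str]  # inclusion order, length = max_features
    auc_by_count: np.ndarray
    sens_by_count: np.ndarray
    spec_by_count: np.ndarray
    pred_by_count: np.ndarray  # (max_features, n_test) hard at-risk calls
    score_by_count: np.ndarray  # (max_features, n_test) decision scores


def run_forward_cv(
    X: pd.DataFrame,
    y,
    groups,
    config: CVConfig,
    params: ClassifierParams | None = None,
    candidates: Sequence[str] | None = None,
    fold_auc: bool = True,
) -> list[IterationTrace]:
    """Run the repeated stratified CV with forward feature inclusion.

    ``groups`` are the three-way labels used for stratification; ``y`` is
    the binary at-risk outcome.  Returns ``k_folds * n_repeats`` traces,
    fully reproducible from the inputs and ``config.seed``.
    """
    config.validate()
    params = params or ClassifierParams()
    params.validate()
    y = np.asarray(y).astype(int)
    groups = np.asarray(groups)
    if candidates is None:
        candidates = list(X.columns)
    candidates = list(candidates)
    max_feats = resolve_max_features(config, len(candidates))

    Xc = X[candidates]
    values = Xc.to_numpy(dtype=float)
    col_of = {name: j for j, name in enumerate(candidates)}

    traces: list[IterationTrace] = []
    for repeat in range(config.n_repeats):
        fold = stratified_folds(groups, config, repeat)
        for test_fold in range(config.k_folds):
            test_mask = fold == test_fold
            train_idx = np.flatnonzero(~test_mask)
            test_idx = np.flatnonzero(test_mask)
            Xtr, ytr = values[train_idx], y[train_idx]
            Xte, yte = values[test_idx], y[test_idx]

            a = univariate_auc(Xtr, ytr)
            key = np.maximum(a, 1.0 - a) if fold_auc else a
            order = sorted(zip(-key, candidates), key=lambda t: (t[0], t[1]))
            ordered = [name for _, name in order[:max_feats]]
            cols = np.array([col_of[name] for name in ordered])

            aucs = np.empty(max_feats)
            sens = np.empty(max_feats)
            spec = np.empty(max_feats)
            preds = np.empty((max_feats, len(test_idx)), dtype=bool)
            scores = np.empty((max_feats, len(test_idx)))
            for c in range(1, max_feats + 1):
                sel = cols[:c]
                est, orient = fit_oriented(Xtr[:, sel], ytr, params)
                s = orient * est.decision_function(Xte[:, sel])
                aucs[c - 1] = auc(s, yte)
                pred = s >= 0.0
                n1 = yte.sum()
                n0 = len(yte) - n1
                sens[c - 1] = np.sum(pred & (yte == 1)) / n1
                spec[c - 1] = np.sum(~pred & (yte == 0)) / n0
                preds[c - 1] = pred
                scores[c - 1] = s
            traces.append(
                IterationTrace(
                    repeat=repeat,
                    test_fold=test_fold,
                    test_index=test_idx,
                    ordered_features=ordered,
                    auc_by_count=aucs,
                    sens_by_count=sens,
                    spec_by_count=spec,
                    pred_by_count=preds,
                    score_by_count=scores,
                )
            )
    return traces


def _percentile_ci(values: np.ndarray, axis: int = 0) -> tuple[np.ndarray, np.ndarray]:
    lo = np.percentile(values, 2.5, axis=axis)
    hi = np.percentile(values, 97.5, axis=axis)
    return lo, hi


@dataclass
class AggregateResult:
    """Mean performance curves, operating point, and incorporation frequencies
    over all CV iterations."""

    n_traces: int
    feature_counts: np.ndarray
    mean_auc: np.ndarray
    ci_auc: tuple[np.ndarray, np.ndarray]
    mean_sensitivity: np.ndarray
    ci_sensitivity: tuple[np.ndarray, np.ndarray]
    mean_specificity: np.ndarray
    ci_specificity: tuple[np.ndarray, np.ndarray]
    operating_point: int
    incorporation_frequency: pd.Series  # percent, descending
    mean_inclusion_rank: pd.Series

    def performance_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_features": self.feature_counts,
                "mean_auc": self.mean_auc,
                "auc_ci_low": self.ci_auc[0],
                "auc_ci_high": self.ci_auc[1],
                "mean_sensitivity": self.mean_sensitivity,
                "sens_ci_low": self.ci_sensitivity[0],
                "sens_ci_high": self.ci_sensitivity[1],
                "mean_specificity": self.mean_specificity,
                "spec_ci_low": self.ci_specificity[0],
                "spec_ci_high": self.ci_specificity[1],
            }
        )

    def frequency_table(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "feature": self.incorporation_frequency.index,
                "frequency_pct": self.incorporation_frequency.to_numpy(),
            }
        )
        out.insert(0, "rank", np.arange(1, len(out) + 1))
        return out


def aggregate(
    traces: Sequence[IterationTrace], candidates: Sequence[str] | None = None
) -> AggregateResult:
    """Aggregate iteration traces into mean/CI curves and frequency tallies.

    The 95% bands are empirical 2.5th/97.5th percentiles of the per-iteration
    values.  The operating point is the smallest feature count attaining the
    maximum mean AUC.  Incorporation frequency counts, for each feature, the
    percentage of iterations whose first operating-point inclusions contain
    it; ties in frequency are broken by mean inclusion rank, then name.
    ``candidates`` widens the tally to features never selected (frequency 0).
    """
    if len(traces) < 2:
        raise ValueError("need at least 2 traces to aggregate")
    lengths = {len(t.auc_by_count) for t in traces}
    if len(lengths) != 1:
        raise ValueError("ragged traces: feature-count curves differ in length")
    (n_counts,) = lengths
    aucs = np.vstack([t.auc_by_count for t in traces])
    sens = np.vstack([t.sens_by_count for t in traces])
    spec = np.vstack([t.spec_by_count for t in traces])
    mean_auc = aucs.mean(axis=0)
    op = int(np.argmax(mean_auc)) + 1  # smallest count on ties (argmax is first)

    feature_set = {f for t in traces for f in t.ordered_features}
    if candidates is not None:
        feature_set |= set(candidates)
    feature_set = sorted(feature_set)
    counts = dict.fromkeys(feature_set, 0)
    rank_sum = dict.fromkeys(feature_set, 0.0)
    miss_rank = n_counts + 1
    for t in traces:
        seen = set()
        for pos, f in enumerate(t.ordered_features):
            rank_sum[f] += pos + 1
            seen.add(f)
        for f in feature_set:
            if f not in seen:
                rank_sum[f] += miss_rank
        for f in t.ordered_features[:op]:
            counts[f] += 1
    freq = pd.Series({f: 100.0 * counts[f] / len(traces) for f in feature_set})
    mean_rank = pd.Series({f: rank_sum[f] / len(traces) for f in feature_set})
    order = sorted(feature_set, key=lambda f: (-freq[f], mean_rank[f], f))
    freq = freq.reindex(order)
    mean_rank = mean_rank.reindex(order)

    return AggregateResult(
        n_traces=len(traces),
        feature_counts=np.arange(1, n_counts + 1),
        mean_auc=mean_auc,
        ci_auc=_percentile_ci(aucs),
        mean_sensitivity=sens.mean(axis=0),
        ci_sensitivity=_percentile_ci(sens),
        mean_specificity=spec.mean(axis=0),
        ci_specificity=_percentile_ci(spec),
        operating_point=op,
        incorporation_frequency=freq,
        mean_inclusion_rank=mean_rank,
    )


def most_frequent_features(result: AggregateResult, x: int) -> list[str]:
    """The ``x`` most frequently incorporated features.

    Frequency ties break by mean inclusion rank, then name (the ordering the
    aggregate already stores).
    """
    if x < 1:
        raise ValueError("x must be >= 1")
    if x > len(result.incorporation_frequency):
        raise ValueError(
            f"x={x} exceeds the {len(result.incorporation_frequency)} ranked features"
        )
    return list(result.incorporation_frequency.index[:x])
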