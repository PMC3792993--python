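"""Final-model training, external-cohort validation, and model comparison.

Three model variants are compared throughout: A uses the eight standard risk
factors, B uses the lipid species, and A+B uses both.  After the
cross-validation stage fixes each variant's operating point x and its x most
frequently incorporated features, a final model per variant is trained on
the entire initial cohort and evaluated once on an independent validation
cohort that was preprocessed (log / impute / z-score) entirely on its own.
The comparison reports mirror the usual incremental-biomarker layout: AUC,
sensitivity, specificity and per-group accuracy per variant, plus the gain
in AUC and the two-category net reclassification improvement of A+B over A.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .classifier import ClassifierParams, TrainedModel, decision_scores, predict, train
from .cohort import CohortSpec, CohortTable, generate_cohort, write_cohort
from .metrics import auc, auc_gain_test, cohort_characteristics, confusion_metrics, nri
from .preprocessing import PreprocessConfig, preprocess
from .selection import (
    AggregateResult,
    CVConfig,
    IterationTrace,
    aggregate,
    most_frequent_features,
    run_forward_cv,
)

VARIANTS = ("risk_factors", "lipids", "combined")

#: Feature-inclusion depth explored per variant: all 8 risk factors for the
#: risk-factor model; 30 for the lipid and combined models, which covers the
#: plateau region of the mean-AUC curve with margin.
VARIANT_MAX_FEATURES: Mapping[str, int] = {
    "risk_factors": 8,
    "lipids": 30,
    "combined": 30,
}


def train_final_model(
    initial: CohortTable,
    features: Sequence[str],
    params: ClassifierParams | None = None,
    preprocess_config: PreprocessConfig | None = None,
    variant: str | None = None,
) -> TrainedModel:
    """Train one model on every subject of the initial cohort (no holdout),
    restricted to the given most-frequent features."""
    matrix = preprocess(initial, preprocess_config)
    missing = [f for f in features if f not in matrix.data.columns]
    if missing:
        raise ValueError(f"features not in cohort: {missing}")
    model = train(matrix.data[list(features)], initial.at_risk, params)
    model.variant = variant
    return model


def external_validate(
    model: TrainedModel,
    validation: CohortTable,
    preprocess_config: PreprocessConfig | None = None,
) -> dict:
    """One-shot evaluation on an independently preprocessed cohort.

    The validation cohort is log-transformed, imputed and z-scored using its
    own statistics only; nothing measured here feeds back into the model.
    """
    matrix = preprocess(validation, preprocess_config)
    missing = [f for f in model.feature_names if f not in matrix.data.columns]
    if missing:
        raise ValueError(f"validation cohort lacks feature columns: {missing}")
    scores = decision_scores(model, matrix.data[list(model.feature_names)])
    truth = validation.at_risk
    groups = validation.labels.to_numpy()
    cm = confusion_metrics(scores, truth, threshold=0.0, groups=groups)
    return {
        "variant": model.variant,
        "n_subjects": len(scores),
        "scores": scores,
        "predictions": scores >= 0.0,
        "truth": truth,
        "groups": groups,
        "auc": auc(scores, truth),
        "sensitivity": cm["sensitivity"],
        "specificity": cm["specificity"],
        "per_group_accuracy": cm["per_group_accuracy"],
    }


def compare_external(results: Mapping[str, dict]) -> dict:
    """Table-6-style report from single-pass external validation results.

    ``results`` maps variant name -> output of :func:`external_validate`;
    the gain in AUC and the NRI compare ``combined`` against
    ``risk_factors`` on the shared subject set.
    """
    for variant in ("risk_factors", "combined"):
        if variant not in results:
            raise ValueError(f"missing variant {variant!r}")
    ns = {r["n_subjects"] for r in results.values()}
    if len(ns) != 1:
        raise ValueError("all variants must be evaluated on identical subjects")
    a, ab = results["risk_factors"], results["combined"]
    if not np.array_equal(a["truth"], ab["truth"]):
        raise ValueError("subject sets differ between variants")
    reclass = nri(a["predictions"], ab["predictions"], a["truth"])
    report = {
        "cohort": "external_validation",
        "models": {
            v: {
                "auc": r["auc"],
                "sensitivity_pct": 100.0 * r["sensitivity"],
                "specificity_pct": 100.0 * r["specificity"],
                "per_group_accuracy_pct": {
                    g: 100.0 * x for g, x in r["per_group_accuracy"].items()
                },
            }
            for v, r in results.items()
        },
        "gain_in_auc": ab["auc"] - a["auc"],
        "nri_pct": 100.0 * reclass.nri,
        "nri_counts": asdict(reclass),
    }
    return report


def _per_iteration_nri(
    traces_a: Sequence[IterationTrace],
    traces_b: Sequence[IterationTrace],
    op_a: int,
    op_b: int,
    y: np.ndarray,
) -> float:
    """Mean over iterations of the held-out-fold NRI of model B (at its
    operating point) over model A (at its own operating point).

    Requires both trace lists to share fold assignments iteration by
    iteration, which holds when both variants ran under the same CV seed.
    """
    vals = []
    for ta, tb in zip(traces_a, traces_b):
        if not np.array_equal(ta.test_index, tb.test_index):
            raise ValueError("trace fold assignments differ between variants")
        truth = y[ta.test_index]
        vals.append(
            nri(ta.pred_by_count[op_a - 1], tb.pred_by_count[op_b - 1], truth).nri
        )
    return float(np.mean(vals))


def _per_group_accuracy_cv(
    traces: Sequence[IterationTrace], op: int, groups: np.ndarray
) -> dict:
    """Mean and percentile CI of per-group accuracy at the operating point."""
    from .cohort import AT_RISK_GROUPS, GROUPS

    per_iter = {g: [] for g in GROUPS}
    for t in traces:
        g = groups[t.test_index]
        pred = t.pred_by_count[op - 1]
        for grp in GROUPS:
            mask = g == grp
            if not mask.any():
                continue
            correct = pred[mask] if grp in AT_RISK_GROUPS else ~pred[mask]
            per_iter[grp].append(np.mean(correct))
    out = {}
    for grp, vals in per_iter.items():
        if not vals:
            out[grp] = {"mean_pct": float("nan"), "ci_pct": [float("nan")] * 2}
            continue
        v = 100.0 * np.asarray(vals)
        out[grp] = {
            "mean_pct": float(v.mean()),
            "ci_pct": [float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5))],
        }
    return out


def compare_cross_validated(
    traces: Mapping[str, Sequence[IterationTrace]],
    aggregates: Mapping[str, AggregateResult],
    y: np.ndarray,
    groups: np.ndarray,
) -> dict:
    """Table-5-style report from the cross-validation stage.

    Per variant: mean AUC / sensitivity / specificity (with percentile CIs)
    at the variant's operating point, and per-group accuracy.  Pairwise
    (combined vs risk factors): gain in mean AUC with a paired t-test over
    per-iteration AUC differences, and the mean per-iteration NRI.
    """
    report = {"cohort": "cross_validated", "models": {}}
    for variant, agg in aggregates.items():
        op = agg.operating_point
        i = op - 1
        report["models"][variant] = {
            "operating_point": op,
            "auc": float(agg.mean_auc[i]),
            "auc_ci": [float(agg.ci_auc[0][i]), float(agg.ci_auc[1][i])],
            "sensitivity_pct": 100.0 * float(agg.mean_sensitivity[i]),
            "sensitivity_ci_pct": [
                100.0 * float(agg.ci_sensitivity[0][i]),
                100.0 * float(agg.ci_sensitivity[1][i]),
            ],
            "specificity_pct": 100.0 * float(agg.mean_specificity[i]),
            "specificity_ci_pct": [
                100.0 * float(agg.ci_specificity[0][i]),
                100.0 * float(agg.ci_specificity[1][i]),
            ],
            "per_group_accuracy": _per_group_accuracy_cv(
                traces[variant], op, np.asarray(groups)
            ),
        }
    if "risk_factors" in aggregates and "combined" in aggregates:
        op_a = aggregates["risk_factors"].operating_point
        op_b = aggregates["combined"].operating_point
        a_samples = [t.auc_by_count[op_a - 1] for t in traces["risk_factors"]]
        b_samples = [t.auc_by_count[op_b - 1] for t in traces["combined"]]
        gain = auc_gain_test(a_samples, b_samples)
        report["gain_in_auc"] = gain["gain"]
        report["gain_p_value"] = gain["p_value"]
        report["nri_pct"] = 100.0 * _per_iteration_nri(
            traces["risk_factors"],
            traces["combined"],
            op_a,
            op_b,
            np.asarray(y),
        )
    return report


@dataclass
class AnalysisConfig:
    """Configuration of the full synthetic-cohort analysis run."""

    seed: int = 0
    initial_spec: CohortSpec = field(default_factory=CohortSpec)
    validation_spec: CohortSpec = field(
        default_factory=lambda: CohortSpec(
            n_per_group={"T2D": 0, "IGT": 101, "NGT": 384},
            batch_scale=1.3,
            batch_log_shift=0.2,
        )
    )
    cv: CVConfig = field(default_factory=CVConfig)
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    variants: tuple[str, ...] = VARIANTS

    def with_seed(self, seed: int) -> "AnalysisConfig":
        """Re-derive every stage seed from one master seed.

        The validation cohort gets an offset seed so the two cohorts are
        independent draws.
        """
        return replace(
            self,
            seed=seed,
            initial_spec=replace(self.initial_spec, seed=seed),
            validation_spec=replace(self.validation_spec, seed=seed + 1_000_003),
            cv=replace(self.cv, seed=seed),
        )

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "initial_spec": self.initial_spec.to_dict(),
            "validation_spec": self.validation_spec.to_dict(),
            "cv": asdict(self.cv),
            "classifier": asdict(self.classifier),
            "preprocess": asdict(self.preprocess),
            "variants": list(self.variants),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        d = dict(d)
        kwargs = {}
        if "initial_spec" in d:
            kwargs["initial_spec"] = CohortSpec.from_dict(d["initial_spec"])
        if "validation_spec" in d:
            kwargs["validation_spec"] = CohortSpec.from_dict(d["validation_spec"])
        if "cv" in d:
            kwargs["cv"] = CVConfig(**d["cv"])
        if "classifier" in d:
            kwargs["classifier"] = ClassifierParams(**d["classifier"])
        if "preprocess" in d:
            kwargs["preprocess"] = PreprocessConfig(**d["preprocess"])
        if "variants" in d:
            kwargs["variants"] = tuple(d["variants"])
        if "seed" in d:
            kwargs["seed"] = d["seed"]
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class AnalysisResult:
    config: AnalysisConfig
    initial: CohortTable
    validation: CohortTable
    characteristics: pd.DataFrame
    traces: dict
    aggregates: dict
    selected_features: dict
    final_models: dict
    cv_report: dict
    external_report: dict


def run_full_analysis(config: AnalysisConfig, out_dir=None) -> AnalysisResult:
    """End-to-end orchestration: generate → preprocess → CV per variant →
    aggregate → final models → external validation → reports.

    Deterministic: rerunning with the same config writes byte-identical
    outputs.  When ``out_dir`` is given, all tables (TSV) and reports (JSON)
    are written there.
    """
    initial = generate_cohort(config.initial_spec)
    validation = generate_cohort(config.validation_spec)
    characteristics = cohort_characteristics(initial)

    matrix = preprocess(initial, config.preprocess)
    y = initial.at_risk
    groups = initial.labels.to_numpy()

    traces: dict = {}
    aggregates: dict = {}
    selected: dict = {}
    finals: dict = {}
    ext_results: dict = {}
    for variant in config.variants:
        candidates = matrix.features_for_variant(variant)
        cv = replace(
            config.cv,
            max_features=config.cv.max_features
            or min(VARIANT_MAX_FEATURES[variant], len(candidates)),
        )
        tr = run_forward_cv(
            matrix.data, y, groups, cv, config.classifier, candidates=candidates
        )
        agg = aggregate(tr, candidates=candidates)
        traces[variant] = tr
        aggregates[variant] = agg
        feats = most_frequent_features(agg, agg.operating_point)
        selected[variant] = feats
        finals[variant] = train_final_model(
            initial, feats, config.classifier, config.preprocess, variant=variant
        )
        ext_results[variant] = external_validate(
            finals[variant], validation, config.preprocess
        )

    cv_report = compare_cross_validated(traces, aggregates, y, groups)
    external_report = compare_external(ext_results)

    result = AnalysisResult(
        config=config,
        initial=initial,
        validation=validation,
        characteristics=characteristics,
        traces=traces,
        aggregates=aggregates,
        selected_features=selected,
        final_models=finals,
        cv_report=cv_report,
        external_report=external_report,
    )
    if out_dir is not None:
        write_analysis_outputs(result, out_dir)
    return result


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_analysis_outputs(result: AnalysisResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_cohort(result.initial, out / "initial_cohort.tsv")
    write_cohort(result.validation, out / "validation_cohort.tsv")
    result.characteristics.to_csv(out / "characteristics.tsv", sep="\t", index=False)
    for variant, agg in result.aggregates.items():
        agg.performance_table().to_csv(
            out / f"performance_{variant}.tsv", sep="\t", index=False
        )
        agg.frequency_table().to_csv(
            out / f"frequency_{variant}.tsv", sep="\t", index=False
        )
    for name, report in (
        ("comparison_cross_validated", result.cv_report),
        ("comparison_external", result.external_report),
    ):
        with open(out / f"{name}.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
            fh.write("\n")
    run_log = {
        "seed": result.config.seed,
        "config": result.config.to_dict(),
        "n_iterations": {v: len(t) for v, t in result.traces.items()},
        "selected_features": result.selected_features,
        "operating_points": {
            v: a.operating_point for v, a in result.aggregates.items()
        },
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
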