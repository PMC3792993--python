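"""Feature transformation chain: log transform, below-LOD imputation, z-scoring.

Lipid abundances are log-transformed; below-limit-of-detection cells are
imputed with a constant on the log scale (default 0, i.e. raw abundance 1 in
measurement units); each cohort is then z-scored on its own.  Standardizing
each cohort separately — never pooled — is what removes per-species
multiplicative batch effects between cohorts measured in different
experimental runs.

Risk factors are also standardized by default: the polynomial-kernel SVM
downstream is scale-sensitive and mixing mmHg with z-scores would let a
single wide-ranged column dominate the kernel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTable


@dataclass
class PreprocessConfig:
    log_base: str = "e"  # "e" or "10"
    standardize_risk_factors: bool = True
    imputed_log_value: float = 0.0

    def validate(self) -> None:
        if self.log_base not in ("e", "10"):
            raise ValueError(f"log_base must be 'e' or '10', got {self.log_base!r}")


@dataclass
class FeatureMatrix:
    """Numeric subject-by-feature matrix aligned to a source cohort.

    ``kinds`` maps each feature name to ``"risk_factor"`` or ``"lipid"``.
    After preprocessing the matrix contains no missing values.
    """

    data: pd.DataFrame
    kinds: pd.Series

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def risk_factor_names(self) -> list[str]:
        return [f for f in self.data.columns if self.kinds[f] == "risk_factor"]

    @property
    def lipid_names(self) -> list[str]:
        return [f for f in self.data.columns if self.kinds[f] == "lipid"]

    def features_for_variant(self, variant: str) -> list[str]:
        """Candidate features for a model variant.

        ``risk_factors`` / ``lipids`` / ``combined``.
        """
        if variant == "risk_factors":
            return self.risk_factor_names
        if variant == "lipids":
            return self.lipid_names
        if variant == "combined":
            return self.feature_names
        raise ValueError(f"unknown model variant {variant!r}")


def log_and_impute(
    table: CohortTable, imputed_log_value: float = 0.0, log_base: str = "e"
) -> FeatureMatrix:
    """Log-transform lipid columns and impute below-LOD cells.

    Observed lipid values must be strictly positive.  Missing (below-LOD)
    cells are set to ``imputed_log_value`` on the log scale.  Risk-factor
    columns pass through unchanged.
    """
    lip = table.lipids
    bad = (lip <= 0).any()
    if bad.any():
        col = bad.index[bad][0]
        sid = lip.index[(lip[col] <= 0).fillna(False)][0]
        raise ValueError(
            f"non-positive lipid abundance at subject {sid!r}, species {col!r}"
        )
    logged = np.log(lip) if log_base == "e" else np.log10(lip)
    logged = logged.where(~table.missing_mask, imputed_log_value)
    data = pd.concat([table.risk_factors, logged], axis=1)
    kinds = pd.Series(
        ["risk_factor"] * len(table.risk_factor_names) + ["lipid"] * len(table.lipid_names),
        index=data.columns,
    )
    return FeatureMatrix(data=data, kinds=kinds)


def zscore_features(
    matrix: FeatureMatrix, standardize_risk_factors: bool = True
) -> FeatureMatrix:
    """Standardize each column to mean 0, sample SD 1 (denominator n - 1).

    Statistics come from the given matrix only — cohorts must be standardized
    separately, never pooled.  Zero-variance columns are set to all zeros and
    a warning is issued.
    """
    if len(matrix.data) < 2:
        raise ValueError("z-scoring requires at least 2 subjects")
    cols = (
        matrix.feature_names
        if standardize_risk_factors
        else matrix.lipid_names
    )
    out = matrix.data.copy()
    values = out[cols].to_numpy(dtype=float)
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    degenerate = sd == 0
    if degenerate.any():
        names = [c for c, d in zip(cols, degenerate) if d]
        warnings.warn(
            f"zero-variance columns set to zeros: {names}", UserWarning, stacklevel=2
        )
    sd_safe = np.where(degenerate, 1.0, sd)
    z = (values - mean) / sd_safe
    z[:, degenerate] = 0.0
    out[cols] = z
    return FeatureMatrix(data=out, kinds=matrix.kinds.copy())


def preprocess(table: CohortTable, config: PreprocessConfig | None = None) -> FeatureMatrix:
    """Full per-cohort chain: log transform, LOD imputation, z-scoring."""
    config = config or PreprocessConfig()
    config.validate()
    m = log_and_impute(
        table, imputed_log_value=config.imputed_log_value, log_base=config.log_base
    )
    return zscore_features(m, standardize_risk_factors=config.standardize_risk_factors)
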