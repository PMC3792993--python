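"""Synthetic lipidomics cohort generation and delimited-text I/O.

The study design this package targets is a case-control style cohort of
subjects with fasting plasma glucose below 6.1 mmol/L, labelled T2D
(undiagnosed type 2 diabetes), IGT (impaired glucose tolerance) or NGT
(normal glucose tolerance), with eight standard clinical risk factors and a
few hundred plasma lipid-species abundances per subject.  No such dataset is
bundled; instead :func:`generate_cohort` draws cohorts with the statistical
structure the downstream analysis assumes:

* log-normal lipid abundances with block covariance by lipid class
  (species within a class co-vary, which makes forward feature selection
  redundantly non-trivial);
* a small set of informative diacylglycerol-like species (named ``DG_*``)
  whose log abundance is shifted in at-risk subjects and partially coupled
  to the plasma triglycerides risk factor;
* left-tail below-limit-of-detection censoring per species;
* an optional multiplicative batch effect (per-species scale on the raw
  abundances plus a common log shift), used to emulate a validation cohort
  measured in a separate experimental batch.

Cohorts are plain subject-by-feature tables; the exchange format is TSV with
``NA`` marking below-LOD cells.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

GROUPS = ("T2D", "IGT", "NGT")
AT_RISK_GROUPS = ("T2D", "IGT")

RISK_FACTORS = (
    "sex",
    "age",
    "systolic_bp",
    "waist",
    "total_cholesterol",
    "hdl_c",
    "triglycerides",
    "hba1c",
)

#: Lipid classes measured by the targeted plasma lipidomics platforms this
#: generator emulates, with the approximate number of species per class.
#: Diacylglycerol (DG) and triacylglycerol (TG) dominate the neutral-lipid
#: panel; phosphatidylcholine (PC) dominates the phospholipids.
LIPID_CLASS_WEIGHTS: Mapping[str, int] = {
    "DG": 25,
    "TG": 48,
    "CE": 22,
    "PC": 45,
    "PC-O": 12,
    "PC-P": 12,
    "LPC": 15,
    "LPC-O": 6,
    "PE": 15,
    "PI": 10,
    "PS": 6,
    "PG": 5,
    "SM": 25,
    "Cer": 10,
    "dhCer": 8,
    "MHC": 8,
    "DHC": 6,
    "THC": 4,
    "GM3": 4,
    "COH": 1,
}

#: Within-class correlation of log abundances.
DEFAULT_CLASS_CORRELATION = 0.5

#: Default standardized group shifts for the risk factors, chosen to echo the
#: typical case-control contrasts in this population: triglycerides and HbA1c
#: are the strongest discriminators, age and systolic blood pressure are
#: moderate, and waist is null because cases and controls are BMI-matched by
#: design.  Sex carries no effect (equal proportions in both groups).
DEFAULT_RISK_FACTOR_EFFECTS: Mapping[str, float] = {
    "sex": 0.0,
    "age": 0.40,
    "systolic_bp": 0.45,
    "waist": 0.0,
    "total_cholesterol": 0.0,
    "hdl_c": 0.0,
    "triglycerides": 0.75,
    "hba1c": 0.70,
}


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    Parameters
    ----------
    n_per_group
        Subjects per 3-way label.  The default mirrors the 246-subject
        initial cohort (36 T2D / 40 IGT / 170 NGT).
    n_lipids
        Number of lipid-species columns (default 287).
    n_informative
        Number of lipid species carrying a group effect.  Informative
        species are the first ``DG_*`` species so recovery tests can assert
        on names.
    effect_size
        Standardized mean shift (in units of each species' log-scale SD) of
        informative species in at-risk (T2D or IGT) subjects.
    tg_coupling
        Correlation in [0, 1) between informative species (log scale) and
        the latent driver of the triglycerides risk factor.  Informative
        species therefore carry signal partly independent of triglycerides.
    lod_quantile
        Fraction in [0, 1) of each species' lowest values censored as below
        the limit of detection.
    batch_scale, batch_log_shift
        Batch effect applied to the whole cohort: every species' raw
        abundances are multiplied by a per-species factor centred on
        ``batch_scale``, and ``batch_log_shift`` is added to all log
        abundances.  Both act as per-species shifts on the log scale, the
        kind of inter-batch distortion per-cohort z-scoring removes.
    risk_factor_effects
        Standardized group shift per risk factor (at-risk minus NGT).
    seed
        Seed for the generator; equal specs yield identical cohorts.
    """

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"T2D": 36, "IGT": 40, "NGT": 170}
    )
    n_lipids: int = 287
    n_informative: int = 5
    effect_size: float = 0.8
    tg_coupling: float = 0.3
    lod_quantile: float = 0.05
    batch_scale: float = 1.0
    batch_log_shift: float = 0.0
    class_correlation: float = DEFAULT_CLASS_CORRELATION
    risk_factor_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RISK_FACTOR_EFFECTS)
    )
    seed: int = 0

    def validate(self) -> None:
        for g, n in self.n_per_group.items():
            if g not in GROUPS:
                raise ValueError(f"n_per_group: unknown group label {g!r}")
            if n < 0:
                raise ValueError(f"n_per_group[{g!r}] must be >= 0, got {n}")
        if self.n_lipids < 1:
            raise ValueError(f"n_lipids must be >= 1, got {self.n_lipids}")
        if not 0 < self.n_informative <= self.n_lipids:
            raise ValueError(
                f"n_informative must be in (0, n_lipids], got {self.n_informative}"
            )
        if not 0 <= self.lod_quantile < 1:
            raise ValueError(f"lod_quantile must be in [0, 1), got {self.lod_quantile}")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect_size must be finite")
        if not 0 <= self.tg_coupling < 1:
            raise ValueError(f"tg_coupling must be in [0, 1), got {self.tg_coupling}")
        if not 0 <= self.class_correlation < 1:
            raise ValueError("class_correlation must be in [0, 1)")
        if self.class_correlation + self.tg_coupling**2 >= 1:
            raise ValueError(
                "class_correlation + tg_coupling**2 must be < 1 so the "
                "informative-species noise variance stays positive"
            )
        if self.batch_scale <= 0:
            raise ValueError(f"batch_scale must be > 0, got {self.batch_scale}")
        for rf in self.risk_factor_effects:
            if rf not in RISK_FACTORS:
                raise ValueError(f"risk_factor_effects: unknown risk factor {rf!r}")

    def to_dict(self) -> dict:
        d = {
            "n_per_group": dict(self.n_per_group),
            "n_lipids": self.n_lipids,
            "n_informative": self.n_informative,
            "effect_size": self.effect_size,
            "tg_coupling": self.tg_coupling,
            "lod_quantile": self.lod_quantile,
            "batch_scale": self.batch_scale,
            "batch_log_shift": self.batch_log_shift,
            "class_correlation": self.class_correlation,
            "risk_factor_effects": dict(self.risk_factor_effects),
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortSpec":
        return cls(**dict(d))


def lipid_names(n_lipids: int, n_informative: int = 0) -> tuple[list[str], list[str]]:
    """Allocate ``n_lipids`` species names across lipid classes.

    Counts are distributed proportionally to :data:`LIPID_CLASS_WEIGHTS`
    (largest-remainder rounding).  The DG class is guaranteed at least
    ``n_informative`` species.  Returns ``(names, class_per_name)``.
    """
    classes = list(LIPID_CLASS_WEIGHTS)
    weights = np.array([LIPID_CLASS_WEIGHTS[c] for c in classes], dtype=float)
    ideal = weights / weights.sum() * n_lipids
    counts = np.floor(ideal).astype(int)
    remainder = ideal - counts
    short = n_lipids - counts.sum()
    for i in np.argsort(-remainder, kind="stable")[:short]:
        counts[i] += 1
    dg = classes.index("DG")
    while counts[dg] < n_informative:
        others = np.array(counts, dtype=float)
        others[dg] = -1
        donor = int(np.argmax(others))
        if counts[donor] == 0:
            raise ValueError("n_informative exceeds what the class layout can host")
        counts[donor] -= 1
        counts[dg] += 1
    names, name_class = [], []
    for cls_name, k in zip(classes, counts):
        for i in range(k):
            names.append(f"{cls_name}_{i + 1:03d}")
            name_class.append(cls_name)
    return names, name_class


@dataclass
class CohortTable:
    """A subject-by-feature cohort table.

    ``data`` is indexed by subject id and holds, in order: ``label`` (one of
    T2D / IGT / NGT), the eight risk-factor columns, then the lipid-species
    columns.  Below-LOD lipid cells are NaN; :attr:`missing_mask` exposes
    them as booleans.  Risk factors are never missing.
    """

    data: pd.DataFrame

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def labels(self) -> pd.Series:
        return self.data["label"]

    @property
    def at_risk(self) -> np.ndarray:
        """Binary outcome: 1 for T2D or IGT, 0 for NGT."""
        return self.labels.isin(AT_RISK_GROUPS).to_numpy().astype(int)

    @property
    def risk_factor_names(self) -> list[str]:
        return [c for c in RISK_FACTORS if c in self.data.columns]

    @property
    def lipid_names(self) -> list[str]:
        skip = {"label", *RISK_FACTORS}
        return [c for c in self.data.columns if c not in skip]

    @property
    def lipids(self) -> pd.DataFrame:
        return self.data[self.lipid_names]

    @property
    def risk_factors(self) -> pd.DataFrame:
        return self.data[self.risk_factor_names]

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.lipids.isna()

    def validate(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate subject_id {dup!r}")
        bad = ~self.labels.isin(GROUPS)
        if bad.any():
            sid = self.data.index[bad][0]
            raise ValueError(
                f"unknown label {self.labels[sid]!r} for subject {sid!r}"
            )
        rf = self.risk_factors
        if rf.isna().any().any():
            col = rf.columns[rf.isna().any()][0]
            raise ValueError(f"missing values in risk-factor column {col!r}")
        lip = self.lipids
        nonpos = (lip <= 0).any()
        if nonpos.any():
            col = nonpos.index[nonpos][0]
            sid = lip.index[(lip[col] <= 0).fillna(False)][0]
            raise ValueError(
                f"non-positive lipid abundance at subject {sid!r}, species {col!r}"
            )

    def equals(self, other: "CohortTable") -> bool:
        return self.data.equals(other.data)


def generate_cohort(spec: CohortSpec) -> CohortTable:
    """Draw a synthetic cohort from ``spec``.

    Deterministic: equal specs (including seed) produce identical tables.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    sizes = [int(spec.n_per_group.get(g, 0)) for g in GROUPS]
    n = sum(sizes)
    labels = np.repeat(list(GROUPS), sizes)
    at_risk = np.isin(labels, AT_RISK_GROUPS).astype(float)
    ids = [f"S{i + 1:04d}" for i in range(n)]

    eff = {**DEFAULT_RISK_FACTOR_EFFECTS, **dict(spec.risk_factor_effects)}

    def shifted(name: str) -> np.ndarray:
        return rng.standard_normal(n) + eff[name] * at_risk

    # Latent triglycerides driver.  Informative lipids load on its centred
    # (within-group) part, so their coupling to triglycerides reflects shared
    # physiology while their group effect stays exactly effect_size and is
    # not inflated by the triglycerides group shift.
    z_tg = rng.standard_normal(n)
    t_tg = z_tg + eff["triglycerides"] * at_risk

    rf = pd.DataFrame(index=pd.Index(ids, name="subject_id"))
    rf["sex"] = rng.integers(0, 2, n).astype(float)
    rf["age"] = 60.0 + 12.0 * shifted("age")
    rf["systolic_bp"] = 135.0 + 16.0 * shifted("systolic_bp")
    rf["waist"] = 91.0 + 11.0 * shifted("waist")
    rf["total_cholesterol"] = np.exp(np.log(5.8) + 0.17 * shifted("total_cholesterol"))
    rf["hdl_c"] = np.exp(np.log(1.40) + 0.21 * shifted("hdl_c"))
    rf["triglycerides"] = np.exp(np.log(1.25) + 0.45 * t_tg)
    rf["hba1c"] = 5.15 + 0.30 * shifted("hba1c")

    names, name_class = lipid_names(spec.n_lipids, spec.n_informative)
    classes = sorted(set(name_class))
    class_idx = {c: i for i, c in enumerate(classes)}
    cls_of = np.array([class_idx[c] for c in name_class])

    rho = spec.class_correlation
    factors = rng.standard_normal((n, len(classes)))
    eps = rng.standard_normal((n, spec.n_lipids))
    z = np.sqrt(rho) * factors[:, cls_of] + np.sqrt(1.0 - rho) * eps

    informative = [i for i, c in enumerate(name_class) if c == "DG"][: spec.n_informative]
    a = spec.tg_coupling
    if informative:
        extra = np.sqrt(max(1.0 - rho - a * a, 0.0))
        z[:, informative] = (
            np.sqrt(rho) * factors[:, [cls_of[i] for i in informative]]
            + a * z_tg[:, None]
            + extra * eps[:, informative]
            + spec.effect_size * at_risk[:, None]
        )

    mu = rng.uniform(-1.0, 3.0, spec.n_lipids)
    sigma = rng.uniform(0.3, 0.8, spec.n_lipids)
    log_abund = mu + sigma * z

    # Batch effect: per-species multiplicative factor on raw abundances
    # (jittered around batch_scale) plus a common additive log shift.
    if spec.batch_scale != 1.0 or spec.batch_log_shift != 0.0:
        species_factor = np.exp(
            np.log(spec.batch_scale) + 0.2 * rng.standard_normal(spec.n_lipids)
        )
        log_abund = log_abund + np.log(species_factor) + spec.batch_log_shift

    abund = np.exp(log_abund)

    # Below-LOD censoring: the lowest lod_quantile fraction of each species.
    if spec.lod_quantile > 0 and n > 0:
        m = int(np.floor(spec.lod_quantile * n))
        if m > 0:
            order = np.argsort(abund, axis=0, kind="stable")
            rows = order[:m, :]
            cols = np.broadcast_to(np.arange(spec.n_lipids), rows.shape)
            abund[rows, cols] = np.nan

    lip = pd.DataFrame(abund, index=rf.index, columns=names)
    data = pd.concat([pd.Series(labels, index=rf.index, name="label"), rf, lip], axis=1)
    table = CohortTable(data)
    table.validate()
    return table


MISSING_TOKEN = "NA"


def write_cohort(table: CohortTable, destination, sep: str = "\t") -> None:
    """Serialize to delimited text; below-LOD cells become the ``NA`` token."""
    table.data.to_csv(destination, sep=sep, na_rep=MISSING_TOKEN, index=True)


def cohort_to_text(table: CohortTable, sep: str = "\t") -> str:
    buf = io.StringIO()
    write_cohort(table, buf, sep=sep)
    return buf.getvalue()


def read_cohort(source, sep: str = "\t") -> CohortTable:
    """Parse a cohort table written by :func:`write_cohort`.

    Raises ``ValueError`` naming the offending row/column on unknown label
    tokens, duplicate subject ids, or non-numeric cells.
    """
    df = pd.read_csv(
        source,
        sep=sep,
        index_col="subject_id",
        na_values=[MISSING_TOKEN],
        keep_default_na=False,
        dtype={"label": str},
        float_precision="round_trip",
    )
    for col in df.columns:
        if col == "label":
            continue
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad_rows = df.index[coerced.isna() & df[col].notna()]
            if len(bad_rows):
                raise ValueError(
                    f"non-numeric cell at subject {bad_rows[0]!r}, column {col!r}"
                )
            df[col] = coerced
        else:
            df[col] = df[col].astype(float)
    table = CohortTable(df)
    if len(df):
        table.validate()
    return table
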