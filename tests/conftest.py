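import numpy as np
import pandas as pd
import pytest

from liporisk.cohort import RISK_FACTORS, CohortTable


def build_cohort(labels, lipids: dict, risk_factors: dict | None = None) -> CohortTable:
    """Hand-build a small CohortTable from label and column dicts.

    Risk factors not supplied are filled with benign constants plus a tiny
    deterministic jitter so z-scoring never degenerates.
    """
    n = len(labels)
    ids = [f"S{i + 1:04d}" for i in range(n)]
    data = pd.DataFrame(index=pd.Index(ids, name="subject_id"))
    data["label"] = list(labels)
    jitter = np.linspace(-0.5, 0.5, n) if n > 1 else np.zeros(n)
    defaults = {
        "sex": np.arange(n) % 2,
        "age": 60 + jitter,
        "systolic_bp": 130 + jitter,
        "waist": 90 + jitter,
        "total_cholesterol": 5.5 + 0.1 * jitter,
        "hdl_c": 1.4 + 0.05 * jitter,
        "triglycerides": 1.3 + 0.1 * jitter,
        "hba1c": 5.2 + 0.05 * jitter,
    }
    risk_factors = risk_factors or {}
    for rf in RISK_FACTORS:
        data[rf] = np.asarray(risk_factors.get(rf, defaults[rf]), dtype=float)
    for name, values in lipids.items():
        data[name] = np.asarray(values, dtype=float)
    return CohortTable(data)


@pytest.fixture
def tiny_cohort():
    """10 subjects, 3 lipid species, one below-LOD cell."""
    lip_a = [1.0, 2.0, 3.0, 4.0, 5.0, 0.5, 0.6, 0.7, 0.8, 0.9]
    lip_b = [2.0, 2.2, 1.9, 2.1, 2.0, 1.0, 1.1, 0.9, 1.2, 1.0]
    lip_c = [np.nan, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0]
    labels = ["T2D", "T2D", "IGT", "IGT", "T2D", "NGT", "NGT", "NGT", "NGT", "NGT"]
    return build_cohort(labels, {"DG_001": lip_a, "TG_001": lip_b, "PC_001": lip_c})
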