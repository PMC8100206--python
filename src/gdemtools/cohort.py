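"""Sample metadata, SJC66 stratification, and the shared covariate design.

The clinical stratifier is the swollen joint count over 66 assessed joints
(SJC66). Samples with SJC66 >= 9 form the high group, samples with
1 <= SJC66 <= 8 the low group, and SJC66 = 0 samples are excluded from
comparative analyses (they are clinically heterogeneous). All differential
tests share one design: intercept + sex + age + DMARD use + group.
"""

from __future__ import annotations

import logging
from typing import Tuple

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SAMPLE_COLUMNS = ["sample_id", "sjc66", "sex", "age", "dmard_use", "joint_source"]

GROUP_HIGH = "high"
GROUP_LOW = "low"
GROUP_EXCLUDED = "excluded"


def dichotomize_sjc66(samples: pd.DataFrame, high_min: int = 9,
                      low_max: int = 8) -> pd.DataFrame:
    """Label each sample high / low / excluded by its SJC66.

    SJC66 >= ``high_min`` -> high; 1..``low_max`` -> low; exactly 0 ->
    excluded. Joint counts are integers, so the defaults partition every
    valid value. Returns a copy with a ``group`` column; idempotent.
    """
    sjc = pd.to_numeric(samples["sjc66"], errors="raise")
    if (sjc < 0).any():
        bad = samples.loc[sjc < 0, "sample_id"].tolist()
        raise ValueError(f"negative SJC66 for samples {bad}")
    if (sjc > 66).any():
        bad = samples.loc[sjc > 66, "sample_id"].tolist()
        raise ValueError(f"SJC66 above 66 for samples {bad}")
    out = samples.copy()
    group = np.where(sjc >= high_min, GROUP_HIGH,
                     np.where(sjc >= 1, GROUP_LOW, GROUP_EXCLUDED))
    out["group"] = group
    return out


def retained(samples: pd.DataFrame) -> pd.DataFrame:
    """Samples entering comparative analyses (high and low groups only)."""
    if "group" not in samples.columns:
        samples = dichotomize_sjc66(samples)
    return samples[samples["group"] != GROUP_EXCLUDED].copy()


def build_design(samples: pd.DataFrame) -> pd.DataFrame:
    """Covariate design matrix: intercept, sex, age, dmard_use, group.

    Sex is coded female=0 / male=1; age is mean-centred to stabilise the
    intercept; DMARD use is 0/1; group is the high-group indicator from
    :func:`dichotomize_sjc66`. Covariates constant across all retained
    samples are dropped with a warning; the group column and intercept are
    always kept. SJC66 = 0 samples never enter the design.

    Returns a DataFrame indexed by sample_id; rows follow the input order
    of the retained samples.
    """
    kept = retained(samples)
    n_high = int((kept["group"] == GROUP_HIGH).sum())
    n_low = int((kept["group"] == GROUP_LOW).sum())
    if n_high < 2 or n_low < 2:
        raise ValueError(
            f"need >= 2 samples per group, got high={n_high}, low={n_low}")

    sex_codes = kept["sex"].map({"female": 0.0, "male": 1.0})
    if sex_codes.isna().any():
        raise ValueError("sex must be 'male' or 'female'")
    age = pd.to_numeric(kept["age"], errors="raise").astype(float)
    dmard = kept["dmard_use"]
    if dmard.dtype == object:
        dmard = dmard.map({"True": 1.0, "False": 0.0, True: 1.0, False: 0.0,
                           "1": 1.0, "0": 0.0})
    dmard = dmard.astype(float)

    design = pd.DataFrame({
        "intercept": 1.0,
        "sex": sex_codes.to_numpy(dtype=float),
        "age": age.to_numpy() - age.to_numpy().mean(),
        "dmard_use": dmard.to_numpy(),
        "group": (kept["group"] == GROUP_HIGH).to_numpy(dtype=float),
    }, index=pd.Index(kept["sample_id"], name="sample_id"))

    for col in ("sex", "age", "dmard_use"):
        if design[col].nunique() <= 1:
            log.warning("covariate %r constant across retained samples; dropped", col)
            design = design.drop(columns=col)

    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return design


def read_samples_tsv(path) -> pd.DataFrame:
    """Read the tab-separated sample metadata table."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns and c != "joint_source"]
    if missing:
        raise ValueError(f"samples table missing columns: {missing}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in samples table")
    if df["dmard_use"].dtype == object:
        df["dmard_use"] = df["dmard_use"].map(
            {"True": True, "False": False, "1": True, "0": False,
             True: True, False: False})
    else:
        df["dmard_use"] = df["dmard_use"].astype(bool)
    return df
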