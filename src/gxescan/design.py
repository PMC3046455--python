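"""Design-matrix builders shared by the descriptive models and the scan.

Reference categories are deterministic: the first study label in sorted
order and the lowest observed age/category bin are the dropped dummies.
Dummies are built from *observed* levels only, so sparse strata never
produce all-zero (rank-deficient) columns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .catalog import SnpDef
from .errors import DegeneratePredictorError
from .factors import RiskFactorSpec

#: age bins used for age adjustment in the descriptive models
AGE_EDGES = (35, 40, 45, 50, 55, 60, 65, 70, 75)
AGE_LABELS = ("<=34", "35-39", "40-44", "45-49", "50-54",
              "55-59", "60-64", "65-69", "70-74", ">=75")


def study_dummies(cohort: pd.DataFrame) -> pd.DataFrame:
    """0/1 indicator columns for every study except the first (sorted)."""
    labels = sorted(cohort["study"].unique())
    study = cohort["study"].to_numpy()
    return pd.DataFrame(
        {f"study[{lab}]": (study == lab).astype(float) for lab in labels[1:]},
        index=cohort.index,
    )


def age_terms(cohort: pd.DataFrame) -> pd.DataFrame:
    """Categorical age-bin dummies (lowest observed bin dropped) + linear age.

    The continuous term accounts for residual case-control age differences
    inside the extreme bins.
    """
    age = cohort["age"].astype(float).to_numpy()
    bins = np.digitize(age, AGE_EDGES, right=False)
    observed = sorted(np.unique(bins))
    cols = {
        f"age[{AGE_LABELS[b]}]": (bins == b).astype(float) for b in observed[1:]
    }
    cols["age"] = age
    return pd.DataFrame(cols, index=cohort.index)


def base_design(cohort: pd.DataFrame, adjust_age: bool = False) -> pd.DataFrame:
    """Intercept + study dummies (+ age terms when requested)."""
    parts = [pd.DataFrame({"intercept": np.ones(len(cohort))}, index=cohort.index),
             study_dummies(cohort)]
    if adjust_age:
        parts.append(age_terms(cohort))
    return pd.concat(parts, axis=1)


def dosage_vector(subset: pd.DataFrame, snp: SnpDef) -> np.ndarray:
    d = subset[snp.rsid].astype(float).to_numpy()
    if np.nanmin(d) == np.nanmax(d):
        raise DegeneratePredictorError(
            f"dosage for {snp.name} is constant in the analysis subset"
        )
    return d


def factor_vector(subset: pd.DataFrame, factor: RiskFactorSpec) -> np.ndarray:
    e = factor.coded(subset[factor.column].astype(float).to_numpy())
    if np.nanmin(e) == np.nanmax(e):
        raise DegeneratePredictorError(
            f"factor {factor.name} is constant in the analysis subset"
        )
    return e


def interaction_design(
    subset: pd.DataFrame, snp: SnpDef, factor: RiskFactorSpec,
    adjust_age: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Full and null designs for the 1-df product-term interaction model.

    Full model: study dummies + per-allele dosage + continuous factor +
    dosage x factor product.  The null model drops only the product term.
    Returns ``(X_full, X_null, y)``.
    """
    d = dosage_vector(subset, snp)
    e = factor_vector(subset, factor)
    x = base_design(subset, adjust_age=adjust_age)
    x_null = x.assign(dosage=d, **{factor.name: e})
    x_full = x_null.assign(**{f"dosage:{factor.name}": d * e})
    y = subset["is_case"].astype(int).to_numpy()
    return x_full, x_null, y
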