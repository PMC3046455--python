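"""Cohort table I/O, validation and analysis-subset construction.

A cohort is a pandas DataFrame with one row per woman and a fixed column
schema: ``study`` (label), ``is_case`` (0/1), ``age`` (years at diagnosis
for cases / interview for controls), ``menarche_age``, ``parous``,
``n_live_births``, ``age_first_birth``, ``bmi``, ``er``, ``pr``, followed
by one 0/1/2 dosage column per SNP named by rsID.  On disk the table is a
UTF-8 TSV with a header row and ``NA`` for missing values.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import SnpCatalog, SnpDef
from .errors import EmptyAnalysisError
from .factors import RiskFactorSpec

BASE_COLUMNS = (
    "study", "is_case", "age", "menarche_age", "parous",
    "n_live_births", "age_first_birth", "bmi", "er", "pr",
)

_INT_COLUMNS = ("is_case", "age", "menarche_age", "parous",
                "n_live_births", "age_first_birth")


def cohort_columns(catalog: SnpCatalog) -> tuple[str, ...]:
    return BASE_COLUMNS + catalog.rsids


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort as UTF-8 TSV with ``NA`` for missing."""
    cohort.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_cohort(path: str | Path, catalog: SnpCatalog | None = None) -> pd.DataFrame:
    """Read a cohort TSV, coercing integer-valued columns to nullable Int64."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False,
                     dtype={"study": str, "er": str, "pr": str})
    int_cols = list(_INT_COLUMNS)
    if catalog is not None:
        int_cols += [r for r in catalog.rsids if r in df.columns]
    else:
        int_cols += [c for c in df.columns if c.startswith("rs")]
    for col in int_cols:
        if col in df.columns:
            df[col] = df[col].astype("Int64")
    return df


def validate_cohort(cohort: pd.DataFrame, catalog: SnpCatalog) -> None:
    """Check schema and record-level invariants; raise ValueError on failure."""
    problems: list[str] = []
    missing_cols = [c for c in cohort_columns(catalog) if c not in cohort.columns]
    if missing_cols:
        problems.append(f"missing columns: {missing_cols}")
    else:
        if not cohort["is_case"].isin([0, 1]).all():
            problems.append("is_case must be 0/1")
        for rsid in catalog.rsids:
            bad = cohort[rsid].dropna()
            if not bad.isin([0, 1, 2]).all():
                problems.append(f"dosage column {rsid} has values outside {{0,1,2}}")
        parous = cohort["parous"]
        nb = cohort["n_live_births"]
        if ((parous == 1) & nb.notna() & (nb < 1)).any():
            problems.append("n_live_births must be >= 1 for parous women")
        if ((parous == 0) & (nb.notna() | cohort["age_first_birth"].notna())).any():
            problems.append("parity fields must be missing for nulliparous women")
        afb = cohort["age_first_birth"]
        if (afb.notna() & (afb > cohort["age"])).any():
            problems.append("age_first_birth must not exceed age")
        bmi = cohort["bmi"]
        if (bmi.notna() & (bmi <= 0)).any():
            problems.append("bmi must be positive when present")
    if problems:
        raise ValueError("invalid cohort: " + "; ".join(problems))


def analysis_subset(cohort: pd.DataFrame, snp: SnpDef,
                    factor: RiskFactorSpec) -> pd.DataFrame:
    """Complete-case subset for one (SNP, factor) analysis.

    Keeps rows with non-missing dosage for the SNP and non-missing factor
    value, restricted by the factor's applicability rule (parous-only for
    parity variables, age stratum for the BMI factors).  Idempotent.

    Raises
    ------
    EmptyAnalysisError
        If no rows remain.
    """
    mask = cohort[snp.rsid].notna() & cohort[factor.column].notna()
    if factor.parous_only:
        mask &= cohort["parous"].eq(1).fillna(False)
    if factor.age_min is not None:
        mask &= (cohort["age"] >= factor.age_min).fillna(False)
    if factor.age_max is not None:
        mask &= (cohort["age"] < factor.age_max).fillna(False)
    subset = cohort.loc[np.asarray(mask, dtype=bool)]
    if subset.empty:
        raise EmptyAnalysisError(
            f"no usable rows for SNP {snp.name} x factor {factor.name}"
        )
    return subset
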