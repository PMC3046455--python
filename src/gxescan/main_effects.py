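"""Descriptive model families: per-allele SNP ORs, risk-factor trends, and
category-stratified per-allele ORs from a single joint model.

Adjustment conventions follow the pooled-consortium design: per-allele ORs
for all genotyped subjects adjust for study only; availability-subset runs
add age (categorical bins + continuous) and the relevant risk factor.
Risk-factor trend models always adjust for study and age; they are intended
for population-based-style cohorts (the function itself is design-agnostic
— restricting to population-based studies is the caller's choice).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import SnpDef
from .cohort import analysis_subset
from .design import base_design, dosage_vector, factor_vector
from .errors import EmptyAnalysisError
from .factors import RiskFactorSpec, categorize_array
from .logistic import ModelFit, fit_logistic, wald_or_ci


@dataclass(frozen=True)
class OrEstimate:
    """A single odds-ratio estimate with its Wald interval and counts."""

    or_: float
    ci_low: float
    ci_high: float
    n_cases: int
    n_controls: int
    fit: ModelFit | None = None


def _counts(df: pd.DataFrame) -> tuple[int, int]:
    case = df["is_case"].astype(int)
    return int((case == 1).sum()), int((case == 0).sum())


def per_allele_or(cohort: pd.DataFrame, snp: SnpDef, *,
                  adjust_age: bool = False,
                  factor: RiskFactorSpec | None = None,
                  level: float = 0.95) -> OrEstimate:
    """Per-allele OR for one SNP under the multiplicative (log-additive) model.

    With ``factor`` given, the analysis is restricted to that factor's
    availability subset and adjusts for the factor's continuous coding (the
    availability-subset column convention); otherwise all rows with a
    non-missing dosage are used and adjustment is study (plus age if
    ``adjust_age``).
    """
    if factor is not None:
        subset = analysis_subset(cohort, snp, factor)
    else:
        subset = cohort.loc[cohort[snp.rsid].notna()]
        if subset.empty:
            raise EmptyAnalysisError(f"no genotyped rows for {snp.name}")
    x = base_design(subset, adjust_age=adjust_age)
    x = x.assign(dosage=dosage_vector(subset, snp))
    if factor is not None:
        x = x.assign(**{factor.name: factor_vector(subset, factor)})
    fit = fit_logistic(x, subset["is_case"].astype(int).to_numpy())
    or_, lo, hi = wald_or_ci(fit, "dosage", level)
    n_cases, n_controls = _counts(subset)
    return OrEstimate(or_, lo, hi, n_cases, n_controls, fit)


def risk_factor_trend(cohort: pd.DataFrame, factor: RiskFactorSpec, *,
                      level: float = 0.95) -> OrEstimate:
    """Trend OR per coded unit of a risk factor, adjusted for study and age."""
    mask = cohort[factor.column].notna()
    if factor.parous_only:
        mask &= cohort["parous"].eq(1).fillna(False)
    if factor.age_min is not None:
        mask &= cohort["age"] >= factor.age_min
    if factor.age_max is not None:
        mask &= cohort["age"] < factor.age_max
    subset = cohort.loc[np.asarray(mask, dtype=bool)]
    if subset.empty:
        raise EmptyAnalysisError(f"no rows with {factor.name} available")
    x = base_design(subset, adjust_age=True)
    x = x.assign(**{factor.name: factor_vector(subset, factor)})
    fit = fit_logistic(x, subset["is_case"].astype(int).to_numpy())
    or_, lo, hi = wald_or_ci(fit, factor.name, level)
    n_cases, n_controls = _counts(subset)
    return OrEstimate(or_, lo, hi, n_cases, n_controls, fit)


@dataclass(frozen=True)
class StratumOr:
    category: str
    or_: float
    ci_low: float
    ci_high: float
    n_cases: int
    n_controls: int
    flagged: str | None = None


@dataclass(frozen=True)
class StratifiedOrTable:
    """Per-category per-allele ORs for one (SNP, factor) pair."""

    snp: str
    factor: str
    rows: tuple[StratumOr, ...]
    fit: ModelFit | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "snp": self.snp, "factor": self.factor, "category": r.category,
            "or": r.or_, "ci_low": r.ci_low, "ci_high": r.ci_high,
            "n_cases": r.n_cases, "n_controls": r.n_controls,
            "flagged": r.flagged or "",
        } for r in self.rows])


def stratified_per_allele_ors(cohort: pd.DataFrame, snp: SnpDef,
                              factor: RiskFactorSpec, *,
                              adjust_age: bool = False,
                              level: float = 0.95) -> StratifiedOrTable:
    """Per-allele ORs by risk-factor category, all from one joint fit.

    The single model contains study dummies, main-effect dummies for the
    factor categories, and one dosage slope per category; each slope's
    exponential is the per-allele OR within that category.  Categories in
    which only one outcome class occurs are flagged and omitted from the
    fit; the others are still returned.
    """
    subset = analysis_subset(cohort, snp, factor)
    cats = categorize_array(subset[factor.column].astype(float).to_numpy(), factor)
    y_all = subset["is_case"].astype(int).to_numpy()

    usable: list[int] = []
    flagged: dict[int, str] = {}
    for k in sorted(np.unique(cats)):
        sel = cats == k
        n_case = int(y_all[sel].sum())
        n_ctrl = int(sel.sum()) - n_case
        if n_case == 0 or n_ctrl == 0:
            flagged[int(k)] = "single outcome class"
        else:
            usable.append(int(k))
    if len(usable) < 1:
        raise EmptyAnalysisError(
            f"no category of {factor.name} has both outcome classes"
        )

    keep = np.isin(cats, usable)
    sub = subset.loc[keep]
    cats_kept = cats[keep]
    d = dosage_vector(sub, snp)
    x = base_design(sub, adjust_age=adjust_age)
    for k in usable[1:]:
        x[f"{factor.name}[{factor.category_labels[k]}]"] = \
            (cats_kept == k).astype(float)
    slope_terms = {}
    for k in usable:
        term = f"dosage@{factor.category_labels[k]}"
        x[term] = d * (cats_kept == k)
        slope_terms[k] = term
    fit = fit_logistic(x, sub["is_case"].astype(int).to_numpy())

    rows: list[StratumOr] = []
    for k in sorted(set(usable) | set(flagged)):
        sel = cats == k
        n_case = int(y_all[sel].sum())
        n_ctrl = int(sel.sum()) - n_case
        label = factor.category_labels[k]
        if k in flagged:
            rows.append(StratumOr(label, float("nan"), float("nan"),
                                  float("nan"), n_case, n_ctrl, flagged[k]))
        else:
            or_, lo, hi = wald_or_ci(fit, slope_terms[k], level)
            rows.append(StratumOr(label, or_, lo, hi, n_case, n_ctrl))
    return StratifiedOrTable(snp.name, factor.name, tuple(rows), fit)


def restrict_to_subtype(cohort: pd.DataFrame, receptor: str,
                        status: str) -> pd.DataFrame:
    """Keep cases of one ER/PR subtype plus all controls.

    ``receptor`` is ``"er"`` or ``"pr"``; ``status`` is ``"positive"`` or
    ``"negative"``.  Cases with the other or unknown status are dropped;
    the full control series is retained (case-control contrast per subtype).
    """
    if receptor not in ("er", "pr"):
        raise ValueError("receptor must be 'er' or 'pr'")
    is_ctrl = cohort["is_case"] == 0
    keep_case = (cohort["is_case"] == 1) & (cohort[receptor] == status)
    return cohort.loc[np.asarray(is_ctrl | keep_case, dtype=bool)]


def forest_plot(table: StratifiedOrTable, path: str) -> None:
    """Forest plot of a stratified OR table.

    Box area is inversely proportional to the squared standard error of the
    log OR (larger boxes = more precise strata).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = [r for r in table.rows if r.flagged is None]
    ys = np.arange(len(rows))[::-1]
    fig, ax = plt.subplots(figsize=(6, 1.0 + 0.6 * len(rows)))
    for y, r in zip(ys, rows):
        se = (np.log(r.ci_high) - np.log(r.ci_low)) / (2 * 1.959963984540054)
        size = 60.0 / max(se, 1e-3) ** 2
        ax.plot([r.ci_low, r.ci_high], [y, y], color="black", lw=1)
        ax.scatter([r.or_], [y], s=min(size, 600.0), marker="s", color="black")
    ax.axvline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_yticks(ys)
    ax.set_yticklabels([r.category for r in rows])
    ax.set_xscale("log")
    ax.set_xlabel("per-allele OR")
    ax.set_title(f"{table.snp} by {table.factor}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
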