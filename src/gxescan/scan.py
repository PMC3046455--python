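"""The interaction scan: a 1-df product-term test per (SNP, factor) pair.

Each test fits, on the pair's complete-case subset, a logistic model with
study dummies, a per-allele dosage term, the continuous factor coding and a
single dosage x factor product term, and compares it by likelihood-ratio
test (1 df) against the model without the product.  The default family is
12 SNPs x 6 factor tests (BMI contributes two age-stratum tests) = 72.

Tests whose subset is empty, degenerate or separated are returned as
flagged results rather than raised, so a scan always yields one row per
grid cell.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import SnpCatalog, SnpDef
from .cohort import analysis_subset
from .design import interaction_design
from .errors import (ConfigError, DegeneratePredictorError, EmptyAnalysisError,
                     SeparationError)
from .factors import DEFAULT_FACTORS, RiskFactorSpec
from .logistic import fit_logistic, lrt, wald_or_ci

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScanGrid:
    """Ordered family of (SNP, factor) tests, SNP-major."""

    snps: tuple[SnpDef, ...]
    factors: tuple[RiskFactorSpec, ...]

    @property
    def tests(self) -> tuple[tuple[SnpDef, RiskFactorSpec], ...]:
        return tuple((s, f) for s in self.snps for f in self.factors)

    def __len__(self) -> int:
        return len(self.snps) * len(self.factors)


def enumerate_tests(snps, factors=None) -> ScanGrid:
    """Build the scan grid (deterministic SNP-major ordering).

    ``snps`` may be a :class:`SnpCatalog` or a sequence of :class:`SnpDef`;
    ``factors`` defaults to the six-factor family.
    """
    snps = tuple(snps)
    if not snps:
        raise ConfigError("empty SNP list")
    names = [s.name for s in snps]
    if len(set(names)) != len(names):
        raise ConfigError("duplicate SNP names in scan grid")
    if factors is None:
        factors = tuple(DEFAULT_FACTORS.values())
    factors = tuple(factors)
    if not factors:
        raise ConfigError("empty factor list")
    return ScanGrid(snps=snps, factors=factors)


@dataclass(frozen=True)
class InteractionResult:
    """One product-term interaction test."""

    snp: str
    factor: str
    n_cases: int = 0
    n_controls: int = 0
    beta_int: float = math.nan
    se: float = math.nan
    or_int: float = math.nan
    ci_low: float = math.nan
    ci_high: float = math.nan
    lrt_stat: float = math.nan
    df: int = 1
    p: float = math.nan
    flag: str | None = None

    @property
    def ok(self) -> bool:
        return self.flag is None


def interaction_test(cohort: pd.DataFrame, snp: SnpDef, factor: RiskFactorSpec,
                     *, adjust_age: bool = False,
                     level: float = 0.95) -> InteractionResult:
    """Run one 1-df interaction test; failures return a flagged result."""
    try:
        subset = analysis_subset(cohort, snp, factor)
        y = subset["is_case"].astype(int).to_numpy()
        if y.min() == y.max():
            raise DegeneratePredictorError("single outcome class in subset")
        x_full, x_null, y = interaction_design(subset, snp, factor,
                                               adjust_age=adjust_age)
        null_fit = fit_logistic(x_null, y)
        full_fit = fit_logistic(x_full, y, beta0=np.append(
            null_fit.coefficients, 0.0))
        stat, df, p = lrt(full_fit, null_fit)
        term = f"dosage:{factor.name}"
        or_, lo, hi = wald_or_ci(full_fit, term, level)
        n_cases = int((y == 1).sum())
        return InteractionResult(
            snp=snp.name, factor=factor.name, n_cases=n_cases,
            n_controls=len(y) - n_cases, beta_int=full_fit.coef(term),
            se=full_fit.se(term), or_int=or_, ci_low=lo, ci_high=hi,
            lrt_stat=stat, df=df, p=p,
        )
    except (EmptyAnalysisError, DegeneratePredictorError, SeparationError) as exc:
        return InteractionResult(snp=snp.name, factor=factor.name,
                                 flag=f"{type(exc).__name__}: {exc}")


def run_scan(cohort: pd.DataFrame, grid: ScanGrid, *,
             adjust_age: bool = False) -> list[InteractionResult]:
    """One result (possibly flagged) per grid test, order preserved."""
    results = [interaction_test(cohort, snp, factor, adjust_age=adjust_age)
               for snp, factor in grid.tests]
    numeric = [r for r in results if r.ok]
    flagged = [r for r in results if not r.ok]
    if numeric:
        best = min(numeric, key=lambda r: r.p)
        logger.info("scan: %d tests, %d flagged; min p = %.3g (%s x %s)",
                    len(results), len(flagged), best.p, best.snp, best.factor)
    else:
        logger.warning("scan: all %d tests flagged", len(results))
    return results


def scan_to_frame(results: list[InteractionResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "snp": r.snp, "factor": r.factor, "n_cases": r.n_cases,
        "n_controls": r.n_controls, "or_int": r.or_int, "ci_low": r.ci_low,
        "ci_high": r.ci_high, "lrt": r.lrt_stat, "p": r.p,
        "flag": r.flag or "",
    } for r in results])


def write_scan(results: list[InteractionResult], path: str | Path) -> None:
    scan_to_frame(results).to_csv(path, sep="\t", index=False, na_rep="NA")
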