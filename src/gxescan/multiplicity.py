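"""Min-p family-wise multiplicity adjustment for the interaction scan.

The single-step min-p procedure compares each observed interaction p-value
with the null distribution of the *minimum* p-value across the whole test
family.  The null distribution is built either by

* **parametric bootstrap** — per test, fit the main-effects-only model
  (study + per-allele SNP + continuous factor), take each subject's fitted
  case probability, redraw a dummy case-control status (uniform draw
  compared against the probability), refit full and null interaction models
  on the dummy outcome and record the LRT p-value; the minimum across tests
  is stored per replicate; or
* **permutation** — the same machinery with case-control labels permuted
  within study inside each test's analysis subset instead of redrawn.

The adjusted p-value for test ``t`` is the proportion of replicate minima
strictly below the observed unadjusted p (the ``"strict"`` tie rule); the
``"add_one"`` rule uses ``(count + 1) / (B + 1)`` and can never return
exactly zero.

Each test keeps its own analysis subset in replicates, mirroring per-test
data availability, so replicate outcome vectors differ across tests.
Closed-form baselines (:func:`sidak`, :func:`bonferroni_threshold`) are the
independence-limit references.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy.stats import chi2

from .cohort import analysis_subset
from .design import interaction_design
from .errors import GxeError
from .logistic import fit_logistic, fit_logistic_many
from .scan import InteractionResult, ScanGrid

logger = logging.getLogger(__name__)

_CHUNK = 256


def null_probabilities(cohort: pd.DataFrame, snp, factor) -> np.ndarray:
    """Fitted case probabilities under the no-interaction null.

    Fits the main-effects-only logistic model (study dummies + per-allele
    dosage + continuous factor) on the pair's analysis subset and returns
    one probability per subject, aligned with the subset's row order.
    """
    subset = analysis_subset(cohort, snp, factor)
    _, x_null, y = interaction_design(subset, snp, factor)
    fit = fit_logistic(x_null, y)
    from scipy.special import expit
    return expit(x_null.to_numpy(dtype=float) @ fit.coefficients)


@dataclass
class _PreparedTest:
    snp: str
    factor: str
    x_full: np.ndarray
    x_null: np.ndarray
    y: np.ndarray
    probs: np.ndarray
    study_blocks: list[np.ndarray]
    null_beta: np.ndarray
    p_unadj: float


def _prepare(cohort: pd.DataFrame, grid: ScanGrid,
             results: list[InteractionResult]) -> tuple[list[_PreparedTest], int]:
    from scipy.special import expit

    if len(results) != len(grid):
        raise ValueError("scan results and grid have different lengths")
    prepared: list[_PreparedTest] = []
    n_excluded = 0
    for res, (snp, factor) in zip(results, grid.tests):
        if (res.snp, res.factor) != (snp.name, factor.name):
            raise ValueError("scan results are not aligned with the grid")
        if not res.ok:
            n_excluded += 1
            continue
        subset = analysis_subset(cohort, snp, factor)
        x_full, x_null, y = interaction_design(subset, snp, factor)
        fit = fit_logistic(x_null, y)
        xn = x_null.to_numpy(dtype=float)
        probs = expit(xn @ fit.coefficients)
        studies = subset["study"].to_numpy()
        blocks = [np.flatnonzero(studies == lab) for lab in np.unique(studies)]
        prepared.append(_PreparedTest(
            snp=snp.name, factor=factor.name,
            x_full=x_full.to_numpy(dtype=float), x_null=xn,
            y=y.astype(float), probs=probs, study_blocks=blocks,
            null_beta=fit.coefficients, p_unadj=res.p,
        ))
    if n_excluded:
        logger.warning("min-p adjustment: %d flagged tests excluded from the "
                       "family", n_excluded)
    if not prepared:
        raise GxeError("no numeric tests to adjust")
    return prepared, n_excluded


def _replicate_outcomes_bootstrap(test: _PreparedTest, n_rep: int,
                                  rng: np.random.Generator) -> np.ndarray:
    u = rng.random((test.probs.size, n_rep))
    return (u < test.probs[:, None]).astype(float)


def _replicate_outcomes_permutation(test: _PreparedTest, n_rep: int,
                                    rng: np.random.Generator) -> np.ndarray:
    out = np.empty((test.y.size, n_rep))
    for idx in test.study_blocks:
        keys = rng.random((idx.size, n_rep))
        order = np.argsort(keys, axis=0)
        out[idx] = test.y[idx][order]
    return out


def _test_replicate_pvals(test: _PreparedTest, n_replicates: int, seed_key: list,
                          method: str) -> tuple[np.ndarray, int]:
    """LRT p-value for each replicate of one test; failed fits give NaN."""
    rng = np.random.default_rng(np.random.SeedSequence(seed_key))
    draw = (_replicate_outcomes_bootstrap if method == "bootstrap"
            else _replicate_outcomes_permutation)
    beta0_full = np.append(test.null_beta, 0.0)
    pvals = np.empty(n_replicates)
    n_failed = 0
    for start in range(0, n_replicates, _CHUNK):
        stop = min(start + _CHUNK, n_replicates)
        y_rep = draw(test, stop - start, rng)
        _, ll_null, ok_null = fit_logistic_many(test.x_null, y_rep,
                                                beta0=test.null_beta)
        _, ll_full, ok_full = fit_logistic_many(test.x_full, y_rep,
                                                beta0=beta0_full)
        stat = np.clip(2.0 * (ll_full - ll_null), 0.0, None)
        p = chi2.sf(stat, 1)
        bad = ~(ok_null & ok_full)
        p[bad] = np.nan
        n_failed += int(bad.sum())
        pvals[start:stop] = p
    return pvals, n_failed


@dataclass(frozen=True)
class AdjustedScan:
    """Family-wise adjusted interaction scan."""

    snps: tuple[str, ...]
    factors: tuple[str, ...]
    p_unadjusted: np.ndarray
    p_adjusted: np.ndarray
    n_replicates: int
    seed: int
    method: str
    tie_rule: str
    minp_sample: np.ndarray
    n_failed_fits: int
    n_excluded_tests: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "snp": self.snps, "factor": self.factors,
            "p_unadjusted": self.p_unadjusted, "p_adjusted": self.p_adjusted,
        })


def adjust_from_minp(p_unadjusted: np.ndarray, minp_sample: np.ndarray,
                     tie_rule: str = "strict") -> np.ndarray:
    """Adjusted p from a replicate min-p sample.

    ``"strict"``: proportion of replicate minima strictly below each
    unadjusted p (can be exactly 0).  ``"add_one"``: ``(count+1)/(B+1)``.
    """
    p_unadjusted = np.asarray(p_unadjusted, dtype=float)
    minp = np.asarray(minp_sample, dtype=float)
    minp = minp[~np.isnan(minp)]
    if minp.size == 0:
        raise GxeError("empty replicate min-p sample")
    counts = (minp[None, :] < p_unadjusted[:, None]).sum(axis=1)
    if tie_rule == "strict":
        return counts / minp.size
    if tie_rule == "add_one":
        return (counts + 1.0) / (minp.size + 1.0)
    raise ValueError(f"unknown tie rule {tie_rule!r}")


def _run_adjustment(results: list[InteractionResult], cohort: pd.DataFrame,
                    grid: ScanGrid, n_replicates: int, seed: int, tie_rule: str,
                    method: str, n_jobs: int,
                    max_fail_fraction: float) -> AdjustedScan:
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    if n_replicates < 100:
        logger.warning("B = %d replicates gives adjusted-p resolution of only "
                       "%.3g", n_replicates, 1.0 / n_replicates)
    prepared, n_excluded = _prepare(cohort, grid, results)

    jobs = [(t, n_replicates, [int(seed), 2 * i + (method == "permutation")],
             method) for i, t in enumerate(prepared)]
    if n_jobs != 1:
        outs = Parallel(n_jobs=n_jobs)(
            delayed(_test_replicate_pvals)(*job) for job in jobs)
    else:
        outs = [_test_replicate_pvals(*job) for job in jobs]
    pmat = np.vstack([p for p, _ in outs])            # (m, B)
    n_failed = sum(nf for _, nf in outs)

    total_fits = pmat.size
    if n_failed > max_fail_fraction * total_fits:
        raise GxeError(
            f"{n_failed}/{total_fits} replicate fits failed "
            f"(> {max_fail_fraction:.0%}); results would be unreliable"
        )
    if n_failed:
        logger.info("min-p adjustment: %d/%d replicate fits failed and were "
                    "dropped from their replicates' minima", n_failed, total_fits)

    all_nan = np.isnan(pmat).all(axis=0)
    minp = np.full(n_replicates, np.nan)
    if (~all_nan).any():
        minp[~all_nan] = np.nanmin(pmat[:, ~all_nan], axis=0)

    p_unadj = np.array([t.p_unadj for t in prepared])
    p_adj = adjust_from_minp(p_unadj, minp, tie_rule)
    return AdjustedScan(
        snps=tuple(t.snp for t in prepared),
        factors=tuple(t.factor for t in prepared),
        p_unadjusted=p_unadj, p_adjusted=p_adj, n_replicates=n_replicates,
        seed=int(seed), method=method, tie_rule=tie_rule, minp_sample=minp,
        n_failed_fits=n_failed, n_excluded_tests=n_excluded,
    )


def adjust_minp(results: list[InteractionResult], cohort: pd.DataFrame,
                grid: ScanGrid, n_replicates: int = 10_000, seed: int = 0,
                tie_rule: str = "strict", n_jobs: int = 1,
                max_fail_fraction: float = 0.01) -> AdjustedScan:
    """Parametric-bootstrap min-p family-wise adjustment (default B=10,000)."""
    return _run_adjustment(results, cohort, grid, n_replicates, seed, tie_rule,
                           "bootstrap", n_jobs, max_fail_fraction)


def permutation_adjust(results: list[InteractionResult], cohort: pd.DataFrame,
                       grid: ScanGrid, n_replicates: int = 10_000, seed: int = 0,
                       tie_rule: str = "strict", n_jobs: int = 1,
                       max_fail_fraction: float = 0.01) -> AdjustedScan:
    """Permutation variant: labels permuted within study per test subset."""
    return _run_adjustment(results, cohort, grid, n_replicates, seed, tie_rule,
                           "permutation", n_jobs, max_fail_fraction)


def sidak(p: float, m: int) -> float:
    """Closed-form family-wise adjustment for m independent tests."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return float(1.0 - (1.0 - p) ** m)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance level controlling FWER at ``alpha`` over m tests."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return float(alpha) / m
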