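"""Logistic regression by IRLS, likelihood-ratio tests and Wald intervals.

This is the numerical core shared by every analysis stage.  Two fitters are
provided:

* :func:`fit_logistic` — one outcome vector, full diagnostics: Newton/IRLS
  with step-halving, separation and collinearity detection, observed-
  information covariance.
* :func:`fit_logistic_many` — one fixed design matrix against many outcome
  vectors simultaneously (the min-p bootstrap refits the same covariates
  against thousands of simulated outcomes; batching the Newton iterations
  across replicates is what makes 10,000-replicate adjustment tractable).

Convergence is declared when the largest score (gradient) component falls
below tolerance; divergence of a coefficient past ``DIVERGENCE_BOUND`` with
a non-vanishing score is reported as separation rather than returned as a
huge odds ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2, norm

from .errors import (CollinearityError, DegenerateVarianceError, NestingError,
                     SeparationError)

DEFAULT_TOL = 1e-8
MAX_ITER = 100
DIVERGENCE_BOUND = 15.0


@dataclass(frozen=True)
class ModelFit:
    """Maximum-likelihood logistic fit."""

    coefficients: np.ndarray
    covariance: np.ndarray
    log_likelihood: float
    n_used: int
    converged: bool
    term_names: tuple[str, ...]
    n_iter: int = 0

    def coef(self, term: str) -> float:
        return float(self.coefficients[self.term_names.index(term)])

    def se(self, term: str) -> float:
        i = self.term_names.index(term)
        return float(np.sqrt(self.covariance[i, i]))

    def to_record(self) -> list[dict]:
        """Serialisable per-term summary (term, beta, SE, OR, 95% CI)."""
        out = []
        for term in self.term_names:
            beta, se = self.coef(term), self.se(term)
            out.append({
                "term": term, "beta": beta, "se": se, "or": float(np.exp(beta)),
                "ci_low": float(np.exp(beta - 1.959963984540054 * se)),
                "ci_high": float(np.exp(beta + 1.959963984540054 * se)),
            })
        return out


def _as_matrix(design) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(design, pd.DataFrame):
        return design.to_numpy(dtype=float), tuple(str(c) for c in design.columns)
    x = np.asarray(design, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    return x, tuple(f"x{i}" for i in range(x.shape[1]))


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # sum y*eta - log(1 + exp(eta)), numerically stable
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(design, outcome, *, tol: float = DEFAULT_TOL,
                 max_iter: int = MAX_ITER, beta0: np.ndarray | None = None) -> ModelFit:
    """Fit a logistic regression by Newton/IRLS.

    Parameters
    ----------
    design
        Predictor table (DataFrame with named columns, or 2-D array).  The
        caller supplies the intercept column explicitly.
    outcome
        Binary 0/1 vector; both classes must be present.
    tol
        Convergence tolerance on the largest absolute score component.
    beta0
        Optional warm start.

    Raises
    ------
    CollinearityError
        If the design is rank deficient (names the dependent column).
    SeparationError
        If a coefficient diverges with non-vanishing score (names the term).
    """
    x, names = _as_matrix(design)
    y = np.asarray(outcome, dtype=float)
    n, p = x.shape
    if y.shape != (n,):
        raise ValueError(f"outcome length {y.shape} does not match design {x.shape}")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome contains a single class")

    # rank check via QR: a tiny diagonal of R pinpoints the dependent column
    r_diag = np.abs(np.diag(np.linalg.qr(x, mode="r")))
    if r_diag.size and r_diag.min() < 1e-10 * max(1.0, r_diag.max()):
        bad = names[int(np.argmin(r_diag))]
        raise CollinearityError(f"design is rank deficient near term {bad!r}")

    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    eta = x @ beta
    ll = _loglik(y, eta)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        mu = expit(eta)
        score = x.T @ (y - mu)
        max_score = np.abs(score).max()
        if max_score < tol:
            break
        if np.abs(beta).max() > DIVERGENCE_BOUND and max_score > 1e-4:
            bad = names[int(np.argmax(np.abs(beta)))]
            raise SeparationError(
                f"likely separation: |beta| diverging for term {bad!r}"
            )
        w = mu * (1.0 - mu)
        hess = (x * w[:, None]).T @ x
        try:
            step = np.linalg.solve(hess, score)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(hess + 1e-10 * np.trace(hess) * np.eye(p), score)
        # step-halving on likelihood decrease
        factor = 1.0
        for _ in range(30):
            beta_new = beta + factor * step
            eta_new = x @ beta_new
            ll_new = _loglik(y, eta_new)
            if ll_new >= ll - 1e-12:
                break
            factor *= 0.5
        beta, eta, ll = beta_new, eta_new, ll_new
    else:
        mu = expit(eta)
        if np.abs(beta).max() > DIVERGENCE_BOUND:
            bad = names[int(np.argmax(np.abs(beta)))]
            raise SeparationError(
                f"likely separation: no convergence, |beta| large for term {bad!r}"
            )

    mu = expit(eta)
    converged = bool(np.abs(x.T @ (y - mu)).max() < tol)
    w = mu * (1.0 - mu)
    hess = (x * w[:, None]).T @ x
    cov = np.linalg.inv(hess)
    return ModelFit(coefficients=beta, covariance=cov, log_likelihood=ll,
                    n_used=n, converged=converged, term_names=names, n_iter=n_iter)


def fit_logistic_many(x: np.ndarray, outcomes: np.ndarray, *,
                      beta0: np.ndarray | None = None, tol: float = 1e-6,
                      max_iter: int = 40) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit one design against many outcome vectors at once.

    Parameters
    ----------
    x
        Design matrix, shape ``(n, p)``.
    outcomes
        Outcome matrix, shape ``(n, B)`` — one logistic fit per column.
    beta0
        Warm start: either ``(p,)`` (shared) or ``(p, B)``.

    Returns
    -------
    betas : ndarray (p, B)
    logliks : ndarray (B,)
    ok : boolean ndarray (B,)
        True where the fit converged without divergence.  Batched fits use
        plain Newton (no step-halving); columns whose coefficients leave
        ``[-DIVERGENCE_BOUND, DIVERGENCE_BOUND]`` or fail to converge are
        flagged False and their results must be discarded by the caller.
    """
    x = np.asarray(x, dtype=float)
    outcomes = np.asarray(outcomes, dtype=float)
    n, p = x.shape
    n2, n_fits = outcomes.shape
    if n2 != n:
        raise ValueError("design and outcomes row counts differ")

    if beta0 is None:
        beta = np.zeros((p, n_fits))
    elif beta0.ndim == 1:
        beta = np.repeat(beta0[:, None], n_fits, axis=1).astype(float)
    else:
        beta = np.asarray(beta0, dtype=float).copy()

    diverged = np.zeros(n_fits, dtype=bool)
    converged = np.zeros(n_fits, dtype=bool)
    eye = np.eye(p)
    for _ in range(max_iter):
        eta = x @ beta
        mu = expit(eta)
        score = x.T @ (outcomes - mu)                        # (p, B)
        converged = np.abs(score).max(axis=0) < tol
        active = ~(converged | diverged)
        if not active.any():
            break
        w = mu * (1.0 - mu)
        hess = np.einsum("np,nb,nq->bpq", x, w, x, optimize=True)
        hess += (1e-10 * n) * eye
        step = np.linalg.solve(hess, score.T[:, :, None])[:, :, 0].T   # (p, B)
        beta[:, active] += step[:, active]
        diverged |= np.abs(beta).max(axis=0) > DIVERGENCE_BOUND

    eta = x @ beta
    logliks = np.sum(outcomes * eta - np.logaddexp(0.0, eta), axis=0)
    ok = converged & ~diverged
    return beta, logliks, ok


def lrt(full: ModelFit, null: ModelFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested logistic fits.

    Returns ``(statistic, df, p)`` with ``statistic = 2(l_full - l_null)``
    (clipped at 0 within numerical tolerance) and the p-value from the
    chi-square upper tail with ``df`` equal to the term-count difference.
    """
    full_terms, null_terms = set(full.term_names), set(null.term_names)
    if not null_terms < full_terms:
        raise NestingError("null model terms are not a strict subset of full model")
    if full.n_used != null.n_used:
        raise NestingError(
            f"fits use different row counts ({full.n_used} vs {null.n_used})"
        )
    stat = 2.0 * (full.log_likelihood - null.log_likelihood)
    if stat < -1e-6:
        raise NestingError(f"negative LRT statistic {stat:.3g}; fits not nested?")
    stat = max(stat, 0.0)
    df = len(full_terms) - len(null_terms)
    return stat, df, float(chi2.sf(stat, df))


def wald_or_ci(fit: ModelFit, term: str,
               level: float = 0.95) -> tuple[float, float, float]:
    """Odds ratio and Wald confidence interval ``exp(beta +/- z*SE)``."""
    i = fit.term_names.index(term)
    beta = float(fit.coefficients[i])
    var = float(fit.covariance[i, i])
    if var <= 0.0:
        raise DegenerateVarianceError(f"non-positive variance for term {term!r}")
    z = norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return float(np.exp(beta)), float(np.exp(beta - half)), float(np.exp(beta + half))
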