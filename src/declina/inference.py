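"""Univariate odds ratios and maximum-likelihood logistic regression.

Odds ratios from 2x2 tables use the cross-product estimate with the Woolf
(log-scale Wald) confidence interval.  Multivariable models are fitted by
iteratively reweighted least squares with step-halving, the textbook Newton
scheme for the binomial log-likelihood; coefficients, covariance, and both
fitted and null log-likelihoods are retained so pseudo-R² and Wald
intervals come straight off the fit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

MAX_ITER = 50
TOL = 1e-8


class InferenceError(ValueError):
    pass


class SeparationWarningError(InferenceError):
    """Raised only when callers demand a converged fit; normally separation
    is reported through ``FittedModel.converged``/``diagnostic``."""


class TwoByTwo(NamedTuple):
    """Cell counts: a = exposed with outcome, b = unexposed with outcome,
    c = exposed without outcome, d = unexposed without outcome."""

    a: int
    b: int
    c: int
    d: int


def odds_ratio(
    t: TwoByTwo, alpha: float = 0.05, continuity: bool = False
) -> tuple[float, float, float]:
    """Cross-product odds ratio (a·d)/(b·c) with the Woolf CI
    exp(ln OR ± z · sqrt(1/a + 1/b + 1/c + 1/d)).

    Zero cells make the OR undefined; pass ``continuity=True`` to add the
    Haldane-Anscombe 0.5 to every cell instead of erroring.
    """
    a, b, c, d = (float(x) for x in t)
    if min(a, b, c, d) < 0:
        raise InferenceError("negative cell count")
    if min(a, b, c, d) == 0:
        if not continuity:
            raise InferenceError(
                "zero cell: odds ratio undefined; pass continuity=True to "
                "apply the 0.5 continuity correction"
            )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = norm.ppf(1 - alpha / 2)
    return or_, or_ * math.exp(-z * se), or_ * math.exp(z * se)


# ---------------------------------------------------------------------------
# Design construction


@dataclass(frozen=True)
class Term:
    """One model term: a continuous column used as-is, or a categorical
    column expanded into treatment dummies against ``reference``."""

    column: str
    kind: str = "continuous"  # or "categorical"
    reference: str | None = None
    levels: tuple | None = None


# Standard terms of the prediction-model ladder.
TERMS = {
    "age": Term("age"),
    "sex": Term("sex", "categorical", reference="male", levels=("male", "female")),
    "polypharmacy": Term("polypharmacy", "categorical", reference=False,
                         levels=(False, True)),
    "multimorbidity": Term("multimorbidity", "categorical", reference=False,
                           levels=(False, True)),
    "living": Term("living", "categorical", reference="independent",
                   levels=("independent", "home_for_older_persons")),
    "gp_opinion": Term("gp_opinion", "categorical", reference="not_vulnerable",
                       levels=("not_vulnerable", "possibly_vulnerable", "vulnerable")),
    "iscope_score": Term("iscope_score", "categorical", reference=0,
                         levels=(0, 1, 2, 3, 4)),
}


def build_design(df: pd.DataFrame, terms: Sequence[Term | str]) -> tuple[np.ndarray, list[str]]:
    """Intercept-first design matrix; categorical terms become one dummy per
    non-reference level, named ``column[level]``."""
    cols: list[np.ndarray] = [np.ones(len(df))]
    names = ["intercept"]
    for t in terms:
        if isinstance(t, str):
            t = TERMS[t]
        if t.kind == "continuous":
            cols.append(df[t.column].to_numpy(dtype=float))
            names.append(t.column)
        else:
            levels = t.levels
            if levels is None:
                levels = tuple(sorted(df[t.column].unique()))
            for lev in levels:
                if lev == t.reference:
                    continue
                cols.append((df[t.column] == lev).to_numpy(dtype=float))
                names.append(f"{t.column}[{lev}]")
    return np.column_stack(cols), names


# ---------------------------------------------------------------------------
# Logistic fit


@dataclass
class FittedModel:
    term_names: list[str]
    coefficients: np.ndarray
    covariance: np.ndarray
    log_likelihood: float
    null_log_likelihood: float
    n_obs: int
    converged: bool
    n_iter: int
    diagnostic: str = ""

    def coef(self, name: str) -> float:
        return float(self.coefficients[self.term_names.index(name)])

    def se(self, name: str) -> float:
        i = self.term_names.index(name)
        return float(math.sqrt(self.covariance[i, i]))

    def wald_ci(self, name: str, alpha: float = 0.05) -> tuple[float, float]:
        z = norm.ppf(1 - alpha / 2)
        b, s = self.coef(name), self.se(name)
        return b - z * s, b + z * s

    def to_dict(self) -> dict:
        return {
            "terms": self.term_names,
            "coefficients": self.coefficients.tolist(),
            "covariance": self.covariance.tolist(),
            "log_likelihood": self.log_likelihood,
            "null_log_likelihood": self.null_log_likelihood,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "diagnostic": self.diagnostic,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _log_likelihood(y: np.ndarray, eta: np.ndarray) -> float:
    # log L = sum y*eta - log(1 + exp(eta)), computed stably
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(y, X: np.ndarray, names: Sequence[str] | None = None) -> FittedModel:
    """Binomial ML fit by IRLS with step-halving.

    Converges when the largest absolute coefficient change is below 1e-8,
    within 50 iterations.  Quasi-complete separation (fitted probabilities
    collapsing to 0/1, diverging coefficients) is flagged through
    ``converged=False`` with a diagnostic, never returned silently.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if y.shape[0] != n:
        raise InferenceError("outcome / design length mismatch")
    if n < p:
        raise InferenceError(f"n = {n} observations < {p} model terms")
    if names is None:
        names = [f"x{j}" for j in range(p)]
    names = list(names)
    _check_collinearity(X, names)

    beta = np.zeros(p)
    ll = _log_likelihood(y, X @ beta)
    diagnostic = ""
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-12)
        # Newton step via weighted least squares
        XtW = X.T * w
        try:
            step = np.linalg.solve(XtW @ X, X.T @ (y - mu))
        except np.linalg.LinAlgError:
            diagnostic = "singular weighted information matrix"
            break
        # step-halving on likelihood decrease
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new = _log_likelihood(y, X @ cand)
            if ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        delta = float(np.max(np.abs(cand - beta)))
        beta, ll = cand, ll_new
        if delta < TOL:
            converged = True
            break
    if converged and float(np.max(np.abs(beta))) > 30.0:
        converged = False
        diagnostic = "complete or quasi-complete separation suspected (diverging coefficients)"
    if not converged and not diagnostic:
        mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
        if np.min(np.abs(mu - y)) < 1e-6 or float(np.max(np.abs(beta))) > 30.0:
            diagnostic = "complete or quasi-complete separation suspected"
        else:
            diagnostic = f"no convergence in {MAX_ITER} iterations"

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(mu * (1.0 - mu), 1e-12)
    info = (X.T * w) @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)

    pbar = float(np.mean(y))
    if 0.0 < pbar < 1.0:
        ll0 = float(n * (pbar * math.log(pbar) + (1 - pbar) * math.log(1 - pbar)))
    else:
        ll0 = 0.0
    return FittedModel(
        term_names=names,
        coefficients=beta,
        covariance=cov,
        log_likelihood=ll,
        null_log_likelihood=ll0,
        n_obs=n,
        converged=converged,
        n_iter=it,
        diagnostic=diagnostic,
    )


def _check_collinearity(X: np.ndarray, names: Sequence[str]) -> None:
    # QR with column pivoting exposes the dependent columns by name
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    dependent = []
    kept: list[int] = []
    for j in range(X.shape[1]):
        trial = X[:, kept + [j]]
        if np.linalg.matrix_rank(trial) > len(kept):
            kept.append(j)
        else:
            dependent.append(names[j])
    raise InferenceError(
        f"collinear design: columns {dependent} are linear combinations of the others"
    )


def fit_model(df: pd.DataFrame, outcome_col: str, terms: Sequence[Term | str]) -> FittedModel:
    """Convenience wrapper: build the design from ``df`` and fit."""
    X, names = build_design(df, terms)
    y = df[outcome_col].to_numpy(dtype=float)
    return fit_logistic(y, X, names)


def nagelkerke_r2(m: FittedModel) -> float:
    """Cox-Snell pseudo-R² rescaled so its maximum is 1:
    R²_CS / (1 - exp(2·L0/n)) with R²_CS = 1 - exp(2(L0 - L1)/n)."""
    if m.n_obs == 0:
        raise InferenceError("empty model")
    if not m.converged:
        raise InferenceError(f"model did not converge: {m.diagnostic}")
    n = m.n_obs
    r2_cs = 1.0 - math.exp(2.0 * (m.null_log_likelihood - m.log_likelihood) / n)
    max_cs = 1.0 - math.exp(2.0 * m.null_log_likelihood / n)
    if max_cs == 0.0:
        return 0.0
    return min(1.0, max(0.0, r2_cs / max_cs))


def predicted_risk(m: FittedModel, X: np.ndarray) -> np.ndarray:
    """Inverse-logit of the linear predictor for design rows ``X``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != len(m.term_names):
        raise InferenceError(
            f"design has {X.shape[1]} columns, model expects terms {m.term_names}"
        )
    return 1.0 / (1.0 + np.exp(-(X @ m.coefficients)))
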