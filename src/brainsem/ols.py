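"""Frequentist multiple regression and the collider-bias algebra.

`fit_linear` is a thin, validated wrapper around statsmodels OLS: point
estimates solve the normal equations and standard errors are the classical
ones (residual variance with an n - p denominator times the diagonal of the
inverse Gram matrix).

`case2_collider_expectation` gives the probability limits of the OLS
coefficients when z is regressed on body size and *absolute* brain size
under the Case II structure brain = body + rel: substituting
rel = brain - body into E[z | body, rel] = gamma_body*body + gamma_brain*rel
yields

    E[z | body, brain] = (gamma_body - gamma_brain)*body + gamma_brain*brain

so the body coefficient converges to gamma_body - gamma_brain, not
gamma_body — the analytic form of the collider bias.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm

__all__ = ["LinearFit", "fit_linear", "case2_collider_expectation", "SingularDesignError"]


class SingularDesignError(ValueError):
    """Raised when the design matrix is rank deficient (collinear columns)."""


@dataclass
class LinearFit:
    """Point estimates and classical standard errors of one OLS fit."""

    coefficient_names: tuple[str, ...]
    estimates: np.ndarray
    standard_errors: np.ndarray
    residual_sd: float
    n_obs: int
    design_labels: str = ""

    def estimate(self, name: str) -> float:
        return float(self.estimates[self.coefficient_names.index(name)])

    def se(self, name: str) -> float:
        return float(self.standard_errors[self.coefficient_names.index(name)])


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Names of columns implicated in a rank deficiency (largest components
    of the right-singular vector of the smallest singular value)."""
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    null_vec = np.abs(vt[-1])
    return [n for n, w in zip(names, null_vec) if w > 1e-8]


def fit_linear(
    response: np.ndarray,
    predictors: Mapping[str, np.ndarray],
    include_intercept: bool = True,
) -> LinearFit:
    """Ordinary least squares of ``response`` on the named predictors.

    Rank-deficient designs raise :class:`SingularDesignError` naming the
    collinear columns rather than silently dropping any — a silently dropped
    column would mask exactly the collider structure this package studies.
    """
    y = np.asarray(response, dtype=float)
    n = y.shape[0]
    names: list[str] = []
    cols: list[np.ndarray] = []
    if include_intercept:
        names.append("intercept")
        cols.append(np.ones(n))
    for name, vec in predictors.items():
        vec = np.asarray(vec, dtype=float)
        if vec.shape[0] != n:
            raise ValueError(
                f"predictor {name!r} has length {vec.shape[0]}, response has {n}"
            )
        names.append(name)
        cols.append(vec)
    X = np.column_stack(cols)
    p = X.shape[1]
    if n <= p:
        raise ValueError(f"need more observations ({n}) than design columns ({p})")
    if np.linalg.matrix_rank(X) < p:
        bad = _collinear_columns(X, names)
        raise SingularDesignError(
            "design matrix is rank deficient; collinear columns: " + ", ".join(bad)
        )
    res = sm.OLS(y, X).fit()
    return LinearFit(
        coefficient_names=tuple(names),
        estimates=np.asarray(res.params, dtype=float),
        standard_errors=np.asarray(res.bse, dtype=float),
        residual_sd=float(np.sqrt(res.scale)),
        n_obs=n,
        design_labels=f"{'+'.join(predictors)} -> response",
    )


def case2_collider_expectation(gamma_body: float, gamma_brain: float) -> tuple[float, float]:
    """Probability limits of the (body, brain) OLS coefficients of z on
    {body, absolute brain} under the Case II structure brain = body + rel.

    Returns ``(gamma_body - gamma_brain, gamma_brain)``: the brain effect is
    recovered, the body effect is shifted by the full brain effect.  With
    gamma_body = gamma_brain the body coefficient converges to exactly 0; a
    strong brain effect makes it negative.
    """
    return (gamma_body - gamma_brain, gamma_brain)
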