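"""Cleartext reference implementations of the association algorithms.

Three dense-algebra twins serve as ground truth for the encrypted circuit:

* ``oracle_logreg`` — the *same* approximate logistic recursion the
  encrypted fit runs (degree-7 sigmoid, fixed-curvature 4 (X'X)^-1 step,
  zero initialization), in numpy.  Agreement with the encrypted fit is a
  correctness check of the circuit, not of the statistics.
* ``oracle_semi_parallel`` — the original semi-parallel algorithm with the
  exact weighted projection (X'WX)^-1 and a fully converged IRLS logistic
  fit; this is the comparator the modified algorithm is measured against.
* ``oracle_modified`` — the exact cleartext twin of the encrypted pipeline:
  approximate logistic fit, Newton-Raphson reciprocal from x0 = 3, and the
  unweighted projection M = I - X (X'X)^-1 X'.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .logreg import precompute_xtx_inv, sigmoid7_poly

__all__ = [
    "OracleResult",
    "oracle_logreg",
    "oracle_semi_parallel",
    "oracle_modified",
    "exact_logistic_fit",
]

_DENOM_EPS = 1e-8


def _exact_sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass
class OracleResult:
    """Cleartext per-SNP effects and error terms, plus the fitted weights."""

    b: np.ndarray | None = None  # original algorithm
    err: np.ndarray | None = None
    b_prime: np.ndarray | None = None  # modified algorithm
    err_prime: np.ndarray | None = None
    beta_exact: np.ndarray | None = None
    beta_approx: np.ndarray | None = None


def oracle_logreg(X, y, kappa: int, return_p: bool = False, sigmoid=sigmoid7_poly):
    """Approximate logistic recursion in dense arithmetic.

    beta starts at zero; each iteration applies
    ``beta += 4 (X'X)^-1 X' (y - sigma7(X beta))``.  The returned ``p``
    (when requested) is the probability vector of the *last* iteration,
    i.e. evaluated at the weights before the final update — matching what
    the encrypted pipeline hands downstream.  ``sigmoid`` swaps the
    polynomial for another link (e.g. the exact sigmoid) in
    approximation-quality studies.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    xtx_inv = precompute_xtx_inv(X)
    beta = np.zeros(X.shape[1])
    p = None
    for _ in range(kappa):
        p = sigmoid(X @ beta)
        beta = beta + 4.0 * (xtx_inv @ (X.T @ (y - p)))
    return (beta, p) if return_p else beta


def exact_logistic_fit(X, y, tol: float = 1e-10, maxiter: int = 50) -> np.ndarray:
    """Exact-Newton (IRLS) logistic coefficients via statsmodels GLM."""
    model = sm.GLM(np.asarray(y, dtype=float), np.asarray(X, dtype=float),
                   family=sm.families.Binomial())
    return np.asarray(model.fit(tol=tol, maxiter=maxiter).params)


def _newton_reciprocal(w: np.ndarray, iters: int, x0: float = 3.0) -> np.ndarray:
    x = np.full_like(w, x0)
    for _ in range(iters):
        x = x * (2.0 - w * x)
    return x


def _assoc(w, z_resid, S_resid):
    """b = (w . z_resid)' S_resid / colsum(w . S_resid^2) and its reciprocal."""
    den = (w[:, None] * S_resid**2).sum(axis=0)
    num = (w * z_resid) @ S_resid
    ok = np.abs(den) > _DENOM_EPS
    b = np.full(den.shape, np.nan)
    err = np.full(den.shape, np.nan)
    b[ok] = num[ok] / den[ok]
    err[ok] = 1.0 / den[ok]
    return b, err


def oracle_semi_parallel(X, y, S, approx_weights: bool = False, kappa: int = 3) -> OracleResult:
    """Original semi-parallel algorithm with the exact weighted projection.

    z = X beta + W^-1 (y - p); S* and z* are residualized with
    ``X (X'WX)^-1 X' W``; b = (W z*)' S* / colsum(W (S*)^2), err the
    reciprocal denominator.  By default the logistic weights come from a
    fully converged IRLS fit; ``approx_weights=True`` instead uses the
    kappa-step approximate recursion (either weight model is a defensible
    comparator, so both are supported).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    S = np.asarray(S, dtype=float)
    if approx_weights:
        beta, p = oracle_logreg(X, y, kappa, return_p=True)
    else:
        beta = exact_logistic_fit(X, y)
        p = 1.0 / (1.0 + np.exp(-(X @ beta)))
    w = p * (1.0 - p)
    z = X @ beta + (y - p) / w
    xtwx = X.T @ (w[:, None] * X)
    try:
        H = X @ np.linalg.solve(xtwx, X.T * w)  # X (X'WX)^-1 X' W
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"X'WX is singular: {exc}") from exc
    S_star = S - H @ S
    z_star = z - H @ z
    b, err = _assoc(w, z_star, S_star)
    return OracleResult(b=b, err=err, beta_exact=beta)


def oracle_modified(
    X, y, S, kappa: int = 3, newton_iters: int = 7, numerator_weight: str = "w",
    exact_reciprocal: bool = False, exact_sigmoid: bool = False,
) -> OracleResult:
    """Cleartext twin of the encrypted modified pipeline.

    Mirrors every approximation the circuit makes: sigma7 logistic
    recursion, Newton reciprocal of w from x0 = 3 with the configured
    iteration count, and the unweighted projection M = I - X (X'X)^-1 X'.
    ``exact_reciprocal`` / ``exact_sigmoid`` swap in the exact operations
    for approximation-quality studies.  ``numerator_weight`` mirrors the
    pipeline flag ("w" for the defining formula, "w_inv" for the
    walkthrough variant).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    S = np.asarray(S, dtype=float)
    link = _exact_sigmoid if exact_sigmoid else sigmoid7_poly
    beta, p = oracle_logreg(X, y, kappa, return_p=True, sigmoid=link)
    w = p * (1.0 - p)
    w_inv = 1.0 / w if exact_reciprocal else _newton_reciprocal(w, newton_iters)
    z = X @ beta + w_inv * (y - p)
    xtx_inv = precompute_xtx_inv(X)
    P = X @ xtx_inv @ X.T
    z_prime = z - P @ z
    S_prime = S - P @ S
    weight = w if numerator_weight == "w" else w_inv
    den = (w[:, None] * S_prime**2).sum(axis=0)
    num = (weight * z_prime) @ S_prime
    ok = np.abs(den) > _DENOM_EPS
    b_prime = np.full(den.shape, np.nan)
    err_prime = np.full(den.shape, np.nan)
    b_prime[ok] = num[ok] / den[ok]
    err_prime[ok] = 1.0 / den[ok]
    return OracleResult(b_prime=b_prime, err_prime=err_prime, beta_approx=beta)
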