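"""Homomorphic logistic regression with a fixed-curvature Newton step.

The covariate-only logistic model is fitted under encryption with two
approximations that make Newton-Raphson HE-friendly:

* the Hessian is replaced by the Bohning-Lindsay lower bound
  ``H~ = (1/4) X'X``, whose inverse is computed once in clear and shipped
  encrypted, so no matrix inversion happens under encryption; and
* the sigmoid is replaced by a degree-7 least-squares polynomial
  ``sigma7(x) = 0.5 + 1.73496 (x/8) - 4.19407 (x/8)^3 + 5.43402 (x/8)^5
  - 2.50739 (x/8)^7``, accurate on |x| <~ 8.

Each of the ``kappa`` iterations then reads
``beta <- beta + 4 (X'X)^-1 X' (y - sigma7(X beta))``, an ascent step on
the log-likelihood.  Because sigma7(0) = 0.5, padding slots beyond the
sample block pick up phantom half-samples; a plaintext 0/1 mask re-zeroes
them every iteration so downstream column sums stay clean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ckks import CkksBackend, NoiseBudgetError, SlotCipher, ceil_pow2
from .cohort import CohortData
from .packing import CPMatrix, RPMatrix, REPMatrix, cp_matvec, pack_cp, pack_rep, pack_rp, rp_matvec

__all__ = [
    "SIGMOID7_COEFFS",
    "sigmoid7",
    "sigmoid7_poly",
    "precompute_xtx_inv",
    "DesignInputs",
    "LogisticState",
    "build_design_inputs",
    "hom_logistic_regression",
]

# Odd-power coefficients of the degree-7 sigmoid approximation in t = x/8
# (least-squares fit of the logistic sigmoid over [-8, 8]).  Note the signs:
# the polynomial must be increasing at 0 to approximate the sigmoid; the
# reflected variant sigma7(-x) sometimes seen in print belongs to the
# convention that codes labels as +-1 and evaluates sigma at -x.
SIGMOID7_COEFFS = {1: 1.73496, 3: -4.19407, 5: 5.43402, 7: -2.50739}


def sigmoid7_poly(x):
    """Cleartext sigma7: the same polynomial on a numpy array."""
    t = np.asarray(x, dtype=float) / 8.0
    t2 = t * t
    c = SIGMOID7_COEFFS
    return 0.5 + t * (c[1] + t2 * (c[3] + t2 * (c[5] + c[7] * t2)))


def sigmoid7(x: SlotCipher) -> SlotCipher:
    """Encrypted sigma7 at four sequential ciphertext-multiplication levels.

    t = x * (1/8) is one plaintext mult; the odd polynomial is then Horner
    in t^2: t2 = t*t, three nested ciphertext mults, with the leading
    coefficient applied as a plaintext mult off the critical chain's start.
    """
    b = x.backend
    c = SIGMOID7_COEFFS
    t = b.mult_plain(x, 0.125)
    t2 = b.mult(t, t)
    r = b.add(b.mult_plain(t2, c[7]), c[5])
    r = b.add(b.mult(r, t2), c[3])
    r = b.add(b.mult(r, t2), c[1])
    return b.add(b.mult(r, t), 0.5)


def precompute_xtx_inv(X) -> np.ndarray:
    """Cleartext (X'X)^-1, the encrypted input standing in for the Hessian.

    Performed in clear before encryption (it depends only on covariates),
    so it is not metered.
    """
    X = np.asarray(X, dtype=float)
    xtx = X.T @ X
    cond = np.linalg.cond(xtx)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"X'X is singular or near-singular (condition number {cond:.3g}); "
            "check for collinear or constant covariates"
        )
    return np.linalg.inv(xtx)


@dataclass
class DesignInputs:
    """Encrypted design: X in the three packings the circuit needs, y, masks."""

    X_cp: CPMatrix  # n x (d+1), intercept column first
    Xt_rp: RPMatrix  # X' as a row-packed matrix (rows = columns of X)
    Xt_rep: REPMatrix  # X' row-expanded with rep_factor ceil2(n), for the projection
    y: SlotCipher
    xtx_inv_cp: CPMatrix  # (d+1) x (d+1), precomputed in clear
    sample_mask: np.ndarray  # 1 on the n sample slots, 0 elsewhere
    n: int
    d: int
    padded_n: int


def build_design_inputs(cohort: CohortData, backend: CkksBackend) -> DesignInputs:
    X, y = cohort.X, cohort.y
    n, dp1 = X.shape
    q = ceil_pow2(n)
    mask = np.zeros(backend.params.slot_count)
    mask[:n] = 1.0
    return DesignInputs(
        X_cp=pack_cp(X, backend),
        Xt_rp=pack_rp(X.T, backend),
        Xt_rep=pack_rep(X.T, backend, rep_factor=q),
        y=backend.encrypt(y),
        xtx_inv_cp=pack_cp(precompute_xtx_inv(X), backend),
        sample_mask=mask,
        n=n,
        d=dp1 - 1,
        padded_n=q,
    )


@dataclass
class LogisticState:
    """Result of the encrypted fit: weights, last-iteration probabilities."""

    beta: SlotCipher  # slots 0..d hold (beta_0 .. beta_d)
    p: SlotCipher  # per-sample probabilities, zero on padding slots
    iteration: int


def hom_logistic_regression(
    inputs: DesignInputs, kappa: int, debug_decrypt=None
) -> LogisticState:
    """Run ``kappa`` fixed-curvature Newton iterations under encryption.

    Per iteration: u = X beta (CP matvec); p = sigma7(u) re-masked to the
    sample block; g = X'(y - p) (RP matvec); beta += 4 (X'X)^-1 g.  beta
    starts from an encrypted zero vector.  The returned ``p`` corresponds
    to the weights *before* the final update, which is what the downstream
    working-response computation consumes.

    ``debug_decrypt(iteration, beta_clear)`` is called with the decrypted
    weights after each iteration when provided.
    """
    if kappa < 1:
        raise ValueError("kappa must be >= 1")
    b = inputs.X_cp.backend
    beta = b.encrypt(np.zeros(inputs.d + 1))
    p = None
    for it in range(1, kappa + 1):
        try:
            u = cp_matvec(inputs.X_cp, beta)
            p = b.mult_plain(sigmoid7(u), inputs.sample_mask)
            g = rp_matvec(inputs.Xt_rp, b.sub(inputs.y, p))
            h = cp_matvec(inputs.xtx_inv_cp, g)
            beta = b.add(beta, b.mult_plain(h, 4.0))
        except NoiseBudgetError as exc:
            raise NoiseBudgetError(f"logistic iteration {it}: {exc}") from exc
        if debug_decrypt is not None:
            debug_decrypt(it, b.decrypt(beta)[: inputs.d + 1].real)
    return LogisticState(beta=beta, p=p, iteration=kappa)
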