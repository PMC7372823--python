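"""The semi-parallel GWAS circuit under (simulated) encryption.

After the covariate-only logistic fit, every SNP's effect is obtained from
shared matrix algebra instead of per-SNP refits.  With W the diagonal IRLS
weight matrix (entries ``p_i (1 - p_i)``) and the working response
``z = X beta + W^-1 (y - p)``, both z and the SNP matrix S are residualized
against the covariates with the *unweighted* projection
``M = I - X (X'X)^-1 X'`` — the same fixed-curvature simplification used in
the logistic fit — giving z' = M z and S' = M S.  The per-SNP effect and
error term are then

    b'   = (w . z')' S'  /  colSum(w . S'^2)        (element-wise by SNP)
    err' = 1 / colSum(w . S'^2)

computed as numerator and denominator ciphertext column sums; the final
division happens after decryption.  (err' is the reciprocal denominator as
defined; a conventional Wald standard error would be sqrt(err').)

HE-specific machinery:

* ``inverse_slots`` — W^-1 slot-wise by Newton-Raphson ``x <- x (2 - w x)``
  from the initial guess 3, valid because w <= 1/4; padding slots are held
  at the iteration's fixed point 1/3 and re-masked to zero afterwards.
* complex SNP pairing — two SNP columns share one slot as ``x + iy``; the
  squares needed by the denominator are disentangled with the conjugate
  trick ``x^2 = Re(z z~ + z^2)/2``, ``y^2 = Re(z z~ - z^2)/2``.
* batching — a CCP product column needs ceil2(n) slots, so one ciphertext
  holds tau = 2 * slot_count / ceil2(n) real SNPs per batch (the factor 2
  from complex pairing).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ckks import (
    CapacityError,
    CkksBackend,
    DepthReport,
    SchemeParams,
    SlotCipher,
    ceil_pow2,
)
from .cohort import CohortData
from .config import RunConfig
from .logreg import (
    DesignInputs,
    LogisticState,
    build_design_inputs,
    hom_logistic_regression,
)
from .packing import (
    CCPMatrix,
    CPMatrix,
    REPMatrix,
    ccp_colsum,
    ccp_to_cp,
    cp_matmul,
    cp_matvec,
    cp_rep_matmul,
    duplicate,
    pack_rep,
    rp_matvec,
)

__all__ = [
    "WorkVectors",
    "SnpBatch",
    "GwasResult",
    "inverse_slots",
    "compute_w_and_z",
    "build_projection",
    "batch_size",
    "pack_snp_block",
    "orthogonalize_snps",
    "snp_square_split",
    "assoc_stats",
    "run_gwas",
    "HomomorphicGWAS",
    "GwasResults",
]

logger = logging.getLogger(__name__)

# Denominators below this magnitude mark monomorphic / empty SNP columns.
DENOM_EPS = 1e-8


@dataclass
class WorkVectors:
    """Per-sample work vectors: IRLS weights, their reciprocal, z and z'."""

    w: SlotCipher
    w_inv: SlotCipher
    z: SlotCipher
    z_prime: SlotCipher


@dataclass
class SnpBatch:
    """One column block of S, complex-paired and row-expanded for M x S."""

    index: int
    n_snps: int
    S_rep: REPMatrix  # n rows, ceil(n_snps/2) complex columns, rep ceil2(n)
    width: int  # complex columns


@dataclass
class GwasResult:
    """Per-SNP association output plus batch bookkeeping."""

    numerator: np.ndarray
    denominator: np.ndarray
    b_prime: np.ndarray
    err_prime: np.ndarray
    batch_index: np.ndarray
    snp_ids: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        ids = self.snp_ids or [f"snp{j+1}" for j in range(len(self.b_prime))]
        return pd.DataFrame(
            {
                "snp_id": ids,
                "numerator": self.numerator,
                "denominator": self.denominator,
                "beta": self.b_prime,
                "err": self.err_prime,
                "batch_index": self.batch_index,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# circuit stages


def inverse_slots(w: SlotCipher, iters: int) -> SlotCipher:
    """Slot-wise reciprocal by Newton-Raphson from the initial guess 3.

    ``x <- x (2 - w x)`` converges quadratically to 1/w for slots with
    ``w x0 in (0, 2)``; since IRLS weights satisfy ``w <= 1/4`` (the maximum
    of p(1-p)), x0 = 3 gives ``w x0 <= 3/4``.  Slots holding exactly 1/3
    (the padding guard) are fixed points.  Divergence on out-of-range slots
    is only detectable on decrypt.
    """
    b = w.backend
    x = b.encrypt(np.full(w.slot_count, 3.0))
    for _ in range(iters):
        t = b.mult(w, x)
        x = b.mult(x, b.sub_from_plain(2.0, t))
    return x


def compute_w_and_z(state: LogisticState, inputs: DesignInputs, iters: int) -> WorkVectors:
    """IRLS weights, their slot reciprocal, and the projected working response.

    w = p (1 - p) masked to the sample block; padding slots are parked at
    1/3 (the Newton fixed point) before inversion and re-masked to zero
    after.  z = X beta + w_inv (y - p); z' = z - X (X'X)^-1 X' z applies the
    modified (unweighted) residualization explicitly.
    """
    b = state.beta.backend
    p = state.p
    w = b.mult_plain(b.mult(p, b.sub_from_plain(1.0, p)), inputs.sample_mask)
    pad_guard = (1.0 - inputs.sample_mask) / 3.0
    w_inv = b.mult_plain(
        inverse_slots(b.add(w, pad_guard), iters), inputs.sample_mask
    )
    resid = b.sub(inputs.y, p)
    z = b.add(cp_matvec(inputs.X_cp, state.beta), b.mult(w_inv, resid))
    xtz = rp_matvec(inputs.Xt_rp, z)
    fitted = cp_matvec(inputs.X_cp, cp_matvec(inputs.xtx_inv_cp, xtz))
    z_prime = b.sub(z, fitted)
    return WorkVectors(w=w, w_inv=w_inv, z=z, z_prime=z_prime)


def build_projection(inputs: DesignInputs) -> CPMatrix:
    """Encrypted M = I - X (X'X)^-1 X' as a CP matrix.

    T = X (X'X)^-1 is a CP x CP product; T X' is a CP x REP product landing
    in a CCP matrix with stride ceil2(n), subtracted from a plaintext
    identity laid out compactly; the result is split back into CP columns
    for the batched M x S products.
    """
    b = inputs.X_cp.backend
    q = inputs.padded_n
    if q * q > b.params.slot_count:
        raise CapacityError(
            f"projection needs ceil2(n)^2 = {q * q} slots, have {b.params.slot_count}; "
            "increase log_ring_degree or reduce the cohort"
        )
    T = cp_matmul(inputs.X_cp, inputs.xtx_inv_cp)
    P = cp_rep_matmul(T, inputs.Xt_rep)
    ident = np.zeros(b.params.slot_count)
    for i in range(inputs.n):
        ident[i * q + i] = 1.0
    M_body = b.sub_from_plain(ident, P.body)
    M_ccp = CCPMatrix(body=M_body, n_rows=inputs.n, n_cols=inputs.n, col_size=q)
    return ccp_to_cp(M_ccp)


def batch_size(n: int, params: SchemeParams) -> int:
    """Maximum SNPs per batch: tau = 2 * slot_count / ceil2(n).

    One CCP product column takes ceil2(n) slots and complex pairing stores
    two SNPs per slot, so tau real SNP columns fit in one ciphertext.
    """
    q = ceil_pow2(n)
    if q > params.slot_count:
        raise CapacityError(f"ceil2(n) = {q} exceeds {params.slot_count} slots")
    tau = 2 * params.slot_count // q
    if tau < 2:
        raise CapacityError(f"slot capacity admits fewer than one complex SNP column (n={n})")
    return tau


def pack_snp_block(S_block, backend: CkksBackend, index: int = 0) -> SnpBatch:
    """Complex-pair a column block of S and row-expand it for the M product.

    Column 2t goes to the real part, column 2t+1 to the imaginary part
    (an odd block leaves the last imaginary part zero).
    """
    S_block = np.asarray(S_block, dtype=float)
    n, m = S_block.shape
    tau = batch_size(n, backend.params)
    if m > tau:
        raise CapacityError(f"block of {m} SNPs exceeds batch capacity tau = {tau}")
    width = (m + 1) // 2
    C = np.zeros((n, width), dtype=np.complex128)
    C.real = S_block[:, 0::2]
    C[:, : m // 2] += 1j * S_block[:, 1::2]
    q = ceil_pow2(n)
    return SnpBatch(index=index, n_snps=m, S_rep=pack_rep(C, backend, rep_factor=q), width=width)


def unpack_snp_block(batch: SnpBatch) -> np.ndarray:
    """Invert pack_snp_block (testing/debug): back to the real n x m block."""
    from .packing import unpack_rep

    C = unpack_rep(batch.S_rep)
    n = C.shape[0]
    out = np.empty((n, batch.n_snps))
    out[:, 0::2] = C.real[:, : (batch.n_snps + 1) // 2]
    out[:, 1::2] = C.imag[:, : batch.n_snps // 2]
    return out


def orthogonalize_snps(M_cp: CPMatrix, batch: SnpBatch) -> CCPMatrix:
    """S' = M S for one complex-paired block (CP x REP -> CCP)."""
    return cp_rep_matmul(M_cp, batch.S_rep)


def snp_square_split(S_prime: CCPMatrix) -> tuple[CCPMatrix, CCPMatrix]:
    """Squares of the paired SNPs via the conjugate trick.

    Returns CCP matrices whose slot *real parts* are x^2 (even SNPs) and
    y^2 (odd SNPs); the imaginary parts carry +-xy and are discarded at
    decrypt time.
    """
    b = S_prime.backend
    body = S_prime.body
    zz = b.mult(body, b.conjugate(body))
    z2 = b.mult(body, body)
    even = b.mult_plain(b.add(zz, z2), 0.5)
    odd = b.mult_plain(b.sub(zz, z2), 0.5)
    shape = dict(n_rows=S_prime.n_rows, n_cols=S_prime.n_cols, col_size=S_prime.col_size)
    return CCPMatrix(body=even, **shape), CCPMatrix(body=odd, **shape)


def assoc_stats(
    vectors: WorkVectors,
    S_prime: CCPMatrix,
    squares: tuple[CCPMatrix, CCPMatrix],
    batch: SnpBatch,
    numerator_weight: str = "w",
) -> tuple[SlotCipher, SlotCipher, SlotCipher]:
    """Per-batch numerator and denominator column sums (still encrypted).

    The weighted working response u = w . z' is tiled across the CCP layout
    and multiplied into S'; colSum then realizes the vector-matrix product,
    leaving the even SNP's numerator in the real part and the odd SNP's in
    the imaginary part of every stride-start slot.  Denominators do the
    same with w against the squared blocks.
    """
    b = S_prime.backend
    weight = vectors.w if numerator_weight == "w" else vectors.w_inv
    u = b.mult(weight, vectors.z_prime)
    u_dup = duplicate(u, S_prime.col_size)
    shape = dict(n_rows=S_prime.n_rows, n_cols=S_prime.n_cols, col_size=S_prime.col_size)
    numerator = ccp_colsum(CCPMatrix(body=b.mult(u_dup, S_prime.body), **shape))
    w_dup = duplicate(vectors.w, S_prime.col_size)
    den_even = ccp_colsum(CCPMatrix(body=b.mult(w_dup, squares[0].body), **shape))
    den_odd = ccp_colsum(CCPMatrix(body=b.mult(w_dup, squares[1].body), **shape))
    return numerator, den_even, den_odd


def _decode_batch(
    backend: CkksBackend,
    ciphers: tuple[SlotCipher, SlotCipher, SlotCipher],
    batch: SnpBatch,
    col_size: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Decrypt one batch's sums and re-interleave even/odd SNP columns."""
    num_ct, den_even_ct, den_odd_ct = ciphers
    starts = np.arange(batch.width) * col_size
    num_c = backend.decrypt(num_ct)[starts]
    den_e = backend.decrypt(den_even_ct)[starts].real
    den_o = backend.decrypt(den_odd_ct)[starts].real
    numerator = np.empty(batch.n_snps)
    denominator = np.empty(batch.n_snps)
    numerator[0::2] = num_c.real[: (batch.n_snps + 1) // 2]
    numerator[1::2] = num_c.imag[: batch.n_snps // 2]
    denominator[0::2] = den_e[: (batch.n_snps + 1) // 2]
    denominator[1::2] = den_o[: batch.n_snps // 2]
    return numerator, denominator


def _log_stage(backend: CkksBackend, stage: str, t0: float) -> None:
    m = backend.meter
    logger.info(
        "stage %-18s %6.2fs | ct-mults %5d pt-mults %5d rotations %6d (depth ct %d / pt %d)",
        stage, time.perf_counter() - t0, m.ct_mults, m.pt_mults, m.rotations,
        m.max_ct_depth, m.max_pt_depth,
    )


def run_gwas(cohort: CohortData, config: RunConfig | None = None):
    """Execute the full encrypted pipeline; returns (GwasResult, DepthReport).

    Stages: logistic regression (kappa iterations), working vectors and
    their projection, encrypted projection matrix, then per-batch SNP
    orthogonalization and association sums.  Numerators and denominators
    are decrypted and concatenated; the division b' = num/den and
    err' = 1/den happen in clear.  Denominators below ~1e-8 (monomorphic
    or padded SNP columns) yield NaN rather than raising.
    """
    config = config or RunConfig()
    params = config.scheme or SchemeParams.minimal_for(cohort.n)
    backend = CkksBackend(params, noise_sigma=config.noise_sigma, seed=config.seed)

    stage = "design packing"
    t0 = time.perf_counter()
    try:
        inputs = build_design_inputs(cohort, backend)
        _log_stage(backend, stage, t0)

        stage, t0 = "logistic regression", time.perf_counter()
        state = hom_logistic_regression(inputs, config.kappa)
        _log_stage(backend, stage, t0)

        stage, t0 = "working vectors", time.perf_counter()
        vectors = compute_w_and_z(state, inputs, config.newton_iters)
        _log_stage(backend, stage, t0)

        stage, t0 = "projection matrix", time.perf_counter()
        M_cp = build_projection(inputs)
        _log_stage(backend, stage, t0)
    except Exception as exc:
        raise type(exc)(f"stage '{stage}' failed: {exc}") from exc

    tau = config.batch_size_override or batch_size(cohort.n, params)
    n_batches = -(-cohort.k // tau)
    nums, dens, batch_idx = [], [], []
    for i in range(n_batches):
        t0 = time.perf_counter()
        block = cohort.S[:, i * tau : (i + 1) * tau]
        try:
            batch = pack_snp_block(block, backend, index=i)
            S_prime = orthogonalize_snps(M_cp, batch)
            squares = snp_square_split(S_prime)
            ciphers = assoc_stats(vectors, S_prime, squares, batch, config.numerator_weight)
            num, den = _decode_batch(backend, ciphers, batch, S_prime.col_size)
        except Exception as exc:
            raise type(exc)(f"stage 'snp batch' (batch {i}) failed: {exc}") from exc
        nums.append(num)
        dens.append(den)
        batch_idx.append(np.full(batch.n_snps, i, dtype=int))
        _log_stage(backend, f"snp batch {i + 1}/{n_batches}", t0)

    numerator = np.concatenate(nums)
    denominator = np.concatenate(dens)
    ok = np.abs(denominator) > DENOM_EPS
    b_prime = np.full(cohort.k, np.nan)
    err_prime = np.full(cohort.k, np.nan)
    b_prime[ok] = numerator[ok] / denominator[ok]
    err_prime[ok] = 1.0 / denominator[ok]

    result = GwasResult(
        numerator=numerator,
        denominator=denominator,
        b_prime=b_prime,
        err_prime=err_prime,
        batch_index=np.concatenate(batch_idx),
        snp_ids=list(cohort.snp_ids),
    )
    return result, backend.report()


# ---------------------------------------------------------------------------
# model / results objects


class HomomorphicGWAS:
    """Semi-parallel GWAS model over encrypted cohort data.

    Parameters
    ----------
    cohort : CohortData
    config : RunConfig, optional

    Examples
    --------
    >>> from hegwas import HomomorphicGWAS, generate_cohort, CohortSpec
    >>> cohort = generate_cohort(CohortSpec(n=32, d=2, k=8, seed=7))
    >>> results = HomomorphicGWAS(cohort).fit()
    >>> effects = results.params  # per-SNP effect estimates b'
    """

    def __init__(self, cohort: CohortData, config: RunConfig | None = None):
        self.cohort = cohort
        self.config = config or RunConfig()

    @classmethod
    def from_files(cls, covariates_path, phenotype_path, snp_path, config=None):
        from .cohort import read_cohort

        return cls(read_cohort(covariates_path, phenotype_path, snp_path), config=config)

    @classmethod
    def from_dataframes(cls, covariates, phenotype, snps, config=None):
        """Build from pandas DataFrames/Series of raw (unstandardized) inputs."""
        cov = pd.DataFrame(covariates)
        S = pd.DataFrame(snps)
        y = np.asarray(phenotype).ravel()
        cohort = CohortData.from_raw(
            cov.to_numpy(dtype=float), y, S.to_numpy(dtype=float),
            covariate_names=list(cov.columns), snp_ids=list(S.columns),
        )
        return cls(cohort, config=config)

    def fit(self) -> "GwasResults":
        result, depth = run_gwas(self.cohort, self.config)
        return GwasResults(self, result, depth)


class GwasResults:
    """Fitted per-SNP effects, their error terms, and circuit diagnostics."""

    def __init__(self, model: HomomorphicGWAS, result: GwasResult, depth: DepthReport):
        self.model = model
        self._result = result
        self.depth_report = depth
        ids = result.snp_ids
        self.params = pd.Series(result.b_prime, index=ids, name="beta")
        self.err = pd.Series(result.err_prime, index=ids, name="err")
        self.numerator = pd.Series(result.numerator, index=ids, name="numerator")
        self.denominator = pd.Series(result.denominator, index=ids, name="denominator")
        self.batch_index = pd.Series(result.batch_index, index=ids, name="batch_index")

    @property
    def raw(self) -> GwasResult:
        return self._result

    def to_frame(self) -> pd.DataFrame:
        return self._result.to_frame()

    def to_tsv(self, path) -> None:
        self._result.to_tsv(path)

    def summary(self, max_snps: int = 10) -> str:
        c = self.model.cohort
        cfg = self.model.config
        d = self.depth_report
        flagged = int(np.isnan(self._result.b_prime).sum())
        lines = [
            "Semi-parallel GWAS (homomorphic, exact slot simulator)"
            if cfg.noise_sigma == 0
            else f"Semi-parallel GWAS (homomorphic, noise sigma={cfg.noise_sigma})",
            "=" * 58,
            f"samples: {c.n}    covariates: {c.d}    SNPs: {c.k}",
            f"kappa (logistic iters): {cfg.kappa}    reciprocal iters: {cfg.newton_iters}",
            f"circuit depth: {d.ct_mult_depth} ct-mults, {d.pt_mult_depth} pt-mults, "
            f"{d.rotation_depth} rotations",
            f"flagged SNPs (zero denominator): {flagged}",
            "-" * 58,
        ]
        head = self.to_frame().head(max_snps)
        lines.append(head.to_string(index=False, float_format=lambda v: f"{v: .6g}"))
        if c.k > max_snps:
            lines.append(f"... ({c.k - max_snps} more SNPs)")
        return "\n".join(lines)
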