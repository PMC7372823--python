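"""The semi-parallel association circuit: stages and end-to-end runs."""

import numpy as np
import pytest

from hegwas.ckks import CapacityError, CkksBackend, SchemeParams
from hegwas.config import RunConfig
from hegwas.gwas import (
    HomomorphicGWAS,
    assoc_stats,
    batch_size,
    build_projection,
    compute_w_and_z,
    inverse_slots,
    orthogonalize_snps,
    pack_snp_block,
    run_gwas,
    snp_square_split,
    unpack_snp_block,
)
from hegwas.logreg import build_design_inputs, hom_logistic_regression
from hegwas.oracle import oracle_logreg, oracle_modified
from hegwas.packing import pack_ccp, pack_cp, unpack_ccp, unpack_cp
from hegwas.synthetic import CohortSpec, generate_cohort


def _newton_scalar(w, iters, x0=3.0):
    x = x0
    for _ in range(iters):
        x = x * (2.0 - w * x)
    return x


class TestInverseSlots:
    def test_fixed_point_one_third(self, make_backend):
        b = make_backend(4)
        out = b.decrypt(inverse_slots(b.encrypt([1 / 3, 1 / 3]), 6))
        assert np.allclose(out[:2].real, 3.0, atol=1e-12)

    def test_upper_bound_weight(self, make_backend):
        # w = 0.25 (the maximum of p(1-p)) inverts to 4 within 1e-6 by 6 iters
        b = make_backend(4)
        out = b.decrypt(inverse_slots(b.encrypt([0.25]), 6))[0].real
        assert abs(out - 4.0) < 1e-6
        assert out == pytest.approx(_newton_scalar(0.25, 6), abs=1e-12)

    def test_matches_scalar_oracle_across_range(self, make_backend):
        b = make_backend(5)
        w = np.linspace(0.05, 0.25, 9)
        out = b.decrypt(inverse_slots(b.encrypt(w), 7))[:9].real
        expect = [_newton_scalar(wi, 7) for wi in w]
        assert np.allclose(out, expect, atol=1e-12)
        assert np.allclose(out, 1.0 / w, atol=1e-6)


@pytest.fixture(scope="module")
def fitted():
    cohort = generate_cohort(CohortSpec(n=16, d=2, k=12, seed=3))
    backend = CkksBackend(SchemeParams.minimal_for(16))
    inputs = build_design_inputs(cohort, backend)
    state = hom_logistic_regression(inputs, kappa=3)
    return cohort, backend, inputs, state


class TestComputeWAndZ:
    def test_uniform_case_after_one_iteration(self):
        cohort = generate_cohort(CohortSpec(n=16, d=2, k=4, seed=5))
        backend = CkksBackend(SchemeParams.minimal_for(16))
        inputs = build_design_inputs(cohort, backend)
        state = hom_logistic_regression(inputs, kappa=1)  # p = 0.5 everywhere
        work = compute_w_and_z(state, inputs, iters=7)
        n = cohort.n
        w = backend.decrypt(work.w)[:n].real
        assert np.allclose(w, 0.25, atol=1e-9)
        beta = backend.decrypt(state.beta)[:3].real
        z_expect = cohort.X @ beta + 4.0 * (cohort.y - 0.5)
        assert np.allclose(backend.decrypt(work.z)[:n].real, z_expect, atol=1e-5)

    def test_matches_cleartext_formulas(self, fitted):
        cohort, backend, inputs, state = fitted
        work = compute_w_and_z(state, inputs, iters=7)
        _, p = oracle_logreg(cohort.X, cohort.y, 3, return_p=True)
        beta = backend.decrypt(state.beta)[:3].real
        n = cohort.n
        w_expect = p * (1 - p)
        assert np.allclose(backend.decrypt(work.w)[:n].real, w_expect, atol=1e-6)
        assert np.allclose(backend.decrypt(work.w_inv)[:n].real, 1 / w_expect, atol=1e-6)
        z_expect = cohort.X @ beta + (cohort.y - p) / w_expect
        assert np.allclose(backend.decrypt(work.z)[:n].real, z_expect, atol=1e-5)
        P = cohort.X @ np.linalg.inv(cohort.X.T @ cohort.X) @ cohort.X.T
        assert np.allclose(
            backend.decrypt(work.z_prime)[:n].real, z_expect - P @ z_expect, atol=1e-5
        )

    def test_padding_slots_exactly_zero(self, fitted):
        cohort, backend, inputs, state = fitted
        work = compute_w_and_z(state, inputs, iters=7)
        for ct in (work.w, work.w_inv, work.z, work.z_prime):
            assert np.all(backend.decrypt(ct)[cohort.n :] == 0.0)


class TestBuildProjection:
    def test_intercept_only_is_centering_matrix(self):
        from types import SimpleNamespace

        n = 8
        backend = CkksBackend(SchemeParams.minimal_for(n))
        cohort = SimpleNamespace(X=np.ones((n, 1)), y=np.zeros(n))
        inputs = build_design_inputs(cohort, backend)
        M = unpack_cp(build_projection(inputs)).real
        assert np.allclose(M, np.eye(n) - np.full((n, n), 1 / n), atol=1e-8)

    def test_annihilates_covariates_and_idempotent(self, fitted):
        cohort, backend, inputs, _ = fitted
        M = unpack_cp(build_projection(inputs)).real
        assert np.max(np.abs(M @ cohort.X)) < 1e-6
        assert np.allclose(M @ M, M, atol=1e-5)

    def test_capacity_error_when_projection_too_large(self):
        # 64 slots cannot hold the 16x16 projection (ceil2(n)^2 = 256); the
        # capacity violation surfaces while packing the row-expanded design
        cohort = generate_cohort(CohortSpec(n=16, d=2, k=4, seed=5))
        backend = CkksBackend(SchemeParams(log_ring_degree=7))
        with pytest.raises(CapacityError):
            build_projection(build_design_inputs(cohort, backend))


class TestBatching:
    def test_reference_parameter_point(self):
        params = SchemeParams(log_ring_degree=17)
        tau = batch_size(245, params)
        assert tau == 512
        assert -(-10643 // tau) == 21

    def test_half_capacity_edge(self):
        params = SchemeParams(log_ring_degree=7)  # 64 slots
        assert batch_size(32, params) == 4

    def test_tau_is_power_of_two(self):
        for n in (3, 17, 100, 245):
            tau = batch_size(n, SchemeParams(log_ring_degree=17))
            assert tau & (tau - 1) == 0


class TestSnpPacking:
    def test_two_columns_one_complex(self, make_backend):
        b = make_backend(7)
        batch = pack_snp_block(np.array([[1.0, 0.0], [0.0, 1.0]]), b)
        assert batch.width == 1
        from hegwas.packing import unpack_rep

        C = unpack_rep(batch.S_rep)
        assert np.allclose(C[:, 0], [1.0, 1.0j])

    @pytest.mark.parametrize("m", [1, 2, 3])
    def test_roundtrip_and_width(self, make_backend, rng, m):
        b = make_backend(7)
        S = rng.integers(0, 3, size=(4, m)).astype(float)
        batch = pack_snp_block(S, b)
        assert batch.width == (m + 1) // 2
        assert np.allclose(unpack_snp_block(batch), S)

    def test_block_larger_than_tau_rejected(self, make_backend, rng):
        b = make_backend(7)  # 64 slots, n=16 -> tau = 8
        with pytest.raises(CapacityError):
            pack_snp_block(rng.integers(0, 3, size=(16, 9)).astype(float), b)


class TestOrthogonalizeAndSquares:
    def test_identity_projection_keeps_block(self, make_backend, rng):
        b = make_backend(7)
        S = rng.integers(0, 3, size=(4, 4)).astype(float)
        batch = pack_snp_block(S, b)
        M = pack_cp(np.eye(4), b)
        S_prime = orthogonalize_snps(M, batch)
        C = unpack_ccp(S_prime)
        assert np.allclose(C.real, S[:, 0::2], atol=1e-8)
        assert np.allclose(C.imag, S[:, 1::2], atol=1e-8)

    def test_real_and_imag_parts_match_dense_projection(self, fitted):
        cohort, backend, inputs, _ = fitted
        M_cp = build_projection(inputs)
        batch = pack_snp_block(cohort.S[:, :6], backend)
        C = unpack_ccp(orthogonalize_snps(M_cp, batch))
        P = cohort.X @ np.linalg.inv(cohort.X.T @ cohort.X) @ cohort.X.T
        M = np.eye(cohort.n) - P
        assert np.allclose(C.real, M @ cohort.S[:, 0:6:2], atol=1e-6)
        assert np.allclose(C.imag, M @ cohort.S[:, 1:6:2], atol=1e-6)
        # each orthogonalized SNP column is annihilated by the covariates
        assert np.max(np.abs(cohort.X.T @ C.real)) < 1e-6

    @pytest.mark.parametrize(
        "z,x2,y2", [(3.0 + 0j, 9.0, 0.0), (2j, 0.0, 4.0), (1 + 2j, 1.0, 4.0)]
    )
    def test_conjugate_squaring_scalars(self, make_backend, z, x2, y2):
        b = make_backend(4)
        ccp = pack_ccp(np.array([[z]]), b, col_size=1)
        even, odd = snp_square_split(ccp)
        assert b.decrypt(even.body)[0].real == pytest.approx(x2, abs=1e-9)
        assert b.decrypt(odd.body)[0].real == pytest.approx(y2, abs=1e-9)


class TestAssocStats:
    def test_small_batch_matches_cleartext(self):
        cohort = generate_cohort(CohortSpec(n=8, d=1, k=4, seed=21))
        backend = CkksBackend(SchemeParams.minimal_for(8))
        inputs = build_design_inputs(cohort, backend)
        state = hom_logistic_regression(inputs, kappa=3)
        work = compute_w_and_z(state, inputs, iters=7)
        M_cp = build_projection(inputs)
        batch = pack_snp_block(cohort.S, backend)
        S_prime = orthogonalize_snps(M_cp, batch)
        ciphers = assoc_stats(work, S_prime, snp_square_split(S_prime), batch)
        from hegwas.gwas import _decode_batch

        num, den = _decode_batch(backend, ciphers, batch, S_prime.col_size)
        # dense evaluation of the same formulas
        _, p = oracle_logreg(cohort.X, cohort.y, 3, return_p=True)
        beta = backend.decrypt(state.beta)[:2].real
        w = p * (1 - p)
        w_inv = np.array([_newton_scalar(v, 7) for v in w])
        z = cohort.X @ beta + w_inv * (cohort.y - p)
        P = cohort.X @ np.linalg.inv(cohort.X.T @ cohort.X) @ cohort.X.T
        zp = z - P @ z
        Sp = cohort.S - P @ cohort.S
        assert np.allclose(num, (w * zp) @ Sp, atol=1e-6)
        assert np.allclose(den, (w[:, None] * Sp**2).sum(axis=0), atol=1e-6)


class TestRunGwas:
    def test_matches_modified_oracle(self):
        cohort = generate_cohort(CohortSpec(n=16, d=2, k=12, seed=3))
        result, _ = run_gwas(cohort, RunConfig())
        orc = oracle_modified(cohort.X, cohort.y, cohort.S)
        assert np.allclose(result.b_prime, orc.b_prime, rtol=1e-4, atol=1e-10)
        assert np.allclose(result.err_prime, orc.err_prime, rtol=1e-4, atol=1e-10)

    @pytest.mark.parametrize("k", [3, 4, 5])
    def test_batch_count_is_ceiling(self, k):
        cohort = generate_cohort(CohortSpec(n=16, d=2, k=k, seed=8))
        result, _ = run_gwas(cohort, RunConfig(batch_size_override=4))
        assert result.batch_index.max() + 1 == -(-k // 4)

    def test_batch_decomposition_transparent(self):
        cohort = generate_cohort(CohortSpec(n=16, d=2, k=8, seed=13))
        one, _ = run_gwas(cohort, RunConfig())
        many, _ = run_gwas(cohort, RunConfig(batch_size_override=2))
        assert np.allclose(one.b_prime, many.b_prime, atol=1e-10)
        assert np.allclose(one.numerator, many.numerator, atol=1e-10)

    def test_constant_snp_flagged_not_raised(self):
        cohort = generate_cohort(CohortSpec(n=16, d=2, k=6, seed=3))
        cohort.S[:, 2] = 0.0
        cohort.S[:, 4] = 2.0  # constant non-zero: killed by the projection
        result, _ = run_gwas(cohort, RunConfig())
        assert np.isnan(result.b_prime[2]) and np.isnan(result.err_prime[2])
        assert np.isnan(result.b_prime[4])
        others = np.delete(result.b_prime, [2, 4])
        assert np.all(np.isfinite(others))

    def test_denominators_positive_for_polymorphic_snps(self):
        cohort = generate_cohort(CohortSpec(n=32, d=2, k=10, seed=17))
        result, _ = run_gwas(cohort, RunConfig())
        assert np.all(result.denominator > 0)

    def test_depth_accounting_critical_path(self):
        cohort = generate_cohort(CohortSpec(n=16, d=2, k=12, seed=3))
        _, report = run_gwas(cohort, RunConfig(kappa=3, newton_iters=7))
        assert report.ct_mult_depth == 40
        assert report.pt_mult_depth == 29

    def test_walkthrough_numerator_variant(self):
        cohort = generate_cohort(CohortSpec(n=16, d=2, k=6, seed=19))
        res, _ = run_gwas(cohort, RunConfig(numerator_weight="w_inv"))
        orc = oracle_modified(cohort.X, cohort.y, cohort.S, numerator_weight="w_inv")
        assert np.allclose(res.b_prime, orc.b_prime, rtol=1e-4, atol=1e-10)

    def test_noise_emulation_stays_close_to_exact(self):
        cohort = generate_cohort(CohortSpec(n=16, d=2, k=6, seed=23))
        exact, _ = run_gwas(cohort, RunConfig())
        noisy, _ = run_gwas(cohort, RunConfig(noise_sigma=1e-9, seed=7))
        assert not np.array_equal(noisy.b_prime, exact.b_prime)
        assert np.allclose(noisy.b_prime, exact.b_prime, atol=1e-3)


class TestModelApi:
    def test_fit_returns_results_with_summary(self):
        cohort = generate_cohort(CohortSpec(n=16, d=2, k=6, seed=3))
        results = HomomorphicGWAS(cohort).fit()
        assert len(results.params) == 6
        assert results.depth_report.ct_mult_depth == 40
        text = results.summary()
        assert "40 ct-mults" in text and "snp1" in text
        orc = oracle_modified(cohort.X, cohort.y, cohort.S)
        assert np.allclose(results.params.to_numpy(), orc.b_prime, rtol=1e-4, atol=1e-10)

    def test_from_dataframes(self):
        import pandas as pd

        rng = np.random.default_rng(0)
        cov = pd.DataFrame({"age": rng.normal(50, 8, 20), "bmi": rng.normal(25, 3, 20)})
        y = rng.integers(0, 2, 20)
        snps = pd.DataFrame(rng.integers(0, 3, size=(20, 4)), columns=list("abcd"))
        results = HomomorphicGWAS.from_dataframes(cov, y, snps).fit()
        assert list(results.params.index) == list("abcd")

    def test_tsv_roundtrip(self, tmp_path):
        import pandas as pd

        cohort = generate_cohort(CohortSpec(n=16, d=2, k=5, seed=3))
        results = HomomorphicGWAS(cohort).fit()
        path = tmp_path / "results.tsv"
        results.to_tsv(path)
        df = pd.read_csv(path, sep="\t")
        assert list(df.columns) == [
            "snp_id", "numerator", "denominator", "beta", "err", "batch_index",
        ]
        assert np.allclose(df["beta"], results.params.to_numpy(), equal_nan=True)
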