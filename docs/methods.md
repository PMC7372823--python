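# Methods

## Model and procedure

`hegwas` estimates per-SNP association effects for a binary trait under a
semi-parallel scheme: one covariate-only logistic fit, then shared matrix
algebra for all SNPs. For cohort data (X ∈ ℝ^{n×(d+1)} with intercept and
standardized covariates, y ∈ {0,1}^n, S ∈ {0,1,2}^{n×k}):

1. **Logistic fit (κ iterations).** β ← β + 4(XᵀX)⁻¹Xᵀ(y − σ₇(Xβ)) from
   β = 0. The fixed matrix ¼XᵀX is the Böhning–Lindsay bound on the
   logistic Hessian; using it makes the "Newton" step a constant matrix
   multiply whose inverse is computed once in clear. σ₇ is the degree-7
   least-squares polynomial approximation of the sigmoid on [−8, 8].
2. **Working vectors.** p from the last iteration; w = p⊙(1−p);
   w⁻¹ slot-wise by Newton–Raphson x ← x(2 − wx), x₀ = 3;
   z = Xβ + w⁻¹⊙(y − p); z′ = z − X(XᵀX)⁻¹Xᵀz.
3. **Projection.** M = I − X(XᵀX)⁻¹Xᵀ, built under encryption as a
   CP×CP product followed by a CP×REP product into a column-compact
   ciphertext, then split back into columns.
4. **Per-SNP statistics, batched.** For each column block of S (two SNPs
   per complex slot): S′ = MS; numerator = colSum((w⊙z′) ⊗ S′);
   denominator = colSum(w ⊗ S′²) via the conjugate-squaring trick.
   Numerators and denominators are decrypted, concatenated, and divided
   element-wise: b′ = num/den, err′ = 1/den.

The substitution of the unweighted projection M for the exact weighted one
X(XᵀWX)⁻¹XᵀW is the method's defining approximation; the cleartext
`oracle_semi_parallel` implements the exact-weighted original for
comparison, and `oracle_modified` is the exact arithmetic twin of the
encrypted circuit (same σ₇, same Newton reciprocal, same projection).

### Assumptions

* y is binary, genotypes are 0/1/2 dosages, covariates are non-constant
  (standardization fails otherwise, by design).
* |Xβ| stays within σ₇'s useful range (|x| ≲ 8); values are not clipped.
  With standardized covariates and moderate effects this holds; strongly
  separable data will degrade the polynomial fit before it breaks the
  arithmetic.
* w ≥ w_min ≈ 0.05 on sample slots for the reciprocal accuracy statement
  below; w ≤ ¼ always (maximum of p(1−p)).
* ⌈n⌉² ≤ N/2 (⌈·⌉ = next power of two): the n×n projection must fit one
  ciphertext, capping n at 256 for the default 2¹⁷ ring.

## The simulator

The backend reproduces CKKS slot semantics exactly: a ciphertext is a
vector of N/2 complex slots plus a remaining noise budget (level). Every
ciphertext-ciphertext multiplication rescales by 45 bits, every
ciphertext-plaintext multiplication by 10 bits (the cheap-plaintext
optimization), from an initial budget of 2440 bits; exceeding the budget
raises rather than silently corrupting. Rotations decompose into
power-of-two steps (one per set bit of the offset, either direction) and
are metered accordingly; conjugation is free of rescale. No keys, RLWE
noise or security estimation are simulated — encrypt/decrypt are lift/open
— so exact mode is a bit-stable oracle. An optional noise mode adds
zero-mean Gaussian perturbation per rescale to emulate CKKS approximation
error.

Operands at different levels are aligned by silently dropping the higher
to the lower (mod-switch analogue). Rescale is bound to multiplication
uniformly; an adapter for a real library that exposes explicit rescale
would need to take control of this.

### Depth metering

Each ciphertext carries the longest operation chain that produced it
(per class: ct-mult, pt-mult, rotation); an operation's result takes the
maximum over its inputs plus one, which makes "successive operations"
well defined for DAG-shaped circuits. The full circuit at κ = 3 measures
**40 successive ciphertext multiplications and 29 plaintext
multiplications**, independent of cohort size. The count is structural
and follows from the stage order: per logistic iteration 7 ct-mults
(matvec, 4 sigmoid levels, RP-matvec dot product, update matvec) and 8
pt-mults (two replicate masks, x/8, leading sigmoid coefficient,
post-sigmoid padding mask, RP vector mask, RP combine mask, the ×4 scale);
then w (1 ct + mask), 7×2 Newton ct-mults, the w⁻¹ re-mask, w⁻¹⊙(y−p),
the explicit three-matvec z′ route, and numerator = (w⊙z′) ⊗ S′ after
Duplicate. Masks are plaintext indicator multiplications and cost the
10-bit rescale, exactly like the accounting the scheme's budget
(40·45 + 29·10 = 2090 ≤ 2440) is sized for.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `log_ring_degree` | 17 (auto-min per cohort) | log₂ N; N/2 complex slots. 2¹⁷ is the smallest ring fitting a 245-sample projection (⌈245⌉² = 2¹⁶ slots). |
| `initial_budget_bits` | 2440 | starting level; covers the measured 2090-bit critical path with headroom above one further rescale. |
| `ct_rescale_bits` / `pt_rescale_bits` | 45 / 10 | rescale amounts for ciphertext vs plaintext multiplications. |
| `kappa` | 3 | logistic iterations; the recursion contracts fast (distance to its fixed point shrinks ~5× per iteration) and each iteration costs 7 ct-mult levels. |
| `newton_iters` | 7 | reciprocal iterations. From x₀ = 3 the residual after t steps is (1−3w)^(2^t)/w; the worst case in w ∈ [0.05, 0.25] is 0.85^(2^t)/0.05 ≈ 6×10⁻⁴ at t = 6 but 2×10⁻⁸ at t = 7, so 7 is the smallest count meeting a 10⁻⁶ target. |
| `numerator_weight` | `"w"` | the defining formula weights the working response by W; `"w_inv"` selects an alternative formulation that uses W⁻¹. |
| `noise_sigma` | 0 | exact mode; >0 perturbs each rescale for robustness studies. |

## Numerical choices

* **Sigmoid sign convention.** The degree-7 coefficients are applied with
  the signs that make the polynomial increasing at 0
  (+1.73496, −4.19407, +5.43402, −2.50739 on (x/8)^{1,3,5,7}); the
  reflected variant σ₇(−x) belongs to a ±1 label-coding convention and makes the ascent recursion diverge.
* **σ₇ evaluation order.** t = x·⅛ (one pt-mult), t², then Horner in t²
  with the leading coefficient as a pt-mult: 4 sequential ct-mult levels,
  the minimum for degree 7, and a deterministic depth.
* **Padding hygiene.** σ₇(0) = ½, so padding slots acquire phantom
  half-samples; a 0/1 plaintext mask re-zeroes slots ≥ n after every
  sigmoid, and w/w⁻¹ are masked likewise. Padding slots of w are parked at
  ⅓ — the Newton fixed point for x₀ = 3 — before inversion, otherwise the
  iteration diverges on zero slots. RP matrix-vector products defensively
  re-mask their vector argument because the dot-product rotate-and-sum
  folds *every* slot into the result.
* **Degenerate SNPs.** Monomorphic or all-zero columns (and the zero
  padding of a ragged final batch) produce denominators below 10⁻⁸ and are
  flagged NaN in b′/err′ rather than raising.
* **err′** is the reciprocal denominator exactly as defined; a
  conventional standard error is √err′.
* **Level alignment** is silent (drop to lower); `add` is free.

## Synthetic cohorts

The generator emulates the reference cohort shape (n = 245, d = 4,
k = 10643): standardized Gaussian covariates; per-SNP minor-allele
frequency uniform on [0.05, 0.5] (kept away from 0 so columns are rarely
monomorphic); genotypes Binomial(2, maf); phenotype Bernoulli with the
*exact* sigmoid link on Xβ_true plus optional planted causal effects
(log-odds per genotype SD). Default truth: intercept −0.3 (prevalence
≈ 0.43), covariate effects alternating ±0.2 — moderate, realistic effect
sizes that keep |Xβ| well inside σ₇'s range.

Deliberately absent: linkage disequilibrium, population stratification,
missing genotypes, genotyping error. Passing tests therefore demonstrate
*circuit correctness* (encrypted = cleartext twin) and statistical sanity
on idealized cohorts, not robustness to real-data structure.

## What the tests establish

* Every packed-matrix operation equals its dense-algebra oracle (100
  randomized cases each, 64-slot backends, tolerances 10⁻⁸–10⁻⁹).
* The encrypted pipeline equals `oracle_modified` to 10⁻⁴ relative
  (measured ~10⁻¹³) on 20 random cohorts with n ≤ 64, k ≤ 64, and on one
  reference-size cohort (n = 245, 2¹⁶ slots).
* Batch decomposition is transparent: 1 batch vs ⌈k/τ⌉ batches agree to
  10⁻¹⁰.
* A planted causal SNP (effect 0.5/SD, maf 0.3, n = 245) gets the correct
  effect sign in ≥ 95% of 200 replicates (replicates via the cleartext
  twin; the twin-circuit equality is checked separately).
* The σ₇ approximation's statistical footprint: swapping in the exact
  reciprocal moves b′ by < 10⁻³ (measured ~10⁻⁹); swapping in the exact
  sigmoid moves it by a few 10⁻³ (the fixed-point offset of the
  approximate recursion is a few hundredths per coefficient).

Problem sizes in the default suite (64-slot unit backends, n ≤ 64
pipelines, one n = 245 run) keep the whole suite under ~10 s while still
exercising the full-ring configuration once.

## Known limitations

* No cryptography: parameter security, encoding error and RLWE noise
  growth are out of scope; conclusions about accuracy under a real CKKS
  library require the noise-emulation mode or a backend adapter.
* n ≤ 256 at the default ring degree (the single-ciphertext projection);
  larger cohorts need a larger ring.
* P-values/Wald tests are not computed (b′ and err′ are the outputs, as
  the method defines them).
* The exact weighted projection is available only in cleartext
  (`oracle_semi_parallel`), matching the method's scope.
* Rotation depth is reported but has no fixed reference value under a
  single convention; it depends on layout choices that leave slot values
  unchanged.
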