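"""Synthetic cohorts with the statistical structure the pipeline assumes.

The original benchmark cohort (245 samples, 4 covariates, 10643 SNPs) is
not redistributable, so this generator emulates its shape: standardized
Gaussian covariates with an intercept, per-SNP genotypes drawn
Binomial(2, maf) with minor-allele frequencies uniform over a configurable
range, and a Bernoulli phenotype from a logistic model over the covariates
plus optional planted causal SNPs.  The phenotype link uses the *exact*
sigmoid — the generator models truth, the pipeline models the
approximation.  Genotypes stay on the 0/1/2 scale; causal effects act on
standardized genotype columns so stated effect sizes are per-SD.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit

from .cohort import CohortData

__all__ = ["CohortSpec", "generate_cohort", "default_beta_true"]


def default_beta_true(d: int) -> np.ndarray:
    """Default truth: intercept -0.3 (prevalence ~0.43 at the mean),
    covariate effects alternating +-0.2."""
    beta = np.empty(d + 1)
    beta[0] = -0.3
    beta[1:] = 0.2 * (-1.0) ** np.arange(d)
    return beta


@dataclass
class CohortSpec:
    """Recipe for one synthetic cohort.

    ``causal`` lists (snp_index, effect) pairs; effects are log-odds per
    standard deviation of genotype.  ``maf_range`` keeps minor-allele
    frequencies away from 0 so columns are rarely monomorphic.
    """

    n: int
    d: int
    k: int
    maf_range: tuple = (0.05, 0.5)
    beta_true: np.ndarray | None = None
    causal: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < self.d + 2:
            raise ValueError(f"need n >= d + 2, got n={self.n}, d={self.d}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        for idx, _ in self.causal:
            if not (0 <= idx < self.k):
                raise ValueError(f"causal SNP index {idx} outside [0, {self.k})")

    def to_json(self) -> str:
        d = asdict(self)
        if self.beta_true is not None:
            d["beta_true"] = list(np.asarray(self.beta_true, dtype=float))
        d["causal"] = [list(c) for c in self.causal]
        return json.dumps(d, indent=2)


def generate_cohort(spec: CohortSpec) -> CohortData:
    """Draw a cohort; fully reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    cov = rng.standard_normal((spec.n, spec.d))
    sd = cov.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("degenerate draw: constant covariate column")
    cov = (cov - cov.mean(axis=0)) / sd

    mafs = rng.uniform(spec.maf_range[0], spec.maf_range[1], spec.k)
    S = rng.binomial(2, mafs, size=(spec.n, spec.k)).astype(float)

    beta = (
        np.asarray(spec.beta_true, dtype=float)
        if spec.beta_true is not None
        else default_beta_true(spec.d)
    )
    if beta.shape[0] != spec.d + 1:
        raise ValueError(f"beta_true must have length d+1={spec.d + 1}, got {beta.shape[0]}")
    X = np.column_stack([np.ones(spec.n), cov])
    eta = X @ beta
    for idx, effect in spec.causal:
        col = S[:, idx]
        colsd = col.std()
        if colsd == 0:
            raise ValueError(f"causal SNP {idx} drawn monomorphic; choose a higher maf or n")
        eta = eta + effect * (col - col.mean()) / colsd
    y = rng.binomial(1, expit(eta)).astype(float)

    return CohortData.from_raw(cov, y, S)


def write_generated(spec: CohortSpec, out_dir) -> dict:
    """Generate, write the cohort CSVs and the spec JSON sidecar."""
    from .cohort import write_cohort

    cohort = generate_cohort(spec)
    paths = write_cohort(cohort, out_dir)
    spec_path = Path(out_dir) / "cohort_spec.json"
    spec_path.write_text(spec.to_json())
    paths["spec"] = spec_path
    return paths
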