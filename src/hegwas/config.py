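"""Run configuration: scheme parameters plus pipeline knobs."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

from .ckks import SchemeParams

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run.

    Parameters
    ----------
    scheme : SchemeParams, optional
        CKKS parameters; when None the minimal ring degree for the cohort
        is chosen automatically (with the default 2440-bit budget).
    kappa : int
        Logistic-regression iterations (default 3).
    newton_iters : int
        Newton-Raphson iterations for the slot-wise reciprocal of the IRLS
        weights (default 7; from the initial guess 3 this bounds the
        reciprocal error below 1e-6 over w in [0.05, 0.25]).
    batch_size_override : int, optional
        Process this many SNPs per batch instead of the capacity formula.
    noise_sigma : float
        Per-rescale Gaussian slot perturbation emulating CKKS approximation
        error; 0 selects the exact simulator.
    seed : int, optional
        Seed for the noise emulator.
    numerator_weight : str
        "w" computes the association numerator as (W z')' S' (the defining
        formula); "w_inv" selects an alternative formulation that
        weights by W^-1 instead.
    w_min : float
        Documented lower-bound assumption on the IRLS weights governing
        reciprocal accuracy; informational, not enforced.
    """

    scheme: SchemeParams | None = None
    kappa: int = 3
    newton_iters: int = 7
    batch_size_override: int | None = None
    noise_sigma: float = 0.0
    seed: int | None = None
    numerator_weight: str = "w"
    w_min: float = 0.05

    def __post_init__(self) -> None:
        if self.kappa < 1:
            raise ValueError("kappa must be >= 1")
        if self.newton_iters < 1:
            raise ValueError("newton_iters must be >= 1")
        if self.numerator_weight not in ("w", "w_inv"):
            raise ValueError("numerator_weight must be 'w' or 'w_inv'")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.batch_size_override is not None and self.batch_size_override < 1:
            raise ValueError("batch_size_override must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.scheme is not None:
            d["scheme"] = asdict(self.scheme)
        return d
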