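"""Simulated CKKS slot semantics with noise-budget and operation metering.

The real CKKS scheme encrypts a vector of ``N/2`` complex "slots" inside a
ring element and supports slot-wise addition, multiplication, cyclic rotation
and complex conjugation.  Every multiplication is followed by a rescale that
consumes part of a finite noise budget (the ciphertext *level*); once the
budget is depleted, decryption returns garbage.

This module reproduces those semantics exactly at the value level (complex
vectors, rotations, conjugation, level book-keeping) without any lattice
cryptography: ``encrypt``/``decrypt`` are slot-level lift/open operations.
The point is to serve as a bit-stable oracle for circuits that a genuine
CKKS library could also run, and to *meter* the circuit: each homomorphic
operation updates global counters and per-ciphertext critical-path depths,
so the longest sequential chain of ciphertext multiplications, plaintext
multiplications and rotations through a circuit can be reported.

An optional noise-emulation mode perturbs slots by a zero-mean Gaussian at
every rescale to mimic CKKS approximation error; it is off by default so
that exact mode remains a clean oracle.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SchemeParams",
    "SlotCipher",
    "OpMeter",
    "DepthReport",
    "CkksBackend",
    "CapacityError",
    "NoiseBudgetError",
    "ShapeError",
    "popcount_rotations",
]


class CapacityError(ValueError):
    """More values than the scheme has slots."""


class ShapeError(ValueError):
    """Operands with incompatible slot counts."""


class NoiseBudgetError(RuntimeError):
    """An operation would drive the remaining noise budget below zero."""


def popcount_rotations(r: int) -> int:
    """Number of power-of-two rotations composing a rotation by ``r`` slots.

    A rotation by ``r`` decomposes into one power-of-two rotation per set bit
    of ``r`` (e.g. 245 = 0b11110101 needs 6, 256 = 0b100000000 needs 1).
    """
    return int(r).bit_count()


@dataclass(frozen=True)
class SchemeParams:
    """CKKS parameter set: ring degree, budget, rescale amounts.

    Parameters
    ----------
    log_ring_degree : int
        log2 of the ring degree N; the scheme packs ``N/2`` complex slots.
    initial_budget_bits : int
        log2 of the initial ciphertext modulus L (fresh-ciphertext level).
    ct_rescale_bits : int
        Bits consumed by the rescale after a ciphertext-ciphertext
        multiplication (default 45).
    pt_rescale_bits : int
        Bits consumed after a ciphertext-plaintext multiplication
        (default 10); smaller because plaintext masks need less precision.
    """

    log_ring_degree: int = 17
    initial_budget_bits: int = 2440
    ct_rescale_bits: int = 45
    pt_rescale_bits: int = 10

    def __post_init__(self) -> None:
        if self.log_ring_degree < 1:
            raise ValueError("log_ring_degree must be >= 1")
        if not (self.initial_budget_bits > self.ct_rescale_bits > self.pt_rescale_bits > 0):
            raise ValueError(
                "require initial_budget_bits > ct_rescale_bits > pt_rescale_bits > 0, "
                f"got {self.initial_budget_bits} / {self.ct_rescale_bits} / {self.pt_rescale_bits}"
            )

    @property
    def slot_count(self) -> int:
        """Number of complex slots, N/2."""
        return 1 << (self.log_ring_degree - 1)

    @classmethod
    def minimal_for(cls, n_samples: int, **kwargs) -> "SchemeParams":
        """Smallest ring degree whose slot count fits the n x n projection.

        The projection matrix is held column-compact in one ciphertext, which
        needs ``ceil2(n)**2`` slots (``ceil2`` = round up to a power of two).
        """
        q = ceil_pow2(n_samples)
        log_n = max(2, int(np.log2(q * q)) + 1)
        return cls(log_ring_degree=log_n, **kwargs)


def ceil_pow2(n: int) -> int:
    """Round ``n`` up to the nearest power of two (the layout ceiling operator)."""
    if n < 1:
        raise ValueError("n must be positive")
    return 1 << (n - 1).bit_length()


@dataclass(frozen=True)
class CipherDepth:
    """Critical-path operation counts accumulated by one ciphertext."""

    ct_mult: int = 0
    pt_mult: int = 0
    rotation: int = 0

    def join(self, other: "CipherDepth") -> "CipherDepth":
        return CipherDepth(
            ct_mult=max(self.ct_mult, other.ct_mult),
            pt_mult=max(self.pt_mult, other.pt_mult),
            rotation=max(self.rotation, other.rotation),
        )

    def bump(self, *, ct: int = 0, pt: int = 0, rot: int = 0) -> "CipherDepth":
        return CipherDepth(
            ct_mult=self.ct_mult + ct,
            pt_mult=self.pt_mult + pt,
            rotation=self.rotation + rot,
        )


_ZERO_DEPTH = CipherDepth()


@dataclass(frozen=True)
class DepthReport:
    """Longest sequential operation chains through a completed circuit."""

    pt_mult_depth: int
    ct_mult_depth: int
    rotation_depth: int
    rescale_counts: dict
    totals: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "pt_mult_depth": self.pt_mult_depth,
                "ct_mult_depth": self.ct_mult_depth,
                "rotation_depth": self.rotation_depth,
                "rescale_counts": {str(k): v for k, v in sorted(self.rescale_counts.items())},
                "totals": dict(self.totals),
            },
            indent=2,
        )


@dataclass
class OpMeter:
    """Running totals and per-ciphertext maxima for homomorphic operations.

    Totals count every operation executed; the ``max_*`` fields track the
    deepest critical path any single ciphertext has accumulated, which is
    what "number of successive operations" (circuit depth) means for a
    DAG-shaped circuit.
    """

    ct_mults: int = 0
    pt_mults: int = 0
    rotations: int = 0
    conjugations: int = 0
    rescales: dict = field(default_factory=dict)
    max_ct_depth: int = 0
    max_pt_depth: int = 0
    max_rotation_depth: int = 0

    def _observe(self, depth: CipherDepth) -> None:
        self.max_ct_depth = max(self.max_ct_depth, depth.ct_mult)
        self.max_pt_depth = max(self.max_pt_depth, depth.pt_mult)
        self.max_rotation_depth = max(self.max_rotation_depth, depth.rotation)

    def record_rescale(self, bits: int) -> None:
        self.rescales[bits] = self.rescales.get(bits, 0) + 1

    def report(self) -> DepthReport:
        return DepthReport(
            pt_mult_depth=self.max_pt_depth,
            ct_mult_depth=self.max_ct_depth,
            rotation_depth=self.max_rotation_depth,
            rescale_counts=dict(self.rescales),
            totals={
                "ct_mults": self.ct_mults,
                "pt_mults": self.pt_mults,
                "rotations": self.rotations,
                "conjugations": self.conjugations,
            },
        )


@dataclass
class SlotCipher:
    """A simulated ciphertext: complex slot vector + remaining budget + depth.

    Instances are immutable by convention: every backend operation returns a
    new cipher.  ``level_bits`` is the remaining noise budget; ``depth``
    records the longest multiplication/rotation chain that produced this
    cipher (max over inputs, plus one for each operation applied).
    """

    slots: np.ndarray
    level_bits: int
    backend: "CkksBackend"
    depth: CipherDepth = _ZERO_DEPTH

    @property
    def slot_count(self) -> int:
        return self.slots.shape[0]

    def __add__(self, other):
        return self.backend.add(self, other)

    def __sub__(self, other):
        return self.backend.sub(self, other)

    def __mul__(self, other):
        if isinstance(other, SlotCipher):
            return self.backend.mult(self, other)
        return self.backend.mult_plain(self, other)

    __radd__ = __add__

    def __rsub__(self, other):
        return self.backend.sub_from_plain(other, self)


class CkksBackend:
    """Exact slot-arithmetic backend satisfying the CKKS operation contract.

    Parameters
    ----------
    params : SchemeParams
    noise_sigma : float
        Standard deviation of the zero-mean Gaussian perturbation added to
        every slot after each rescale.  0 (default) gives exact arithmetic.
    seed : int, optional
        Seed for the noise generator (only relevant when noise_sigma > 0).
    """

    def __init__(self, params: SchemeParams, noise_sigma: float = 0.0, seed: int | None = None):
        self.params = params
        self.meter = OpMeter()
        self.noise_sigma = float(noise_sigma)
        self._rng = np.random.default_rng(seed)

    # -- encode / encrypt ---------------------------------------------------

    def encode(self, values) -> np.ndarray:
        """Pad a vector of <= slot_count complex values with zeros to a full slot vector."""
        v = np.asarray(values, dtype=np.complex128).ravel()
        n = self.params.slot_count
        if v.shape[0] > n:
            raise CapacityError(
                f"cannot encode {v.shape[0]} values into {n} slots "
                f"(log_ring_degree={self.params.log_ring_degree})"
            )
        out = np.zeros(n, dtype=np.complex128)
        out[: v.shape[0]] = v
        return out

    def decode(self, slots: np.ndarray) -> np.ndarray:
        return np.asarray(slots, dtype=np.complex128).copy()

    def encrypt(self, values) -> SlotCipher:
        """Lift a plaintext vector into a fresh ciphertext at full level."""
        return SlotCipher(
            slots=self.encode(values),
            level_bits=self.params.initial_budget_bits,
            backend=self,
        )

    def decrypt(self, ct: SlotCipher) -> np.ndarray:
        return self.decode(ct.slots)

    # -- internals ----------------------------------------------------------

    def _check_shapes(self, a: SlotCipher, b: SlotCipher) -> None:
        if a.slot_count != b.slot_count:
            raise ShapeError(f"slot counts differ: {a.slot_count} vs {b.slot_count}")

    def _rescale(self, slots: np.ndarray, level: int, bits: int, op: str) -> tuple[np.ndarray, int]:
        if level < bits:
            raise NoiseBudgetError(
                f"noise budget exhausted in {op}: level {level} bits < rescale amount {bits}"
            )
        self.meter.record_rescale(bits)
        if self.noise_sigma > 0.0:
            slots = slots + (
                self._rng.normal(0.0, self.noise_sigma, slots.shape)
                + 1j * self._rng.normal(0.0, self.noise_sigma, slots.shape)
            )
        return slots, level - bits

    # -- homomorphic operations --------------------------------------------

    def add(self, a: SlotCipher, b) -> SlotCipher:
        """Slot-wise sum.  Ciphertext-plaintext addition is free of rescale."""
        if isinstance(b, SlotCipher):
            self._check_shapes(a, b)
            ct = SlotCipher(
                slots=a.slots + b.slots,
                level_bits=min(a.level_bits, b.level_bits),
                backend=self,
                depth=a.depth.join(b.depth),
            )
        else:
            ct = SlotCipher(
                slots=a.slots + self.encode(b) if np.ndim(b) else a.slots + b,
                level_bits=a.level_bits,
                backend=self,
                depth=a.depth,
            )
        self.meter._observe(ct.depth)
        return ct

    def sub(self, a: SlotCipher, b) -> SlotCipher:
        if isinstance(b, SlotCipher):
            return self.add(a, self.negate(b))
        return self.add(a, -np.asarray(b, dtype=np.complex128))

    def sub_from_plain(self, plain, b: SlotCipher) -> SlotCipher:
        """plain - ct (used e.g. for 1 - p and 2 - w*x); no budget cost."""
        return self.add(self.negate(b), plain)

    def negate(self, a: SlotCipher) -> SlotCipher:
        return SlotCipher(slots=-a.slots, level_bits=a.level_bits, backend=self, depth=a.depth)

    def mult(self, a: SlotCipher, b: SlotCipher) -> SlotCipher:
        """Ciphertext-ciphertext product with automatic ct rescale.

        Operands at unequal levels are silently aligned to the lower level
        (mod-switch analogue) before multiplying.
        """
        self._check_shapes(a, b)
        level = min(a.level_bits, b.level_bits)
        slots, level = self._rescale(
            a.slots * b.slots, level, self.params.ct_rescale_bits, "ct-ct mult"
        )
        self.meter.ct_mults += 1
        ct = SlotCipher(
            slots=slots, level_bits=level, backend=self, depth=a.depth.join(b.depth).bump(ct=1)
        )
        self.meter._observe(ct.depth)
        return ct

    def mult_plain(self, a: SlotCipher, plain) -> SlotCipher:
        """Ciphertext-plaintext product; cheaper rescale (pt_rescale_bits)."""
        pv = plain if np.ndim(plain) == 0 else self.encode(plain)
        slots, level = self._rescale(
            a.slots * pv, a.level_bits, self.params.pt_rescale_bits, "ct-pt mult"
        )
        self.meter.pt_mults += 1
        ct = SlotCipher(slots=slots, level_bits=level, backend=self, depth=a.depth.bump(pt=1))
        self.meter._observe(ct.depth)
        return ct

    def rotate(self, a: SlotCipher, r: int) -> SlotCipher:
        """Cyclic rotation to the right: slot i moves to slot (i + r) mod N/2.

        Negative ``r`` rotates left.  The meter charges one power-of-two
        rotation per set bit of ``|r|``, mirroring the decomposition a real
        HE library performs (rotation keys are held for signed powers of
        two, so a left rotation is as cheap as a right one).
        """
        n = a.slot_count
        if not (-n < r < n):
            warnings.warn(f"rotation amount {r} reduced mod {n}", stacklevel=2)
            r = int(np.sign(r)) * (abs(r) % n)
        cost = popcount_rotations(abs(r))
        self.meter.rotations += cost
        ct = SlotCipher(
            slots=np.roll(a.slots, r),
            level_bits=a.level_bits,
            backend=self,
            depth=a.depth.bump(rot=cost),
        )
        self.meter._observe(ct.depth)
        return ct

    def conjugate(self, a: SlotCipher) -> SlotCipher:
        """Slot-wise complex conjugation; no rescale."""
        self.meter.conjugations += 1
        ct = SlotCipher(
            slots=np.conj(a.slots), level_bits=a.level_bits, backend=self, depth=a.depth
        )
        self.meter._observe(ct.depth)
        return ct

    def report(self) -> DepthReport:
        return self.meter.report()
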