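"""Packed-matrix encodings over CKKS slots and their algebra.

Four ways of laying a matrix out over ciphertext slots, each tuned to one
step of the pipeline:

* **CP** (column-packed): one ciphertext per column, rows in the slot
  prefix.  The workhorse for matrix-vector products.
* **CCP** (column-compact-packed): all columns concatenated into a single
  ciphertext with a power-of-two column stride; the natural output of a
  CP x REP product and the layout over which per-column sums are taken.
* **RP** (row-packed): one ciphertext per row; used for transposed
  matrix-vector products via slot-wise dot products.
* **REP** (row-expanded-packed): one ciphertext per row with every entry
  repeated ``q`` times contiguously, pre-aligning it against a CP matrix
  whose columns are tiled with ``Duplicate``.

All packing routines zero-pad to the next power of two; downstream
operations rely on (and preserve) those zeros.  Every operation here is a
circuit of backend primitives — add / mult / rotate — so running them on
the metering simulator yields both the exact result and its depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ckks import (
    CapacityError,
    CkksBackend,
    ShapeError,
    SlotCipher,
    ceil_pow2,
)

__all__ = [
    "CPMatrix",
    "CCPMatrix",
    "RPMatrix",
    "REPMatrix",
    "pack_cp",
    "pack_rp",
    "pack_rep",
    "pack_ccp",
    "unpack_cp",
    "unpack_ccp",
    "unpack_rp",
    "unpack_rep",
    "replicate",
    "duplicate",
    "cp_matvec",
    "cp_matmul",
    "ccp_colsum",
    "dotprod",
    "rp_matvec",
    "cp_rep_matmul",
    "ccp_to_cp",
    "dump_packed",
]


@dataclass
class CPMatrix:
    """Column-packed matrix: ``columns[j]`` holds column j in its slot prefix."""

    columns: list
    n_rows: int
    n_cols: int
    padded_rows: int

    @property
    def backend(self) -> CkksBackend:
        return self.columns[0].backend


@dataclass
class CCPMatrix:
    """Column-compact-packed matrix: slot ``j*col_size + i`` holds entry (i, j)."""

    body: SlotCipher
    n_rows: int
    n_cols: int
    col_size: int

    @property
    def backend(self) -> CkksBackend:
        return self.body.backend


@dataclass
class RPMatrix:
    """Row-packed matrix: ``rows[i]`` holds row i in its slot prefix."""

    rows: list
    n_rows: int
    n_cols: int
    padded_cols: int

    @property
    def backend(self) -> CkksBackend:
        return self.rows[0].backend


@dataclass
class REPMatrix:
    """Row-expanded-packed matrix: row i holds entry (i, j) repeated
    ``rep_factor`` times at slots ``[j*rep_factor, (j+1)*rep_factor)``."""

    rows: list
    n_rows: int
    n_cols: int
    rep_factor: int

    @property
    def backend(self) -> CkksBackend:
        return self.rows[0].backend


# ---------------------------------------------------------------------------
# packing / unpacking


def _as_2d(dense) -> np.ndarray:
    a = np.asarray(dense)
    if a.ndim != 2:
        raise ShapeError(f"expected a 2-D matrix, got shape {a.shape}")
    return a


def pack_cp(dense, backend: CkksBackend) -> CPMatrix:
    a = _as_2d(dense)
    n_rows, n_cols = a.shape
    return CPMatrix(
        columns=[backend.encrypt(a[:, j]) for j in range(n_cols)],
        n_rows=n_rows,
        n_cols=n_cols,
        padded_rows=ceil_pow2(n_rows),
    )


def pack_rp(dense, backend: CkksBackend) -> RPMatrix:
    a = _as_2d(dense)
    n_rows, n_cols = a.shape
    return RPMatrix(
        rows=[backend.encrypt(a[i, :]) for i in range(n_rows)],
        n_rows=n_rows,
        n_cols=n_cols,
        padded_cols=ceil_pow2(n_cols),
    )


def pack_rep(dense, backend: CkksBackend, rep_factor: int) -> REPMatrix:
    a = _as_2d(dense)
    n_rows, n_cols = a.shape
    q = int(rep_factor)
    if q & (q - 1) or q < 1:
        raise ValueError(f"rep_factor must be a power of two, got {q}")
    if n_cols * q > backend.params.slot_count:
        raise CapacityError(
            f"REP row needs {n_cols}*{q} slots, have {backend.params.slot_count}"
        )
    return REPMatrix(
        rows=[backend.encrypt(np.repeat(a[i, :], q)) for i in range(n_rows)],
        n_rows=n_rows,
        n_cols=n_cols,
        rep_factor=q,
    )


def pack_ccp(dense, backend: CkksBackend, col_size: int | None = None) -> CCPMatrix:
    a = _as_2d(dense)
    n_rows, n_cols = a.shape
    cs = int(col_size) if col_size is not None else ceil_pow2(n_rows)
    if cs & (cs - 1) or cs < n_rows:
        raise ValueError(f"col_size must be a power of two >= n_rows, got {cs}")
    if n_cols * cs > backend.params.slot_count:
        raise CapacityError(f"CCP needs {n_cols}*{cs} slots, have {backend.params.slot_count}")
    flat = np.zeros(n_cols * cs, dtype=np.complex128)
    for j in range(n_cols):
        flat[j * cs : j * cs + n_rows] = a[:, j]
    return CCPMatrix(body=backend.encrypt(flat), n_rows=n_rows, n_cols=n_cols, col_size=cs)


def unpack_cp(m: CPMatrix) -> np.ndarray:
    b = m.backend
    out = np.empty((m.n_rows, m.n_cols), dtype=np.complex128)
    for j, c in enumerate(m.columns):
        out[:, j] = b.decrypt(c)[: m.n_rows]
    return out


def unpack_ccp(m: CCPMatrix) -> np.ndarray:
    flat = m.backend.decrypt(m.body)
    out = np.empty((m.n_rows, m.n_cols), dtype=np.complex128)
    for j in range(m.n_cols):
        out[:, j] = flat[j * m.col_size : j * m.col_size + m.n_rows]
    return out


def unpack_rp(m: RPMatrix) -> np.ndarray:
    b = m.backend
    out = np.empty((m.n_rows, m.n_cols), dtype=np.complex128)
    for i, c in enumerate(m.rows):
        out[i, :] = b.decrypt(c)[: m.n_cols]
    return out


def unpack_rep(m: REPMatrix) -> np.ndarray:
    b = m.backend
    q = m.rep_factor
    out = np.empty((m.n_rows, m.n_cols), dtype=np.complex128)
    for i, c in enumerate(m.rows):
        out[i, :] = b.decrypt(c)[: m.n_cols * q : q]
    return out


def dump_packed(m, path) -> None:
    """Write the decrypted dense form of any packed matrix to delimited text."""
    unpackers = {
        CPMatrix: unpack_cp,
        CCPMatrix: unpack_ccp,
        RPMatrix: unpack_rp,
        REPMatrix: unpack_rep,
    }
    dense = unpackers[type(m)](m)
    if np.allclose(dense.imag, 0.0):
        np.savetxt(path, dense.real, delimiter="\t")
    else:
        np.savetxt(path, dense, delimiter="\t", fmt="%s")


# ---------------------------------------------------------------------------
# slot-vector utilities


def _indicator(backend: CkksBackend, start: int, stop: int) -> np.ndarray:
    mask = np.zeros(backend.params.slot_count)
    mask[start:stop] = 1.0
    return mask


def replicate(v: SlotCipher, n: int) -> list:
    """Broadcast each of the first ``n`` entries of ``v`` into its own cipher.

    Naive form: mask out slot i, rotate it to slot 0, then spread it to every
    slot by log2(slot_count) rotate-and-add doubling rounds.  Cipher i holds
    ``v[i]`` in every slot.
    """
    b = v.backend
    nslots = v.slot_count
    if n > nslots:
        raise CapacityError(f"cannot replicate {n} entries from {nslots} slots")
    out = []
    for i in range(n):
        c = b.mult_plain(v, _indicator(b, i, i + 1))
        if i:
            c = b.rotate(c, -i)
        step = 1
        while step < nslots:
            c = b.add(c, b.rotate(c, step))
            step <<= 1
        out.append(c)
    return out


def duplicate(v: SlotCipher, k: int) -> SlotCipher:
    """Tile the first ``k`` slots of ``v`` periodically across all slots.

    Requires ``k`` to be a power of two dividing the slot count and all
    slots >= k to be zero; realized with log2(slot_count / k) rotation +
    addition rounds.
    """
    nslots = v.slot_count
    if k < 1 or (k & (k - 1)) or nslots % k:
        raise ValueError(f"k must be a power of two dividing {nslots}, got {k}")
    b = v.backend
    step = k
    while step < nslots:
        v = b.add(v, b.rotate(v, step))
        step <<= 1
    return v


# ---------------------------------------------------------------------------
# matrix operations


def cp_matvec(a: CPMatrix, v: SlotCipher) -> SlotCipher:
    """CP matrix times vector: replicate v, multiply into columns, sum."""
    b = a.backend
    reps = replicate(v, a.n_cols)
    acc = b.mult(a.columns[0], reps[0])
    for j in range(1, a.n_cols):
        acc = b.add(acc, b.mult(a.columns[j], reps[j]))
    return acc


def cp_matmul(a: CPMatrix, other: CPMatrix) -> CPMatrix:
    """CP matrix product: one cp_matvec per right-hand column."""
    if a.n_cols != other.n_rows:
        raise ShapeError(f"inner dimensions differ: {a.n_cols} vs {other.n_rows}")
    return CPMatrix(
        columns=[cp_matvec(a, col) for col in other.columns],
        n_rows=a.n_rows,
        n_cols=other.n_cols,
        padded_rows=a.padded_rows,
    )


def ccp_colsum(m: CCPMatrix) -> SlotCipher:
    """Sum each column of a CCP matrix into its first slot.

    log2(col_size) left-rotation + addition rounds; slot ``j*col_size``
    ends up holding the sum of column j (other slots hold partial sums).
    """
    b = m.backend
    c = m.body
    step = 1
    while step < m.col_size:
        c = b.add(c, b.rotate(c, -step))
        step <<= 1
    return c


def dotprod(u: SlotCipher, v: SlotCipher, length: int) -> SlotCipher:
    """Slot dot product over a power-of-two prefix, result in every slot.

    Both operands must be zero beyond ``length``.  The slot-wise product is
    tiled with Duplicate, then summed within each period, so every slot of
    the result carries the full dot product.
    """
    if length & (length - 1) or length < 1:
        raise ValueError(f"length must be a power of two, got {length}")
    b = u.backend
    t = duplicate(b.mult(u, v), length)
    step = 1
    while step < length:
        t = b.add(t, b.rotate(t, -step))
        step <<= 1
    return t


def rp_matvec(a: RPMatrix, v: SlotCipher) -> SlotCipher:
    """RP matrix times vector via per-row dot products and indicator masks.

    The vector is defensively re-masked to the matrix's column span first:
    dotprod's rotate-and-sum folds *every* slot into the result, so a stray
    non-zero beyond the data region would silently corrupt all rows.
    """
    b = a.backend
    vm = b.mult_plain(v, _indicator(b, 0, a.n_cols))
    acc = None
    for i, row in enumerate(a.rows):
        d = dotprod(row, vm, a.padded_cols)
        masked = b.mult_plain(d, _indicator(b, i, i + 1))
        acc = masked if acc is None else b.add(acc, masked)
    return acc


def cp_rep_matmul(a: CPMatrix, rep: REPMatrix) -> CCPMatrix:
    """CP x REP product, landing in a CCP matrix with stride ``padded_rows``.

    Duplicate tiles each CP column across all slots; multiplied against the
    matching REP row, slot ``s`` holds ``A[s mod q, i] * B[i, s div q]``,
    and the sum over i is exactly (A.B) laid out column-compactly.
    """
    if a.n_cols != rep.n_rows:
        raise ShapeError(f"inner dimensions differ: {a.n_cols} vs {rep.n_rows}")
    if rep.rep_factor != a.padded_rows:
        raise ShapeError(
            f"layout mismatch: rep_factor {rep.rep_factor} != padded_rows {a.padded_rows}"
        )
    b = a.backend
    if rep.n_cols * rep.rep_factor > b.params.slot_count:
        raise CapacityError("CP x REP product exceeds slot capacity")
    acc = None
    for i in range(a.n_cols):
        term = b.mult(duplicate(a.columns[i], a.padded_rows), rep.rows[i])
        acc = term if acc is None else b.add(acc, term)
    return CCPMatrix(body=acc, n_rows=a.n_rows, n_cols=rep.n_cols, col_size=a.padded_rows)


def ccp_to_cp(m: CCPMatrix) -> CPMatrix:
    """Split a CCP body into per-column ciphertexts (mask + rotate down)."""
    b = m.backend
    cols = []
    for j in range(m.n_cols):
        c = b.mult_plain(m.body, _indicator(b, j * m.col_size, (j + 1) * m.col_size))
        if j:
            c = b.rotate(c, -j * m.col_size)
        cols.append(c)
    return CPMatrix(columns=cols, n_rows=m.n_rows, n_cols=m.n_cols, padded_rows=m.col_size)
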