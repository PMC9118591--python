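"""Aitchison-simplex primitives for time-use compositions.

A 24-hour day split into sleep, sedentary behaviour (SB), light physical
activity (LPA) and moderate-to-vigorous physical activity (MVPA) carries only
relative information: the four durations are constrained to a fixed total
(24 h, or 1440 min).  Standard Euclidean statistics are therefore applied to
*logratio coordinates* rather than to the raw durations.  This module provides
the simplex operations the regression layer builds on:

* ``closure`` — rescale a positive vector to a fixed total;
* ``clr`` / ``clr_inverse`` — the centred logratio transform;
* ``pivot_coordinates`` / ``pivot_inverse`` — orthonormal (pivot / olr)
  logratio coordinates in which the first coordinate isolates one chosen part
  against the geometric mean of the remaining parts;
* ``perturb`` / ``power`` — the Aitchison group operations;
* ``zero_replace`` — multiplicative replacement of zero parts.

All functions accept plain sequences or arrays; :class:`Composition` is a
small validated container used at module boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_PARTS",
    "Composition",
    "ClrVector",
    "PivotBasis",
    "closure",
    "zero_replace",
    "geometric_mean",
    "clr",
    "clr_inverse",
    "clr_matrix",
    "pivot_basis_matrix",
    "pivot_coordinates",
    "pivot_coordinates_matrix",
    "pivot_inverse",
    "pivot_inverse_matrix",
    "perturb",
    "power",
]

#: Storage order of the four 24-hour movement behaviours.
DEFAULT_PARTS: tuple[str, ...] = ("sleep", "SB", "LPA", "MVPA")

_CLOSURE_RTOL = 1e-9
_CLR_ATOL = 1e-10


@dataclass(frozen=True)
class Composition:
    """A strictly positive D-part composition closed to a fixed total.

    Parameters
    ----------
    values : array-like of float
        Strictly positive part values summing to ``total``.
    parts : tuple of str
        Part labels, same length as ``values``.
    total : float
        Closure constant (1, 24 or 1440 depending on the working scale).
    """

    values: np.ndarray
    parts: tuple[str, ...] = DEFAULT_PARTS
    total: float = 1440.0

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "parts", tuple(self.parts))
        if vals.ndim != 1:
            raise ValueError("Composition values must be one-dimensional")
        if len(self.parts) != vals.size:
            raise ValueError(
                f"{len(self.parts)} part labels for {vals.size} values"
            )
        if vals.size < 2:
            raise ValueError("a composition needs at least 2 parts")
        if self.total <= 0:
            raise ValueError("total must be positive")
        if not np.all(vals > 0):
            bad = [p for p, v in zip(self.parts, vals) if v <= 0]
            raise ValueError(f"non-positive part value(s): {bad}")
        if not math.isclose(float(vals.sum()), self.total,
                            rel_tol=_CLOSURE_RTOL):
            raise ValueError(
                f"values sum to {vals.sum()!r}, expected total {self.total}"
            )

    @property
    def D(self) -> int:
        return self.values.size

    def proportions(self) -> np.ndarray:
        return self.values / self.total

    def reorder(self, order: tuple[str, ...]) -> "Composition":
        idx = [self.parts.index(p) for p in order]
        return Composition(self.values[idx], tuple(order), self.total)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.parts, self.values))


@dataclass(frozen=True)
class ClrVector:
    """A centred-logratio vector; components sum to zero."""

    values: np.ndarray
    parts: tuple[str, ...] = DEFAULT_PARTS

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "parts", tuple(self.parts))
        if len(self.parts) != vals.size:
            raise ValueError("part labels and values length mismatch")
        if abs(float(vals.sum())) > _CLR_ATOL:
            raise ValueError(
                f"clr components must sum to 0 (got {vals.sum():.3e})"
            )


@dataclass(frozen=True)
class PivotBasis:
    """Pivot (olr) coordinate basis with one part placed first.

    The first coordinate contrasts ``pivot_part`` against the geometric mean
    of the remaining parts; remaining parts keep the order given (defaults to
    storage order with the pivot moved to the front).
    """

    pivot_part: str
    parts: tuple[str, ...] = DEFAULT_PARTS
    order: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "parts", tuple(self.parts))
        if self.pivot_part not in self.parts:
            raise ValueError(
                f"pivot part {self.pivot_part!r} not among parts {self.parts}"
            )
        if not self.order:
            rest = tuple(p for p in self.parts if p != self.pivot_part)
            object.__setattr__(self, "order", (self.pivot_part,) + rest)
        else:
            object.__setattr__(self, "order", tuple(self.order))
            if sorted(self.order) != sorted(self.parts):
                raise ValueError("order must be a permutation of parts")
            if self.order[0] != self.pivot_part:
                raise ValueError("order must place the pivot part first")

    @property
    def D(self) -> int:
        return len(self.parts)

    def permutation(self) -> list[int]:
        """Indices mapping storage order to basis order."""
        return [self.parts.index(p) for p in self.order]

    def contrast_matrix(self) -> np.ndarray:
        """(D-1, D) log-contrast matrix in *storage* order."""
        B = pivot_basis_matrix(self.D)
        out = np.zeros_like(B)
        out[:, self.permutation()] = B
        return out


def pivot_basis_matrix(D: int) -> np.ndarray:
    """Orthonormal pivot log-contrast matrix for D parts (basis order).

    Row k (0-based) encodes
    ``z_k = sqrt((D-k-1)/(D-k)) * ln(x_k / gm(x_{k+1..D}))``: rows are
    orthonormal and sum to zero, so ``z = B @ ln(x)`` are isometric logratio
    coordinates.
    """
    if D < 2:
        raise ValueError("need at least 2 parts")
    B = np.zeros((D - 1, D))
    for k in range(D - 1):
        r = D - k - 1  # number of parts after the k-th
        a = math.sqrt(r / (r + 1))
        B[k, k] = a
        B[k, k + 1:] = -a / r
    return B


def closure(raw_values, total: float = 1.0,
            parts: tuple[str, ...] | None = None) -> Composition:
    """Rescale strictly positive values to sum to ``total``.

    Raises ``ValueError`` naming the offending part on non-positive input;
    use :func:`zero_replace` first when zeros are expected.
    """
    vals = np.asarray(raw_values, dtype=float)
    if parts is None:
        parts = (DEFAULT_PARTS if vals.size == len(DEFAULT_PARTS)
                 else tuple(f"part{i + 1}" for i in range(vals.size)))
    if total <= 0:
        raise ValueError("total must be positive")
    if not np.all(vals > 0):
        bad = [p for p, v in zip(parts, vals) if v <= 0]
        raise ValueError(
            f"cannot close non-positive part value(s): {bad}; "
            "apply zero_replace first"
        )
    return Composition(vals * (total / vals.sum()), parts, total)


def close_rows(mat: np.ndarray, total: float = 1.0) -> np.ndarray:
    """Row-wise closure of a strictly positive (n, D) matrix."""
    mat = np.asarray(mat, dtype=float)
    if np.any(mat <= 0):
        raise ValueError("cannot close non-positive values")
    return mat * (total / mat.sum(axis=-1, keepdims=True))


def zero_replace(raw_values, floor: float = 1.0) -> np.ndarray:
    """Multiplicative replacement of zeros by ``floor``.

    Zeros become ``floor``; positive entries are scaled down multiplicatively
    so the vector total is preserved.  A vector without zeros is returned
    unchanged.
    """
    vals = np.asarray(raw_values, dtype=float)
    if floor <= 0:
        raise ValueError("floor must be positive")
    if np.any(vals < 0):
        raise ValueError("negative values are not replaceable")
    zero = vals == 0
    if not zero.any():
        return vals.copy()
    if zero.all():
        raise ValueError("all-zero vector has no compositional information")
    total = vals.sum()
    n_zero = int(zero.sum())
    scale = (total - n_zero * floor) / total
    if scale <= 0:
        raise ValueError(
            f"floor {floor} too large for vector total {total} "
            f"with {n_zero} zero(s)"
        )
    out = vals * scale
    out[zero] = floor
    return out


def geometric_mean(values) -> float:
    """Geometric mean of strictly positive values."""
    vals = np.asarray(values, dtype=float)
    if not np.all(vals > 0):
        raise ValueError("geometric mean requires strictly positive values")
    return float(np.exp(np.mean(np.log(vals))))


def clr(x: Composition) -> ClrVector:
    """Centred logratio transform: ln(x_j / gm(x))."""
    logs = np.log(x.values)
    vals = logs - logs.mean()
    return ClrVector(vals - vals.mean(), x.parts)  # re-centre for exactness


def clr_inverse(v: ClrVector, total: float = 1.0) -> Composition:
    """Map a clr vector back to a composition closed to ``total``."""
    return closure(np.exp(v.values), total, v.parts)


def clr_matrix(mat: np.ndarray) -> np.ndarray:
    """Row-wise clr of a strictly positive (n, D) matrix."""
    logs = np.log(np.asarray(mat, dtype=float))
    return logs - logs.mean(axis=-1, keepdims=True)


def pivot_coordinates(x: Composition, basis: PivotBasis) -> np.ndarray:
    """Pivot (olr) coordinates of ``x`` in the given basis, length D-1."""
    if tuple(x.parts) != tuple(basis.parts):
        raise ValueError("composition and basis part labels differ")
    return basis.contrast_matrix() @ np.log(x.values)


def pivot_coordinates_matrix(mat: np.ndarray, basis: PivotBasis) -> np.ndarray:
    """Row-wise pivot coordinates of an (n, D) matrix of positive values."""
    return np.log(np.asarray(mat, dtype=float)) @ basis.contrast_matrix().T


def pivot_inverse(z, basis: PivotBasis, total: float = 1.0) -> Composition:
    """Invert pivot coordinates back to a composition closed to ``total``."""
    z = np.asarray(z, dtype=float)
    if z.size != basis.D - 1:
        raise ValueError(f"expected {basis.D - 1} coordinates, got {z.size}")
    clr_vals = basis.contrast_matrix().T @ z
    return closure(np.exp(clr_vals), total, basis.parts)


def pivot_inverse_matrix(z: np.ndarray, basis: PivotBasis,
                         total: float = 1.0) -> np.ndarray:
    """Row-wise inverse of (n, D-1) pivot coordinates."""
    clr_vals = np.asarray(z, dtype=float) @ basis.contrast_matrix()
    return close_rows(np.exp(clr_vals), total)


def perturb(x: Composition, p: Composition) -> Composition:
    """Aitchison perturbation: closure of the elementwise product."""
    if tuple(x.parts) != tuple(p.parts):
        raise ValueError("perturbation requires identical part labels")
    return closure(x.values * p.values, x.total, x.parts)


def power(x: Composition, a: float) -> Composition:
    """Aitchison powering: closure of elementwise ``x ** a``."""
    return closure(x.values ** a, x.total, x.parts)
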