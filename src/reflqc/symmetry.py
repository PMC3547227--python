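"""Unit-cell geometry and Laue-class symmetry for reflection merging.

Supports the two Laue classes that matter for tetragonal lysozyme-style
data: 4/mmm (the tetragonal holohedry, 16 operators) and its orthorhombic
subgroup mmm (8 operators).  Reflections are mapped to a canonical
asymmetric-unit (ASU) representative — the lexicographically greatest
member of the symmetry orbit — so that symmetry-equivalent observations
share a merge key.

Only orthogonal cells are supported: every crystal this package targets is
tetragonal or orthorhombic, so 1/d**2 = h**2/a**2 + k**2/b**2 + l**2/c**2.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Tuple

import numpy as np

__all__ = [
    "UnitCell",
    "MillerIndex",
    "LaueClass",
    "LAUE_4MMM",
    "LAUE_MMM",
    "get_laue_class",
    "d_spacing",
    "map_to_asu",
    "map_to_asu_array",
    "generate_unique",
]

MillerIndex = Tuple[int, int, int]


class UnsupportedCellError(ValueError):
    """Raised for cells outside the orthogonal family this package handles."""


@dataclass(frozen=True)
class UnitCell:
    """Unit-cell parameters in ångström / degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180) degrees")

    @property
    def is_orthogonal(self) -> bool:
        return all(abs(ang - 90.0) < 1e-8 for ang in (self.alpha, self.beta, self.gamma))

    def is_tetragonal(self, tol: float = 1e-6) -> bool:
        """a == b within tol and all angles 90 deg (checkable, never enforced)."""
        return self.is_orthogonal and abs(self.a - self.b) <= tol * max(self.a, self.b)


def _check_orthogonal(cell: UnitCell) -> None:
    if not cell.is_orthogonal:
        raise UnsupportedCellError(
            "only orthogonal cells (alpha=beta=gamma=90) are supported"
        )


def d_spacing(cell: UnitCell, hkl: MillerIndex) -> float:
    """Resolution d (Å) of reflection hkl in an orthogonal cell.

    s = 1/(2d) is the sin(theta)/lambda coordinate used by the Wilson fit.
    """
    _check_orthogonal(cell)
    h, k, l = hkl
    if h == 0 and k == 0 and l == 0:
        raise ValueError("(0,0,0) is not a reflection")
    inv_d2 = (h / cell.a) ** 2 + (k / cell.b) ** 2 + (l / cell.c) ** 2
    return 1.0 / np.sqrt(inv_d2)


def d_spacing_array(cell: UnitCell, hkl: np.ndarray) -> np.ndarray:
    """Vectorised :func:`d_spacing` for an (n, 3) integer array."""
    _check_orthogonal(cell)
    hkl = np.asarray(hkl)
    inv_d2 = (
        (hkl[:, 0] / cell.a) ** 2
        + (hkl[:, 1] / cell.b) ** 2
        + (hkl[:, 2] / cell.c) ** 2
    )
    return 1.0 / np.sqrt(inv_d2)


def _build_group(generators: Sequence[np.ndarray]) -> list[np.ndarray]:
    """Close a set of integer 3x3 generators under multiplication."""
    seen: dict[bytes, np.ndarray] = {}
    frontier = [np.eye(3, dtype=np.int64)] + [np.asarray(g, dtype=np.int64) for g in generators]
    for m in frontier:
        seen[m.tobytes()] = m
    while frontier:
        nxt = []
        for a, b in itertools.product(list(seen.values()), repeat=2):
            m = a @ b
            key = m.tobytes()
            if key not in seen:
                seen[key] = m
                nxt.append(m)
        frontier = nxt
    return list(seen.values())


@dataclass(frozen=True)
class LaueClass:
    """A Laue class as an explicit set of integer operator matrices on (h,k,l)."""

    name: str
    operators: tuple = field(repr=False, default=())

    def __len__(self) -> int:
        return len(self.operators)

    @property
    def operator_stack(self) -> np.ndarray:
        """Operators as a single (n_ops, 3, 3) int array."""
        return np.stack([np.asarray(m) for m in self.operators])


_INV = -np.eye(3, dtype=np.int64)
_MIRROR_X = np.diag([-1, 1, 1]).astype(np.int64)
_MIRROR_Y = np.diag([1, -1, 1]).astype(np.int64)
# 4-fold rotation about c: (h,k,l) -> (-k,h,l)
_FOUR_FOLD_C = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], dtype=np.int64)

LAUE_MMM = LaueClass(
    "mmm",
    tuple(m for m in _build_group([_INV, _MIRROR_X, _MIRROR_Y])),
)
LAUE_4MMM = LaueClass(
    "4/mmm",
    tuple(m for m in _build_group([_INV, _MIRROR_X, _FOUR_FOLD_C])),
)

_CLASSES = {"mmm": LAUE_MMM, "4/mmm": LAUE_4MMM}


def get_laue_class(name: str) -> LaueClass:
    try:
        return _CLASSES[name]
    except KeyError:
        raise ValueError(f"unknown Laue class {name!r}; known: {sorted(_CLASSES)}") from None


def map_to_asu(hkl: MillerIndex, lc: LaueClass) -> MillerIndex:
    """Canonical ASU representative: lexicographic maximum of the orbit."""
    h, k, l = hkl
    if h == 0 and k == 0 and l == 0:
        raise ValueError("(0,0,0) is not a reflection")
    v = np.array([h, k, l], dtype=np.int64)
    orbit = [tuple(int(x) for x in (m @ v)) for m in lc.operators]
    return max(orbit)


def map_to_asu_array(hkl: np.ndarray, lc: LaueClass) -> np.ndarray:
    """Vectorised ASU mapping for an (n, 3) integer array."""
    hkl = np.asarray(hkl, dtype=np.int64)
    # (n_ops, n, 3): every operator applied to every index
    images = np.einsum("oij,nj->oni", lc.operator_stack, hkl)
    # lexicographic max over the operator axis
    order = (
        images[:, :, 0].astype(np.float64) * 2**42
        + images[:, :, 1].astype(np.float64) * 2**21
        + images[:, :, 2]
    )
    best = np.argmax(order, axis=0)
    return images[best, np.arange(hkl.shape[0]), :]


def generate_unique(
    cell: UnitCell, lc: LaueClass, d_min: float, d_max: float
) -> set[MillerIndex]:
    """All ASU representatives with d_min <= d <= d_max.

    Laue-level only: space-group systematic absences are NOT removed, so
    this is the completeness denominator used throughout the package.
    """
    _check_orthogonal(cell)
    if not 0 < d_min < d_max:
        raise ValueError("require 0 < d_min < d_max")
    hmax = int(np.floor(cell.a / d_min))
    kmax = int(np.floor(cell.b / d_min))
    lmax = int(np.floor(cell.c / d_min))
    h, k, l = np.meshgrid(
        np.arange(0, hmax + 1), np.arange(0, kmax + 1), np.arange(0, lmax + 1),
        indexing="ij",
    )
    hkl = np.column_stack([h.ravel(), k.ravel(), l.ravel()])
    hkl = hkl[(hkl != 0).any(axis=1)]
    d = d_spacing_array(cell, hkl)
    hkl = hkl[(d >= d_min) & (d <= d_max)]
    if hkl.shape[0] == 0:
        return set()
    reps = map_to_asu_array(hkl, lc)
    return {tuple(int(x) for x in row) for row in reps}
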