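"""Core 2x2 count-table type, validation, and matrix factorizations.

A 2x2 table of nonnegative counts

    =========  =========  ========
    .          column 1   column 2
    row 1      a          b
    row 2      c          d
    =========  =========  ========

factors as a product ``diag(left) @ P @ diag(right)`` where ``P`` is a
proportion matrix whose rows or columns are points in the standard
one-simplex and the diagonal factors carry the marginal sums.  Four distinct
factorizations exist, indexed by the normalizing side (``column`` or ``row``)
and the grouping mode (``unit`` or ``dual``); see :func:`factorize`.

Matrix orientation convention: ``proportion[i][j]`` indexes row ``i``,
column ``j`` of the table above (row 1 holds ``(a, b)``).  This convention
is used everywhere in the package.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Tuple

import numpy as np

from .errors import DegenerateTableError, DomainError, ZeroMarginError

__all__ = [
    "CountTable2x2",
    "Factorization",
    "make_table",
    "factorize",
    "u_scale",
    "yule_symmetrize",
    "marginal_ratio",
]

logger = logging.getLogger(__name__)

Side = Literal["column", "row"]
Mode = Literal["unit", "dual"]


@dataclass(frozen=True)
class CountTable2x2:
    """Validated 2x2 table of nonnegative real counts.

    Counts are real-valued (not only integral) so that rescaled and
    symmetrized tables are first-class values.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise DomainError(f"count {name!r} is not finite: {v!r}")
            if v < 0:
                raise DomainError(f"count {name!r} is negative: {v!r}")
        if self.n == 0:
            raise DegenerateTableError("all four counts are zero")

    @property
    def row_sums(self) -> Tuple[float, float]:
        return (self.a + self.b, self.c + self.d)

    @property
    def col_sums(self) -> Tuple[float, float]:
        return (self.a + self.c, self.b + self.d)

    @property
    def n(self) -> float:
        """Grand total of all four counts."""
        return self.a + self.b + self.c + self.d

    @property
    def counts(self) -> Tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)

    def to_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    def is_integral(self, tol: float = 1e-9) -> bool:
        return all(abs(v - round(v)) <= tol for v in self.counts)


def make_table(a: float, b: float, c: float, d: float) -> CountTable2x2:
    """Build a validated :class:`CountTable2x2` from four counts.

    Raises
    ------
    DomainError
        If any count is negative or non-finite.
    DegenerateTableError
        If all four counts are zero.
    """
    return CountTable2x2(float(a), float(b), float(c), float(d))


@dataclass(frozen=True)
class Factorization:
    """Decomposition ``diag(left_diag) @ proportion @ diag(right_diag)``.

    ``side`` selects whether column sums or row sums act as the proportional
    scale; ``mode`` selects the grouping: ``unit`` puts the marginal sums on
    the simplex axis directly (normalizers ``n1 = n2 = 1``) while ``dual``
    renormalizes the transverse axis so the opposite axis lands in the
    simplex.  Simplex axis by (side, mode):

    - column/unit: columns sum to 1
    - column/dual: rows sum to 1
    - row/unit: rows sum to 1
    - row/dual: columns sum to 1
    """

    side: Side
    mode: Mode
    left_diag: Tuple[float, float]
    proportion: np.ndarray = field(repr=False)
    right_diag: Tuple[float, float]
    n1: float
    n2: float

    def reconstruct(self) -> np.ndarray:
        return (
            np.diag(self.left_diag) @ self.proportion @ np.diag(self.right_diag)
        )

    @property
    def simplex_axis(self) -> Literal["rows", "columns"]:
        if (self.side, self.mode) in (("column", "unit"), ("row", "dual")):
            return "columns"
        return "rows"


def factorize(t: CountTable2x2, side: Side = "column", mode: Mode = "unit") -> Factorization:
    """Factor ``t`` as ``diag(left) @ P @ diag(right)``.

    For ``side="column"`` the right diagonal carries the column sums and the
    unit mode gives the familiar column-proportion matrix
    ``[[a/(a+c), b/(b+d)], [c/(a+c), d/(b+d)]]``.  The dual mode divides each
    row of that matrix by its sum (``n1`` and ``n2``), moving the simplex
    property to the rows while keeping invariance to column rescaling.
    ``side="row"`` is the transpose-symmetric construction.

    Raises
    ------
    ZeroMarginError
        If a marginal sum on the chosen side is zero.
    DegenerateTableError
        If a dual normalizer is zero (the simplex point is undefined).
    """
    if side not in ("column", "row"):
        raise ValueError(f"side must be 'column' or 'row', got {side!r}")
    if mode not in ("unit", "dual"):
        raise ValueError(f"mode must be 'unit' or 'dual', got {mode!r}")

    a, b, c, d = t.counts
    if side == "column":
        s1, s2 = t.col_sums
        if s1 == 0 or s2 == 0:
            raise ZeroMarginError(f"zero column sum in {t.counts}")
        unit = np.array([[a / s1, b / s2], [c / s1, d / s2]])
        if mode == "unit":
            return Factorization(
                side=side, mode=mode,
                left_diag=(1.0, 1.0), proportion=unit, right_diag=(s1, s2),
                n1=1.0, n2=1.0,
            )
        n1 = unit[0, 0] + unit[0, 1]
        n2 = unit[1, 0] + unit[1, 1]
        if n1 == 0 or n2 == 0:
            raise DegenerateTableError(
                f"degenerate row: dual normalizer zero for {t.counts}"
            )
        prop = unit / np.array([[n1], [n2]])
        return Factorization(
            side=side, mode=mode,
            left_diag=(n1, n2), proportion=prop, right_diag=(s1, s2),
            n1=n1, n2=n2,
        )

    s1, s2 = t.row_sums
    if s1 == 0 or s2 == 0:
        raise ZeroMarginError(f"zero row sum in {t.counts}")
    unit = np.array([[a / s1, b / s1], [c / s2, d / s2]])
    if mode == "unit":
        return Factorization(
            side=side, mode=mode,
            left_diag=(s1, s2), proportion=unit, right_diag=(1.0, 1.0),
            n1=1.0, n2=1.0,
        )
    n1 = unit[0, 0] + unit[1, 0]
    n2 = unit[0, 1] + unit[1, 1]
    if n1 == 0 or n2 == 0:
        raise DegenerateTableError(
            f"degenerate column: dual normalizer zero for {t.counts}"
        )
    prop = unit / np.array([[n1, n2]])
    return Factorization(
        side=side, mode=mode,
        left_diag=(s1, s2), proportion=prop, right_diag=(n1, n2),
        n1=n1, n2=n2,
    )


def u_scale(t: CountTable2x2, j: float, k: float) -> CountTable2x2:
    """Unitary diagonal scaling ``(a, b, c, d) -> (k*a, b/j, j*c, d/k)``.

    Preserves the cross-product ratio ``ad/bc`` exactly for any ``j, k > 0``.
    """
    if not (j > 0 and k > 0):
        raise DomainError(f"u-scale factors must be positive, got j={j}, k={k}")
    return CountTable2x2(k * t.a, t.b / j, j * t.c, t.d / k)


def yule_symmetrize(t: CountTable2x2) -> CountTable2x2:
    """Geometric averaging of the diagonals: ``(sqrt(ad), sqrt(bc), sqrt(bc),
    sqrt(ad))``.

    The result has all four marginal sums equal to ``sqrt(ad) + sqrt(bc)``
    and the same cross-product ratio as ``t``.  Zeros propagate as zeros.
    """
    g = math.sqrt(t.a * t.d)
    h = math.sqrt(t.b * t.c)
    return CountTable2x2(g, h, h, g)


def marginal_ratio(t: CountTable2x2) -> float:
    """Marginal-sum ratio product ``(a+b)(c+d) / ((a+c)(b+d))``.

    Quantifies the imbalance between row and column sums; equals 1 when the
    row sums coincide with the column sums.
    """
    r1, r2 = t.row_sums
    c1, c2 = t.col_sums
    if c1 == 0 or c2 == 0:
        raise ZeroMarginError(f"zero column sum in {t.counts}")
    return (r1 * r2) / (c1 * c2)
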