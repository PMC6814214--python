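"""Scalar effect-size measures and the center-of-mass coordinate system.

A 2x2 table carries two degrees of freedom of proportional variation once
marginal sums are factored out.  Each of four *forms* extracts a pair of
points in the standard one-simplex (see :func:`simplex_pair`); the pair
reduces to center-of-mass coordinates ``(delta, mu)`` — half-difference and
mean of the two first coordinates.  Classical measures (odds ratio, Yule's
Q, relative risk, ratio difference) are perspective functions of
``(delta, mu)``; margin-dependent measures (phi, the simple matching
coefficient) factor into a margin term times a proportional displacement.

Sign conventions
----------------
``delta`` is always the *halved* difference ``(p_beta - p_alpha) / 2``; the
un-halved difference is exposed as ``displacement``.  For the ``csum_rows``
form the pair is ordered (a-element, c-element), so its ``delta`` is the
c-minus-a orientation; the a-minus-c orientation is its negation.  The phi
factorizations ``phi = M * D`` hold with the un-halved displacement ``D``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Literal, Optional, Tuple

import numpy as np
from scipy import stats as _sps

from .errors import DomainError, UndefinedStatisticError, ZeroMarginError
from .tables import CountTable2x2, factorize, marginal_ratio, yule_symmetrize

__all__ = [
    "FormId",
    "SimplexPair",
    "ComCoords",
    "PerspectiveMeasures",
    "SimpleMatchingDecomposition",
    "RxCMeasures",
    "EffectSizeReport",
    "simplex_pair",
    "com_coords",
    "odds_ratio",
    "yules_q",
    "relative_risk",
    "perspective_measures",
    "phi",
    "phi_factorization",
    "delta_s",
    "simple_matching",
    "rxc_measures",
    "effect_size_report",
    "cohen_label",
]

logger = logging.getLogger(__name__)

FormId = Literal["csum_rows", "csum_cols", "rsum_rows", "rsum_cols", "symmetric"]

FORMS: Tuple[str, ...] = ("csum_rows", "csum_cols", "rsum_rows", "rsum_cols")

# Which of (p_alpha, p_beta) corresponds to the group containing cell `a`
# in each form; used to orient the relative risk.
_A_SIDE: Dict[str, str] = {
    "csum_rows": "alpha",
    "csum_cols": "beta",
    "rsum_rows": "beta",
    "rsum_cols": "beta",
}


@dataclass(frozen=True)
class SimplexPair:
    """First coordinates of two points in the one-simplex plus provenance."""

    p_alpha: float
    p_beta: float
    form_id: str

    def __post_init__(self) -> None:
        for name in ("p_alpha", "p_beta"):
            v = getattr(self, name)
            if not (-1e-12 <= v <= 1 + 1e-12):
                raise DomainError(f"{name} out of [0,1]: {v!r}")


@dataclass(frozen=True)
class ComCoords:
    """Center-of-mass coordinates of a simplex pair.

    ``delta = (p_beta - p_alpha)/2`` and ``mu = (p_alpha + p_beta)/2``; both
    ``mu - delta`` and ``mu + delta`` lie in [0, 1].
    """

    delta: float
    mu: float
    form_id: str

    @property
    def displacement(self) -> float:
        """Un-halved difference ``p_beta - p_alpha``."""
        return 2.0 * self.delta

    @property
    def p_alpha(self) -> float:
        return self.mu - self.delta

    @property
    def p_beta(self) -> float:
        return self.mu + self.delta


@dataclass(frozen=True)
class PerspectiveMeasures:
    """Effect sizes recomputed from ``(delta, mu)`` as perspective functions."""

    omega: float
    q: float
    rho: float
    ratio_diff: float


def simplex_pair(t: CountTable2x2, form: str) -> SimplexPair:
    """Extract the simplex-point pair of the requested form.

    - ``csum_rows``: rows of the column-side dual matrix; pair =
      (a-element, c-element).  Invariant to column rescaling.
    - ``csum_cols``: columns of the column-side unit matrix; pair =
      (b-column, a-column) first coordinates.  Invariant to column rescaling.
    - ``rsum_rows``: rows of the row-side unit matrix; pair =
      (c-row, a-row) first coordinates.  Invariant to row rescaling.
    - ``rsum_cols``: columns of the row-side dual matrix; pair =
      (b-element, a-element) of the first row.  Invariant to row rescaling.
    - ``symmetric``: for a diagonally symmetric table ``(x, y, y, x)``, the
      pair ``(y, x)/(x+y)`` underlying the symmetric proportion difference.
    """
    if form == "csum_rows":
        p = factorize(t, "column", "dual").proportion
        return SimplexPair(p[0, 0], p[1, 0], form)
    if form == "csum_cols":
        p = factorize(t, "column", "unit").proportion
        return SimplexPair(p[0, 1], p[0, 0], form)
    if form == "rsum_rows":
        p = factorize(t, "row", "unit").proportion
        return SimplexPair(p[1, 0], p[0, 0], form)
    if form == "rsum_cols":
        p = factorize(t, "row", "dual").proportion
        return SimplexPair(p[0, 1], p[0, 0], form)
    if form == "symmetric":
        if not (math.isclose(t.a, t.d, rel_tol=1e-9, abs_tol=1e-12)
                and math.isclose(t.b, t.c, rel_tol=1e-9, abs_tol=1e-12)):
            raise DomainError(
                "symmetric form requires a diagonally symmetric table "
                f"(a=d, b=c); got {t.counts}"
            )
        x, y = t.a, t.b
        if x + y == 0:
            raise UndefinedStatisticError("symmetric pair undefined for x+y=0")
        return SimplexPair(y / (x + y), x / (x + y), form)
    raise ValueError(f"unknown form {form!r}")


def com_coords(sp: SimplexPair) -> ComCoords:
    """Center-of-mass reduction of a simplex pair."""
    return ComCoords(
        delta=(sp.p_beta - sp.p_alpha) / 2.0,
        mu=(sp.p_alpha + sp.p_beta) / 2.0,
        form_id=sp.form_id,
    )


def odds_ratio(t: CountTable2x2) -> float:
    """Cross-product ratio ``ad/bc``.

    Returns ``inf`` when ``bc = 0 < ad`` and ``0`` when ``ad = 0 < bc``.
    """
    ad, bc = t.a * t.d, t.b * t.c
    if bc == 0:
        if ad == 0:
            raise UndefinedStatisticError(f"odds ratio 0/0 for {t.counts}")
        return math.inf
    return ad / bc


def yules_q(t: CountTable2x2) -> float:
    """Yule's Q, ``(ad - bc)/(ad + bc)`` — the robust form, finite whenever
    ``ad + bc > 0``."""
    ad, bc = t.a * t.d, t.b * t.c
    if ad + bc == 0:
        raise UndefinedStatisticError(f"Yule's Q 0/0 for {t.counts}")
    return (ad - bc) / (ad + bc)


def relative_risk(t: CountTable2x2, orientation: str = "rsum_rows") -> float:
    """Ratio of the a-side group proportion over the other group's, in the
    chosen form.

    The default ``rsum_rows`` gives the conventional row-wise relative risk
    ``[a/(a+b)] / [c/(c+d)]``.
    """
    sp = simplex_pair(t, orientation)
    if orientation not in _A_SIDE:
        raise ValueError(f"no relative-risk orientation for form {orientation!r}")
    if _A_SIDE[orientation] == "alpha":
        num, den = sp.p_alpha, sp.p_beta
    else:
        num, den = sp.p_beta, sp.p_alpha
    if den == 0:
        if num == 0:
            raise UndefinedStatisticError("relative risk 0/0")
        return math.inf
    return num / den


def perspective_measures(cc: ComCoords) -> PerspectiveMeasures:
    """Recompute omega, Q, rho, and the ratio difference from ``(delta, mu)``.

    With ``s = delta**2 + mu*(1 - mu)``:

    - ``omega = (s + delta)/(s - delta)``
    - ``q = delta/s``
    - ``rho = (mu + delta)/(mu - delta)``
    - ``ratio_diff = 2*delta / (1 + mu*(mu - 2) - delta**2)``, which equals
      ``p_beta/(1-p_beta) - p_alpha/(1-p_alpha)``.
    """
    d, m = cc.delta, cc.mu
    s = d * d + m * (1.0 - m)
    if s == 0:
        raise UndefinedStatisticError(
            f"perspective measures undefined at (delta, mu)=({d}, {m})"
        )
    q = d / s
    omega = math.inf if s - d == 0 else (s + d) / (s - d)
    if m - d == 0:
        rho = math.inf if m + d > 0 else math.nan
    else:
        rho = (m + d) / (m - d)
    denom = 1.0 + m * (m - 2.0) - d * d
    ratio_diff = math.inf if denom == 0 else 2.0 * d / denom
    return PerspectiveMeasures(omega=omega, q=q, rho=rho, ratio_diff=ratio_diff)


def phi(t: CountTable2x2) -> float:
    """Phi (matthews/Pearson) coefficient ``(ad - bc)/sqrt(prod of margins)``."""
    r1, r2 = t.row_sums
    c1, c2 = t.col_sums
    if min(r1, r2, c1, c2) == 0:
        raise ZeroMarginError(f"phi undefined: zero margin in {t.counts}")
    return (t.a * t.d - t.b * t.c) / math.sqrt(r1 * r2 * c1 * c2)


def phi_factorization(t: CountTable2x2, form: str = "rsum") -> Tuple[float, float]:
    """Factor phi as ``M * D`` for the row-sum or column-sum form.

    ``D`` is the un-halved dual-matrix element difference (``rsum``:
    a-element minus b-element of the row-side dual matrix; ``csum``:
    a-element minus c-element of the column-side dual matrix); ``M`` is a
    closed-form function of the marginal sums.  ``M = 1`` for diagonally
    symmetric tables, where ``D`` reduces to phi itself.

    Returns ``(M, D)``.
    """
    a, b, c, d = t.counts
    r1, r2 = t.row_sums
    c1, c2 = t.col_sums
    if min(r1, r2, c1, c2) == 0:
        raise ZeroMarginError(f"phi factorization undefined: zero margin in {t.counts}")
    root = math.sqrt(r1 * r2 * c1 * c2)
    if form == "rsum":
        p = factorize(t, "row", "dual").proportion
        disp = p[0, 0] - p[0, 1]
        m = (a + c * r1 / r2) * (b * r2 / r1 + d) / root
    elif form == "csum":
        p = factorize(t, "column", "dual").proportion
        disp = p[0, 0] - p[1, 0]
        m = (a + b * c1 / c2) * (c * c2 / c1 + d) / root
    else:
        raise ValueError(f"form must be 'rsum' or 'csum', got {form!r}")
    return m, disp


def delta_s(sp: SimplexPair) -> float:
    """Symmetric proportion difference ``(x - y)/(x + y)`` of a symmetric
    pair.

    For a Yule-symmetrized table this is the coefficient of colligation
    ``(sqrt(ad) - sqrt(bc))/(sqrt(ad) + sqrt(bc))`` and coincides with phi
    of the symmetrized table.
    """
    if sp.form_id != "symmetric":
        raise DomainError(f"delta_s requires the symmetric form, got {sp.form_id!r}")
    return sp.p_beta - sp.p_alpha


@dataclass(frozen=True)
class SimpleMatchingDecomposition:
    weights: Tuple[float, float]
    proportions: Tuple[float, float]

    def value(self) -> float:
        return (self.weights[0] * self.proportions[0]
                + self.weights[1] * self.proportions[1])


def simple_matching(
    t: CountTable2x2,
) -> Tuple[float, Optional[SimpleMatchingDecomposition], Optional[SimpleMatchingDecomposition]]:
    """Simple matching coefficient ``(a + d)/N`` with its column and row
    weighted-proportion decompositions.

    The column decomposition weights the column proportions ``a/(a+c)`` and
    ``d/(b+d)`` by the column-sum fractions; the row decomposition is the
    analog with rows.  A decomposition whose margin is zero is omitted
    (returned as ``None``) with a logged warning.
    """
    s_m = (t.a + t.d) / t.n
    c1, c2 = t.col_sums
    r1, r2 = t.row_sums
    col_dec = row_dec = None
    if c1 > 0 and c2 > 0:
        col_dec = SimpleMatchingDecomposition(
            weights=(c1 / t.n, c2 / t.n),
            proportions=(t.a / c1, t.d / c2),
        )
    else:
        logger.warning("zero column sum: column decomposition of s_M omitted")
    if r1 > 0 and r2 > 0:
        row_dec = SimpleMatchingDecomposition(
            weights=(r1 / t.n, r2 / t.n),
            proportions=(t.a / r1, t.d / r2),
        )
    else:
        logger.warning("zero row sum: row decomposition of s_M omitted")
    return s_m, col_dec, row_dec


@dataclass(frozen=True)
class RxCMeasures:
    chi2: float
    cramers_v: float
    tau_col: float
    tau_row: float


def _goodman_kruskal_tau(p: np.ndarray, axis: int) -> float:
    """Goodman-Kruskal tau with the variable along ``axis`` as dependent.

    Proportional reduction in expected misclassification (Gini-based): with
    cell proportions ``p``, margins ``p_dep`` (dependent) and ``p_ind``,

        tau = (sum_ij p_ij^2 / p_ind_i - sum_j p_dep_j^2) / (1 - sum_j p_dep_j^2)
    """
    p_dep = p.sum(axis=1 - axis)
    p_ind = p.sum(axis=axis)
    denom = 1.0 - float(np.sum(p_dep ** 2))
    if denom == 0:
        return 0.0
    if axis == 1:  # columns dependent: condition on rows
        cond = np.sum(p ** 2 / p_ind[:, None])
    else:  # rows dependent: condition on columns
        cond = np.sum(p ** 2 / p_ind[None, :])
    return float((cond - np.sum(p_dep ** 2)) / denom)


def rxc_measures(table) -> RxCMeasures:
    """Chi-squared, Cramer's V, and Goodman-Kruskal tau (both directions)
    for an r x c count matrix.

    For a 2x2 input, ``V = |phi|`` and ``tau_col = tau_row = phi**2``.
    """
    m = np.asarray(
        table.to_array() if isinstance(table, CountTable2x2) else table,
        dtype=float,
    )
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise DomainError(f"expected an r x c matrix with r,c >= 2, got shape {m.shape}")
    if np.any(m < 0):
        raise DomainError("negative cell count")
    if np.any(m.sum(axis=0) == 0) or np.any(m.sum(axis=1) == 0):
        raise ZeroMarginError("zero marginal sum in r x c table")
    n = m.sum()
    chi2 = float(_sps.chi2_contingency(m, correction=False)[0])
    q = min(m.shape)
    v = math.sqrt(chi2 / (n * (q - 1)))
    p = m / n
    return RxCMeasures(
        chi2=chi2,
        cramers_v=v,
        tau_col=_goodman_kruskal_tau(p, axis=1),
        tau_row=_goodman_kruskal_tau(p, axis=0),
    )


_COHEN_THRESHOLDS = ((0.5, "large"), (0.3, "medium"), (0.1, "small"))


def cohen_label(value: float) -> str:
    """Qualitative Cohen-style label for ``|delta|`` or ``|phi|``.

    Caveat (logged once per call site): these thresholds ignore the ``mu``
    coordinate entirely.
    """
    v = abs(value)
    for thr, name in _COHEN_THRESHOLDS:
        if v >= thr:
            return name
    return "negligible"


@dataclass(frozen=True)
class EffectSizeReport:
    """All scalar measures plus the per-form coordinate sets for one table."""

    counts: Tuple[float, float, float, float]
    omega: float
    q: float
    rho: float
    ratio_diff: float
    phi: float
    omega_m: float
    s_m: float
    cramers_v: float
    tau_col: float
    tau_row: float
    forms: Dict[str, Dict[str, float]]
    m_factors: Dict[str, float]

    def to_dict(self) -> dict:
        return {
            "counts": {k: v for k, v in zip("abcd", self.counts)},
            "omega": self.omega,
            "q": self.q,
            "rho": self.rho,
            "ratio_diff": self.ratio_diff,
            "phi": self.phi,
            "omega_m": self.omega_m,
            "s_m": self.s_m,
            "cramers_v": self.cramers_v,
            "tau_col": self.tau_col,
            "tau_row": self.tau_row,
            "forms": self.forms,
            "m_factors": self.m_factors,
            "labels": {
                "phi": cohen_label(self.phi),
                "delta_csum_rows": cohen_label(self.forms["csum_rows"]["delta"]),
            },
        }


def effect_size_report(t: CountTable2x2) -> EffectSizeReport:
    """Compute every supported measure and coordinate set for one table.

    Requires all four margins positive (the full report touches every form).
    """
    forms: Dict[str, Dict[str, float]] = {}
    for form in FORMS:
        cc = com_coords(simplex_pair(t, form))
        forms[form] = {
            "p_alpha": cc.p_alpha,
            "p_beta": cc.p_beta,
            "delta": cc.delta,
            "mu": cc.mu,
            "displacement": cc.displacement,
        }
    m_r, _ = phi_factorization(t, "rsum")
    m_c, _ = phi_factorization(t, "csum")
    rxc = rxc_measures(t)
    pm = perspective_measures(
        ComCoords(
            delta=-forms["csum_rows"]["delta"],
            mu=forms["csum_rows"]["mu"],
            form_id="csum_rows",
        )
    )
    s_m, _, _ = simple_matching(t)
    return EffectSizeReport(
        counts=t.counts,
        omega=odds_ratio(t),
        q=yules_q(t),
        rho=relative_risk(t),
        ratio_diff=pm.ratio_diff,
        phi=phi(t),
        omega_m=marginal_ratio(t),
        s_m=s_m,
        cramers_v=rxc.cramers_v,
        tau_col=rxc.tau_col,
        tau_row=rxc.tau_row,
        forms=forms,
        m_factors={"rsum": m_r, "csum": m_c},
    )
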