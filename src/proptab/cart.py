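"""Binary association scan of one continuous covariate against a binary class.

For each candidate threshold ``t`` the samples split into subnodes
``S1 = {x <= t}`` (row 1) and ``S2 = {x > t}`` (row 2); columns hold the two
classes (column 1 = class 0, column 2 = class 1).  Per-threshold records
carry the impurity-based information gains, phi^2, Yule's Q, the
column-sum-invariant subnode-composition coordinates ``(delta_c, mu_c)``,
the row-sum-invariant analog ``delta_r``, and the marginal factors — every
record satisfies the identity ``IG_Gini = G(parent) * phi^2``.

``delta_c`` is the csum_rows center-of-mass delta (c-element minus
a-element, halved), which is invariant to rescaling either class's sample
size; ``delta_r`` is the rsum_rows delta (a-row minus c-row, halved).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np

from .errors import DegenerateTableError, DomainError
from . import effect_sizes as es
from .tables import CountTable2x2, marginal_ratio

__all__ = [
    "LabeledSample",
    "SplitRecord",
    "AssociationScan",
    "SelectedSplit",
    "candidate_thresholds",
    "impurity",
    "info_gain",
    "association_scan",
    "select_splits",
]

DEFAULT_MIN_NODE = 5

MEASURES = ("ig_gini", "ig_entropy", "phi2", "q", "delta_c", "mu_c",
            "delta_r", "omega_m", "m2")


@dataclass(frozen=True)
class LabeledSample:
    """One observation: continuous covariate ``x`` and binary class ``y``."""

    x: float
    y: int

    def __post_init__(self) -> None:
        if not math.isfinite(self.x):
            raise DomainError(f"non-finite covariate {self.x!r}")
        if self.y not in (0, 1):
            raise DomainError(f"class label must be 0 or 1, got {self.y!r}")


@dataclass(frozen=True)
class SplitRecord:
    """All measures for one binary partition."""

    threshold: float
    table: CountTable2x2
    n1: int
    n2: int
    ig_gini: float
    ig_entropy: float
    phi2: float
    q: float
    delta_c: float
    mu_c: float
    delta_r: float
    omega_m: float
    m2: float

    def measure(self, name: str) -> float:
        return getattr(self, name)


@dataclass(frozen=True)
class SelectedSplit:
    threshold: float
    measure: str
    value: float
    n1: int
    n2: int
    s1_class_proportions: Tuple[float, float]
    s2_class_proportions: Tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "split_value": self.threshold,
            "measure": self.measure,
            "value": self.value,
            "s1": {"n": self.n1, "class_proportions": list(self.s1_class_proportions)},
            "s2": {"n": self.n2, "class_proportions": list(self.s2_class_proportions)},
        }


@dataclass(frozen=True)
class AssociationScan:
    """Ordered per-threshold records for one covariate."""

    records: List[SplitRecord]
    covariate: str = "x"
    min_node: int = DEFAULT_MIN_NODE

    @property
    def thresholds(self) -> np.ndarray:
        return np.array([r.threshold for r in self.records])

    def measure_values(self, name: str) -> np.ndarray:
        return np.array([r.measure(name) for r in self.records])

    def to_frame(self):
        import pandas as pd

        rows = []
        for r in self.records:
            row = {"threshold": r.threshold, "n1": r.n1, "n2": r.n2,
                   "a": r.table.a, "b": r.table.b, "c": r.table.c, "d": r.table.d}
            row.update({m: r.measure(m) for m in MEASURES})
            rows.append(row)
        return pd.DataFrame(rows)


def candidate_thresholds(xs: Sequence[float], min_node: int = DEFAULT_MIN_NODE) -> np.ndarray:
    """Midpoints between consecutive distinct sorted values, restricted to
    splits leaving at least ``min_node`` samples on each side."""
    x = np.sort(np.asarray(xs, dtype=float))
    n = len(x)
    if n < 2 * min_node:
        raise DomainError(f"need at least {2 * min_node} samples, got {n}")
    distinct = np.unique(x)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    keep = []
    for t in mids:
        n1 = int(np.sum(x <= t))
        if min_node <= n1 <= n - min_node:
            keep.append(t)
    return np.array(keep)


def impurity(p: Sequence[float], kind: Literal["gini", "entropy"] = "gini") -> float:
    """Gini (``1 - sum p^2``) or entropy (``-sum p ln p``, natural log)
    impurity of a class-proportion vector."""
    p = np.asarray(p, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise DomainError(f"proportions must sum to 1, got {p.tolist()}")
    if kind == "gini":
        return float(1.0 - np.sum(p ** 2))
    if kind == "entropy":
        nz = p[p > 0]
        return float(-np.sum(nz * np.log(nz)))
    raise ValueError(f"kind must be 'gini' or 'entropy', got {kind!r}")


def info_gain(t: CountTable2x2, kind: Literal["gini", "entropy"] = "gini") -> float:
    """Information gain for a binary partition (table rows = subnodes,
    columns = classes): parent impurity from column sums minus size-weighted
    subnode impurities from row class-proportions."""
    r1, r2 = t.row_sums
    if r1 == 0 or r2 == 0:
        raise DegenerateTableError("empty subnode in info_gain")
    n = t.n
    parent = impurity(np.array(t.col_sums) / n, kind)
    i1 = impurity(np.array([t.a, t.b]) / r1, kind)
    i2 = impurity(np.array([t.c, t.d]) / r2, kind)
    return parent - (r1 / n) * i1 - (r2 / n) * i2


def _split_record(threshold: float, a: int, b: int, c: int, d: int) -> SplitRecord:
    t = CountTable2x2(a, b, c, d)
    cc_c = es.com_coords(es.simplex_pair(t, "csum_rows"))
    cc_r = es.com_coords(es.simplex_pair(t, "rsum_rows"))
    m_c, _ = es.phi_factorization(t, "csum")
    ph = es.phi(t)
    return SplitRecord(
        threshold=threshold,
        table=t,
        n1=int(a + b),
        n2=int(c + d),
        ig_gini=info_gain(t, "gini"),
        ig_entropy=info_gain(t, "entropy"),
        phi2=ph * ph,
        q=es.yules_q(t),
        delta_c=cc_c.delta,
        mu_c=cc_c.mu,
        delta_r=cc_r.delta,
        omega_m=marginal_ratio(t),
        m2=m_c * m_c,
    )


def association_scan(
    samples: Sequence[LabeledSample],
    min_node: int = DEFAULT_MIN_NODE,
    covariate: str = "x",
) -> AssociationScan:
    """Scan all candidate thresholds and record every measure per split.

    Both classes must be present; thresholds where a class margin of the
    split table is zero cannot occur since the class margins equal the fixed
    overall class counts.
    """
    x = np.array([s.x for s in samples], dtype=float)
    y = np.array([s.y for s in samples], dtype=int)
    if len(np.unique(y)) < 2:
        raise DegenerateTableError("association scan requires both classes present")
    thresholds = candidate_thresholds(x, min_node)
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    n_pos_cum = np.cumsum(ys)
    records = []
    for t in thresholds:
        n1 = int(np.searchsorted(xs, t, side="right"))
        b = int(n_pos_cum[n1 - 1])
        a = n1 - b
        d = int(n_pos_cum[-1] - b)
        c = len(xs) - n1 - d
        records.append(_split_record(float(t), a, b, c, d))
    return AssociationScan(records=records, covariate=covariate, min_node=min_node)


def _selected(rec: SplitRecord, measure: str) -> SelectedSplit:
    t = rec.table
    return SelectedSplit(
        threshold=rec.threshold,
        measure=measure,
        value=rec.measure(measure),
        n1=rec.n1,
        n2=rec.n2,
        s1_class_proportions=(t.a / (t.a + t.b), t.b / (t.a + t.b)),
        s2_class_proportions=(t.c / (t.c + t.d), t.d / (t.c + t.d)),
    )


def select_splits(
    scan: AssociationScan,
    measure: str = "ig_gini",
    mode: Literal["global_max", "two_sided"] = "global_max",
) -> List[SelectedSplit]:
    """Pick split(s) from a scan.

    ``global_max`` returns the threshold maximizing the measure (ties go to
    the smallest threshold).  ``two_sided`` — for signed measures such as
    ``delta_c`` — returns the thresholds maximizing and minimizing the
    measure, as lower/upper partition candidates.
    """
    if not scan.records:
        raise DomainError("empty scan")
    values = scan.measure_values(measure)
    if mode == "global_max":
        i = int(np.argmax(values))  # argmax returns first index on ties
        return [_selected(scan.records[i], measure)]
    if mode == "two_sided":
        i_max = int(np.argmax(values))
        i_min = int(np.argmin(values))
        lo, hi = sorted({i_max, i_min})
        out = [_selected(scan.records[lo], measure)]
        if hi != lo:
            out.append(_selected(scan.records[hi], measure))
        return out
    raise ValueError(f"mode must be 'global_max' or 'two_sided', got {mode!r}")
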