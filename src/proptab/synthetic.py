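"""Seeded fixture generators: random tables, two-class overlapping covariate
data, and logistic-model samples.

All generators are pure functions of their seed and parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .cart import LabeledSample
from .errors import DomainError
from .tables import CountTable2x2

__all__ = [
    "TwoClassSpec",
    "TwoClassDataset",
    "random_tables",
    "two_class_dataset",
    "logistic_samples",
]


def random_tables(n: int, max_total: int = 200, seed: int = 0) -> List[CountTable2x2]:
    """Random 2x2 tables with strictly positive margins.

    Cell probabilities ~ symmetric Dirichlet(1,1,1,1), totals uniform on
    [20, max_total], cells multinomial; tables with a zero margin are
    rejected and redrawn.
    """
    if n < 1:
        raise DomainError("n must be >= 1")
    if max_total < 20:
        raise DomainError("max_total must be >= 20")
    rng = np.random.default_rng(seed)
    out: List[CountTable2x2] = []
    while len(out) < n:
        probs = rng.dirichlet(np.ones(4))
        total = int(rng.integers(20, max_total + 1))
        a, b, c, d = rng.multinomial(total, probs)
        if min(a + b, c + d, a + c, b + d) == 0:
            continue
        out.append(CountTable2x2(float(a), float(b), float(c), float(d)))
    return out


@dataclass(frozen=True)
class TwoClassSpec:
    """Two overlapping Gaussian class-conditional distributions."""

    n_neg: int
    n_pos: int
    mean_neg: float = 20.0
    mean_pos: float = 25.0
    sd_neg: float = 5.0
    sd_pos: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neg < 1 or self.n_pos < 1:
            raise DomainError("class sizes must be >= 1")
        if self.sd_neg <= 0 or self.sd_pos <= 0:
            raise DomainError("class sds must be positive")


@dataclass(frozen=True)
class TwoClassDataset:
    samples: List[LabeledSample] = field(repr=False)
    spec: TwoClassSpec
    crossings: Tuple[float, ...]
    crossing_defined: bool


def _gaussian_crossings(spec: TwoClassSpec) -> Tuple[Tuple[float, ...], bool]:
    """Crossing points of the two unit-normalized class densities.

    Equal sds: the mean midpoint (undefined when the means coincide).
    Unequal sds: the roots of the log-density-difference quadratic.
    """
    m0, m1 = spec.mean_neg, spec.mean_pos
    s0, s1 = spec.sd_neg, spec.sd_pos
    if s0 == s1:
        if m0 == m1:
            return (), False
        return ((m0 + m1) / 2.0,), True
    a = 1.0 / (2 * s0 ** 2) - 1.0 / (2 * s1 ** 2)
    b = m1 / s1 ** 2 - m0 / s0 ** 2
    c = m0 ** 2 / (2 * s0 ** 2) - m1 ** 2 / (2 * s1 ** 2) - math.log(s1 / s0)
    disc = b * b - 4 * a * c
    if disc < 0:
        return (), False
    r = math.sqrt(disc)
    roots = sorted(((-b - r) / (2 * a), (-b + r) / (2 * a)))
    return tuple(roots), True


def two_class_dataset(spec: TwoClassSpec) -> TwoClassDataset:
    """Draw the two class-conditional Gaussian samples and record the
    analytic density crossings for split-recovery tests."""
    rng = np.random.default_rng(spec.seed)
    x_neg = rng.normal(spec.mean_neg, spec.sd_neg, size=spec.n_neg)
    x_pos = rng.normal(spec.mean_pos, spec.sd_pos, size=spec.n_pos)
    samples = [LabeledSample(float(v), 0) for v in x_neg]
    samples += [LabeledSample(float(v), 1) for v in x_pos]
    crossings, defined = _gaussian_crossings(spec)
    return TwoClassDataset(
        samples=samples, spec=spec, crossings=crossings, crossing_defined=defined
    )


def logistic_samples(
    b: float,
    x0: float,
    n_neg_target: int,
    n_pos_target: int,
    x_grid: Optional[Tuple[float, float, int]] = None,
    seed: int = 0,
) -> List[LabeledSample]:
    """Samples from the imbalanced logistic model
    ``P(y=1|x) = 1/(1 + (n_neg/n_pos) exp(-b (x - x0)))``.

    ``x_grid = (lo, hi, n_points)`` defaults to 8 logistic widths around
    ``x0``.  Realized class counts are random; targets fix the odds offset.
    """
    if b == 0:
        raise DomainError("slope b must be nonzero")
    if x_grid is None:
        half = 8.0 / abs(b)
        x_grid = (x0 - half, x0 + half, 2000)
    lo, hi, n_points = x_grid
    rng = np.random.default_rng(seed)
    x = np.linspace(lo, hi, int(n_points))
    from scipy.special import expit

    ratio = n_neg_target / n_pos_target
    p = expit(b * (x - x0) - math.log(ratio))
    y = rng.random(len(x)) < p
    return [LabeledSample(float(xi), int(yi)) for xi, yi in zip(x, y)]
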