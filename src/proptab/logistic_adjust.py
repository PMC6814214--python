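"""One-covariate logistic fit with a sample-size-adjusted reparameterization.

The fitted model ``y = 1/(1 + exp(-(a0 + b*x)))`` depends on the class
sample sizes through its intercept.  Rewriting ``a0 = -b*x0 - ln(n_neg/n_pos)``
yields ``y = 1/(1 + (n_neg/n_pos) * exp(-b*(x - x0)))`` with
``y(x0) = n_pos/(n_neg + n_pos)``, so ``(b, x0)`` are sample-size-independent
parameters and the *adjusted* (equal-class-size) curve is
``1/(1 + exp(-b*(x - x0)))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .cart import LabeledSample
from .errors import ConvergenceError, DegenerateTableError, DomainError

__all__ = [
    "LogisticFit",
    "AdjustedLogistic",
    "fit_logistic",
    "adjust_for_sample_size",
    "reweighted_proportion",
    "moving_average_proportion",
    "default_window",
]


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood intercept/slope fit of class-1 probability on x."""

    intercept: float
    slope: float
    n_neg: int
    n_pos: int
    converged: bool
    iterations: int

    def predict(self, x) -> np.ndarray:
        from scipy.special import expit

        return expit(self.intercept + self.slope * np.asarray(x, dtype=float))


@dataclass(frozen=True)
class AdjustedLogistic:
    """Sample-size-independent parameterization ``(b, x0)``."""

    b: float
    x0: float
    n_neg: int
    n_pos: int

    @property
    def balance_proportion(self) -> float:
        return self.n_pos / (self.n_neg + self.n_pos)

    def predict_adjusted(self, x) -> np.ndarray:
        """Equal-class-size curve ``1/(1 + exp(-b (x - x0)))``."""
        z = self.b * (np.asarray(x, dtype=float) - self.x0)
        return 1.0 / (1.0 + np.exp(-z))

    def predict_original(self, x) -> np.ndarray:
        """Original-scale curve ``1/(1 + (n_neg/n_pos) exp(-b (x - x0)))``."""
        z = self.b * (np.asarray(x, dtype=float) - self.x0)
        return 1.0 / (1.0 + (self.n_neg / self.n_pos) * np.exp(-z))


def fit_logistic(
    samples: Sequence[LabeledSample],
    tol: float = 1e-10,
    max_iter: int = 100,
) -> LogisticFit:
    """Fit ``P(y=1|x) = 1/(1+exp(-(a0 + b x)))`` by Newton-Raphson.

    Deterministic given the data.  Raises :class:`ConvergenceError` when the
    score does not converge within ``max_iter`` iterations (e.g. perfect
    separation) and :class:`DomainError` for degenerate inputs.
    """
    x = np.array([s.x for s in samples], dtype=float)
    y = np.array([s.y for s in samples], dtype=float)
    if len(x) < 2:
        raise DomainError("need at least 2 samples")
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DegenerateTableError("both classes must be present for a logistic fit")
    if np.ptp(x) == 0:
        raise DomainError("covariate is constant")

    # design matrix [1, x]; Newton on the 2-parameter log-likelihood
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    beta[0] = math.log(n_pos / n_neg)  # intercept-only start
    converged = False
    it = 0
    from scipy.special import expit

    for it in range(1, max_iter + 1):
        p = expit(X @ beta)
        score = X.T @ (y - p)
        if np.linalg.norm(score) < tol:
            converged = True
            break
        w = p * (1.0 - p)
        hess = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(hess, score)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular Hessian at iteration {it}") from exc
        beta = beta + step
        if not np.all(np.isfinite(beta)) or abs(beta[1]) > 1e8:
            raise ConvergenceError(
                "diverging parameters; data may be perfectly separated"
            )
    if not converged:
        raise ConvergenceError(
            f"no convergence in {max_iter} iterations "
            f"(score norm {np.linalg.norm(score):.3g}); "
            "data may be perfectly separated"
        )
    # saturated probabilities mean the MLE diverged to a step function
    if np.all(np.abs(y - expit(X @ beta)) < 1e-6):
        raise ConvergenceError(
            "perfect separation: fitted probabilities saturated at 0/1"
        )
    return LogisticFit(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        n_neg=n_neg,
        n_pos=n_pos,
        converged=True,
        iterations=it,
    )


def adjust_for_sample_size(fit: LogisticFit) -> AdjustedLogistic:
    """Reparameterize a fit as ``(b, x0)`` with
    ``x0 = -(a0 + ln(n_neg/n_pos))/b``.

    The original curve evaluated at ``x0`` equals ``n_pos/(n_neg + n_pos)``
    by construction.
    """
    if fit.slope == 0:
        raise DomainError("midpoint undefined for zero slope")
    x0 = -(fit.intercept + math.log(fit.n_neg / fit.n_pos)) / fit.slope
    return AdjustedLogistic(b=fit.slope, x0=x0, n_neg=fit.n_neg, n_pos=fit.n_pos)


def reweighted_proportion(p: float, n_neg: int, n_pos: int) -> float:
    """Inverse-class-size reweighting of a class-1 proportion.

    ``p_adj = p*n_neg / (p*n_neg + (1-p)*n_pos)``: maps the class-size
    balance point ``n_pos/(n_neg+n_pos)`` to 1/2, and is the identity when
    the classes are equal-sized.
    """
    if not (0.0 <= p <= 1.0):
        raise DomainError(f"proportion out of [0,1]: {p!r}")
    num = p * n_neg
    den = p * n_neg + (1.0 - p) * n_pos
    if den == 0:
        raise DomainError("degenerate reweighting (0/0)")
    return num / den


def default_window(n: int) -> int:
    """Default moving-average window: n/20 samples, rounded to odd."""
    w = max(1, round(n / 20))
    return w if w % 2 == 1 else w + 1


def moving_average_proportion(
    samples: Sequence[LabeledSample], window: int
) -> List[Tuple[float, float]]:
    """Sliding-window class-1 proportion over rank-ordered x.

    Returns ``(window median x, class-1 proportion)`` per window position.
    """
    if window < 1:
        raise DomainError("window must be >= 1")
    if window > len(samples):
        raise DomainError(f"window {window} exceeds sample count {len(samples)}")
    x = np.array([s.x for s in samples], dtype=float)
    y = np.array([s.y for s in samples], dtype=float)
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    csum = np.concatenate([[0.0], np.cumsum(ys)])
    out = []
    for i in range(len(xs) - window + 1):
        prop = (csum[i + window] - csum[i]) / window
        center = float(np.median(xs[i:i + window]))
        out.append((center, float(prop)))
    return out
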