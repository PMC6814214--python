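"""Monte Carlo table distributions and confidence intervals.

A source 2x2 table induces a distribution of tables under a sampling scheme
that holds some margins fixed: binomial columns (``fixed_colsums``),
binomial rows (``fixed_rowsums``), or a single multinomial over the four
cells (``fixed_total``).  Any registered statistic is evaluated over the
draws; draws where it is undefined are excluded and counted, never imputed.

Reproducibility: a root seed plus the run index seed an independent
``numpy`` Generator per run, so runs are order-insensitive.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Literal, Optional, Sequence, Tuple, Union

import numpy as np

from .errors import DegenerateTableError, ZeroMarginError
from . import effect_sizes as es
from .tables import CountTable2x2

__all__ = [
    "MCScheme",
    "RunSummary",
    "MCResult",
    "CIResult",
    "Statistic",
    "STATISTICS",
    "get_statistic",
    "sample_counts",
    "sample_tables",
    "statistic_distribution",
    "confidence_interval",
]

logger = logging.getLogger(__name__)

SchemeKind = Literal["fixed_colsums", "fixed_rowsums", "fixed_total"]


@dataclass(frozen=True)
class MCScheme:
    """Sampling scheme: source table, scheme kind, and replication sizes."""

    kind: SchemeKind
    table: CountTable2x2
    n_tables: int = 10000
    n_runs: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("fixed_colsums", "fixed_rowsums", "fixed_total"):
            raise ValueError(f"unknown scheme kind {self.kind!r}")
        if self.n_tables < 1 or self.n_runs < 1:
            raise ValueError("n_tables and n_runs must be >= 1")


def _int_margin(x: float, what: str) -> int:
    r = round(x)
    if abs(x - r) > 1e-9:
        logger.warning("non-integer %s %.6g rounded to %d for sampling", what, x, r)
    return int(r)


def sample_counts(scheme: MCScheme, run_index: int = 0) -> np.ndarray:
    """Draw ``scheme.n_tables`` tables as an ``(n, 4)`` array of cell counts
    ``(a, b, c, d)``, reproducible from ``(scheme.seed, run_index)``."""
    t = scheme.table
    rng = np.random.default_rng([scheme.seed, run_index])
    n = scheme.n_tables
    if scheme.kind == "fixed_colsums":
        c1, c2 = t.col_sums
        if c1 == 0 or c2 == 0:
            raise ZeroMarginError("fixed_colsums requires positive column sums")
        n1 = _int_margin(c1, "column sum")
        n2 = _int_margin(c2, "column sum")
        a = rng.binomial(n1, t.a / c1, size=n)
        b = rng.binomial(n2, t.b / c2, size=n)
        out = np.column_stack([a, b, n1 - a, n2 - b])
    elif scheme.kind == "fixed_rowsums":
        r1, r2 = t.row_sums
        if r1 == 0 or r2 == 0:
            raise ZeroMarginError("fixed_rowsums requires positive row sums")
        n1 = _int_margin(r1, "row sum")
        n2 = _int_margin(r2, "row sum")
        a = rng.binomial(n1, t.a / r1, size=n)
        c = rng.binomial(n2, t.c / r2, size=n)
        out = np.column_stack([a, n1 - a, c, n2 - c])
    else:
        total = _int_margin(t.n, "total")
        p = np.array(t.counts) / t.n
        out = rng.multinomial(total, p, size=n)
    return out.astype(float)


def sample_tables(scheme: MCScheme, run_index: int = 0) -> List[CountTable2x2]:
    """Like :func:`sample_counts` but wrapped as table objects."""
    return [CountTable2x2(*row) for row in sample_counts(scheme, run_index)]


# ---------------------------------------------------------------------------
# Statistics registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Statistic:
    """A named scalar statistic over a 2x2 table.

    ``func`` evaluates one table (raising on undefined input); ``vfunc``, if
    given, evaluates an ``(n, 4)`` count array to an ``(n,)`` float array
    with NaN marking undefined draws.
    """

    name: str
    func: Callable[[CountTable2x2], float]
    vfunc: Optional[Callable[[np.ndarray], np.ndarray]] = None

    def evaluate(self, counts: np.ndarray) -> np.ndarray:
        if self.vfunc is not None:
            return self.vfunc(counts)
        out = np.empty(len(counts))
        for i, row in enumerate(counts):
            try:
                out[i] = self.func(CountTable2x2(*row))
            except Exception:
                out[i] = np.nan
        return out


def _dual_col_elems(counts: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """(a-element, c-element) of the column-side dual matrix, vectorized."""
    a, b, c, d = counts.T
    with np.errstate(divide="ignore", invalid="ignore"):
        pa = a / (a + c)
        pb = b / (b + d)
        pc = c / (a + c)
        pd = d / (b + d)
        n1 = pa + pb
        n2 = pc + pd
        return pa / n1, pc / n2


def _v_delta_c_cma(counts: np.ndarray) -> np.ndarray:
    ea, ec = _dual_col_elems(counts)
    return (ec - ea) / 2.0


def _v_mu_c_apc(counts: np.ndarray) -> np.ndarray:
    ea, ec = _dual_col_elems(counts)
    return (ea + ec) / 2.0


def _v_yules_q(counts: np.ndarray) -> np.ndarray:
    a, b, c, d = counts.T
    ad, bc = a * d, b * c
    with np.errstate(divide="ignore", invalid="ignore"):
        return (ad - bc) / (ad + bc)


def _v_phi(counts: np.ndarray) -> np.ndarray:
    a, b, c, d = counts.T
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.sqrt((a + b) * (c + d) * (a + c) * (b + d))
        out = (a * d - b * c) / denom
    out[denom == 0] = np.nan
    return out


def _v_odds_ratio(counts: np.ndarray) -> np.ndarray:
    a, b, c, d = counts.T
    ad, bc = a * d, b * c
    with np.errstate(divide="ignore", invalid="ignore"):
        out = ad / bc
    out[(ad == 0) & (bc == 0)] = np.nan
    return out


def _form_delta(form: str) -> Callable[[CountTable2x2], float]:
    def f(t: CountTable2x2) -> float:
        return es.com_coords(es.simplex_pair(t, form)).delta
    return f


def _form_mu(form: str) -> Callable[[CountTable2x2], float]:
    def f(t: CountTable2x2) -> float:
        return es.com_coords(es.simplex_pair(t, form)).mu
    return f


STATISTICS: Dict[str, Statistic] = {
    "delta_c_cma": Statistic(
        "delta_c_cma",
        lambda t: es.com_coords(es.simplex_pair(t, "csum_rows")).delta,
        _v_delta_c_cma,
    ),
    "mu_c_apc": Statistic(
        "mu_c_apc",
        lambda t: es.com_coords(es.simplex_pair(t, "csum_rows")).mu,
        _v_mu_c_apc,
    ),
    "delta_csum_cols": Statistic("delta_csum_cols", _form_delta("csum_cols")),
    "delta_rsum_rows": Statistic("delta_rsum_rows", _form_delta("rsum_rows")),
    "delta_rsum_cols": Statistic("delta_rsum_cols", _form_delta("rsum_cols")),
    "mu_csum_cols": Statistic("mu_csum_cols", _form_mu("csum_cols")),
    "mu_rsum_rows": Statistic("mu_rsum_rows", _form_mu("rsum_rows")),
    "yules_q": Statistic("yules_q", es.yules_q, _v_yules_q),
    "odds_ratio": Statistic("odds_ratio", es.odds_ratio, _v_odds_ratio),
    "phi": Statistic("phi", es.phi, _v_phi),
    "relative_risk": Statistic("relative_risk", es.relative_risk),
    "s_m": Statistic("s_m", lambda t: (t.a + t.d) / t.n,
                     lambda m: (m[:, 0] + m[:, 3]) / m.sum(axis=1)),
    "total": Statistic("total", lambda t: t.n, lambda m: m.sum(axis=1)),
}


def get_statistic(statistic: Union[str, Statistic, Callable]) -> Statistic:
    if isinstance(statistic, Statistic):
        return statistic
    if callable(statistic):
        return Statistic(getattr(statistic, "__name__", "custom"), statistic)
    try:
        return STATISTICS[statistic]
    except KeyError:
        raise KeyError(
            f"unknown statistic {statistic!r}; known: {sorted(STATISTICS)}"
        ) from None


# ---------------------------------------------------------------------------
# Distribution summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunSummary:
    mean: float
    median: float
    variance: float
    sd: float
    n: int
    n_excluded: int


@dataclass(frozen=True)
class MCResult:
    """Per-run summaries plus a pooled histogram for one statistic."""

    statistic: str
    per_run: List[RunSummary]
    pooled_mean: float
    pooled_sd: float
    hist_edges: np.ndarray = field(repr=False)
    hist_counts: np.ndarray = field(repr=False)
    n_excluded: int
    values: np.ndarray = field(repr=False)

    @property
    def mean_of_run_means(self) -> float:
        return float(np.mean([r.mean for r in self.per_run]))

    @property
    def mean_of_run_sds(self) -> float:
        return float(np.mean([r.sd for r in self.per_run]))

    @property
    def sd_of_run_means(self) -> float:
        """Convergence diagnostic: scatter of per-run means."""
        return float(np.std([r.mean for r in self.per_run], ddof=0))

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "n_runs": len(self.per_run),
            "pooled_mean": self.pooled_mean,
            "pooled_sd": self.pooled_sd,
            "mean_of_run_means": self.mean_of_run_means,
            "mean_of_run_sds": self.mean_of_run_sds,
            "sd_of_run_means": self.sd_of_run_means,
            "n_excluded": self.n_excluded,
            "hist_edges": self.hist_edges.tolist(),
            "hist_counts": self.hist_counts.tolist(),
            "per_run": [vars(r) for r in self.per_run],
        }


def _summarize_run(values: np.ndarray) -> RunSummary:
    ok = values[np.isfinite(values)]
    n_excl = len(values) - len(ok)
    if len(ok) == 0:
        raise DegenerateTableError("all draws degenerate for this statistic")
    return RunSummary(
        mean=float(np.mean(ok)),
        median=float(np.median(ok)),
        variance=float(np.var(ok, ddof=0)),
        sd=float(np.std(ok, ddof=0)),
        n=len(ok),
        n_excluded=n_excl,
    )


def statistic_distribution(
    tables: Union[Sequence[CountTable2x2], np.ndarray, Sequence[np.ndarray]],
    statistic: Union[str, Statistic, Callable],
    bin_width: float = 0.01,
) -> MCResult:
    """Evaluate a statistic over sampled tables and summarize.

    ``tables`` is either one run (a sequence of tables or an ``(n, 4)``
    array) or a list of runs (list of such arrays).  Undefined draws are
    excluded and counted.
    """
    stat = get_statistic(statistic)
    if isinstance(tables, np.ndarray) and tables.ndim == 2:
        runs = [tables]
    elif len(tables) and isinstance(tables[0], CountTable2x2):
        runs = [np.array([t.counts for t in tables], dtype=float)]
    else:
        runs = [
            r if isinstance(r, np.ndarray)
            else np.array([t.counts for t in r], dtype=float)
            for r in tables
        ]
    run_values = [stat.evaluate(r) for r in runs]
    per_run = [_summarize_run(v) for v in run_values]
    pooled = np.concatenate(run_values)
    ok = pooled[np.isfinite(pooled)]
    lo, hi = float(ok.min()), float(ok.max())
    span = max(hi - lo, bin_width)
    nbins = max(1, int(math.ceil(span / bin_width)))
    hist_counts, hist_edges = np.histogram(ok, bins=nbins, range=(lo, lo + nbins * bin_width))
    return MCResult(
        statistic=stat.name,
        per_run=per_run,
        pooled_mean=float(np.mean(ok)),
        pooled_sd=float(np.std(ok, ddof=0)),
        hist_edges=hist_edges,
        hist_counts=hist_counts,
        n_excluded=int(len(pooled) - len(ok)),
        values=ok,
    )


@dataclass(frozen=True)
class CIResult:
    """Percentile and normal-approximation confidence intervals."""

    statistic: str
    level: float
    percentile_lower: float
    percentile_upper: float
    normal_lower: float
    normal_upper: float
    mean: float
    sd: float
    median: float
    convergence_sd: float
    n_draws: int
    n_excluded: int

    def to_dict(self) -> dict:
        return dict(vars(self))


def confidence_interval(
    scheme: MCScheme,
    statistic: Union[str, Statistic, Callable],
    level: float = 0.95,
    bin_width: float = 0.01,
) -> Tuple[CIResult, MCResult]:
    """Monte Carlo confidence interval for a statistic under a scheme.

    Returns the percentile interval over the pooled draws (asymmetric by
    construction) plus the normal-approximation mean +/- 2 sd interval, and
    the underlying :class:`MCResult`.
    """
    if not (0 < level < 1):
        raise ValueError(f"level must be in (0, 1), got {level}")
    runs = [sample_counts(scheme, i) for i in range(scheme.n_runs)]
    mc = statistic_distribution(runs, statistic, bin_width=bin_width)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(mc.values, [alpha, 1.0 - alpha])
    ci = CIResult(
        statistic=mc.statistic,
        level=level,
        percentile_lower=float(lo),
        percentile_upper=float(hi),
        normal_lower=mc.pooled_mean - 2.0 * mc.pooled_sd,
        normal_upper=mc.pooled_mean + 2.0 * mc.pooled_sd,
        mean=mc.pooled_mean,
        sd=mc.pooled_sd,
        median=float(np.median(mc.values)),
        convergence_sd=mc.sd_of_run_means,
        n_draws=len(mc.values),
        n_excluded=mc.n_excluded,
    )
    return ci, mc
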