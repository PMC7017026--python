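"""Downstream statistics: exact contingency-table tests, Welch's t-test,
and relative expression by the ddCt method.

The exact tests use the point-probability criterion for two-sidedness: the
p-value is the null probability of all margin-fixed tables whose conditional
probability does not exceed that of the observed table (for 2x2 this is the
classical two-sided Fisher test; for RxC it is the Freeman-Halton
extension, computed by full enumeration).  Ties in table probability are
resolved *exactly* in integer arithmetic, so the p-value never depends on
floating-point grace factors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
from scipy.special import gammaln

__all__ = [
    "ContingencyTable",
    "FisherResult",
    "MonteCarloResult",
    "WelchResult",
    "FoldChangeResult",
    "fisher_exact",
    "monte_carlo_exact",
    "welch_t",
    "ddct_fold_change",
]

log = logging.getLogger(__name__)

#: enumeration cap for RxC tables (grand total); larger tables need Monte Carlo
MAX_ENUMERATION_TOTAL = 200

# log-float slack below which a probability tie is re-checked exactly
_TIE_EPS = 1e-9


@dataclass
class ContingencyTable:
    """Labeled RxC table of non-negative integer counts."""

    counts: np.ndarray
    row_labels: Sequence[str] | None = None
    col_labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or min(self.counts.shape) < 2:
            raise ValueError("contingency table must be at least 2x2")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = np.round(self.counts).astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        self.counts = self.counts.astype(np.int64)
        if self.counts.sum() == 0:
            raise ValueError("table total must be > 0")
        if self.row_labels is not None and len(self.row_labels) != self.counts.shape[0]:
            raise ValueError("row_labels length mismatch")
        if self.col_labels is not None and len(self.col_labels) != self.counts.shape[1]:
            raise ValueError("col_labels length mismatch")

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, row: str, col: str
    ) -> "ContingencyTable":
        """Cross-tabulate two categorical columns of a cohort table."""
        tab = pd.crosstab(frame[row], frame[col])
        return cls(
            counts=tab.to_numpy(),
            row_labels=[str(x) for x in tab.index],
            col_labels=[str(x) for x in tab.columns],
        )


def _as_counts(table) -> np.ndarray:
    if isinstance(table, ContingencyTable):
        return table.counts
    return ContingencyTable(np.asarray(table)).counts


@lru_cache(maxsize=4096)
def _fact(n: int) -> int:
    return math.factorial(n)


def _cell_fact_product(cells: Iterator[int]) -> int:
    out = 1
    for c in cells:
        out *= _fact(int(c))
    return out


def _row_fills(s: int, caps: tuple[int, ...]) -> Iterator[tuple[int, ...]]:
    """All ways to fill one row summing to s with per-cell caps."""
    if len(caps) == 1:
        if s <= caps[0]:
            yield (s,)
        return
    tail = sum(caps[1:])
    for v in range(max(0, s - tail), min(caps[0], s) + 1):
        for rest in _row_fills(s - v, caps[1:]):
            yield (v,) + rest


def _tables_fixed_margins(
    row_m: tuple[int, ...], cols_left: tuple[int, ...]
) -> Iterator[tuple[int, ...]]:
    """All tables (flattened row-major) with the given margins."""
    if len(row_m) == 1:
        yield cols_left
        return
    for row in _row_fills(row_m[0], cols_left):
        rest_cols = tuple(c - v for c, v in zip(cols_left, row))
        for rest in _tables_fixed_margins(row_m[1:], rest_cols):
            yield row + rest


@dataclass(frozen=True)
class FisherResult:
    """Exact-test result: two-sided p, point probability of the observed table."""

    p_value: float
    point_prob: float
    n_tables: int  # tables enumerated with the observed margins

    def __iter__(self):  # tuple-unpacking convenience
        return iter((self.p_value, self.point_prob))


def fisher_exact(table) -> FisherResult:
    """Two-sided exact test of independence for an RxC contingency table.

    2x2 tables use hypergeometric tail summation over the single free cell;
    larger tables use Freeman-Halton full enumeration of all margin-fixed
    tables.  In both cases the p-value is the total conditional probability
    of tables whose probability is <= that of the observed table, with ties
    decided exactly in integer arithmetic.

    Raises
    ------
    ValueError
        If an RxC (non-2x2) table has grand total above
        :data:`MAX_ENUMERATION_TOTAL` — use :func:`monte_carlo_exact` then.
    """
    counts = _as_counts(table)
    n_rows, n_cols = counts.shape
    if (n_rows, n_cols) != (2, 2) and counts.sum() > MAX_ENUMERATION_TOTAL:
        raise ValueError(
            f"table total {counts.sum()} too large for full enumeration "
            f"(cap {MAX_ENUMERATION_TOTAL}); use monte_carlo_exact instead"
        )
    row_m = tuple(int(x) for x in counts.sum(axis=1))
    col_m = tuple(int(x) for x in counts.sum(axis=0))

    if (n_rows, n_cols) == (2, 2):
        r1, c1 = row_m[0], col_m[0]
        total = sum(row_m)
        k_lo = max(0, r1 + c1 - total)
        k_hi = min(r1, c1)
        ks = np.arange(k_lo, k_hi + 1)
        cells = np.stack([ks, r1 - ks, c1 - ks, total - r1 - c1 + ks], axis=1)
        flat_obs = tuple(int(x) for x in counts.ravel())
        obs_idx = int(counts[0, 0]) - k_lo
        all_tables = [tuple(int(x) for x in row) for row in cells]
    else:
        flat_obs = tuple(int(x) for x in counts.ravel())
        all_tables = list(_tables_fixed_margins(row_m, col_m))
        obs_idx = all_tables.index(flat_obs)

    # log "surprise" s = sum log(cell!); pmf <= pmf_obs  <=>  s >= s_obs
    cell_arr = np.asarray(all_tables, dtype=np.int64)
    s = gammaln(cell_arr + 1).sum(axis=1)
    s_obs = s[obs_idx]
    include = s >= s_obs - _TIE_EPS
    borderline = np.flatnonzero(np.abs(s - s_obs) <= 2 * _TIE_EPS)
    if borderline.size:
        denom_obs = _cell_fact_product(iter(flat_obs))
        for i in borderline:
            include[i] = _cell_fact_product(iter(all_tables[i])) >= denom_obs

    pmf = np.exp(-(s - s.min()))
    p = float(pmf[include].sum() / pmf.sum())
    point = float(pmf[obs_idx] / pmf.sum())
    return FisherResult(
        p_value=min(1.0, p), point_prob=point, n_tables=len(all_tables)
    )


@dataclass(frozen=True)
class MonteCarloResult:
    """Monte-Carlo exact-test estimate with a binomial confidence interval."""

    p_value: float
    ci_low: float
    ci_high: float
    n_draws: int
    n_extreme: int


def monte_carlo_exact(table, n_draws: int = 10_000, seed: int = 0) -> MonteCarloResult:
    """Monte-Carlo estimate of the two-sided exact p for large RxC tables.

    Samples ``n_draws`` tables with the observed margins (Boyett/Patefield
    sampling via :func:`scipy.stats.random_table`) and reports the
    add-one-corrected proportion ``(k + 1) / (n + 1)`` of draws at least as
    extreme (probability <= observed), with a 95% Clopper-Pearson interval
    on the raw proportion.
    """
    if n_draws < 1000:
        raise ValueError("n_draws must be >= 1000")
    counts = _as_counts(table)
    row_m = counts.sum(axis=1)
    col_m = counts.sum(axis=0)
    total = int(counts.sum())
    rng = np.random.default_rng(seed)
    draws = sps.random_table(row_m, col_m).rvs(n_draws, random_state=rng)
    draws = np.asarray(draws, dtype=np.int64).reshape(n_draws, -1)

    lgf = gammaln(np.arange(total + 1) + 1.0)
    s = lgf[draws].sum(axis=1)
    s_obs = float(gammaln(counts + 1).sum())
    extreme = s >= s_obs - _TIE_EPS
    borderline = np.flatnonzero(np.abs(s - s_obs) <= 2 * _TIE_EPS)
    if borderline.size:
        denom_obs = _cell_fact_product(int(x) for x in counts.ravel())
        for i in borderline:
            extreme[i] = (
                _cell_fact_product(int(x) for x in draws[i]) >= denom_obs
            )
    k = int(extreme.sum())
    ci = sps.binomtest(k, n_draws).proportion_ci(confidence_level=0.95)
    return MonteCarloResult(
        p_value=(k + 1) / (n_draws + 1),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        n_draws=n_draws,
        n_extreme=k,
    )


@dataclass(frozen=True)
class WelchResult:
    """Welch's unequal-variance t-test result."""

    statistic: float
    df: float
    p_value: float

    def __iter__(self):
        return iter((self.statistic, self.df, self.p_value))


def welch_t(sample_a, sample_b) -> WelchResult:
    """Two-sided Welch's t-test (unequal variances, Welch-Satterthwaite df).

    Degenerate input with both sample variances zero returns p = 1 for equal
    means and p = 0 otherwise (the test statistic is then unbounded).

    Raises
    ------
    ValueError
        If either sample has fewer than two observations.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least two observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return WelchResult(0.0, float(len(a) + len(b) - 2), 1.0)
        sign = 1.0 if a.mean() > b.mean() else -1.0
        return WelchResult(sign * math.inf, float("nan"), 0.0)
    res = sps.ttest_ind(a, b, equal_var=False)
    return WelchResult(float(res.statistic), float(res.df), float(res.pvalue))


@dataclass
class FoldChangeResult:
    """Relative expression by the ddCt method.

    ``per_group`` has one row per group: ``group, n, mean_dct, ddct,
    fold_change`` (fold change ``2**(-ddct)`` vs the calibrator, which is 1
    by construction).  ``per_sample`` carries per-sample relative quantities
    ``2**(-(dCt - mean dCt of calibrator))`` for plotting and t-testing.
    """

    per_group: pd.DataFrame
    per_sample: pd.DataFrame
    calibrator_group: str
    target_gene: str
    reference_gene: str

    def fold_change(self, group: str) -> float:
        rows = self.per_group[self.per_group["group"] == group]
        if rows.empty:
            raise KeyError(f"no such group: {group!r}")
        return float(rows["fold_change"].iloc[0])

    def relative_quantities(self, group: str) -> np.ndarray:
        return self.per_sample.loc[
            self.per_sample["group"] == group, "rel_quantity"
        ].to_numpy()

    def summary(self) -> str:
        lines = [
            f"ddCt relative expression: {self.target_gene} "
            f"(normalized to {self.reference_gene}, "
            f"calibrator {self.calibrator_group!r})",
            "",
            f"{'group':<12}{'n':>4}{'mean dCt':>10}{'ddCt':>8}{'fold':>8}",
        ]
        for r in self.per_group.itertuples(index=False):
            lines.append(
                f"{r.group:<12}{r.n:>4}{r.mean_dct:>10.3f}"
                f"{r.ddct:>8.3f}{r.fold_change:>8.3f}"
            )
        return "\n".join(lines)


def ddct_fold_change(
    data: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    calibrator_group: str,
) -> FoldChangeResult:
    """Relative expression of ``target_gene`` per group by the ddCt method.

    ``data`` is a long Ct table with columns ``sample_id, group, gene, ct``.
    Per sample, dCt = Ct(target) - Ct(reference); per group, ddCt = mean dCt
    minus the calibrator-group mean dCt, and fold change = 2**(-ddCt).
    Samples lacking a Ct for either gene are excluded with a warning;
    technical replicates (several Cts per sample and gene) are averaged.

    Raises
    ------
    ValueError
        If the calibrator group has no usable samples, or any Ct is
        non-finite or non-positive.
    """
    cts = data["ct"].to_numpy(dtype=float)
    if not np.all(np.isfinite(cts)) or np.any(cts <= 0):
        raise ValueError("Ct values must be finite and > 0")
    sub = data[data["gene"].isin([target_gene, reference_gene])]
    wide = sub.pivot_table(
        index=["sample_id", "group"], columns="gene", values="ct", aggfunc="mean"
    )
    for gene in (target_gene, reference_gene):
        if gene not in wide.columns:
            wide[gene] = np.nan
    complete = wide.dropna(subset=[target_gene, reference_gene])
    n_dropped = len(wide) - len(complete)
    if n_dropped:
        log.warning(
            "%d sample(s) lack a Ct for %s or %s; excluded",
            n_dropped, target_gene, reference_gene,
        )
    per_sample = complete.reset_index()
    per_sample["dct"] = per_sample[target_gene] - per_sample[reference_gene]

    groups = list(dict.fromkeys(per_sample["group"]))
    if calibrator_group not in groups:
        raise ValueError(
            f"calibrator group {calibrator_group!r} has no usable samples"
        )
    cal_mean = float(
        per_sample.loc[per_sample["group"] == calibrator_group, "dct"].mean()
    )
    per_sample["rel_quantity"] = 2.0 ** (-(per_sample["dct"] - cal_mean))

    rows = []
    for group in groups:
        dct = per_sample.loc[per_sample["group"] == group, "dct"]
        ddct = float(dct.mean()) - cal_mean
        rows.append(
            {
                "group": group,
                "n": int(len(dct)),
                "mean_dct": float(dct.mean()),
                "ddct": ddct,
                "fold_change": 2.0 ** (-ddct),
            }
        )
    per_group = pd.DataFrame(rows)
    return FoldChangeResult(
        per_group=per_group,
        per_sample=per_sample.loc[:, ["sample_id", "group", "dct", "rel_quantity"]],
        calibrator_group=calibrator_group,
        target_gene=target_gene,
        reference_gene=reference_gene,
    )
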