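"""Differential cell-type abundance: odds ratios, exact CIs, hypergeometric tests.

For a cell type C, with m cells sequenced in the treatment condition and n
in the control, k cells of type C in total and q of them in the treatment,
the null of no abundance shift makes q hypergeometric: k type-C cells drawn
without replacement into an m-cell treatment "sample" from the m+n pooled
cells.  The effect size is the cross-product odds ratio of the 2x2 table
``[[q, m-q], [k-q, n-(k-q)]]``; its confidence interval comes from inverting
the exact conditional (Fisher noncentral hypergeometric) test, matching the
convention of exact-test routines.  The same urn law powers the gene-set
Venn-overlap test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats


@dataclass
class CompositionTable:
    """Cell-type x condition contingency counts for a two-condition design."""

    cell_types: list[str]
    q: dict[str, int]  # per type: count in treatment condition
    k: dict[str, int]  # per type: total count
    m: int  # treatment total (all types)
    n: int  # control total (all types)
    treatment: str
    control: str

    def __post_init__(self) -> None:
        if sum(self.q.values()) != self.m:
            raise ValueError("per-type treatment counts do not sum to m")
        if sum(self.k.values()) != self.m + self.n:
            raise ValueError("per-type totals do not sum to m + n")
        for t in self.cell_types:
            if not 0 <= self.q[t] <= min(self.k[t], self.m):
                raise ValueError(f"inconsistent counts for type {t!r}")


@dataclass
class ShiftResult:
    """Abundance-shift statistics for one cell type."""

    cell_type: str
    q: int
    k: int
    m: int
    n: int
    odds_ratio: float
    haldane_corrected: bool
    ci_low: float
    ci_high: float
    ci_level: float
    p_two_sided: float
    p_lower: float
    p_upper: float
    tail: str  # 'enriched' (OR > 1) / 'depleted' / 'balanced'

    def __post_init__(self) -> None:
        if self.odds_ratio < 0:
            raise ValueError("odds ratio must be >= 0")
        for p in (self.p_two_sided, self.p_lower, self.p_upper):
            if not 0 <= p <= 1 + 1e-12:
                raise ValueError("p-value outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "cell_type": self.cell_type,
            "q": self.q,
            "k": self.k,
            "m": self.m,
            "n": self.n,
            "odds_ratio": self.odds_ratio,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_two_sided": self.p_two_sided,
            "p_lower": self.p_lower,
            "p_upper": self.p_upper,
            "tail": self.tail,
        }


# ---------------------------------------------------------------------------
# Tabulation
# ---------------------------------------------------------------------------


def tabulate_composition(
    cell_type_labels,
    condition_labels,
    condition_pair: tuple[str, str] | None = None,
) -> CompositionTable:
    """Contingency counts of annotated cell types by condition.

    ``condition_pair`` is (treatment, control); by default the
    later-appearing condition in the label vector is taken as treatment
    (generated cohorts emit the reference condition first).
    """
    types = np.asarray(cell_type_labels, dtype=object)
    conds = np.asarray(condition_labels, dtype=object)
    if len(types) != len(conds):
        raise ValueError("label vectors differ in length")
    if len(types) == 0:
        raise ValueError("empty assignment")
    bad = [i for i, (t, c) in enumerate(zip(types, conds)) if not t or not c]
    if bad:
        raise ValueError(f"unlabeled cells at positions {bad[:10]}")
    seen = list(dict.fromkeys(conds))
    if condition_pair is None:
        if len(seen) != 2:
            raise ValueError(f"need exactly two conditions, got {seen}")
        treatment, control = seen[1], seen[0]
    else:
        treatment, control = condition_pair
        if set(seen) != {treatment, control}:
            raise ValueError("condition_pair does not match labels")
    cell_types = sorted(set(types))
    q = {t: int(((types == t) & (conds == treatment)).sum()) for t in cell_types}
    k = {t: int((types == t).sum()) for t in cell_types}
    return CompositionTable(
        cell_types=cell_types,
        q=q,
        k=k,
        m=int((conds == treatment).sum()),
        n=int((conds == control).sum()),
        treatment=str(treatment),
        control=str(control),
    )


# ---------------------------------------------------------------------------
# Hypergeometric machinery
# ---------------------------------------------------------------------------


def hypergeom_tail(
    q: int, K: int, N: int, n_draw: int, tail: str = "upper"
) -> float:
    """Exact hypergeometric tail probability.

    X counts successes when ``n_draw`` items are drawn without replacement
    from a population of ``N`` containing ``K`` successes.
    ``tail='lower'`` returns P(X <= q); ``'upper'`` returns P(X >= q).
    """
    if tail not in ("lower", "upper"):
        raise ValueError("tail must be 'lower' or 'upper'")
    if not (0 <= K <= N and 0 <= n_draw <= N):
        raise ValueError("inconsistent urn: need 0 <= K <= N and 0 <= n_draw <= N")
    if not 0 <= q <= min(K, n_draw):
        raise ValueError(f"q={q} outside [0, min(K, n_draw)]")
    dist = stats.hypergeom(N, K, n_draw)
    if tail == "lower":
        return float(dist.cdf(q))
    return float(dist.sf(q - 1))


def _two_sided_point_prob(q: int, K: int, N: int, n_draw: int) -> float:
    """Two-sided exact p: total probability of outcomes no more likely
    than the observed one (2x2 exact-test convention)."""
    dist = stats.hypergeom(N, K, n_draw)
    lo = max(0, n_draw - (N - K))
    hi = min(K, n_draw)
    support = np.arange(lo, hi + 1)
    logpmf = dist.logpmf(support)
    obs = dist.logpmf(q)
    mass = np.exp(logpmf[logpmf <= obs + 1e-7])
    return float(min(1.0, mass.sum()))


def _conditional_or_ci(
    q: int, K: int, N: int, n_draw: int, level: float
) -> tuple[float, float]:
    """Exact conditional CI for the odds ratio by inverting the Fisher
    noncentral hypergeometric tails (the fisher.test convention)."""
    alpha = 1.0 - level
    lo_support = max(0, n_draw - (N - K))
    hi_support = min(K, n_draw)

    def upper_tail(log_psi: float) -> float:
        # P(X >= q | psi)
        d = stats.nchypergeom_fisher(N, K, n_draw, np.exp(log_psi))
        return float(d.sf(q - 1))

    def lower_tail(log_psi: float) -> float:
        d = stats.nchypergeom_fisher(N, K, n_draw, np.exp(log_psi))
        return float(d.cdf(q))

    def _solve(f) -> float:
        # f must be increasing in log psi; expand a bracket around psi = 1
        lo, hi = -1.0, 1.0
        while f(lo) > 0 and lo > -60:
            lo *= 2
        while f(hi) < 0 and hi < 60:
            hi *= 2
        return float(np.exp(optimize.brentq(f, lo, hi, xtol=1e-8)))

    if q == lo_support:
        ci_low = 0.0
    else:
        ci_low = _solve(lambda lp: upper_tail(lp) - alpha / 2)
    if q == hi_support:
        ci_high = np.inf
    else:
        ci_high = _solve(lambda lp: alpha / 2 - lower_tail(lp))
    return ci_low, ci_high


def abundance_shift_test(
    table: CompositionTable,
    cell_type: str,
    level: float = 0.95,
    compute_ci: bool = True,
) -> ShiftResult:
    """Exact test of one cell type's abundance shift between conditions.

    2x2 table: ``[[q, m-q], [k-q, n-(k-q)]]`` (type C vs rest, treatment vs
    control).  Odds ratio by cross-product, with the Haldane 0.5 correction
    iff a zero cell exists (flagged).  Two-sided p by the point-probability
    method; both one-sided hypergeometric tails are also reported.
    ``compute_ci=False`` skips the (comparatively expensive) exact CI
    inversion and reports NaN bounds.
    """
    if cell_type not in table.k:
        raise ValueError(f"cell type {cell_type!r} not in table")
    if table.m == 0 or table.n == 0:
        raise ValueError("a condition has zero total cells")
    q, k, m, n = table.q[cell_type], table.k[cell_type], table.m, table.n
    a, b, c, d = q, m - q, k - q, n - (k - q)
    has_zero = 0 in (a, b, c, d)
    if has_zero:
        orr = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        orr = a * d / (b * c)
    N = m + n
    p_lower = hypergeom_tail(q, K=k, N=N, n_draw=m, tail="lower")
    p_upper = hypergeom_tail(q, K=k, N=N, n_draw=m, tail="upper")
    p_two = _two_sided_point_prob(q, K=k, N=N, n_draw=m)
    if compute_ci:
        ci_low, ci_high = _conditional_or_ci(q, K=k, N=N, n_draw=m, level=level)
    else:
        ci_low, ci_high = float("nan"), float("nan")
    expected = k * m / N
    tail = "enriched" if q > expected else ("depleted" if q < expected else "balanced")
    return ShiftResult(
        cell_type=cell_type,
        q=q,
        k=k,
        m=m,
        n=n,
        odds_ratio=float(orr),
        haldane_corrected=has_zero,
        ci_low=ci_low,
        ci_high=ci_high,
        ci_level=level,
        p_two_sided=p_two,
        p_lower=p_lower,
        p_upper=p_upper,
        tail=tail,
    )


# ---------------------------------------------------------------------------
# Set overlap
# ---------------------------------------------------------------------------


def overlap_test(
    set_a, set_b, universe
) -> tuple[int, float, float, float]:
    """Hypergeometric test of the overlap between two gene sets.

    Returns ``(overlap, expected, p_two_sided, p_enrichment)`` where the
    two-sided p uses the point-probability rule and ``p_enrichment`` is the
    upper tail P(X >= overlap).
    """
    a, b, u = set(set_a), set(set_b), set(universe)
    if not a <= u or not b <= u:
        raise ValueError("sets must be subsets of the universe")
    q = len(a & b)
    N, K, n_draw = len(u), len(a), len(b)
    expected = K * n_draw / N if N else 0.0
    p_two = _two_sided_point_prob(q, K=K, N=N, n_draw=n_draw)
    p_enrich = hypergeom_tail(q, K=K, N=N, n_draw=n_draw, tail="upper")
    return q, float(expected), p_two, p_enrich
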