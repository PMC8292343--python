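"""Exact 2x2 inference and the rare-variant gene-burden scan.

The carrier-count comparisons use the exact conditional framework paired
with Fisher's test:

* two-sided p — the sum of central hypergeometric probabilities, over all
  tables with the observed margins, whose point probability does not exceed
  the observed table's (with a 1e-7 relative tolerance absorbing
  floating-point ties);
* odds ratio — the conditional maximum-likelihood estimate, i.e. the
  noncentrality psi of Fisher's noncentral hypergeometric distribution
  maximizing the likelihood of the observed cell given all margins (found by
  solving the score equation E_psi[X] = x);
* confidence interval — exact conditional bounds, inverting the one-sided
  tail tests at alpha/2 each.

These are the conventions of R's ``fisher.test``; in particular the
conditional MLE differs from the sample cross-product ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln, logsumexp

__all__ = [
    "Contingency2x2",
    "ExactResult",
    "GeneBurdenRow",
    "fisher_two_sided",
    "or_conditional_mle",
    "exact_2x2",
    "burden_scan",
    "variant_level_test",
    "association_tables",
    "rank_sum_test",
]

_TIE_RTOL = 1e-7


@dataclass(frozen=True)
class Contingency2x2:
    """Counts [[a, b], [c, d]]: rows = groups, columns = positive/negative."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("at least one margin must be positive")

    @property
    def table(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])

    @property
    def degenerate(self) -> bool:
        """True when a margin is empty, pinning the table to a single value."""
        return (
            self.a + self.b == 0
            or self.c + self.d == 0
            or self.a + self.c == 0
            or self.b + self.d == 0
        )


@dataclass
class ExactResult:
    p_two_sided: float
    or_cmle: Optional[float]  # None when margins are degenerate
    ci_low: Optional[float]
    ci_high: Optional[float]
    alpha: float = 0.05
    degenerate: bool = False


def _support(t: Contingency2x2) -> tuple[np.ndarray, np.ndarray]:
    """Attainable values of the a-cell given margins, and their log weights
    at psi=1 (unnormalized central hypergeometric)."""
    r1, r2, c1 = t.a + t.b, t.c + t.d, t.a + t.c
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    k = np.arange(lo, hi + 1)
    logw = (
        gammaln(r1 + 1) - gammaln(k + 1) - gammaln(r1 - k + 1)
        + gammaln(r2 + 1) - gammaln(c1 - k + 1) - gammaln(r2 - c1 + k + 1)
    )
    return k, logw


def fisher_two_sided(t: Contingency2x2) -> float:
    """Two-sided Fisher exact p by the point-probability criterion."""
    if t.degenerate:
        return 1.0
    k, logw = _support(t)
    logp = logw - logsumexp(logw)
    obs = logp[k == t.a][0]
    keep = logp <= obs + math.log1p(_TIE_RTOL)
    return float(min(1.0, math.exp(logsumexp(logp[keep]))))


def _log_tail(logw: np.ndarray, k: np.ndarray, s: float, x: int, upper: bool) -> float:
    """log P(X >= x) (upper) or log P(X <= x) at log-psi = s."""
    w = logw + k * s
    mask = k >= x if upper else k <= x
    return float(logsumexp(w[mask]) - logsumexp(w))

def _mean(logw: np.ndarray, k: np.ndarray, s: float) -> float:
    w = logw + k * s
    p = np.exp(w - logsumexp(w))
    return float(p @ k)


def _solve(f, lo: float = -1.0, hi: float = 1.0) -> float:
    """Root of a monotone-increasing f on an expanding log-psi bracket."""
    while f(lo) > 0 and lo > -750:
        lo *= 2
    while f(hi) < 0 and hi < 750:
        hi *= 2
    from scipy.optimize import brentq

    return float(brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16))


def or_conditional_mle(t: Contingency2x2, alpha: float = 0.05) -> ExactResult:
    """Conditional-MLE odds ratio with exact conditional CI (and the p-value).

    The estimate solves the score equation E_psi[X] = a.  When the observed
    cell sits at the bottom (top) of its attainable range the MLE is 0
    (+infinity) and the corresponding CI bound collapses to it; the other
    bound still inverts the exact one-sided tail at alpha/2.
    """
    p = fisher_two_sided(t)
    if t.degenerate:
        return ExactResult(p, None, None, None, alpha, degenerate=True)
    k, logw = _support(t)
    lo_k, hi_k = int(k[0]), int(k[-1])
    a = t.a

    if a == lo_k == hi_k:  # single attainable table
        return ExactResult(p, None, None, None, alpha, degenerate=True)

    if a == lo_k:
        est = 0.0
    elif a == hi_k:
        est = math.inf
    else:
        est = math.exp(_solve(lambda s: _mean(logw, k, s) - a))

    half = math.log(alpha / 2.0)
    # lower bound: psi with P(X >= a) = alpha/2 (tail increasing in psi)
    ci_low = 0.0 if a == lo_k else math.exp(
        _solve(lambda s: _log_tail(logw, k, s, a, upper=True) - half)
    )
    # upper bound: psi with P(X <= a) = alpha/2 (tail decreasing in psi)
    ci_high = math.inf if a == hi_k else math.exp(
        _solve(lambda s: -(_log_tail(logw, k, s, a, upper=False) - half))
    )
    return ExactResult(p, est, ci_low, ci_high, alpha)


def exact_2x2(t: Contingency2x2, alpha: float = 0.05) -> ExactResult:
    """Convenience wrapper: two-sided p plus conditional OR and exact CI."""
    return or_conditional_mle(t, alpha)


@dataclass
class GeneBurdenRow:
    gene: str
    n_case_nonls: int
    n_case_ls: int
    n_case_total: int
    n_reference: int
    nonls_vs_ref: ExactResult
    ls_vs_ref: ExactResult
    significant: bool = False  # non-LS p below the report threshold
    p_bh_nonls: Optional[float] = None


def burden_scan(
    case_carriers: Mapping[str, Mapping[str, set]],
    reference_carriers: Mapping[str, set],
    group_sizes: Mapping[str, int],
    min_case_carriers: int = 2,
    significance: float = 0.01,
    benjamini_hochberg: bool = False,
) -> list[GeneBurdenRow]:
    """Per-gene carrier-burden scan of cases against the reference cohort.

    ``case_carriers`` maps gene -> {"non_LS": set, "LS": set} of carrier
    patient ids; ``group_sizes`` needs keys non_LS, LS, reference.  Only
    genes carried by at least ``min_case_carriers`` case patients in total
    are reported (the recurrence rule), ordered by ascending non-LS p.
    """
    n_nonls = group_sizes["non_LS"]
    n_ls = group_sizes["LS"]
    n_ref = group_sizes["reference"]
    rows = []
    for gene, groups in case_carriers.items():
        nl = len(groups.get("non_LS", ()))
        ls = len(groups.get("LS", ()))
        if nl > n_nonls or ls > n_ls:
            raise ValueError(f"{gene}: carrier count exceeds group size")
        if nl + ls < min_case_carriers:
            continue
        ref = len(reference_carriers.get(gene, ()))
        row = GeneBurdenRow(
            gene=gene,
            n_case_nonls=nl,
            n_case_ls=ls,
            n_case_total=nl + ls,
            n_reference=ref,
            nonls_vs_ref=exact_2x2(Contingency2x2(nl, n_nonls - nl, ref, n_ref - ref)),
            ls_vs_ref=exact_2x2(Contingency2x2(ls, n_ls - ls, ref, n_ref - ref)),
        )
        row.significant = row.nonls_vs_ref.p_two_sided < significance
        rows.append(row)
    rows.sort(key=lambda r: (r.nonls_vs_ref.p_two_sided, r.gene))
    if benjamini_hochberg and rows:
        p = np.array([r.nonls_vs_ref.p_two_sided for r in rows])
        m = len(p)
        order = np.argsort(p)
        adj = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        adj = np.minimum(adj, 1.0)
        for idx, r in zip(order, adj):
            rows[idx].p_bh_nonls = float(r)
    return rows


def variant_level_test(
    case_carriers_of_variant: int, n_case: int, ref_carriers: int, n_ref: int
) -> float:
    """Two-sided Fisher p on a single variant's carrier table."""
    if case_carriers_of_variant > n_case or ref_carriers > n_ref:
        raise ValueError("carrier count exceeds group size")
    return fisher_two_sided(
        Contingency2x2(
            case_carriers_of_variant,
            n_case - case_carriers_of_variant,
            ref_carriers,
            n_ref - ref_carriers,
        )
    )


def association_tables(
    patients: Iterable,
) -> list[tuple[str, Contingency2x2, Optional[ExactResult]]]:
    """Carrier-status association tables for the derived clinical labels.

    ``patients`` yields objects with boolean ``is_carrier``, ``early_onset``,
    ``synchronous`` and tri-state ``strong_fh`` (None = unknown, excluded
    from the family-history table's denominators).  Rows are carriers vs
    non-carriers; columns label-positive vs label-negative.  Degenerate
    tables are flagged with no estimate.
    """
    pts = list(patients)

    def build(label: str, value) -> tuple[str, Contingency2x2, Optional[ExactResult]]:
        cells = [0, 0, 0, 0]
        for p in pts:
            v = value(p)
            if v is None:
                continue
            i = 0 if p.is_carrier else 2
            cells[i if v else i + 1] += 1
        t = Contingency2x2(*cells)
        if t.degenerate:
            return (label, t, None)
        return (label, t, exact_2x2(t))

    return [
        build("eoMPC", lambda p: p.early_onset),
        build("strong_family_history", lambda p: p.strong_fh),
        build("synchronous", lambda p: p.synchronous),
    ]


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact enumeration for small samples without ties; normal approximation
    with tie correction (and continuity correction) otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (max(x.size, y.size) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(min(1.0, res.pvalue))
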