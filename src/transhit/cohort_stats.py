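"""Cohort summaries and the green-gene enrichment statistic.

The enrichment of diagnostic-grade ("green") panel genes among probable
candidates is tested with Fisher's exact test.  The reported odds ratio is
the conditional maximum-likelihood estimate (CMLE): the noncentrality
parameter psi of Fisher's noncentral hypergeometric distribution for which
the expected top-left cell count equals the observed one.  The CMLE is what
standard exact-test implementations (e.g. R's fisher.test) print, and for
small unbalanced tables it differs noticeably from the sample cross-product
ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln
from scipy.stats import hypergeom


@dataclass(frozen=True)
class TwoByTwo:
    """Counts a=exposed∧outcome, b=exposed∧not, c=other∧outcome, d=other∧not."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


def _log_binom(n: int, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def noncentral_hypergeom_mean(log_psi: float, r1: int, r2: int, c1: int) -> float:
    """E[X] for Fisher's noncentral hypergeometric with odds psi.

    X is the top-left cell of a 2x2 table with row margins r1, r2 and first
    column margin c1.  The mean is strictly increasing in psi, so the CMLE
    root is unique.
    """
    lo, hi = max(0, c1 - r2), min(r1, c1)
    x = np.arange(lo, hi + 1)
    logw = _log_binom(r1, x) + _log_binom(r2, c1 - x) + x * log_psi
    w = np.exp(logw - logw.max())
    return float((x * w).sum() / w.sum())


def _cmle_odds_ratio(t: TwoByTwo, rtol: float = 1e-8) -> float:
    r1, r2, c1, _ = t.margins
    lo, hi = max(0, c1 - r2), min(r1, c1)
    if t.a == lo:
        return 0.0
    if t.a == hi:
        return math.inf

    def f(log_psi: float) -> float:
        return noncentral_hypergeom_mean(log_psi, r1, r2, c1) - t.a

    lo_b, hi_b = -1.0, 1.0
    while f(lo_b) > 0:
        lo_b *= 2
    while f(hi_b) < 0:
        hi_b *= 2
    root = brentq(f, lo_b, hi_b, xtol=1e-12, rtol=4 * np.finfo(float).eps)
    return float(np.exp(root))


def fisher_exact(t: TwoByTwo, alternative: str = "minlike") -> dict[str, float]:
    """Fisher's exact test with conditional-MLE odds ratio for a 2x2 table.

    The two-sided p-value sums hypergeometric probabilities of all tables
    with the same margins whose probability does not exceed the observed
    one (``alternative="minlike"``, the standard exact-test convention);
    ``alternative="doubling"`` doubles the smaller tail instead.  Returns
    ``p_two_sided``, the conditional-MLE odds ratio ``or_cmle``, and the
    sample cross-product ratio ``or_sample`` (inf when b*c == 0).

    With a degenerate margin the test is vacuous: p is 1 and the odds
    ratios are undefined (NaN).
    """
    r1, r2, c1, c2 = t.margins
    if min(r1, r2, c1, c2) == 0:
        return {"p_two_sided": 1.0, "or_cmle": math.nan, "or_sample": math.nan}

    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    x = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(x, n, r1, c1)
    p_obs = hypergeom.pmf(t.a, n, r1, c1)
    if alternative == "minlike":
        p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    elif alternative == "doubling":
        lower = float(pmf[x <= t.a].sum())
        upper = float(pmf[x >= t.a].sum())
        p = min(1.0, 2.0 * min(lower, upper))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = min(1.0, p)

    or_sample = math.inf if t.b * t.c == 0 else (t.a * t.d) / (t.b * t.c)
    return {
        "p_two_sided": p,
        "or_cmle": _cmle_odds_ratio(t),
        "or_sample": or_sample,
    }


def percent(numerator: int, denominator: int) -> float:
    """Percentage rounded to one decimal, half away from zero."""
    if denominator == 0:
        raise ZeroDivisionError("percent() with zero denominator")
    value = Decimal(100 * numerator) / Decimal(denominator)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CohortSummary:
    """Exact aggregation of the search's cohort-level counts."""

    n_trios: int
    n_probands_with_hit: int
    n_pairs: int
    n_pairs_with_secondhit: int
    n_combinations: int
    region_class_counts: Mapping[str, int]
    per_proband_hit_histogram: Mapping[int, int]
    per_pair_secondhit_histogram: Mapping[int, int]

    @property
    def pct_pairs_with_secondhit(self) -> float:
        return percent(self.n_pairs_with_secondhit, self.n_pairs)


def summarize(pairs, candidates, prioritized=None, n_trios: int | None = None) -> CohortSummary:
    """Aggregate pair and candidate tables into a cohort summary.

    ``pairs`` are the proband-variant pairs searched; ``candidates`` the
    retained second-hit combinations (one per proband-variant-second-hit).
    Every candidate must reference a supplied pair.
    """
    pair_ids = {(p.proband_id, p.gene_id, p.coding_variant) for p in pairs}
    per_pair: dict[tuple, int] = {}
    region_counts: dict[str, int] = {}
    for c in candidates:
        pid = (c.pair.proband_id, c.pair.gene_id, c.pair.coding_variant)
        if pid not in pair_ids:
            raise ValueError(f"candidate references unknown pair {pid}")
        per_pair[pid] = per_pair.get(pid, 0) + 1
        rc = c.region_class or "unassigned"
        region_counts[rc] = region_counts.get(rc, 0) + 1

    hits_per_proband: dict[str, int] = {}
    for p in pairs:
        hits_per_proband[p.proband_id] = hits_per_proband.get(p.proband_id, 0) + 1
    proband_hist: dict[int, int] = {}
    for n in hits_per_proband.values():
        proband_hist[n] = proband_hist.get(n, 0) + 1
    secondhit_hist: dict[int, int] = {}
    for n in per_pair.values():
        secondhit_hist[n] = secondhit_hist.get(n, 0) + 1

    return CohortSummary(
        n_trios=n_trios if n_trios is not None else len(hits_per_proband),
        n_probands_with_hit=len(hits_per_proband),
        n_pairs=len(pairs),
        n_pairs_with_secondhit=len(per_pair),
        n_combinations=len(list(candidates)),
        region_class_counts=dict(sorted(region_counts.items())),
        per_proband_hit_histogram=dict(sorted(proband_hist.items())),
        per_pair_secondhit_histogram=dict(sorted(secondhit_hist.items())),
    )


def green_gene_table(
    probable_genes: Sequence[str],
    other_genes: Sequence[str],
    green_genes: Sequence[str],
) -> TwoByTwo:
    """2x2 table of probable vs other candidates against green-panel status."""
    green = set(green_genes)
    a = sum(g in green for g in probable_genes)
    b = len(probable_genes) - a
    c = sum(g in green for g in other_genes)
    d = len(other_genes) - c
    return TwoByTwo(a, b, c, d)
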