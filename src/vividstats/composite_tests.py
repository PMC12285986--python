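"""Composite and bespoke tests: Fisher combination, ordering binomial,
sign-consistency, 2x2 chi-squared (with or without Yates correction), and
explicit percent-difference conventions.

Binomial tail sums run in log space: with 57 regions and a 1/120 per-region
probability, the upper tail is far below the underflow threshold of a naive
product-and-sum.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .datatypes import Chi2Result, OrderingTestResult

__all__ = [
    "fishers_method",
    "ordering_match_count",
    "ORDERING_ROLES",
    "binomial_at_least",
    "sign_consistency",
    "chi2_2x2",
    "percent_difference",
]

#: Predicted descending order of the five volume categories.
ORDERING_ROLES = (
    "hphant",
    "high_group_mean",
    "sample_mean",
    "low_group_mean",
    "aphant",
)


def fishers_method(pvals: Sequence[float]):
    """Combine independent p-values: chi2 = -2 sum(ln p) on 2k df.

    Returns ``(chi2, df, p_combined)``. A zero input p makes the statistic
    infinite and is rejected.
    """
    pvals = [float(p) for p in pvals]
    if not pvals:
        raise ValueError("need at least one p-value")
    for p in pvals:
        if not 0 < p <= 1:
            raise ValueError(f"p-values must lie in (0, 1], got {p}")
    chi2 = -2.0 * sum(math.log(p) for p in pvals)
    df = 2 * len(pvals)
    return chi2, df, float(stats.chi2.sf(chi2, df))


def binomial_at_least(n: int, k: int, p: float) -> float:
    """Upper-tail binomial probability P(X >= k), computed in log space."""
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    if not 0 <= p <= 1:
        raise ValueError("p must be a probability")
    if k == 0:
        return 1.0
    if p == 0:
        return 0.0
    if p == 1:
        return 1.0
    ks = np.arange(k, n + 1)
    return float(np.exp(logsumexp(stats.binom.logpmf(ks, n, p))))


def sign_consistency(n_regions: int, k_directional: int) -> float:
    """Sign-test tail: P(at least k of n regions agree in direction | p=1/2)."""
    return binomial_at_least(n_regions, k_directional, 0.5)


def ordering_match_count(
    category_means: Mapping[str, Mapping[str, float]],
    roles: Sequence[str] = ORDERING_ROLES,
) -> OrderingTestResult:
    """Count regions whose five category values follow the predicted order.

    ``category_means`` maps region -> {role -> value}. A region matches iff
    its values are strictly decreasing in the given role order; any tie makes
    the region a non-match (recorded in ``tied_regions``). The per-region
    probability of a match by chance is 1/c! for c categories.
    """
    c = len(roles)
    per_trial_p = 1.0 / math.factorial(c)
    matched, tied = [], []
    for region, vals in category_means.items():
        missing = [r for r in roles if r not in vals]
        if missing:
            raise ValueError(f"region {region!r} missing categories {missing}")
        seq = [float(vals[r]) for r in roles]
        if len(set(seq)) < c:
            tied.append(region)
            continue
        if all(a > b for a, b in zip(seq, seq[1:])):
            matched.append(region)
    n = len(category_means)
    k = len(matched)
    return OrderingTestResult(
        n_regions=n,
        k_matches=k,
        per_trial_p=per_trial_p,
        p_at_least_k=binomial_at_least(n, k, per_trial_p),
        matched_regions=tuple(matched),
        tied_regions=tuple(tied),
    )


def chi2_2x2(counts, yates: bool = False) -> Chi2Result:
    """Pearson chi-squared on a 2x2 table, df = 1.

    The Yates variant subtracts 0.5 from each |O - E| before squaring,
    floored at zero. Zero row or column margins leave the expected cells
    undefined and are rejected.
    """
    obs = np.asarray(counts, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("counts must form a 2x2 table")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("zero margin: expected cells undefined")
    expected = np.outer(rows, cols) / obs.sum()
    dev = np.abs(obs - expected)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)
    chi2 = float((dev**2 / expected).sum())
    return Chi2Result(
        chi2=chi2,
        df=1,
        p=float(stats.chi2.sf(chi2, 1)),
        yates_applied=yates,
        expected=tuple(expected.ravel()),
    )


def percent_difference(
    reference: float, other: float, denominator: str = "reference"
) -> float:
    """Signed percentage difference, 100 * (other - reference) / denominator.

    The denominator convention is explicit and mandatory because percentage
    differences between two group means are ambiguous; ``reference`` (the
    default), ``other`` and ``midpoint`` are supported.
    """
    denoms = {
        "reference": reference,
        "other": other,
        "midpoint": (reference + other) / 2.0,
    }
    if denominator not in denoms:
        raise ValueError(f"unknown denominator convention {denominator!r}")
    d = denoms[denominator]
    if d == 0:
        raise ValueError("zero denominator")
    return 100.0 * (other - reference) / d
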