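"""Single case versus control sample: Bayesian effect size and frequentist oracle.

Tests whether one individual's score (the aphant's or hphant's, here) is
abnormal relative to a modest control sample, treating the controls as a
sample rather than a fixed population. The Bayesian routine follows the
standard noninformative-prior construction for this problem: per Monte Carlo
iteration, draw the control-population variance from its scaled inverse
chi-square posterior, the mean from the conditional normal posterior, form
the standardised case-control difference z = (x_case - mu)/sqrt(psi), and
average Phi(z) to estimate the proportion of controls falling below the
case. The point estimate is the posterior median of z with a 95% credible
interval from the 2.5/97.5 percentiles.

The closed-form frequentist analogue — the modified t comparing a single
case to n controls, t = (x - xbar) / (s * sqrt((n+1)/n)) on n-1 df — is the
oracle: the Bayesian tail probability converges to its one-tailed p exactly
as the iteration count grows.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import stats

from .datatypes import SingleCaseResult, SummaryStats, TTestResult

__all__ = ["single_case_test", "crawford_howell_t"]


def single_case_test(
    x_case: float,
    controls: SummaryStats,
    n_iter: int = 100_000,
    seed: Optional[int] = None,
) -> SingleCaseResult:
    """Bayesian point and interval estimate of the case-controls effect size."""
    if controls.sd <= 0:
        raise ValueError("control SD must be positive: posterior undefined")
    if n_iter < 1:
        raise ValueError("n_iter must be positive")
    n, xbar, s = controls.n, controls.mean, controls.sd
    rng = np.random.default_rng(seed)
    psi = (n - 1) * s**2 / rng.chisquare(n - 1, n_iter)
    mu = rng.normal(xbar, np.sqrt(psi / n))
    z = (x_case - mu) / np.sqrt(psi)
    p_below = float(stats.norm.cdf(z).mean())
    lo, mid, hi = np.percentile(z, [2.5, 50.0, 97.5])
    return SingleCaseResult(
        z_cc_point=float(mid),
        z_cc_mean=float(z.mean()),
        z_cc_ci95=(float(lo), float(hi)),
        p_below=p_below,
        p_two_sided=float(2 * min(p_below, 1 - p_below)),
        n_iter=n_iter,
        seed=seed,
    )


def crawford_howell_t(x_case: float, controls: SummaryStats) -> TTestResult:
    """Modified t-test of one case against a control sample (two-tailed p).

    The effect-size slot carries the case-controls standardised difference
    (x_case - xbar) / s.
    """
    if controls.sd <= 0:
        raise ValueError("control SD must be positive")
    n, xbar, s = controls.n, controls.mean, controls.sd
    t = (x_case - xbar) / (s * np.sqrt((n + 1) / n))
    df = n - 1
    p = float(2 * stats.t.sf(abs(t), df))
    tcrit = stats.t.ppf(0.975, df)
    se = s * np.sqrt((n + 1) / n)
    diff = x_case - xbar
    ci = (diff - tcrit * se, diff + tcrit * se)
    return TTestResult(
        t=float(t),
        df=float(df),
        p=p,
        ci95=ci,
        d=float((x_case - xbar) / s),
        tails=2,
        method="case-controls",
    )
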