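"""t-tests, correlation and split-plot (mixed) ANOVA with Type III sums of squares.

The ANOVA implements the classical univariate split-plot decomposition used
by SPSS GLM repeated measures: between-subject effects are tested against
the subject-within-groups error stratum; each within-subject effect and its
interactions with between-subject factors are tested against the matching
subject x within-effect residual stratum. Type III sums of squares come from
sum-to-zero effect coding and full-vs-reduced model comparisons, which keeps
the tests meaningful under unbalanced group sizes (6:4, 5:5 splits). Degrees
of freedom are reported uncorrected; a Greenhouse-Geisser correction is
available behind a flag since sphericity is never guaranteed with three
sides or twelve regions as repeated measures.

Implementation: for each within-effect stratum an orthonormal contrast
matrix (Kronecker products of per-factor Helmert contrasts and unit mean
vectors) transforms every subject's within-cell response vector; ordinary
least squares of the transformed scores on the effect-coded between design
then yields the stratum's sums of squares. With orthonormal contrasts these
equal the classical full-data decomposition exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import helmert

from .datatypes import SummaryStats, TTestResult

__all__ = [
    "t_from_summary",
    "summary_stats",
    "pearson_correlation",
    "mixed_anova",
]


def summary_stats(x: Sequence[float]) -> SummaryStats:
    x = np.asarray(x, dtype=float)
    return SummaryStats(float(x.mean()), float(x.std(ddof=1)), int(x.size))


def t_from_summary(
    a: SummaryStats,
    b: SummaryStats,
    variance: str = "pooled",
    tails: int = 2,
) -> TTestResult:
    """Independent-samples t-test from printed means, SDs and group sizes.

    ``pooled`` uses the (n-1)-weighted pooled variance on n1+n2-2 df;
    ``welch`` uses the Satterthwaite approximation. Cohen's d always uses the
    pooled SD. The confidence interval is the two-sided 95% interval on the
    mean difference a - b.
    """
    if variance not in ("pooled", "welch"):
        raise ValueError(f"unknown variance option {variance!r}")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    diff = a.mean - b.mean
    if a.sd == 0 and b.sd == 0:
        if diff != 0:
            raise ValueError(
                "both groups have zero SD with unequal means: t is infinite"
            )
        df = a.n + b.n - 2
        return TTestResult(0.0, df, 1.0, (0.0, 0.0), 0.0, tails, variance)

    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / (a.n + b.n - 2)
    d = diff / np.sqrt(sp2) if sp2 > 0 else 0.0
    if variance == "pooled":
        se = np.sqrt(sp2 * (1 / a.n + 1 / b.n))
        df = a.n + b.n - 2.0
    else:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        se = np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    t = diff / se
    p = float(stats.t.sf(abs(t), df) * tails)
    tcrit = stats.t.ppf(0.975, df)
    ci = (diff - tcrit * se, diff + tcrit * se)
    return TTestResult(float(t), float(df), p, ci, float(d), tails, variance)


def pearson_correlation(x: Sequence[float], y: Sequence[float]):
    """Pearson's r with a two-tailed p from the t transform on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# split-plot mixed ANOVA
# ---------------------------------------------------------------------------


@dataclass
class _Term:
    name: str
    cols: slice  # columns of the between-design matrix


def _effect_code(values: np.ndarray, levels: Sequence) -> np.ndarray:
    """Sum-to-zero (deviation) coding: k levels -> k-1 columns."""
    n = len(values)
    k = len(levels)
    X = np.zeros((n, k - 1))
    for j, lev in enumerate(levels[:-1]):
        X[values == lev, j] = 1.0
    X[values == levels[-1], :] = -1.0
    return X


def _between_design(subj_df: pd.DataFrame, between: Sequence[str], covariate):
    """Effect-coded between-subjects design matrix with named terms."""
    n = len(subj_df)
    blocks = [np.ones((n, 1))]
    terms = [_Term("Intercept", slice(0, 1))]
    start = 1
    factor_codes = {}
    for f in between:
        levels = sorted(subj_df[f].unique(), key=str)
        if len(levels) < 2:
            raise ValueError(f"between factor {f!r} has fewer than 2 levels")
        factor_codes[f] = _effect_code(subj_df[f].to_numpy(), levels)
    if covariate is not None:
        cov = subj_df[covariate].to_numpy(dtype=float)
        blocks.append((cov - cov.mean()).reshape(-1, 1))
        terms.append(_Term(covariate, slice(start, start + 1)))
        start += 1
    for r in range(1, len(between) + 1):
        for combo in itertools.combinations(between, r):
            X = factor_codes[combo[0]]
            for f in combo[1:]:
                X = np.einsum("ij,ik->ijk", X, factor_codes[f]).reshape(n, -1)
            blocks.append(X)
            terms.append(_Term(":".join(combo), slice(start, start + X.shape[1])))
            start += X.shape[1]
    return np.hstack(blocks), terms


def _sse(X: np.ndarray, Z: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, Z, rcond=None)
    resid = Z - X @ beta
    return float((resid**2).sum())


def mixed_anova(
    data: pd.DataFrame,
    dv: str = "response",
    subject: str = "subject",
    between: Sequence[str] = (),
    within: Sequence[str] = (),
    covariate: Optional[str] = None,
    sphericity_correction: bool = False,
) -> pd.DataFrame:
    """Split-plot ANOVA table for a long-format response table.

    Every subject must have every within-factor cell exactly once and a
    constant value on each between factor. The covariate (a per-subject
    scalar such as a head-size scaling factor) is centred and enters the
    between-subject stratum only.

    Returns a DataFrame with one row per effect plus one error row per
    stratum: columns ``effect, stratum, SS, df1, df2, MS, F, p,
    partial_eta_sq`` (and ``p_gg`` when the Greenhouse-Geisser flag is set).
    """
    between = list(between)
    within = list(within)
    if not between and not within:
        raise ValueError("need at least one factor")
    missing = [c for c in [dv, subject, *between, *within] if c not in data.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")

    # within-cell layout
    wlevels = {f: sorted(data[f].unique(), key=str) for f in within}
    cells = list(itertools.product(*[wlevels[f] for f in within])) if within else [()]
    if within:
        counts = data.groupby([subject, *within], sort=True).size()
        bad = counts[counts != 1]
        if len(bad):
            raise ValueError(
                "within-subject layout incomplete or duplicated for: "
                f"{sorted(set(i[0] for i in bad.index))}"
            )
        per_subject = counts.groupby(level=0).size()
        incomplete = per_subject[per_subject != len(cells)]
        if len(incomplete):
            raise ValueError(
                f"within-subject cells missing (subjects {list(incomplete.index)})"
            )

    # between factors constant within subject
    subj_cols = [*between] + ([covariate] if covariate else [])
    if subj_cols:
        nun = data.groupby(subject)[subj_cols].nunique()
        varying = nun[(nun != 1).any(axis=1)]
        if len(varying):
            raise ValueError(
                f"between-subject values vary within subjects {list(varying.index)}"
            )

    subjects = sorted(data[subject].unique(), key=str)
    n = len(subjects)
    # wide response matrix, subjects x cells
    if within:
        wide = data.set_index([subject, *within])[dv].unstack(within)
        col_order = cells if len(within) > 1 else [c[0] for c in cells]
        wide = wide.reindex(index=subjects, columns=col_order)
        Y = wide.to_numpy(dtype=float)
    else:
        Y = (
            data.groupby(subject)[dv]
            .mean()
            .reindex(subjects)
            .to_numpy(dtype=float)
            .reshape(-1, 1)
        )
    if np.isnan(Y).any():
        raise ValueError("missing responses in within-subject layout")
    subj_df = data.groupby(subject).first().reindex(subjects)

    # per-factor orthonormal contrasts and mean vectors
    contr = {f: helmert(len(wlevels[f])).T for f in within}  # k x (k-1), orthonormal
    means = {f: np.full((len(wlevels[f]), 1), 1 / np.sqrt(len(wlevels[f]))) for f in within}

    rows = []
    for r in range(0, len(within) + 1):
        for wcombo in itertools.combinations(within, r):
            M = np.ones((1, 1))
            for f in within:  # preserve cell (kron) ordering
                M = np.kron(M, contr[f] if f in wcombo else means[f])
            Z = Y @ M  # n x q
            q = M.shape[1]
            is_between_stratum = r == 0
            X, terms = _between_design(
                subj_df, between, covariate if is_between_stratum else None
            )
            rank = np.linalg.matrix_rank(X)
            if rank < X.shape[1]:
                raise ValueError(
                    "rank-deficient between-subjects design after effect coding "
                    f"(rank {rank} < {X.shape[1]} columns)"
                )
            sse_full = _sse(X, Z)
            df_err = (n - X.shape[1]) * q
            if df_err <= 0:
                raise ValueError("no residual degrees of freedom in stratum")
            stratum = "between" if is_between_stratum else "within:" + ":".join(wcombo)
            eps = None
            if sphericity_correction and q > 1:
                beta, *_ = np.linalg.lstsq(X, Z, rcond=None)
                R = Z - X @ beta
                S = R.T @ R / (n - X.shape[1])
                eps = float(np.trace(S) ** 2 / (q * np.trace(S @ S)))
                eps = min(1.0, max(eps, 1.0 / q))
            for term in terms:
                if term.name == "Intercept" and is_between_stratum:
                    continue  # grand mean, not a reported effect
                Xr = np.delete(X, np.arange(term.cols.start, term.cols.stop), axis=1)
                ss = _sse(Xr, Z) - sse_full
                df1 = (term.cols.stop - term.cols.start) * q
                if term.name == "Intercept":
                    name = ":".join(wcombo)
                else:
                    name = (
                        term.name
                        if is_between_stratum
                        else term.name + ":" + ":".join(wcombo)
                    )
                F = (ss / df1) / (sse_full / df_err)
                row = {
                    "effect": name,
                    "stratum": stratum,
                    "SS": ss,
                    "df1": df1,
                    "df2": df_err,
                    "MS": ss / df1,
                    "F": F,
                    "p": float(stats.f.sf(F, df1, df_err)),
                    "partial_eta_sq": ss / (ss + sse_full) if ss + sse_full > 0 else 0.0,
                }
                if sphericity_correction:
                    row["p_gg"] = (
                        float(stats.f.sf(F, df1 * eps, df_err * eps))
                        if eps is not None
                        else row["p"]
                    )
                rows.append(row)
            err_row = {
                "effect": f"Error({stratum})",
                "stratum": stratum,
                "SS": sse_full,
                "df1": df_err,
                "df2": np.nan,
                "MS": sse_full / df_err,
                "F": np.nan,
                "p": np.nan,
                "partial_eta_sq": np.nan,
            }
            if sphericity_correction:
                err_row["p_gg"] = np.nan
            rows.append(err_row)
    return pd.DataFrame(rows)
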