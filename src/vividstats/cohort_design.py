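"""Extreme-groups selection on a score, with boundary-tie expansion.

The study protocol compares the k highest against the k lowest scorers on a
variable (VVIQ total, or age). Subjects tied exactly at a boundary value are
all included under the default ``expand`` policy, so a group may exceed k —
as when three subjects tied at the older age boundary made the older group
11 instead of 10. ``strict`` mode keeps groups at exactly k, breaking
boundary ties by a seeded draw that is reported in the result.
"""

from __future__ import annotations

from typing import Optional, Union

import numpy as np
import pandas as pd

from .datatypes import GroupAssignment

__all__ = ["select_extreme_groups"]

_LABELS = {"vviq_total": ("low", "high"), "age_years": ("younger", "older")}


def select_extreme_groups(
    subjects: pd.DataFrame,
    k: int,
    score_field: str = "vviq_total",
    tie_policy: str = "expand",
    seed: Optional[int] = None,
) -> GroupAssignment:
    """Assign subjects to bottom-k / top-k groups on ``score_field``.

    Returns a :class:`GroupAssignment` mapping every subject to the low
    label, the high label, or ``"none"``, together with the score gap
    ``min(high) - max(low)``. Assignment depends only on score values, never
    on input order.
    """
    if tie_policy not in ("expand", "strict"):
        raise ValueError(f"unknown tie_policy {tie_policy!r}")
    if score_field not in subjects.columns:
        raise ValueError(f"score field {score_field!r} missing from subject table")
    scores = subjects[score_field]
    if scores.isna().any():
        raise ValueError("scores must be present for all subjects")
    n = len(subjects)
    if k <= 0:
        raise ValueError("k must be positive")
    if 2 * k > n:
        raise ValueError(f"2k = {2 * k} exceeds the number of subjects ({n})")

    low_label, high_label = _LABELS.get(score_field, ("low", "high"))
    order = np.sort(scores.to_numpy())
    low_boundary = order[k - 1]
    high_boundary = order[n - k]

    ids = subjects["subject_id"].to_numpy()
    vals = scores.to_numpy()
    if tie_policy == "expand":
        low_ids = set(ids[vals <= low_boundary])
        high_ids = set(ids[vals >= high_boundary])
    else:
        rng = np.random.default_rng(seed)
        # seeded tie-break keyed to subject_id so input row order never matters
        jitter = np.empty(n)
        jitter[np.argsort(ids)] = rng.permutation(n)

        def pick(ascending: bool) -> set:
            key = vals if ascending else -vals
            idx = np.lexsort((jitter, key))
            return set(ids[idx[:k]])

        low_ids = pick(True)
        high_ids = pick(False)
    overlap = low_ids & high_ids
    if overlap:
        raise ValueError(
            f"groups overlap after tie handling (subjects {sorted(overlap)}); "
            "scores too coarse for 2k groups"
        )
    labels = {
        sid: (low_label if sid in low_ids else high_label if sid in high_ids else "none")
        for sid in ids
    }
    low_scores = vals[np.isin(ids, list(low_ids))]
    high_scores = vals[np.isin(ids, list(high_ids))]
    gap = float(high_scores.min() - low_scores.max())
    if gap < 0:
        raise ValueError("groups overlap in score range; gap would be negative")
    return GroupAssignment(
        labels=labels,
        low_label=low_label,
        high_label=high_label,
        gap=gap,
        n_low=len(low_ids),
        n_high=len(high_ids),
        expanded=(len(low_ids) > k or len(high_ids) > k),
    )
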