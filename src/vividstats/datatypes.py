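"""Core record types shared across the package.

The pipeline passes tabular data around as :class:`pandas.DataFrame` objects;
the dataclasses here define the validated per-record views plus the small
result containers returned by the statistical routines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "ScreenGeometry",
    "SubjectRecord",
    "MixtureParams",
    "TaskConfig",
    "TrialRecord",
    "VolumeRecord",
    "TrialClassification",
    "SummaryStats",
    "TTestResult",
    "SingleCaseResult",
    "GroupAssignment",
    "OrderingTestResult",
    "Chi2Result",
    "VVIQ_MIN",
    "VVIQ_MAX",
]

#: VVIQ questionnaire bounds: 16 items rated 1-5.
VVIQ_MIN = 16
VVIQ_MAX = 80


@dataclass(frozen=True)
class ScreenGeometry:
    """Touch-screen pixel matrix on which the object-location task runs."""

    width_px: int = 1536
    height_px: int = 2048

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("screen dimensions must be positive")


@dataclass(frozen=True)
class SubjectRecord:
    """Demographics, VVIQ total and head-size scaling factor for one subject."""

    subject_id: str
    age_years: float
    sex: str  # "female" | "male"
    vviq_total: int
    scaling_factor: float = 1.0

    def __post_init__(self) -> None:
        if not VVIQ_MIN <= self.vviq_total <= VVIQ_MAX:
            raise ValueError(
                f"vviq_total {self.vviq_total} outside [{VVIQ_MIN}, {VVIQ_MAX}]"
            )
        if self.age_years < 0:
            raise ValueError("age_years must be non-negative")
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if self.scaling_factor <= 0:
            raise ValueError("scaling_factor must be positive")


@dataclass(frozen=True)
class MixtureParams:
    """Generative mixture weights for placement responses in one condition.

    A response is drawn from the target-centred Gaussian with probability
    ``p_target``, from a Gaussian centred on a uniformly chosen non-target
    ("misbinding") with probability ``p_misbind``, and uniformly over the
    screen ("guessing") with probability ``p_guess``.
    """

    p_target: float
    p_misbind: float
    p_guess: float
    sigma_px: float = 50.0
    ident_accuracy: float = 0.9
    rt_mean_s: float = 1.5
    rt_sd_s: float = 0.5

    def __post_init__(self) -> None:
        total = self.p_target + self.p_misbind + self.p_guess
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"mixture weights sum to {total}, expected 1")
        if min(self.p_target, self.p_misbind, self.p_guess) < 0:
            raise ValueError("mixture weights must be non-negative")
        if self.sigma_px <= 0:
            raise ValueError("sigma_px must be positive")
        if not 0 <= self.ident_accuracy <= 1:
            raise ValueError("ident_accuracy must be a probability")
        if self.rt_mean_s <= 0 or self.rt_sd_s <= 0:
            raise ValueError("response-time parameters must be positive")


@dataclass(frozen=True)
class TaskConfig:
    """Layout of the object-location task.

    Defaults reproduce the study task: four conditions (1 or 3 items crossed
    with 1 or 4 s delay), 30 trials per condition spread over 3 blocks, on a
    1536 x 2048 pixel screen.
    """

    conditions: tuple = ((1, 1), (1, 4), (3, 1), (3, 4))
    trials_per_condition: int = 30
    blocks: int = 3
    screen: ScreenGeometry = field(default_factory=ScreenGeometry)
    min_item_separation_px: float = 200.0

    def __post_init__(self) -> None:
        if self.trials_per_condition % self.blocks != 0:
            raise ValueError("trials_per_condition must be divisible by blocks")
        for n_items, delay_s in self.conditions:
            if n_items not in (1, 3):
                raise ValueError(f"n_items must be 1 or 3, got {n_items}")
            if delay_s <= 0:
                raise ValueError("delay_s must be positive")
        if self.min_item_separation_px < 0:
            raise ValueError("min_item_separation_px must be non-negative")


@dataclass(frozen=True)
class TrialRecord:
    """One object-location trial: geometry, identification flag and response."""

    subject_id: str
    block: int
    n_items: int
    delay_s: float
    target_xy: tuple
    nontargets_xy: tuple  # () for 1-item trials, 2 points for 3-item trials
    identified_correctly: bool
    response_xy: tuple
    response_time_s: float

    def __post_init__(self) -> None:
        if self.n_items == 1 and len(self.nontargets_xy) != 0:
            raise ValueError("1-item trials carry no non-targets")
        if self.n_items == 3 and len(self.nontargets_xy) != 2:
            raise ValueError("3-item trials carry exactly two non-targets")
        if self.response_time_s <= 0:
            raise ValueError("response_time_s must be positive")


@dataclass(frozen=True)
class VolumeRecord:
    """One regional volume measurement (mm^3) for one subject and side."""

    subject_id: str
    region: str
    side: str  # "left" | "right" | "bilateral"
    set_label: str  # "A" | "B" | "C" | "D"
    volume_mm3: float

    def __post_init__(self) -> None:
        if self.side not in ("left", "right", "bilateral"):
            raise ValueError(f"unknown side {self.side!r}")
        if self.set_label not in ("A", "B", "C", "D"):
            raise ValueError(f"unknown set label {self.set_label!r}")
        if self.volume_mm3 <= 0:
            raise ValueError("volume_mm3 must be positive")


@dataclass(frozen=True)
class TrialClassification:
    """Per-trial target / misbinding / guessing probabilities."""

    p_target: float
    p_misbind: float
    p_guess: float
    n_resamples_used: object  # int or "exact"

    def __post_init__(self) -> None:
        total = self.p_target + self.p_misbind + self.p_guess
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"class probabilities sum to {total}, expected 1")


@dataclass(frozen=True)
class SummaryStats:
    """Mean, SD and n of one sample, as printed in a results table."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n < 2:
            raise ValueError("n must be at least 2")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    ci95: tuple
    d: float
    tails: int = 2
    method: str = "pooled"


@dataclass(frozen=True)
class SingleCaseResult:
    """Case-versus-controls effect size with credible interval.

    ``z_cc_point`` is the median posterior standardised difference between the
    case and the control population; ``p_below`` estimates the proportion of
    the control population falling below the case's score.
    """

    z_cc_point: float
    z_cc_mean: float
    z_cc_ci95: tuple
    p_below: float
    p_two_sided: float
    n_iter: int
    seed: object


@dataclass(frozen=True)
class GroupAssignment:
    """Extreme-groups split on a score, with boundary-tie bookkeeping."""

    labels: Mapping[str, str]  # subject_id -> low label / high label / "none"
    low_label: str
    high_label: str
    gap: float
    n_low: int
    n_high: int
    expanded: bool


@dataclass(frozen=True)
class OrderingTestResult:
    """Count of regions matching a predicted strict ordering of 5 categories."""

    n_regions: int
    k_matches: int
    per_trial_p: float
    p_at_least_k: float
    matched_regions: Sequence[str]
    tied_regions: Sequence[str] = ()


@dataclass(frozen=True)
class Chi2Result:
    chi2: float
    df: int
    p: float
    yates_applied: bool
    expected: tuple  # 2x2 expected cell counts, row-major
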