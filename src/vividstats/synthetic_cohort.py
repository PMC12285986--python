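"""Seeded synthetic cohort: subjects, object-location trials, regional volumes.

The generator emulates the statistical structure the analysis pipeline
assumes: a middle-aged to older cohort with a wide vividness (VVIQ) spread
containing planted extreme scorers; placement responses drawn from a
target/misbinding/guessing mixture under the four task conditions (1 or 3
items crossed with 1 or 4 s delay); and a regional-volume table whose
vividness-group effect is confined to the imagery-active region sets (A and
B), with the amygdala (C) and motor areas (D) as controls.

All randomness flows through a single :class:`numpy.random.Generator` per
call, so identical seeds reproduce identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .datatypes import (
    VVIQ_MAX,
    VVIQ_MIN,
    MixtureParams,
    ScreenGeometry,
    SubjectRecord,
    TaskConfig,
)

__all__ = [
    "GroupSpec",
    "RegionSpec",
    "VolumeEffectSpec",
    "generate_subjects",
    "generate_trials",
    "generate_volumes",
    "default_group_spec",
    "default_mixture_params",
    "mixture_for_subject",
    "default_region_catalogue",
    "subjects_to_frame",
    "TRIAL_COLUMNS",
]

#: Canonical column order of the trials table.
TRIAL_COLUMNS = [
    "subject_id",
    "block",
    "n_items",
    "delay_s",
    "target_x",
    "target_y",
    "nt1_x",
    "nt1_y",
    "nt2_x",
    "nt2_y",
    "identified_correctly",
    "response_x",
    "response_y",
    "response_time_s",
]


@dataclass(frozen=True)
class GroupSpec:
    """Sampling distribution for one recruitment group of subjects."""

    size: int
    vviq_mean: float
    vviq_sd: float
    female_ratio: float = 0.5
    age_mean: float = 68.0
    age_sd: float = 7.2
    age_min: float = 54.0
    age_max: float = 80.0


def default_group_spec() -> dict:
    """Three-group structure mirroring the study sample.

    Ten high scorers (mean 75.5, SD 2.72), ten low scorers (mean 41.9,
    SD 11.99) and a mid-range remainder; 53 subjects overall with a roughly
    55% female split and ages 54-80 around a mean of 68.
    """
    return {
        "high": GroupSpec(10, 75.5, 2.72, female_ratio=0.6),
        "low": GroupSpec(10, 41.9, 11.99, female_ratio=0.5),
        "mid": GroupSpec(33, 62.2, 9.0, female_ratio=0.55),
    }


def generate_subjects(
    n: int,
    group_spec: Optional[Mapping[str, GroupSpec]] = None,
    plant_extremes: bool = True,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Draw ``n`` subjects from the group structure.

    VVIQ totals are rounded truncated Gaussians clipped to [16, 80]; with
    ``plant_extremes`` exactly one subject carries the minimum score 16 (the
    aphant) and exactly one the maximum 80 (the hphant). Head-size scaling
    factors are drawn around 1. Returns a DataFrame with columns
    ``subject_id, group, age_years, sex, vviq_total, scaling_factor``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if group_spec is None:
        group_spec = default_group_spec()
    if not group_spec:
        raise ValueError("group_spec must not be empty")
    sizes = sum(g.size for g in group_spec.values())
    if sizes > n:
        raise ValueError(f"group sizes sum to {sizes} > n = {n}")
    if plant_extremes and n < 2:
        raise ValueError("plant_extremes needs at least two subjects")

    rng = np.random.default_rng(seed)
    rows = []
    specs = dict(group_spec)
    if sizes < n:
        specs["rest"] = GroupSpec(n - sizes, 62.2, 12.5, female_ratio=0.547)
    idx = 0
    for name in specs:  # insertion order: deterministic
        g = specs[name]
        vviq = np.clip(
            np.rint(rng.normal(g.vviq_mean, g.vviq_sd, g.size)),
            VVIQ_MIN,
            VVIQ_MAX,
        ).astype(int)
        age = np.clip(
            np.rint(rng.normal(g.age_mean, g.age_sd, g.size)), g.age_min, g.age_max
        ).astype(int)
        n_female = int(round(g.size * g.female_ratio))
        sex = np.array(["female"] * n_female + ["male"] * (g.size - n_female))
        rng.shuffle(sex)
        scaling = np.exp(rng.normal(0.0, 0.05, g.size))
        for j in range(g.size):
            rows.append(
                {
                    "subject_id": f"S{idx + 1:03d}",
                    "group": name,
                    "age_years": int(age[j]),
                    "sex": sex[j],
                    "vviq_total": int(vviq[j]),
                    "scaling_factor": float(scaling[j]),
                }
            )
            idx += 1
    df = pd.DataFrame(rows)
    if plant_extremes:
        # keep the planted scores unique in the cohort
        inner = df["vviq_total"].clip(VVIQ_MIN + 1, VVIQ_MAX - 1)
        lo = int(inner.idxmin())
        hi = int(inner.idxmax())
        if lo == hi:  # degenerate constant scores; pick distinct rows
            hi = (lo + 1) % len(df)
        df["vviq_total"] = inner
        df.loc[lo, "vviq_total"] = VVIQ_MIN
        df.loc[hi, "vviq_total"] = VVIQ_MAX
    return df


def subjects_to_frame(subjects: Iterable[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "age_years": s.age_years,
                "sex": s.sex,
                "vviq_total": s.vviq_total,
                "scaling_factor": s.scaling_factor,
            }
            for s in subjects
        ]
    )


# ---------------------------------------------------------------------------
# trials
# ---------------------------------------------------------------------------


def default_mixture_params() -> dict:
    """Study-like mixture weights per condition.

    Three-item conditions mix genuine target memory with misbinding (the
    response lands on a non-target's location) and uniform guessing at rates
    in line with the observed classified scores; one-item conditions cannot
    misbind. Memory degrades slightly at the longer delay.
    """
    return {
        (1, 1): MixtureParams(0.95, 0.0, 0.05, ident_accuracy=0.95),
        (1, 4): MixtureParams(0.92, 0.0, 0.08, ident_accuracy=0.93),
        (3, 1): MixtureParams(0.72, 0.15, 0.13, ident_accuracy=0.88),
        (3, 4): MixtureParams(0.68, 0.15, 0.17, ident_accuracy=0.86),
    }


def mixture_for_subject(
    subject: Union[SubjectRecord, Mapping],
    base: Optional[Mapping] = None,
    vviq_shift: float = 0.20,
    sex_shift: float = 0.05,
    age_shift: float = 0.08,
) -> dict:
    """Tilt the base mixture by the subject's vividness, sex and age.

    High-VVIQ, female and younger subjects get more target responses (and
    proportionally less guessing/misbinding), emulating the direction of the
    group effects the analysis is designed to detect. Shifts are expressed as
    the change in ``p_target`` between the extremes of each attribute.
    """
    if base is None:
        base = default_mixture_params()
    get = subject.get if isinstance(subject, Mapping) else lambda k: getattr(subject, k)
    vviq = float(get("vviq_total"))
    sex = get("sex")
    age = float(get("age_years"))
    # centred covariates in [-0.5, 0.5]
    zv = (vviq - (VVIQ_MIN + VVIQ_MAX) / 2) / (VVIQ_MAX - VVIQ_MIN)
    zs = 0.5 if sex == "female" else -0.5
    za = (67.0 - age) / 26.0  # 54..80 -> +-0.5
    delta = vviq_shift * zv + sex_shift * zs + age_shift * za
    out = {}
    for cond, p in base.items():
        pt = float(np.clip(p.p_target + delta, 0.05, 0.995))
        rest = 1.0 - pt
        base_rest = p.p_misbind + p.p_guess
        if base_rest > 0:
            pm = rest * p.p_misbind / base_rest
            pg = rest * p.p_guess / base_rest
        else:
            pm, pg = 0.0, rest
        out[cond] = MixtureParams(
            pt, pm, pg, p.sigma_px, p.ident_accuracy, p.rt_mean_s, p.rt_sd_s
        )
    return out


def _uniform_points(rng: np.random.Generator, shape, screen: ScreenGeometry):
    pts = rng.random(shape + (2,))
    pts[..., 0] *= screen.width_px
    pts[..., 1] *= screen.height_px
    return pts


def _place_items(rng, m: int, n_items: int, screen: ScreenGeometry, min_sep: float):
    """Uniform item positions subject to a minimum pairwise separation.

    Resamples whole trials until the separation constraint holds, which keeps
    the marginal distribution uniform (no edge clipping artefacts).
    """
    pts = _uniform_points(rng, (m, n_items), screen)
    if n_items > 1 and min_sep > 0:
        while True:
            diff = pts[:, :, None, :] - pts[:, None, :, :]
            dist = np.sqrt((diff**2).sum(-1))
            iu = np.triu_indices(n_items, 1)
            bad = (dist[:, iu[0], iu[1]] < min_sep).any(axis=1)
            if not bad.any():
                break
            pts[bad] = _uniform_points(rng, (int(bad.sum()), n_items), screen)
    return pts


def _truncated_gaussian_xy(rng, centres, sigma, screen: ScreenGeometry):
    """Isotropic Gaussian around each centre, resampled into screen bounds."""
    out = centres + rng.normal(0.0, sigma, centres.shape)
    while True:
        bad = (
            (out[:, 0] < 0)
            | (out[:, 0] >= screen.width_px)
            | (out[:, 1] < 0)
            | (out[:, 1] >= screen.height_px)
        )
        if not bad.any():
            return out
        k = int(bad.sum())
        out[bad] = centres[bad] + rng.normal(0.0, sigma, (k, 2))


def _positive_truncated(rng, mean, sd, size):
    out = rng.normal(mean, sd, size)
    while True:
        bad = out <= 0
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, int(bad.sum()))


def generate_trials(
    subject: Union[SubjectRecord, Mapping, str],
    params_by_condition: Optional[Mapping] = None,
    task: Optional[TaskConfig] = None,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Generate the full trial table for one subject.

    Placement responses follow the mixture in ``params_by_condition``: a
    target-centred isotropic Gaussian, a Gaussian centred on a uniformly
    chosen non-target (misbinding, 3-item conditions only), or a uniform
    point on the screen (guessing). Identification correctness is Bernoulli
    and response times are positive-truncated Gaussians.
    """
    if task is None:
        task = TaskConfig()
    if params_by_condition is None:
        params_by_condition = default_mixture_params()
    if isinstance(subject, str):
        subject_id = subject
    elif isinstance(subject, Mapping):
        subject_id = subject["subject_id"]
    else:
        subject_id = subject.subject_id

    for cond in task.conditions:
        if cond not in params_by_condition:
            raise ValueError(f"no MixtureParams for condition {cond}")
        if cond[0] == 1 and params_by_condition[cond].p_misbind > 0:
            raise ValueError(f"p_misbind > 0 for 1-item condition {cond}")

    rng = np.random.default_rng(seed)
    screen = task.screen
    m = task.trials_per_condition
    per_block = m // task.blocks
    frames = []
    for n_items, delay_s in task.conditions:
        p = params_by_condition[(n_items, delay_s)]
        items = _place_items(rng, m, n_items, screen, task.min_item_separation_px)
        target = items[:, 0, :]
        nts = items[:, 1:, :]  # (m, n_items-1, 2)

        u = rng.random(m)
        is_target = u < p.p_target
        is_misbind = (~is_target) & (u < p.p_target + p.p_misbind)
        is_guess = ~(is_target | is_misbind)

        centres = target.copy()
        if n_items == 3:
            pick = rng.integers(0, 2, m)
            centres[is_misbind] = nts[is_misbind, pick[is_misbind], :]
        response = _truncated_gaussian_xy(rng, centres, p.sigma_px, screen)
        guesses = _uniform_points(rng, (m,), screen)
        response[is_guess] = guesses[is_guess]

        identified = rng.random(m) < p.ident_accuracy
        rt = _positive_truncated(rng, p.rt_mean_s, p.rt_sd_s, m)

        frames.append(
            pd.DataFrame(
                {
                    "subject_id": subject_id,
                    "block": np.repeat(np.arange(1, task.blocks + 1), per_block),
                    "n_items": n_items,
                    "delay_s": delay_s,
                    "target_x": target[:, 0],
                    "target_y": target[:, 1],
                    "nt1_x": nts[:, 0, 0] if n_items == 3 else np.nan,
                    "nt1_y": nts[:, 0, 1] if n_items == 3 else np.nan,
                    "nt2_x": nts[:, 1, 0] if n_items == 3 else np.nan,
                    "nt2_y": nts[:, 1, 1] if n_items == 3 else np.nan,
                    "identified_correctly": identified,
                    "response_x": response[:, 0],
                    "response_y": response[:, 1],
                    "response_time_s": rt,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegionSpec:
    """Catalogue entry: set membership, available sides and volume scale."""

    set_label: str
    sides: tuple  # subset of ("left", "right"); bilateral derived as the sum
    baseline_mm3: float
    sd_mm3: float
    has_bilateral: bool = True


def default_region_catalogue() -> dict:
    """The 57-volume region catalogue (11 + 36 + 3 + 7 across Sets A-D).

    Set A: large imagery-active areas; Set B: 12 hippocampal subfields with
    left/right/bilateral volumes; Set C: amygdala (control); Set D: motor
    areas (control, no bilateral score for BA4a/BA4p). Baselines are typical
    adult volumes in mm^3; between-subject SD is ~12% of baseline.
    """
    lr = ("left", "right")

    def spec(set_label, baseline, bilateral=True):
        return RegionSpec(set_label, lr, baseline, 0.12 * baseline, bilateral)

    cat = {
        # Set A (11 volumes: 3 + 2 + 3 + 3)
        "hippocampus": spec("A", 3500.0),
        "whole_hippocampus": spec("A", 3400.0, bilateral=False),
        "V1": spec("A", 5200.0),
        "fusiform_gyrus": spec("A", 8000.0),
        # Set B (36 volumes: 12 subfields x left/right/bilateral)
        "parasubiculum": spec("B", 65.0),
        "presubiculum": spec("B", 300.0),
        "subiculum": spec("B", 450.0),
        "CA1": spec("B", 650.0),
        "CA3": spec("B", 220.0),
        "CA4": spec("B", 250.0),
        "GC-ML-DG": spec("B", 290.0),
        "HATA": spec("B", 60.0),
        "fimbria": spec("B", 60.0),
        "molecular_layer": spec("B", 580.0),
        "hippocampal_fissure": spec("B", 160.0),
        "hippocampal_tail": spec("B", 550.0),
        # Set C (3 volumes)
        "amygdala": spec("C", 1310.0),
        # Set D (7 volumes: 2 + 2 + 3)
        "BA4a": spec("D", 2600.0, bilateral=False),
        "BA4p": spec("D", 2100.0, bilateral=False),
        "B4": spec("D", 4700.0),
    }
    return cat


@dataclass(frozen=True)
class VolumeEffectSpec:
    """Planted effect structure of the synthetic volume table.

    The vividness-group multiplier applies to Sets A and B only (control Sets
    C and D stay at exactly 1), to subjects at or above ``vviq_threshold``.
    The sex multiplier (males) likewise applies to Sets A and B. Planted
    extreme-case multipliers apply to every set, emulating the reported
    across-the-board aphant/hphant contrast.
    """

    catalogue: Mapping[str, RegionSpec] = field(default_factory=default_region_catalogue)
    vviq_group_multiplier: float = 1.10
    vviq_threshold: float = 62.0
    sex_multiplier: float = 1.10
    planted_case_multipliers: Mapping[str, float] = field(
        default_factory=lambda: {"aphant": 0.85, "hphant": 1.05}
    )

    def __post_init__(self) -> None:
        if self.vviq_group_multiplier <= 0 or self.sex_multiplier <= 0:
            raise ValueError("multipliers must be positive")
        for v in self.planted_case_multipliers.values():
            if v <= 0:
                raise ValueError("case multipliers must be positive")


def generate_volumes(
    subjects: Union[pd.DataFrame, Sequence[SubjectRecord]],
    spec: Optional[VolumeEffectSpec] = None,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """One volume per subject x region x available side (plus bilateral sums).

    Expected volume = baseline x applicable multipliers; additive Gaussian
    noise independent across subjects and sides, resampled to stay positive.
    Bilateral volumes are the exact left + right sums wherever both exist.
    """
    if spec is None:
        spec = VolumeEffectSpec()
    if not spec.catalogue:
        raise ValueError("region catalogue must not be empty")
    if not isinstance(subjects, pd.DataFrame):
        subjects = subjects_to_frame(subjects)

    for region, rs in spec.catalogue.items():
        if rs.set_label not in ("A", "B", "C", "D"):
            raise ValueError(f"unknown set label {rs.set_label!r} for {region}")

    rng = np.random.default_rng(seed)
    rows = []
    for _, s in subjects.iterrows():
        vviq = s["vviq_total"]
        role = "aphant" if vviq == VVIQ_MIN else "hphant" if vviq == VVIQ_MAX else None
        for region, rs in spec.catalogue.items():
            mult = 1.0
            if rs.set_label in ("A", "B"):
                if vviq >= spec.vviq_threshold:
                    mult *= spec.vviq_group_multiplier
                if s["sex"] == "male":
                    mult *= spec.sex_multiplier
            if role is not None:
                mult *= spec.planted_case_multipliers.get(role, 1.0)
            side_values = {}
            for side in rs.sides:
                v = rs.baseline_mm3 * mult + rng.normal(0.0, rs.sd_mm3)
                while v <= 0:
                    v = rs.baseline_mm3 * mult + rng.normal(0.0, rs.sd_mm3)
                side_values[side] = v
            if rs.has_bilateral and {"left", "right"} <= set(rs.sides):
                side_values["bilateral"] = side_values["left"] + side_values["right"]
            for side, v in side_values.items():
                rows.append(
                    {
                        "subject_id": s["subject_id"],
                        "region": region,
                        "side": side,
                        "set_label": rs.set_label,
                        "volume_mm3": float(v),
                    }
                )
    return pd.DataFrame(rows)
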