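"""End-to-end re-analysis pipeline.

Order of stages, mirroring the study's results structure: score the trial
table; select extreme VVIQ and age groups; run the visual short-term memory
split-plot ANOVAs (vividness group, gender with head-size covariate, age)
and combine the three vividness outcomes with Fisher's method; run the
per-Set volume ANOVAs (Sets A, B, D four-way with Side and Region within;
Set C, a single region, three-way with Side only); per-region group
t-tests feeding the active-vs-control 2x2 chi-squared; single-case analyses
for the planted extreme scorers; and the sign-consistency and five-category
ordering tests. Every stochastic stage has its own seed derived from the run
seed, so a run is reproducible bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .cohort_design import select_extreme_groups
from .composite_tests import (
    ORDERING_ROLES,
    chi2_2x2,
    fishers_method,
    ordering_match_count,
    percent_difference,
    sign_consistency,
)
from .datatypes import VVIQ_MAX, VVIQ_MIN, Chi2Result, ScreenGeometry
from .inferential_stats import mixed_anova, summary_stats, t_from_summary
from .single_case_bayes import single_case_test
from .synthetic_cohort import (
    TRIAL_COLUMNS,
    VolumeEffectSpec,
    generate_subjects,
    generate_trials,
    generate_volumes,
    mixture_for_subject,
)
from .vstm_scoring import classify_trials, summarise_conditions

__all__ = [
    "AnalysisConfig",
    "ReportBundle",
    "load_subject_table",
    "load_trial_table",
    "load_volume_table",
    "simulate_cohort",
    "run_full_analysis",
    "write_report",
]

SUBJECT_COLUMNS = ["subject_id", "age_years", "sex", "vviq_total", "scaling_factor"]
VOLUME_COLUMNS = ["subject_id", "region", "side", "set_label", "volume_mm3"]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class AnalysisConfig:
    """Everything a run needs; round-trips losslessly through YAML."""

    seed: int = 0
    n_subjects: int = 53
    k_extreme: int = 10
    n_resamples: object = 5000  # int, or "exact" for the enumeration oracle
    n_iter_singlecase: int = 100_000
    alpha: float = 0.05
    tails: int = 2
    percent_denominator: str = "reference"
    subjects_path: Optional[str] = None
    trials_path: Optional[str] = None
    volumes_path: Optional[str] = None
    output_dir: Optional[str] = None

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _stage_seeds(seed: int, n: int = 8):
    """Independent per-stage seeds derived from the run seed."""
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s % (2**31)) for s in state]


# ---------------------------------------------------------------------------
# loaders
# ---------------------------------------------------------------------------


def _check_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what} table is missing required columns: {missing}")


def load_subject_table(path) -> pd.DataFrame:
    """Read and validate subjects.csv; malformed rows are reported by line."""
    df = pd.read_csv(path)
    _check_columns(df, SUBJECT_COLUMNS, "subject")
    errors = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        if not VVIQ_MIN <= row["vviq_total"] <= VVIQ_MAX:
            errors.append(f"line {line}: vviq_total {row['vviq_total']} outside [16, 80]")
        if row["age_years"] < 0:
            errors.append(f"line {line}: negative age")
        if row["sex"] not in ("female", "male"):
            errors.append(f"line {line}: sex must be 'female' or 'male'")
        if row["scaling_factor"] <= 0:
            errors.append(f"line {line}: non-positive scaling_factor")
    if errors:
        raise ValueError("invalid subject rows:\n" + "\n".join(errors))
    if df["subject_id"].duplicated().any():
        raise ValueError("duplicate subject_id values")
    return df


def load_trial_table(
    path, screen: Optional[ScreenGeometry] = None, strict_bounds: bool = False
) -> pd.DataFrame:
    """Read and validate trials.csv.

    Coordinates outside the screen raise in strict mode and warn otherwise.
    """
    import warnings

    df = pd.read_csv(path)
    _check_columns(df, TRIAL_COLUMNS, "trial")
    screen = screen or ScreenGeometry()
    errors = []
    for i, row in df.iterrows():
        line = i + 2
        if row["n_items"] not in (1, 3):
            errors.append(f"line {line}: n_items must be 1 or 3")
            continue
        nt_cols = ["nt1_x", "nt1_y", "nt2_x", "nt2_y"]
        has_nt = row[nt_cols].notna()
        if row["n_items"] == 1 and has_nt.any():
            errors.append(f"line {line}: 1-item trial carries non-target coordinates")
        if row["n_items"] == 3 and not has_nt.all():
            errors.append(f"line {line}: 3-item trial missing non-target coordinates")
        if row["response_time_s"] <= 0:
            errors.append(f"line {line}: non-positive response_time_s")
    if errors:
        raise ValueError("invalid trial rows:\n" + "\n".join(errors))
    for prefix in ("target", "response"):
        x, y = df[f"{prefix}_x"], df[f"{prefix}_y"]
        out = (x < 0) | (x >= screen.width_px) | (y < 0) | (y >= screen.height_px)
        if out.any():
            msg = (
                f"{int(out.sum())} {prefix} coordinates outside the "
                f"{screen.width_px}x{screen.height_px} screen"
            )
            if strict_bounds:
                raise ValueError(msg)
            warnings.warn(msg, stacklevel=2)
    df["identified_correctly"] = df["identified_correctly"].astype(bool)
    return df


def load_volume_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, VOLUME_COLUMNS, "volume")
    errors = []
    for i, row in df.iterrows():
        line = i + 2
        if row["side"] not in ("left", "right", "bilateral"):
            errors.append(f"line {line}: unknown side {row['side']!r}")
        if row["set_label"] not in ("A", "B", "C", "D"):
            errors.append(f"line {line}: unknown set label {row['set_label']!r}")
        if not row["volume_mm3"] > 0:
            errors.append(f"line {line}: volume_mm3 must be positive")
    if errors:
        raise ValueError("invalid volume rows:\n" + "\n".join(errors))
    return df


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def simulate_cohort(config: AnalysisConfig):
    """Generate subjects, trials and volumes under the default study conditions."""
    from .synthetic_cohort import GroupSpec

    s_subj, s_trials, s_vols, *_ = _stage_seeds(config.seed)
    n = config.n_subjects
    # keep the high/low/mid proportions of the 53-subject design at any n
    k = max(2, round(10 * n / 53))
    spec = {
        "high": GroupSpec(k, 75.5, 2.72, female_ratio=0.6),
        "low": GroupSpec(k, 41.9, 11.99, female_ratio=0.5),
        "mid": GroupSpec(n - 2 * k, 62.2, 9.0, female_ratio=0.55),
    }
    subjects = generate_subjects(n, spec, plant_extremes=True, seed=s_subj)
    trial_seeds = _stage_seeds(s_trials, len(subjects))
    frames = [
        generate_trials(
            row["subject_id"],
            mixture_for_subject(row),
            seed=trial_seeds[i],
        )
        for i, (_, row) in enumerate(subjects.iterrows())
    ]
    trials = pd.concat(frames, ignore_index=True)
    volumes = generate_volumes(subjects, VolumeEffectSpec(), seed=s_vols)
    return subjects, trials, volumes


# ---------------------------------------------------------------------------
# analysis
# ---------------------------------------------------------------------------


@dataclass
class ReportBundle:
    """All result tables of one run, with the manifest that reproduces them."""

    subjects: pd.DataFrame
    summaries: pd.DataFrame
    vviq_assignment: Mapping[str, str]
    age_assignment: Mapping[str, str]
    vviq_gap: float
    age_gap: float
    vstm_anovas: Mapping[str, pd.DataFrame]
    fisher_combined: tuple  # (chi2, df, p)
    vstm_percent_differences: pd.DataFrame
    volume_anovas: Mapping[str, pd.DataFrame]
    region_tests: pd.DataFrame
    chi2_table: np.ndarray
    chi2_result: Chi2Result
    sign_counts: tuple  # (k_high_larger, n_regions)
    sign_p: float
    ordering: object
    single_case: pd.DataFrame
    aphant_hphant_paired: Mapping[str, float]
    manifest: Mapping


def _condition_label(n_items, delay_s) -> str:
    return f"{int(n_items)}item_{int(delay_s)}s"


def _vstm_long(summaries, subjects, assignment, measure, conditions=None):
    df = summaries.copy()
    df["condition"] = [
        _condition_label(a, b) for a, b in zip(df["n_items"], df["delay_s"])
    ]
    if conditions is not None:
        df = df[df["condition"].isin(conditions)]
    df = df.merge(subjects[["subject_id", "sex", "scaling_factor"]], on="subject_id")
    cols = ["subject_id", "condition", "response", "sex", "scaling_factor"]
    if assignment is not None:
        df["group"] = df["subject_id"].map(assignment)
        df = df[df["group"] != "none"]
        cols.append("group")
    return df.rename(columns={measure: "response"})[cols]


def _anova_p(table: pd.DataFrame, effect: str) -> float:
    row = table[table["effect"] == effect]
    if not len(row):
        raise KeyError(f"effect {effect!r} not in ANOVA table")
    return float(row["p"].iloc[0])


def run_full_analysis(config: AnalysisConfig) -> ReportBundle:
    """Execute the whole re-analysis; see the module docstring for the order."""
    seeds = _stage_seeds(config.seed)
    if config.trials_path or config.subjects_path or config.volumes_path:
        if not (config.trials_path and config.subjects_path and config.volumes_path):
            raise ValueError("provide all three input paths, or none (simulate)")
        subjects = load_subject_table(config.subjects_path)
        trials = load_trial_table(config.trials_path)
        volumes = load_volume_table(config.volumes_path)
    else:
        subjects, trials, volumes = simulate_cohort(config)

    # --- scoring ---------------------------------------------------------
    classified = classify_trials(trials, config.n_resamples, seed=seeds[3])
    summaries = summarise_conditions(classified)

    # --- group selection -------------------------------------------------
    vviq = select_extreme_groups(subjects, config.k_extreme, "vviq_total")
    age = select_extreme_groups(subjects, config.k_extreme, "age_years")

    # --- VSTM ANOVAs -----------------------------------------------------
    all_conditions = sorted(
        {_condition_label(a, b) for a, b in zip(summaries["n_items"], summaries["delay_s"])}
    )
    misbind_conditions = [c for c in all_conditions if c.startswith("3item")]
    vstm_anovas = {}
    group_ps = {}
    for measure, conds in [
        ("avg_error_px", None),
        ("guess_rate", None),
        ("misbind_rate", misbind_conditions),
    ]:
        long = _vstm_long(summaries, subjects, vviq.labels, measure, conds)
        tab = mixed_anova(
            long, dv="response", subject="subject_id",
            between=["group"], within=["condition"],
        )
        vstm_anovas[f"vviq_{measure}"] = tab
        group_ps[measure] = _anova_p(tab, "group")

        sex_long = _vstm_long(summaries, subjects, None, measure, conds)
        vstm_anovas[f"gender_{measure}"] = mixed_anova(
            sex_long, dv="response", subject="subject_id",
            between=["sex"], within=["condition"], covariate="scaling_factor",
        )
        age_long = _vstm_long(summaries, subjects, age.labels, measure, conds)
        vstm_anovas[f"age_{measure}"] = mixed_anova(
            age_long, dv="response", subject="subject_id",
            between=["group"], within=["condition"],
        )

    fisher_combined = fishers_method(
        [group_ps["avg_error_px"], group_ps["guess_rate"], group_ps["misbind_rate"]]
    )

    # percent differences High vs Low (reference = High group mean)
    pct_rows = []
    merged = summaries.merge(subjects[["subject_id"]], on="subject_id")
    merged["vviq_group"] = merged["subject_id"].map(vviq.labels)
    for measure in ["avg_error_px", "guess_rate", "misbind_rate"]:
        sub = merged.dropna(subset=[measure])
        hi = sub.loc[sub["vviq_group"] == "high", measure].mean()
        lo = sub.loc[sub["vviq_group"] == "low", measure].mean()
        pct_rows.append(
            {
                "measure": measure,
                "high_mean": hi,
                "low_mean": lo,
                "percent_difference": percent_difference(
                    hi, lo, config.percent_denominator
                ),
                "denominator": config.percent_denominator,
            }
        )
    pct = pd.DataFrame(pct_rows)

    # --- volume ANOVAs per Set ------------------------------------------
    vol = volumes.merge(
        subjects[["subject_id", "sex", "vviq_total"]], on="subject_id"
    )
    vol["vviq_group"] = vol["subject_id"].map(vviq.labels)
    grouped = vol[vol["vviq_group"] != "none"]
    volume_anovas = {}
    for set_label in ["A", "B", "C", "D"]:
        sub = grouped[grouped["set_label"] == set_label]
        if set_label == "D":
            sub = sub[sub["side"].isin(["left", "right"])]
        else:
            # keep regions measured on all three sides for a complete layout
            full = sub.groupby("region")["side"].nunique()
            sub = sub[sub["region"].isin(full[full == 3].index)]
        within = ["side"] if sub["region"].nunique() == 1 else ["region", "side"]
        volume_anovas[set_label] = mixed_anova(
            sub.rename(columns={"volume_mm3": "response"}),
            dv="response", subject="subject_id",
            between=["vviq_group", "sex"], within=within,
        )

    # --- per-region t-tests and the active/control 2x2 ------------------
    region_rows = []
    for (region, side, set_label), g in vol.groupby(["region", "side", "set_label"]):
        hi = g.loc[g["vviq_group"] == "high", "volume_mm3"]
        lo = g.loc[g["vviq_group"] == "low", "volume_mm3"]
        res = t_from_summary(
            summary_stats(hi), summary_stats(lo), variance="welch",
            tails=config.tails,
        )
        region_rows.append(
            {
                "region": region,
                "side": side,
                "set_label": set_label,
                "high_mean": hi.mean(),
                "low_mean": lo.mean(),
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "significant": res.p < config.alpha and res.t > 0,
            }
        )
    region_tests = pd.DataFrame(region_rows)
    active = region_tests["set_label"].isin(["A", "B"])
    table = np.array(
        [
            [int((active & region_tests["significant"]).sum()),
             int((~active & region_tests["significant"]).sum())],
            [int((active & ~region_tests["significant"]).sum()),
             int((~active & ~region_tests["significant"]).sum())],
        ]
    )
    chi2_result = chi2_2x2(table, yates=False)

    # --- sign consistency over the active (A and B) volumes -------------
    ab = region_tests[active]
    k_sign = int((ab["high_mean"] > ab["low_mean"]).sum())
    sign_p = sign_consistency(len(ab), k_sign)

    # --- ordering test over all volumes ----------------------------------
    aphant_ids = subjects.loc[subjects["vviq_total"] == VVIQ_MIN, "subject_id"]
    hphant_ids = subjects.loc[subjects["vviq_total"] == VVIQ_MAX, "subject_id"]
    ordering = None
    if len(aphant_ids) == 1 and len(hphant_ids) == 1:
        aphant_id, hphant_id = aphant_ids.iloc[0], hphant_ids.iloc[0]
        cat = {}
        for (region, side), g in vol.groupby(["region", "side"]):
            g = g.set_index("subject_id")["volume_mm3"]
            cat[f"{region}:{side}"] = {
                "hphant": g[hphant_id],
                "high_group_mean": g[
                    [s for s, lab in vviq.labels.items() if lab == "high"]
                ].mean(),
                "sample_mean": g.mean(),
                "low_group_mean": g[
                    [s for s, lab in vviq.labels.items() if lab == "low"]
                ].mean(),
                "aphant": g[aphant_id],
            }
        ordering = ordering_match_count(cat, ORDERING_ROLES)

    # --- single-case analyses -------------------------------------------
    sc_rows = []
    paired = {}
    if len(aphant_ids) == 1 and len(hphant_ids) == 1:
        sc_seeds = _stage_seeds(seeds[4], 64)
        si = 0
        wide = summaries.copy()
        wide["condition"] = [
            _condition_label(a, b) for a, b in zip(wide["n_items"], wide["delay_s"])
        ]
        for measure in ["avg_error_px", "guess_rate", "misbind_rate", "ident_acc", "rt_s"]:
            for cond in all_conditions:
                col = wide[(wide["condition"] == cond)].set_index("subject_id")[measure]
                col = col.dropna()
                if col.empty:
                    continue
                for role, sid in [("aphant", aphant_id), ("hphant", hphant_id)]:
                    if sid not in col.index:
                        continue
                    ctrl = col.drop(index=[aphant_id, hphant_id], errors="ignore")
                    if len(ctrl) < 2 or ctrl.std(ddof=1) == 0:
                        continue
                    res = single_case_test(
                        float(col[sid]),
                        summary_stats(ctrl),
                        n_iter=config.n_iter_singlecase,
                        seed=sc_seeds[si % len(sc_seeds)],
                    )
                    si += 1
                    sc_rows.append(
                        {
                            "case": role,
                            "measure": measure,
                            "condition": cond,
                            "case_value": float(col[sid]),
                            "control_mean": ctrl.mean(),
                            "control_sd": ctrl.std(ddof=1),
                            "z_cc": res.z_cc_point,
                            "z_cc_lo": res.z_cc_ci95[0],
                            "z_cc_hi": res.z_cc_ci95[1],
                            "p_below": res.p_below,
                            "p_two_sided": res.p_two_sided,
                        }
                    )
        # paired contrast over active-set volumes, hphant vs aphant
        ab_vol = vol[vol["set_label"].isin(["A", "B"])]
        a = ab_vol[ab_vol["subject_id"] == aphant_id].set_index(["region", "side"])[
            "volume_mm3"
        ]
        h = ab_vol[ab_vol["subject_id"] == hphant_id].set_index(["region", "side"])[
            "volume_mm3"
        ]
        common = a.index.intersection(h.index)
        tt = stats.ttest_rel(a[common], h[common])
        paired = {
            "t": float(tt.statistic),
            "df": float(len(common) - 1),
            "p": float(tt.pvalue),
            "n_regions": int(len(common)),
            "mean_percent_difference": float(
                percent_difference(a[common].mean(), h[common].mean(), "reference")
            ),
        }
    single_case = pd.DataFrame(sc_rows)

    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "stage_seeds": seeds,
        "n_subjects": int(len(subjects)),
        "n_trials": int(len(trials)),
        "n_volumes": int(len(volumes)),
        "vviq_groups": {"low": vviq.n_low, "high": vviq.n_high, "gap": vviq.gap},
        "age_groups": {"low": age.n_low, "high": age.n_high, "gap": age.gap},
    }
    return ReportBundle(
        subjects=subjects,
        summaries=summaries,
        vviq_assignment=vviq.labels,
        age_assignment=age.labels,
        vviq_gap=vviq.gap,
        age_gap=age.gap,
        vstm_anovas=vstm_anovas,
        fisher_combined=fisher_combined,
        vstm_percent_differences=pct,
        volume_anovas=volume_anovas,
        region_tests=region_tests,
        chi2_table=table,
        chi2_result=chi2_result,
        sign_counts=(k_sign, int(len(ab))),
        sign_p=sign_p,
        ordering=ordering,
        single_case=single_case,
        aphant_hphant_paired=paired,
        manifest=manifest,
    )


def write_report(bundle: ReportBundle, outdir) -> None:
    """Write all bundle tables as CSV plus a JSON run manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.subjects.to_csv(out / "subjects.csv", index=False)
    bundle.summaries.to_csv(out / "vstm_summaries.csv", index=False)
    pd.DataFrame(
        {
            "subject_id": list(bundle.vviq_assignment),
            "vviq_group": list(bundle.vviq_assignment.values()),
            "age_group": [bundle.age_assignment[s] for s in bundle.vviq_assignment],
        }
    ).to_csv(out / "group_assignment.csv", index=False)
    for name, tab in bundle.vstm_anovas.items():
        tab.to_csv(out / f"anova_vstm_{name}.csv", index=False)
    for name, tab in bundle.volume_anovas.items():
        tab.to_csv(out / f"anova_volumes_set{name}.csv", index=False)
    bundle.region_tests.to_csv(out / "region_tests.csv", index=False)
    bundle.vstm_percent_differences.to_csv(out / "percent_differences.csv", index=False)
    if len(bundle.single_case):
        bundle.single_case.to_csv(out / "single_case.csv", index=False)
    composite = {
        "fisher": {
            "chi2": bundle.fisher_combined[0],
            "df": bundle.fisher_combined[1],
            "p": bundle.fisher_combined[2],
        },
        "chi2_2x2": {
            "table": bundle.chi2_table.tolist(),
            "chi2": bundle.chi2_result.chi2,
            "p": bundle.chi2_result.p,
        },
        "sign_consistency": {
            "k": bundle.sign_counts[0],
            "n": bundle.sign_counts[1],
            "p": bundle.sign_p,
        },
        "ordering": (
            {
                "k_matches": bundle.ordering.k_matches,
                "n_regions": bundle.ordering.n_regions,
                "per_trial_p": bundle.ordering.per_trial_p,
                "p_at_least_k": bundle.ordering.p_at_least_k,
            }
            if bundle.ordering is not None
            else None
        ),
        "aphant_hphant_paired": bundle.aphant_hphant_paired,
    }
    (out / "composite_tests.json").write_text(json.dumps(composite, indent=2))
    (out / "manifest.json").write_text(json.dumps(bundle.manifest, indent=2))
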