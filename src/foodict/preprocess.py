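"""Preregistered screening, adherence and data-exclusion pipeline.

Produces the analysis-ready dataset together with a per-participant audit
of every triggered rule. Rule identifiers are namespaced:
``eligibility.*`` (recruitment screen), ``adherence.*`` (training-log
rules), ``ratings.*`` (palatability pipeline) and ``weight.*``.

Outlier screening uses the median absolute deviation: a value is flagged
when it lies outside median +/- k * 1.4826 * MAD, with k = 2.5 for raw
distributions (moderately conservative) and k = 3 for weight deltas. The
1.4826 factor is the consistency constant making the scaled MAD estimate
the SD under normality; it can be switched off for an unscaled rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

ELIGIBILITY_FIELDS = (
    "age",
    "bmi",
    "sweet_liking",
    "salty_liking",
    "medication_last_7d",
    "eating_disorder_history",
    "weight_change_6mo_pct",
    "restrictive_diet",
    "plans_weight_loss",
    "prior_ict_study",
)

TRAINING_DAYS = 20
MIN_DAILY_MINUTES = 20.0
MAX_MISSED_DAYS = 2
MAX_SHORT_DAYS = 5
LOW_LEVEL_THRESHOLD = 5      # difficulty level that must be exceeded
MAX_LOW_LEVEL_DAYS = 7       # "more than a third of the training days"
MIN_RT_MS = 300.0
TRIM_FRACTION = 0.20
MISSING_WEIGHT_SWITCH = 0.20  # strict "more than 20%"


@dataclass(frozen=True)
class MadFilterParams:
    k: float = 2.5
    scale_constant: float = 1.4826

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be > 0")


@dataclass
class ExclusionReport:
    """participant id -> ordered list of triggered rule identifiers;
    an absent/empty entry means the participant is retained."""

    reasons: dict[str, list[str]] = field(default_factory=dict)

    def add(self, participant_id: str, rule: str) -> None:
        self.reasons.setdefault(participant_id, []).append(rule)

    def excluded(self) -> set[str]:
        return {p for p, r in self.reasons.items() if r}

    def to_json_dict(self) -> dict[str, list[str]]:
        return dict(self.reasons)


@dataclass(frozen=True)
class AnalysisPlan:
    """Weight-analysis design chosen by the missingness decision rule."""

    weight_design: str  # "joint_2x4" | "three_contrasts"
    missing_fraction: float

    def __post_init__(self) -> None:
        if self.weight_design not in ("joint_2x4", "three_contrasts"):
            raise ValueError("unknown weight design")


def check_eligibility(profile: Mapping) -> tuple[bool, list[str]]:
    """Recruitment screen.

    Include iff 18-45 years, BMI > 20, at most 2 Likert points between
    sweet and salty liking, and none of: medication in the last 7 days,
    eating-disorder history, >10% weight change in 6 months, restrictive
    diet, weight-loss plan, prior inhibitory-control-training study.
    """
    for name in ELIGIBILITY_FIELDS:
        if name not in profile or profile[name] is None:
            raise ValueError(f"missing eligibility field: {name}")
    reasons = []
    if not 18 <= profile["age"] <= 45:
        reasons.append("eligibility.age")
    if not profile["bmi"] > 20:
        reasons.append("eligibility.bmi")
    if abs(profile["sweet_liking"] - profile["salty_liking"]) > 2:
        reasons.append("eligibility.taste_balance")
    if profile["medication_last_7d"]:
        reasons.append("eligibility.medication")
    if profile["eating_disorder_history"]:
        reasons.append("eligibility.eating_disorder")
    if abs(profile["weight_change_6mo_pct"]) > 10:
        reasons.append("eligibility.weight_change")
    if profile["restrictive_diet"]:
        reasons.append("eligibility.restrictive_diet")
    if profile["plans_weight_loss"]:
        reasons.append("eligibility.weight_loss_plan")
    if profile["prior_ict_study"]:
        reasons.append("eligibility.prior_ict")
    return (not reasons, reasons)


def adherence_filter(training_days: pd.DataFrame) -> tuple[bool, list[str]]:
    """Training-log screen over the 20-day intervention.

    Drop when more than 2 days were not trained at all, when more than 5
    days fall short of the 20-minute requirement, or when 7 or more days
    never exceeded difficulty level 5 in either task (a day without
    training trivially fails the level rule too). Expects columns
    ``day``, ``minutes``, ``max_level_gng``, ``max_level_cat``.
    """
    if len(training_days) != TRAINING_DAYS:
        raise ValueError(f"expected a {TRAINING_DAYS}-day log, got {len(training_days)}")
    minutes = training_days["minutes"].to_numpy(float)
    missed = int((minutes <= 0).sum())
    short = int(((minutes > 0) & (minutes < MIN_DAILY_MINUTES)).sum())
    reasons = []
    if missed > MAX_MISSED_DAYS:
        reasons.append("adherence.missed_days")
    if short > MAX_SHORT_DAYS:
        reasons.append("adherence.short_days")
    for task, col in (("gng", "max_level_gng"), ("cat", "max_level_cat")):
        low = int((training_days[col].to_numpy(float) <= LOW_LEVEL_THRESHOLD).sum())
        if low >= MAX_LOW_LEVEL_DAYS:
            reasons.append(f"adherence.low_level_{task}")
    return (not reasons, reasons)


def _subcategory(items: pd.DataFrame) -> pd.Series:
    return items["category"].astype(str) + "_" + items["taste"].astype(str)


def select_trained_items(pre_ratings: pd.DataFrame, items: pd.DataFrame) -> pd.DataFrame:
    """Per participant, the items entering training: within each of the
    four subcategories (healthy/unhealthy x sweet/salty), the items rated
    strictly above the subcategory median at pre-intervention.

    If no item is strictly above the median (all ratings tied), the top
    half by the deterministic tie-break (ascending item id) is used
    instead. Returns rows (participant_id, item_id).
    """
    rated = items[items["category"].isin(("healthy", "unhealthy"))].copy()
    rated["subcategory"] = _subcategory(rated)
    merged = pre_ratings.merge(
        rated[["id", "subcategory"]], left_on="item_id", right_on="id", how="right"
    )
    if merged["rating"].isna().any():
        missing = merged.loc[merged["rating"].isna(), "item_id"].dropna().tolist()
        raise ValueError(f"unrated items at pre-intervention: {missing[:5]}")
    out = []
    for (pid, _sub), grp in merged.groupby(["participant_id", "subcategory"]):
        med = grp["rating"].median()
        chosen = grp[grp["rating"] > med]
        if chosen.empty:
            chosen = grp.sort_values("item_id").head(len(grp) // 2)
        out.append(pd.DataFrame({"participant_id": pid, "item_id": chosen["item_id"]}))
    return pd.concat(out, ignore_index=True)


def rt_filter(responses: pd.DataFrame, min_rt_ms: float = MIN_RT_MS) -> pd.DataFrame:
    """Drop analogue-scale answers faster than 300 ms (too fast to be a
    considered rating); the boundary itself is kept."""
    kept = responses[responses["rt_ms"] >= min_rt_ms]
    if kept.empty and not responses.empty:
        warnings.warn("all responses fell below the RT threshold", stacklevel=2)
    return kept


def trim_items(
    pre_ratings: pd.DataFrame,
    items: pd.DataFrame,
    fraction: float = TRIM_FRACTION,
) -> pd.DataFrame:
    """Per participant x category, drop the floor(fraction * m) lowest-
    and highest-rated items at pre-intervention, keeping the middle of
    the distribution (the items with room to change). Returns rows
    (participant_id, item_id, category)."""
    rated = items[items["category"].isin(("healthy", "unhealthy"))]
    merged = pre_ratings.merge(
        rated[["id", "category"]], left_on="item_id", right_on="id"
    )
    out = []
    for (pid, cat), grp in merged.groupby(["participant_id", "category"]):
        m = len(grp)
        if m < 5:
            raise ValueError(
                f"need >= 5 items per category to trim, got {m} for {pid}/{cat}"
            )
        k = int(np.floor(fraction * m))
        ordered = grp.sort_values(["rating", "item_id"], kind="mergesort")
        kept = ordered.iloc[k: m - k] if k else ordered
        out.append(
            pd.DataFrame(
                {"participant_id": pid, "item_id": kept["item_id"], "category": cat}
            )
        )
    return pd.concat(out, ignore_index=True)


def mad_outliers(
    values: Sequence[float] | np.ndarray, params: MadFilterParams = MadFilterParams()
) -> np.ndarray:
    """Boolean mask of values outside median +/- k * scaled MAD.

    A zero MAD (more than half the values identical) flags every value
    differing from the median, with a warning.
    """
    values = np.asarray(values, float)
    if len(values) < 3:
        raise ValueError("need >= 3 values for MAD screening")
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    if mad == 0:
        if (values != med).any():
            warnings.warn(
                "MAD is zero; flagging every value different from the median",
                stacklevel=2,
            )
        return values != med
    return np.abs(values - med) > params.k * params.scale_constant * mad


def participant_scores(
    ratings: pd.DataFrame, items: pd.DataFrame, fraction: float = TRIM_FRACTION
) -> pd.DataFrame:
    """Trimmed mean rating per participant x category x session over the
    trained items: the analysis-level palatability score."""
    pre = ratings[ratings["session"] == "pre"]
    trained = select_trained_items(pre, items)
    kept = trained.merge(ratings, on=["participant_id", "item_id"])
    pre_trained = kept[kept["session"] == "pre"][
        ["participant_id", "item_id", "rating"]
    ]
    retained = trim_items(pre_trained, items, fraction)
    scored = retained.merge(ratings, on=["participant_id", "item_id"])
    out = (
        scored.groupby(["participant_id", "category", "session"], observed=True)["rating"]
        .mean()
        .reset_index()
    )
    return out


def palatability_exclusions(
    ratings: pd.DataFrame,
    items: pd.DataFrame,
    mad_params: MadFilterParams = MadFilterParams(k=2.5),
    min_rt_ms: float = MIN_RT_MS,
) -> tuple[ExclusionReport, pd.DataFrame]:
    """Full palatability pipeline: completeness, RT filter, trained-item
    selection, trimming, then 2.5-MAD screening of the healthy and
    unhealthy participant-mean distributions.

    Returns the exclusion report and the analysis-ready score table
    (participant_id, category, session, rating) restricted to retained
    participants.
    """
    report = ExclusionReport()
    sessions = ratings.groupby("participant_id")["session"].agg(set)
    complete = sessions[sessions.apply(lambda s: {"pre", "post"} <= s)].index
    for pid in sessions.index.difference(complete):
        report.add(pid, "ratings.incomplete")
    kept = ratings[ratings["participant_id"].isin(complete)]
    kept = rt_filter(kept, min_rt_ms)
    scores = participant_scores(kept, items)

    pooled = (
        scores.groupby(["participant_id", "category"], observed=True)["rating"]
        .mean()
        .unstack("category")
    )
    for cat in ("healthy", "unhealthy"):
        mask = mad_outliers(pooled[cat].to_numpy(), mad_params)
        for pid in pooled.index[mask]:
            report.add(pid, f"ratings.mad_{cat}")
    retained = [p for p in pooled.index if p not in report.excluded()]
    return report, scores[scores["participant_id"].isin(retained)].reset_index(drop=True)


def weight_missingness_policy(weights: pd.DataFrame) -> AnalysisPlan:
    """Choose the weight design: the joint 2 x 4 ANOVA when at most 20% of
    participants miss any weight point, otherwise three independent
    pre-vs-later contrasts (strictly more than 20% triggers the switch)."""
    per = weights.groupby("participant_id")["missing"].any()
    frac = float(per.mean()) if len(per) else 0.0
    design = "three_contrasts" if frac > MISSING_WEIGHT_SWITCH else "joint_2x4"
    return AnalysisPlan(weight_design=design, missing_fraction=frac)


def weight_exclusions(
    weights: pd.DataFrame, plan: AnalysisPlan
) -> tuple[ExclusionReport, pd.DataFrame]:
    """Weight-side exclusions under the chosen plan.

    Always: records whose measurement guideline was not followed are
    dropped, and the participant-level weight distribution is screened at
    2.5 MAD. Under the joint plan, participants missing any point are
    excluded and pre-post/post-m1/m1-m4 delta outliers (3 MAD) remove the
    participant; under the contrast plan each delta outlier only removes
    the offending data points, and participants with partial data stay.
    """
    report = ExclusionReport()
    w = weights.copy()
    bad_guideline = w.loc[~w["guideline_followed"].astype(bool), "participant_id"]
    for pid in bad_guideline.unique():
        report.add(pid, "weight.guideline")
    w = w[w["guideline_followed"].astype(bool)]

    mean_w = w.dropna(subset=["kg"]).groupby("participant_id")["kg"].mean()
    if len(mean_w) >= 3:
        mask = mad_outliers(mean_w.to_numpy(), MadFilterParams(k=2.5))
        for pid in mean_w.index[mask]:
            report.add(pid, "weight.mad_distribution")

    wide = w.pivot_table(index="participant_id", columns="timepoint", values="kg")
    contrasts = (("pre", "post"), ("pre", "m1"), ("pre", "m4"))
    dropped_points: set[tuple[str, str]] = set()
    for t0, t1 in contrasts:
        if t0 not in wide.columns or t1 not in wide.columns:
            continue
        d = (wide[t1] - wide[t0]).dropna()
        if len(d) < 3:
            continue
        mask = mad_outliers(d.to_numpy(), MadFilterParams(k=3.0))
        for pid in d.index[mask]:
            if plan.weight_design == "joint_2x4":
                report.add(pid, f"weight.mad_delta_{t0}_{t1}")
            else:
                # contrast plan: only the offending later point is dropped
                dropped_points.add((pid, t1))

    if plan.weight_design == "joint_2x4":
        missing_any = weights.groupby("participant_id")["missing"].any()
        for pid in missing_any.index[missing_any]:
            report.add(pid, "weight.missing_point")

    clean = w[~w["participant_id"].isin(report.excluded())].copy()
    if dropped_points:
        drop_mask = clean.apply(
            lambda r: (r["participant_id"], r["timepoint"]) in dropped_points, axis=1
        )
        clean = clean[~drop_mask]
    return report, clean.reset_index(drop=True)
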