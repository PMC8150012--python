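"""Exclusion-pipeline tests: the recruitment screen, adherence rules,
trained-item selection, RT filter, trimming, MAD screening and the
missing-weight decision algorithm."""

import numpy as np
import pandas as pd
import pytest

from foodict import preprocess as pp
from foodict import synthetic_cohort as sc


def _profile(**overrides):
    base = dict(
        age=25, bmi=24.0, sweet_liking=3.0, salty_liking=3.5,
        medication_last_7d=False, eating_disorder_history=False,
        weight_change_6mo_pct=2.0, restrictive_diet=False,
        plans_weight_loss=False, prior_ict_study=False,
    )
    base.update(overrides)
    return base


# ---------------------------------------------------------------------------
# eligibility


def test_compliant_profile_included():
    ok, reasons = pp.check_eligibility(_profile())
    assert ok and reasons == []


@pytest.mark.parametrize(
    "overrides, reason",
    [
        ({"bmi": 19.5}, "eligibility.bmi"),
        ({"bmi": 20.0}, "eligibility.bmi"),          # strict "> 20"
        ({"age": 17}, "eligibility.age"),
        ({"age": 46}, "eligibility.age"),
        ({"sweet_liking": 5.0, "salty_liking": 2.0}, "eligibility.taste_balance"),
        ({"medication_last_7d": True}, "eligibility.medication"),
        ({"eating_disorder_history": True}, "eligibility.eating_disorder"),
        ({"weight_change_6mo_pct": -11.0}, "eligibility.weight_change"),
        ({"restrictive_diet": True}, "eligibility.restrictive_diet"),
        ({"plans_weight_loss": True}, "eligibility.weight_loss_plan"),
        ({"prior_ict_study": True}, "eligibility.prior_ict"),
    ],
)
def test_screen_violations(overrides, reason):
    ok, reasons = pp.check_eligibility(_profile(**overrides))
    assert not ok and reason in reasons


def test_two_point_taste_difference_is_allowed():
    ok, _ = pp.check_eligibility(_profile(sweet_liking=5.0, salty_liking=3.0))
    assert ok


def test_missing_field_named():
    profile = _profile()
    del profile["bmi"]
    with pytest.raises(ValueError, match="bmi"):
        pp.check_eligibility(profile)


# ---------------------------------------------------------------------------
# adherence


def _log(minutes=None, gng=None, cat=None):
    return pd.DataFrame(
        {
            "day": range(1, 21),
            "minutes": minutes if minutes is not None else [25.0] * 20,
            "max_level_gng": gng if gng is not None else [10] * 20,
            "max_level_cat": cat if cat is not None else [10] * 20,
        }
    )


def test_perfect_log_kept():
    keep, reasons = pp.adherence_filter(_log())
    assert keep and reasons == []


def test_three_missed_days_dropped():
    minutes = [0.0] * 3 + [25.0] * 17
    keep, reasons = pp.adherence_filter(_log(minutes=minutes))
    assert not keep and "adherence.missed_days" in reasons


def test_two_missed_days_kept():
    minutes = [0.0] * 2 + [25.0] * 18
    gng = [10] * 20
    keep, _ = pp.adherence_filter(_log(minutes=minutes))
    assert keep


def test_six_short_days_dropped():
    minutes = [15.0] * 6 + [25.0] * 14
    keep, reasons = pp.adherence_filter(_log(minutes=minutes))
    assert not keep and "adherence.short_days" in reasons


def test_seven_low_level_days_dropped():
    gng = [5] * 7 + [10] * 13
    keep, reasons = pp.adherence_filter(_log(gng=gng))
    assert not keep and "adherence.low_level_gng" in reasons


def test_six_low_level_days_kept():
    cat = [4] * 6 + [10] * 14
    keep, _ = pp.adherence_filter(_log(cat=cat))
    assert keep


def test_wrong_log_length_errors():
    with pytest.raises(ValueError, match="20-day"):
        pp.adherence_filter(_log().head(19))


# ---------------------------------------------------------------------------
# trained-item selection and trimming


def _ratings_frame(ratings, participant="P0"):
    return pd.DataFrame(
        {
            "participant_id": participant,
            "item_id": [f"i{k:02d}" for k in range(len(ratings))],
            "session": "pre",
            "rating": ratings,
            "rt_ms": 1000.0,
        }
    )


def _items_frame(n, category="unhealthy", taste="sweet"):
    return pd.DataFrame(
        {
            "id": [f"i{k:02d}" for k in range(n)],
            "category": category,
            "taste": taste,
            "kcal_per_100g": 250.0,
            "base_palatability": 60.0,
        }
    )


def test_select_top_half_above_median():
    pre = _ratings_frame([90, 80, 70, 60, 50, 40])
    chosen = pp.select_trained_items(pre, _items_frame(6))
    assert sorted(chosen["item_id"]) == ["i00", "i01", "i02"]


def test_select_all_tied_falls_back_to_half():
    pre = _ratings_frame([50.0] * 6)
    chosen = pp.select_trained_items(pre, _items_frame(6))
    assert len(chosen) == 3
    assert sorted(chosen["item_id"]) == ["i00", "i01", "i02"]  # id tie-break


def test_select_odd_count_distinct_ratings():
    pre = _ratings_frame(list(range(25)))
    chosen = pp.select_trained_items(pre, _items_frame(25))
    assert len(chosen) == 12  # strictly above the median of 25 values


def test_select_unrated_item_errors():
    pre = _ratings_frame([1, 2, 3]).iloc[:2]
    with pytest.raises(ValueError, match="unrated"):
        pp.select_trained_items(pre, _items_frame(3))


def test_rt_filter_boundary():
    df = pd.DataFrame({"rt_ms": [299.0, 300.0, 301.0]})
    kept = pp.rt_filter(df)
    assert kept["rt_ms"].tolist() == [300.0, 301.0]


def test_rt_filter_warns_when_everything_dropped():
    df = pd.DataFrame({"rt_ms": [100.0, 200.0]})
    with pytest.warns(UserWarning):
        kept = pp.rt_filter(df)
    assert kept.empty


def test_trim_25_items_keeps_middle_15():
    pre = _ratings_frame(list(np.linspace(10, 90, 25)))
    kept = pp.trim_items(pre, _items_frame(25))
    assert len(kept) == 15


def test_trim_10_items_keeps_middle_6():
    pre = _ratings_frame([10, 20, 30, 40, 50, 60, 70, 80, 90, 100])
    kept = pp.trim_items(pre, _items_frame(10))
    assert sorted(kept["item_id"]) == [f"i{k:02d}" for k in range(2, 8)]


def test_trim_fraction_zero_identity():
    pre = _ratings_frame([10, 20, 30, 40, 50])
    kept = pp.trim_items(pre, _items_frame(5), fraction=0.0)
    assert len(kept) == 5


def test_trim_too_few_items_errors():
    pre = _ratings_frame([1, 2, 3, 4])
    with pytest.raises(ValueError, match=">= 5"):
        pp.trim_items(pre, _items_frame(4))


# ---------------------------------------------------------------------------
# MAD screening


def test_mad_flags_planted_outlier():
    mask = pp.mad_outliers([70, 71, 69, 70, 120])
    assert mask.tolist() == [False, False, False, False, True]


def test_mad_constant_vector_unflagged():
    assert not pp.mad_outliers([5.0, 5.0, 5.0, 5.0]).any()


def test_mad_zero_mad_flags_off_median_with_warning():
    with pytest.warns(UserWarning, match="MAD is zero"):
        mask = pp.mad_outliers([0.0, 0.0, 0.0, 5.0])
    assert mask.tolist() == [False, False, False, True]


def test_mad_too_few_values():
    with pytest.raises(ValueError):
        pp.mad_outliers([1.0, 2.0])


def test_mad_matches_brute_force_oracle():
    rng = np.random.default_rng(0)
    for _ in range(200):
        v = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), rng.integers(5, 40))
        med = float(np.median(sorted(v)))
        abs_dev = sorted(abs(x - med) for x in v)
        m = len(abs_dev)
        mad = (abs_dev[m // 2] if m % 2 else (abs_dev[m // 2 - 1] + abs_dev[m // 2]) / 2)
        expected = [abs(x - med) > 2.5 * 1.4826 * mad for x in v]
        assert pp.mad_outliers(v).tolist() == expected


# ---------------------------------------------------------------------------
# palatability pipeline


def test_clean_cohort_no_exclusions(small_trial):
    report, scores = pp.palatability_exclusions(
        small_trial["ratings"], small_trial["items"]
    )
    assert report.excluded() == set()
    n = small_trial["participants"].shape[0]
    assert scores["participant_id"].nunique() == n


def test_incomplete_post_questionnaire_excluded(small_trial):
    ratings = small_trial["ratings"]
    victim = ratings["participant_id"].iloc[0]
    broken = ratings[~((ratings["participant_id"] == victim)
                       & (ratings["session"] == "post"))]
    report, scores = pp.palatability_exclusions(broken, small_trial["items"])
    assert report.reasons[victim] == ["ratings.incomplete"]
    assert victim not in set(scores["participant_id"])


def test_planted_extreme_participant_flagged(small_trial):
    ratings = small_trial["ratings"].copy()
    victim = ratings["participant_id"].iloc[0]
    ratings.loc[ratings["participant_id"] == victim, "rating"] = 0.5
    report, _ = pp.palatability_exclusions(ratings, small_trial["items"])
    assert any(r.startswith("ratings.mad") for r in report.reasons.get(victim, []))


def test_pipeline_idempotent(small_trial):
    report1, scores1 = pp.palatability_exclusions(
        small_trial["ratings"], small_trial["items"]
    )
    kept = small_trial["ratings"][
        small_trial["ratings"]["participant_id"].isin(scores1["participant_id"])
    ]
    report2, scores2 = pp.palatability_exclusions(kept, small_trial["items"])
    assert set(scores2["participant_id"]) == set(scores1["participant_id"])


# ---------------------------------------------------------------------------
# weight policy


def _weights(n, missing_ids=(), timepoint="m4"):
    rows = []
    for i in range(n):
        for t in sc.TIMEPOINTS:
            miss = i in missing_ids and t == timepoint
            rows.append(
                {
                    "participant_id": f"P{i}",
                    "timepoint": t,
                    "kg": np.nan if miss else 70.0 + i * 0.1,
                    "guideline_followed": True,
                    "missing": miss,
                }
            )
    return pd.DataFrame(rows)


def test_policy_switches_at_a_third_missing():
    plan = pp.weight_missingness_policy(_weights(30, missing_ids=range(10)))
    assert plan.weight_design == "three_contrasts"
    assert plan.missing_fraction == pytest.approx(1 / 3)


def test_policy_complete_data_joint():
    plan = pp.weight_missingness_policy(_weights(30))
    assert plan.weight_design == "joint_2x4"


def test_policy_exactly_twenty_percent_is_joint():
    plan = pp.weight_missingness_policy(_weights(30, missing_ids=range(6)))
    assert plan.missing_fraction == pytest.approx(0.2)
    assert plan.weight_design == "joint_2x4"


def test_weight_exclusions_guideline_and_missing():
    w = _weights(10, missing_ids=(0,))
    w.loc[(w["participant_id"] == "P1") & (w["timepoint"] == "pre"),
          "guideline_followed"] = False
    plan = pp.AnalysisPlan("joint_2x4", 0.1)
    report, clean = pp.weight_exclusions(w, plan)
    assert "weight.missing_point" in report.reasons["P0"]
    assert "weight.guideline" in report.reasons["P1"]
    assert not set(clean["participant_id"]) & {"P0", "P1"}
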