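"""Statistics-engine tests: the mixed ANOVA against closed forms and an
independent implementation, BIC Bayes factors, gated mediation,
distribution screening and the expectation-share decomposition."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from foodict import power
from foodict import stats_analysis as sa


def _tidy_2x2(changes_by_group, pre=10.0):
    rows = []
    i = 0
    for g, changes in changes_by_group.items():
        for ch in changes:
            rows += [(f"S{i}", g, "pre", pre), (f"S{i}", g, "post", pre + ch)]
            i += 1
    return pd.DataFrame(rows, columns=["participant_id", "group", "session", "value"])


def test_toy_interaction_f_sixteen():
    """Group A changes {0,0}, group B {3,5}: t on change scores is 4, so
    the interaction F is 16 with df (1,2)."""
    df = _tidy_2x2({"A": [0, 0], "B": [3, 5]})
    res = sa.mixed_anova(df, "value", "participant_id", "group", ["session"])
    inter = res[res["term"] == "group * session"].iloc[0]
    assert inter["F"] == pytest.approx(16.0)
    assert (inter["df_num"], inter["df_den"]) == (1, 2)


def test_group_relabelling_preserves_within_terms():
    df = _tidy_2x2({"A": [1, 2, 0], "B": [3, 5, 4]})
    swapped = df.assign(group=df["group"].map({"A": "B", "B": "A"}))
    a = sa.mixed_anova(df, "value", "participant_id", "group", ["session"])
    b = sa.mixed_anova(swapped, "value", "participant_id", "group", ["session"])
    for term in ("session", "group * session"):
        fa = a.loc[a["term"] == term, "F"].iloc[0]
        fb = b.loc[b["term"] == term, "F"].iloc[0]
        assert fa == pytest.approx(fb)


def test_interaction_equals_t_squared_on_random_datasets():
    """2 x 2 mixed-ANOVA interaction F == pooled two-sample t^2 on change
    scores, to numerical precision, on random balanced datasets."""
    rng = np.random.default_rng(8)
    for _ in range(200):
        n = int(rng.integers(3, 12))
        spec = power.h1a_spec(reps=100, seed=int(rng.integers(1e6)))
        df = power.simulate_dataset(spec, n, rng)
        res = sa.mixed_anova(df, "value", "participant_id", "group", ["session"])
        F = res.loc[res["term"] == "group * session", "F"].iloc[0]
        wide = df.pivot_table(index="participant_id", columns="session", values="value")
        groups = df.groupby("participant_id")["group"].first().loc[wide.index]
        ch = wide["post"] - wide["pre"]
        t, _ = stats.ttest_ind(ch[groups == "experimental"], ch[groups == "control"])
        assert F == pytest.approx(t**2, rel=1e-8)


def test_triple_interaction_equals_t_squared_on_difference_scores():
    rng = np.random.default_rng(9)
    spec = power.h1_spec(reps=100, seed=3)
    df = power.simulate_dataset(spec, 15, rng)
    res = sa.mixed_anova(df, "value", "participant_id", "group",
                         ["session", "category"])
    F = res.loc[res["term"] == "group * session * category", "F"].iloc[0]
    scores, groups = sa.interaction_scores(df, "value", "participant_id",
                                           "group", ["session", "category"])
    t, _ = stats.ttest_ind(scores[groups == "experimental"],
                           scores[groups == "control"])
    assert F == pytest.approx(t**2, rel=1e-8)


def test_matches_independent_mixed_anova_implementation():
    """Exact agreement with pingouin's mixed ANOVA on an unbalanced
    two-group dataset."""
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(7)
    rows = []
    for i in range(23):
        g = "experimental" if i < 10 else "control"
        b = rng.normal(0, 15)
        for s in ("pre", "post"):
            rows.append((f"S{i}", g, s, 50 + b + rng.normal(0, 7)))
    df = pd.DataFrame(rows, columns=["participant_id", "group", "session", "value"])
    ours = sa.mixed_anova(df, "value", "participant_id", "group", ["session"])
    theirs = pg.mixed_anova(df, dv="value", within="session",
                            subject="participant_id", between="group")
    for term, source in (("group", "group"), ("session", "session"),
                         ("group * session", "Interaction")):
        row = ours[ours["term"] == term].iloc[0]
        ref = theirs[theirs["Source"] == source].iloc[0]
        assert row["F"] == pytest.approx(ref["F"], rel=1e-10)
        assert row["p"] == pytest.approx(ref["p_unc"], rel=1e-10)
        assert row["eta_p2"] == pytest.approx(ref["np2"], rel=1e-10)


def test_effect_sizes_bounded(small_trial):
    rng = np.random.default_rng(11)
    df = power.simulate_dataset(power.h1_spec(reps=100, seed=5), 12, rng)
    res = sa.mixed_anova(df, "value", "participant_id", "group",
                         ["session", "category"])
    assert res["eta_p2"].between(0, 1).all()
    assert res["eta_G2"].between(0, 1).all()
    assert (res["F"] >= 0).all()
    assert res["p"].between(0, 1).all()


def test_oneway_effect_sizes_coincide():
    rng = np.random.default_rng(12)
    values = np.concatenate([rng.normal(0, 1, 20), rng.normal(1, 1, 20)])
    groups = np.array(["a"] * 20 + ["b"] * 20)
    res = sa.oneway_anova(values, groups)
    assert res["eta_p2"] == pytest.approx(res["eta_G2"])


def test_missing_cell_errors():
    df = _tidy_2x2({"A": [1, 2], "B": [3, 4]})
    broken = df.drop(index=df.index[-1])
    with pytest.raises(sa.AnalysisError):
        sa.mixed_anova(broken, "value", "participant_id", "group", ["session"])


# ---------------------------------------------------------------------------
# Bayes factors


def test_bf01_direction_with_planted_effect():
    rng = np.random.default_rng(13)
    df = power.simulate_dataset(power.h1a_spec(reps=100, seed=5), 80, rng)
    assert sa.bf01(df, "value", "participant_id", "group", ["session"]) < 1


def test_bf01_supports_null_on_noise():
    spec = power.h1a_spec(reps=100, seed=5)
    spec.effects = {}
    rng = np.random.default_rng(14)
    df = power.simulate_dataset(spec, 150, rng)
    assert sa.bf01(df, "value", "participant_id", "group", ["session"]) > 1


def test_bf01_reciprocal_identity():
    rng = np.random.default_rng(15)
    scores = rng.normal(0, 1, 40)
    groups = np.array(["a"] * 20 + ["b"] * 20)
    bf01 = sa.bf01_from_scores(scores, groups)
    bf10 = 1.0 / bf01
    assert bf01 * bf10 == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# mediation


def test_mediation_null_covers_zero():
    rng = np.random.default_rng(16)
    x = np.repeat([0.0, 1.0], 100)
    m = rng.normal(0, 1, 200)
    y = rng.normal(0, 1, 200)
    res = sa.mediation_acme(x, m, y, rng=np.random.default_rng(0))
    assert res.acme_ci[0] <= 0 <= res.acme_ci[1]
    assert abs(res.acme) < 0.3


def test_mediation_recovers_planted_paths():
    rng = np.random.default_rng(17)
    x = np.repeat([0.0, 1.0], 100)
    m = x + rng.normal(0, 0.1, 200)          # a = 1
    y = m + rng.normal(0, 0.1, 200)          # b = 1, direct effect 0
    res = sa.mediation_acme(x, m, y, rng=np.random.default_rng(1))
    assert res.acme_ci[0] <= 1.0 <= res.acme_ci[1]
    assert res.acme == pytest.approx(1.0, abs=0.1)
    assert res.total == pytest.approx(res.acme + res.ade, abs=1e-8)


def test_mediation_seeded_bootstrap_reproducible():
    x = np.repeat([0.0, 1.0], 30)
    m = x * 0.5 + np.linspace(-1, 1, 60)
    y = m + x
    a = sa.mediation_acme(x, m, y, rng=np.random.default_rng(2))
    b = sa.mediation_acme(x, m, y, rng=np.random.default_rng(2))
    assert a == b


def test_mediation_gate_refusal():
    with pytest.raises(sa.MediationGateError, match="not performed"):
        sa.mediation_acme(np.zeros(3), np.zeros(3), np.zeros(3), gate_open=False)


def test_mediation_acme_bias_small():
    """Parameter recovery: ACME bias below 0.05 at n=500 over seeded
    replications with a = b = 1."""
    rng = np.random.default_rng(18)
    estimates = []
    for _ in range(100):
        x = np.repeat([0.0, 1.0], 250)
        m = x + rng.normal(0, 1, 500)
        y = m + rng.normal(0, 1, 500)
        a, b, _ = sa._ab_paths(x, m, y)
        estimates.append(a * b)
    assert abs(np.mean(estimates) - 1.0) < 0.05


# ---------------------------------------------------------------------------
# distribution checks and expectation share


def test_distribution_check_normal_passes():
    rng = np.random.default_rng(19)
    chk = sa.distribution_check(rng.normal(0, 1, 500))
    assert chk.passed


def test_distribution_check_exponential_skew_near_two():
    rng = np.random.default_rng(20)
    chk = sa.distribution_check(rng.exponential(1.0, 20000))
    assert chk.skewness == pytest.approx(2.0, abs=0.15)


def test_distribution_check_constant_fails():
    chk = sa.distribution_check(np.full(20, 3.0))
    assert not chk.passed


@pytest.mark.parametrize(
    "du, dh, expected", [(13.1, 5.6, 57), (10.0, 10.0, 0), (10.0, 0.0, 100)]
)
def test_expectation_share(du, dh, expected):
    assert sa.expectation_share(du, dh) == expected


def test_expectation_share_requires_devaluation():
    with pytest.raises(sa.AnalysisError):
        sa.expectation_share(0.0, 5.0)


def test_delta_ci_close_to_bootstrap_percentile():
    rng = np.random.default_rng(21)
    values = rng.normal(2.0, 5.0, 100)
    mean, lo, hi = sa._delta_ci(values)
    boots = np.array([
        rng.choice(values, len(values)).mean() for _ in range(4000)
    ])
    blo, bhi = np.percentile(boots, [2.5, 97.5])
    assert (hi - lo) == pytest.approx(bhi - blo, rel=0.10)


# ---------------------------------------------------------------------------
# confirmatory pipeline


@pytest.fixture(scope="module")
def planted_report():
    from foodict import preprocess as pp
    from foodict import synthetic_cohort as sc

    cfg = sc.EffectConfig(
        weight_effect={(g, t): 0.0 for g in sc.GROUPS for t in sc.TIMEPOINTS},
        missing_rate={t: 0.0 for t in sc.TIMEPOINTS},
        seed=33,
    )
    tables = sc.generate_trial(40, cfg)
    _, scores = pp.palatability_exclusions(tables["ratings"], tables["items"])
    scores = scores.merge(tables["participants"][["id", "group"]],
                          left_on="participant_id", right_on="id").drop(columns="id")
    plan = pp.weight_missingness_policy(tables["weights"])
    _, weights = pp.weight_exclusions(tables["weights"], plan)
    weights = weights.merge(tables["participants"][["id", "group"]],
                            left_on="participant_id", right_on="id").drop(columns="id")
    return sa.run_confirmatory(scores, weights, plan.weight_design,
                               rng=np.random.default_rng(0))


def test_confirmatory_detects_planted_rating_effects(planted_report):
    assert planted_report["h1"]["triple_interaction"]["p"] < 0.05
    assert planted_report["h1a"]["interaction"]["p"] < 0.05
    exp = planted_report["h1a"]["deltas"]["experimental"]
    assert exp["ci"][0] <= -5.0 <= exp["ci"][1]


def test_confirmatory_null_weight_reports_bf01(planted_report):
    contrasts = planted_report["h2"]["contrasts"]
    assert contrasts  # at least the pre/post contrast ran
    for entry in contrasts.values():
        if entry["interaction"]["p"] > 0.05:
            assert entry.get("bf01", 0) > 0


def test_confirmatory_gates_mediation_on_null_weights(planted_report):
    assert planted_report["h3"]["performed"] is False
    assert "not performed" in planted_report["h3"]["reason"]


def test_confirmatory_report_renders(planted_report):
    from foodict import report as rp

    md = rp.render(planted_report, "md")
    assert "Palatability" in md and "Weight" in md
    csv = rp.render(planted_report, "csv")
    assert "contrast" in csv
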