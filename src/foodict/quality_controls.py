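"""Positive controls and quality checks.

Four checks guard the trial's causal interpretation: (1) baseline balance
of demographics and pre-intervention ratings between arms (Cohen's
d < 0.3); (2) balance of the game-experience global index, with iterative
participant removal if unbalanced; (3) the items-liking check that
trained items really are liked (d > 0.3 against the scale midpoint of
50); and (4) expectancy blinding, measured by the phi coefficient of the
2x2 group-by-expectancy contingency tables, brought below 0.2 by
removing (or replacing) participants from the most divergent cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_cohort import GEQ_COMPONENTS, GEQ_REVERSED

PHI_THRESHOLD = 0.2
BALANCE_THRESHOLD = 0.3
GEQ_ITEM_MAX = 4
FISHER_MIN_CELL = 5


class BalanceError(RuntimeError):
    """A balancing criterion that cannot be satisfied."""


def cohens_d(x, y) -> float:
    """Two-sample Cohen's d with the df-pooled (unbiased-variance) SD."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 values per group")
    sp2 = ((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1)) / (
        len(x) + len(y) - 2
    )
    if sp2 == 0:
        raise ValueError("zero pooled variance")
    return float((x.mean() - y.mean()) / math.sqrt(sp2))


def cohens_d_from_stats(m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int) -> float:
    """Cohen's d from printed summary statistics."""
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    if sp2 == 0:
        raise ValueError("zero pooled variance")
    return float((m1 - m2) / math.sqrt(sp2))


def one_sample_d(x, reference: float) -> float:
    x = np.asarray(x, float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance")
    return float((x.mean() - reference) / sd)


def baseline_balance(
    participants: pd.DataFrame,
    pre_scores: pd.DataFrame | None = None,
    threshold: float = BALANCE_THRESHOLD,
) -> pd.DataFrame:
    """Standardized baseline differences between the two arms.

    Covers BMI, age and the gender ratio (standardized proportion
    difference), plus -- when a pre-intervention score table
    (participant_id, category, rating) is supplied -- the trained healthy
    and unhealthy ratings. A variable passes when |d| < threshold.
    """
    exp = participants[participants["group"] == "experimental"]
    ctl = participants[participants["group"] == "control"]
    rows = []
    for var in ("bmi", "age"):
        d = cohens_d(exp[var], ctl[var])
        rows.append({"variable": var, "d": d, "passed": abs(d) < threshold})
    p1 = (exp["gender"] == "F").mean()
    p2 = (ctl["gender"] == "F").mean()
    pooled = (exp["gender"] == "F").sum() + (ctl["gender"] == "F").sum()
    pbar = pooled / (len(exp) + len(ctl))
    d_gender = float((p1 - p2) / math.sqrt(pbar * (1 - pbar))) if 0 < pbar < 1 else 0.0
    rows.append({"variable": "gender_ratio", "d": d_gender,
                 "passed": abs(d_gender) < threshold})
    if pre_scores is not None:
        merged = pre_scores.merge(
            participants[["id", "group"]], left_on="participant_id", right_on="id"
        )
        for cat in ("healthy", "unhealthy"):
            sub = merged[merged["category"] == cat]
            d = cohens_d(
                sub.loc[sub["group"] == "experimental", "rating"],
                sub.loc[sub["group"] == "control", "rating"],
            )
            rows.append({"variable": f"trained_{cat}_rating", "d": d,
                         "passed": abs(d) < threshold})
    return pd.DataFrame(rows)


def geq_scores(
    responses: pd.DataFrame,
    component_map: dict[str, list[str]] = GEQ_COMPONENTS,
    reversed_components: tuple[str, ...] = GEQ_REVERSED,
) -> pd.DataFrame:
    """Game Experience Questionnaire component and global scores.

    Components are sums of their 0-4 Likert items; tension/annoyance and
    negative affect are reversed item-wise (4 - raw) so that a higher
    score always reads as a better experience. The global index is the
    sum of the six component scores.
    """
    out = pd.DataFrame({"participant_id": responses["participant_id"]})
    for comp, item_ids in component_map.items():
        for item in item_ids:
            if item not in responses.columns:
                raise ValueError(f"missing questionnaire item: {item}")
            if responses[item].isna().any():
                raise ValueError(f"missing responses for item: {item}")
        block = responses[item_ids]
        if comp in reversed_components:
            block = GEQ_ITEM_MAX - block
        out[comp] = block.sum(axis=1)
    out["global"] = out[list(component_map)].sum(axis=1)
    return out


def balance_by_exclusion(
    values: pd.Series,
    groups: pd.Series,
    mode: str,
    threshold: float = BALANCE_THRESHOLD,
    reference: float = 50.0,
    min_group_size: int = 10,
) -> list:
    """Iterative participant removal until a balance criterion holds.

    mode="balance" (game-experience check): while the between-group
    |d| >= threshold, remove the participant whose value lies farthest
    from the pooled median.
    mode="diverge" (items-liking check): while the pooled one-sample
    |d| vs the scale midpoint is <= threshold, remove the participant
    whose value is closest to the midpoint.

    Returns the ordered list of removed ids; raises
    :class:`BalanceError` when a group would shrink below
    ``min_group_size`` with the criterion still unmet.
    """
    if mode not in ("balance", "diverge"):
        raise ValueError("mode must be 'balance' or 'diverge'")
    values = values.copy().astype(float)
    groups = groups.loc[values.index]
    removed = []
    glevels = sorted(groups.unique())

    def criterion_met() -> bool:
        if mode == "balance":
            d = cohens_d(values[groups == glevels[0]], values[groups == glevels[1]])
            return abs(d) < threshold
        return abs(one_sample_d(values, reference)) > threshold

    while True:
        try:
            if criterion_met():
                return removed
        except ValueError as exc:  # zero variance: degenerate input
            raise BalanceError(f"criterion cannot be evaluated: {exc}") from exc
        if any((groups == g).sum() <= min_group_size for g in glevels):
            raise BalanceError(
                "minimum group size reached before the criterion was met"
            )
        if mode == "balance":
            med = values.median()
            worst = (values - med).abs().idxmax()
        else:
            worst = (values - reference).abs().idxmin()
        removed.append(worst)
        values = values.drop(worst)
        groups = groups.drop(worst)


def phi_coefficient(table) -> float:
    """phi = (ad - bc) / sqrt of the product of the four margins, for a
    2x2 contingency table [[a, b], [c, d]]."""
    t = np.asarray(table, float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of nonnegative counts")
    a, b = t[0]
    c, d = t[1]
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        raise ValueError("zero margin: phi undefined")
    return float((a * d - b * c) / math.sqrt(margins))


@dataclass(frozen=True)
class MatchAction:
    step: int
    action: str  # "remove" | "replace"
    participant_id: str
    cell: tuple[int, int]
    phi_before: float
    phi_after: float


def _table_from_assignments(groups: pd.Series, values: pd.Series, glevels) -> np.ndarray:
    return np.array(
        [
            [
                int(((groups == g) & (values == v)).sum())
                for v in (1, 0)
            ]
            for g in glevels
        ]
    )


def expectancy_match(
    assignments: pd.DataFrame,
    mode: str = "remove",
    rng: np.random.Generator | None = None,
    base_rate: dict[str, float] | None = None,
    threshold: float = PHI_THRESHOLD,
    min_group_size: int = 10,
    value_col: str = "value",
) -> tuple[list[MatchAction], float, pd.DataFrame]:
    """Brute-force expectancy balancing.

    While the group x expectancy phi exceeds the threshold, the cell
    whose count most exceeds its independence-expected count is
    identified (ties broken by the smallest cell index) and one uniformly
    random participant is removed from it -- or, in replace mode, kept
    but redrawn at the group's configured base expectancy rate. All
    actions are logged; the final assignment table is returned alongside.
    """
    if mode not in ("remove", "replace"):
        raise ValueError("mode must be 'remove' or 'replace'")
    if mode == "replace" and base_rate is None:
        raise ValueError("replace mode needs per-group base rates")
    rng = rng or np.random.default_rng()
    df = assignments.copy().reset_index(drop=True)
    glevels = sorted(df["group"].unique())
    actions: list[MatchAction] = []
    step = 0
    max_steps = 10 * len(df)  # replace mode is stochastic; cap the loop

    while True:
        if step > max_steps:
            raise BalanceError("expectancy matching failed to converge")
        table = _table_from_assignments(df["group"], df[value_col], glevels)
        phi = phi_coefficient(table)
        if abs(phi) <= threshold:
            return actions, phi, df
        if any((df["group"] == g).sum() <= min_group_size for g in glevels):
            raise BalanceError(
                f"minimum group size reached with phi still {phi:.3f} > {threshold}"
            )
        expected = table.sum(axis=1, keepdims=True) * table.sum(axis=0) / table.sum()
        divergence = (table - expected).ravel()
        # ties (exact up to roundoff) break toward the smallest cell index
        idx = int(np.argmax(divergence > divergence.max() - 1e-9))
        cell = np.unravel_index(idx, (2, 2))
        g = glevels[cell[0]]
        v = (1, 0)[cell[1]]
        pool = df[(df["group"] == g) & (df[value_col] == v)]
        pick = pool.index[rng.integers(0, len(pool))]
        pid = df.loc[pick, "participant_id"]
        if mode == "remove":
            df = df.drop(pick)
        else:
            df.loc[pick, value_col] = int(rng.random() < base_rate[g])
        new_phi = phi_coefficient(
            _table_from_assignments(df["group"], df[value_col], glevels)
        )
        actions.append(
            MatchAction(step, mode, pid, (int(cell[0]), int(cell[1])), phi, new_phi)
        )
        step += 1


def association_test(table) -> tuple[float, float, str]:
    """Group-expectancy association, reported descriptively: Fisher's
    exact test when any cell count is below 5, otherwise the chi-squared
    test without continuity correction (so that chi2 = n * phi^2)."""
    t = np.asarray(table, float)
    if t.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if (t < FISHER_MIN_CELL).any():
        odds, p = stats.fisher_exact(t)
        return float(odds), float(p), "fisher"
    chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(chi2), float(p), "chi2"
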