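"""Simulation-based power analysis for the trial's mixed factorial
designs, plus the closed-form mediation sample size.

Procedure (per hypothesis): fix the smallest effect of interest and the
between-/within-subject variance components; simulate many datasets per
candidate sample size from the same generative model the synthetic cohort
uses (pre = mu + b_i, later sessions = pre + delta + eps); fit the mixed
ANOVA and record the fraction of interaction p-values below alpha; report
the smallest per-group n reaching the target power. The candidate grid
(20..60 by 10) is refined by integer bisection between the bracketing
grid points, since the power crossing generally falls off-grid.

The interaction tests are computed with closed-form equivalents of the
mixed-ANOVA F (vectorized across replicates): for the 2 x 2 and 2 x 2 x 2
designs the interaction F is the squared two-sample t on (difference of)
change scores; for the 2 x 4 design the full repeated-measures F is
computed from its sums of squares. Each equivalence to the
``stats_analysis`` engine is asserted in the test suite.

Every evaluated sample size uses an RNG seeded from (seed, n), so power
estimates -- and hence the minimal n -- do not depend on which grid the
scan started from.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DESIGNS = ("S2x2", "S2x2x2", "S2x4")


@dataclass(frozen=True)
class MediationPowerParams:
    """Inputs of the closed-form mediation sample size: the smallest
    mediator-outcome slope of interest b2, the SD of the mediator change,
    the SD of the outcome error, and the exposure-outcome correlation."""

    b2: float = 0.1
    sigma_m: float = 7.0
    sigma_e: float = 1.0
    rho: float = 0.3
    alpha: float = 0.05
    power: float = 0.9

    def __post_init__(self) -> None:
        if self.sigma_m <= 0 or self.sigma_e <= 0:
            raise ValueError("sigma_m and sigma_e must be > 0")
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be < 1")


@dataclass
class PowerSpec:
    """One simulation-based power analysis.

    ``effects`` maps each group to its within-cell mean offsets:
    - S2x2: a single post - pre change (floats);
    - S2x2x2: a (healthy, unhealthy) pair of changes;
    - S2x4: a length-4 offset profile over (pre, post, m1, m4).
    Unlisted groups default to zero effects.
    """

    design: str
    between_sd: float
    change_sd: float
    effects: dict[str, tuple[float, ...] | float] = field(default_factory=dict)
    alpha: float = 0.05
    target_power: float = 0.9
    n_grid: tuple[int, ...] = (20, 30, 40, 50, 60)
    reps: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.design not in DESIGNS:
            raise ValueError(f"design must be one of {DESIGNS}")
        if not 0 < self.alpha < 1 or not 0 < self.target_power < 1:
            raise ValueError("alpha and target_power must be in (0,1)")
        if self.reps < 100:
            raise ValueError("reps must be >= 100")
        if self.between_sd <= 0 or self.change_sd <= 0:
            raise ValueError("SDs must be > 0")


def h1_spec(**kw) -> PowerSpec:
    """Triple interaction on ratings: -5 unhealthy / +5 healthy points of
    change in the experimental arm, SDs 15 (between) and 7 (change)."""
    return PowerSpec("S2x2x2", 15.0, 7.0,
                     {"experimental": (5.0, -5.0), "control": (0.0, 0.0)}, **kw)


def h1a_spec(**kw) -> PowerSpec:
    """Group x session on unhealthy ratings alone: -5 points change."""
    return PowerSpec("S2x2", 15.0, 7.0,
                     {"experimental": -5.0, "control": 0.0}, **kw)


def h1b_spec(**kw) -> PowerSpec:
    """Group x session on healthy ratings alone: +5 points change
    (assumed symmetric to the unhealthy decrease)."""
    return PowerSpec("S2x2", 15.0, 7.0,
                     {"experimental": 5.0, "control": 0.0}, **kw)


def h2_spec(**kw) -> PowerSpec:
    """Group x session on weight over four sessions: 1 kg lost by post
    and maintained, SDs 10 kg (between) and 1 kg (per measurement)."""
    return PowerSpec("S2x4", 10.0, 1.0,
                     {"experimental": (0.0, -1.0, -1.0, -1.0),
                      "control": (0.0, 0.0, 0.0, 0.0)}, **kw)


def _effect_arrays(spec: PowerSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-group effect arrays for (experimental, control) in a canonical
    cell order."""
    def get(group):
        eff = spec.effects.get(group, 0.0)
        if spec.design == "S2x2":
            return np.array([float(eff) if np.isscalar(eff) else float(eff[0])])
        arr = np.asarray(eff, float)
        want = 2 if spec.design == "S2x2x2" else 4
        if np.isscalar(eff) or arr.ndim == 0:
            arr = np.full(want, float(eff))
        if arr.shape != (want,):
            raise ValueError(f"effects for {group!r} must have length {want}")
        return arr

    return get("experimental"), get("control")


def simulate_dataset(
    spec: PowerSpec, n_per_group: int, rng: np.random.Generator
) -> pd.DataFrame:
    """One tidy cell-level dataset, consumable by
    ``stats_analysis.mixed_anova``."""
    batch = _simulate_batch(spec, n_per_group, 1, rng)
    n = 2 * n_per_group
    groups = np.array(["experimental"] * n_per_group + ["control"] * n_per_group)
    rows = []
    if spec.design == "S2x2":
        pre, post = batch["pre"][0], batch["post"][0]
        for i in range(n):
            rows.append((f"S{i:04d}", groups[i], "pre", pre[i]))
            rows.append((f"S{i:04d}", groups[i], "post", post[i]))
        return pd.DataFrame(rows, columns=["participant_id", "group", "session", "value"])
    if spec.design == "S2x2x2":
        pre, post = batch["pre"][0], batch["post"][0]  # (n, 2) healthy/unhealthy
        cats = ("healthy", "unhealthy")
        for i in range(n):
            for ci, c in enumerate(cats):
                rows.append((f"S{i:04d}", groups[i], "pre", c, pre[i, ci]))
                rows.append((f"S{i:04d}", groups[i], "post", c, post[i, ci]))
        return pd.DataFrame(
            rows, columns=["participant_id", "group", "session", "category", "value"]
        )
    y = batch["y"][0]  # (n, 4)
    tps = ("pre", "post", "m1", "m4")
    for i in range(n):
        for ti, t in enumerate(tps):
            rows.append((f"S{i:04d}", groups[i], t, y[i, ti]))
    return pd.DataFrame(rows, columns=["participant_id", "group", "timepoint", "value"])


def _simulate_batch(
    spec: PowerSpec, n_per_group: int, reps: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Vectorized batch of replicate datasets.

    S2x2 / S2x2x2: pre = mu + b_i (b_i shared across food-type cells);
    post = pre + delta + eps with eps drawn per cell.
    S2x4: session value = (mu + b_i) + offset_t + eps_t per measurement.
    """
    n = 2 * n_per_group
    eff_exp, eff_ctl = _effect_arrays(spec)
    delta = np.concatenate(
        [np.tile(eff_exp, (n_per_group, 1)), np.tile(eff_ctl, (n_per_group, 1))]
    )  # (n, cells)
    b = rng.normal(0.0, spec.between_sd, (reps, n, 1))
    if spec.design in ("S2x2", "S2x2x2"):
        ncell = delta.shape[1]
        pre = b + np.zeros((reps, n, ncell))
        eps = rng.normal(0.0, spec.change_sd, (reps, n, ncell))
        post = pre + delta[None] + eps
        if spec.design == "S2x2":
            return {"pre": pre[..., 0], "post": post[..., 0]}
        return {"pre": pre, "post": post}
    eps = rng.normal(0.0, spec.change_sd, (reps, n, 4))
    y = b + delta[None] + eps
    return {"y": y}


def _p_two_sample(scores: np.ndarray, n_per_group: int) -> np.ndarray:
    """Vectorized pooled two-sample t-test p-values; scores (reps, N) with
    the first n subjects in one group. Equals the mixed-ANOVA interaction
    test (F = t^2) on these per-subject contrast scores."""
    a, b = scores[:, :n_per_group], scores[:, n_per_group:]
    na, nb = a.shape[1], b.shape[1]
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    t = (a.mean(axis=1) - b.mean(axis=1)) / np.sqrt(sp2 * (1 / na + 1 / nb))
    return stats.f.sf(t**2, 1, na + nb - 2)


def _p_rm_interaction(y: np.ndarray, n_per_group: int) -> np.ndarray:
    """Vectorized group x session interaction p of the balanced two-group
    repeated-measures ANOVA; y is (reps, N, T)."""
    reps, N, T = y.shape
    n = n_per_group
    m = y.mean(axis=(1, 2), keepdims=True)
    m_i = y.mean(axis=2, keepdims=True)
    m_t = y.mean(axis=1, keepdims=True)
    g = np.repeat([0, 1], n)
    m_g = np.stack([y[:, g == 0].mean(axis=(1, 2)), y[:, g == 1].mean(axis=(1, 2))], axis=1)
    m_gt = np.stack([y[:, g == 0].mean(axis=1), y[:, g == 1].mean(axis=1)], axis=1)
    ss_int = n * ((m_gt - m_g[:, :, None] - m_t + m) ** 2).sum(axis=(1, 2))
    resid = y - m_gt[:, g, :] - m_i + m_g[:, g, None]
    ss_err = (resid**2).sum(axis=(1, 2))
    df1, df2 = T - 1, (N - 2) * (T - 1)
    F = (ss_int / df1) / (ss_err / df2)
    return stats.f.sf(F, df1, df2)


def interaction_pvalues(
    spec: PowerSpec, n_per_group: int, reps: int, rng: np.random.Generator
) -> np.ndarray:
    """p-values of the target interaction for ``reps`` simulated datasets."""
    batch = _simulate_batch(spec, n_per_group, reps, rng)
    if spec.design == "S2x2":
        change = batch["post"] - batch["pre"]
        return _p_two_sample(change, n_per_group)
    if spec.design == "S2x2x2":
        change = batch["post"] - batch["pre"]  # (reps, n, 2) healthy/unhealthy
        dd = change[..., 0] - change[..., 1]
        return _p_two_sample(dd, n_per_group)
    return _p_rm_interaction(batch["y"], n_per_group)


@dataclass
class PowerCurve:
    """Power per sample size with Monte Carlo standard errors."""

    points: dict[int, tuple[float, float]]
    reps: int
    alpha: float

    def power(self, n: int) -> float:
        return self.points[n][0]


def _power_at(spec: PowerSpec, n: int, reps: int) -> tuple[float, float]:
    # per-n seeding: estimates are independent of the evaluation order
    rng = np.random.default_rng([spec.seed, n])
    p = interaction_pvalues(spec, n, reps, rng)
    power = float((p < spec.alpha).mean())
    return power, math.sqrt(max(power * (1 - power), 1e-12) / reps)


def estimate_power(spec: PowerSpec, n_grid: tuple[int, ...] | None = None) -> PowerCurve:
    """Estimated power at each grid sample size (per group)."""
    grid = tuple(n_grid or spec.n_grid)
    if spec.reps * (1 - spec.target_power) < 50:
        warnings.warn("reps may be too small for the requested precision")
    return PowerCurve(
        points={n: _power_at(spec, n, spec.reps) for n in grid},
        reps=spec.reps,
        alpha=spec.alpha,
    )


def minimal_n(
    spec: PowerSpec,
    target_power: float | None = None,
    return_curve: bool = False,
) -> int | tuple[int, PowerCurve]:
    """Smallest per-group n whose estimated power reaches the target.

    Scans the coarse grid, then bisects on integers between the bracketing
    grid points at full replicate count.
    """
    target = spec.target_power if target_power is None else target_power
    curve = estimate_power(spec)
    grid = sorted(curve.points)
    above = [n for n in grid if curve.points[n][0] >= target]
    if not above:
        best = max(p for p, _ in curve.points.values())
        raise ValueError(
            f"target power {target} unreachable on grid "
            f"(max achieved {best:.3f} at n={grid[-1]})"
        )
    hi = min(above)
    below = [n for n in grid if n < hi]
    lo = max(below) if below else max(1, grid[0] - 1)
    if not below:
        # extend the bracket downward so off-grid minima below the grid
        # floor are still found
        lo = 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        power, se = _power_at(spec, mid, spec.reps)
        curve.points[mid] = (power, se)
        if power >= target:
            hi = mid
        else:
            lo = mid
    return (hi, curve) if return_curve else hi


def mediation_sample_size(params: MediationPowerParams, ceil: bool = True) -> float:
    """Closed-form total sample size for the mediation model:

    n = (z_{1-alpha/2} + z_{power})^2 * sigma_e^2
        / (b2^2 * sigma_m^2 * (1 - rho^2))
    """
    z_a = stats.norm.ppf(1 - params.alpha / 2)
    z_b = stats.norm.ppf(params.power)
    n = (z_a + z_b) ** 2 * params.sigma_e**2 / (
        params.b2**2 * params.sigma_m**2 * (1 - params.rho**2)
    )
    return int(math.ceil(n - 1e-12)) if ceil else float(n)
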