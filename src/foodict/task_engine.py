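"""Headless state machine for the gamified Go/NoGo (GNG) and Cue-Approach
Training (CAT) tasks.

The engine reproduces the behavioural contingencies of the intervention
without any rendering: trial scheduling with the biased (experimental) or
unbiased (control) stimulus-response mapping, response classification into
the hit / miss / false-alarm / correct-rejection / too-late taxonomy, the
18-level staircase that shrinks the response window, the two five-level
"life" gauges, scoring, and the cross-task power-up economy. Synthetic
responder agents (lognormal reaction times, configurable commission and
miss probabilities) drive it to produce training logs for the adherence
pipeline.

Difficulty semantics: for GNG the staircased parameter is the reaction
time threshold (RTT) itself; for CAT the table lists the response window
after cue onset (stimulus duration minus go-signal delay), which shrinks
as the level rises -- the only reading under which a higher level is
harder.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

GNG, CAT = "GNG", "CAT"
OUTCOMES = ("hit", "miss", "false_alarm", "correct_rejection", "too_late")

#: Staircase windows in seconds at levels 1-18 (strictly decreasing).
DIFFICULTY_TABLE: dict[str, tuple[float, ...]] = {
    GNG: (1.1, 1.0, 0.9, 0.8, 0.725, 0.675, 0.625, 0.575, 0.55, 0.525,
          0.5, 0.475, 0.4525, 0.43, 0.407, 0.387, 0.36, 0.33),
    CAT: (0.88, 0.81, 0.74, 0.67, 0.62, 0.57, 0.53, 0.49, 0.455, 0.42,
          0.39, 0.36, 0.335, 0.31, 0.29, 0.27, 0.26, 0.25),
}
N_LEVELS = 18

#: Successive successes needed for a promotion: six Go-or-NoGo successes
#: for GNG, three cued hits for CAT.
PROMOTION_THRESHOLD = {GNG: 6, CAT: 3}

#: Item-category mix per (group, trial condition); rows sum to 1.
CATEGORY_MAP: dict[tuple[str, str], dict[str, float]] = {
    ("experimental", "go"): {"healthy": 0.8, "unhealthy": 0.0, "neutral": 0.2},
    ("experimental", "nogo"): {"healthy": 0.0, "unhealthy": 0.8, "neutral": 0.2},
    ("control", "go"): {"healthy": 0.4, "unhealthy": 0.4, "neutral": 0.2},
    ("control", "nogo"): {"healthy": 0.4, "unhealthy": 0.4, "neutral": 0.2},
}

BASE_HIT_POINTS = 10  # multiplied by the current level
GAUGE_MAX = 5

POWERUPS = ("regeneration", "life_increase", "score_multiplier", "difficulty_decrease")
POWERUP_COST = {p: 100 for p in POWERUPS}
REGENERATION_PERIOD_MS = 20_000


class PowerupRejected(RuntimeError):
    """A power-up purchase or application that the shop refuses."""


@dataclass(frozen=True)
class TaskConfig:
    task: str
    go_rate: float
    stimulus_duration_ms: tuple[float, float]  # (lo, hi); lo == hi means fixed
    feedback_ms: float
    isi_ms: tuple[float, float]
    category_map: dict[tuple[str, str], dict[str, float]] = field(
        default_factory=lambda: CATEGORY_MAP
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.go_rate <= 1.0:
            raise ValueError("go_rate must be in [0,1]")
        for row in self.category_map.values():
            if abs(sum(row.values()) - 1.0) > 1e-9:
                raise ValueError(f"category map row does not sum to 1: {row}")

    @classmethod
    def gng(cls, go_rate: float = 0.70) -> "TaskConfig":
        return cls(GNG, go_rate, (1250.0, 1250.0), 250.0, (1000.0, 2000.0))

    @classmethod
    def cat(cls, go_rate: float = 0.25) -> "TaskConfig":
        # Shorter ISI than GNG: responses occur on only a quarter of trials.
        return cls(CAT, go_rate, (1000.0, 1500.0), 250.0, (800.0, 1300.0))


@dataclass(frozen=True)
class TrialSpec:
    task: str
    is_go: bool  # GNG Go / CAT cued
    item_category: str
    level: int
    stimulus_duration_ms: float
    window_ms: float
    isi_ms: float


@dataclass(frozen=True)
class TrialOutcome:
    kind: str
    rt_ms: float | None
    points: int


@dataclass(frozen=True)
class GameState:
    task: str
    level: int = 1
    success_count: int = 0
    speed_gauge: int = GAUGE_MAX
    accuracy_gauge: int = GAUGE_MAX
    speed_max: int = GAUGE_MAX
    accuracy_max: int = GAUGE_MAX
    score: int = 0
    score_multiplier: int = 1
    active_powerups: frozenset[str] = frozenset()
    game_over: bool = False


@dataclass(frozen=True)
class AgentParams:
    """Synthetic responder: lognormal RTs, lapse and commission rates."""

    rt_median_ms: float = 450.0
    rt_log_sd: float = 0.25
    commission_prob: float = 0.05
    miss_prob: float = 0.02

    def __post_init__(self) -> None:
        if not (0 <= self.commission_prob <= 1 and 0 <= self.miss_prob <= 1):
            raise ValueError("probabilities must be in [0,1]")


def difficulty_value(task: str, level: int) -> float:
    """Staircase window (seconds) at a given level: exact table lookup."""
    if task not in DIFFICULTY_TABLE:
        raise ValueError(f"unknown task {task!r}")
    if not 1 <= level <= N_LEVELS:
        raise ValueError(f"level must be in [1,{N_LEVELS}], got {level}")
    return DIFFICULTY_TABLE[task][level - 1]


def schedule_trial(
    group: str, config: TaskConfig, rng: np.random.Generator, level: int = 1
) -> TrialSpec:
    """Draw one trial: condition at the task's Go rate, item category from
    the group's mapping row, timings uniform in their configured ranges."""
    if group not in ("experimental", "control"):
        raise ValueError(f"unknown group {group!r}")
    is_go = bool(rng.random() < config.go_rate)
    row = config.category_map[(group, "go" if is_go else "nogo")]
    cats = list(row)
    category = str(rng.choice(cats, p=[row[c] for c in cats]))
    lo, hi = config.stimulus_duration_ms
    duration = float(lo if lo == hi else rng.uniform(lo, hi))
    window = difficulty_value(config.task, level) * 1000.0
    if config.task == CAT:
        window = min(window, duration)
    return TrialSpec(
        task=config.task,
        is_go=is_go,
        item_category=category,
        level=level,
        stimulus_duration_ms=duration,
        window_ms=window,
        isi_ms=float(rng.uniform(*config.isi_ms)),
    )


def classify_response(
    trial: TrialSpec, responded: bool, rt_ms: float | None = None
) -> TrialOutcome:
    """Map a (trial, response) pair onto the outcome taxonomy and award
    points.

    Go/cued trials: a response within the current window is a hit, a
    slower response is 'too late', no response is a miss. NoGo/uncued
    trials: any response is a false alarm, withholding is a correct
    rejection. Hits earn the base points times the level; a CAT correct
    rejection earns a third of the hit points, a design choice of the game
    meant to avoid building an attentional bias toward uncued items.
    """
    if responded and rt_ms is None:
        raise ValueError("rt_ms required when a response occurred")
    if not responded and rt_ms is not None:
        raise ValueError("rt_ms given without a response")
    if rt_ms is not None and rt_ms < 0:
        raise ValueError("rt_ms must be >= 0")

    hit_points = BASE_HIT_POINTS * trial.level
    if trial.is_go:
        if not responded:
            return TrialOutcome("miss", None, 0)
        if rt_ms <= trial.window_ms:
            return TrialOutcome("hit", rt_ms, hit_points)
        return TrialOutcome("too_late", rt_ms, 0)
    if responded:
        return TrialOutcome("false_alarm", rt_ms, 0)
    points = hit_points // 3 if trial.task == CAT else 0
    return TrialOutcome("correct_rejection", None, points)


def _is_success(task: str, kind: str) -> bool:
    if kind == "hit":
        return True
    return task == GNG and kind == "correct_rejection"


def update_difficulty(state: GameState, outcome: TrialOutcome) -> GameState:
    """Advance the staircase: consecutive successes (GNG: hits and correct
    rejections; CAT: cued hits only) promote after the task's threshold;
    any error resets the streak; level capped at 18. A CAT correct
    rejection neither counts nor resets."""
    if _is_success(state.task, outcome.kind):
        count = state.success_count + 1
        if count >= PROMOTION_THRESHOLD[state.task]:
            return replace(state, level=min(N_LEVELS, state.level + 1), success_count=0)
        return replace(state, success_count=count)
    if outcome.kind in ("miss", "false_alarm", "too_late"):
        return replace(state, success_count=0)
    return state


def update_gauges(state: GameState, outcome: TrialOutcome) -> GameState:
    """Apply the two-gauge life system: 'too late' drains the speed gauge,
    misses and false alarms drain the accuracy gauge; an empty gauge ends
    the run."""
    if state.game_over:
        raise ValueError("cannot update gauges of a finished run")
    speed, acc = state.speed_gauge, state.accuracy_gauge
    if outcome.kind == "too_late":
        speed -= 1
    elif outcome.kind in ("miss", "false_alarm"):
        acc -= 1
    return replace(
        state,
        speed_gauge=speed,
        accuracy_gauge=acc,
        game_over=(speed == 0 or acc == 0),
    )


def apply_score(state: GameState, outcome: TrialOutcome) -> GameState:
    return replace(state, score=state.score + outcome.points * state.score_multiplier)


def buy_powerup(task: str, powerup: str, wallet: dict[str, int]) -> dict[str, int]:
    """Spend currency on a power-up for ``task``.

    Currency is task-specific and power-ups for one task can only be paid
    with the *other* task's currency, forcing balanced practice.
    """
    if powerup not in POWERUPS:
        raise ValueError(f"unknown power-up {powerup!r}")
    other = CAT if task == GNG else GNG
    cost = POWERUP_COST[powerup]
    if wallet.get(other, 0) < cost:
        raise PowerupRejected(
            f"power-ups for {task} cost {cost} {other} currency; "
            f"wallet has {wallet.get(other, 0)}"
        )
    new = dict(wallet)
    new[other] -= cost
    return new


def apply_powerup(state: GameState, powerup: str) -> GameState:
    """Apply an owned power-up to the running game."""
    if powerup == "difficulty_decrease":
        return replace(state, level=max(1, state.level - 2))
    if powerup == "life_increase":
        # two supplementary gauge levels, granted at run start
        return replace(
            state,
            speed_max=state.speed_max + 2,
            accuracy_max=state.accuracy_max + 2,
            speed_gauge=state.speed_gauge + 2,
            accuracy_gauge=state.accuracy_gauge + 2,
        )
    if powerup == "score_multiplier":
        return replace(state, score_multiplier=2,
                       active_powerups=state.active_powerups | {powerup})
    if powerup == "regeneration":
        return replace(state, active_powerups=state.active_powerups | {powerup})
    raise ValueError(f"unknown power-up {powerup!r}")


def regeneration_tick(state: GameState) -> GameState:
    """One 20 s regeneration tick: both gauges up one level, capped."""
    return replace(
        state,
        speed_gauge=min(state.speed_max, state.speed_gauge + 1),
        accuracy_gauge=min(state.accuracy_max, state.accuracy_gauge + 1),
    )


@dataclass
class SessionLog:
    participant: str
    day: int
    task: str
    minutes: float
    max_level: int
    n_trials: int
    n_game_overs: int
    trials: list[dict]

    def to_jsonl(self) -> str:
        return "\n".join(json.dumps(t) for t in self.trials)


def run_session(
    agent: AgentParams,
    group: str,
    task: str,
    duration_min: float,
    rng: np.random.Generator,
    config: TaskConfig | None = None,
    participant: str = "agent",
    day: int = 1,
) -> SessionLog:
    """Simulate one training session of ``duration_min`` minutes.

    The agent responds to Go/cued trials with lognormal latency (missing
    with ``miss_prob``) and commits on NoGo/uncued trials with
    ``commission_prob``. Runs restart at level 1 with full gauges after a
    game over; the log records every trial with its level, outcome and
    reward.
    """
    if duration_min <= 0:
        raise ValueError("duration_min must be > 0")
    config = config or (TaskConfig.gng() if task == GNG else TaskConfig.cat())
    state = GameState(task=task)
    clock_ms = 0.0
    budget_ms = duration_min * 60_000.0
    trials: list[dict] = []
    max_level = 1
    n_game_overs = 0
    regen_elapsed = 0.0

    while clock_ms < budget_ms:
        trial = schedule_trial(group, config, rng, state.level)
        if trial.is_go:
            responded = not (rng.random() < agent.miss_prob)
        else:
            responded = bool(rng.random() < agent.commission_prob)
        rt = None
        if responded:
            rt = float(agent.rt_median_ms * np.exp(rng.normal(0.0, agent.rt_log_sd)))
            # GNG stimuli vanish at offset; a response cannot come later.
            rt = min(rt, trial.stimulus_duration_ms)
        outcome = classify_response(trial, responded, rt)
        state = update_difficulty(state, outcome)
        state = update_gauges(state, outcome)
        state = apply_score(state, outcome)
        max_level = max(max_level, state.level)
        trials.append(
            {
                "participant": participant,
                "day": day,
                "task": task,
                "level": trial.level,
                "trial_type": "go" if trial.is_go else "nogo",
                "item_category": trial.item_category,
                "outcome": outcome.kind,
                "rt_ms": None if rt is None else round(rt, 1),
                "points": outcome.points,
                "timestamp_ms": round(clock_ms, 1),
            }
        )
        shown = rt if rt is not None else trial.stimulus_duration_ms
        step = shown + config.feedback_ms + trial.isi_ms
        clock_ms += step
        if "regeneration" in state.active_powerups:
            regen_elapsed += step
            while regen_elapsed >= REGENERATION_PERIOD_MS:
                state = regeneration_tick(state)
                regen_elapsed -= REGENERATION_PERIOD_MS
        if state.game_over:
            n_game_overs += 1
            state = GameState(task=task)

    return SessionLog(
        participant=participant,
        day=day,
        task=task,
        minutes=duration_min,
        max_level=max_level,
        n_trials=len(trials),
        n_game_overs=n_game_overs,
        trials=trials,
    )


def write_jsonl(logs: Iterable[SessionLog], path) -> None:
    with open(path, "w") as fh:
        for log in logs:
            for t in log.trials:
                fh.write(json.dumps(t) + "\n")
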