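"""Generative model of the two-stage Markov decision task.

A trial consists of a first-stage choice between two pictures (``x``/``y``,
coded 0/1) in state A, a probabilistic transition to one of two second-stage
states (B/C, coded 0/1), a second-stage choice between two pictures, and an
outcome at one of three levels (1 = low, 2 = medium, 3 = high) that maps to a
juice amount.  The transition structure is fixed: action 0 leads to state B
with probability ``p_common`` (0.7 by default) and action 1 to state C; the
minority successor is the "rare" transition.

Each of the four second-stage options carries an independent outcome-level
schedule: the level dwells for a uniformly drawn 5-9 trials and is then redrawn
uniformly over the three levels (so it stays with probability 1/3).  High and
medium levels pay juice from non-overlapping duration windows with a clipped
Gaussian drift; the low level pays nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

N_FIRST_ACTIONS = 2
N_SECOND_ACTIONS = 2
N_SECOND_STATES = 2
LEVELS = (1, 2, 3)  # low, medium, high

ERROR_CODES = (
    "no-choice",
    "no-fixation",
    "fixation-break",
    "early-joystick",
    "joystick-not-centred",
    "wrong-location",
)


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the task environment.

    Reward windows are (lo, hi) juice durations in ms per outcome level; the
    defaults follow subject C's profile (high 682-962 ms with 200 ms drift SD,
    medium 117-390 ms with 100 ms drift SD, low = 0).  ``delay_ms`` records the
    extra pre-juice delay per level; it is informational only and plays no role
    in valuation.
    """

    p_common: float = 0.7
    dwell_min: int = 5
    dwell_max: int = 9
    p_stay_level: float = 1.0 / 3.0
    forced_rate: float = 0.15
    error_rate: float = 0.0
    reward_window_high: tuple[float, float] = (682.0, 962.0)
    reward_window_medium: tuple[float, float] = (117.0, 390.0)
    drift_sd_high: float = 200.0
    drift_sd_medium: float = 100.0
    delay_ms: tuple[float, float, float] = (2500.0, 750.0, 0.0)  # low, med, high
    n_first_actions: int = 2
    n_second_actions: int = 2

    def __post_init__(self) -> None:
        if not (0.5 < self.p_common <= 1.0):
            raise ValueError(f"p_common must lie in (0.5, 1], got {self.p_common}")
        if self.dwell_min > self.dwell_max:
            raise ValueError("dwell_min must not exceed dwell_max")
        if self.dwell_min < 1:
            raise ValueError("dwell_min must be >= 1")
        lo_m, hi_m = self.reward_window_medium
        lo_h, hi_h = self.reward_window_high
        if not (0 <= lo_m < hi_m and lo_m < hi_m <= lo_h < hi_h):
            raise ValueError("reward windows must be ordered and non-overlapping")
        if not (0.0 <= self.forced_rate <= 1.0 and 0.0 <= self.error_rate <= 1.0):
            raise ValueError("rates must be probabilities")

    def window(self, level: int) -> tuple[float, float]:
        if level == 3:
            return self.reward_window_high
        if level == 2:
            return self.reward_window_medium
        return (0.0, 0.0)

    def drift_sd(self, level: int) -> float:
        return {3: self.drift_sd_high, 2: self.drift_sd_medium, 1: 0.0}[level]

    def common_successor(self, a1: int) -> int:
        # fixed mapping kept throughout the experiment: action 0 -> B, 1 -> C
        return a1

    def to_yaml(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "TaskConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("reward_window_high", "reward_window_medium", "delay_ms"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


# Subject J's printed windows, for convenience when emulating the second animal.
SUBJECT_J_CONFIG = TaskConfig(
    reward_window_high=(976.0, 1257.0),
    reward_window_medium=(507.0, 826.0),
    delay_ms=(4000.0, 1500.0, 0.0),
)


@dataclass
class OutcomeSchedule:
    """Latent outcome-level walks for the four second-stage options.

    ``levels`` has shape (n_trials, 2 states, 2 actions) with entries in
    {1, 2, 3}; ``juice_ms`` the matching realized durations; ``segments`` the
    per-option trial indices at which the level was (re)drawn.
    """

    levels: np.ndarray
    juice_ms: np.ndarray
    segments: list[list[int]]

    @property
    def n_trials(self) -> int:
        return self.levels.shape[0]


def sample_outcome_schedule(
    config: TaskConfig, n_trials: int, rng: np.random.Generator
) -> OutcomeSchedule:
    """Sample the dwell-then-redraw outcome process for every option.

    At every (re)draw the level is uniform over the three levels, so it stays
    with probability 1/3, and a fresh dwell length (uniform on
    ``[dwell_min, dwell_max]``) is drawn -- including after a same-level
    continuation.  Juice durations follow a Gaussian random walk inside the
    level's window, clipped at the window edges; the low level pays 0.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    levels = np.empty((n_trials, N_SECOND_STATES, N_SECOND_ACTIONS), dtype=np.int64)
    juice = np.zeros_like(levels, dtype=np.float64)
    segments: list[list[int]] = []
    for s in range(N_SECOND_STATES):
        for a in range(N_SECOND_ACTIONS):
            bounds: list[int] = []
            t = 0
            level = int(rng.integers(1, 4))
            while t < n_trials:
                bounds.append(t)
                dwell = int(rng.integers(config.dwell_min, config.dwell_max + 1))
                lo, hi = config.window(level)
                sd = config.drift_sd(level)
                if level == 1:
                    ms = 0.0
                else:
                    ms = float(rng.uniform(lo, hi))
                for _ in range(dwell):
                    if t >= n_trials:
                        break
                    levels[t, s, a] = level
                    juice[t, s, a] = ms
                    if level != 1:
                        ms = float(np.clip(ms + rng.normal(0.0, sd), lo, hi))
                    t += 1
                level = int(rng.integers(1, 4))  # uniform redraw incl. stays
            segments.append(bounds)
    return OutcomeSchedule(levels=levels, juice_ms=juice, segments=segments)


def transition_step(
    a1: int, config: TaskConfig, rng: np.random.Generator
) -> tuple[int, str]:
    """Draw the second-stage state for first-stage action ``a1``.

    Returns ``(s2, label)`` where the label is "common" iff ``s2`` is the
    majority successor of ``a1``.
    """
    if a1 not in (0, 1):
        raise ValueError(f"invalid first-stage action {a1}")
    major = config.common_successor(a1)
    if rng.random() < config.p_common:
        return major, "common"
    return 1 - major, "rare"


@dataclass
class TrialRecord:
    """One trial of a session; error trials may leave downstream fields None."""

    session_id: str
    trial_index: int
    forced_stage: int = 0  # 0 = free, 1/2 = forced at that stage
    error_code: Optional[str] = None
    a1: Optional[int] = None
    s2: Optional[int] = None
    transition: Optional[str] = None
    a2: Optional[int] = None
    outcome_level: Optional[int] = None
    juice_ms: Optional[float] = None
    rt1: Optional[float] = None
    rt2: Optional[float] = None
    fix_rt: Optional[float] = None
    side1: Optional[int] = None
    side2: Optional[int] = None
    forced_option1: Optional[int] = None
    forced_option2: Optional[int] = None

    @property
    def is_error(self) -> bool:
        return self.error_code is not None

    def validate(self, config: TaskConfig) -> None:
        if self.is_error:
            return
        expected = (
            "common" if self.s2 == config.common_successor(self.a1) else "rare"
        )
        if self.transition != expected:
            raise ValueError(
                f"trial {self.trial_index}: transition label {self.transition!r} "
                f"contradicts s2={self.s2} for a1={self.a1}"
            )
        if self.outcome_level == 1 and self.juice_ms not in (0, 0.0):
            raise ValueError(f"trial {self.trial_index}: low outcome with juice")


@dataclass
class SessionData:
    """Ordered trials of one session plus the reward normalization constant."""

    trials: list[TrialRecord]
    subject_id: str = "synthetic"
    session_id: str = "s0"
    schedule: Optional[OutcomeSchedule] = None

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def max_juice_ms(self) -> float:
        vals = [t.juice_ms for t in self.trials if t.juice_ms is not None]
        return max(vals) if vals else 0.0

    def normalized_rewards(self) -> np.ndarray:
        """r2 per trial: juice divided by the session maximum (NaN on errors)."""
        mx = self.max_juice_ms
        out = np.full(self.n_trials, np.nan)
        for i, t in enumerate(self.trials):
            if t.juice_ms is not None:
                out[i] = t.juice_ms / mx if mx > 0 else 0.0
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.trials:
            d = asdict(t)
            d["subject_id"] = self.subject_id
            rows.append(d)
        return pd.DataFrame(rows)


def run_session(
    agent,
    config: TaskConfig,
    schedule: OutcomeSchedule,
    n_trials: int,
    rng: np.random.Generator,
    session_id: str = "s0",
    subject_id: str = "synthetic",
) -> SessionData:
    """Simulate a session by letting ``agent`` interact with the environment.

    ``agent`` must expose ``simulate_trial(record, rng)`` filling in the
    choices given the environment draws (see :class:`twostep.agents.Agent`).
    The trial-type sequence (forced stage/option, injected errors) is
    pre-generated at session start and followed regardless of errors.
    """
    if schedule.n_trials < n_trials:
        raise ValueError("schedule does not cover n_trials")
    # pre-generated trial-type sequence
    forced = rng.random(n_trials) < config.forced_rate
    forced_stage = np.where(forced, rng.integers(1, 3, n_trials), 0)
    forced_opt = rng.integers(0, 2, size=(n_trials, 2))
    errors = rng.random(n_trials) < config.error_rate
    error_codes = rng.integers(0, len(ERROR_CODES), n_trials)
    sides = rng.integers(0, 3, size=(n_trials, 2))

    trials: list[TrialRecord] = []
    for t in range(n_trials):
        rec = TrialRecord(
            session_id=session_id,
            trial_index=t,
            forced_stage=int(forced_stage[t]),
            side1=int(sides[t, 0]),
            side2=int(sides[t, 1]),
        )
        if forced_stage[t] == 1:
            rec.forced_option1 = int(forced_opt[t, 0])
        elif forced_stage[t] == 2:
            rec.forced_option2 = int(forced_opt[t, 1])
        if errors[t]:
            rec.error_code = ERROR_CODES[int(error_codes[t])]
            trials.append(rec)
            continue
        try:
            a1 = agent.simulate_first_stage(rec, rng)
            s2, label = transition_step(a1, config, rng)
            rec.a1, rec.s2, rec.transition = a1, s2, label
            a2 = agent.simulate_second_stage(rec, rng)
            rec.a2 = a2
            rec.outcome_level = int(schedule.levels[t, s2, a2])
            rec.juice_ms = float(schedule.juice_ms[t, s2, a2])
            agent.observe_outcome(rec)
        except Exception as exc:  # annotate failures with the trial index
            raise RuntimeError(f"agent failure at trial {t}") from exc
        trials.append(rec)
    return SessionData(
        trials=trials, subject_id=subject_id, session_id=session_id,
        schedule=schedule,
    )
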