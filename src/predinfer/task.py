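"""Change-point particle-catching task: schedules, outcomes and scoring.

The task is a predictive-inference game on a circle with 360 positions.
On every trial a particle lands at an angle drawn from a Gaussian centred
on a hidden generative mean (SD ``sigma_gen``); at change-point trials the
mean is re-sampled uniformly over the circle.  A session interleaves one
stable stretch (hazard 0.025, 4 change-points in 150 trials) and one
volatile stretch (hazard 0.125, 19 change-points), split into 4 blocks of
75 trials.  Players place a bucket (an arc) to catch the particle and earn
+10 points on a hit, -10 on a miss.

Positions are integer degrees in [1, 360]; signed angular differences live
in (-180, 180] with +180 chosen at the antipode.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TaskConfig",
    "Schedule",
    "wrap_position",
    "wrap_degrees",
    "signed_arc",
    "circular_distance",
    "build_schedule",
    "sample_generative_means",
    "sample_outcomes",
    "score_trial",
    "simulate_task",
    "write_trial_table",
    "read_trial_table",
]

STABLE = "stable"
VOLATILE = "volatile"

#: column order of the tidy trial table written by :func:`write_trial_table`
TRIAL_COLUMNS = [
    "subject", "trial", "block", "condition", "hazard", "mean", "outcome",
    "is_cp", "bucket", "confidence", "hit", "points",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class TaskConfig:
    """Task constants.

    Defaults reproduce the standard session: 300 trials in 4 blocks of 75,
    two 150-trial hazard stretches with fixed change-point counts, outcome
    noise SD 12 degrees, confidence reported on 1-100, and +/-10 points per
    trial.  ``bucket_halfwidth`` (the catching arc's half width, degrees) is
    a free parameter of the simulation: any quantity that depends on hit
    rates inherits this choice.
    """

    n_trials: int = 300
    n_blocks: int = 4
    block_len: int = 75
    stretch_len: int = 150
    hazard_stable: float = 0.025
    hazard_volatile: float = 0.125
    cp_count_stable: int = 4
    cp_count_volatile: int = 19
    sigma_gen: float = 12.0
    circle_points: int = 360
    bucket_halfwidth: float = 25.0
    points_hit: int = 10
    points_miss: int = -10
    confidence_min: int = 1
    confidence_max: int = 100
    confidence_start_options: tuple[int, int] = (25, 75)

    def __post_init__(self) -> None:
        if not (0.0 < self.hazard_stable < 1.0 and 0.0 < self.hazard_volatile < 1.0):
            raise ValueError("hazard rates must lie in (0, 1)")
        if self.sigma_gen < 0:
            raise ValueError("sigma_gen must be non-negative")
        if self.stretch_len * 2 != self.n_trials:
            raise ValueError("two stretches must tile the session: 2*stretch_len == n_trials")
        if self.n_blocks * self.block_len != self.n_trials:
            raise ValueError("blocks must tile the session: n_blocks*block_len == n_trials")
        for c in (self.cp_count_stable, self.cp_count_volatile):
            if c < 0 or c >= self.stretch_len:
                raise ValueError("change-point counts must satisfy 0 <= count < stretch_len")

    @property
    def sigma_gen2(self) -> float:
        return float(self.sigma_gen) ** 2

    def to_dict(self) -> dict:
        d = asdict(self)
        d["confidence_start_options"] = list(self.confidence_start_options)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        d = dict(d)
        if "confidence_start_options" in d:
            d["confidence_start_options"] = tuple(d["confidence_start_options"])
        return cls(**d)


# ---------------------------------------------------------------------------
# circular arithmetic
# ---------------------------------------------------------------------------

def wrap_position(x):
    """Round to the nearest circle point and wrap into [1, 360]."""
    return (np.round(np.asarray(x, dtype=float) - 1.0) % 360) + 1


def wrap_degrees(x):
    """Wrap a continuous angle into (0, 360] without rounding."""
    r = np.asarray(x, dtype=float) % 360.0
    return np.where(r == 0.0, 360.0, r)


def signed_arc(a, b):
    """Minimal signed arc from ``b`` to ``a``, in (-180, 180]; +180 at the antipode."""
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    return np.where(d > 180.0, d - 360.0, d)


def circular_distance(a, b):
    """Absolute circular distance in [0, 180]."""
    return np.abs(signed_arc(a, b))


# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------

@dataclass
class Schedule:
    """Per-trial hazard condition and change-point flags for one session."""

    condition: np.ndarray  # str per trial: "stable" | "volatile"
    hazard: np.ndarray     # float per trial
    is_cp: np.ndarray      # bool per trial
    config: TaskConfig = field(repr=False, default_factory=TaskConfig)

    @property
    def n_trials(self) -> int:
        return len(self.hazard)

    @property
    def block(self) -> np.ndarray:
        return np.arange(self.n_trials) // self.config.block_len

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(self.n_trials),
                "block": self.block,
                "condition": self.condition,
                "hazard": self.hazard,
                "is_cp": self.is_cp,
            }
        )


def build_schedule(config: TaskConfig, seed) -> Schedule:
    """Build a session schedule: two hazard stretches in random order, each
    containing exactly its configured number of change-points.

    Change-point positions are drawn uniformly without replacement from
    trials 2..stretch_len of each stretch (the first trial of the session
    is not a change-point by convention), so the realised change-point
    counts — and hence the empirical hazards 4/150 and 19/150 — hold for
    every seed.
    """
    rng = np.random.default_rng(seed)
    order = [STABLE, VOLATILE]
    rng.shuffle(order)

    condition = np.empty(config.n_trials, dtype=object)
    hazard = np.empty(config.n_trials, dtype=float)
    is_cp = np.zeros(config.n_trials, dtype=bool)
    haz = {STABLE: config.hazard_stable, VOLATILE: config.hazard_volatile}
    cnt = {STABLE: config.cp_count_stable, VOLATILE: config.cp_count_volatile}

    for k, cond in enumerate(order):
        lo = k * config.stretch_len
        hi = lo + config.stretch_len
        condition[lo:hi] = cond
        hazard[lo:hi] = haz[cond]
        n_cp = cnt[cond]
        if n_cp > 0:
            # relative trial 0 of each stretch excluded
            pos = rng.choice(np.arange(1, config.stretch_len), size=n_cp, replace=False)
            is_cp[lo + np.sort(pos)] = True

    return Schedule(condition=condition, hazard=hazard, is_cp=is_cp, config=config)


def sample_generative_means(schedule: Schedule, config: TaskConfig, seed) -> np.ndarray:
    """Piecewise-constant generative means: uniform over the circle's points
    at the session start and at every change-point."""
    rng = np.random.default_rng(seed)
    n = schedule.n_trials
    means = np.empty(n, dtype=float)
    current = float(rng.integers(1, config.circle_points + 1))
    for t in range(n):
        if schedule.is_cp[t]:
            current = float(rng.integers(1, config.circle_points + 1))
        means[t] = current
    return means


def sample_outcomes(means: Sequence[float], config: TaskConfig, seed) -> np.ndarray:
    """Particle landing locations: mean plus Gaussian noise (SD ``sigma_gen``),
    rounded and wrapped to the integer circle positions."""
    rng = np.random.default_rng(seed)
    means = np.asarray(means, dtype=float)
    eps = rng.normal(0.0, config.sigma_gen, size=means.shape) if config.sigma_gen > 0 else 0.0
    return wrap_position(means + eps)


def score_trial(bucket, outcome, config: TaskConfig):
    """Hit/miss scoring: a hit iff the particle lands within the bucket arc
    (inclusive boundary); +points_hit on a hit, points_miss otherwise."""
    hit = circular_distance(outcome, bucket) <= config.bucket_halfwidth
    points = np.where(hit, config.points_hit, config.points_miss)
    if np.isscalar(bucket) and np.isscalar(outcome):
        return bool(hit), int(points)
    return hit, points


def simulate_task(config: TaskConfig, seed) -> pd.DataFrame:
    """Convenience wrapper: schedule + means + outcomes as one tidy frame."""
    ss = np.random.SeedSequence(seed)
    s_sched, s_mean, s_out = ss.spawn(3)
    schedule = build_schedule(config, s_sched)
    means = sample_generative_means(schedule, config, s_mean)
    outcomes = sample_outcomes(means, config, s_out)
    df = schedule.to_frame()
    df["mean"] = means
    df["outcome"] = outcomes
    return df


# ---------------------------------------------------------------------------
# tidy-table IO
# ---------------------------------------------------------------------------

def write_trial_table(df: pd.DataFrame, path) -> None:
    cols = [c for c in TRIAL_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df.loc[:, cols].to_csv(path, index=False)


def read_trial_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
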