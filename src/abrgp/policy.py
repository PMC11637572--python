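"""Active-learning stimulus selection and threshold inference.

The policy approaches hearing threshold from above by locating a descending
ladder of amplitude targets T1..T5 (0.5 down to 0.15 µV) at each frequency,
each "located" once the posterior SD at its most-likely level drops below a
per-target confidence threshold delta_i.  If the posterior says even the
maximum test level cannot reach the current target, testing is redirected to
the maximum level, and the target is abandoned (skipped) once the posterior
there is confident; a frequency whose five targets are all unreachable is
censored — the profound-loss surrogate.  The next stimulus is always the
candidate location (over the still-active frequencies) with the largest
posterior SD.  Once every frequency has located or abandoned all targets,
hearing threshold is read off as the most likely level where the growth
function is zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gp import Posterior
from .simulate import StimulusSpec

#: Amplitude targets T1..T5, µV (descending ladder).
TARGETS_UV = (0.5, 0.3, 0.25, 0.2, 0.15)
#: Posterior-SD confidence thresholds delta_1..delta_5, µV.
DELTAS_UV = (0.2, 0.15, 0.1, 0.075, 0.05)
#: Maximum test level, dB HL.
MAX_LEVEL_DB = 70.0
#: Candidate-amplitude grid for the most-likely-amplitude rule, µV.
AMP_GRID_UV = np.round(np.arange(0.0, 1.25 + 1e-9, 0.005), 3)


@dataclass(frozen=True)
class TargetSchedule:
    """The descending amplitude-target ladder with its confidence thresholds."""

    targets: tuple[float, ...] = TARGETS_UV
    deltas: tuple[float, ...] = DELTAS_UV
    max_level: float = MAX_LEVEL_DB

    def __post_init__(self) -> None:
        if len(self.targets) != len(self.deltas):
            raise ValueError("targets and deltas must have equal length")
        if list(self.targets) != sorted(self.targets, reverse=True) or len(
            set(self.targets)
        ) != len(self.targets):
            raise ValueError("targets must be strictly decreasing")
        if list(self.deltas) != sorted(self.deltas, reverse=True) or len(
            set(self.deltas)
        ) != len(self.deltas):
            raise ValueError("deltas must be strictly decreasing")

    @property
    def n_targets(self) -> int:
        return len(self.targets)


@dataclass
class FrequencyState:
    """Per-frequency progress through the target ladder."""

    frequency: float
    target_idx: int = 0  # 0-based index of the current target
    located: list = field(default_factory=list)
    unreachable: list = field(default_factory=list)
    capped: bool = False
    epochs: int = 0

    def __post_init__(self) -> None:
        if not self.located:
            self.located = [False] * len(TARGETS_UV)
        if not self.unreachable:
            self.unreachable = [False] * len(TARGETS_UV)

    @property
    def done(self) -> bool:
        return self.capped or self.target_idx >= len(self.located)

    @property
    def censored(self) -> bool:
        """True when no target could be confirmed reachable at this frequency."""
        return self.capped or all(self.unreachable)


def locate_target_level(
    post: Posterior,
    target: float,
    frequency: float,
    levels: np.ndarray | None = None,
) -> float:
    """Most likely stimulus level where the growth function equals ``target``.

    Maximises the univariate posterior density N(target; mean, var) over the
    candidate levels (default: the grid's 81 levels); exact ties resolve to
    the highest level, the conservative approach-from-above choice.
    """
    if levels is None:
        levels = post.grid.levels
    levels = np.asarray(levels, dtype=float)
    if levels.size == 0:
        raise ValueError("candidate level vector is empty")
    mu = np.empty(levels.size)
    var = np.empty(levels.size)
    for k, lvl in enumerate(levels):
        mu[k], var[k] = post.marginal(lvl, frequency)
    var = np.maximum(var, 1e-300)
    logpdf = -0.5 * np.log(2 * np.pi * var) - (target - mu) ** 2 / (2 * var)
    return float(levels[np.flatnonzero(logpdf == logpdf.max())[-1]])


def target_located(
    post: Posterior, target: float, frequency: float, delta: float
) -> bool:
    """Is the posterior SD at the target's most-likely level below delta?

    Strict comparison: an SD exactly equal to delta is not yet located.
    """
    level = locate_target_level(post, target, frequency)
    return post.sd(level, frequency) < delta


def most_likely_amp_at_max(
    post: Posterior,
    frequency: float,
    amp_grid: np.ndarray | None = None,
    max_level: float = MAX_LEVEL_DB,
) -> float:
    """Most likely PTTa at the maximum test level.

    Maximises N(a; mean, var) at (max_level, frequency) over the amplitude
    grid — the grid point nearest the posterior mean, clamped to the grid
    range (so a negative-dipping mean maps to 0).
    """
    if amp_grid is None:
        amp_grid = AMP_GRID_UV
    mu, var = post.marginal(max_level, frequency)
    var = max(var, 1e-300)
    dens = -((amp_grid - mu) ** 2) / (2 * var)
    return float(amp_grid[int(np.argmax(dens))])


def check_reachable(
    post: Posterior,
    target: float,
    frequency: float,
    amp_grid: np.ndarray | None = None,
    max_level: float = MAX_LEVEL_DB,
) -> bool:
    """Can the growth function plausibly reach ``target`` at the max level?"""
    return most_likely_amp_at_max(post, frequency, amp_grid, max_level) >= target


def advance_stages(
    states: list[FrequencyState], post: Posterior, schedule: TargetSchedule
) -> None:
    """Advance each frequency's target ladder as far as the posterior allows.

    A target is passed either by being located (reachable, SD below delta) or
    abandoned as unreachable (max-level amplitude below the target and the
    max-level SD below delta, reusing delta's confidence semantics for the
    give-up decision).  The target index never decreases.
    """
    for state in states:
        while not state.done:
            i = state.target_idx
            target, delta = schedule.targets[i], schedule.deltas[i]
            if check_reachable(post, target, state.frequency, max_level=schedule.max_level):
                if target_located(post, target, state.frequency, delta):
                    state.located[i] = True
                    state.target_idx += 1
                    continue
            else:
                if post.sd(schedule.max_level, state.frequency) < delta:
                    state.unreachable[i] = True
                    state.target_idx += 1
                    continue
            break


def select_next_stimulus(
    states: list[FrequencyState], post: Posterior, schedule: TargetSchedule
) -> StimulusSpec | None:
    """Choose the next stimulus, or None to STOP.

    Each active frequency contributes one candidate: its current target's
    most-likely level when the target is reachable, else the maximum level.
    The candidate with the largest posterior SD wins; exact SD ties resolve
    to the lowest frequency.  STOP (None) once every frequency has located or
    abandoned all targets.
    """
    best: StimulusSpec | None = None
    best_sd = -np.inf
    for state in sorted(states, key=lambda s: s.frequency):
        if state.done:
            continue
        target = schedule.targets[state.target_idx]
        if check_reachable(post, target, state.frequency, max_level=schedule.max_level):
            level = locate_target_level(post, target, state.frequency)
        else:
            level = schedule.max_level
        sd = post.sd(level, state.frequency)
        if sd > best_sd:
            best_sd = sd
            best = StimulusSpec(level=level, frequency=state.frequency)
    return best


@dataclass(frozen=True)
class ThresholdEstimate:
    """One audiogram entry: estimated threshold with its censoring flag."""

    threshold: float
    censored: bool


def infer_thresholds(
    post: Posterior, states: list[FrequencyState], schedule: TargetSchedule
) -> dict[float, ThresholdEstimate]:
    """Per-frequency hearing threshold: the target-location rule with T = 0.

    The censored flag marks frequencies where no amplitude target could be
    confirmed reachable (or the epoch cap fired), i.e. the reported level is
    a lower bound rather than a threshold.
    """
    out: dict[float, ThresholdEstimate] = {}
    for state in sorted(states, key=lambda s: s.frequency):
        level = locate_target_level(post, 0.0, state.frequency)
        out[state.frequency] = ThresholdEstimate(level, state.censored)
    return out
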