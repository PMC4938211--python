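"""Trial schedules for the pro/anti-saccade delayed-response design.

Each run interleaves pro- and anti-saccade trials.  A trial consists of a
preparation cue (the participant knows the upcoming saccade type but not its
direction), an execution target after a preparation interval of 6, 10 or 14 s,
a variable post-saccade hold, a return-saccade cue, and a variable inter-trial
interval.  Hold and ITI durations are integer seconds drawn from a Poisson
distribution truncated to [2, 12] s whose rate is calibrated so the truncated
mean is exactly the nominal 4 s.  Runs begin and end with 15 s of blank screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

#: Event kinds modelled as separate regressors in the direction-resolved scheme.
EVENT_KINDS = (
    "prep_pro",
    "prep_anti",
    "exec_pro_left",
    "exec_pro_right",
    "exec_anti_left",
    "exec_anti_right",
    "return_saccade",
)

PREP_KINDS = ("prep_pro", "prep_anti")
EXEC_KINDS = (
    "exec_pro_left",
    "exec_pro_right",
    "exec_anti_left",
    "exec_anti_right",
)


@dataclass(frozen=True)
class DesignConfig:
    """Timing parameters of one scanner run.

    Durations are in seconds.  ``prep_durations`` is the discrete set from
    which preparation intervals are drawn uniformly; hold and ITI delays come
    from the truncated-Poisson sampler with mean ``delay_mean`` on
    [``delay_min``, ``delay_max``].
    """

    n_trials_per_run: int = 20
    n_pro: int = 10
    n_anti: int = 10
    prep_durations: tuple[float, ...] = (6.0, 10.0, 14.0)
    delay_mean: float = 4.0
    delay_min: int = 2
    delay_max: int = 12
    lead_s: float = 15.0
    trail_s: float = 15.0
    impulse_s: float = 0.5
    tr: float = 1.5

    def __post_init__(self) -> None:
        if self.n_pro + self.n_anti != self.n_trials_per_run:
            raise ValueError(
                f"n_pro + n_anti = {self.n_pro + self.n_anti} "
                f"!= n_trials_per_run = {self.n_trials_per_run}"
            )
        if not (self.delay_min <= self.delay_mean <= self.delay_max):
            raise ValueError("require delay_min <= delay_mean <= delay_max")
        for name in ("lead_s", "trail_s", "impulse_s", "tr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(d <= 0 for d in self.prep_durations):
            raise ValueError("preparation durations must be positive")


@dataclass(frozen=True)
class TrialEvent:
    """A timed impulse event within a run (onset in seconds from run start)."""

    onset: float
    kind: str
    duration: float

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError("onset must be non-negative")
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass(frozen=True)
class RunSchedule:
    """Ordered event list for one run plus derived volume bookkeeping."""

    events: tuple[TrialEvent, ...]
    total_duration: float
    tr: float
    n_volumes: int = field(default=0)

    def __post_init__(self) -> None:
        onsets = [e.onset for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("events must be strictly increasing in onset")
        expected = math.ceil(self.total_duration / self.tr)
        if self.n_volumes == 0:
            object.__setattr__(self, "n_volumes", expected)
        elif self.n_volumes != expected:
            raise ValueError("n_volumes inconsistent with total_duration / tr")

    def onsets_of(self, kind: str) -> np.ndarray:
        return np.array([e.onset for e in self.events if e.kind == kind])


def sample_preparation_duration(
    rng: np.random.Generator, durations: Sequence[float] = (6.0, 10.0, 14.0)
) -> float:
    """Draw one preparation interval uniformly from the allowed set."""
    return float(durations[rng.integers(len(durations))])


def calibrate_truncated_poisson_rate(
    delay_mean: float, delay_min: int, delay_max: int
) -> float:
    """Rate lambda* such that a Poisson(lambda*) truncated to the integer
    support [delay_min, delay_max] has mean exactly ``delay_mean``.

    A Poisson with rate equal to the nominal mean overshoots once truncated
    (e.g. Poisson(4) on [2, 12] has mean ~4.33), so the rate is found by
    root-finding on the truncated expectation, which is strictly increasing
    in the rate.
    """
    support = np.arange(delay_min, delay_max + 1)

    def truncated_mean(lam: float) -> float:
        pmf = stats.poisson.pmf(support, lam)
        return float(np.sum(support * pmf) / np.sum(pmf))

    lo, hi = 1e-6, float(delay_max)
    if not truncated_mean(lo) <= delay_mean <= truncated_mean(hi):
        raise ValueError(
            f"no Poisson rate on ({lo}, {hi}) achieves truncated mean "
            f"{delay_mean} on [{delay_min}, {delay_max}]"
        )
    return float(
        optimize.brentq(lambda lam: truncated_mean(lam) - delay_mean, lo, hi)
    )


def truncated_poisson_pmf(lam: float, delay_min: int, delay_max: int) -> np.ndarray:
    """Normalised pmf of the truncated Poisson over its integer support."""
    support = np.arange(delay_min, delay_max + 1)
    pmf = stats.poisson.pmf(support, lam)
    return pmf / pmf.sum()


def sample_truncated_poisson_delay(
    rng: np.random.Generator,
    delay_mean: float = 4.0,
    delay_min: int = 2,
    delay_max: int = 12,
    *,
    rate: float | None = None,
    size: int | None = None,
):
    """Draw integer-second delays from the calibrated truncated Poisson.

    ``rate`` can be supplied to skip recalibration when drawing repeatedly.
    Returns a scalar when ``size`` is None, else an ndarray.
    """
    if not (delay_min <= delay_mean <= delay_max):
        raise ValueError("require delay_min <= delay_mean <= delay_max")
    if rate is None:
        rate = calibrate_truncated_poisson_rate(delay_mean, delay_min, delay_max)
    support = np.arange(delay_min, delay_max + 1)
    p = truncated_poisson_pmf(rate, delay_min, delay_max)
    draws = rng.choice(support, size=size if size is not None else 1, p=p)
    return int(draws[0]) if size is None else draws.astype(int)


def build_run_schedule(rng: np.random.Generator, config: DesignConfig) -> RunSchedule:
    """Assemble one run: shuffled trials, each contributing a preparation
    event, an execution event (type x direction), and a return event.

    Half of each trial type's executions are leftward, half rightward; the
    trial order is a uniform shuffle.  Segment bookkeeping: run duration =
    lead + sum over trials of (preparation + hold + ITI) + trail.
    """
    if config.n_pro % 2 or config.n_anti % 2:
        raise ValueError(
            "n_pro and n_anti must be even to split directions evenly"
        )
    rate = calibrate_truncated_poisson_rate(
        config.delay_mean, config.delay_min, config.delay_max
    )

    trial_types: list[tuple[str, str]] = []
    for sacc, n in (("pro", config.n_pro), ("anti", config.n_anti)):
        for i in range(n):
            trial_types.append((sacc, "left" if i < n // 2 else "right"))
    order = rng.permutation(len(trial_types))

    events: list[TrialEvent] = []
    t = config.lead_s
    for idx in order:
        sacc, direction = trial_types[idx]
        prep_dur = sample_preparation_duration(rng, config.prep_durations)
        hold = sample_truncated_poisson_delay(
            rng, config.delay_mean, config.delay_min, config.delay_max, rate=rate
        )
        iti = sample_truncated_poisson_delay(
            rng, config.delay_mean, config.delay_min, config.delay_max, rate=rate
        )
        events.append(TrialEvent(t, f"prep_{sacc}", config.impulse_s))
        events.append(TrialEvent(t + prep_dur, f"exec_{sacc}_{direction}", config.impulse_s))
        events.append(TrialEvent(t + prep_dur + hold, "return_saccade", config.impulse_s))
        t += prep_dur + hold + iti
    total = t + config.trail_s
    return RunSchedule(events=tuple(events), total_duration=total, tr=config.tr)
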