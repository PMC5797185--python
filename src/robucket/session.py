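"""Deterministic session state machine.

:func:`run_session` consumes a time-ordered nose-poke stream and applies
the reinforcement schedule, the post-response timeout, and the
termination rules (session clock, optional reward cap), producing a
complete :class:`EventLog`.

Timing model
------------
All bookkeeping is done in integer milliseconds from session start.
Incoming times in seconds are converted once on entry (round half up),
so replaying a logged stream reproduces the log bit for bit. A counted
active poke at time ``t`` opens a timeout window ``(t, t + timeout]``:
any poke in either well whose time falls inside the window is logged
with ``in_timeout=True`` and ``counted=False`` and does not extend the
window. Ties in the input are broken by input order — the second of two
equal-time pokes is treated as infinitesimally later, so it lands inside
a window opened by the first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .schedules import ScheduleKind, ScheduleSpec, requirement_for

__all__ = [
    "Well",
    "Phase",
    "EndReason",
    "SessionConfig",
    "PokeEvent",
    "RewardEvent",
    "EventLog",
    "run_session",
    "is_terminated",
]


class Well(str, Enum):
    ACTIVE = "ACTIVE"
    INACTIVE = "INACTIVE"


class Phase(str, Enum):
    FR1 = "FR1"
    FR5 = "FR5"
    PR = "PR"


class EndReason(str, Enum):
    TIME_LIMIT = "TIME_LIMIT"
    REWARD_CAP = "REWARD_CAP"


@dataclass(frozen=True)
class SessionConfig:
    """Session parameters.

    ``max_rewards`` is ``None`` for an uncapped session. The reward cap
    is part of the standard FR1 acquisition protocol (50 reinforcements);
    FR5 and PR sessions conventionally run the full clock.
    """

    schedule: ScheduleSpec
    max_duration_s: float = 3600.0
    max_rewards: int | None = None
    timeout_s: float = 1.0
    reward_volume_ul: float = 10.0
    sucrose_pct: float = 20.0

    def __post_init__(self) -> None:
        if self.max_duration_s <= 0:
            raise ValueError("max_duration_s must be positive")
        if self.timeout_s < 0:
            raise ValueError("timeout_s must be non-negative")
        if self.max_rewards is not None and self.max_rewards < 1:
            raise ValueError("max_rewards must be >= 1 or None")

    @classmethod
    def for_phase(cls, phase: Phase | str, **overrides) -> "SessionConfig":
        """Standard per-phase configuration: FR1 with a 50-reward cap,
        FR5 and PR uncapped, all 60 minutes with a 1-second timeout."""
        phase = Phase(phase)
        if phase is Phase.FR1:
            defaults = dict(schedule=ScheduleSpec.fixed(1), max_rewards=50)
        elif phase is Phase.FR5:
            defaults = dict(schedule=ScheduleSpec.fixed(5), max_rewards=None)
        else:
            defaults = dict(schedule=ScheduleSpec.progressive(), max_rewards=None)
        defaults.update(overrides)
        return cls(**defaults)


@dataclass(frozen=True)
class PokeEvent:
    t_s: float
    well: Well
    in_timeout: bool
    counted: bool


@dataclass(frozen=True)
class RewardEvent:
    t_s: float
    index: int


def _ms(t_s: float) -> int:
    return int(math.floor(t_s * 1000.0 + 0.5))


@dataclass
class EventLog:
    """One session's complete event record.

    Event times are stored as integer milliseconds in numpy arrays;
    ``pokes`` / ``rewards`` expose them as event objects in seconds.
    """

    mouse_id: str
    genotype: str
    day: int
    phase: Phase
    config: SessionConfig
    poke_t_ms: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    poke_well: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int8))
    poke_in_timeout: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))
    poke_counted: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))
    reward_t_ms: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    end_t_ms: int = 0
    end_reason: EndReason = EndReason.TIME_LIMIT

    @property
    def n_pokes(self) -> int:
        return int(self.poke_t_ms.size)

    @property
    def n_rewards(self) -> int:
        return int(self.reward_t_ms.size)

    @property
    def end_t_s(self) -> float:
        return self.end_t_ms / 1000.0

    @property
    def pokes(self) -> list[PokeEvent]:
        return [
            PokeEvent(
                t_s=t / 1000.0,
                well=Well.ACTIVE if w else Well.INACTIVE,
                in_timeout=bool(it),
                counted=bool(c),
            )
            for t, w, it, c in zip(
                self.poke_t_ms.tolist(),
                self.poke_well.tolist(),
                self.poke_in_timeout.tolist(),
                self.poke_counted.tolist(),
            )
        ]

    @property
    def rewards(self) -> list[RewardEvent]:
        return [
            RewardEvent(t_s=t / 1000.0, index=i + 1)
            for i, t in enumerate(self.reward_t_ms.tolist())
        ]

    def poke_stream(self) -> tuple[np.ndarray, np.ndarray]:
        """The raw (t_s, well) stream, suitable for replay through
        :func:`run_session`."""
        return self.poke_t_ms / 1000.0, self.poke_well.copy()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EventLog):
            return NotImplemented
        return (
            self.mouse_id == other.mouse_id
            and self.genotype == other.genotype
            and self.day == other.day
            and self.phase == other.phase
            and self.config == other.config
            and self.end_t_ms == other.end_t_ms
            and self.end_reason == other.end_reason
            and np.array_equal(self.poke_t_ms, other.poke_t_ms)
            and np.array_equal(self.poke_well, other.poke_well)
            and np.array_equal(self.poke_in_timeout, other.poke_in_timeout)
            and np.array_equal(self.poke_counted, other.poke_counted)
            and np.array_equal(self.reward_t_ms, other.reward_t_ms)
        )


def _process(
    t_ms: list[int],
    well: list[int],
    schedule: ScheduleSpec,
    timeout_ms: int,
    max_duration_ms: int,
    max_rewards: int | None,
) -> tuple[list[bool], list[bool], list[int], list[int], int, EndReason, int]:
    """Core counting loop over an ms-resolution poke stream.

    Returns (counted, in_timeout, reward_t_ms, reward_poke_idx, end_t_ms,
    end_reason, n_pokes_kept). Pokes at or after session end are dropped.
    """
    fixed = schedule.kind is ScheduleKind.FIXED_RATIO
    req = schedule.fixed_ratio if fixed else requirement_for(schedule, 0)
    progress = 0
    counted: list[bool] = []
    in_timeout: list[bool] = []
    reward_t: list[int] = []
    reward_idx: list[int] = []
    timeout_until = -1
    end_t = max_duration_ms
    end_reason = EndReason.TIME_LIMIT
    n_kept = 0
    append_c = counted.append
    append_it = in_timeout.append
    for i in range(len(t_ms)):
        t = t_ms[i]
        if t >= max_duration_ms:
            break
        n_kept += 1
        if t <= timeout_until:
            append_c(False)
            append_it(True)
            continue
        append_c(True)
        append_it(False)
        if well[i]:
            timeout_until = t + timeout_ms
            progress += 1
            if progress >= req:
                reward_t.append(t)
                reward_idx.append(i)
                progress = 0
                if max_rewards is not None and len(reward_t) >= max_rewards:
                    end_t = t
                    end_reason = EndReason.REWARD_CAP
                    break
                if not fixed:
                    req = requirement_for(schedule, len(reward_t))
    return counted, in_timeout, reward_t, reward_idx, end_t, end_reason, n_kept


def _coerce_stream(
    poke_stream: Iterable[tuple[float, object]] | tuple[Sequence[float], Sequence[int]],
) -> tuple[np.ndarray, np.ndarray]:
    """Accept either an iterable of (t_s, well) pairs or a (times, wells)
    array pair; wells may be Well enums, 'ACTIVE'/'INACTIVE' strings, or
    0/1 integers (1 = active)."""
    if isinstance(poke_stream, tuple) and len(poke_stream) == 2 and not np.isscalar(poke_stream[0]):
        t = np.asarray(poke_stream[0], dtype=float)
        w_raw = poke_stream[1]
    else:
        pairs = list(poke_stream)  # type: ignore[arg-type]
        t = np.asarray([p[0] for p in pairs], dtype=float)
        w_raw = [p[1] for p in pairs]
    if isinstance(w_raw, np.ndarray) and w_raw.dtype.kind in "iub":
        w = w_raw.astype(np.int8)
    else:
        w = np.asarray(
            [
                1 if (x in (1, True, Well.ACTIVE, "ACTIVE", "active")) else 0
                for x in (w_raw.tolist() if isinstance(w_raw, np.ndarray) else w_raw)
            ],
            dtype=np.int8,
        )
    if t.shape != w.shape:
        raise ValueError("poke times and wells must have equal length")
    return t, w


def run_session(
    config: SessionConfig,
    poke_stream: Iterable[tuple[float, object]] | tuple[Sequence[float], Sequence[int]],
    *,
    mouse_id: str = "",
    genotype: str = "",
    day: int = 1,
    phase: Phase | str = Phase.FR1,
) -> EventLog:
    """Run a poke stream through the session state machine.

    Parameters
    ----------
    config
        Schedule, clock, timeout and cap parameters.
    poke_stream
        Time-ordered pokes, either an iterable of ``(t_s, well)`` pairs or
        a pair of arrays ``(times_s, wells)`` with wells coded 1=active.
        Times are seconds from session start, non-decreasing and >= 0.

    Returns
    -------
    EventLog
        Complete log: every poke at ms resolution with its timeout and
        counted flags, reward events, session end time and reason.
    """
    t_s, wells = _coerce_stream(poke_stream)
    if t_s.size and float(t_s.min()) < 0:
        raise ValueError("poke times must be non-negative")
    if t_s.size > 1 and np.any(np.diff(t_s) < 0):
        raise ValueError("poke stream must be sorted by time")
    t_ms = np.floor(t_s * 1000.0 + 0.5).astype(np.int64)

    counted, in_timeout, reward_t, _, end_t, end_reason, n_kept = _process(
        t_ms.tolist(),
        wells.tolist(),
        config.schedule,
        _ms(config.timeout_s),
        _ms(config.max_duration_s),
        config.max_rewards,
    )
    return EventLog(
        mouse_id=mouse_id,
        genotype=genotype,
        day=day,
        phase=Phase(phase),
        config=config,
        poke_t_ms=t_ms[:n_kept].copy(),
        poke_well=wells[:n_kept].copy(),
        poke_in_timeout=np.asarray(in_timeout, dtype=bool),
        poke_counted=np.asarray(counted, dtype=bool),
        reward_t_ms=np.asarray(reward_t, dtype=np.int64),
        end_t_ms=end_t,
        end_reason=end_reason,
    )


def is_terminated(
    config: SessionConfig, rewards: int, t_s: float
) -> tuple[bool, EndReason | None]:
    """Termination test: the session is over once the clock reaches
    ``max_duration_s`` or the reward cap (if any) is reached — whichever
    comes first decides the end reason."""
    if config.max_rewards is not None and rewards >= config.max_rewards:
        return True, EndReason.REWARD_CAP
    if t_s >= config.max_duration_s:
        return True, EndReason.TIME_LIMIT
    return False, None
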