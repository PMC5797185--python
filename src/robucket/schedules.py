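"""Reinforcement schedules.

A schedule maps the number of rewards already earned in a session to the
number of counted active-well responses required for the next reward.
Two families are implemented:

* **Fixed ratio (FR-n)** — every ``n`` active responses earn one reward.
* **Progressive ratio (PR)** — the requirement grows exponentially with
  each reward: ``R = round(scale * exp(N * rate) - scale)`` where
  ``N = rewards_earned + 1`` and ``round`` is round-half-away-from-zero.
  With the default constants (scale 5, rate 0.2) the requirement series
  is 1, 2, 4, 6, 9, 12, 15, 20, 25, 32, ...

The architecture admits further schedule families (variable ratio,
variable interval, ...) by extending :class:`ScheduleKind` and
:func:`requirement_for`; none are implemented here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

__all__ = [
    "ScheduleKind",
    "ScheduleSpec",
    "requirement_for",
    "pr_sequence",
    "cumulative_pokes_for",
]


class ScheduleKind(str, Enum):
    FIXED_RATIO = "FR"
    PROGRESSIVE_RATIO = "PR"


@dataclass(frozen=True)
class ScheduleSpec:
    """A reinforcement schedule.

    Parameters
    ----------
    kind
        ``FIXED_RATIO`` or ``PROGRESSIVE_RATIO``.
    fixed_ratio
        Responses per reward; required iff ``kind`` is ``FIXED_RATIO``.
    pr_scale, pr_rate
        Scale and exponential growth rate of the progressive-ratio
        requirement curve. Defaults 5 and 0.2.
    """

    kind: ScheduleKind
    fixed_ratio: int | None = None
    pr_scale: float = 5.0
    pr_rate: float = 0.2

    def __post_init__(self) -> None:
        kind = ScheduleKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if kind is ScheduleKind.FIXED_RATIO:
            if self.fixed_ratio is None:
                raise ValueError("fixed_ratio is required for a fixed-ratio schedule")
            if int(self.fixed_ratio) != self.fixed_ratio or self.fixed_ratio < 1:
                raise ValueError(f"fixed_ratio must be a positive integer, got {self.fixed_ratio!r}")
            object.__setattr__(self, "fixed_ratio", int(self.fixed_ratio))
        elif self.fixed_ratio is not None:
            raise ValueError("fixed_ratio only applies to fixed-ratio schedules")
        if not (self.pr_scale > 0 and self.pr_rate > 0):
            raise ValueError("pr_scale and pr_rate must be positive")

    @classmethod
    def fixed(cls, n: int) -> "ScheduleSpec":
        """FR-``n`` schedule."""
        return cls(kind=ScheduleKind.FIXED_RATIO, fixed_ratio=n)

    @classmethod
    def progressive(cls, scale: float = 5.0, rate: float = 0.2) -> "ScheduleSpec":
        """Progressive-ratio schedule with the given constants."""
        return cls(kind=ScheduleKind.PROGRESSIVE_RATIO, pr_scale=scale, pr_rate=rate)


def _round_half_away(x: float) -> int:
    # round-half-away-from-zero: deterministic, unlike banker's rounding
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def requirement_for(spec: ScheduleSpec, rewards_earned: int) -> int:
    """Active-well responses required for the next reward.

    For a progressive-ratio schedule the requirement is
    ``round(scale * exp((rewards_earned + 1) * rate) - scale)``, clamped to a
    minimum of one response. For a fixed-ratio schedule it is constant.
    """
    if rewards_earned < 0:
        raise ValueError(f"rewards_earned must be >= 0, got {rewards_earned}")
    if spec.kind is ScheduleKind.FIXED_RATIO:
        return spec.fixed_ratio  # type: ignore[return-value]
    n = rewards_earned + 1
    raw = spec.pr_scale * math.exp(n * spec.pr_rate) - spec.pr_scale
    return max(1, _round_half_away(raw))


def pr_sequence(spec: ScheduleSpec, k: int) -> list[int]:
    """The first ``k`` response requirements of a schedule."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    return [requirement_for(spec, i) for i in range(k)]


def cumulative_pokes_for(spec: ScheduleSpec, k: int) -> int:
    """Total counted active responses needed to earn ``k`` rewards."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    return sum(pr_sequence(spec, k))
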