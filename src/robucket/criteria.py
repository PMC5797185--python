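"""Task-progression criteria.

FR1 acquisition requires, on each of three consecutive daily sessions,
an active:inactive discrimination ratio of at least 3:1 together with at
least 20 reinforcements; mice that have not met this by day 17 are
excluded. FR5 runs for a fixed three days regardless of performance.
A progressive-ratio breakpoint is considered stabilized once the daily
reward counts of three consecutive sessions agree to within ±10% (or
within ±1 reward when fewer than ten rewards are being earned).

Interpretation choices (the operational wording leaves two details
open): the ±10% band is anchored on the 3-day window mean, and the
reported stabilized breakpoint is that window mean. Both alternatives
(first-day anchoring, final-day value) are available via
``anchor='first'`` / ``breakpoint='final'`` for comparison with rigs
that resolve the ambiguity differently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .event_io import SessionSummary

__all__ = [
    "CriteriaConfig",
    "MouseProgress",
    "StabilizationResult",
    "fr1_day_passes",
    "fr1_acquisition_day",
    "pr_stabilization",
]


@dataclass(frozen=True)
class CriteriaConfig:
    fr1_ratio_min: float = 3.0
    fr1_rewards_min: int = 20
    consecutive_days: int = 3
    fr1_max_days: int = 17
    fr5_days: int = 3
    pr_rel_tol: float = 0.10
    pr_abs_tol: float = 1.0
    pr_small_threshold: float = 10.0

    def __post_init__(self) -> None:
        for name in (
            "fr1_ratio_min",
            "fr1_rewards_min",
            "consecutive_days",
            "fr1_max_days",
            "fr5_days",
            "pr_rel_tol",
            "pr_abs_tol",
            "pr_small_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class StabilizationResult:
    """Day (1-based, last day of the earliest stabilizing window) and the
    stabilized breakpoint for that window."""

    day: int
    breakpoint: float


@dataclass
class MouseProgress:
    """Per-mouse progression through the FR1 → FR5 → PR protocol."""

    mouse_id: str
    genotype: str
    fr1_days_to_criteria: Optional[int] = None
    excluded: bool = False
    fr5_sessions: int = 0
    pr_days: int = 0
    pr_stabilization_day: Optional[int] = None
    breakpoint: Optional[float] = None


def fr1_day_passes(summary: SessionSummary, cfg: CriteriaConfig = CriteriaConfig()) -> bool:
    """Did this FR1 session meet the daily acquisition criterion?

    An infinite ratio (no inactive pokes at all) passes the
    discrimination test: the mouse is maximally discriminating.
    """
    ratio = summary.active_inactive_ratio
    if ratio is None:
        return False
    return ratio >= cfg.fr1_ratio_min and summary.rewards >= cfg.fr1_rewards_min


def fr1_acquisition_day(
    summaries: Sequence[SessionSummary], cfg: CriteriaConfig = CriteriaConfig()
) -> Optional[int]:
    """Day on which the third (``consecutive_days``-th) consecutive
    passing FR1 session occurs, or ``None`` if the criterion is not met
    by ``fr1_max_days`` (the mouse is excluded from further testing).

    ``summaries`` must cover contiguous days starting at day 1.
    """
    for i, s in enumerate(summaries):
        if s.day != i + 1:
            raise ValueError(f"summaries must cover contiguous days from 1; got day {s.day} at position {i}")
    streak = 0
    for s in summaries:
        streak = streak + 1 if fr1_day_passes(s, cfg) else 0
        if streak >= cfg.consecutive_days and s.day <= cfg.fr1_max_days:
            return s.day
    return None


def pr_stabilization(
    rewards_by_day: Sequence[float],
    cfg: CriteriaConfig = CriteriaConfig(),
    *,
    anchor: str = "mean",
    breakpoint: str = "mean",
) -> Optional[StabilizationResult]:
    """Scan for the earliest stabilized breakpoint window.

    A window of ``consecutive_days`` consecutive daily reward counts
    stabilizes when every day lies within ``tol`` of the anchor, where
    ``tol = max(pr_abs_tol, pr_rel_tol * anchor)`` for anchors of at
    least ``pr_small_threshold`` rewards and ``pr_abs_tol`` below it
    (the relative band would otherwise be stricter than one reward).

    Returns ``None`` when no window of the required length stabilizes.
    """
    if anchor not in ("mean", "first"):
        raise ValueError("anchor must be 'mean' or 'first'")
    if breakpoint not in ("mean", "final"):
        raise ValueError("breakpoint must be 'mean' or 'final'")
    w = cfg.consecutive_days
    n = len(rewards_by_day)
    for start in range(n - w + 1):
        window = rewards_by_day[start : start + w]
        ref = sum(window) / w if anchor == "mean" else window[0]
        tol = max(cfg.pr_abs_tol, cfg.pr_rel_tol * ref) if ref >= cfg.pr_small_threshold else cfg.pr_abs_tol
        if all(abs(x - ref) <= tol for x in window):
            bp = sum(window) / w if breakpoint == "mean" else float(window[-1])
            return StabilizationResult(day=start + w, breakpoint=bp)
    return None
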