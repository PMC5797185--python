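"""Event-log CSV format and per-session summaries.

The canonical log is a plain CSV with the fixed header::

    mouse_id,genotype,day,phase,t_ms,event,well,in_timeout,counted

one row per event (``session_start``, ``poke``, ``reward``,
``session_end``), sorted by ``t_ms`` with a reward row immediately after
the poke that earned it. Boundary rows carry session metadata in the
otherwise-unused ``well`` column: the start row holds the session
configuration as a JSON blob, the end row holds the end reason. Times
are integer milliseconds, which keeps the format free of float
formatting drift and makes the write/read round trip exact.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, TextIO

import numpy as np
import pandas as pd

from .schedules import ScheduleKind, ScheduleSpec
from .session import EndReason, EventLog, Phase, SessionConfig

__all__ = [
    "HEADER",
    "SessionSummary",
    "write_log",
    "read_log",
    "summarize",
    "summaries_to_frame",
    "ParseError",
    "LogValidationError",
]

HEADER = ["mouse_id", "genotype", "day", "phase", "t_ms", "event", "well", "in_timeout", "counted"]


class ParseError(ValueError):
    """Malformed row or header; carries the 1-based line number."""

    def __init__(self, line: int, message: str):
        self.line = line
        super().__init__(f"line {line}: {message}")


class LogValidationError(ValueError):
    """Structurally valid CSV that violates event-log semantics."""


@dataclass(frozen=True)
class SessionSummary:
    """Per-session metrics.

    ``active_inactive_ratio`` is ``inf`` when there are active but no
    inactive pokes (a maximally discriminating session) and ``None``
    when there are no pokes at all. ``breakpoint`` — the number of
    reinforcements earned — is reported for progressive-ratio sessions
    only. Timeout pokes are physical pokes and are included in the
    active/inactive/total counts, with a separate tally.
    """

    mouse_id: str
    genotype: str
    day: int
    phase: Phase
    active_pokes: int
    inactive_pokes: int
    total_pokes: int
    timeout_pokes: int
    rewards: int
    active_inactive_ratio: float | None
    breakpoint: int | None
    session_duration_s: float


def _config_to_json(config: SessionConfig) -> str:
    d = asdict(config)
    d["schedule"]["kind"] = config.schedule.kind.value
    return json.dumps(d, sort_keys=True, separators=(",", ":"))


def _config_from_json(blob: str) -> SessionConfig:
    d = json.loads(blob)
    s = d.pop("schedule")
    schedule = ScheduleSpec(
        kind=ScheduleKind(s["kind"]),
        fixed_ratio=s.get("fixed_ratio"),
        pr_scale=s.get("pr_scale", 5.0),
        pr_rate=s.get("pr_rate", 0.2),
    )
    return SessionConfig(schedule=schedule, **d)


def write_log(log: EventLog, destination: str | Path | TextIO) -> None:
    """Write one session's :class:`EventLog` as canonical CSV."""
    if hasattr(destination, "write"):
        _write_rows(log, destination)  # type: ignore[arg-type]
    else:
        with open(destination, "w", newline="", encoding="utf-8") as fh:
            _write_rows(log, fh)


def _write_rows(log: EventLog, fh: TextIO) -> None:
    w = csv.writer(fh, lineterminator="\n")
    w.writerow(HEADER)
    meta = [log.mouse_id, log.genotype, log.day, log.phase.value]
    w.writerow(meta + [0, "session_start", _config_to_json(log.config), "", ""])
    pt = log.poke_t_ms.tolist()
    pw = log.poke_well.tolist()
    pit = log.poke_in_timeout.tolist()
    pc = log.poke_counted.tolist()
    rt = log.reward_t_ms.tolist()
    ri = 0
    for i in range(len(pt)):
        w.writerow(
            meta
            + [
                pt[i],
                "poke",
                "ACTIVE" if pw[i] else "INACTIVE",
                "true" if pit[i] else "false",
                "true" if pc[i] else "false",
            ]
        )
        # a reward is triggered by a counted active poke: emit right
        # after that poke (ties: not after a coincident other poke)
        while ri < len(rt) and (
            rt[ri] < pt[i] or (rt[ri] == pt[i] and pc[i] and pw[i])
        ):
            w.writerow(meta + [rt[ri], "reward", "", "", ""])
            ri += 1
    while ri < len(rt):  # defensive; rewards always coincide with a poke
        w.writerow(meta + [rt[ri], "reward", "", "", ""])
        ri += 1
    w.writerow(meta + [log.end_t_ms, "session_end", log.end_reason.value, "", ""])


def _parse_bool(value: str, line: int) -> bool:
    if value == "true":
        return True
    if value == "false":
        return False
    raise ParseError(line, f"expected 'true' or 'false', got {value!r}")


def read_log(source: str | Path | TextIO) -> EventLog:
    """Read a canonical event-log CSV back into an :class:`EventLog`.

    Validates the header, time monotonicity, flag consistency
    (``counted`` and ``in_timeout`` are mutually exclusive), and event
    ordering (no reward before a counted active poke, exactly one
    start/end pair framing the log).
    """
    if hasattr(source, "read"):
        return _read_rows(source)  # type: ignore[arg-type]
    with open(source, "r", newline="", encoding="utf-8") as fh:
        return _read_rows(fh)


def _read_rows(fh: TextIO) -> EventLog:
    reader = csv.reader(fh)
    try:
        header = next(reader)
    except StopIteration:
        raise ParseError(1, "empty file") from None
    if header != HEADER:
        raise ParseError(1, f"bad header {header!r}")

    meta: tuple[str, str, int, Phase] | None = None
    config: SessionConfig | None = None
    end_t_ms: int | None = None
    end_reason: EndReason | None = None
    pt: list[int] = []
    pw: list[int] = []
    pit: list[bool] = []
    pc: list[bool] = []
    rt: list[int] = []
    prev_t = -1
    counted_active = 0

    for lineno, row in enumerate(reader, start=2):
        if len(row) != len(HEADER):
            raise ParseError(lineno, f"expected {len(HEADER)} fields, got {len(row)}")
        mouse_id, genotype, day_s, phase_s, t_s, event, well, in_to, cnt = row
        try:
            day = int(day_s)
            t_ms = int(t_s)
            phase = Phase(phase_s)
        except ValueError as exc:
            raise ParseError(lineno, str(exc)) from None
        if meta is None:
            if event != "session_start":
                raise LogValidationError(f"line {lineno}: first event must be session_start")
            meta = (mouse_id, genotype, day, phase)
            try:
                config = _config_from_json(well)
            except (json.JSONDecodeError, KeyError, TypeError) as exc:
                raise ParseError(lineno, f"bad config blob: {exc}") from None
            prev_t = t_ms
            continue
        if end_reason is not None:
            raise LogValidationError(f"line {lineno}: event after session_end")
        if (mouse_id, genotype, day, phase) != meta:
            raise LogValidationError(f"line {lineno}: inconsistent session metadata")
        if t_ms < prev_t:
            raise LogValidationError(f"line {lineno}: non-monotone t_ms")
        prev_t = t_ms
        if event == "poke":
            if well not in ("ACTIVE", "INACTIVE"):
                raise ParseError(lineno, f"bad well {well!r}")
            is_timeout = _parse_bool(in_to, lineno)
            is_counted = _parse_bool(cnt, lineno)
            if is_counted and is_timeout:
                raise LogValidationError(f"line {lineno}: counted poke flagged in_timeout")
            pt.append(t_ms)
            pw.append(1 if well == "ACTIVE" else 0)
            pit.append(is_timeout)
            pc.append(is_counted)
            if is_counted and well == "ACTIVE":
                counted_active += 1
        elif event == "reward":
            if counted_active == 0:
                raise LogValidationError(f"line {lineno}: reward before any counted active poke")
            rt.append(t_ms)
        elif event == "session_end":
            try:
                end_reason = EndReason(well)
            except ValueError:
                raise ParseError(lineno, f"bad end reason {well!r}") from None
            end_t_ms = t_ms
        elif event == "session_start":
            raise LogValidationError(f"line {lineno}: duplicate session_start")
        else:
            raise ParseError(lineno, f"unknown event {event!r}")

    if meta is None or config is None:
        raise LogValidationError("log has no session_start row")
    if end_reason is None or end_t_ms is None:
        raise LogValidationError("log has no session_end row")
    return EventLog(
        mouse_id=meta[0],
        genotype=meta[1],
        day=meta[2],
        phase=meta[3],
        config=config,
        poke_t_ms=np.asarray(pt, dtype=np.int64),
        poke_well=np.asarray(pw, dtype=np.int8),
        poke_in_timeout=np.asarray(pit, dtype=bool),
        poke_counted=np.asarray(pc, dtype=bool),
        reward_t_ms=np.asarray(rt, dtype=np.int64),
        end_t_ms=end_t_ms,
        end_reason=end_reason,
    )


def summarize(log: EventLog) -> SessionSummary:
    """Reduce one session to its per-session metrics."""
    active = int(np.count_nonzero(log.poke_well))
    total = log.n_pokes
    inactive = total - active
    timeout = int(np.count_nonzero(log.poke_in_timeout))
    rewards = log.n_rewards
    if total == 0:
        ratio: float | None = None
    elif inactive == 0:
        ratio = math.inf if active > 0 else None
    else:
        ratio = active / inactive
    return SessionSummary(
        mouse_id=log.mouse_id,
        genotype=log.genotype,
        day=log.day,
        phase=log.phase,
        active_pokes=active,
        inactive_pokes=inactive,
        total_pokes=total,
        timeout_pokes=timeout,
        rewards=rewards,
        active_inactive_ratio=ratio,
        breakpoint=rewards if log.phase is Phase.PR else None,
        session_duration_s=log.end_t_ms / 1000.0,
    )


def summaries_to_frame(summaries: Iterable[SessionSummary]) -> pd.DataFrame:
    """Tidy table of summaries, one row per mouse-day."""
    rows = []
    for s in summaries:
        d = asdict(s)
        d["phase"] = s.phase.value
        rows.append(d)
    return pd.DataFrame(
        rows,
        columns=[
            "mouse_id",
            "genotype",
            "day",
            "phase",
            "active_pokes",
            "inactive_pokes",
            "total_pokes",
            "timeout_pokes",
            "rewards",
            "active_inactive_ratio",
            "breakpoint",
            "session_duration_s",
        ],
    )
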