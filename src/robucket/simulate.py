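"""Virtual-mouse simulator.

A stochastic agent stands in for a food-restricted mouse working an
operant chamber through the FR1 → FR5 → PR protocol. The behavioral
model has three mechanisms, each tied to one empirical signature:

* **Throughput** — while engaged, inter-poke intervals are exponential
  with rate ``poke_rate_hz``, so a fully engaged 60-minute session
  yields about ``3600 * poke_rate_hz`` pokes.
* **Learning** — each poke targets the active well with probability
  ``p_active(day) = floor + (ceiling - floor) * logistic((day - midpoint)
  / slope)``; the day counter accumulates across phases, so
  discrimination learned during FR1 carries into FR5 and PR.
* **Persistence** — in progressive-ratio sessions only, immediately
  after earning reward *k* the agent remains engaged with probability
  ``exp(-r_{k+1} / persistence)``, where ``r_{k+1}`` is the next
  response requirement. Disengagement is absorbing for the rest of the
  session: the agent then pokes at ``disengaged_rate_hz`` with
  ``disengaged_p_active``, which keeps the breakpoint interpretable as
  the final reinforcement earned. Fixed-ratio sessions skip the check.

Genotype cohorts are drawn from :class:`GenotypeProfile` distributions
(lognormal for positive parameters, logit-normal for probabilities).
In the frozen default profiles only ``persistence`` differs between
genotypes — a motivation-specific deficit with fixed-ratio performance
left intact.

Randomness is seeded through a single master seed; each mouse gets its
own :class:`numpy.random.SeedSequence` child and each session a child
of that, so enlarging a cohort never perturbs mice already simulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .criteria import CriteriaConfig, MouseProgress, fr1_day_passes, pr_stabilization
from .event_io import SessionSummary, summaries_to_frame, summarize
from .schedules import ScheduleKind, requirement_for
from .session import EventLog, Phase, SessionConfig, _ms, _process, run_session

__all__ = [
    "ParamDist",
    "AgentParams",
    "GenotypeProfile",
    "ProtocolConfig",
    "CohortSpec",
    "CohortResult",
    "sample_agent",
    "simulate_session",
    "simulate_protocol",
    "simulate_cohort",
    "default_profiles",
    "default_protocol",
]


# ---------------------------------------------------------------------------
# parameters and their between-mouse distributions


@dataclass(frozen=True)
class AgentParams:
    """Behavioral parameters of a single virtual mouse.

    ``poke_rate_hz`` — engaged poke rate (Hz). ``p_active_floor`` /
    ``p_active_ceiling`` — pre- and post-learning probability of
    choosing the active well. ``learning_midpoint_day`` /
    ``learning_slope_days`` — center and width (days) of the logistic
    learning curve. ``persistence`` — effort scale (pokes) of the
    progressive-ratio engagement check. ``disengaged_rate_hz`` /
    ``disengaged_p_active`` — residual poking after disengagement.
    """

    poke_rate_hz: float
    p_active_floor: float = 0.5
    p_active_ceiling: float = 0.9
    learning_midpoint_day: float = 4.5
    learning_slope_days: float = 1.0
    persistence: float = 100.0
    disengaged_rate_hz: float = 0.01
    disengaged_p_active: float = 0.5

    def __post_init__(self) -> None:
        if self.poke_rate_hz <= 0:
            raise ValueError("poke_rate_hz must be positive")
        for name in ("p_active_floor", "p_active_ceiling", "disengaged_p_active"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a probability")
        if self.p_active_floor > self.p_active_ceiling:
            raise ValueError("p_active_floor must not exceed p_active_ceiling")
        if self.learning_midpoint_day <= 0 or self.learning_slope_days <= 0:
            raise ValueError("learning curve parameters must be positive")
        if not self.persistence > 0:
            raise ValueError("persistence must be positive")
        if self.disengaged_rate_hz < 0:
            raise ValueError("disengaged_rate_hz must be non-negative")

    def p_active(self, day: float) -> float:
        """Active-well choice probability on a given (global) day."""
        z = (day - self.learning_midpoint_day) / self.learning_slope_days
        return self.p_active_floor + (self.p_active_ceiling - self.p_active_floor) / (
            1.0 + math.exp(-z)
        )


@dataclass(frozen=True)
class ParamDist:
    """Between-mouse distribution of one parameter.

    ``lognormal``: ``dispersion`` is the SD of log values; ``mean`` is
    the arithmetic mean of the distribution. ``logit_normal``:
    ``dispersion`` is the SD on the logit scale around ``logit(mean)``.
    Zero dispersion collapses to the mean exactly.
    """

    mean: float
    dispersion: float = 0.0
    kind: str = "lognormal"

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.kind not in ("lognormal", "logit_normal"):
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if self.kind == "lognormal":
            if self.mean < 0:
                raise ValueError("lognormal mean must be non-negative")
            if self.mean == 0 and self.dispersion > 0:
                raise ValueError("zero mean requires zero dispersion")
        if self.kind == "logit_normal" and not 0.0 < self.mean < 1.0:
            raise ValueError("logit_normal mean must be in (0, 1)")

    def draw(self, rng: np.random.Generator) -> float:
        z = rng.standard_normal()  # one draw even at zero dispersion keeps streams aligned
        if self.dispersion == 0.0:
            return self.mean
        if self.kind == "lognormal":
            if math.isinf(self.mean) or self.mean == 0:
                return self.mean
            mu = math.log(self.mean) - 0.5 * self.dispersion**2
            return math.exp(mu + self.dispersion * z)
        logit = math.log(self.mean / (1.0 - self.mean))
        return 1.0 / (1.0 + math.exp(-(logit + self.dispersion * z)))


_PARAM_NAMES = (
    "poke_rate_hz",
    "p_active_floor",
    "p_active_ceiling",
    "learning_midpoint_day",
    "learning_slope_days",
    "persistence",
    "disengaged_rate_hz",
    "disengaged_p_active",
)


@dataclass(frozen=True)
class GenotypeProfile:
    """A genotype's label and per-parameter between-mouse distributions."""

    label: str
    params: dict[str, ParamDist]

    def __post_init__(self) -> None:
        unknown = set(self.params) - set(_PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameters: {sorted(unknown)}")
        missing = set(_PARAM_NAMES) - set(self.params)
        if missing:
            raise ValueError(f"missing parameters: {sorted(missing)}")


def sample_agent(profile: GenotypeProfile, rng: np.random.Generator) -> AgentParams:
    """Draw one virtual mouse from a genotype profile.

    A rare learning-ceiling draw below the floor is clamped to the
    floor: such a mouse never discriminates (and is later excluded at
    the FR1 cap) rather than being an invalid agent.
    """
    draws = {name: profile.params[name].draw(rng) for name in _PARAM_NAMES}
    if draws["p_active_ceiling"] < draws["p_active_floor"]:
        draws["p_active_ceiling"] = draws["p_active_floor"]
    return AgentParams(**draws)


# ---------------------------------------------------------------------------
# frozen default profiles and protocol
#
# Calibrated once by grid search against the study conditions this
# simulator emulates: FR1 acquisition in ~7.5 +/- 2.4 days with ~5% of
# mice excluded, ~273 total pokes per fully engaged 60-minute FR5
# session, and a ~37-46% reduction in the stabilized progressive-ratio
# breakpoint of the mutant genotype with a large effect size. Only
# `persistence` differs between genotypes.

_SHARED_PARAMS = dict(
    poke_rate_hz=ParamDist(0.076, 0.17),
    p_active_floor=ParamDist(0.5, 0.0, "logit_normal"),
    p_active_ceiling=ParamDist(0.92, 0.80, "logit_normal"),
    learning_midpoint_day=ParamDist(4.2, 0.50),
    learning_slope_days=ParamDist(1.0, 0.20),
    disengaged_rate_hz=ParamDist(0.01, 0.0),
    disengaged_p_active=ParamDist(0.5, 0.0, "logit_normal"),
)

WILD_TYPE_PERSISTENCE = ParamDist(330.0, 0.90)
MUTANT_PERSISTENCE = ParamDist(58.0, 1.00)


def default_profiles() -> tuple[GenotypeProfile, GenotypeProfile]:
    """Frozen wild-type (Htt+/+) and mutant (HttQ111/+) profiles."""
    wt = GenotypeProfile("Htt+/+", {**_SHARED_PARAMS, "persistence": WILD_TYPE_PERSISTENCE})
    mut = GenotypeProfile("HttQ111/+", {**_SHARED_PARAMS, "persistence": MUTANT_PERSISTENCE})
    return wt, mut


@dataclass(frozen=True)
class ProtocolConfig:
    """Phase order, per-phase session configs, and progression criteria.

    ``phases`` may be restricted (e.g. ``("PR",)`` with ``start_day``
    set past the learning curve) for breakpoint-focused experiments.
    ``pr_max_days`` is a safety cap; a mouse that has not stabilized by
    then is reported with ``pr_stabilization_day=None``.
    """

    fr1: SessionConfig = field(default_factory=lambda: SessionConfig.for_phase(Phase.FR1))
    fr5: SessionConfig = field(default_factory=lambda: SessionConfig.for_phase(Phase.FR5))
    pr: SessionConfig = field(default_factory=lambda: SessionConfig.for_phase(Phase.PR))
    criteria: CriteriaConfig = field(default_factory=CriteriaConfig)
    phases: tuple[str, ...] = ("FR1", "FR5", "PR")
    pr_max_days: int = 30
    start_day: int = 1


def default_protocol(**overrides) -> ProtocolConfig:
    return ProtocolConfig(**overrides)


# ---------------------------------------------------------------------------
# session generation


def _poisson_stream(
    rate_hz: float, p_active: float, t0_s: float, t_end_s: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Homogeneous-Poisson poke stream on (t0, t_end): times (s) and wells."""
    if rate_hz <= 0 or t_end_s <= t0_s:
        return np.empty(0), np.empty(0, dtype=np.int8)
    span = t_end_s - t0_s
    expected = rate_hz * span
    times = np.empty(0)
    n_next = int(expected + 6.0 * math.sqrt(expected + 1.0) + 8.0)
    last = t0_s
    while True:
        gaps = rng.exponential(1.0 / rate_hz, n_next)
        times = np.concatenate([times, last + np.cumsum(gaps)])
        if times[-1] >= t_end_s:
            break
        last = float(times[-1])
        n_next = max(8, int(0.2 * expected))
    times = times[times < t_end_s]
    wells = (rng.random(times.size) < p_active).astype(np.int8)
    return times, wells


def simulate_session(
    agent: AgentParams,
    config: SessionConfig,
    day: int,
    rng: np.random.Generator,
    *,
    mouse_id: str = "sim",
    genotype: str = "",
    phase: Phase | str = Phase.FR1,
    session_day: Optional[int] = None,
) -> EventLog:
    """Simulate one session and return its full :class:`EventLog`.

    ``day`` drives the learning curve (global, accumulating across
    phases); ``session_day`` is the label recorded in the log (defaults
    to ``day``). The progressive-ratio engagement check applies iff the
    session's schedule is progressive-ratio.
    """
    phase = Phase(phase)
    p_act = agent.p_active(day)
    duration = config.max_duration_s
    t, w = _poisson_stream(agent.poke_rate_hz, p_act, 0.0, duration, rng)

    if config.schedule.kind is ScheduleKind.PROGRESSIVE_RATIO:
        t_ms = np.floor(t * 1000.0 + 0.5).astype(np.int64)
        # First pass: rewards the agent would earn if it never quit.
        _, _, reward_t, reward_idx, _, _, _ = _process(
            t_ms.tolist(),
            w.tolist(),
            config.schedule,
            _ms(config.timeout_s),
            _ms(duration),
            None,
        )
        cut: Optional[int] = None  # poke index of the reward after which the agent quits
        quit_t = duration
        for k in range(len(reward_t)):
            r_next = requirement_for(config.schedule, k + 1)
            p_stay = math.exp(-r_next / agent.persistence) if math.isfinite(agent.persistence) else 1.0
            if rng.random() >= p_stay:
                cut = reward_idx[k]
                quit_t = reward_t[k] / 1000.0
                break
        if cut is not None:
            t, w = t[: cut + 1], w[: cut + 1]
            t_tail, w_tail = _poisson_stream(
                agent.disengaged_rate_hz, agent.disengaged_p_active, quit_t, duration, rng
            )
            t = np.concatenate([t, t_tail])
            w = np.concatenate([w, w_tail])

    return run_session(
        config,
        (t, w),
        mouse_id=mouse_id,
        genotype=genotype,
        day=session_day if session_day is not None else day,
        phase=phase,
    )


# ---------------------------------------------------------------------------
# protocols and cohorts


def simulate_protocol(
    agent: AgentParams,
    protocol: ProtocolConfig,
    seed: np.random.SeedSequence | int,
    *,
    mouse_id: str = "sim",
    genotype: str = "",
    keep_logs: bool = True,
) -> tuple[list[EventLog], MouseProgress, list[SessionSummary]]:
    """Run one virtual mouse through the full protocol.

    FR1 sessions run daily until the acquisition criterion (or exclusion
    at the 17-day cap), then a fixed block of FR5 sessions, then PR
    sessions daily until breakpoint stabilization (or the ``pr_max_days``
    safety cap). The learning-day counter accumulates across phases.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    crit = protocol.criteria
    logs: list[EventLog] = []
    summaries: list[SessionSummary] = []
    progress = MouseProgress(mouse_id=mouse_id, genotype=genotype)
    global_day = protocol.start_day

    def _rng() -> np.random.Generator:
        return np.random.default_rng(ss.spawn(1)[0])

    def _run(cfg: SessionConfig, phase: Phase, phase_day: int) -> SessionSummary:
        nonlocal global_day
        log = simulate_session(
            agent,
            cfg,
            global_day,
            _rng(),
            mouse_id=mouse_id,
            genotype=genotype,
            phase=phase,
            session_day=phase_day,
        )
        global_day += 1
        if keep_logs:
            logs.append(log)
        s = summarize(log)
        summaries.append(s)
        return s

    if "FR1" in protocol.phases:
        streak = 0
        for d in range(1, crit.fr1_max_days + 1):
            s = _run(protocol.fr1, Phase.FR1, d)
            streak = streak + 1 if fr1_day_passes(s, crit) else 0
            if streak >= crit.consecutive_days:
                progress.fr1_days_to_criteria = d
                break
        if progress.fr1_days_to_criteria is None:
            progress.excluded = True
            return logs, progress, summaries

    if "FR5" in protocol.phases:
        for d in range(1, crit.fr5_days + 1):
            _run(protocol.fr5, Phase.FR5, d)
            progress.fr5_sessions += 1

    if "PR" in protocol.phases:
        rewards_by_day: list[int] = []
        for d in range(1, protocol.pr_max_days + 1):
            s = _run(protocol.pr, Phase.PR, d)
            progress.pr_days = d
            rewards_by_day.append(s.rewards)
            stab = pr_stabilization(rewards_by_day, crit)
            if stab is not None:
                progress.pr_stabilization_day = stab.day
                progress.breakpoint = stab.breakpoint
                break

    return logs, progress, summaries


@dataclass(frozen=True)
class CohortSpec:
    """Cohort design: genotype profiles, group sizes, protocol, seed."""

    profiles: tuple[GenotypeProfile, ...]
    n_per_genotype: tuple[int, ...]
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.profiles) != len(self.n_per_genotype):
            raise ValueError("profiles and n_per_genotype must align")
        if any(n < 1 for n in self.n_per_genotype):
            raise ValueError("each genotype needs n >= 1")


@dataclass
class CohortResult:
    """All per-session summaries, per-mouse progress, and (optionally)
    the raw event logs of one simulated cohort."""

    spec: CohortSpec
    summaries: pd.DataFrame
    progress: pd.DataFrame
    logs: list[EventLog] = field(default_factory=list)

    def group_breakpoints(self) -> dict[str, np.ndarray]:
        """Stabilized breakpoints per genotype (mice that stabilized)."""
        out: dict[str, np.ndarray] = {}
        for label, g in self.progress.groupby("genotype", sort=False):
            out[label] = g["breakpoint"].dropna().to_numpy(dtype=float)
        return out


def simulate_cohort(spec: CohortSpec, *, keep_logs: bool = False) -> CohortResult:
    """Simulate independent virtual mice for every genotype.

    The master seed is split into one substream per mouse (agent draw +
    all of its sessions), so changing cohort sizes leaves earlier mice
    untouched.
    """
    master = np.random.SeedSequence(spec.seed)
    total = sum(spec.n_per_genotype)
    children = master.spawn(total)
    logs: list[EventLog] = []
    all_summaries: list[SessionSummary] = []
    prog_rows = []
    i = 0
    for profile, n in zip(spec.profiles, spec.n_per_genotype):
        for j in range(n):
            child = children[i]
            i += 1
            agent_ss, protocol_ss = child.spawn(2)
            agent = sample_agent(profile, np.random.default_rng(agent_ss))
            mouse_id = f"{profile.label}_{j + 1:02d}"
            mlogs, progress, msums = simulate_protocol(
                agent,
                spec.protocol,
                protocol_ss,
                mouse_id=mouse_id,
                genotype=profile.label,
                keep_logs=keep_logs,
            )
            logs.extend(mlogs)
            all_summaries.extend(msums)
            prog_rows.append(
                dict(
                    mouse_id=progress.mouse_id,
                    genotype=progress.genotype,
                    fr1_days_to_criteria=progress.fr1_days_to_criteria,
                    excluded=progress.excluded,
                    fr5_sessions=progress.fr5_sessions,
                    pr_days=progress.pr_days,
                    pr_stabilization_day=progress.pr_stabilization_day,
                    breakpoint=progress.breakpoint,
                )
            )
    return CohortResult(
        spec=spec,
        summaries=summaries_to_frame(all_summaries),
        progress=pd.DataFrame(prog_rows),
        logs=logs,
    )
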