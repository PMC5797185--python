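"""YAML configuration loading.

Schedules are written as ``{kind: FR, n: 5}`` or
``{kind: PR, scale: 5.0, rate: 0.2}``. A cohort file looks like::

    seed: 42
    genotypes:
      - label: "Htt+/+"
        n: 8
        params:
          persistence: {mean: 330.0, dispersion: 0.55}
      - label: "HttQ111/+"
        n: 12
        params:
          persistence: {mean: 75.0, dispersion: 0.55}
    protocol:
      pr_max_days: 30

Genotype ``params`` override individual entries of the frozen default
profile; omitted parameters keep their defaults.
"""

from __future__ import annotations

from pathlib import Path
from typing import IO, Any

import yaml

from .criteria import CriteriaConfig
from .schedules import ScheduleSpec
from .session import Phase, SessionConfig
from .simulate import (
    _PARAM_NAMES,
    _SHARED_PARAMS,
    CohortSpec,
    GenotypeProfile,
    ParamDist,
    ProtocolConfig,
    default_profiles,
)

__all__ = [
    "load_schedule",
    "load_session_config",
    "load_criteria",
    "load_protocol",
    "load_cohort_spec",
]

_DEFAULT_DIST_KIND = {
    name: dist.kind for name, dist in {**_SHARED_PARAMS, "persistence": ParamDist(1.0)}.items()
}


def load_schedule(d: dict[str, Any]) -> ScheduleSpec:
    kind = str(d.get("kind", "")).upper()
    if kind in ("FR", "FIXED_RATIO"):
        return ScheduleSpec.fixed(int(d["n"]))
    if kind in ("PR", "PROGRESSIVE_RATIO"):
        return ScheduleSpec.progressive(
            scale=float(d.get("scale", 5.0)), rate=float(d.get("rate", 0.2))
        )
    raise ValueError(f"unknown schedule kind {d.get('kind')!r}")


def load_session_config(d: dict[str, Any], phase: Phase | str | None = None) -> SessionConfig:
    d = dict(d)
    if "schedule" in d:
        d["schedule"] = load_schedule(d["schedule"])
        return SessionConfig(**d)
    if phase is None:
        raise ValueError("session config needs a schedule or a phase")
    return SessionConfig.for_phase(phase, **d)


def load_criteria(d: dict[str, Any]) -> CriteriaConfig:
    return CriteriaConfig(**d)


def load_protocol(d: dict[str, Any]) -> ProtocolConfig:
    kwargs: dict[str, Any] = {}
    for phase in ("fr1", "fr5", "pr"):
        if phase in d:
            kwargs[phase] = load_session_config(d[phase], phase.upper())
    if "criteria" in d:
        kwargs["criteria"] = load_criteria(d["criteria"])
    for key in ("phases", "pr_max_days", "start_day"):
        if key in d:
            kwargs[key] = tuple(d[key]) if key == "phases" else int(d[key])
    return ProtocolConfig(**kwargs)


def _load_profile(d: dict[str, Any]) -> GenotypeProfile:
    label = str(d["label"])
    base: dict[str, ParamDist] = dict(default_profiles()[0].params)
    for name, spec in (d.get("params") or {}).items():
        if name not in _PARAM_NAMES:
            raise ValueError(f"unknown agent parameter {name!r}")
        if isinstance(spec, dict):
            base[name] = ParamDist(
                mean=float(spec["mean"]),
                dispersion=float(spec.get("dispersion", 0.0)),
                kind=str(spec.get("kind", _DEFAULT_DIST_KIND[name])),
            )
        else:
            base[name] = ParamDist(float(spec), 0.0, _DEFAULT_DIST_KIND[name])
    return GenotypeProfile(label=label, params=base)


def load_cohort_spec(source: str | Path | IO[str]) -> CohortSpec:
    """Load a cohort specification from a YAML file or stream."""
    if hasattr(source, "read"):
        d = yaml.safe_load(source)
    else:
        with open(source, "r", encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
    if not isinstance(d, dict) or "genotypes" not in d:
        raise ValueError("cohort config must be a mapping with a 'genotypes' list")
    profiles = []
    ns = []
    for g in d["genotypes"]:
        profiles.append(_load_profile(g))
        ns.append(int(g.get("n", 12)))
    protocol = load_protocol(d.get("protocol") or {})
    return CohortSpec(
        profiles=tuple(profiles),
        n_per_genotype=tuple(ns),
        protocol=protocol,
        seed=int(d.get("seed", 0)),
    )
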