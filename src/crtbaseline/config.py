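"""YAML configuration for trial scenarios.

A scenario file mirrors the design fields in calendar units (months), plus
the correlation parameters and time-effect choice, e.g.::

    months: 24
    m: 172
    crossover_months: 15
    closure_months: 6
    implementation_months: 3
    control_recruits_in_transition: false
    no_baseline: false
    rho: 0.05
    tau: 1.0
    sigma2: 1.0
    time_effect: step        # or: polynomial
    degree: 0

Calendar durations are converted to the normalised [0, 1] trial clock by the
single ``months`` duration.
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

from .design import ConfigurationError, CorrelationParams, DesignSpec, TimeEffectSpec

__all__ = ["Scenario", "load_scenario"]

_KNOWN_KEYS = {
    "months",
    "m",
    "crossover_months",
    "closure_months",
    "implementation_months",
    "control_recruits_in_transition",
    "no_baseline",
    "rho",
    "tau",
    "sigma2",
    "time_effect",
    "degree",
}


@dataclass(frozen=True)
class Scenario:
    design: DesignSpec
    corr: CorrelationParams
    time_effect: TimeEffectSpec
    months: float


def scenario_from_dict(raw: dict) -> Scenario:
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
    months = float(raw.get("months", 1.0))
    if months <= 0:
        raise ConfigurationError("months must be positive")
    no_baseline = bool(raw.get("no_baseline", False))
    implementation = float(raw.get("implementation_months", 0.0)) / months
    closure = float(raw.get("closure_months", 0.0)) / months
    if no_baseline:
        design = DesignSpec.without_baseline(
            m=int(raw["m"]),
            implementation=implementation,
            control_recruits_in_transition=bool(
                raw.get("control_recruits_in_transition", False)
            ),
        )
    else:
        if "crossover_months" not in raw:
            raise ConfigurationError("crossover_months is required unless no_baseline")
        design = DesignSpec(
            m=int(raw["m"]),
            crossover=float(raw["crossover_months"]) / months,
            closure=closure,
            implementation=implementation,
            control_recruits_in_transition=bool(
                raw.get("control_recruits_in_transition", False)
            ),
        )
    corr = CorrelationParams(
        rho=float(raw.get("rho", 0.0)),
        tau=float(raw.get("tau", 1.0)),
        sigma2=float(raw.get("sigma2", 1.0)),
    )
    kind = raw.get("time_effect", "step")
    te = TimeEffectSpec(kind=kind, degree=int(raw.get("degree", 3 if kind == "polynomial" else 0)))
    return Scenario(design=design, corr=corr, time_effect=te, months=months)


def load_scenario(path) -> Scenario:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("scenario file must be a mapping")
    return scenario_from_dict(raw)
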