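"""Trial designs and their realised observation grids.

A two-arm cluster randomised trial recruits participants continuously over a
fixed calendar period, normalised to the unit interval.  The intervention arm
may start with a *baseline* period under the control condition and cross over
to the intervention at time ``t*`` (``crossover``).  A *transition* window
immediately before the cross-over — a closure period (control participants
clear the system) followed by an implementation period (the intervention is
set up) — yields observations that cannot be attributed cleanly to either
condition and are excluded from analysis.

All computations here are per cluster pattern: one control cluster and one
intervention cluster.  Scaling to ``J`` clusters per arm is by the
``sigma^2 / J`` multiplier rule (see :mod:`crtbaseline.variance`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CONTROL = "control"
INTERVENTION = "intervention"

__all__ = [
    "ConfigurationError",
    "DesignSpec",
    "ObservationGrid",
    "CorrelationParams",
    "TimeEffectSpec",
    "build_observation_grid",
    "arrival_table",
]


class ConfigurationError(ValueError):
    """A design specification violates one of its structural constraints."""


@dataclass(frozen=True)
class DesignSpec:
    """One candidate trial design.

    Parameters
    ----------
    m
        Arrivals per cluster over the whole trial period (the cluster size,
        equivalently the recruitment rate on the normalised clock).  Arrivals
        are regularly spaced at ``1/m, 2/m, ..., m/m``.
    crossover
        Time ``t*`` in ``[0, 1]`` at which recruitment under the intervention
        condition begins in the intervention arm.
    closure
        Duration of the closure component of the transition period.
    implementation
        Duration of the implementation component of the transition period.
    control_recruits_in_transition
        If True, control-arm arrivals during the intervention arm's
        transition window are retained in the analysis; by default they are
        excluded along with the intervention arm's.
    no_baseline
        If True, the intervention arm starts the trial in the intervention
        condition.  No closure period is needed; recruitment in the
        intervention arm is delayed only by the implementation period, and
        ``crossover == implementation`` by construction.
    """

    m: int
    crossover: float
    closure: float = 0.0
    implementation: float = 0.0
    control_recruits_in_transition: bool = False
    no_baseline: bool = False

    def __post_init__(self) -> None:
        if not (isinstance(self.m, (int, np.integer)) and self.m >= 1):
            raise ConfigurationError(f"m must be a positive integer, got {self.m!r}")
        for name in ("closure", "implementation"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1), got {v}")
        if self.closure + self.implementation >= 1.0:
            raise ConfigurationError(
                "transition period (closure + implementation = "
                f"{self.closure + self.implementation}) must be shorter than the trial"
            )
        if not 0.0 <= self.crossover <= 1.0:
            raise ConfigurationError(f"crossover must lie in [0, 1], got {self.crossover}")
        if self.no_baseline:
            if self.closure != 0.0:
                raise ConfigurationError(
                    "a no-baseline design has no closure period; set closure=0"
                )
            if abs(self.crossover - self.implementation) > 1e-12:
                raise ConfigurationError(
                    "in a no-baseline design crossover equals the implementation "
                    f"duration by construction (got crossover={self.crossover}, "
                    f"implementation={self.implementation})"
                )
        else:
            if self.crossover < self.closure + self.implementation - 1e-12:
                raise ConfigurationError(
                    f"negative baseline: crossover ({self.crossover}) is earlier than "
                    f"the transition duration ({self.closure + self.implementation}); "
                    "the transition window must fit before the cross-over"
                )

    @classmethod
    def without_baseline(
        cls,
        m: int,
        implementation: float = 0.0,
        control_recruits_in_transition: bool = False,
    ) -> "DesignSpec":
        """The design in which the intervention arm starts treated."""
        return cls(
            m=m,
            crossover=implementation,
            closure=0.0,
            implementation=implementation,
            control_recruits_in_transition=control_recruits_in_transition,
            no_baseline=True,
        )

    @property
    def transition_window(self) -> tuple[float, float]:
        """Half-open exclusion window ``[start, t*)`` on the normalised clock."""
        if self.no_baseline:
            return (0.0, self.implementation)
        return (self.crossover - self.closure - self.implementation, self.crossover)

    @property
    def baseline_duration(self) -> float:
        """Length of the prospective baseline period (0 for no-baseline designs)."""
        if self.no_baseline:
            return 0.0
        return self.transition_window[0]

    def arrival_times(self) -> np.ndarray:
        """Regularly spaced arrival times ``i/m`` for ``i = 1..m``."""
        return np.arange(1, self.m + 1) / self.m


@dataclass(frozen=True)
class CorrelationParams:
    """Decaying intracluster-correlation model.

    Two same-cluster outcomes sampled a time ``|dt|`` apart (on the
    normalised clock) correlate as ``rho * tau ** |dt|``:  ``rho`` is the ICC
    at zero lag and ``tau`` the factor by which it has decayed across the
    whole trial period.  ``tau = 1`` recovers compound symmetry.
    """

    rho: float
    tau: float = 1.0
    sigma2: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise ConfigurationError(f"rho must lie in [0, 1), got {self.rho}")
        if not 0.0 < self.tau <= 1.0:
            raise ConfigurationError(f"tau must lie in (0, 1], got {self.tau}")
        if not self.sigma2 > 0.0:
            raise ConfigurationError(f"sigma2 must be positive, got {self.sigma2}")

    def covariance(self, times: np.ndarray) -> np.ndarray:
        """Within-cluster covariance matrix for outcomes observed at `times`."""
        t = np.asarray(times, dtype=float)
        lag = np.abs(t[:, None] - t[None, :])
        v = self.sigma2 * self.rho * self.tau**lag
        np.fill_diagonal(v, self.sigma2)
        return v


@dataclass(frozen=True)
class TimeEffectSpec:
    """Fixed effect of time on the outcome.

    ``kind="step"`` models a piecewise-constant time effect with its
    discontinuity exactly at the cross-over: columns are an intercept and a
    post-cross-over indicator.  With ``degree > 0``, polynomial terms are
    appended to the step model (the treatment variance is provably unchanged
    by such additions; see the invariance tests).

    ``kind="polynomial"`` models a continuous polynomial trend of the given
    degree: intercept plus powers of time, evaluated internally on the
    centred, scaled basis ``(2t - 1)**k`` for numerical conditioning.  The
    reported treatment variance is basis-invariant.
    """

    kind: str = "step"
    degree: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("step", "polynomial"):
            raise ConfigurationError(f"kind must be 'step' or 'polynomial', got {self.kind!r}")
        if not (isinstance(self.degree, (int, np.integer)) and self.degree >= 0):
            raise ConfigurationError(f"degree must be a non-negative integer, got {self.degree!r}")
        if self.kind == "polynomial" and self.degree < 1:
            raise ConfigurationError("polynomial time effect needs degree >= 1")

    @classmethod
    def step(cls, extra_degree: int = 0) -> "TimeEffectSpec":
        return cls(kind="step", degree=extra_degree)

    @classmethod
    def polynomial(cls, degree: int = 3) -> "TimeEffectSpec":
        return cls(kind="polynomial", degree=degree)

    def columns(self, times: np.ndarray, crossover: float) -> tuple[np.ndarray, list[str]]:
        """Fixed-effect time columns evaluated at `times`."""
        t = np.asarray(times, dtype=float)
        cols = [np.ones_like(t)]
        names = ["intercept"]
        if self.kind == "step":
            cols.append((t >= crossover).astype(float))
            names.append("post")
        s = 2.0 * t - 1.0  # centred/scaled basis for conditioning
        for k in range(1, self.degree + 1):
            cols.append(s**k)
            names.append(f"time^{k}")
        return np.column_stack(cols), names


@dataclass(frozen=True)
class ObservationGrid:
    """Retained arrivals of one control and one intervention cluster.

    Observations are stored control block first, then intervention block.
    ``treated`` is 1 exactly for intervention-arm observations at or after
    the cross-over.
    """

    times: np.ndarray
    arm: np.ndarray
    treated: np.ndarray
    n_control: int
    n_intervention: int

    def times_in(self, arm: str) -> np.ndarray:
        return self.times[self.arm == arm]

    def treated_in(self, arm: str) -> np.ndarray:
        return self.treated[self.arm == arm]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"arm": self.arm, "time": self.times, "treated": self.treated}
        )


def _retained_mask(spec: DesignSpec, times: np.ndarray, arm: str) -> np.ndarray:
    lo, hi = spec.transition_window
    in_window = (times >= lo) & (times < hi)
    if arm == CONTROL and spec.control_recruits_in_transition:
        return np.ones_like(times, dtype=bool)
    return ~in_window


def build_observation_grid(spec: DesignSpec) -> ObservationGrid:
    """Materialise a design into the retained observations of one cluster per arm.

    Arrivals occur at ``i/m``; intervention-arm arrivals inside the half-open
    transition window ``[t* - closure - implementation, t*)`` are dropped,
    and control-arm arrivals in the same window are dropped unless the design
    retains them.  An observation is treated iff it belongs to the
    intervention arm and arrives at or after the cross-over.
    """
    t = spec.arrival_times()
    ctrl_t = t[_retained_mask(spec, t, CONTROL)]
    int_t = t[_retained_mask(spec, t, INTERVENTION)]
    times = np.concatenate([ctrl_t, int_t])
    arm = np.concatenate(
        [np.full(ctrl_t.size, CONTROL), np.full(int_t.size, INTERVENTION)]
    )
    treated = ((arm == INTERVENTION) & (times >= spec.crossover)).astype(np.int8)
    return ObservationGrid(
        times=times,
        arm=arm,
        treated=treated,
        n_control=int(ctrl_t.size),
        n_intervention=int(int_t.size),
    )


def arrival_table(spec: DesignSpec) -> pd.DataFrame:
    """Tidy table of every arrival in both arms, retained or not.

    Columns: ``arm``, ``index`` (1-based arrival number), ``time``,
    ``treated``, ``retained``.
    """
    t = spec.arrival_times()
    rows = []
    for arm in (CONTROL, INTERVENTION):
        keep = _retained_mask(spec, t, arm)
        treated = ((arm == INTERVENTION) & (t >= spec.crossover) & keep).astype(int)
        rows.append(
            pd.DataFrame(
                {
                    "arm": arm,
                    "index": np.arange(1, spec.m + 1),
                    "time": t,
                    "treated": treated,
                    "retained": keep.astype(int),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
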