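"""Monte-Carlo validation of the analytic variance.

Outcomes are drawn from the same model the variance engine assumes: each
cluster's outcome vector is multivariate normal with mean given by the fixed
time effect plus the treatment effect, and covariance ``sigma^2 * rho *
tau**|dt|`` within cluster (clusters independent).  Refitting each replicate
by GLS with the covariance treated as known — the design-stage assumption —
lets the empirical variance of the treatment-effect estimates be compared
with the analytic multiplier.

The true time effect is specified by coefficients on the same column basis
the fitted model uses (intercept, post indicator and/or centred-scaled
polynomial terms; see :class:`crtbaseline.design.TimeEffectSpec`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky
from scipy.stats import chi2

from .design import (
    CONTROL,
    INTERVENTION,
    ConfigurationError,
    CorrelationParams,
    DesignSpec,
    TimeEffectSpec,
    build_observation_grid,
)
from .variance import build_model_matrices

__all__ = [
    "SimulationConfig",
    "GLSFit",
    "ValidationResult",
    "simulate_trial",
    "fit_gls",
    "validate_design",
]


@dataclass(frozen=True)
class SimulationConfig:
    design: DesignSpec
    corr: CorrelationParams
    time_effect: TimeEffectSpec
    theta: float = 0.0
    time_coefficients: tuple[float, ...] | None = None
    j_clusters: int = 1
    replications: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replications < 1:
            raise ConfigurationError("replications must be >= 1")
        if self.j_clusters < 1:
            raise ConfigurationError("j_clusters must be >= 1")


def _arm_patterns(config: SimulationConfig):
    """Per-arm (times, mean vector, covariance Cholesky factor)."""
    grid = build_observation_grid(config.design)
    out = {}
    for arm in (CONTROL, INTERVENTION):
        t = grid.times_in(arm)
        T, _ = config.time_effect.columns(t, config.design.crossover)
        coef = (
            np.zeros(T.shape[1])
            if config.time_coefficients is None
            else np.asarray(config.time_coefficients, dtype=float)
        )
        if coef.size != T.shape[1]:
            raise ConfigurationError(
                f"time_coefficients must have {T.shape[1]} entries for this "
                f"time effect, got {coef.size}"
            )
        mean = T @ coef + config.theta * grid.treated_in(arm)
        L = cholesky(config.corr.covariance(t), lower=True)
        out[arm] = (t, grid.treated_in(arm), mean, L)
    return grid, out


def _draw(config: SimulationConfig) -> dict[str, np.ndarray]:
    """Outcome draws, shape (replications, j_clusters, n_obs) per arm."""
    rng = np.random.default_rng(config.seed)
    _, patterns = _arm_patterns(config)
    draws = {}
    for arm in (CONTROL, INTERVENTION):
        _, _, mean, L = patterns[arm]
        n = mean.size
        z = rng.standard_normal((config.replications, config.j_clusters, n))
        draws[arm] = mean + z @ L.T
    return draws


def simulate_trial(config: SimulationConfig) -> pd.DataFrame:
    """Generate per-replication outcome tables.

    Returns a long table with columns ``replication``, ``arm``, ``cluster``,
    ``time``, ``treated``, ``y``.  Clusters are labelled ``1..J`` within each
    arm.  Reproducible: the seed fully determines the output.
    """
    _, patterns = _arm_patterns(config)
    draws = _draw(config)
    frames = []
    for arm in (CONTROL, INTERVENTION):
        t, treated, _, _ = patterns[arm]
        y = draws[arm]  # (R, J, n)
        R, J, n = y.shape
        frames.append(
            pd.DataFrame(
                {
                    "replication": np.repeat(np.arange(R), J * n),
                    "arm": arm,
                    "cluster": np.tile(np.repeat(np.arange(1, J + 1), n), R),
                    "time": np.tile(t, R * J),
                    "treated": np.tile(treated, R * J),
                    "y": y.ravel(),
                }
            )
        )
    return (
        pd.concat(frames, ignore_index=True)
        .sort_values(["replication", "arm", "cluster"], kind="stable")
        .reset_index(drop=True)
    )


@dataclass(frozen=True)
class GLSFit:
    theta_hat: float
    model_se: float


def fit_gls(
    outcomes: pd.DataFrame,
    design: DesignSpec,
    corr: CorrelationParams,
    time_effect: TimeEffectSpec,
) -> GLSFit:
    """GLS fit of one replication with the covariance treated as known.

    `outcomes` holds one replication's rows (columns ``arm``, ``cluster``,
    ``time``, ``y``); every cluster must carry the full retained grid of its
    arm.  The model standard error equals the analytic multiplier scaled by
    ``sigma^2 / J`` for every replication, since V is known.
    """
    grid = build_observation_grid(design)
    mm = build_model_matrices(grid, corr, time_effect, design.crossover)
    p = mm.Z_blocks[0].shape[1]
    info = np.zeros((p, p))
    rhs = np.zeros(p)
    arm_block = {CONTROL: 0, INTERVENTION: 1}
    for (arm, _cluster), rows in outcomes.groupby(["arm", "cluster"], sort=True):
        Zb = mm.Z_blocks[arm_block[arm]]
        Vb = mm.V_blocks[arm_block[arm]]
        y = rows.sort_values("time")["y"].to_numpy()
        if y.size != Zb.shape[0]:
            raise ConfigurationError(
                f"cluster in arm {arm!r} has {y.size} outcomes; the design "
                f"retains {Zb.shape[0]}"
            )
        c = cho_factor(Vb, lower=True)
        info += Zb.T @ cho_solve(c, Zb)
        rhs += Zb.T @ cho_solve(c, y)
    beta = np.linalg.solve(info, rhs)
    cov = np.linalg.inv(info)
    ti = mm.treatment_index
    return GLSFit(theta_hat=float(beta[ti]), model_se=float(np.sqrt(cov[ti, ti])))


@dataclass(frozen=True)
class ValidationResult:
    """Empirical vs analytic variance of the treatment-effect estimator."""

    analytic_variance: float
    empirical_variance: float
    ratio: float
    band: tuple[float, float]
    within_band: bool
    mean_theta_hat: float
    theta: float
    mc_se_mean: float
    replications: int
    seed: int


def validate_design(
    config: SimulationConfig, band_level: float = 0.99
) -> ValidationResult:
    """Simulate, refit every replication, and compare variances.

    The acceptance band is the two-sided chi-square interval for a sample
    variance of ``replications`` normal estimates around the analytic value.
    """
    grid = build_observation_grid(config.design)
    mm = build_model_matrices(grid, config.corr, config.time_effect, config.design.crossover)
    p = mm.Z_blocks[0].shape[1]
    info = np.zeros((p, p))
    solves = {}
    for arm, Zb, Vb in zip(
        (CONTROL, INTERVENTION), mm.Z_blocks, mm.V_blocks
    ):
        c = cho_factor(Vb, lower=True)
        solves[arm] = cho_solve(c, Zb)  # V^{-1} Z, reused across clusters/reps
        info += config.j_clusters * (Zb.T @ solves[arm])
    ti = mm.treatment_index
    analytic = float(np.linalg.inv(info)[ti, ti])

    draws = _draw(config)
    rhs = np.zeros((config.replications, p))
    for arm in (CONTROL, INTERVENTION):
        rhs += draws[arm].sum(axis=1) @ solves[arm]  # sum clusters in arm
    betas = np.linalg.solve(info, rhs.T).T  # (R, p)
    theta_hats = betas[:, ti]

    r = config.replications
    emp = float(np.var(theta_hats, ddof=1)) if r > 1 else float("nan")
    lo = chi2.ppf((1 - band_level) / 2, r - 1) / (r - 1)
    hi = chi2.ppf(1 - (1 - band_level) / 2, r - 1) / (r - 1)
    band = (analytic * lo, analytic * hi)
    return ValidationResult(
        analytic_variance=analytic,
        empirical_variance=emp,
        ratio=emp / analytic,
        band=band,
        within_band=bool(band[0] <= emp <= band[1]),
        mean_theta_hat=float(theta_hats.mean()),
        theta=config.theta,
        mc_se_mean=float(np.sqrt(emp / r)),
        replications=r,
        seed=config.seed,
    )
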