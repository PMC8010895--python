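"""GLS variance of the treatment-effect estimator.

The outcome model is ``Y = Z beta + e`` with ``e ~ N(0, V)``, where the
fixed-effect columns of ``Z`` are the time-effect columns plus the treatment
indicator, and ``V`` is block-diagonal by cluster with within-cluster
covariance ``sigma^2 * rho * tau ** |dt|`` off the diagonal.  The variance of
the GLS estimator of the treatment effect is the corresponding diagonal entry
of ``(Z' V^-1 Z)^-1``.

Because every cluster in an arm shares the same retained arrival times, the
information matrix is assembled from just two blocks (one control pattern,
one intervention pattern); ``J`` clusters per arm scale the variance by
``1/J`` and the outcome variance enters as ``sigma^2``, so everything is
computed once at ``sigma^2 = 1, J = 1`` as a *multiplier*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import (
    LinAlgError,
    block_diag,
    cholesky,
    solve_triangular,
)

from .design import (
    CONTROL,
    INTERVENTION,
    ConfigurationError,
    CorrelationParams,
    DesignSpec,
    ObservationGrid,
    TimeEffectSpec,
    build_observation_grid,
)

__all__ = [
    "DegenerateDesignError",
    "ModelMatrices",
    "VarianceResult",
    "build_model_matrices",
    "gls_variance",
    "design_variance",
]

# relative singular-value threshold for deciding column-rank questions
_RANK_RTOL = 1e-10


class DegenerateDesignError(ConfigurationError):
    """The treatment effect is not estimable under this design."""


@dataclass(frozen=True)
class ModelMatrices:
    """Per-cluster-pattern design and covariance blocks.

    ``Z_blocks`` and ``V_blocks`` are ordered (control, intervention);
    ``columns`` names the retained columns of Z and ``treatment_index``
    locates the treatment-indicator column.
    """

    Z_blocks: tuple[np.ndarray, ...]
    V_blocks: tuple[np.ndarray, ...]
    columns: tuple[str, ...]
    treatment_index: int
    dropped_columns: tuple[str, ...] = ()

    @property
    def Z(self) -> np.ndarray:
        return np.vstack(self.Z_blocks)

    @property
    def V(self) -> np.ndarray:
        return block_diag(*self.V_blocks)

    @property
    def n_observations(self) -> int:
        return sum(b.shape[0] for b in self.Z_blocks)


@dataclass(frozen=True)
class VarianceResult:
    """Variance multiplier: ``Var(theta_hat) = multiplier * sigma^2 / J``."""

    multiplier: float
    n_retained: int

    def variance(self, sigma2: float = 1.0, j_clusters: int = 1) -> float:
        return self.multiplier * sigma2 / j_clusters


def _prune_columns(Z: np.ndarray, names: list[str]) -> tuple[list[int], list[str]]:
    """Greedily keep columns that increase rank; treatment column comes last.

    Deterministic: columns are scanned in their construction order and a
    later column collinear with the kept ones is dropped.  If the treatment
    column itself adds no rank the design is degenerate.
    """
    scale = np.linalg.norm(Z) * _RANK_RTOL
    kept: list[int] = []
    dropped: list[str] = []
    for j in range(Z.shape[1] - 1):  # time-effect columns
        cand = kept + [j]
        if np.linalg.matrix_rank(Z[:, cand], tol=scale) == len(cand):
            kept.append(j)
        else:
            dropped.append(names[j])
    tcol = Z.shape[1] - 1
    if np.linalg.matrix_rank(Z[:, kept + [tcol]], tol=scale) != len(kept) + 1:
        raise DegenerateDesignError(
            "treatment indicator is collinear with the time-effect columns "
            "(no information about the treatment effect under this design)"
        )
    kept.append(tcol)
    return kept, dropped


def build_model_matrices(
    grid: ObservationGrid,
    corr: CorrelationParams,
    time_effect: TimeEffectSpec,
    crossover: float,
) -> ModelMatrices:
    """Assemble fixed-effect and covariance blocks for one cluster per arm.

    Redundant fixed-effect columns (e.g. a post-cross-over indicator that
    duplicates the intercept when every retained observation is post) are
    removed deterministically with a warning.
    """
    if grid.times.size == 0:
        raise DegenerateDesignError("observation grid is empty")

    Z_blocks, V_blocks = [], []
    names: list[str] = []
    for arm in (CONTROL, INTERVENTION):
        t = grid.times_in(arm)
        T, names = time_effect.columns(t, crossover)
        delta = grid.treated_in(arm).astype(float)
        Z_blocks.append(np.column_stack([T, delta]))
        V_blocks.append(corr.covariance(t))
    names = names + ["treatment"]

    Z_all = np.vstack(Z_blocks)
    kept, dropped = _prune_columns(Z_all, names)
    if dropped:
        warnings.warn(
            f"dropping redundant fixed-effect column(s): {', '.join(dropped)}",
            stacklevel=2,
        )
    return ModelMatrices(
        Z_blocks=tuple(Z[:, kept] for Z in Z_blocks),
        V_blocks=tuple(V_blocks),
        columns=tuple(names[j] for j in kept),
        treatment_index=len(kept) - 1,
        dropped_columns=tuple(dropped),
    )


def gls_variance(matrices: ModelMatrices) -> VarianceResult:
    """Treatment-coefficient entry of the inverse GLS information matrix.

    Each cluster block is whitened through the Cholesky factor of its
    covariance (no explicit inverses); the stacked whitened design is then
    orthogonalised by QR so the inverse information is obtained without
    forming the normal equations, which would square the condition number.
    The result is identical to accumulating ``Z' V^-1 Z`` block by block and
    inverting (the oracle-equivalence tests assert this).
    """
    whitened = []
    for Zb, Vb in zip(matrices.Z_blocks, matrices.V_blocks):
        try:
            L = cholesky(Vb, lower=True)
        except LinAlgError as err:  # unreachable for rho < 1, tau <= 1
            raise ConfigurationError(
                "covariance block is not positive definite; check rho and tau"
            ) from err
        whitened.append(solve_triangular(L, Zb, lower=True))
    W = np.vstack(whitened)
    R = np.linalg.qr(W, mode="r")
    diag = np.abs(np.diag(R))
    if np.any(diag <= _RANK_RTOL * diag.max()):
        raise DegenerateDesignError("singular information matrix")
    e = np.zeros(W.shape[1])
    e[matrices.treatment_index] = 1.0
    # (R'R)^{-1}_tt = || R^{-T} e_t ||^2
    y = solve_triangular(R, e, trans="T", lower=False)
    multiplier = float(y @ y)
    if not multiplier > 0.0:
        raise DegenerateDesignError("non-positive treatment variance")
    return VarianceResult(multiplier=multiplier, n_retained=matrices.n_observations)


def design_variance(
    spec: DesignSpec,
    corr: CorrelationParams,
    time_effect: TimeEffectSpec,
) -> VarianceResult:
    """Variance multiplier of a design in one call."""
    grid = build_observation_grid(spec)
    mm = build_model_matrices(grid, corr, time_effect, spec.crossover)
    return gls_variance(mm)
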