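"""GLS variance of the treatment effect estimator under a decaying ICC.

Within a cluster the correlation between the outcomes of two participants
presenting a time ``d`` apart is ``rho * tau**d``: ``rho`` is the
time-specific ICC (two participants presenting at the same instant) and
``tau`` the factor by which the ICC has decayed over the whole unit
recruitment interval (``tau = 1`` recovers the exchangeable model).
Different clusters are independent, so the covariance of the stacked outcome
vector is block diagonal with identical blocks ``sigma^2 * V_c``.

The treatment effect is estimated by generalised least squares adjusting for
the piecewise-constant time effect; its variance is the leading diagonal
element of ``(X' V^{-1} X)^{-1}``. Because every cluster in a sequence
contributes the same regressor block, the information matrix aggregates per
sequence, weighted by the allocation proportions, and the variance takes the
form ``theta * sigma^2 / J`` with ``theta`` free of both ``sigma^2`` and the
number of clusters ``J``. ``theta`` is the quantity this module computes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .design import TrialDesign, recruitment_times, time_effect_design

__all__ = [
    "CorrelationStructure",
    "CorrelationSummary",
    "VarianceResult",
    "IdentifiabilityError",
    "correlation_matrix",
    "correlation_summary",
    "theta_variance",
]

#: relative tolerance for rank decisions when pruning collinear time columns
RANK_TOL = 1e-10


class IdentifiabilityError(ValueError):
    """The treatment effect is not identified: its regressor lies in the
    span of the (pooled) time-effect columns."""


@dataclass(frozen=True)
class CorrelationStructure:
    """Within-cluster correlation: ``Corr = rho * tau**d`` at separation ``d``.

    ``0 <= rho < 1`` and ``0 < tau <= 1``. ``tau = 1`` is the exchangeable
    (constant-ICC) limit; smaller ``tau`` means faster decay.
    """

    rho: float
    tau: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho < 1.0):
            raise ValueError(f"rho must satisfy 0 <= rho < 1, got {self.rho!r}")
        if not (0.0 < self.tau <= 1.0):
            raise ValueError(f"tau must satisfy 0 < tau <= 1, got {self.tau!r}")


@dataclass(frozen=True)
class CorrelationSummary:
    """Summaries governing the design problem.

    ``R = m * rho / (1 - rho)`` determines the correlation between
    within-cluster half-means: for a cluster crossing over half-way, the
    correlation between the pre- and post-crossover means of ``m/2``
    participants each is ``R / (2 + R)`` (exchangeable case).
    """

    R: float
    half_split_corr: float | None


def correlation_matrix(m: int, corr: CorrelationStructure) -> np.ndarray:
    """The ``m x m`` within-cluster correlation matrix at times ``i/m``.

    Unit diagonal; entry ``(i, i')`` is ``rho * tau**(|i - i'| / m)``.
    Symmetric positive definite for ``rho < 1``, ``tau > 0``.
    """
    t = recruitment_times(m)
    D = np.abs(t[:, None] - t[None, :])
    V = corr.rho * corr.tau**D
    np.fill_diagonal(V, 1.0)
    return V


def correlation_summary(m: int, rho: float) -> CorrelationSummary:
    """Compute ``R = m rho / (1 - rho)`` and the half-split mean correlation.

    The half-split correlation ``R / (2 + R)`` presumes two halves of
    ``m / 2`` participants, so it is reported only for even ``m`` (``None``
    otherwise).
    """
    if not (0.0 <= rho < 1.0):
        raise ValueError(f"rho must satisfy 0 <= rho < 1, got {rho!r}")
    if not isinstance(m, (int, np.integer)) or m < 1:
        raise ValueError(f"m must be a positive integer, got {m!r}")
    R = m * rho / (1.0 - rho)
    half = R / (2.0 + R) if m % 2 == 0 else None
    return CorrelationSummary(R=R, half_split_corr=half)


@dataclass(frozen=True)
class VarianceResult:
    """``theta`` such that ``Var(delta_hat) = theta * sigma^2 / J``.

    ``dropped_columns`` lists the 0-based indices of time-effect columns
    pruned as collinear (e.g. the ``H(t - s)`` column duplicates the
    intercept at ``s = 0``); ``condition_diagnostic`` is the 2-norm
    condition number of the aggregated information matrix.
    """

    theta: float
    dropped_columns: tuple[int, ...]
    condition_diagnostic: float


def kept_time_columns(T: np.ndarray, tol: float = RANK_TOL) -> list[int]:
    """Greedy left-to-right selection of a maximal independent subset of the
    time-effect columns. The intercept (column 0) is always kept; later
    columns are kept only if they increase the numerical rank at relative
    tolerance ``tol``."""
    keep = [0]
    for j in range(1, T.shape[1]):
        cand = T[:, keep + [j]]
        rank_tol = tol * max(cand.shape) * np.abs(cand).max()
        if np.linalg.matrix_rank(cand, tol=rank_tol) == len(keep) + 1:
            keep.append(j)
    return keep


def _sequence_design_matrices(
    design: TrialDesign, keep: list[int] | None = None
) -> tuple[list[np.ndarray], list[int]]:
    """Per-sequence regressor matrices ``[treatment | kept time columns]``.

    The treatment indicator of sequence ``k`` equals step column ``k`` of the
    time-effect basis, so everything is sliced out of one ``m x 4`` matrix.
    """
    T = time_effect_design(design)
    if keep is None:
        keep = kept_time_columns(T)
    Xs = [np.column_stack([T[:, k], T[:, keep]]) for k in (1, 2, 3)]
    return Xs, keep


def _check_identifiable(Xs: list[np.ndarray], weights, keep: list[int]) -> None:
    """Raise unless the pooled treatment column is outside the span of the
    pooled time-effect columns (only sequences with positive weight count)."""
    active = [X for X, p in zip(Xs, weights) if p > 0]
    if not active:
        raise IdentifiabilityError("no sequence has positive allocation")
    W = np.vstack(active)
    rank_tol = RANK_TOL * max(W.shape) * max(np.abs(W).max(), 1.0)
    if np.linalg.matrix_rank(W, tol=rank_tol) < W.shape[1]:
        raise IdentifiabilityError(
            "treatment indicator lies in the span of the time-effect columns; "
            "the design does not identify the treatment effect"
        )


def theta_variance(
    design: TrialDesign,
    corr: CorrelationStructure,
    *,
    cholesky: np.ndarray | None = None,
) -> VarianceResult:
    """Variance multiplier ``theta`` of the GLS treatment effect estimator.

    Parameters
    ----------
    design, corr
        The design point and the within-cluster correlation parameters.
    cholesky
        Optional pre-computed lower Cholesky factor of
        ``correlation_matrix(design.m, corr)``. The factor does not depend
        on ``(s, w)``, so callers sweeping the design space should compute
        it once and pass it in.

    Notes
    -----
    Collinear time-effect columns (duplicated knots, ``s = 0``) are pruned
    before inversion; the treatment column is never pruned. ``theta`` is
    invariant to which member of a mutually collinear set is kept, since the
    fit spans the same column space.
    """
    Xs, keep = _sequence_design_matrices(design)
    dropped = tuple(j for j in range(4) if j not in keep)
    p = design.allocation
    _check_identifiable(Xs, p, keep)
    if cholesky is None:
        L = np.linalg.cholesky(correlation_matrix(design.m, corr))
    else:
        L = cholesky
    k = Xs[0].shape[1]
    A = np.zeros((k, k))
    for X, pk in zip(Xs, p):
        if pk == 0:
            continue
        Z = solve_triangular(L, X, lower=True)
        A += pk * (Z.T @ Z)
    e1 = np.zeros(k)
    e1[0] = 1.0
    try:
        c, low = cho_factor(A)
    except np.linalg.LinAlgError as err:  # pragma: no cover - guarded above
        raise IdentifiabilityError(f"singular information matrix: {err}") from err
    theta = float(cho_solve((c, low), e1)[0])
    return VarianceResult(
        theta=theta,
        dropped_columns=dropped,
        condition_diagnostic=float(np.linalg.cond(A)),
    )
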