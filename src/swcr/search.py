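"""Search of the (s, w) design space for efficient designs.

The variance multiplier ``theta(s, w)`` is evaluated on a grid over the
design space ``0 <= s < 0.5``, ``0 <= w < 1`` and mapped on the log scale.
Contour levels are spaced ``log(1.1)`` apart, anchored at the surface
minimum, so the innermost contour delimits the designs whose variance is
within 10% of the minimum attainable. The grid optimum is refined by a
derivative-free simplex search.

The expensive object — the Cholesky factor of the within-cluster
correlation matrix — does not depend on ``(s, w)``, and for a given first
cross-over time ``s`` all regressors are drawn from the same four step
columns, so a whole row of the surface costs one ``m x 4`` triangular solve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.optimize import minimize

from .design import TrialDesign, time_effect_design
from .variance import (
    CorrelationStructure,
    IdentifiabilityError,
    correlation_matrix,
    kept_time_columns,
    theta_variance,
)

__all__ = [
    "VarianceSurface",
    "evaluate_surface",
    "find_optimum",
    "near_optimal_region",
    "robust_design_report",
]

#: default grid resolutions over the half-open design ranges
DEFAULT_S_POINTS = 100
DEFAULT_W_POINTS = 100

_S_MAX = 0.5 - 1e-9
_W_MAX = 1.0 - 1e-9


def default_s_grid(n: int = DEFAULT_S_POINTS) -> np.ndarray:
    return np.arange(n) * (0.5 / n)


def default_w_grid(n: int = DEFAULT_W_POINTS) -> np.ndarray:
    return np.arange(n) * (1.0 / n)


@dataclass
class VarianceSurface:
    """Gridded log-variance multiplier over the design space.

    ``log_theta[i, j]`` is ``log theta(s_grid[i], w_grid[j])``; cells where
    the design is non-identifiable are NaN and counted in ``n_failed``.
    ``min_point`` is ``(s*, w*, theta*)`` — the refined optimum once
    :func:`find_optimum` has run, otherwise the best grid cell.
    """

    m: int
    corr: CorrelationStructure
    s_grid: np.ndarray
    w_grid: np.ndarray
    log_theta: np.ndarray
    n_failed: int = 0
    min_point: tuple[float, float, float] | None = None

    @property
    def theta(self) -> np.ndarray:
        return np.exp(self.log_theta)

    def grid_min(self) -> tuple[float, float, float]:
        """Best grid cell ``(s, w, theta)``; ties broken by smallest s, then w."""
        lo = np.nanmin(self.log_theta)
        i, j = np.argwhere(self.log_theta == lo)[0]
        return (float(self.s_grid[i]), float(self.w_grid[j]), float(np.exp(lo)))

    def min_theta(self) -> float:
        return self.min_point[2] if self.min_point is not None else self.grid_min()[2]

    def contour_levels(self, n: int | None = None) -> np.ndarray:
        """Increasing levels spaced ``log(1.1)`` starting at the surface minimum."""
        lo = math.log(self.min_theta())
        hi = np.nanmax(self.log_theta)
        if n is None:
            n = int(math.floor((hi - lo) / math.log(1.1))) + 1
        return lo + math.log(1.1) * np.arange(n)

    def to_frame(self, ratio: float = 1.1) -> pd.DataFrame:
        """Tidy long-format table: s, w, theta, log_theta, near-optimal flag."""
        mask = near_optimal_region(self, ratio=ratio)
        s, w = np.meshgrid(self.s_grid, self.w_grid, indexing="ij")
        return pd.DataFrame(
            {
                "s": s.ravel(),
                "w": w.ravel(),
                "theta": self.theta.ravel(),
                "log_theta": self.log_theta.ravel(),
                f"near_optimal_{ratio:.2f}": mask.ravel(),
            }
        )


def evaluate_surface(
    m: int,
    corr: CorrelationStructure,
    s_grid: np.ndarray | None = None,
    w_grid: np.ndarray | None = None,
) -> VarianceSurface:
    """Evaluate ``log theta`` over a rectangular (s, w) grid.

    Shares one Cholesky factorisation of the correlation matrix across the
    whole grid and one triangular solve per ``s`` value; the result is
    identical (to floating precision) to calling :func:`theta_variance`
    pointwise.
    """
    if s_grid is None:
        s_grid = default_s_grid()
    if w_grid is None:
        w_grid = default_w_grid()
    s_grid = np.asarray(s_grid, dtype=float)
    w_grid = np.asarray(w_grid, dtype=float)
    if s_grid.size == 0 or w_grid.size == 0:
        raise ValueError("grids must be non-empty")
    if s_grid.min() < 0 or s_grid.max() >= 0.5:
        raise ValueError("s grid must lie in [0, 0.5)")
    if w_grid.min() < 0 or w_grid.max() >= 1.0:
        raise ValueError("w grid must lie in [0, 1)")

    L = np.linalg.cholesky(correlation_matrix(m, corr))
    log_theta = np.full((s_grid.size, w_grid.size), np.nan)
    n_failed = 0

    outer = (1.0 - w_grid) / 2.0
    e1 = np.zeros(5)
    e1[0] = 1.0
    for i, s in enumerate(s_grid):
        design = TrialDesign(s=float(s), w=0.0, m=m)
        T = time_effect_design(design)
        keep = kept_time_columns(T)
        Z = solve_triangular(L, T, lower=True)
        M = Z.T @ Z  # 4x4 cross-products of all distinct columns
        # X_k = [step col k | kept time cols]; its Gram block is a slice of M
        idx = [np.array([k] + keep) for k in (1, 2, 3)]
        B = [M[np.ix_(ix, ix)] for ix in idx]
        k = B[0].shape[0]
        A = (
            outer[:, None, None] * (B[0] + B[2])[None]
            + w_grid[:, None, None] * B[1][None]
        )
        for j in range(w_grid.size):
            try:
                _check_point(T, keep, w_grid[j])
                x = np.linalg.solve(A[j], e1[:k])
                log_theta[i, j] = math.log(x[0])
            except (np.linalg.LinAlgError, IdentifiabilityError, ValueError):
                n_failed += 1
    return VarianceSurface(
        m=m,
        corr=corr,
        s_grid=s_grid,
        w_grid=w_grid,
        log_theta=log_theta,
        n_failed=n_failed,
    )


def _check_point(T: np.ndarray, keep: list[int], w: float) -> None:
    """Cheap identifiability screen for one grid point: with all three
    sequences active (w > 0) the treatment column escapes the pooled time
    span unless the three step columns coincide; with w = 0 the middle
    sequence drops out and the outer pair must differ."""
    if w > 0:
        same = np.array_equal(T[:, 1], T[:, 2]) and np.array_equal(T[:, 2], T[:, 3])
    else:
        same = np.array_equal(T[:, 1], T[:, 3])
    if same:
        raise IdentifiabilityError("all active step columns coincide")


def find_optimum(surface: VarianceSurface) -> tuple[float, float, float]:
    """Refine the surface optimum with a Nelder–Mead simplex search.

    Starts from the best grid cell, constrained (by clipping) to the box
    ``0 <= s < 0.5``, ``0 <= w < 1``; converged when theta changes by less
    than 1e-8 relative. The refined point is stored on ``surface.min_point``
    and never exceeds the best grid value.
    """
    if surface.s_grid.size < 3 or surface.w_grid.size < 3:
        raise ValueError("refinement needs a grid of at least 3x3")
    s0, w0, theta0 = surface.grid_min()
    L = np.linalg.cholesky(correlation_matrix(surface.m, surface.corr))

    def objective(x: np.ndarray) -> float:
        s = float(np.clip(x[0], 0.0, _S_MAX))
        w = float(np.clip(x[1], 0.0, _W_MAX))
        try:
            return theta_variance(
                TrialDesign(s=s, w=w, m=surface.m), surface.corr, cholesky=L
            ).theta
        except IdentifiabilityError:
            return np.inf

    res = minimize(
        objective,
        x0=np.array([s0, w0]),
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8 * theta0, "maxiter": 500},
    )
    s_star = float(np.clip(res.x[0], 0.0, _S_MAX))
    w_star = float(np.clip(res.x[1], 0.0, _W_MAX))
    theta_star = float(res.fun)
    # a simplex handles box boundaries poorly and the optimum often sits on
    # one (s = 0 for small m*rho); project onto the boundaries and keep the best
    candidates = [(s0, w0, theta0)]
    for s_c, w_c in ((0.0, w_star), (s_star, 0.0), (0.0, 0.0)):
        candidates.append((s_c, w_c, objective(np.array([s_c, w_c]))))
    for s_c, w_c, th_c in candidates:
        if th_c <= theta_star:
            s_star, w_star, theta_star = s_c, w_c, th_c
    surface.min_point = (s_star, w_star, theta_star)
    return surface.min_point


def near_optimal_region(surface: VarianceSurface, ratio: float = 1.1) -> np.ndarray:
    """Boolean grid mask of designs with ``theta <= ratio * theta*``.

    ``ratio = 1.1`` reproduces the innermost contour: the region within 10%
    of the minimum attainable variance. Uses the refined optimum when
    available, otherwise the grid minimum.
    """
    if not ratio > 1.0:
        raise ValueError(f"ratio must exceed 1, got {ratio!r}")
    threshold = math.log(ratio * surface.min_theta())
    with np.errstate(invalid="ignore"):
        return surface.log_theta <= threshold


def robust_design_report(
    scenarios: list[tuple[int, float, float]],
    candidates: list[tuple[float, float]],
    *,
    s_points: int = 50,
    w_points: int = 50,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Efficiency of candidate designs across correlation scenarios.

    Parameters
    ----------
    scenarios
        List of ``(m, rho, tau)`` triples.
    candidates
        List of ``(s, w)`` design points.
    threshold
        If given, adds a boolean ``robust`` column flagging candidates whose
        worst-case ratio across scenarios is at most ``threshold``.

    Returns
    -------
    DataFrame with one row per candidate: ``theta`` and the efficiency ratio
    ``theta_candidate / theta*`` (always >= 1 up to refinement error) per
    scenario, plus the worst-case ratio.
    """
    if not scenarios or not candidates:
        raise ValueError("scenarios and candidates must be non-empty")
    rows: dict[tuple[float, float], dict[str, float]] = {c: {} for c in candidates}
    for m, rho, tau in scenarios:
        corr = CorrelationStructure(rho=rho, tau=tau)
        surf = evaluate_surface(
            m, corr, default_s_grid(s_points), default_w_grid(w_points)
        )
        _, _, theta_star = find_optimum(surf)
        L = np.linalg.cholesky(correlation_matrix(m, corr))
        label = f"m={m},rho={rho:g},tau={tau:g}"
        for s, w in candidates:
            th = theta_variance(
                TrialDesign(s=s, w=w, m=m), corr, cholesky=L
            ).theta
            rows[(s, w)][f"theta[{label}]"] = th
            rows[(s, w)][f"ratio[{label}]"] = th / theta_star
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index = pd.MultiIndex.from_tuples(out.index, names=["s", "w"])
    ratio_cols = [c for c in out.columns if c.startswith("ratio[")]
    out["worst_case_ratio"] = out[ratio_cols].max(axis=1)
    if threshold is not None:
        out["robust"] = out["worst_case_ratio"] <= threshold
    return out
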