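"""Three-sequence centrosymmetric stepped wedge designs with continuous recruitment.

A design is described by two parameters on the unit-scaled recruitment
interval: ``s``, the time of the first cross-over (the third sequence then
crosses at ``1 - s`` by centrosymmetry, and the middle sequence at 0.5), and
``w``, the proportion of clusters allocated to the middle sequence (the outer
sequences each receive ``(1 - w) / 2``). Each cluster recruits ``m``
participants at the regularly spaced times ``i / m``, ``i = 1..m``.

The secular trend is modelled as piecewise constant with jumps at the three
cross-over times, so the regressors adjusting for time are step functions at
the same knots as the treatment switch. The step convention is ``H(0) = 1``:
a participant presenting exactly at a cross-over time is under the
intervention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TrialDesign",
    "OutcomeModel",
    "recruitment_times",
    "step_indicator",
    "treatment_indicator",
    "time_effect_design",
]


def recruitment_times(m: int) -> np.ndarray:
    """Regularly spaced recruitment times ``(1/m, 2/m, ..., 1)``.

    Every cluster shares the same schedule: participant ``i`` presents at
    ``i / m`` on the unit-scaled recruitment interval. There is no recruit
    at time 0.
    """
    if not isinstance(m, (int, np.integer)) or m < 1:
        raise ValueError(f"m must be a positive integer, got {m!r}")
    return np.arange(1, m + 1) / m


def step_indicator(m: int, knot: float) -> np.ndarray:
    """0/1 vector over the ``m`` recruitment times: 1 where ``t_i >= knot``.

    Implemented by an index rule rather than a floating comparison: recruit
    ``i`` is past the knot iff ``i >= ceil(m * knot - 1e-9)``.  ``i/m`` and
    the knot (e.g. 10/120 versus 1/12) can differ in the last ulp in binary
    floating point; the small slack makes the ``H(0) = 1`` convention
    bit-stable.
    """
    if not isinstance(m, (int, np.integer)) or m < 1:
        raise ValueError(f"m must be a positive integer, got {m!r}")
    first = max(int(math.ceil(m * knot - 1e-9)), 1)
    out = np.zeros(m)
    if first <= m:
        out[first - 1 :] = 1.0
    return out


@dataclass(frozen=True)
class TrialDesign:
    """A centrosymmetric three-sequence design on the unit interval.

    Parameters
    ----------
    s : float
        First cross-over time, ``0 <= s < 0.5``. The three sequences cross
        over at ``s``, ``0.5`` and ``1 - s``. ``s = 0`` gives a hybrid
        design in which the outer sequences stay in one condition
        throughout (up to the single boundary recruit at ``t = 1``).
    w : float
        Proportion of clusters allocated to the middle sequence,
        ``0 <= w < 1``. The outer sequences each take ``(1 - w) / 2``;
        fractional cluster counts are deliberately allowed because the
        variance works with allocation proportions.
    m : int
        Recruits per cluster over the unit interval, ``m >= 1``.
    """

    s: float
    w: float
    m: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.s < 0.5):
            raise ValueError(f"s must satisfy 0 <= s < 0.5, got {self.s!r}")
        if not (0.0 <= self.w < 1.0):
            raise ValueError(f"w must satisfy 0 <= w < 1, got {self.w!r}")
        if not isinstance(self.m, (int, np.integer)) or self.m < 1:
            raise ValueError(f"m must be a positive integer, got {self.m!r}")

    @property
    def crossover_times(self) -> tuple[float, float, float]:
        """Ordered cross-over times ``(s, 0.5, 1 - s)``, symmetric about 0.5."""
        return (self.s, 0.5, 1.0 - self.s)

    @property
    def allocation(self) -> tuple[float, float, float]:
        """Sequence allocation proportions ``((1-w)/2, w, (1-w)/2)``."""
        outer = (1.0 - self.w) / 2.0
        return (outer, self.w, outer)

    def to_dict(self) -> dict:
        return {"s": self.s, "w": self.w, "m": int(self.m)}

    @classmethod
    def from_dict(cls, d: dict) -> "TrialDesign":
        return cls(s=float(d["s"]), w=float(d["w"]), m=int(d["m"]))


@dataclass(frozen=True)
class OutcomeModel:
    """Generating model for a continuous outcome.

    The expected outcome is ``delta * (treated) + T(t)`` where ``T`` is the
    piecewise-constant time effect ``beta[0] + beta[1] H(t - s) +
    beta[2] H(t - 0.5) + beta[3] H(t - 1 + s)``, and the residual standard
    deviation is ``sqrt(sigma2)``.
    """

    delta: float
    beta: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    sigma2: float = 1.0

    def __post_init__(self) -> None:
        if len(self.beta) != 4:
            raise ValueError("beta must have four components")
        if not self.sigma2 > 0:
            raise ValueError(f"sigma2 must be positive, got {self.sigma2!r}")


def treatment_indicator(design: TrialDesign, sequence_index: int) -> np.ndarray:
    """Treatment status of each recruit in a given sequence (1, 2 or 3).

    Entry ``i`` is 1 iff ``t_i >= t*`` where ``t*`` is the sequence's
    cross-over time; the vector is non-decreasing.
    """
    if sequence_index not in (1, 2, 3):
        raise ValueError(f"sequence_index must be 1, 2 or 3, got {sequence_index!r}")
    knot = design.crossover_times[sequence_index - 1]
    return step_indicator(design.m, knot)


def time_effect_design(design: TrialDesign) -> np.ndarray:
    """The ``m x 4`` piecewise-constant time-effect basis at the recruitment times.

    Column 1 is the intercept; columns 2-4 are the step indicators
    ``H(t - s)``, ``H(t - 0.5)`` and ``H(t - 1 + s)``. The basis is shared
    by all sequences (the secular trend is assumed common to all clusters),
    and its step columns coincide with the three treatment indicators.
    """
    m = design.m
    cols = [np.ones(m)]
    cols += [step_indicator(m, k) for k in design.crossover_times]
    return np.column_stack(cols)
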