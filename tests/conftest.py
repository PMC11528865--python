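import numpy as np
import pytest

from swcr import CorrelationStructure, TrialDesign

# The weight-loss worked example: m=120 recruits per clinic over the unit
# interval, candidate designs with first cross-over at 1/12 vs 1/4, both
# giving the middle sequence a third of the clusters.
NONSTANDARD = dict(s=1.0 / 12.0, w=1.0 / 3.0, m=120)
STANDARD = dict(s=0.25, w=1.0 / 3.0, m=120)
EXAMPLE_SD = 10.7


@pytest.fixture(scope="session")
def nonstandard_design() -> TrialDesign:
    return TrialDesign(**NONSTANDARD)


@pytest.fixture(scope="session")
def standard_design() -> TrialDesign:
    return TrialDesign(**STANDARD)


def theta_full_stacked(design: TrialDesign, corr: CorrelationStructure,
                       counts: tuple[int, int, int], keep: list[int]) -> float:
    """Brute-force oracle: assemble the complete stacked regressor matrix and
    block-diagonal covariance over all J clusters, invert the full
    information matrix directly, and rescale the leading element by J.

    Independent of the per-sequence aggregation path: no Cholesky reuse, no
    blockwise shortcut — one explicit (J*m) x (J*m) system.
    """
    from swcr import correlation_matrix, time_effect_design

    m = design.m
    J = sum(counts)
    V = correlation_matrix(m, corr)
    T = time_effect_design(design)
    blocks = []
    for k, n_k in zip((1, 2, 3), counts):
        X = np.column_stack([T[:, k], T[:, keep]])
        blocks.extend([X] * n_k)
    Xfull = np.vstack(blocks)
    Vfull = np.kron(np.eye(J), V)
    info = Xfull.T @ np.linalg.inv(Vfull) @ Xfull
    return float(J * np.linalg.inv(info)[0, 0])
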