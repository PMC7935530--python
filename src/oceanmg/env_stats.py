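"""Association statistics between abundances, environment and station groups.

Spearman rank correlation uses mid-ranks for ties and a permutation null for
the p-value (exhaustive when the sample is small enough to enumerate, sampled
otherwise), which is appropriate for the small station counts typical of
oceanographic transects.  Group comparisons use Welch's unequal-variance
t-test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["StatResult", "spearman", "welch_t"]


@dataclass(frozen=True)
class StatResult:
    statistic: float
    p_value: float
    n: int
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def _rho_of_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


def spearman(x, y, n_perm: int = 10000, seed: int = 0) -> StatResult:
    """Spearman rank correlation with a two-sided permutation p-value.

    Ranks are mid-ranks (ties get their average rank).  When ``n! <= n_perm``
    all permutations of one vector are enumerated and the p-value is exact;
    otherwise ``n_perm`` random permutations are drawn (seeded) and the
    add-one estimator is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = _rho_of_ranks(rx, ry)
    tol = 1e-12
    if math.factorial(n) <= n_perm:
        rhos = np.array([_rho_of_ranks(rx, np.array(p)) for p in itertools.permutations(ry)])
        p = float(np.mean(np.abs(rhos) >= abs(rho) - tol))
        method = "spearman_exact_permutation"
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            if abs(_rho_of_ranks(rx, rng.permutation(ry))) >= abs(rho) - tol:
                hits += 1
        p = (1 + hits) / (1 + n_perm)
        method = "spearman_permutation"
    return StatResult(rho, p, n, method)


def welch_t(group_a, group_b) -> StatResult:
    """Welch's unequal-variance t-test (two-sided), with Welch–Satterthwaite
    degrees of freedom."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if np.allclose(a.mean(), b.mean()):
            return StatResult(0.0, 1.0, a.size + b.size, "welch_t")
        raise ValueError("both groups have zero variance with different means")
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return StatResult(float(t), float(p), a.size + b.size, "welch_t")
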