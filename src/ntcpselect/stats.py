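"""Paired nonparametric testing and descriptive summaries.

The workhorse is the two-sided Wilcoxon signed-rank test with the classic
conventions: zero differences dropped before ranking (their count is exposed
through ``n_effective``), midranks for tied absolute differences, statistic
W = min(W+, W-). For n_effective <= 25 the p-value is permutation-exact —
computed from the full null distribution of W+ over all 2^n sign assignments
(a dynamic program over doubled midranks, identical to brute-force
enumeration) — otherwise a normal approximation with tie correction and a
0.5 continuity correction is used.

The implementation is deliberately self-contained so that library routines
(e.g. ``scipy.stats.wilcoxon``) remain available as independent cross-checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np
from scipy.special import ndtr
from scipy.stats import rankdata

from .errors import AllZeroDifferences, DomainError

EXACT_MAX_N = 25


@dataclass(frozen=True)
class PairedSample:
    """Paired measurements (photon x, proton y) for one endpoint."""

    ids: Sequence[str]
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if len(self.x) != len(self.y) or len(self.x) < 1:
            raise DomainError("x and y must have equal length >= 1")
        if len(self.ids) != len(self.x):
            raise DomainError("ids must match the number of pairs")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise DomainError("paired values must be finite")

    def __len__(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class TestResult:
    """Signed-rank test outcome. ``statistic`` is W = min(W+, W-)."""

    statistic: float
    p_value: float
    n_effective: int
    method: str  # "exact" | "normal_approx"


def _exact_wplus_distribution(ranks: np.ndarray) -> np.ndarray:
    """Null distribution of 2*W+ over all sign assignments.

    Midranks are multiples of 0.5, so doubling makes them integers; the
    returned array c satisfies P(2*W+ = k) = c[k] / 2^n.
    """
    doubled = np.rint(2.0 * ranks).astype(int)
    dist = np.zeros(doubled.sum() + 1)
    dist[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: len(dist) - r]
        dist = dist + shifted
    return dist / dist.sum()


def wilcoxon_signed_rank(
    sample: PairedSample, alternative: str = "two-sided"
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences x - y.

    Zero differences are dropped (``n_effective`` reports the remainder);
    exact enumeration for n_effective <= 25, normal approximation with tie
    and continuity correction above.
    """
    if alternative != "two-sided":
        raise DomainError("only the two-sided alternative is implemented")
    d = sample.x - sample.y
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        raise AllZeroDifferences(
            "all paired differences are zero; the signed-rank test is "
            "undefined"
        )
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    total = float(ranks.sum())  # = n(n+1)/2 irrespective of ties
    w_minus = total - w_plus
    w = min(w_plus, w_minus)

    if n <= EXACT_MAX_N:
        dist = _exact_wplus_distribution(ranks)
        k = int(np.rint(2.0 * w))
        upper = int(np.rint(2.0 * (total - w)))
        p = dist[: k + 1].sum() + dist[upper:].sum()
        p = float(min(1.0, p))
        method = "exact"
    else:
        mean = total / 2.0
        var = float(np.sum(ranks**2)) / 4.0  # tie-corrected variance
        # continuity correction: shift W+ half a unit toward the mean
        z = (abs(w_plus - mean) - 0.5) / np.sqrt(var)
        z = max(z, 0.0)
        p = float(min(1.0, 2.0 * (1.0 - ndtr(z))))
        method = "normal_approx"
    return TestResult(statistic=w, p_value=p, n_effective=n, method=method)


def paired_summary(sample: PairedSample) -> Dict[str, float]:
    """Averages and medians of x, y and the per-pair differences x - y."""
    d = sample.x - sample.y
    return {
        "average_x": float(sample.x.mean()),
        "median_x": float(np.median(sample.x)),
        "average_y": float(sample.y.mean()),
        "median_y": float(np.median(sample.y)),
        "average_diff": float(d.mean()),
        "median_diff": float(np.median(d)),
    }
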