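"""Cumulative dose-volume histograms and the dose metrics derived from them.

A :class:`DVHCurve` is the atomic dosimetric input of the pipeline: the
cumulative curve V(d) giving the fraction of a structure's volume receiving at
least d Gy, sampled at strictly increasing dose edges starting at 0 Gy where
V = 1. All metrics (Dmean, Dx, Vx, Dmax, gEUD, target-coverage flags) are
computed from the piecewise-linear interpolant of that curve; the differential
form (bin volume fractions between consecutive edges) is used for gEUD and the
midpoint-rule mean.

Conventions
-----------
* Dose axis is absolute Gy, assumed RBE-weighted. :func:`apply_rbe` rescales a
  curve for users who export physical proton dose.
* Interpolation is linear on the cumulative curve. ``Dx`` at a plateau returns
  the lowest qualifying dose; ``Dx`` below the minimum reachable volume
  returns the last dose edge with a logged warning (coarse exports often
  truncate tails).
* Dmean is the trapezoid integral of V(d) over dose, which equals the
  midpoint-rule sum over differential bins whenever the curve reaches V = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np

from .errors import (
    BadOrigin,
    DomainError,
    LengthMismatch,
    NegativeBin,
    NonMonotoneVolume,
    ZeroDoseWithNegativeExponent,
)

logger = logging.getLogger(__name__)

_TOL = 1e-9

TECHNIQUES = ("photon", "proton")


@dataclass(frozen=True)
class DVHCurve:
    """Cumulative DVH of one structure under one plan.

    Parameters
    ----------
    patient_id, structure_id : str
        Opaque patient identifier and canonical organ name (with an
        ipsi/contra laterality tag where relevant, e.g.
        ``ipsilateral_cochlea``).
    technique : str
        ``"photon"`` or ``"proton"``.
    dose_edges : array-like
        Strictly increasing absolute doses in Gy, starting at 0.
    cum_volume : array-like
        Volume fractions in [0, 1], same length, non-increasing, starting
        at 1.0.
    absolute_volume_cc : float, optional
        Structure volume; metadata only — all metrics operate on fractions.
    """

    patient_id: str
    structure_id: str
    technique: str
    dose_edges: np.ndarray
    cum_volume: np.ndarray
    absolute_volume_cc: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "dose_edges", np.asarray(self.dose_edges, dtype=float)
        )
        object.__setattr__(
            self, "cum_volume", np.asarray(self.cum_volume, dtype=float)
        )

    def __len__(self) -> int:
        return len(self.dose_edges)


@dataclass(frozen=True)
class DifferentialDVH:
    """Differential form of a cumulative DVH: volume fraction per dose bin."""

    bin_lower: np.ndarray
    bin_upper: np.ndarray
    bin_volume_fraction: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "bin_lower", np.asarray(self.bin_lower, dtype=float))
        object.__setattr__(self, "bin_upper", np.asarray(self.bin_upper, dtype=float))
        object.__setattr__(
            self,
            "bin_volume_fraction",
            np.asarray(self.bin_volume_fraction, dtype=float),
        )

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.bin_lower + self.bin_upper)


@dataclass(frozen=True)
class DoseMetrics:
    """Summary metrics of one structure under one plan."""

    dmean: float
    dmax: float
    d_at_volume: Mapping[float, float] = field(default_factory=dict)
    v_at_dose: Mapping[float, float] = field(default_factory=dict)


@dataclass(frozen=True)
class CoverageReport:
    """Target-coverage check: D95 > 98% and D2 < 107% of the prescription."""

    d95_ok: bool
    d2_ok: bool
    d95_gy: float
    d2_gy: float
    prescription_gy: float


def validate_dvh(curve: DVHCurve) -> DVHCurve:
    """Return *curve* unchanged if all DVHCurve invariants hold.

    Raises
    ------
    LengthMismatch, BadOrigin, NonMonotoneVolume
    """
    d, v = curve.dose_edges, curve.cum_volume
    if d.ndim != 1 or v.ndim != 1 or len(d) != len(v) or len(d) < 2:
        raise LengthMismatch(
            f"{curve.patient_id}/{curve.structure_id}/{curve.technique}: "
            f"need equal-length 1-d arrays of length >= 2, "
            f"got {d.shape} and {v.shape}"
        )
    if abs(d[0]) > _TOL or abs(v[0] - 1.0) > _TOL:
        raise BadOrigin(
            f"{curve.structure_id}: curve must start at (0 Gy, volume 1.0), "
            f"got ({d[0]!r}, {v[0]!r})"
        )
    if np.any(np.diff(d) <= 0):
        raise NonMonotoneVolume(
            f"{curve.structure_id}: dose_edges must be strictly increasing"
        )
    if np.any(np.diff(v) > _TOL):
        raise NonMonotoneVolume(
            f"{curve.structure_id}: cumulative volume increases along dose"
        )
    if np.any(v < -_TOL) or np.any(v > 1.0 + _TOL):
        raise NonMonotoneVolume(
            f"{curve.structure_id}: volume fractions outside [0, 1]"
        )
    return curve


def apply_rbe(curve: DVHCurve, rbe_factor: float) -> DVHCurve:
    """Rescale the dose axis by a constant RBE factor (e.g. 1.1 for protons).

    Use only when the supplied curve carries *physical* proton dose; planning
    systems normally export RBE-weighted dose already.
    """
    if rbe_factor <= 0:
        raise DomainError("rbe_factor must be positive")
    if rbe_factor == 1.0:
        return curve
    return replace(curve, dose_edges=curve.dose_edges * rbe_factor)


def cumulative_to_differential(curve: DVHCurve) -> DifferentialDVH:
    """Convert a cumulative curve to per-bin volume fractions."""
    validate_dvh(curve)
    v = curve.cum_volume
    frac = v[:-1] - v[1:]
    # clip away -1e-16 style noise permitted by the validation tolerance
    frac = np.where(np.abs(frac) < _TOL, np.maximum(frac, 0.0), frac)
    return DifferentialDVH(
        bin_lower=curve.dose_edges[:-1],
        bin_upper=curve.dose_edges[1:],
        bin_volume_fraction=frac,
    )


def differential_to_cumulative(
    d: DifferentialDVH,
    patient_id: str = "",
    structure_id: str = "",
    technique: str = "photon",
) -> DVHCurve:
    """Exact right-inverse of :func:`cumulative_to_differential`."""
    if np.any(d.bin_volume_fraction < 0):
        raise NegativeBin("differential DVH has a negative bin volume")
    if len(d.bin_lower) == 0:
        raise LengthMismatch("differential DVH needs at least one bin")
    edges = np.concatenate([d.bin_lower[:1], d.bin_upper])
    total = d.bin_volume_fraction.sum()
    cum = np.concatenate([[total], total - np.cumsum(d.bin_volume_fraction)])
    return DVHCurve(
        patient_id=patient_id,
        structure_id=structure_id,
        technique=technique,
        dose_edges=edges,
        cum_volume=cum,
    )


def dose_at_volume(curve: DVHCurve, volume_fraction: float) -> float:
    """Dose d (Gy) at which the interpolated cumulative volume equals
    *volume_fraction* — e.g. ``dose_at_volume(c, 0.95)`` is D95.

    At plateaus the lowest qualifying dose is returned. A request below the
    curve's minimum reachable volume returns the last dose edge (with a
    warning), since coarse exports often truncate the tail.
    """
    if not 0.0 < volume_fraction <= 1.0:
        raise DomainError(
            f"volume_fraction must lie in (0, 1], got {volume_fraction}"
        )
    validate_dvh(curve)
    d, v = curve.dose_edges, curve.cum_volume
    below = v <= volume_fraction
    if not below.any():
        logger.warning(
            "%s/%s: requested volume fraction %.4g below curve minimum %.4g; "
            "returning last dose edge",
            curve.structure_id,
            curve.technique,
            volume_fraction,
            v[-1],
        )
        return float(d[-1])
    i = int(np.argmax(below))  # first index where V <= target
    if i == 0:
        return float(d[0])
    # linear interpolation inside the bracketing segment; exact when
    # v[i] == volume_fraction (ratio 1 -> d[i], the lowest qualifying dose)
    ratio = (v[i - 1] - volume_fraction) / (v[i - 1] - v[i])
    return float(d[i - 1] + ratio * (d[i] - d[i - 1]))


def volume_at_dose(curve: DVHCurve, dose: float) -> float:
    """Interpolated cumulative volume fraction at *dose* Gy; 0 beyond the
    last edge."""
    if dose < 0:
        raise DomainError(f"dose must be non-negative, got {dose}")
    validate_dvh(curve)
    return float(
        np.interp(dose, curve.dose_edges, curve.cum_volume, right=0.0)
    )


def mean_dose(curve: DVHCurve) -> float:
    """Mean structure dose: trapezoid integral of V(d) over [0, last edge].

    Equals the midpoint-rule sum over differential bins for curves that reach
    V = 0; for truncated curves the residual volume beyond the last edge is
    (conservatively) not extrapolated.
    """
    validate_dvh(curve)
    return float(np.trapezoid(curve.cum_volume, curve.dose_edges))


def max_dose(curve: DVHCurve) -> float:
    """Smallest dose where the interpolated V reaches 0, or the last edge if
    it never does."""
    validate_dvh(curve)
    zero = curve.cum_volume <= _TOL
    if not zero.any():
        return float(curve.dose_edges[-1])
    return float(curve.dose_edges[int(np.argmax(zero))])


def geud_from_bins(
    fractions: np.ndarray, midpoints: np.ndarray, a: float
) -> float:
    """gEUD = (sum_i v_i D_i^a / sum_i v_i)^(1/a) on differential bins."""
    if a == 0:
        raise DomainError("gEUD exponent a must be non-zero")
    fractions = np.asarray(fractions, dtype=float)
    midpoints = np.asarray(midpoints, dtype=float)
    keep = fractions > 0
    fractions, midpoints = fractions[keep], midpoints[keep]
    if fractions.size == 0:
        return 0.0
    if a < 0 and np.any(midpoints <= 0):
        raise ZeroDoseWithNegativeExponent(
            "gEUD with a < 0 undefined for zero-dose bins"
        )
    total = fractions.sum()
    return float((np.sum(fractions * midpoints**a) / total) ** (1.0 / a))


def _bin_power_mean(lower: np.ndarray, upper: np.ndarray, a: float) -> np.ndarray:
    """Average of D^a over [lower, upper] under a uniform dose density."""
    w = upper - lower
    if a == -1.0:
        return (np.log(upper) - np.log(lower)) / w
    return (upper ** (a + 1.0) - lower ** (a + 1.0)) / ((a + 1.0) * w)


def generalized_eud(curve: DVHCurve, a: float) -> float:
    """Generalized equivalent uniform dose of *curve* with exponent *a*:
    the power mean (integral of D^a dV)^(1/a) of the dose distribution.

    The cumulative curve is interpreted, consistently with
    :func:`mean_dose`, as piecewise linear — i.e. each differential bin's
    volume is spread uniformly over the bin — and D^a is integrated exactly
    per bin. ``a = 1`` reduces to the mean dose; large ``a`` weights the
    hottest bins (serial organs). For ``a < 0`` any occupied bin touching
    0 Gy makes the power mean undefined (the integral diverges for
    a <= -1 and the convention ill-posed otherwise).
    """
    if a == 0:
        raise DomainError("gEUD exponent a must be non-zero")
    diff = cumulative_to_differential(curve)
    keep = diff.bin_volume_fraction > 0
    frac = diff.bin_volume_fraction[keep]
    lower, upper = diff.bin_lower[keep], diff.bin_upper[keep]
    if frac.size == 0:
        return 0.0
    if a < 0 and lower[0] <= 0.0:
        raise ZeroDoseWithNegativeExponent(
            "gEUD with a < 0 undefined when volume receives zero dose"
        )
    total = frac.sum()
    return float(
        (np.sum(frac * _bin_power_mean(lower, upper, a)) / total)
        ** (1.0 / a)
    )


def check_target_coverage(
    ctv_curve: DVHCurve, prescription: float
) -> CoverageReport:
    """Check the clinical goals D95 > 98% and D2 < 107% of the prescription."""
    if prescription <= 0:
        raise DomainError("prescription dose must be positive")
    d95 = dose_at_volume(ctv_curve, 0.95)
    d2 = dose_at_volume(ctv_curve, 0.02)
    return CoverageReport(
        d95_ok=bool(d95 > 0.98 * prescription),
        d2_ok=bool(d2 < 1.07 * prescription),
        d95_gy=d95,
        d2_gy=d2,
        prescription_gy=prescription,
    )


def compute_dose_metrics(
    curve: DVHCurve,
    volume_fractions: tuple = (0.99, 0.98, 0.95, 0.02, 0.01),
    doses: tuple = (),
) -> DoseMetrics:
    """Bundle the standard summary metrics of one curve."""
    return DoseMetrics(
        dmean=mean_dose(curve),
        dmax=max_dose(curve),
        d_at_volume={v: dose_at_volume(curve, v) for v in volume_fractions},
        v_at_dose={d: volume_at_dose(curve, d) for d in doses},
    )
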