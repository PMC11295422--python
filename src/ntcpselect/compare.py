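"""Photon-vs-proton plan comparison and NIPP qualification.

Per patient and endpoint the comparison is the NTCP difference
``delta_ntcp = NTCP_photon - NTCP_proton`` (positive values favor protons).
A patient qualifies for proton therapy under the Dutch National Indication
Protocol for Proton therapy (NIPP) when delta_ntcp >= 10% for any grade >= 2
endpoint and/or >= 5% for any grade >= 3 endpoint — inclusive thresholds,
inclusive "or" across endpoints.

Cohort-level dose comparisons follow the paired design: the average of
per-patient differences (which, for means, equals the difference of the two
column averages by linearity) and the median of per-patient differences
(which in general does *not* equal the difference of the column medians —
both are emitted with explicit labels).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set

import numpy as np

from . import dvh as _dvh
from .errors import (
    DomainError,
    DuplicatePatient,
    EmptyCohort,
    UnknownModel,
)
from .models import NTCPResult


@dataclass
class PlanPair:
    """Paired photon/proton plan of one patient: structure DVHs for both
    techniques, prescription levels, and clinical covariates."""

    patient_id: str
    laterality: str  # "left" | "right"
    photon: Dict[str, _dvh.DVHCurve]
    proton: Dict[str, _dvh.DVHCurve]
    prescriptions: Dict[str, float] = field(default_factory=dict)
    clinical: Dict[str, float] = field(default_factory=dict)

    def metrics(self, technique: str, structure_id: str) -> _dvh.DoseMetrics:
        curves = self.photon if technique == "photon" else self.proton
        return _dvh.compute_dose_metrics(curves[structure_id])


@dataclass(frozen=True)
class EndpointComparison:
    """NTCP of both techniques and their difference for one patient x model."""

    patient_id: str
    model: str
    ntcp_photon: float
    ntcp_proton: float
    delta_ntcp: float


@dataclass(frozen=True)
class QualificationResult:
    """Set of qualifying endpoints and the NIPP decision for one patient."""

    patient_id: str
    qualifying_endpoints: frozenset
    qualified: bool


@dataclass(frozen=True)
class NIPPThresholds:
    """Qualification thresholds on delta NTCP by toxicity grade class."""

    ge2_threshold: float = 0.10
    ge3_threshold: float = 0.05

    def __post_init__(self) -> None:
        for t in (self.ge2_threshold, self.ge3_threshold):
            if not 0.0 < t < 1.0:
                raise DomainError("thresholds must lie in (0, 1)")
        if self.ge3_threshold > self.ge2_threshold:
            raise DomainError("ge3 threshold must not exceed ge2 threshold")

    def for_grade(self, grade_class: str) -> float:
        if grade_class == "ge2":
            return self.ge2_threshold
        if grade_class == "ge3":
            return self.ge3_threshold
        raise DomainError(f"unknown grade class {grade_class!r}")


def delta_ntcp(ntcp_photon: float, ntcp_proton: float) -> float:
    """Photon NTCP minus proton NTCP; positive favors protons."""
    for p in (ntcp_photon, ntcp_proton):
        if not 0.0 <= p <= 1.0:
            raise DomainError(f"NTCP must lie in [0, 1], got {p}")
    return ntcp_photon - ntcp_proton


def build_endpoint_comparisons(
    results: Iterable[NTCPResult],
) -> List[EndpointComparison]:
    """Pair photon/proton NTCP results per (patient, model) into comparisons,
    in deterministic (patient, model) order."""
    by_key: Dict[tuple, Dict[str, float]] = {}
    for r in results:
        by_key.setdefault((r.patient_id, r.model), {})[r.technique] = r.ntcp
    out = []
    for (pid, model), pair in sorted(by_key.items()):
        if set(pair) != {"photon", "proton"}:
            raise DomainError(
                f"patient {pid}, model {model}: need exactly one photon and "
                f"one proton NTCP, got {sorted(pair)}"
            )
        out.append(
            EndpointComparison(
                patient_id=pid,
                model=model,
                ntcp_photon=pair["photon"],
                ntcp_proton=pair["proton"],
                delta_ntcp=delta_ntcp(pair["photon"], pair["proton"]),
            )
        )
    return out


def qualify_patient(
    comparisons: Sequence[EndpointComparison],
    grade_class: Mapping[str, str],
    thresholds: NIPPThresholds = NIPPThresholds(),
) -> QualificationResult:
    """Apply the NIPP rule to one patient's endpoint comparisons.

    An endpoint qualifies iff its delta_ntcp >= the threshold of its grade
    class (inclusive); the patient qualifies iff any endpoint does.
    """
    if not comparisons:
        raise EmptyCohort("no endpoint comparisons supplied")
    pids = {c.patient_id for c in comparisons}
    if len(pids) != 1:
        raise DomainError(f"comparisons span several patients: {sorted(pids)}")
    qualifying: Set[str] = set()
    for c in comparisons:
        if c.model not in grade_class:
            raise UnknownModel(c.model)
        if c.delta_ntcp >= thresholds.for_grade(grade_class[c.model]):
            qualifying.add(c.model)
    return QualificationResult(
        patient_id=comparisons[0].patient_id,
        qualifying_endpoints=frozenset(qualifying),
        qualified=bool(qualifying),
    )


def _round_half_up_pct(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class QualificationSummary:
    """Cohort-level qualification counts."""

    n_qualified_any: int
    cohort_size: int
    pct_of_cohort: int
    per_endpoint: Mapping[str, int]
    combination_breakdown: Mapping[tuple, int]


def cohort_qualification_summary(
    results: Sequence[QualificationResult], cohort_size: int
) -> QualificationSummary:
    """Summarize per-patient qualification decisions over the cohort.

    ``per_endpoint`` counts patients qualifying for each endpoint;
    ``combination_breakdown`` counts patients per exact (sorted) endpoint
    combination. Percentages are rounded half-up to integers.
    """
    pids = [r.patient_id for r in results]
    dupes = [p for p, n in Counter(pids).items() if n > 1]
    if dupes:
        raise DuplicatePatient(f"duplicate patient ids: {sorted(dupes)}")
    if cohort_size < len(results):
        raise DomainError("cohort_size smaller than number of results")
    qualified = [r for r in results if r.qualified]
    per_endpoint: Counter = Counter()
    combos: Counter = Counter()
    for r in qualified:
        per_endpoint.update(r.qualifying_endpoints)
        combos[tuple(sorted(r.qualifying_endpoints))] += 1
    n_any = len(qualified)
    pct = _round_half_up_pct(100.0 * n_any / cohort_size) if cohort_size else 0
    return QualificationSummary(
        n_qualified_any=n_any,
        cohort_size=cohort_size,
        pct_of_cohort=pct,
        per_endpoint=dict(sorted(per_endpoint.items())),
        combination_breakdown=dict(sorted(combos.items())),
    )


def delta_dose_summary(
    cohort: Sequence[PlanPair],
    structures: Optional[Sequence[str]] = None,
    metric: str = "dmean",
) -> Dict[str, Dict[str, float]]:
    """Per-structure cohort summary of photon, proton and photon-proton dose.

    For each structure the average and median of the photon values, the
    proton values and the per-patient differences are reported, together with
    the difference-of-column-statistics (``delta_of_averages``,
    ``delta_of_medians``) mirroring published table layouts. Structures
    missing for some patient are skipped with a logged warning.
    """
    import logging

    log = logging.getLogger(__name__)
    if not cohort:
        raise EmptyCohort("delta_dose_summary needs at least one patient")
    if structures is None:
        structures = sorted(
            set.intersection(*(set(p.photon) for p in cohort))
        )

    def value(curve: _dvh.DVHCurve) -> float:
        if metric == "dmean":
            return _dvh.mean_dose(curve)
        if metric == "dmax":
            return _dvh.max_dose(curve)
        if metric.startswith("d") and metric[1:].isdigit():
            return _dvh.dose_at_volume(curve, float(metric[1:]) / 100.0)
        raise DomainError(f"unknown metric {metric!r}")

    out: Dict[str, Dict[str, float]] = {}
    for sid in structures:
        x, y = [], []
        for p in cohort:
            if sid not in p.photon or sid not in p.proton:
                log.warning(
                    "patient %s: structure %s missing in one plan; skipped",
                    p.patient_id,
                    sid,
                )
                continue
            x.append(value(p.photon[sid]))
            y.append(value(p.proton[sid]))
        if not x:
            continue
        x_arr, y_arr = np.asarray(x), np.asarray(y)
        d = x_arr - y_arr
        out[sid] = {
            "photon_average": float(x_arr.mean()),
            "photon_median": float(np.median(x_arr)),
            "proton_average": float(y_arr.mean()),
            "proton_median": float(np.median(y_arr)),
            "delta_average": float(d.mean()),
            "delta_median": float(np.median(d)),
            "delta_of_averages": float(x_arr.mean() - y_arr.mean()),
            "delta_of_medians": float(np.median(x_arr) - np.median(y_arr)),
            "n": int(len(x)),
        }
    return out
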