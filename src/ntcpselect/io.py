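"""Readers and writers for all on-disk artifacts.

Interchange formats (all plain text, deterministic, UTF-8, decimal dot):

* **DVH table** — long-format CSV with the exact header
  ``patient_id,structure_id,technique,dose_gy,cum_volume_fraction``; the rows
  of one (patient, structure, technique) group form a cumulative DVH after
  sorting by dose. Volumes are stored as fractions in [0, 1], never cc or %.
* **Cohort manifest** — one row per patient: ``patient_id``, ``laterality``,
  one ``<level>_gy`` column per prescription level (blank when absent), any
  further column a clinical covariate.
* **Model registry** — JSON array of NTCP model specifications, schema
  validated on load; unknown fields are rejected and names must be unique.
* **Comparison report** — per-patient CSV, cohort-summary CSV, and a plain
  text summary with qualification counts and percentages.

Numbers are serialized with up to 9 significant digits, which round-trips
below every tolerance used in the pipeline.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from pydantic import ValidationError

from .compare import (
    EndpointComparison,
    NIPPThresholds,
    PlanPair,
    QualificationResult,
    QualificationSummary,
)
from .dvh import DVHCurve, validate_dvh
from .errors import (
    DuplicateModelName,
    HeaderMismatch,
    ParseError,
    SchemaError,
)
from .models import NTCPModelSpec
from .stats import PairedSample, paired_summary, wilcoxon_signed_rank

DVH_HEADER = [
    "patient_id",
    "structure_id",
    "technique",
    "dose_gy",
    "cum_volume_fraction",
]

_FLOAT_FMT = "%.9g"

GroupKey = Tuple[str, str, str]  # (patient_id, structure_id, technique)


def _format(x: float) -> str:
    return _FLOAT_FMT % x


# --------------------------------------------------------------- DVH tables
def read_dvh_table(path) -> Dict[GroupKey, DVHCurve]:
    """Read a long-format DVH CSV into validated curves keyed by
    (patient_id, structure_id, technique)."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().strip()
    if header != ",".join(DVH_HEADER):
        raise HeaderMismatch(
            f"{path}: expected header {','.join(DVH_HEADER)!r}, got {header!r}"
        )
    df = pd.read_csv(path, dtype={c: str for c in DVH_HEADER[:3]})
    for col in ("dose_gy", "cum_volume_fraction"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise ParseError(f"{path}:{line}: non-numeric value in {col}")
        if converted.isna().any():
            line = int(converted.isna().idxmax()) + 2
            raise ParseError(f"{path}:{line}: missing value in {col}")
        df[col] = converted

    curves: Dict[GroupKey, DVHCurve] = {}
    for key, group in df.groupby(
        ["patient_id", "structure_id", "technique"], sort=True
    ):
        group = group.sort_values("dose_gy")
        doses = group["dose_gy"].to_numpy()
        if np.any(np.diff(doses) == 0):
            raise ParseError(
                f"{path}: duplicate dose rows in group {key}"
            )
        curves[key] = validate_dvh(
            DVHCurve(
                patient_id=key[0],
                structure_id=key[1],
                technique=key[2],
                dose_edges=doses,
                cum_volume=group["cum_volume_fraction"].to_numpy(),
            )
        )
    return curves


def write_dvh_table(curves: Mapping[GroupKey, DVHCurve], path) -> Path:
    """Write curves as a long-format CSV with deterministic row order
    (patient, structure, technique, dose)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(DVH_HEADER) + "\n")
        for key in sorted(curves):
            c = curves[key]
            for d, v in zip(c.dose_edges, c.cum_volume):
                fh.write(
                    f"{key[0]},{key[1]},{key[2]},{_format(d)},{_format(v)}\n"
                )
    return path


# ------------------------------------------------------------------ manifest
def write_manifest(pairs: Sequence[PlanPair], path) -> Path:
    """One row per patient: laterality, prescription levels, clinical keys."""
    path = Path(path)
    levels = sorted({lab for p in pairs for lab in p.prescriptions})
    clin_keys = sorted({k for p in pairs for k in p.clinical})
    rows = []
    for p in sorted(pairs, key=lambda p: p.patient_id):
        row: Dict[str, object] = {
            "patient_id": p.patient_id,
            "laterality": p.laterality,
        }
        for lab in levels:
            row[f"{lab}_gy"] = (
                _format(p.prescriptions[lab]) if lab in p.prescriptions else ""
            )
        for k in clin_keys:
            row[k] = _format(p.clinical[k]) if k in p.clinical else ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, lineterminator="\n")
    return path


def read_manifest(path) -> Dict[str, dict]:
    """Read a manifest into {patient_id: {laterality, prescriptions,
    clinical}}."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    if "patient_id" not in df.columns or "laterality" not in df.columns:
        raise HeaderMismatch(
            f"{path}: manifest needs patient_id and laterality columns"
        )
    if df["patient_id"].duplicated().any():
        dupes = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise ParseError(f"{path}: duplicate patient ids {dupes}")
    out: Dict[str, dict] = {}
    level_cols = [c for c in df.columns if c.endswith("_gy")]
    other = [
        c
        for c in df.columns
        if c not in level_cols + ["patient_id", "laterality"]
    ]
    for _, row in df.iterrows():
        prescriptions = {
            c[:-3]: float(row[c])
            for c in level_cols
            if isinstance(row[c], str) and row[c] != ""
        }
        clinical = {
            c: float(row[c])
            for c in other
            if isinstance(row[c], str) and row[c] != ""
        }
        out[row["patient_id"]] = {
            "laterality": row["laterality"],
            "prescriptions": prescriptions,
            "clinical": clinical,
        }
    return out


def assemble_plan_pairs(
    curves: Mapping[GroupKey, DVHCurve], manifest: Mapping[str, dict]
) -> List[PlanPair]:
    """Join DVH curves and manifest rows into per-patient plan pairs."""
    pairs: List[PlanPair] = []
    for pid in sorted(manifest):
        photon = {
            sid: c
            for (p, sid, tech), c in curves.items()
            if p == pid and tech == "photon"
        }
        proton = {
            sid: c
            for (p, sid, tech), c in curves.items()
            if p == pid and tech == "proton"
        }
        if set(photon) != set(proton):
            only = set(photon) ^ set(proton)
            raise ParseError(
                f"patient {pid}: structures present under one technique "
                f"only: {sorted(only)}"
            )
        entry = manifest[pid]
        pairs.append(
            PlanPair(
                patient_id=pid,
                laterality=entry["laterality"],
                photon=photon,
                proton=proton,
                prescriptions=entry["prescriptions"],
                clinical=entry["clinical"],
            )
        )
    return pairs


# ------------------------------------------------------------ model registry
def _parse_registry(raw: object, source: str) -> List[NTCPModelSpec]:
    if not isinstance(raw, list):
        raise SchemaError(f"{source}: registry must be a JSON array")
    specs: List[NTCPModelSpec] = []
    for i, entry in enumerate(raw):
        try:
            specs.append(NTCPModelSpec.model_validate(entry))
        except ValidationError as exc:
            first = exc.errors()[0]
            pointer = "/" + "/".join(str(p) for p in (i, *first["loc"]))
            raise SchemaError(
                f"{source}: invalid model at {pointer}: {first['msg']}"
            ) from exc
    names = [s.name for s in specs]
    dupes = sorted({n for n in names if names.count(n) > 1})
    if dupes:
        raise DuplicateModelName(f"{source}: duplicate model names {dupes}")
    return specs


def load_model_registry(path) -> List[NTCPModelSpec]:
    """Load and schema-validate a JSON model registry."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        raw = json.load(fh)
    return _parse_registry(raw, str(path))


def dump_model_registry(specs: Sequence[NTCPModelSpec], path) -> Path:
    """Serialize a registry losslessly (load ∘ dump = identity)."""
    path = Path(path)
    payload = [s.model_dump(exclude_none=True) for s in specs]
    path.write_text(
        json.dumps(payload, indent=2) + "\n", encoding="utf-8"
    )
    return path


def load_default_registry() -> List[NTCPModelSpec]:
    """The shipped illustrative registry (placeholder coefficients)."""
    ref = resources.files("ntcpselect.data") / "illustrative_registry.json"
    return _parse_registry(
        json.loads(ref.read_text(encoding="utf-8")), "illustrative_registry"
    )


def default_registry_path() -> Path:
    return Path(
        str(resources.files("ntcpselect.data") / "illustrative_registry.json")
    )


# -------------------------------------------------------- comparison reports
def write_comparison_report(
    comparisons: Sequence[EndpointComparison],
    qual_results: Sequence[QualificationResult],
    summary: QualificationSummary,
    registry: Sequence[NTCPModelSpec],
    out_dir,
    prefix: str = "report",
    thresholds: NIPPThresholds = NIPPThresholds(),
) -> Dict[str, Path]:
    """Write the per-patient comparison CSV, the cohort-summary CSV and a
    plain-text qualification summary; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    grade = {m.name: m.grade_class for m in registry}
    qual_sets = {q.patient_id: q.qualifying_endpoints for q in qual_results}

    # per-patient rows
    rows = []
    for c in sorted(comparisons, key=lambda c: (c.patient_id, c.model)):
        rows.append(
            {
                "patient_id": c.patient_id,
                "endpoint": c.model,
                "grade_class": grade.get(c.model, ""),
                "ntcp_photon": _format(c.ntcp_photon),
                "ntcp_proton": _format(c.ntcp_proton),
                "delta_ntcp": _format(c.delta_ntcp),
                "qualifies": c.model in qual_sets.get(c.patient_id, ()),
            }
        )
    patient_csv = out_dir / f"{prefix}_comparisons.csv"
    pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "endpoint",
            "grade_class",
            "ntcp_photon",
            "ntcp_proton",
            "delta_ntcp",
            "qualifies",
        ],
    ).to_csv(patient_csv, index=False, lineterminator="\n")

    # cohort summary per endpoint
    summary_rows = []
    endpoints = sorted({c.model for c in comparisons})
    for m in endpoints:
        sub = [c for c in comparisons if c.model == m]
        sample = PairedSample(
            ids=[c.patient_id for c in sub],
            x=[c.ntcp_photon for c in sub],
            y=[c.ntcp_proton for c in sub],
        )
        stats = paired_summary(sample)
        try:
            p_value: Optional[float] = wilcoxon_signed_rank(sample).p_value
        except Exception:
            p_value = None  # e.g. all differences zero
        summary_rows.append(
            {
                "endpoint": m,
                "grade_class": grade.get(m, ""),
                "n": len(sub),
                "average_ntcp_photon": _format(stats["average_x"]),
                "median_ntcp_photon": _format(stats["median_x"]),
                "average_ntcp_proton": _format(stats["average_y"]),
                "median_ntcp_proton": _format(stats["median_y"]),
                "average_delta_ntcp": _format(stats["average_diff"]),
                "median_delta_ntcp": _format(stats["median_diff"]),
                "wilcoxon_p": "" if p_value is None else _format(p_value),
                "n_qualified": summary.per_endpoint.get(m, 0),
            }
        )
    cohort_csv = out_dir / f"{prefix}_cohort_summary.csv"
    pd.DataFrame(summary_rows).to_csv(
        cohort_csv, index=False, lineterminator="\n"
    )

    # plain-text summary
    lines = [
        "NIPP qualification summary",
        "==========================",
        f"Cohort size: {summary.cohort_size}",
        f"Thresholds: delta NTCP >= {thresholds.ge2_threshold:.0%} "
        f"(grade >=2) and/or >= {thresholds.ge3_threshold:.0%} (grade >=3)",
        f"Qualified for proton therapy: {summary.n_qualified_any} "
        f"({summary.pct_of_cohort}%)",
        "",
        "Per endpoint:",
    ]
    for m, n in summary.per_endpoint.items():
        pct = (
            int(np.floor(100.0 * n / summary.cohort_size + 0.5))
            if summary.cohort_size
            else 0
        )
        lines.append(f"  {m}: {n} ({pct}%)")
    lines.append("")
    lines.append("Endpoint combinations:")
    for combo, n in summary.combination_breakdown.items():
        lines.append(f"  {' + '.join(combo)}: {n}")
    lines.append("")
    lines.append(
        f"Note: {len(endpoints)} endpoints tested; reported p-values are "
        "raw (no multiple-testing correction)."
    )
    txt = out_dir / f"{prefix}_summary.txt"
    txt.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return {"comparisons": patient_csv, "cohort_summary": cohort_csv, "summary": txt}
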