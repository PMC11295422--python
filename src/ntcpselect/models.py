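"""Registry and evaluator for normal tissue complication probability models.

Two model families cover the registry:

* ``logistic_linear`` — multivariable logistic dose-response,
  NTCP = 1 / (1 + exp(-S)) with linear predictor
  S = beta0 + sum_i beta_i * x_i over dose metrics and clinical covariates.
* ``lkb_probit`` — Lyman-Kutcher-Burman,
  NTCP = Phi((gEUD - TD50) / (m * TD50)) with Phi the standard normal CDF,
  gEUD computed from the named structure's DVH with volume exponent ``a``.

Model coefficients are *configuration*, not code: they are loaded from a JSON
registry (see :mod:`ntcpselect.io`) and validated against the schema below.
The package ships an illustrative registry whose values are literature-
plausible placeholders; users applying published models transcribe the
original coefficients into their own registry file.

Dose covariates are addressed as ``"structure.metric"`` keys with metric in
``{dmean, geud, d2, d1, dmax}`` (``geud`` in a logistic term uses exponent 1,
i.e. the midpoint-rule mean). Keys without a dot are clinical covariates
resolved from the patient's covariate vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, List, Literal, Mapping, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.special import expit, ndtr

from . import dvh as _dvh
from .errors import DomainError, MissingCovariate, MissingStructure

if TYPE_CHECKING:  # pragma: no cover
    from .compare import PlanPair

DOSE_METRICS = ("dmean", "geud", "d2", "d1", "dmax")


class ModelTerm(BaseModel):
    """One additive term of a logistic linear predictor."""

    model_config = ConfigDict(extra="forbid")

    covariate_key: str
    coefficient: float


class LKBParams(BaseModel):
    """LKB-probit parameters: TD50 (Gy), slope m, volume exponent a, and the
    structure whose gEUD drives the model."""

    model_config = ConfigDict(extra="forbid")

    td50: float = Field(gt=0)
    m: float = Field(gt=0)
    a: float = 1.0
    structure: str

    @model_validator(mode="after")
    def _nonzero_exponent(self) -> "LKBParams":
        if self.a == 0:
            raise ValueError("lkb.a must be non-zero")
        return self


class NTCPModelSpec(BaseModel):
    """One endpoint's dose-response model, as stored in the registry."""

    model_config = ConfigDict(extra="forbid")

    name: str
    endpoint_label: str
    grade_class: Literal["ge2", "ge3"] = "ge2"
    form: Literal["logistic_linear", "lkb_probit"]
    intercept: Optional[float] = None
    terms: List[ModelTerm] = Field(default_factory=list)
    lkb: Optional[LKBParams] = None
    evidence_level: str = ""
    source_citation: str = ""

    @model_validator(mode="after")
    def _form_consistency(self) -> "NTCPModelSpec":
        if self.form == "logistic_linear":
            if not self.terms:
                raise ValueError(f"{self.name}: logistic_linear needs terms")
            if self.intercept is None:
                raise ValueError(
                    f"{self.name}: logistic_linear needs an intercept"
                )
        if self.form == "lkb_probit" and self.lkb is None:
            raise ValueError(f"{self.name}: lkb_probit needs an lkb block")
        return self


@dataclass(frozen=True)
class NTCPResult:
    """NTCP of one model for one patient under one technique."""

    patient_id: str
    technique: str
    model: str
    ntcp: float
    covariates_used: Mapping[str, float]


def logistic_ntcp(linear_predictor: float) -> float:
    """NTCP = 1 / (1 + exp(-S))."""
    if not np.isfinite(linear_predictor):
        raise DomainError("linear predictor must be finite")
    return float(expit(linear_predictor))


def lkb_ntcp(geud: float, td50: float, m: float) -> float:
    """LKB-probit NTCP = Phi((gEUD - TD50) / (m * TD50))."""
    if td50 <= 0 or m <= 0:
        raise DomainError("td50 and m must be positive")
    return float(ndtr((geud - td50) / (m * td50)))


def _resolve_dose_covariate(
    key: str, curves: Mapping[str, "_dvh.DVHCurve"]
) -> float:
    structure, metric = key.rsplit(".", 1)
    if structure not in curves:
        raise MissingStructure(structure)
    curve = curves[structure]
    if metric == "dmean":
        return _dvh.mean_dose(curve)
    if metric == "geud":
        return _dvh.generalized_eud(curve, a=1.0)
    if metric == "dmax":
        return _dvh.max_dose(curve)
    if metric == "d2":
        return _dvh.dose_at_volume(curve, 0.02)
    if metric == "d1":
        return _dvh.dose_at_volume(curve, 0.01)
    raise MissingCovariate(f"unknown dose metric {metric!r} in {key!r}")


def resolve_covariates(
    keys: Iterable[str],
    curves: Mapping[str, "_dvh.DVHCurve"],
    clinical: Optional[Mapping[str, float]] = None,
) -> dict:
    """Build a covariate vector for *keys* from DVH curves and clinical data."""
    clinical = clinical or {}
    out = {}
    for key in keys:
        last = key.rsplit(".", 1)
        if len(last) == 2 and last[1] in DOSE_METRICS:
            out[key] = _resolve_dose_covariate(key, curves)
        elif key in clinical:
            out[key] = float(clinical[key])
        else:
            raise MissingCovariate(key)
    return out


def linear_predictor(model: NTCPModelSpec, cov: Mapping[str, float]) -> float:
    """S = intercept + sum_i coefficient_i * covariate_i."""
    if model.form != "logistic_linear":
        raise DomainError(f"{model.name}: not a logistic_linear model")
    s = model.intercept
    for term in model.terms:
        if term.covariate_key not in cov:
            raise MissingCovariate(term.covariate_key)
        s += term.coefficient * cov[term.covariate_key]
    return float(s)


def evaluate_model(
    model: NTCPModelSpec,
    curves: Mapping[str, "_dvh.DVHCurve"],
    clinical: Optional[Mapping[str, float]] = None,
    patient_id: str = "",
    technique: str = "",
) -> NTCPResult:
    """Evaluate one NTCP model on one plan's structure DVHs.

    Dose covariates are pulled from the named structures' curves (gEUD
    computed on demand for LKB models); clinical covariates from *clinical*.
    """
    if model.form == "lkb_probit":
        p = model.lkb
        if p.structure not in curves:
            raise MissingStructure(p.structure)
        geud = _dvh.generalized_eud(curves[p.structure], a=p.a)
        ntcp = lkb_ntcp(geud, p.td50, p.m)
        used = {f"{p.structure}.geud": geud}
    else:
        cov = resolve_covariates(
            [t.covariate_key for t in model.terms], curves, clinical
        )
        ntcp = logistic_ntcp(linear_predictor(model, cov))
        used = cov
    return NTCPResult(
        patient_id=patient_id,
        technique=technique,
        model=model.name,
        ntcp=ntcp,
        covariates_used=used,
    )


def evaluate_cohort(
    registry: List[NTCPModelSpec],
    cohort: List["PlanPair"],
    allow_missing: bool = False,
) -> List[NTCPResult]:
    """Evaluate every registry model on every patient and technique.

    Returns one :class:`NTCPResult` per patient x model x technique in
    deterministic (patient, model, technique) order. By default a missing
    structure is a hard error naming the patient; with ``allow_missing`` the
    (patient, model) pair is skipped for *both* techniques with a logged
    warning, so downstream deltas never mix defined and undefined NTCPs.
    """
    import logging

    log = logging.getLogger(__name__)
    results: List[NTCPResult] = []
    for pair in cohort:
        for model in registry:
            per_tech = []
            try:
                for technique in _dvh.TECHNIQUES:
                    curves = (
                        pair.photon if technique == "photon" else pair.proton
                    )
                    per_tech.append(
                        evaluate_model(
                            model,
                            curves,
                            clinical=pair.clinical,
                            patient_id=pair.patient_id,
                            technique=technique,
                        )
                    )
            except (MissingStructure, MissingCovariate) as exc:
                if not allow_missing:
                    raise type(exc)(
                        f"patient {pair.patient_id}, model {model.name}: "
                        f"{exc.args[0]}"
                    ) from exc
                log.warning(
                    "patient %s, model %s: %s missing; NTCP undefined, "
                    "pair excluded from summaries",
                    pair.patient_id,
                    model.name,
                    exc.args[0],
                )
                continue
            results.extend(per_tech)
    return results
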