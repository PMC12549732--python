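"""FHIR-flavoured digital-twin documents with knowledge-graph export.

Each child's clinical variables and gait metrics are stored as a bundle of
Patient-like and Observation-like resources keyed by a local code system,
serializable to JSON (lossless round trip) and to canonical RDF Turtle.
Documents are pseudonymised: the raw child identifier never appears in any
serialized byte stream.

The resources mirror the Patient/Observation shapes of the FHIR standard
without claiming conformance to a specific FHIR release; the code system is
local to the package (a production deployment would bind SNOMED-CT/LOINC).
"""

from __future__ import annotations

import hashlib
import hmac
import json
from datetime import datetime, timezone
from typing import Literal, Optional, Union

import pandas as pd
import rdflib
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .cohort import ChildRecord
from .errors import ValidationError
from .features import FEATURE_NAMES

Timepoint = Literal["T0", "T3", "T6", "T12", "T18", "T24"]
TIMEPOINTS = ("T0", "T3", "T6", "T12", "T18", "T24")

#: Local code system: feature/clinical name -> (code, display, UCUM-ish unit).
#: Units use "1" for dimensionless quantities.
CODE_SYSTEM: dict[str, tuple[str, str, str]] = {
    "sex": ("GT-SEX", "Sex", ""),
    "ga_weeks": ("GT-GA", "Gestational age at birth", "wk"),
    "twin": ("GT-TWIN", "Twin pregnancy", ""),
    "bw_g": ("GT-BW", "Birth weight", "g"),
    "length_birth_cm": ("GT-LB", "Length at birth", "cm"),
    "length_t24_cm": ("GT-L24", "Length at 24 months", "cm"),
    "weight_t24_g": ("GT-W24", "Weight at 24 months", "g"),
    "walk_exp_weeks": ("GT-WALKEXP", "Independent walking experience", "wk"),
    "cog_score": ("GT-COG", "Cognitive standardised score", "1"),
    "risk": ("GT-RISK", "Clinical risk class", ""),
    "group": ("GT-GROUP", "Birth group", ""),
    # Table-style clinical domains without numeric payload in this cohort,
    # recorded as presence/absence flags.
    "brain_imaging_available": ("GT-IMG", "Brain imaging data available", ""),
    "nutrition_data_available": ("GT-NUTR", "Nutrition data available", ""),
    "pregnancy_delivery_recorded": ("GT-PREG", "Pregnancy and delivery data recorded", ""),
    "neonatal_period_recorded": ("GT-NEO", "Early neonatal period data recorded", ""),
    "nicu_stay_recorded": ("GT-NICU", "NICU stay data recorded", ""),
}

_METRIC_UNITS = {"strideT": "s", "stepT": "s", "stanceT": "%", "DS": "%",
                 "strideT_SD1": "s", "strideT_SD2": "s", "strideT_std": "s",
                 "stepT_SD1": "s", "stepT_SD2": "s", "stepT_std": "s",
                 "DS_SD1": "%", "DS_SD2": "%", "DS_std": "%",
                 "symm_stride": "%", "symm_step": "%"}
for _name in FEATURE_NAMES:
    if _name not in CODE_SYSTEM:
        CODE_SYSTEM[_name] = (f"GT-{_name.upper().replace('_', '-')}",
                              _name, _METRIC_UNITS.get(_name, "1"))


def pseudonymise(raw_id: str, salt: str) -> str:
    """Deterministic keyed pseudonym: 16 hex chars of HMAC-SHA256(salt, id)."""
    if not raw_id:
        raise ValidationError("empty raw_id")
    if not salt:
        raise ValidationError("empty salt")
    mac = hmac.new(salt.encode(), raw_id.encode(), hashlib.sha256)
    return mac.hexdigest()[:16]


class CodedObservation(BaseModel):
    model_config = ConfigDict(extra="forbid")

    code: str
    display: str
    value: Union[float, int, str, bool]
    unit: str = ""
    timepoint: Timepoint

    @model_validator(mode="after")
    def _numeric_needs_unit(self) -> "CodedObservation":
        if isinstance(self.value, (int, float)) and not isinstance(self.value, bool):
            if self.unit == "":
                raise ValidationError(f"numeric observation {self.code} lacks a unit")
        return self


class MotorAssessment(BaseModel):
    model_config = ConfigDict(extra="forbid")

    task: str = "independent_walking"
    timepoint: Timepoint = "T24"
    metric_codes: list[str] = Field(default_factory=list)


class TwinDocument(BaseModel):
    model_config = ConfigDict(extra="forbid")

    subject: str                     # pseudonym
    demographics: dict[str, Union[str, float, bool]]
    observations: list[CodedObservation]
    assessments: list[MotorAssessment] = Field(default_factory=list)
    audit: dict[str, str] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check(self) -> "TwinDocument":
        seen = set()
        for obs in self.observations:
            key = (obs.code, obs.timepoint)
            if key in seen:
                raise ValidationError(f"duplicate observation {key}")
            seen.add(key)
        return self


def build_twin(child: ChildRecord, metrics: Optional[dict] = None,
               timepoint: Timepoint = "T24", salt: str = "gaittwin",
               config_hash: str = "", created: Optional[str] = None) -> TwinDocument:
    """Assemble one child's twin document from record and metric vector.

    ``metrics`` is a metric-vector row (as produced by
    :func:`gaittwin.features.assemble_metric_vector`); its child_id must match.
    """
    if metrics is not None and metrics.get("child_id") != child.child_id:
        raise ValidationError("child/metrics id mismatch")
    subject = pseudonymise(child.child_id, salt)
    obs: list[CodedObservation] = []

    def add(name: str, value, tp: Timepoint) -> None:
        code, display, unit = CODE_SYSTEM[name]
        if isinstance(value, float) and pd.isna(value):
            return
        obs.append(CodedObservation(code=code, display=display, value=value,
                                    unit=unit, timepoint=tp))

    add("sex", child.sex, "T0")
    add("ga_weeks", child.ga_weeks, "T0")
    add("twin", child.twin, "T0")
    add("bw_g", child.bw_g, "T0")
    add("length_birth_cm", child.length_birth_cm, "T0")
    add("risk", child.risk, "T0")
    add("group", child.group, "T0")
    for flag in ("brain_imaging_available", "nutrition_data_available",
                 "pregnancy_delivery_recorded", "neonatal_period_recorded",
                 "nicu_stay_recorded"):
        add(flag, False, "T0")
    add("length_t24_cm", child.length_t24_cm, timepoint)
    add("weight_t24_g", child.weight_t24_g, timepoint)
    add("walk_exp_weeks", child.walk_exp_weeks, timepoint)
    if child.cog_score is not None:
        add("cog_score", child.cog_score, timepoint)

    metric_codes = []
    if metrics is not None:
        for name in FEATURE_NAMES:
            if name in ("sex", "twin", "length_birth_cm", "length_t24_cm",
                        "weight_t24_g", "walk_exp_weeks", "cog_score"):
                continue
            v = metrics.get(name)
            if v is None or (isinstance(v, float) and pd.isna(v)):
                continue
            add(name, float(v), timepoint)
            metric_codes.append(CODE_SYSTEM[name][0])

    return TwinDocument(
        subject=subject,
        demographics={"sex": child.sex, "ga_weeks": child.ga_weeks,
                      "birth_date_surrogate": f"GA{child.ga_weeks:.0f}wk"},
        observations=obs,
        assessments=[MotorAssessment(timepoint=timepoint,
                                     metric_codes=metric_codes)] if metric_codes else [],
        audit={"created": created or datetime.now(timezone.utc).isoformat(),
               "config_hash": config_hash},
    )


# ---------------------------------------------------------------------------
# JSON bundle round trip

def to_fhir_json(doc: TwinDocument) -> str:
    """Serialize as a FHIR-flavoured Bundle (1 Patient + n Observations)."""
    patient = {"resourceType": "Patient", "id": doc.subject,
               "extension": doc.demographics, "audit": doc.audit,
               "assessments": [a.model_dump() for a in doc.assessments]}
    entries = [{"resource": patient}]
    for o in doc.observations:
        entries.append({"resource": {
            "resourceType": "Observation",
            "subject": {"reference": f"Patient/{doc.subject}"},
            "code": {"coding": [{"system": "urn:gaittwin:codes", "code": o.code,
                                 "display": o.display}]},
            "value": o.value, "unit": o.unit, "timepoint": o.timepoint,
        }})
    return json.dumps({"resourceType": "Bundle", "type": "collection",
                       "entry": entries}, indent=1, sort_keys=True)


def from_fhir_json(text: Union[str, bytes]) -> TwinDocument:
    try:
        bundle = json.loads(text)
    except json.JSONDecodeError as e:
        raise ValidationError(f"malformed JSON at line {e.lineno}, col {e.colno}: {e.msg}")
    try:
        entries = bundle["entry"]
        patient = entries[0]["resource"]
        if patient["resourceType"] != "Patient":
            raise ValidationError("first bundle entry must be the Patient resource")
        observations = []
        for i, e in enumerate(entries[1:]):
            r = e["resource"]
            try:
                observations.append(CodedObservation(
                    code=r["code"]["coding"][0]["code"],
                    display=r["code"]["coding"][0]["display"],
                    value=r["value"], unit=r.get("unit", ""),
                    timepoint=r["timepoint"]))
            except (KeyError, ValidationError) as err:
                raise ValidationError(f"entry[{i + 1}].resource: {err}")
        return TwinDocument(
            subject=patient["id"], demographics=patient["extension"],
            observations=observations,
            assessments=[MotorAssessment(**a) for a in patient.get("assessments", [])],
            audit=patient.get("audit", {}))
    except KeyError as e:
        raise ValidationError(f"missing bundle field {e}")


# ---------------------------------------------------------------------------
# RDF export

NS = rdflib.Namespace("urn:gaittwin:")


def _doc_graph(doc: TwinDocument) -> rdflib.Graph:
    g = rdflib.Graph()
    g.bind("gt", NS)
    subj = NS[f"patient/{doc.subject}"]
    g.add((subj, rdflib.RDF.type, NS["Patient"]))
    for k, v in doc.demographics.items():
        g.add((subj, NS[f"demographics/{k}"], rdflib.Literal(v)))
    for o in doc.observations:
        node = NS[f"obs/{doc.subject}/{o.timepoint}/{o.code}"]
        g.add((node, rdflib.RDF.type, NS["Observation"]))
        g.add((node, NS["subject"], subj))
        g.add((node, NS["code"], rdflib.Literal(o.code)))
        g.add((node, NS["value"], rdflib.Literal(o.value)))
        if o.unit:
            g.add((node, NS["unit"], rdflib.Literal(o.unit)))
        g.add((node, NS["timepoint"], rdflib.Literal(o.timepoint)))
    return g


def canonical_turtle(g: rdflib.Graph) -> str:
    """Turtle with deterministic triple ordering (byte-reproducible)."""
    lines = ["@prefix gt: <urn:gaittwin:> .",
             "@prefix rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#> .",
             "@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .",
             "@prefix xsd: <http://www.w3.org/2001/XMLSchema#> .",
             ""]
    triples = sorted(g, key=lambda t: (str(t[0]), str(t[1]), str(t[2])))
    for s, p, o in triples:
        lines.append(f"{s.n3(g.namespace_manager)} {p.n3(g.namespace_manager)} "
                     f"{o.n3(g.namespace_manager)} .")
    return "\n".join(lines) + "\n"


def to_rdf_turtle(doc: TwinDocument) -> str:
    """Canonical Turtle serialization of one twin document."""
    return canonical_turtle(_doc_graph(doc))


# ---------------------------------------------------------------------------
# Knowledge graph

CONCEPTS = ("Child", "Examination", "MotorTask", "Metric", "RiskFactor", "Timepoint")


def export_knowledge_graph(docs: list[TwinDocument]) -> tuple[str, pd.DataFrame]:
    """Concept + instance graph over a cohort of twin documents.

    Returns canonical Turtle text and a (source, relation, target) edge list.
    """
    if not docs:
        raise ValidationError("need at least one document")
    g = rdflib.Graph()
    g.bind("gt", NS)
    edges: list[tuple[str, str, str]] = []

    def add(s: str, p: str, o: str) -> None:
        pred = rdflib.RDF.type if p == "rdf:type" else NS[p]
        g.add((NS[s], pred, NS[o]))
        edges.append((s, p, o))

    for c in CONCEPTS:
        g.add((NS[c], rdflib.RDF.type, rdflib.RDFS.Class))
        edges.append((c, "rdf:type", "rdfs:Class"))
    for doc in docs:
        child = f"child/{doc.subject}"
        add(child, "rdf:type", "Child")
        risk = next((str(o.value) for o in doc.observations if o.code == "GT-RISK"), None)
        if risk:
            add(f"riskfactor/{risk}", "rdf:type", "RiskFactor")
            add(child, "has_risk_factor", f"riskfactor/{risk}")
        for a in doc.assessments:
            ax = f"assessment/{doc.subject}/{a.timepoint}/{a.task}"
            add(ax, "rdf:type", "Examination")
            add(child, "has_assessment", ax)
            add(ax, "at_timepoint", f"timepoint/{a.timepoint}")
            add(f"timepoint/{a.timepoint}", "rdf:type", "Timepoint")
            add(ax, "of_task", f"motortask/{a.task}")
            add(f"motortask/{a.task}", "rdf:type", "MotorTask")
            for code in a.metric_codes:
                add(ax, "measured_by", f"metric/{code}")
                add(f"metric/{code}", "rdf:type", "Metric")

    frame = pd.DataFrame(sorted(set(edges)), columns=["source", "relation", "target"])
    return canonical_turtle(g), frame
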