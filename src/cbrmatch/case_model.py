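"""Domain types for clinical cases and case bases.

A *case* is one solved clinical episode: an attribute vector ``x`` of mixed
discrete and continuous values, a class (outcome/disease) label ``y``, free-text
sections keyed by the seven clinical entity categories, and quality metadata.
A *case base* is the retrieval substrate: an attribute schema, the finite class
value set Y, and an ordered collection of cases.

This module owns serialization (CSV and JSON-lines dialects), validation,
min-max normalization of continuous attributes, and irreversible privacy
masking of metadata/text fields.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace

__all__ = [
    "ENTITY_CATEGORIES",
    "MASK_TOKEN",
    "AttributeSchema",
    "Case",
    "CaseBase",
    "Thresholds",
    "NormalizationMap",
    "CaseBaseError",
    "read_case_base",
    "write_case_base",
    "validate_case",
    "normalize_continuous",
    "mask_private_fields",
]

#: The seven clinical entity categories used throughout the pipeline:
#: patient information, time, disease, symptom, examination test,
#: treatment plan, other.
ENTITY_CATEGORIES = ("CL1", "CL2", "CL3", "CL4", "CL5", "CL6", "CL7")

#: Replacement written over masked private fields.  Identical for every case so
#: the original value cannot be recovered or even distinguished.
MASK_TOKEN = "***MASKED***"


class CaseBaseError(ValueError):
    """Raised for malformed case bases, rows, or schema violations."""


@dataclass(frozen=True)
class AttributeSchema:
    """One attribute of the case vector.

    Parameters
    ----------
    name : str
        Unique attribute name.
    kind : {"discrete", "continuous"}
        Drives the distance component used for this attribute: value-difference
        metric for discrete, squared difference for continuous.
    domain : tuple
        For discrete attributes the finite set of admissible values; for
        continuous attributes the observed ``(min, max)`` pair (may be empty
        until data is seen).
    missing_token : str
        Sentinel written to disk for absent values.
    """

    name: str
    kind: str
    domain: tuple = ()
    missing_token: str = "NA"

    def __post_init__(self):
        if self.kind not in ("discrete", "continuous"):
            raise CaseBaseError(f"unknown attribute kind {self.kind!r} for {self.name!r}")
        if self.kind == "continuous" and len(self.domain) == 2:
            lo, hi = self.domain
            if lo > hi:
                raise CaseBaseError(f"continuous domain min > max for {self.name!r}")


@dataclass
class Case:
    """One clinical case: ID, mixed attribute vector, label, text, metadata."""

    case_id: str
    x: list
    y: object = None
    patient_id: str = ""
    sections: dict = field(default_factory=dict)
    audit_features: list = field(default_factory=list)
    class_features: list = field(default_factory=list)
    scores: dict = field(default_factory=dict)
    flags: set = field(default_factory=set)

    def copy(self) -> "Case":
        return Case(
            case_id=self.case_id,
            x=list(self.x),
            y=self.y,
            patient_id=self.patient_id,
            sections=dict(self.sections),
            audit_features=list(self.audit_features),
            class_features=list(self.class_features),
            scores=dict(self.scores),
            flags=set(self.flags),
        )


@dataclass
class CaseBase:
    """Schema + class value set Y + ordered case collection.

    Case order is the stable tie-break ordering for retrieval everywhere
    downstream, so it is preserved by every operation and by I/O.
    """

    schema: list
    class_values: tuple
    cases: list = field(default_factory=list)

    def __post_init__(self):
        names = [a.name for a in self.schema]
        if len(set(names)) != len(names):
            raise CaseBaseError("duplicate attribute names in schema")
        ids = [c.case_id for c in self.cases]
        if len(set(ids)) != len(ids):
            raise CaseBaseError("duplicate case_id values in case base")
        observed = {c.y for c in self.cases if c.y is not None}
        self.class_values = tuple(sorted(set(self.class_values) | observed, key=str))
        for c in self.cases:
            report = validate_case(c, self)
            if report:
                raise CaseBaseError(f"case {c.case_id!r} invalid: {'; '.join(report)}")

    def __len__(self) -> int:
        return len(self.cases)

    def attribute_names(self) -> list:
        return [a.name for a in self.schema]

    def copy(self) -> "CaseBase":
        return CaseBase(
            schema=list(self.schema),
            class_values=tuple(self.class_values),
            cases=[c.copy() for c in self.cases],
        )


@dataclass(frozen=True)
class Thresholds:
    """Triage thresholds: sigma/gamma on the 0-100 score scale, omega in (0,1).

    sigma cuts Score1 (audit quality), gamma cuts Score2 (expert readability),
    omega is the disease-frequency cut below which a case counts as rare.
    """

    sigma: float = 60.0
    gamma: float = 60.0
    omega: float = 0.01

    def __post_init__(self):
        if not (0 <= self.sigma <= 100):
            raise CaseBaseError("sigma must lie in [0, 100]")
        if not (0 <= self.gamma <= 100):
            raise CaseBaseError("gamma must lie in [0, 100]")
        if not (0 < self.omega < 1):
            raise CaseBaseError("omega must lie strictly in (0, 1)")


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_case(case: Case, base: CaseBase) -> list:
    """Report-style validation of a case against a base's schema.

    Returns a list of human-readable violations; empty iff the case is valid.
    """
    report = []
    if len(case.x) != len(base.schema):
        report.append(
            f"attribute vector length {len(case.x)} != schema length {len(base.schema)}"
        )
        return report
    for attr, value in zip(base.schema, case.x):
        if value is None:
            continue
        if attr.kind == "discrete":
            if attr.domain and value not in attr.domain:
                report.append(f"value {value!r} outside domain of {attr.name!r}")
        else:
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                report.append(f"non-numeric continuous value {value!r} for {attr.name!r}")
            elif not math.isfinite(value):
                report.append(f"non-finite continuous value for {attr.name!r}")
    if case.y is not None and base.class_values and case.y not in base.class_values:
        report.append(f"label {case.y!r} not in class value set")
    return report


# ---------------------------------------------------------------------------
# I/O — CSV and JSON-lines dialects
# ---------------------------------------------------------------------------
# CSV: UTF-8, comma-separated; first row is the header, second row declares
# column kinds (id / discrete / continuous / class / text).  A column named
# "patient_id" with kind id is the patient ID; any other id column is the case
# ID.  Text columns named CL1..CL7 populate the case's sections.
# JSONL: first line is a schema object, each following line one case object;
# this dialect round-trips every Case field.


def _parse_cell(token: str, attr: AttributeSchema, row_no: int):
    if token == attr.missing_token or token == "":
        return None
    if attr.kind == "continuous":
        try:
            return float(token)
        except ValueError:
            raise CaseBaseError(
                f"row {row_no}: non-numeric value {token!r} for continuous "
                f"attribute {attr.name!r}"
            ) from None
    return token


def _read_csv(path) -> CaseBase:
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 2:
        raise CaseBaseError("CSV needs a header row and a kinds row")
    header, kinds = rows[0], rows[1]
    if len(header) != len(kinds):
        raise CaseBaseError("header and kinds rows differ in length")
    attr_cols, id_col, patient_col, class_col, text_cols = [], None, None, None, []
    for j, (name, kind) in enumerate(zip(header, kinds)):
        if kind in ("discrete", "continuous"):
            attr_cols.append((j, name, kind))
        elif kind == "id":
            if name == "patient_id":
                patient_col = j
            else:
                id_col = j
        elif kind == "class":
            class_col = j
        elif kind == "text":
            text_cols.append((j, name))
        else:
            raise CaseBaseError(f"unknown attribute kind {kind!r} in column {name!r}")
    if id_col is None:
        raise CaseBaseError("no id column declared")

    body = rows[2:]
    # discrete domains are the observed value sets
    domains = {name: set() for _, name, kind in attr_cols if kind == "discrete"}
    parsed = []
    for r, row in enumerate(body, start=3):
        if len(row) != len(header):
            raise CaseBaseError(f"row {r}: expected {len(header)} cells, got {len(row)}")
        parsed.append(row)
        for j, name, kind in attr_cols:
            if kind == "discrete" and row[j] not in ("", "NA"):
                domains[name].add(row[j])

    schema = [
        AttributeSchema(
            name=name,
            kind=kind,
            domain=tuple(sorted(domains[name])) if kind == "discrete" else (),
        )
        for _, name, kind in attr_cols
    ]
    cases = []
    for r, row in enumerate(parsed, start=3):
        x = [
            _parse_cell(row[j], attr, r)
            for (j, _, _), attr in zip(attr_cols, schema)
        ]
        y = row[class_col] if class_col is not None and row[class_col] != "" else None
        sections = {name: row[j] for j, name in text_cols if row[j] != ""}
        cases.append(
            Case(
                case_id=row[id_col],
                x=x,
                y=y,
                patient_id=row[patient_col] if patient_col is not None else "",
                sections=sections,
            )
        )
    labels = tuple(sorted({c.y for c in cases if c.y is not None}, key=str))
    return CaseBase(schema=schema, class_values=labels, cases=cases)


def _read_jsonl(path) -> CaseBase:
    with open(path, encoding="utf-8") as fh:
        lines = [ln for ln in fh if ln.strip()]
    if not lines:
        raise CaseBaseError("empty JSONL file")
    head = json.loads(lines[0])
    if head.get("record") != "schema":
        raise CaseBaseError("JSONL must start with a schema object")
    schema = [
        AttributeSchema(
            name=a["name"],
            kind=a["kind"],
            domain=tuple(a.get("domain", ())),
            missing_token=a.get("missing_token", "NA"),
        )
        for a in head["attributes"]
    ]
    cases = []
    for r, ln in enumerate(lines[1:], start=2):
        try:
            obj = json.loads(ln)
        except json.JSONDecodeError as exc:
            raise CaseBaseError(f"row {r}: malformed JSON ({exc})") from None
        cases.append(
            Case(
                case_id=obj["case_id"],
                x=obj["x"],
                y=obj.get("y"),
                patient_id=obj.get("patient_id", ""),
                sections=obj.get("sections", {}),
                audit_features=obj.get("audit_features", []),
                class_features=obj.get("class_features", []),
                scores=obj.get("scores", {}),
                flags=set(obj.get("flags", [])),
            )
        )
    return CaseBase(
        schema=schema, class_values=tuple(head.get("class_values", ())), cases=cases
    )


def read_case_base(path, format: str = "csv") -> CaseBase:
    """Read a case base from ``path`` in the ``csv`` or ``jsonl`` dialect."""
    if format == "csv":
        return _read_csv(path)
    if format == "jsonl":
        return _read_jsonl(path)
    raise CaseBaseError(f"unknown format {format!r}")


def write_case_base(base: CaseBase, path, format: str = "csv") -> None:
    """Write ``base`` so that :func:`read_case_base` reproduces its content.

    The CSV dialect carries ids, attributes, class and text sections; the JSONL
    dialect additionally round-trips quality metadata and flags.
    """
    if format == "csv":
        section_names = sorted({k for c in base.cases for k in c.sections})
        header = ["case_id", "patient_id"] + base.attribute_names() + ["y"] + section_names
        kinds = ["id", "id"] + [a.kind for a in base.schema] + ["class"] + (
            ["text"] * len(section_names)
        )
        with open(path, "w", newline="", encoding="utf-8") as fh:
            wr = csv.writer(fh)
            wr.writerow(header)
            wr.writerow(kinds)
            for c in base.cases:
                cells = [c.case_id, c.patient_id]
                for attr, v in zip(base.schema, c.x):
                    if v is None:
                        cells.append(attr.missing_token)
                    elif attr.kind == "continuous":
                        cells.append(repr(float(v)))
                    else:
                        cells.append(str(v))
                cells.append("" if c.y is None else str(c.y))
                cells.extend(c.sections.get(s, "") for s in section_names)
                wr.writerow(cells)
    elif format == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            head = {
                "record": "schema",
                "attributes": [
                    {
                        "name": a.name,
                        "kind": a.kind,
                        "domain": list(a.domain),
                        "missing_token": a.missing_token,
                    }
                    for a in base.schema
                ],
                "class_values": list(base.class_values),
            }
            fh.write(json.dumps(head) + "\n")
            for c in base.cases:
                fh.write(
                    json.dumps(
                        {
                            "case_id": c.case_id,
                            "patient_id": c.patient_id,
                            "x": c.x,
                            "y": c.y,
                            "sections": c.sections,
                            "audit_features": c.audit_features,
                            "class_features": c.class_features,
                            "scores": c.scores,
                            "flags": sorted(c.flags),
                        }
                    )
                    + "\n"
                )
    else:
        raise CaseBaseError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Continuous normalization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalizationMap:
    """Per-attribute (min, max) statistics frozen from a reference base.

    Transforms values by (v - min) / (max - min) into [0, 1]; constant
    attributes map to 0; later target-case values are clipped to [0, 1] so a
    query outside the training range cannot dominate the distance.
    """

    stats: dict  # attr name -> (min, max)

    def transform_value(self, name: str, value):
        if value is None:
            return None
        lo, hi = self.stats[name]
        if hi == lo:
            return 0.0
        return min(1.0, max(0.0, (float(value) - lo) / (hi - lo)))

    def transform_case(self, case: Case, schema: list) -> Case:
        out = case.copy()
        out.x = [
            self.transform_value(a.name, v) if a.kind == "continuous" else v
            for a, v in zip(schema, case.x)
        ]
        return out

    def transform_base(self, base: CaseBase) -> CaseBase:
        out = base.copy()
        out.cases = [self.transform_case(c, base.schema) for c in base.cases]
        return out


def normalize_continuous(base: CaseBase):
    """Min-max normalize every continuous attribute of ``base`` to [0, 1].

    Returns ``(normalized_base, normalization_map)``; the map re-applies the
    same statistics to later target cases (with clipping).  The squared
    difference used for continuous attributes is unnormalized, so without this
    step a wide-range attribute would dominate the value-difference terms,
    which are bounded.
    """
    stats = {}
    for i, attr in enumerate(base.schema):
        if attr.kind != "continuous":
            continue
        vals = [c.x[i] for c in base.cases if c.x[i] is not None]
        if not vals:
            raise CaseBaseError(f"attribute {attr.name!r} has no non-missing values")
        stats[attr.name] = (min(vals), max(vals))
    nmap = NormalizationMap(stats=stats)
    out = nmap.transform_base(base)
    out.schema = [
        replace(a, domain=(0.0, 1.0)) if a.kind == "continuous" else a
        for a in base.schema
    ]
    return out, nmap


# ---------------------------------------------------------------------------
# Privacy masking
# ---------------------------------------------------------------------------

def mask_private_fields(base: CaseBase, fields: list) -> CaseBase:
    """Irreversibly mask metadata/text fields named in ``fields``.

    ``"patient_id"`` masks the patient identifier; any entity-category or
    section name masks that text section.  Attribute vectors, class labels and
    case count are never touched, so retrieval over a masked base is identical
    to retrieval over the original.
    """
    known = {"patient_id"} | {k for c in base.cases for k in c.sections}
    for f in fields:
        if f not in known and f not in ENTITY_CATEGORIES:
            raise CaseBaseError(f"unknown private field {f!r}")
    out = base.copy()
    for c in out.cases:
        for f in fields:
            if f == "patient_id":
                c.patient_id = MASK_TOKEN
            elif f in c.sections:
                c.sections[f] = MASK_TOKEN
    return out
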