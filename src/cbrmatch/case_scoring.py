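"""Quality scoring and triage of a case base.

Two sigmoid-normalized linear scores drive the triage:

* ``Score1 = 100 * sigmoid(sum_i a_i x_i)`` over audit indices (x1 =
  knowledge richness, x2 = curative effect / treatment time, ...), selecting
  high-quality cases at threshold sigma;
* ``Score2 = 100 * sigmoid(sum_i b_i z_i)`` over readability indices (z1 =
  accuracy of wording, z2 = simplicity, ...), selecting well-known-physician
  cases at threshold gamma.

The raw sigmoid lies in (0, 1) while the thresholds are stated on a 0-100
scale, so scores are reported as 100 x sigmoid.  Rare-disease triage flags
every case whose class-label relative frequency falls below omega in (0, 1).

Audit/readability feature values are supplied per case; two reference
extractors (entity-section richness, CL2 treatment-time span) are shipped as
replaceable defaults since the indices name concepts, not computations.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .case_model import ENTITY_CATEGORIES, Case, CaseBase, CaseBaseError

__all__ = [
    "AuditConfig",
    "ReadabilityConfig",
    "sigmoid",
    "score1",
    "score2",
    "score_case_base",
    "select_cases",
    "disease_frequency",
    "classify_rare",
    "audit_knowledge_richness",
    "audit_treatment_time",
]


@dataclass(frozen=True)
class AuditConfig:
    """Audit index names and weights a_1..a_n for Score1."""

    index_names: tuple = ("knowledge_richness", "treatment_time")
    weights: tuple = (1.0, 1.0)

    def __post_init__(self):
        if len(self.index_names) != len(self.weights):
            raise CaseBaseError("audit index names and weights differ in length")
        if not np.all(np.isfinite(self.weights)):
            raise CaseBaseError("audit weights must be finite")


@dataclass(frozen=True)
class ReadabilityConfig:
    """Readability index names and weights b_1..b_n for Score2."""

    index_names: tuple = ("wording_accuracy", "simplicity")
    weights: tuple = (1.0, 1.0)

    def __post_init__(self):
        if len(self.index_names) != len(self.weights):
            raise CaseBaseError("readability index names and weights differ in length")
        if not np.all(np.isfinite(self.weights)):
            raise CaseBaseError("readability weights must be finite")


def sigmoid(x: float) -> float:
    """Logistic normalization 1 / (1 + e^-x), strictly increasing on R."""
    # split to avoid overflow for large |x|
    if x >= 0:
        return 1.0 / (1.0 + np.exp(-x))
    z = np.exp(x)
    return float(z / (1.0 + z))


def score1(case: Case, config: AuditConfig) -> float:
    """Audit score 100 * sigmoid(sum a_i x_i), strictly inside (0, 100)."""
    if len(case.audit_features) != len(config.weights):
        raise CaseBaseError(
            f"case {case.case_id!r}: {len(case.audit_features)} audit features "
            f"but {len(config.weights)} audit weights"
        )
    return 100.0 * sigmoid(float(np.dot(config.weights, case.audit_features)))


def score2(case: Case, config: ReadabilityConfig) -> float:
    """Readability score 100 * sigmoid(sum b_i z_i), strictly inside (0, 100)."""
    if len(case.class_features) != len(config.weights):
        raise CaseBaseError(
            f"case {case.case_id!r}: {len(case.class_features)} readability "
            f"features but {len(config.weights)} readability weights"
        )
    return 100.0 * sigmoid(float(np.dot(config.weights, case.class_features)))


def score_case_base(base: CaseBase, audit: AuditConfig = None,
                    readability: ReadabilityConfig = None) -> CaseBase:
    """Compute and attach score1/score2 to every case; returns a new base."""
    out = base.copy()
    for c in out.cases:
        if audit is not None:
            c.scores["score1"] = score1(c, audit)
        if readability is not None:
            c.scores["score2"] = score2(c, readability)
    return out


_SCORE_FLAGS = {"score1": "high_quality", "score2": "well_known"}


def select_cases(base: CaseBase, score_name: str, threshold: float):
    """Flag every case whose stored score >= threshold; removes nothing.

    ``score1`` at sigma flags ``high_quality``; ``score2`` at gamma flags
    ``well_known``.  Returns ``(flagged_base, selected_count)``.
    """
    if score_name not in _SCORE_FLAGS:
        raise CaseBaseError(f"unknown score {score_name!r}")
    flag = _SCORE_FLAGS[score_name]
    out = base.copy()
    count = 0
    for c in out.cases:
        if score_name not in c.scores:
            raise CaseBaseError(f"case {c.case_id!r} has no {score_name} computed")
        if c.scores[score_name] >= threshold:
            c.flags.add(flag)
            count += 1
    return out, count


def disease_frequency(base: CaseBase) -> dict:
    """Relative frequency of each observed class (disease) label; sums to 1."""
    labels = [c.y for c in base.cases if c.y is not None]
    if not labels:
        raise CaseBaseError("cannot compute disease frequencies on an empty base")
    counts = Counter(labels)
    n = len(labels)
    return {lab: cnt / n for lab, cnt in counts.items()}


def classify_rare(base: CaseBase, omega: float):
    """Flag every case whose disease frequency < omega as ``rare``.

    Returns ``(flagged_base, rare_label_list)``.
    """
    if not (0 < omega < 1):
        raise CaseBaseError("omega must lie strictly in (0, 1)")
    freqs = disease_frequency(base)
    rare = sorted((lab for lab, f in freqs.items() if f < omega), key=str)
    rare_set = set(rare)
    out = base.copy()
    for c in out.cases:
        if c.y in rare_set:
            c.flags.add("rare")
    return out, rare


# ---------------------------------------------------------------------------
# Reference audit-feature extractors (replaceable defaults)
# ---------------------------------------------------------------------------

def audit_knowledge_richness(case: Case) -> float:
    """Fraction of the 7 entity categories with non-empty text in the case."""
    present = sum(1 for cat in ENTITY_CATEGORIES if case.sections.get(cat, "").strip())
    return present / len(ENTITY_CATEGORIES)


_DATE_RE = re.compile(r"(\d{4})-(\d{2})-(\d{2})")


def audit_treatment_time(case: Case) -> float:
    """Days between the first and last parseable date stamp in the CL2 (time)
    section; 0.0 when fewer than two stamps parse."""
    import datetime

    stamps = []
    for m in _DATE_RE.finditer(case.sections.get("CL2", "")):
        try:
            stamps.append(datetime.date(*map(int, m.groups())))
        except ValueError:
            continue
    if len(stamps) < 2:
        return 0.0
    return float(abs((max(stamps) - min(stamps)).days))
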