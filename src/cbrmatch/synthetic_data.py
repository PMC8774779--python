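"""Synthetic data: case bases, pseudo-EMR corpora, and rater score matrices.

These generators make the whole pipeline testable without clinical data and
with ground truth attached:

* :func:`gen_case_base` draws mixed-type case bases in which a known subset of
  attributes is class-informative (continuous: class-shifted unit-variance
  Gaussians; discrete: class-linked categoricals with 0.7 majority mass) and
  the rest pure noise, optionally planting a rare disease label;
* :func:`gen_emr_corpus` writes pseudo-EMR documents with gold character-level
  BMES segmentation, gold word-level entity categories, a semi-structured
  numeric record per patient, and simulated ensemble outputs of configurable
  fidelity;
* :func:`gen_rater_scores` produces rater ranking matrices with a dial from
  perfect concordance to independence.

Everything is deterministic per seed (numpy Generator, fixed algorithm).
Documents use English tokens concatenated without separators, so character
level BMES segmentation is exercised exactly as it would be on Chinese text;
the fusion arithmetic is script-agnostic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .case_model import AttributeSchema, Case, CaseBase, CaseBaseError
from .text_extraction import BMES, ExtractionError, LabeledSentence

__all__ = [
    "CaseGenSpec",
    "CorpusGenSpec",
    "DEFAULT_TEMPLATES",
    "RARE_LABEL",
    "gen_case_base",
    "standard_noisy_spec",
    "gen_emr_corpus",
    "simulate_seg_ensemble",
    "simulate_entity_ensemble",
    "write_corpus",
    "read_corpus",
    "gen_rater_scores",
]

RARE_LABEL = "RARE"


# ---------------------------------------------------------------------------
# Case-base generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CaseGenSpec:
    """Recipe for a synthetic mixed-type case base with known ground truth."""

    n_cases: int = 400
    n_classes: int = 2
    n_cont_informative: int = 1
    n_disc_informative: int = 1
    n_noise: int = 8
    separation: float = 2.0
    disc_cardinality: int = 4
    rare_label_freq: float = None
    seed: int = 0

    def __post_init__(self):
        if self.n_cont_informative + self.n_disc_informative + self.n_noise < 1:
            raise CaseBaseError("at least one attribute is required")
        if self.separation < 0:
            raise CaseBaseError("separation must be >= 0")
        if self.rare_label_freq is not None and not (0 < self.rare_label_freq < 1):
            raise CaseBaseError("rare_label_freq must lie in (0, 1)")
        if self.n_classes < 1 or self.disc_cardinality < 2:
            raise CaseBaseError("need >= 1 class and discrete cardinality >= 2")


def standard_noisy_spec(seed: int = 0) -> CaseGenSpec:
    """The standard noisy generator setting used across the evaluation
    harness: 2 informative attributes (1 continuous + 1 discrete) buried in 8
    noise attributes, class separation 2, 400 cases, 2 classes."""
    return CaseGenSpec(
        n_cases=400, n_classes=2, n_cont_informative=1, n_disc_informative=1,
        n_noise=8, separation=2.0, seed=seed,
    )


def gen_case_base(spec: CaseGenSpec):
    """Generate a case base plus a ground-truth descriptor.

    The descriptor records which attribute names are informative/noise and
    the planted rare label (if any), sufficient for weight-recovery tests.
    Audit and readability features are drawn standard-normal so Score1/Score2
    are computable and enumerable.
    """
    rng = np.random.default_rng(spec.seed)
    classes = [f"C{k}" for k in range(spec.n_classes)]
    card = spec.disc_cardinality
    disc_domain = tuple(f"v{j}" for j in range(card))
    # Discrete class linkage scales with separation so that separation 0 means
    # *no* attribute carries class signal; at the standard separation 2 the
    # majority mass on the class-linked value is exactly 0.7.
    majority = 1.0 / card + (0.7 - 1.0 / card) * min(spec.separation / 2.0, 1.0)

    schema, informative, noise_names = [], [], []
    for i in range(spec.n_cont_informative):
        name = f"cont_inf_{i}"
        schema.append(AttributeSchema(name=name, kind="continuous"))
        informative.append(name)
    for i in range(spec.n_disc_informative):
        name = f"disc_inf_{i}"
        schema.append(AttributeSchema(name=name, kind="discrete", domain=disc_domain))
        informative.append(name)
    for i in range(spec.n_noise):
        kind = "continuous" if i % 2 == 0 else "discrete"
        name = f"noise_{i}"
        schema.append(AttributeSchema(
            name=name, kind=kind,
            domain=disc_domain if kind == "discrete" else (),
        ))
        noise_names.append(name)

    labels = []
    for _ in range(spec.n_cases):
        if spec.rare_label_freq is not None and rng.random() < spec.rare_label_freq:
            labels.append(RARE_LABEL)
        else:
            labels.append(classes[rng.integers(spec.n_classes)])
    all_labels = classes + ([RARE_LABEL] if spec.rare_label_freq is not None else [])
    label_index = {lab: k for k, lab in enumerate(all_labels)}

    cases = []
    for idx, lab in enumerate(labels):
        k = label_index[lab]
        x = []
        for attr in schema:
            if attr.name.startswith("cont_inf"):
                x.append(float(rng.normal(spec.separation * k, 1.0)))
            elif attr.name.startswith("disc_inf"):
                linked = k % card
                if rng.random() < majority:
                    x.append(disc_domain[linked])
                else:
                    others = [v for j, v in enumerate(disc_domain) if j != linked]
                    x.append(others[rng.integers(len(others))])
            elif attr.kind == "continuous":
                x.append(float(rng.normal(0.0, 1.0)))
            else:
                x.append(disc_domain[rng.integers(card)])
        cases.append(Case(
            case_id=f"case_{idx:05d}",
            patient_id=f"patient_{idx:05d}",
            x=x,
            y=lab,
            audit_features=[float(v) for v in rng.normal(0.0, 1.0, size=2)],
            class_features=[float(v) for v in rng.normal(0.0, 1.0, size=2)],
        ))

    base = CaseBase(schema=schema, class_values=tuple(sorted(all_labels)),
                    cases=cases)
    descriptor = {
        "informative": informative,
        "noise": noise_names,
        "classes": classes,
        "rare_label": RARE_LABEL if spec.rare_label_freq is not None else None,
        "seed": spec.seed,
    }
    return base, descriptor


# ---------------------------------------------------------------------------
# Pseudo-EMR corpus generator
# ---------------------------------------------------------------------------

#: Token templates per entity category.  Tokens are concatenated without
#: separators; each token is one gold "word".
DEFAULT_TEMPLATES = {
    "CL1": ["patient", "male", "female", "aged62", "aged45"],
    "CL2": ["2021-03-05", "2021-03-12", "2021-04-02", "morning"],
    "CL3": ["diabetes", "hypertension", "gastritis", "anemia"],
    "CL4": ["thirst", "fatigue", "dizziness", "nausea"],
    "CL5": ["bloodtest", "urinalysis", "ctscan", "ecg"],
    "CL6": ["metformin", "insulin", "dietplan", "exercise"],
    "CL7": ["and", "then", "note", "also"],
}


@dataclass(frozen=True)
class CorpusGenSpec:
    """Recipe for a pseudo-EMR corpus with gold labels and simulated
    ensembles of fidelity q (probability mass the simulated classifier puts on
    the label it believes; the believed label is gold with probability q)."""

    n_docs: int = 20
    templates: dict = field(default_factory=lambda: dict(DEFAULT_TEMPLATES))
    classifier_fidelity: float = 0.9
    M: int = 3
    N: int = 3
    words_per_doc: int = 8
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.classifier_fidelity <= 1):
            raise ExtractionError("classifier_fidelity must lie in (0, 1]")
        if self.M < 1 or self.N < 1:
            raise ExtractionError("ensemble sizes M, N must be >= 1")
        missing = [c for c in ("CL1", "CL2", "CL3", "CL4", "CL5", "CL6", "CL7")
                   if not self.templates.get(c)]
        if missing:
            raise ExtractionError(f"templates missing categories: {missing}")


def _noisy_columns(gold_idx: np.ndarray, n_labels: int, q: float,
                   n_members: int, rng) -> np.ndarray:
    """Simulated ensemble stack, shape (units, n_labels, members).

    Per unit and member: the believed label is gold with probability q,
    otherwise uniform over the other labels; the column puts mass q on the
    believed label and (1-q)/(n_labels-1) on each other label.  q = 1
    reproduces gold exactly; q = 1/n_labels is exactly uniform.
    """
    P = len(gold_idx)
    out = np.full((P, n_labels, n_members), (1 - q) / (n_labels - 1))
    for m in range(n_members):
        correct = rng.random(P) < q
        offsets = rng.integers(1, n_labels, size=P)
        believed = np.where(correct, gold_idx, (gold_idx + offsets) % n_labels)
        out[np.arange(P), believed, m] = q
    return out


def simulate_seg_ensemble(gold_bmes: str, q: float, M: int, rng) -> np.ndarray:
    gold_idx = np.array([BMES.index(g) for g in gold_bmes])
    return _noisy_columns(gold_idx, 4, q, M, rng)


def simulate_entity_ensemble(gold_categories, q: float, N: int, rng) -> np.ndarray:
    cats = ("CL1", "CL2", "CL3", "CL4", "CL5", "CL6", "CL7")
    gold_idx = np.array([cats.index(g) for g in gold_categories])
    return _noisy_columns(gold_idx, 7, q, N, rng)


def gen_emr_corpus(spec: CorpusGenSpec):
    """Generate labeled pseudo-EMR documents with simulated ensemble outputs.

    Each document samples ``words_per_doc`` words (every category present at
    least once, CL3 carrying the document's disease), concatenated without
    separators; gold BMES labels mark token boundaries, gold entity spans the
    token categories.  A semi-structured numeric record for the regex
    extractor rides along as ``numeric_text``.
    """
    rng = np.random.default_rng(spec.seed)
    cats = ("CL1", "CL2", "CL3", "CL4", "CL5", "CL6", "CL7")
    docs = []
    for d in range(spec.n_docs):
        picks = [(c, spec.templates[c][rng.integers(len(spec.templates[c]))])
                 for c in cats]
        while len(picks) < spec.words_per_doc:
            c = cats[rng.integers(7)]
            picks.append((c, spec.templates[c][rng.integers(len(spec.templates[c]))]))
        order = rng.permutation(len(picks))
        picks = [picks[i] for i in order]

        text, bmes, entities = "", "", []
        for cat, tok in picks:
            start = len(text)
            text += tok
            bmes += "S" if len(tok) == 1 else "B" + "M" * (len(tok) - 2) + "E"
            entities.append((start, len(text), cat))

        glucose = round(float(rng.uniform(4.0, 12.0)), 1)
        post = round(float(rng.uniform(6.0, 16.0)), 1)
        numeric_text = (
            f"fasting blood glucose {glucose} mmol/L; "
            f"postprandial blood glucose {post} mmol/L"
        )
        sent = LabeledSentence(
            text=text,
            gold_bmes=bmes,
            gold_entities=entities,
            seg_probs=simulate_seg_ensemble(bmes, spec.classifier_fidelity,
                                            spec.M, rng),
            ent_probs=simulate_entity_ensemble(
                [c for _, _, c in entities], spec.classifier_fidelity,
                spec.N, rng),
            patient_id=f"patient_{d:05d}",
        )
        docs.append({"sentence": sent, "numeric_text": numeric_text})
    return docs


def write_corpus(docs, path) -> None:
    """Write a corpus as JSON lines: text, gold_bmes, gold_entities
    (0-based half-open spans), patient_id, numeric_text."""
    with open(path, "w", encoding="utf-8") as fh:
        for d in docs:
            s = d["sentence"]
            fh.write(json.dumps({
                "text": s.text,
                "gold_bmes": s.gold_bmes,
                "gold_entities": [list(e) for e in s.gold_entities],
                "patient_id": s.patient_id,
                "numeric_text": d.get("numeric_text", ""),
            }) + "\n")


def read_corpus(path) -> list:
    """Read a gold-labeled corpus written by :func:`write_corpus`.

    Ensemble probability stacks are not serialized; callers re-simulate them
    (seeded) or plug in real base classifiers.
    """
    docs = []
    with open(path, encoding="utf-8") as fh:
        for ln in fh:
            if not ln.strip():
                continue
            obj = json.loads(ln)
            docs.append({
                "sentence": LabeledSentence(
                    text=obj["text"],
                    gold_bmes=obj["gold_bmes"],
                    gold_entities=[tuple(e) for e in obj["gold_entities"]],
                    seg_probs=None,
                    ent_probs=None,
                    patient_id=obj.get("patient_id", ""),
                ),
                "numeric_text": obj.get("numeric_text", ""),
            })
    return docs


# ---------------------------------------------------------------------------
# Rater score matrices
# ---------------------------------------------------------------------------

def gen_rater_scores(m_raters: int, n_items: int, agreement: float,
                     seed: int = 0) -> np.ndarray:
    """m x n rater score matrix; each row is a rank permutation of 1..n.

    agreement 1 gives identical rankings for all raters; agreement 0 gives
    independent random rankings; intermediate values interpolate by Gaussian
    noise injection before re-ranking.
    """
    if m_raters < 2 or n_items < 2:
        raise CaseBaseError("need at least 2 raters and 2 items")
    if not (0 <= agreement <= 1):
        raise CaseBaseError("agreement must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    consensus = rng.permutation(n_items).astype(float)
    rows = []
    for _ in range(m_raters):
        if agreement == 0:
            latent = rng.standard_normal(n_items)
        else:
            noise_sd = (1 - agreement) / max(agreement, 1e-12) * n_items / 4
            latent = consensus + rng.normal(0.0, noise_sd, size=n_items)
        rows.append(rankdata(latent))
    return np.asarray(rows)
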