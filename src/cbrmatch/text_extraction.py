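"""Key-feature extraction from semi-structured medical text.

The extraction pipeline turns a pseudo-EMR document into a key-feature case
record in four steps:

1. embed each character through a medical word-vector dictionary (Z x d);
2. segment the character stream into words by fusing the BMES probability
   columns of M base classifiers under learned ensemble weights WS;
3. assign each word one of seven clinical entity categories (CL1..CL7:
   patient information, time, disease, symptom, examination test, treatment
   plan, other) by fusing N base taggers under weights WT;
4. pull structured numeric indices (e.g. fasting blood glucose) out of the
   text with named regular expressions and merge everything per patient ID.

The fusion rule for both ensembles is identical: multiply each classifier's
probability column by its weight, sum across classifiers row-wise, renormalize
the resulting label vector to sum 1, and take the argmax row (lowest row index
wins ties: B<M<E<S, CL1<...<CL7).  Because of the renormalization the fused
output is invariant to scaling all weights by a positive constant.

Ensemble weights are fitted by minimizing the total loss
``Loss = Loss1 + Loss2`` where Loss1 is the mean fused probability mass
missing from the gold BMES label over characters, and Loss2 the same over
words and entity categories.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .case_model import ENTITY_CATEGORIES

__all__ = [
    "BMES",
    "WordVectorDictionary",
    "EnsembleWeights",
    "KeyPattern",
    "KeyFeatureRecord",
    "LabeledSentence",
    "ExtractionError",
    "embed_sentence",
    "fuse_segmentation",
    "decode_words",
    "word_feature_vectors",
    "fuse_entity_tags",
    "segmentation_loss",
    "entity_loss",
    "total_loss",
    "fit_ensemble_weights",
    "extract_key_data",
    "assemble_key_features",
    "DictionarySegmenter",
]

logger = logging.getLogger(__name__)

#: Character-level word segmentation labels, in fixed tie-break order:
#: Beginning, Middle, End of a multi-character word, or Single-character word.
BMES = ("B", "M", "E", "S")


class ExtractionError(ValueError):
    """Raised for malformed extraction inputs or configuration."""


# ---------------------------------------------------------------------------
# Word-vector dictionary
# ---------------------------------------------------------------------------

@dataclass
class WordVectorDictionary:
    """Character/word -> vector lookup of dimension ``d`` with an OOV fallback.

    Stands in for a skip-gram-trained medical dictionary of size Z x d; any
    mapping with a fallback vector satisfies the contract, so toy one-hot or
    seeded random dictionaries are fine for pipeline work.
    """

    entries: dict
    dimension: int
    fallback: np.ndarray = None

    def __post_init__(self):
        for k, v in self.entries.items():
            v = np.asarray(v, dtype=float)
            if v.shape != (self.dimension,):
                raise ExtractionError(f"vector for {k!r} has wrong dimension")
            self.entries[k] = v
        if self.fallback is None:
            self.fallback = np.zeros(self.dimension)
        self.fallback = np.asarray(self.fallback, dtype=float)
        if self.fallback.shape != (self.dimension,):
            raise ExtractionError("fallback vector has wrong dimension")

    @property
    def size(self) -> int:
        return len(self.entries)

    @classmethod
    def random(cls, vocabulary, dimension: int = 8, seed: int = 0):
        rng = np.random.default_rng(seed)
        entries = {tok: rng.standard_normal(dimension) for tok in vocabulary}
        return cls(entries=entries, dimension=dimension,
                   fallback=rng.standard_normal(dimension))


def embed_sentence(text: str, dictionary: WordVectorDictionary) -> np.ndarray:
    """Embed a P-character sentence as a P x d matrix of dictionary vectors."""
    if len(text) == 0:
        raise ExtractionError("cannot embed empty text")
    return np.stack(
        [dictionary.entries.get(ch, dictionary.fallback) for ch in text]
    )


# ---------------------------------------------------------------------------
# Ensemble fusion
# ---------------------------------------------------------------------------

@dataclass
class EnsembleWeights:
    """Classifier weights WS (length M) and tagger weights WT (length N).

    Each weight lies in [0, 1]; at least one weight per ensemble must be
    positive (the fusion renormalization is undefined for an all-zero
    ensemble).
    """

    WS: np.ndarray
    WT: np.ndarray

    def __post_init__(self):
        self.WS = np.asarray(self.WS, dtype=float)
        self.WT = np.asarray(self.WT, dtype=float)
        for name, w in (("WS", self.WS), ("WT", self.WT)):
            if w.ndim != 1 or np.any(w < 0) or np.any(w > 1):
                raise ExtractionError(f"{name} must be a vector with entries in [0, 1]")


def _check_prob_stack(probs: np.ndarray, n_labels: int) -> np.ndarray:
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 3 or probs.shape[1] != n_labels:
        raise ExtractionError(
            f"probability stack must have shape (units, {n_labels}, ensemble)"
        )
    if np.any(probs < -1e-12) or np.any(probs > 1 + 1e-12):
        raise ExtractionError("probabilities outside [0, 1]")
    colsums = probs.sum(axis=1)
    if not np.allclose(colsums, 1.0, atol=1e-9):
        raise ExtractionError("each classifier column must sum to 1")
    return probs


def _fuse(probs: np.ndarray, weights: np.ndarray, n_labels: int):
    """Weighted row-sum + column normalization shared by both ensembles."""
    probs = _check_prob_stack(probs, n_labels)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (probs.shape[2],):
        raise ExtractionError("weight vector length does not match ensemble size")
    if np.all(weights == 0):
        raise ExtractionError("all ensemble weights are zero")
    fused = (probs * weights[None, None, :]).sum(axis=2)
    fused /= fused.sum(axis=1, keepdims=True)
    labels = np.argmax(fused, axis=1)  # first max index: B<M<E<S, CL1<...<CL7
    return fused, labels


def fuse_segmentation(probs: np.ndarray, WS: np.ndarray):
    """Fuse per-character 4 x M BMES probability columns into labels.

    Parameters
    ----------
    probs : array, shape (P, 4, M)
        For character p, column i is classifier i's probability distribution
        over {B, M, E, S}.
    WS : array, shape (M,)
        Classifier weights.

    Returns
    -------
    labels : list of str
        One of ``B M E S`` per character.
    fused : array, shape (P, 4)
        The fused, renormalized probability vectors h(c(p)).
    """
    fused, idx = _fuse(probs, WS, 4)
    return [BMES[i] for i in idx], fused


def fuse_entity_tags(probs: np.ndarray, WT: np.ndarray):
    """Fuse per-word 7 x N entity-category columns into CL1..CL7 labels."""
    fused, idx = _fuse(probs, WT, 7)
    return [ENTITY_CATEGORIES[i] for i in idx], fused


def decode_words(labels, text: str):
    """Turn a BMES label sequence into the segmented word list.

    B...E runs and S singletons become words.  Fused argmax sequences are not
    guaranteed well-formed, so malformed runs are repaired: a M or E with no
    open run opens one (its first character is treated as B).  By construction
    the concatenation of the returned words always reproduces ``text``.

    Returns ``(words, spans)`` with 0-based half-open character spans.
    """
    if len(labels) != len(text):
        raise ExtractionError("labels and text differ in length")
    words, spans = [], []
    start = None
    for p, lab in enumerate(labels):
        if lab == "S":
            if start is not None:
                words.append(text[start:p]); spans.append((start, p))
                start = None
            words.append(text[p]); spans.append((p, p + 1))
        elif lab == "B":
            if start is not None:
                words.append(text[start:p]); spans.append((start, p))
            start = p
        elif lab == "M":
            if start is None:
                start = p  # repair: unopened run starts here
        elif lab == "E":
            if start is None:
                start = p
            words.append(text[start:p + 1]); spans.append((start, p + 1))
            start = None
        else:
            raise ExtractionError(f"unknown BMES label {lab!r}")
    if start is not None:
        words.append(text[start:]); spans.append((start, len(text)))
    return words, spans


def word_feature_vectors(char_vectors_per_word) -> np.ndarray:
    """Per-word 4-vectors wq: row-sum of the word's fused character vectors,
    renormalized to sum 1."""
    out = []
    for vecs in char_vectors_per_word:
        vecs = np.asarray(vecs, dtype=float)
        if vecs.size == 0:
            raise ExtractionError("empty word has no character vectors")
        w = vecs.reshape(-1, 4).sum(axis=0)
        out.append(w / w.sum())
    return np.stack(out)


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def segmentation_loss(fused: np.ndarray, gold) -> float:
    """Loss1 = (1/P) * sum_p (1 - h_true(c(p))).

    ``fused`` holds the fused BMES probability vectors; ``gold`` the correct
    label per character.  Zero iff the fused mass on every gold label is 1.
    """
    fused = np.asarray(fused, dtype=float)
    if fused.shape[0] != len(gold):
        raise ExtractionError("fused vectors and gold labels differ in length")
    if len(gold) == 0:
        raise ExtractionError("empty sequence")
    idx = [BMES.index(g) for g in gold]
    return float(np.mean(1.0 - fused[np.arange(len(gold)), idx]))


def entity_loss(fused: np.ndarray, gold) -> float:
    """Loss2 = (1/Q) * sum_q (1 - e_true(w(q))) over words and CL categories."""
    fused = np.asarray(fused, dtype=float)
    if fused.shape[0] != len(gold):
        raise ExtractionError("fused vectors and gold labels differ in length")
    if len(gold) == 0:
        raise ExtractionError("empty sequence")
    idx = [ENTITY_CATEGORIES.index(g) for g in gold]
    return float(np.mean(1.0 - fused[np.arange(len(gold)), idx]))


def total_loss(corpus, weights: EnsembleWeights) -> float:
    """Loss = Loss1 + Loss2, pooled over all characters and words of a corpus."""
    seg_fused, seg_gold, ent_fused, ent_gold = [], [], [], []
    for s in corpus:
        _, f = fuse_segmentation(s.seg_probs, weights.WS)
        seg_fused.append(f); seg_gold.extend(s.gold_bmes)
        _, g = fuse_entity_tags(s.ent_probs, weights.WT)
        ent_fused.append(g); ent_gold.extend(s.gold_categories)
    loss1 = segmentation_loss(np.concatenate(seg_fused), seg_gold)
    loss2 = entity_loss(np.concatenate(ent_fused), ent_gold)
    return loss1 + loss2


# ---------------------------------------------------------------------------
# Weight fitting
# ---------------------------------------------------------------------------

@dataclass
class LabeledSentence:
    """One gold-labeled corpus sentence with base classifier/tagger outputs.

    ``gold_bmes`` is a string over BMES aligned to ``text``; ``gold_entities``
    a list of ``(start, end, category)`` half-open character spans whose
    categories, in order, are the per-word gold labels ``gold_categories``.
    ``seg_probs`` has shape (P, 4, M), ``ent_probs`` shape (Q, 7, N) aligned to
    the gold words.
    """

    text: str
    gold_bmes: str
    gold_entities: list
    seg_probs: np.ndarray
    ent_probs: np.ndarray
    patient_id: str = ""

    @property
    def gold_categories(self):
        return [cat for _, _, cat in self.gold_entities]


@dataclass
class FitConfig:
    """Coordinate-descent settings for ensemble-weight fitting."""

    tol: float = 1e-6
    max_passes: int = 50
    xatol: float = 1e-4


def fit_ensemble_weights(corpus, initial: EnsembleWeights,
                         config: FitConfig = None):
    """Fit WS and WT by round-robin bounded scalar minimization of the total
    loss.

    Each weight in turn is optimized on [0, 1] with the others held fixed;
    passes repeat until the loss improves by less than ``tol`` or
    ``max_passes`` is reached.  A candidate that would zero out an entire
    ensemble is rejected.  Deterministic: no randomness is involved.

    Returns ``(weights, loss_trace)`` with one total-loss entry per accepted
    state (non-increasing).
    """
    if not corpus:
        raise ExtractionError("empty corpus")
    config = config or FitConfig()
    WS = np.asarray(initial.WS, dtype=float).copy()
    WT = np.asarray(initial.WT, dtype=float).copy()

    def loss_at(ws, wt):
        if np.all(ws == 0) or np.all(wt == 0):
            return np.inf
        return total_loss(corpus, EnsembleWeights(WS=ws, WT=wt))

    current = loss_at(WS, WT)
    trace = [current]
    for _ in range(config.max_passes):
        before = current
        for vec, other, is_ws in ((WS, WT, True), (WT, WS, False)):
            for i in range(len(vec)):
                def objective(v, i=i, vec=vec, is_ws=is_ws):
                    trial = vec.copy(); trial[i] = v
                    return loss_at(trial, WT) if is_ws else loss_at(WS, trial)
                res = minimize_scalar(objective, bounds=(0.0, 1.0),
                                      method="bounded",
                                      options={"xatol": config.xatol})
                if res.fun < current - 1e-15:
                    vec[i] = float(res.x)
                    current = float(res.fun)
        trace.append(current)
        if before - current < config.tol:
            break
    return EnsembleWeights(WS=WS, WT=WT), trace


# ---------------------------------------------------------------------------
# Regex key-data extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KeyPattern:
    """A named index pattern, e.g. fasting blood glucose.

    ``regex`` must contain at least one capturing group; group 1 is parsed as
    the numeric value.  ``unit`` is informational.
    """

    name: str
    regex: str
    unit: str = ""


def extract_key_data(text: str, patterns) -> list:
    """Extract ``(index name, value)`` pairs from semi-structured text.

    All non-overlapping matches over all patterns are returned in text order;
    when spans from different patterns overlap, the earlier-starting match
    wins.
    """
    hits = []
    for pat in patterns:
        compiled = re.compile(pat.regex)
        if compiled.groups < 1:
            raise ExtractionError(
                f"pattern {pat.name!r} has no numeric capture group"
            )
        for m in compiled.finditer(text):
            try:
                value = float(m.group(1))
            except (TypeError, ValueError):
                continue
            hits.append((m.start(), m.end(), pat.name, value))
    hits.sort(key=lambda h: (h[0], h[1]))
    out, last_end = [], -1
    for start, end, name, value in hits:
        if start < last_end:
            continue
        out.append((name, value))
        last_end = end
    return out


@dataclass
class KeyFeatureRecord:
    """Per-patient merged record: numeric key data + categorized text spans."""

    patient_id: str
    key_data: list = field(default_factory=list)   # (index name, value)
    key_text: list = field(default_factory=list)   # (text span, CL category)


def assemble_key_features(key_data, key_text, patient_id: str) -> KeyFeatureRecord:
    """Merge key data and key text for one patient ID.

    Duplicate index names keep the last occurrence (a later measurement
    supersedes an earlier one in the same record) and log a warning.
    """
    for span, cat in key_text:
        if cat not in ENTITY_CATEGORIES:
            raise ExtractionError(f"unknown entity category {cat!r}")
    for _, v in key_data:
        if not np.isfinite(v):
            raise ExtractionError("non-finite key-data value")
    merged = {}
    for name, value in key_data:
        if name in merged:
            logger.warning(
                "patient %s: duplicate index %r, keeping last value %r",
                patient_id, name, value,
            )
        merged[name] = value
    return KeyFeatureRecord(
        patient_id=patient_id,
        key_data=list(merged.items()),
        key_text=list(key_text),
    )


# ---------------------------------------------------------------------------
# A simple pluggable base classifier
# ---------------------------------------------------------------------------

class DictionarySegmenter:
    """Forward maximum-match segmenter emitting near-one-hot BMES columns.

    One concrete base classifier for the segmentation ensemble; any callable
    mapping text to a (P, 4) column of probabilities can stand beside it.
    """

    def __init__(self, vocabulary, confidence: float = 0.97):
        self.vocabulary = set(vocabulary)
        self.max_len = max((len(w) for w in vocabulary), default=1)
        self.confidence = confidence

    def __call__(self, text: str) -> np.ndarray:
        labels = []
        i = 0
        while i < len(text):
            match_len = 1
            for L in range(min(self.max_len, len(text) - i), 1, -1):
                if text[i:i + L] in self.vocabulary:
                    match_len = L
                    break
            if match_len == 1:
                labels.append("S")
            else:
                labels.extend(["B"] + ["M"] * (match_len - 2) + ["E"])
            i += match_len
        out = np.full((len(text), 4), (1 - self.confidence) / 3)
        for p, lab in enumerate(labels):
            out[p, BMES.index(lab)] = self.confidence
        return out
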