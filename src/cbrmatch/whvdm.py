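"""The weighted heterogeneous value distance measure (WHVDM) and retrieval.

Between a target case t and a stored case r over n attributes,

    WHVDM(t, r) = sum_i w_i * d_i^2(t, r)

where d_i^2 is a value-difference term for discrete attributes and a squared
difference for continuous ones, and w is an attribute weight vector with
0 <= w_i <= 1 and sum w_i = 1.

For a discrete attribute the value difference metric (VDM) compares how the
two values distribute over the class set Y:

    classic:     sum_a (Pr(y=a | x_i = x_t,i) - Pr(y=a | x_i = x_r,i))^2
    as_printed:  classic * sum_a Pr(y=a | x_i = x_t,i)^2

The ``as_printed`` variant carries a trailing target-side factor that breaks
the symmetry of the classic Stanfill-Waltz form; both are available because
sources disagree, with ``as_printed`` the default.  Conditional class
probabilities are add-alpha estimates from the stored case base; an unseen
value yields the pure-alpha (uniform) distribution.

Continuous attributes are assumed min-max normalized to [0, 1]
(:func:`cbrmatch.case_model.normalize_continuous`), so the squared difference
is scale-comparable with the bounded VDM terms.  A missing value on either
side of any attribute contributes ``missing_penalty`` (default 1.0, the
maximum normalized continuous contribution).

Prediction is 1-NN: the class of the stored case at minimum WHVDM, with ties
broken by case order in the base.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .case_model import Case, CaseBase, CaseBaseError

__all__ = [
    "DistanceConfig",
    "ConditionalProbTable",
    "check_weight_vector",
    "uniform_weights",
    "estimate_cond_probs",
    "vdm_component",
    "diff2_component",
    "whvdm_distance",
    "component_tensor",
    "retrieve_top_k",
    "predict_class",
    "evaluate",
]


@dataclass(frozen=True)
class DistanceConfig:
    """Distance settings.

    vdm_variant : {"as_printed", "classic"}
        Whether the discrete term carries the trailing target-side factor.
    missing_penalty : float
        d_i^2 contribution when either value is missing.
    alpha : float
        Add-alpha smoothing for the conditional class probabilities.
    """

    vdm_variant: str = "as_printed"
    missing_penalty: float = 1.0
    alpha: float = 1.0

    def __post_init__(self):
        if self.vdm_variant not in ("as_printed", "classic"):
            raise CaseBaseError(f"unknown vdm_variant {self.vdm_variant!r}")
        if self.missing_penalty < 0 or self.alpha < 0:
            raise CaseBaseError("missing_penalty and alpha must be >= 0")


def check_weight_vector(w, n: int) -> np.ndarray:
    """Validate 0 <= w_i <= 1 and sum w_i = 1 (within 1e-9); returns an array."""
    w = np.asarray(w, dtype=float)
    if w.shape != (n,):
        raise CaseBaseError(f"weight vector has length {w.size}, expected {n}")
    if np.any(w < -1e-12) or np.any(w > 1 + 1e-12):
        raise CaseBaseError("weights must lie in [0, 1]")
    if abs(w.sum() - 1.0) > 1e-9:
        raise CaseBaseError("weights must sum to 1")
    return w


def uniform_weights(n: int) -> np.ndarray:
    return np.full(n, 1.0 / n)


@dataclass
class ConditionalProbTable:
    """Pr(y = a | x_i = v) for every discrete attribute i and seen value v.

    Estimated with add-alpha smoothing:

        Pr(y=a | x_i=v) = (count(x_i=v, y=a) + alpha) / (count(x_i=v) + alpha*|Y|)

    ``prob(name, v)`` returns the distribution as a vector over
    ``class_order``; an unseen value gives the pure-alpha (uniform)
    distribution, which is also the alpha=0 fallback.
    """

    class_order: tuple
    alpha: float
    tables: dict = field(default_factory=dict)  # attr name -> {value: np.ndarray}

    def prob(self, name: str, value) -> np.ndarray:
        table = self.tables.get(name, {})
        dist = table.get(value)
        if dist is None:
            return np.full(len(self.class_order), 1.0 / len(self.class_order))
        return dist


def estimate_cond_probs(base: CaseBase, alpha: float = 1.0) -> ConditionalProbTable:
    """Estimate the conditional class probability table from a stored base.

    Cases with a missing value for an attribute or a missing label do not
    contribute to that attribute's counts.
    """
    if len(base.cases) == 0:
        raise CaseBaseError("cannot estimate probabilities from an empty base")
    Y = tuple(base.class_values)
    if not Y:
        raise CaseBaseError("case base has no class labels")
    y_index = {a: k for k, a in enumerate(Y)}
    tables = {}
    for i, attr in enumerate(base.schema):
        if attr.kind != "discrete":
            continue
        counts = {}
        for c in base.cases:
            v = c.x[i]
            if v is None or c.y is None:
                continue
            counts.setdefault(v, np.zeros(len(Y)))[y_index[c.y]] += 1
        table = {}
        for v, cnt in counts.items():
            denom = cnt.sum() + alpha * len(Y)
            if denom == 0:
                table[v] = np.full(len(Y), 1.0 / len(Y))
            else:
                table[v] = (cnt + alpha) / denom
        tables[attr.name] = table
    return ConditionalProbTable(class_order=Y, alpha=alpha, tables=tables)


# ---------------------------------------------------------------------------
# Per-attribute distance components
# ---------------------------------------------------------------------------

def vdm_component(i: int, t: Case, r: Case, base: CaseBase,
                  table: ConditionalProbTable,
                  config: DistanceConfig = DistanceConfig()) -> float:
    """VDM term for discrete attribute ``i`` between target t and stored r."""
    attr = base.schema[i]
    if attr.kind != "discrete":
        raise CaseBaseError(f"attribute {attr.name!r} is not discrete")
    vt, vr = t.x[i], r.x[i]
    if vt is None or vr is None:
        return config.missing_penalty
    if vt == vr:
        return 0.0
    pt = table.prob(attr.name, vt)
    pr = table.prob(attr.name, vr)
    d = float(np.sum((pt - pr) ** 2))
    if config.vdm_variant == "as_printed":
        d *= float(np.sum(pt ** 2))
    return d


def diff2_component(i: int, t: Case, r: Case, base: CaseBase,
                    config: DistanceConfig = DistanceConfig()) -> float:
    """Squared-difference term for continuous attribute ``i``."""
    attr = base.schema[i]
    if attr.kind != "continuous":
        raise CaseBaseError(f"attribute {attr.name!r} is not continuous")
    vt, vr = t.x[i], r.x[i]
    if vt is None or vr is None:
        return config.missing_penalty
    return float((vt - vr) ** 2)


def whvdm_distance(t: Case, r: Case, w, base: CaseBase,
                   table: ConditionalProbTable,
                   config: DistanceConfig = DistanceConfig()) -> float:
    """WHVDM(t, r) = sum_i w_i * d_i^2(t, r); zero when t and r coincide."""
    w = check_weight_vector(w, len(base.schema))
    total = 0.0
    for i, attr in enumerate(base.schema):
        if attr.kind == "discrete":
            total += w[i] * vdm_component(i, t, r, base, table, config)
        else:
            total += w[i] * diff2_component(i, t, r, base, config)
    return total


# ---------------------------------------------------------------------------
# Vectorized bulk path
# ---------------------------------------------------------------------------

def component_tensor(targets, reference: CaseBase, table: ConditionalProbTable,
                     config: DistanceConfig = DistanceConfig(),
                     discrete_as_overlap: bool = False) -> np.ndarray:
    """All per-attribute components d_i^2(t, r) as an (n, |T|, |R|) tensor.

    Computing the tensor once makes weight search cheap: the full distance
    matrix for any weight vector w is ``np.tensordot(w, D, axes=1)``.  With
    ``discrete_as_overlap`` the discrete term is the 0/1 value mismatch
    instead of VDM (the plain heterogeneous-Euclidean baseline).
    """
    refs = reference.cases
    n = len(reference.schema)
    D = np.empty((n, len(targets), len(refs)))
    for i, attr in enumerate(reference.schema):
        tv = [t.x[i] for t in targets]
        rv = [r.x[i] for r in refs]
        if attr.kind == "continuous":
            ta = np.array([np.nan if v is None else v for v in tv], dtype=float)
            ra = np.array([np.nan if v is None else v for v in rv], dtype=float)
            comp = (ta[:, None] - ra[None, :]) ** 2
            comp[np.isnan(comp)] = config.missing_penalty
            D[i] = comp
        elif discrete_as_overlap:
            comp = np.array(
                [[1.0 if (a is None or b is None or a != b) else 0.0 for b in rv]
                 for a in tv]
            )
            D[i] = comp
        else:
            values = sorted({v for v in tv + rv if v is not None}, key=str)
            vidx = {v: k for k, v in enumerate(values)}
            P = np.stack([table.prob(attr.name, v) for v in values]) if values \
                else np.zeros((0, len(table.class_order)))
            # pairwise squared distances between value distributions
            sq = np.sum((P[:, None, :] - P[None, :, :]) ** 2, axis=2)
            if config.vdm_variant == "as_printed":
                sq = sq * np.sum(P ** 2, axis=1)[:, None]
            ti = np.array([-1 if v is None else vidx[v] for v in tv])
            ri = np.array([-1 if v is None else vidx[v] for v in rv])
            comp = np.where(
                (ti[:, None] < 0) | (ri[None, :] < 0),
                config.missing_penalty,
                sq[ti[:, None], ri[None, :]],
            )
            # identical values are at distance 0 by construction (sq diagonal)
            D[i] = comp
    return D


# ---------------------------------------------------------------------------
# Retrieval, prediction, evaluation
# ---------------------------------------------------------------------------

def retrieve_top_k(t: Case, base: CaseBase, w, table: ConditionalProbTable,
                   config: DistanceConfig = DistanceConfig(), k: int = 5):
    """The k stored cases nearest to ``t`` in non-decreasing WHVDM order.

    Ties are broken by case order in the base (stable sort).  Asking for more
    cases than stored returns everything.

    Returns a list of ``(case, distance)`` pairs.
    """
    if k < 1:
        raise CaseBaseError("k must be >= 1")
    if len(base.cases) == 0:
        raise CaseBaseError("cannot retrieve from an empty base")
    if k > len(base.cases):
        import warnings

        warnings.warn("k exceeds case-base size; returning all cases")
        k = len(base.cases)
    w = check_weight_vector(w, len(base.schema))
    D = component_tensor([t], base, table, config)
    dist = np.tensordot(w, D, axes=1)[0]
    order = np.argsort(dist, kind="stable")[:k]
    return [(base.cases[j], float(dist[j])) for j in order]


def predict_class(t: Case, base: CaseBase, w, table: ConditionalProbTable,
                  config: DistanceConfig = DistanceConfig()):
    """1-NN prediction: the label of s(t) = argmin_r WHVDM(t, r)."""
    [(nearest, _)] = retrieve_top_k(t, base, w, table, config, k=1)
    return nearest.y


def _predict_bulk(targets, reference: CaseBase, w,
                  table: ConditionalProbTable, config: DistanceConfig,
                  discrete_as_overlap: bool = False):
    w = check_weight_vector(w, len(reference.schema))
    D = component_tensor(targets, reference, table, config,
                         discrete_as_overlap=discrete_as_overlap)
    dist = np.tensordot(w, D, axes=1)
    nearest = np.argmin(dist, axis=1)  # first min = earliest stored case
    return [reference.cases[j].y for j in nearest]


def macro_f_value(y_true, y_pred):
    """Macro-averaged F-value: unweighted mean over labels of the harmonic
    mean of precision and recall.  Labels with no predicted and no true
    instances are excluded; a label with zero precision+recall scores 0."""
    labels = sorted(set(y_true) | set(y_pred), key=str)
    per_class = {}
    for lab in labels:
        tp = sum(1 for yt, yp in zip(y_true, y_pred) if yt == lab and yp == lab)
        fp = sum(1 for yt, yp in zip(y_true, y_pred) if yt != lab and yp == lab)
        fn = sum(1 for yt, yp in zip(y_true, y_pred) if yt == lab and yp != lab)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        per_class[lab] = {"precision": prec, "recall": rec, "f1": f1}
    f = float(np.mean([v["f1"] for v in per_class.values()])) if per_class else 0.0
    return f, per_class


def evaluate(reference: CaseBase, test: CaseBase, w,
             config: DistanceConfig = DistanceConfig(),
             table: ConditionalProbTable = None,
             discrete_as_overlap: bool = False) -> dict:
    """Holdout evaluation: accuracy = (1/|T|) sum_t I(y_t = y_s(t)) and the
    macro F-value of 1-NN predictions of the test labels.

    The conditional probability table is estimated from the reference set
    only (no test leakage) unless one is passed in.  ``discrete_as_overlap``
    swaps the VDM term for a 0/1 mismatch (the plain Euclidean baseline).
    """
    if len(test.cases) == 0:
        raise CaseBaseError("empty test set")
    if table is None:
        table = estimate_cond_probs(reference, alpha=config.alpha)
    preds = _predict_bulk(test.cases, reference, w, table, config,
                          discrete_as_overlap=discrete_as_overlap)
    truths = [c.y for c in test.cases]
    accuracy = sum(1 for yt, yp in zip(truths, preds) if yt == yp) / len(truths)
    f, per_class = macro_f_value(truths, preds)
    return {
        "accuracy": accuracy,
        "f_value": f,
        "per_class": per_class,
        "predictions": preds,
    }
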