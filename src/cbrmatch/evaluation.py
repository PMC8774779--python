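"""Evaluation harness: Kendall's W, method comparison, end-to-end pipeline.

:func:`kendalls_w` is the coefficient of concordance used to check whether
multiple raters rank the same items consistently (1 = identical rankings,
0 = no agreement).  :func:`compare_methods` mirrors the case-matching study
design at synthetic scale: it benchmarks GA-weighted WHVDM retrieval against
uniform-weight WHVDM, an unweighted Euclidean/overlap baseline, and
expert-supplied weights over seeded replicates.  :func:`run_pipeline` drives
the full case-base construction flow from a gold-labeled pseudo-EMR corpus to
the triaged high-quality / well-known / rare case bases on disk.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import rankdata

from .case_model import (
    AttributeSchema,
    Case,
    CaseBase,
    CaseBaseError,
    write_case_base,
)
from .case_scoring import (
    AuditConfig,
    ReadabilityConfig,
    audit_knowledge_richness,
    audit_treatment_time,
    classify_rare,
    score_case_base,
    select_cases,
)
from .ga_weights import GAConfig, learn_weights
from .synthetic_data import (
    CaseGenSpec,
    gen_case_base,
    read_corpus,
    simulate_entity_ensemble,
    simulate_seg_ensemble,
)
from .text_extraction import (
    EnsembleWeights,
    KeyPattern,
    assemble_key_features,
    decode_words,
    extract_key_data,
    fuse_entity_tags,
    fuse_segmentation,
)
from .whvdm import DistanceConfig, evaluate, uniform_weights

__all__ = [
    "kendalls_w",
    "stratified_split",
    "compare_methods",
    "PipelineConfig",
    "run_pipeline",
    "DEFAULT_PATTERNS",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Kendall's coefficient of concordance
# ---------------------------------------------------------------------------

def kendalls_w(scores, tie_correction: bool = True) -> float:
    """Kendall's W over an m x n rater score matrix.

    Scores are converted to within-rater ranks (mean ranks for ties).  With
    rank-column sums R_j and S = sum_j (R_j - mean R)^2,

        W = 12 S / (m^2 (n^3 - n))                     (no ties)
        W = 12 S / (m^2 (n^3 - n) - m sum_k T_k)       (tie-corrected)

    where T_k = sum over tie groups of rater k of (t^3 - t).  W lies in
    [0, 1]; 1 means identical rankings.  A rater with constant scores is
    undefined without the tie correction and raises.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2:
        raise CaseBaseError("scores must be an m x n matrix")
    m, n = scores.shape
    if m < 2 or n < 2:
        raise CaseBaseError("need at least 2 raters and 2 items")
    ranks = np.apply_along_axis(rankdata, 1, scores)
    if not tie_correction:
        for k in range(m):
            if np.unique(scores[k]).size == 1:
                raise CaseBaseError(
                    f"rater {k} has constant scores; W undefined without "
                    "tie correction"
                )
    col_sums = ranks.sum(axis=0)
    S = float(np.sum((col_sums - col_sums.mean()) ** 2))
    denom = m * m * (n ** 3 - n)
    if tie_correction:
        T = 0.0
        for k in range(m):
            _, counts = np.unique(ranks[k], return_counts=True)
            T += float(np.sum(counts ** 3 - counts))
        denom -= m * T
    if denom <= 0:
        raise CaseBaseError("degenerate rank matrix: W undefined (all ties)")
    return 12.0 * S / denom


# ---------------------------------------------------------------------------
# Method comparison harness
# ---------------------------------------------------------------------------

def stratified_split(base: CaseBase, test_frac: float, seed: int):
    """Class-stratified reference/test split preserving case order within
    each side.  Returns ``(reference, test)`` as new CaseBase objects."""
    rng = np.random.default_rng(seed)
    test_idx = set()
    by_class = {}
    for j, c in enumerate(base.cases):
        by_class.setdefault(c.y, []).append(j)
    for lab, idxs in sorted(by_class.items(), key=lambda kv: str(kv[0])):
        n_test = int(round(len(idxs) * test_frac))
        chosen = rng.choice(len(idxs), size=n_test, replace=False)
        test_idx.update(idxs[i] for i in chosen)
    ref_cases = [c.copy() for j, c in enumerate(base.cases) if j not in test_idx]
    test_cases = [c.copy() for j, c in enumerate(base.cases) if j in test_idx]
    mk = lambda cs: CaseBase(schema=list(base.schema),
                             class_values=tuple(base.class_values), cases=cs)
    return mk(ref_cases), mk(test_cases)


def compare_methods(spec: CaseGenSpec, ga: GAConfig = GAConfig(),
                    dist: DistanceConfig = DistanceConfig(),
                    n_seeds: int = 5) -> dict:
    """Benchmark retrieval methods over seeded synthetic replicates.

    Per seed: generate a case base, min-max normalize, split 70/30 stratified
    by class, then evaluate

    * ``whvdm_ga`` — WHVDM with GA-learned weights (learned on an inner
      70/30 split of the reference set; the outer test set is untouched),
    * ``whvdm_uniform`` — WHVDM with uniform weights,
    * ``euclidean_uniform`` — unweighted baseline: squared differences for
      continuous attributes, 0/1 mismatch for discrete ones,
    * ``expert_weights`` — mass spread uniformly over the generator's
      informative attributes (a stand-in for physician-supplied weights).

    Returns a report with per-seed metrics, means, and deltas of each method
    against the ``euclidean_uniform`` baseline.
    """
    if n_seeds < 1:
        raise CaseBaseError("n_seeds must be >= 1")
    from .case_model import normalize_continuous

    methods = ["whvdm_ga", "whvdm_uniform", "euclidean_uniform", "expert_weights"]
    per_seed = {meth: [] for meth in methods}
    for s in range(n_seeds):
        sp = replace(spec, seed=spec.seed + s)
        base, desc = gen_case_base(sp)
        base, _ = normalize_continuous(base)
        reference, test = stratified_split(base, 0.3, seed=sp.seed)
        n = len(base.schema)

        inner_ref, inner_val = stratified_split(reference, 0.3, seed=sp.seed + 10_000)
        ga_seeded = replace(ga, seed=ga.seed + sp.seed)
        w_ga, _ = learn_weights(inner_ref, inner_val, ga_seeded, dist)

        w_uni = uniform_weights(n)
        informative = set(desc["informative"])
        w_exp = np.array([1.0 if a.name in informative else 0.0
                          for a in base.schema])
        w_exp = w_exp / w_exp.sum()

        for meth, w, overlap in (
            ("whvdm_ga", w_ga, False),
            ("whvdm_uniform", w_uni, False),
            ("euclidean_uniform", w_uni, True),
            ("expert_weights", w_exp, False),
        ):
            res = evaluate(reference, test, w, dist, discrete_as_overlap=overlap)
            per_seed[meth].append(
                {"seed": sp.seed, "accuracy": res["accuracy"],
                 "f_value": res["f_value"]}
            )

    report = {"methods": {}, "deltas": {}, "n_seeds": n_seeds}
    for meth in methods:
        accs = [r["accuracy"] for r in per_seed[meth]]
        fs = [r["f_value"] for r in per_seed[meth]]
        report["methods"][meth] = {
            "accuracy_mean": float(np.mean(accs)),
            "f_value_mean": float(np.mean(fs)),
            "per_seed": per_seed[meth],
        }
    base_acc = report["methods"]["euclidean_uniform"]["accuracy_mean"]
    base_f = report["methods"]["euclidean_uniform"]["f_value_mean"]
    for meth in methods:
        report["deltas"][meth] = {
            "accuracy": report["methods"][meth]["accuracy_mean"] - base_acc,
            "f_value": report["methods"][meth]["f_value_mean"] - base_f,
        }
    return report


# ---------------------------------------------------------------------------
# End-to-end case-base construction pipeline
# ---------------------------------------------------------------------------

#: Reference key-data patterns for the glucose indices clinicians name for
#: diabetes records.  Group 1 is always the numeric value.
DEFAULT_PATTERNS = (
    KeyPattern(name="fasting blood glucose",
               regex=r"fasting blood glucose\s*([0-9]+(?:\.[0-9]+)?)",
               unit="mmol/L"),
    KeyPattern(name="postprandial blood glucose",
               regex=r"postprandial blood glucose\s*([0-9]+(?:\.[0-9]+)?)",
               unit="mmol/L"),
)


@dataclass(frozen=True)
class PipelineConfig:
    """Settings for :func:`run_pipeline`."""

    patterns: tuple = DEFAULT_PATTERNS
    sigma: float = 50.0
    gamma: float = 50.0
    omega: float = 0.1
    ensemble_q: float = 0.9
    M: int = 3
    N: int = 3
    seed: int = 0
    audit: AuditConfig = AuditConfig()
    readability: ReadabilityConfig = ReadabilityConfig()
    weights: EnsembleWeights = None  # None -> uniform ensembles


def _readability_features(text: str, categories) -> list:
    """Default readability proxies: share of words with a substantive (non
    CL7) category, and a brevity score decaying with text length."""
    if categories:
        substantive = sum(1 for c in categories if c != "CL7") / len(categories)
    else:
        substantive = 0.0
    return [substantive, 100.0 / (100.0 + len(text))]


def run_pipeline(corpus_path, config: PipelineConfig = PipelineConfig(),
                 out_dir: str = ".") -> dict:
    """Construct triaged case bases from a gold-labeled pseudo-EMR corpus.

    Stages: simulate/fuse ensemble labels -> decode words -> regex key-data
    extraction -> per-patient assembly -> initial case base (key-data indices
    as continuous attributes, first CL3 word as the disease label) -> Score1
    selection at sigma -> Score2 selection at gamma within the high-quality
    base -> rare triage at omega.  Writes ``initial/high_quality/well_known/
    rare`` JSONL bases plus a JSON report of stage counts into ``out_dir``.
    """
    docs = read_corpus(corpus_path)
    rng = np.random.default_rng(config.seed)
    counts = {"documents": len(docs)}
    records = []
    for d in docs:
        s = d["sentence"]
        if s.seg_probs is None:
            s.seg_probs = simulate_seg_ensemble(s.gold_bmes, config.ensemble_q,
                                                config.M, rng)
        if s.ent_probs is None:
            s.ent_probs = simulate_entity_ensemble(
                s.gold_categories, config.ensemble_q, config.N, rng)
        WS = (config.weights.WS if config.weights is not None
              else np.ones(config.M))
        WT = (config.weights.WT if config.weights is not None
              else np.ones(config.N))
        labels, _ = fuse_segmentation(s.seg_probs, WS)
        words, _ = decode_words(labels, s.text)
        cat_labels, _ = fuse_entity_tags(s.ent_probs, WT)
        key_text = [(s.text[a:b], cat)
                    for (a, b, _), cat in zip(s.gold_entities, cat_labels)]
        key_data = extract_key_data(d["numeric_text"], config.patterns)
        rec = assemble_key_features(key_data, key_text, s.patient_id)
        records.append((rec, s, words))

    index_names = sorted({name for rec, _, _ in records
                          for name, _ in rec.key_data})
    schema = [AttributeSchema(name=nm, kind="continuous") for nm in index_names]
    cases = []
    for j, (rec, s, words) in enumerate(records):
        data = dict(rec.key_data)
        sections = {}
        categories = []
        for span, cat in rec.key_text:
            sections[cat] = (sections.get(cat, "") + " " + span).strip()
            categories.append(cat)
        disease = next((span for span, cat in rec.key_text if cat == "CL3"), None)
        case = Case(
            case_id=f"case_{j:05d}",
            patient_id=rec.patient_id,
            x=[data.get(nm) for nm in index_names],
            y=disease,
            sections=sections,
        )
        case.audit_features = [audit_knowledge_richness(case),
                               audit_treatment_time(case)]
        case.class_features = _readability_features(s.text, categories)
        cases.append(case)
    labels = tuple(sorted({c.y for c in cases if c.y is not None}, key=str))
    initial = CaseBase(schema=schema, class_values=labels, cases=cases)
    counts["initial"] = len(initial)

    os.makedirs(out_dir, exist_ok=True)
    paths = {"initial": os.path.join(out_dir, "initial.jsonl")}
    write_case_base(initial, paths["initial"], format="jsonl")

    if len(initial) == 0:
        counts.update({"high_quality": 0, "well_known": 0, "rare": 0})
        for name in ("high_quality", "well_known", "rare"):
            paths[name] = os.path.join(out_dir, f"{name}.jsonl")
            write_case_base(CaseBase(schema=schema, class_values=(), cases=[]),
                            paths[name], format="jsonl")
    else:
        scored = score_case_base(initial, config.audit, config.readability)
        scored, n_hq = select_cases(scored, "score1", config.sigma)
        logger.info("Score1 >= %.1f selected %d/%d cases",
                    config.sigma, n_hq, len(scored))
        hq = CaseBase(schema=schema, class_values=labels,
                      cases=[c for c in scored.cases if "high_quality" in c.flags])
        counts["high_quality"] = len(hq)
        paths["high_quality"] = os.path.join(out_dir, "high_quality.jsonl")
        write_case_base(hq, paths["high_quality"], format="jsonl")

        if len(hq):
            hq_scored, n_wk = select_cases(hq, "score2", config.gamma)
            wk = CaseBase(schema=schema, class_values=labels,
                          cases=[c for c in hq_scored.cases
                                 if "well_known" in c.flags])
            rare_base, rare_labels = classify_rare(hq_scored, config.omega)
            rare = CaseBase(schema=schema, class_values=labels,
                            cases=[c for c in rare_base.cases
                                   if "rare" in c.flags])
        else:
            wk = CaseBase(schema=schema, class_values=(), cases=[])
            rare = CaseBase(schema=schema, class_values=(), cases=[])
            rare_labels = []
        counts["well_known"] = len(wk)
        counts["rare"] = len(rare)
        paths["well_known"] = os.path.join(out_dir, "well_known.jsonl")
        paths["rare"] = os.path.join(out_dir, "rare.jsonl")
        write_case_base(wk, paths["well_known"], format="jsonl")
        write_case_base(rare, paths["rare"], format="jsonl")
        counts["rare_labels"] = list(rare_labels)

    report = {"counts": counts, "paths": paths,
              "thresholds": {"sigma": config.sigma, "gamma": config.gamma,
                             "omega": config.omega}}
    with open(os.path.join(out_dir, "pipeline_report.json"), "w",
              encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)
    return report
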