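# Methods

## Scope and data model

A *case* is a solved clinical episode: a mixed discrete/continuous attribute
vector `x` aligned to a schema, a class label `y` from a finite set `Y`
(typically the diagnosed disease or outcome), optional free-text sections
keyed by the seven clinical entity categories CL1–CL7, and quality metadata.
A *case base* is an ordered collection of such cases plus the schema and `Y`.
Case order is the stable tie-break ordering everywhere: retrieval, 1-NN
prediction, and GA fitness all resolve distance ties in favour of the
earlier-stored case, which makes every result deterministic.

## Retrieval metric

`WHVDM(t, r) = Σᵢ wᵢ dᵢ²(t, r)` with per-attribute components:

* **continuous** — squared difference of min-max-normalized values.
  Normalization statistics are frozen from the reference base
  (`normalize_continuous`); later target values are clipped to [0, 1].
  Without this step the unbounded squared difference would dominate the
  bounded VDM terms, so normalization is applied before any distance
  computation. Constant attributes map to 0 (they then contribute nothing,
  which is the right degenerate behaviour).
* **discrete** — a value difference metric over the conditional class
  distributions of the two values. Two variants are provided because printed
  sources disagree on the form: `classic` is the symmetric Stanfill–Waltz
  sum of squared probability differences; `as_printed` (default) multiplies
  that sum by `Σ_a Pr(y=a|xᵢ=x_t,i)²`, a target-side factor that breaks
  symmetry. Identical values are at distance 0 under both.

Conditional probabilities use add-α smoothing with α = 1 by default:
`Pr(y=a|xᵢ=v) = (count(v,a)+α)/(count(v)+α|Y|)`. A value never seen in the
reference base gets the pure-α (uniform) distribution, which is also the
fallback at α = 0. Cases with a missing value or label are excluded from the
counts.

**Missing values** contribute `missing_penalty` (default 1.0, the maximum
possible normalized continuous contribution) to `dᵢ²` on either side of any
attribute: incomparability is penalized rather than imputed or discarded.

**Prediction** is 1-NN because the weight-learning objective is defined
through the single nearest case; top-k retrieval is presentation, not voting.
Evaluation reports accuracy and the macro-averaged F-value (unweighted mean
over observed labels of the per-class F1); for a binary task this reduces to
averaging the two class F1s.

## Weight learning

The GA maximizes the integer count of correctly predicted held-out cases.
Design choices (none forced by the metric itself):

* encoding: non-negative real genes, decoded by `g / Σg` — every decoded
  individual satisfies the simplex constraints by construction, no repair;
* initialization: flat Dirichlet population plus one exact uniform-weights
  individual, so the baseline is always in the gene pool and the final
  weights can never do worse than uniform on the fitness split;
* operators: tournament selection (size 3), arithmetic blend crossover
  (child = u·p₁ + (1−u)·p₂, u ~ U(0,1)), additive Gaussian mutation
  (sd 0.05 per gene at rate 0.1) clipped at 0, single-elite carryover;
* budget: population 50 × 100 generations, early stop at perfect fitness;
* determinism: a single `numpy` Generator seeded from `GAConfig.seed`; equal
  seeds give bitwise-identical traces and weights.

The per-attribute component tensor `D[i, t, r]` does not depend on `w`, so it
is computed once and each generation's fitness for the whole population is a
single matrix product followed by an argmin — the GA's cost is essentially
independent of the metric's cost. Probability tables are estimated from the
reference set only; the fitness split never contaminates them.

With a single attribute the simplex forces `w = (1.0)` and no search runs.

### Behaviour of the learned weights

Two properties of this objective are worth knowing before interpreting
learned weights:

1. **VDM self-discounts uninformative discrete attributes.** A discrete
   attribute whose values are class-independent has all conditional
   distributions near the class prior, so its VDM between any two values is
   near 0. Weight parked on such an attribute barely changes any distance.
   This is a virtue for retrieval (irrelevant discrete attributes cannot
   hurt) but it means learned weight *mass* is not a reliable relevance
   signal for discrete attributes.
2. **Count fitness on a finite holdout is overfittable.** On a ~100-case
   holdout the GA reliably finds weightings that flip a handful of borderline
   neighbours, beating the "place all mass on the truly informative
   attributes" solution by several counts. The learned vector therefore
   enriches informative attributes (roughly doubling their uniform share in
   the standard setting, as `scripts/acceptance.py` measures) without
   concentrating most of its mass there, while still improving holdout
   accuracy over uniform weights. Alternative protocols were evaluated
   (cross-validated count fitness within the reference set, per-generation
   resampled validation splits); they do not change this picture, so the
   package keeps the simplest protocol: fitness on the caller-supplied
   holdout.

## Text extraction and ensemble fusion

Both ensembles (BMES segmentation over characters, CL1–CL7 entity tagging
over words) fuse identically: multiply each member's probability column by
its weight, sum row-wise, renormalize to a distribution, take the argmax row.
The renormalization makes fusion invariant to scaling all weights by a
positive constant; an all-zero weight vector is an error. Argmax ties break
to the lowest row index (B<M<E<S, CL1<…<CL7) for determinism.

Fused argmax sequences are not guaranteed well-formed BMES, so decoding
repairs malformed runs: an M or E with no open run opens one (its first
character acts as B). By construction the decoded words always concatenate
back to the input text.

Losses are the mean fused probability mass missing from the gold label,
pooled over all characters (`Loss1`) and all words (`Loss2`) of the corpus;
the total is their sum, bounded in [0, 2] and zero iff the fused mass on
every gold label is 1. The fused (not per-member) probability enters the
loss, which is what makes the loss respond to the ensemble weights. Weight
fitting is derivative-free coordinate descent: each weight in turn is
minimized on [0, 1] (bounded Brent, `xatol` 1e-4), round-robin until a full
pass improves the total loss by less than 1e-6 or 50 passes elapse; updates
are accepted only when they improve, so the loss trace is non-increasing.

Base classifiers are pluggable — anything that emits per-unit probability
columns. The repository ships a forward maximum-match dictionary segmenter
and a noisy-oracle simulator; skip-gram dictionary training is out of scope,
so word-vector dictionaries are toy (seeded random or one-hot) objects
satisfying the same lookup contract with an out-of-vocabulary fallback.

Key-data extraction runs named regular expressions (group 1 = numeric value)
over the semi-structured text; matches are returned in text order, earlier
spans win overlaps, and duplicate index names in per-patient assembly keep
the last occurrence (a later measurement supersedes an earlier one) with a
logged warning.

## Scoring and triage

`Score1 = 100·sigmoid(Σ aᵢxᵢ)` and `Score2 = 100·sigmoid(Σ bᵢzᵢ)` with
user-supplied index weights; the ×100 puts scores on the same 0–100 scale as
the thresholds σ and γ. Since the sigmoid is strictly inside (0, 1),
threshold 0 selects everything and threshold 100 nothing. Selection flags
cases (`high_quality`, `well_known`) without removing them; rare triage flags
every case whose label frequency is strictly below ω. The audit/readability
index weights have no canonical values — they are configuration — and the
repository ships replaceable reference extractors for the two leading audit
indices (entity-section richness; CL2 time-stamp span in days).

## Synthetic data

The generators define the study conditions for all tests:

* **case bases** — class-shifted unit-variance Gaussians for continuous
  informative attributes (shift = `separation`, default 2, i.e. a two-sigma
  class gap); class-linked categoricals for discrete informative attributes
  whose majority mass interpolates from uniform at separation 0 to 0.7 at
  separation 2, so "separation 0" genuinely means no attribute carries
  signal; class-independent noise attributes alternating continuous/
  discrete; optionally a planted rare label drawn per case at
  `rare_label_freq`. The standard noisy setting is 400 cases, 2 classes,
  1 continuous + 1 discrete informative attribute, 8 noise attributes.
  Audit/readability features are standard normal so the sigmoid scores are
  enumerable.
* **pseudo-EMR corpora** — English tokens concatenated without separators
  (so character-level BMES segmentation is exercised exactly as on Chinese
  text; the fusion arithmetic is script-agnostic), gold BMES and entity
  spans by construction, a numeric record string per patient for the regex
  extractor, and simulated ensembles: per unit and member the believed label
  is gold with probability `q`, and the column puts mass `q` on the believed
  label, the rest uniform. `q = 1` reproduces gold exactly; `q = 0.25` (or
  `1/7`) is exactly uniform.
* **rater panels** — per-rater rankings obtained by noising a consensus
  permutation and re-ranking; agreement 1 gives identical rankings,
  agreement 0 independent ones. Under independence Kendall's W concentrates
  near 1/m, not 0, so "no agreement" checks need enough raters.

What the generators do **not** emulate: real clinical language, real missing
value mechanisms, attribute correlations, label noise, or class imbalance
beyond the single planted rare label. Passing tests demonstrate the
machinery's correctness and the method's qualitative behaviour under known
ground truth, not clinical performance.

## Kendall's W

Ranks are computed per rater (mean ranks for ties);
`W = 12S / (m²(n³−n) − m ΣT)` with the tie term included only when the
correction flag is set. A rater with constant scores is undefined without the
correction and raises; a fully tied matrix (denominator 0) raises under
either setting. For tie-free matrices W equals the mean pairwise Spearman
correlation mapped through `r̄ = (mW−1)/(m−1)`, which the tests use as an
independent route.

## Problem sizes

The default test suite and the acceptance script use the standard generator
(n = 400, 5 replicate seeds) for the method comparison and GA runs, a
1,000-case base for triage counts, 50-case bases for retrieval oracles, and
corpora of 5–20 documents; the whole suite completes in well under a minute
on one CPU thanks to the precomputed component tensor.

## Known limitations

* The as-printed VDM variant is asymmetric; retrieval is always phrased as
  target-vs-stored, so the asymmetry is consistent, but the metric is not a
  mathematical distance. Use the classic variant where symmetry matters.
* Learned weight mass is interpretable only jointly with the VDM
  self-discounting effect described above.
* The word-level feature vectors fed to entity taggers are 4-dimensional
  (derived from the BMES distributions); the tagger interface accepts any
  fixed feature dimension so richer features can be substituted.
* Case adaptation/revision and approximate nearest-neighbour indexing are
  out of scope; retrieval is exact and linear in the base size.
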