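# cbrmatch

Case-based reasoning (CBR) over mixed-type clinical case bases: build a
quality-scored case base from semi-structured medical records, then retrieve
and classify with a weighted heterogeneous value distance measure whose
attribute weights are learned by a genetic algorithm.

The package is aimed at clinical decision-support and medical knowledge
engineering work: given a repository of solved cases (attribute vector *x*,
outcome/disease label *y*), it recommends the most similar historical cases
for a new patient and predicts the class label, and it automates the
construction and triage of the case repository itself from pseudo-EMR text.

## The model

**Retrieval metric.** The distance between a target case *t* and a stored
case *r* over *n* attributes is

```
WHVDM(t, r) = Σᵢ wᵢ · dᵢ²(t, r),      0 ≤ wᵢ ≤ 1,  Σᵢ wᵢ = 1
```

where `dᵢ²` is a squared difference `(x_t,i − x_r,i)²` for continuous
attributes (min-max normalized to [0, 1]) and a value difference metric (VDM)
for discrete ones:

```
vdmᵢ(t, r) = Σ_a (Pr(y=a | xᵢ=x_t,i) − Pr(y=a | xᵢ=x_r,i))² · Σ_a Pr(y=a | xᵢ=x_t,i)²
```

The trailing factor breaks the symmetry of the classic Stanfill–Waltz VDM;
both variants are available (`DistanceConfig(vdm_variant="classic")` drops
it). Conditional class probabilities are add-α estimates from the stored
base. Prediction is 1-NN: the label of `s(t) = argmin_r WHVDM(t, r)`.

**Weight learning.** A genetic algorithm evolves *w* to maximize the count of
correctly predicted held-out cases `Σ_t I(y_t = y_s(t))`. Chromosomes are
non-negative gene vectors decoded by simplex normalization, with tournament
selection, blend crossover, Gaussian mutation, and elitism.

**Case-base construction.** Semi-structured records are turned into cases by
(1) ensemble BMES word segmentation and (2) ensemble entity tagging over the
seven clinical categories CL1–CL7 (patient information, time, disease,
symptom, examination test, treatment plan, other), with ensemble weights
fitted by minimizing `Loss = Loss1 + Loss2` (the fused probability mass
missing from the gold labels); (3) regex extraction of numeric indices such
as fasting blood glucose; (4) per-patient merging. Cases are then triaged by
two sigmoid scores on a 0–100 scale — `Score1 = 100·σ(Σ aᵢxᵢ)` (audit
quality, threshold σ) and `Score2 = 100·σ(Σ bᵢzᵢ)` (expert readability,
threshold γ) — and by rare-disease frequency (threshold ω).

## Worked example

Learn attribute weights on a synthetic base whose ground truth is known
(2 informative attributes hidden among 8 pure-noise ones), then compare
GA-weighted retrieval with uniform weights:

```python
from cbrmatch import (
    DistanceConfig, GAConfig, evaluate, gen_case_base, learn_weights,
    normalize_continuous, standard_noisy_spec, uniform_weights,
)
from cbrmatch.evaluation import stratified_split

base, truth = gen_case_base(standard_noisy_spec(seed=7))
base, _ = normalize_continuous(base)
reference, test = stratified_split(base, 0.3, seed=7)

w, trace = learn_weights(reference, test, GAConfig(seed=7), DistanceConfig())
for name, wi in zip(base.attribute_names(), w):
    marker = " informative" if name in truth["informative"] else ""
    print(f"{name:>12s}  w = {wi:.3f}{marker}")

ga = evaluate(reference, test, w)
uni = evaluate(reference, test, uniform_weights(len(base.schema)))
print(f"GA-weighted 1-NN accuracy: {ga['accuracy']:.3f}  (macro F {ga['f_value']:.3f})")
print(f"uniform-weight accuracy:   {uni['accuracy']:.3f}  (macro F {uni['f_value']:.3f})")
```

Output:

```
  cont_inf_0  w = 0.120 informative
  disc_inf_0  w = 0.308 informative
     noise_0  w = 0.012
     noise_1  w = 0.052
     noise_2  w = 0.037
     noise_3  w = 0.031
     noise_4  w = 0.096
     noise_5  w = 0.130
     noise_6  w = 0.082
     noise_7  w = 0.133
GA-weighted 1-NN accuracy: 0.892  (macro F 0.891)
uniform-weight accuracy:   0.758  (macro F 0.754)
```

The two informative attributes end up with 0.43 of the weight mass (uniform
would give them 0.2), and GA-weighted retrieval gains 13 accuracy points over
uniform weighting on the held-out cases.

The same facilities are available from the shell:

```
cbrmatch gen-data --kind corpus --out corpus.jsonl --seed 1 --n 50
cbrmatch build-casebase corpus.jsonl --out-dir bases --sigma 55 --gamma 50 --omega 0.1
cbrmatch compare --seed 1 --out comparison.json
```

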