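# multirep-ner

A hybrid biomedical named-entity recognition pipeline that learns *which
data representation to trust* instead of committing to one. It is aimed at
text-mining practitioners who already have entity lexicons (from curated
life-science knowledge bases) and want a candidate filter that combines
hand-designed morphology features with general-purpose word embeddings in
a principled, inspectable way.

## The method

The pipeline has two stages:

1. **Gazetteer look-up.** A trie-based dictionary matcher scans each
   document for lexicon terms (leftmost-longest, non-overlapping, on word
   boundaries) and emits *candidate* mentions. This stage has high recall
   and low precision: gold annotations among the candidates become
   positive training examples, the remaining candidates negatives. Gold
   mentions the dictionary never proposes are unreachable downstream and
   are charged as false negatives at evaluation time.

2. **Machine-learning filter.** Each candidate surface is described by ten
   base representations φ_r: 12 orthographic "grammar" features, 20 affix
   occurrence scores (2/3-character prefixes and suffixes against 5
   terminological resources, max-rescaled into [0, 1]), 16 word-shape
   features over the 4-symbol normalized token (classes `a`, `A`, `0`,
   `-`), binary p-spectrum maps of the run-compressed normalized token for
   p = 1..5, and two word-embedding lookups (domain-specific and
   general-purpose). A binary classifier accepts or rejects each
   candidate.

Representations are aggregated under three schemes: **single** (validation
picks one view), **concatenation** (one static stacked feature space), and
**combination** — the interesting one. For kernel machines the combination
is learned by **EasyMKL**: with base Gram matrices K_r, labels Y = diag(y)
and the bi-simplex Γ = {γ ≥ 0, Σ_{y_i=+1} γ_i = 1, Σ_{y_i=−1} γ_i = 1},

    max_μ min_{γ∈Γ} (1−λ) γᵀ Y (Σ_r μ_r K_r) Y γ + λ‖γ‖²,   μ_r ≥ 0,

solved in the standard relaxed two-step form (γ on the unweighted kernel
sum, then μ_r ∝ γᵀ Y K_r Y γ), with the combined kernel feeding a
hard-margin SVM. The kernel bank holds each non-spectrum view in linear
and homogeneous polynomial form (degrees 2–5) plus the five spectrum
linear kernels — 30 kernels, cosine-normalized. λ ∈ {0.1, …, 0.9, 1} and
C ∈ {10^i, i = −5..5} are chosen on a stratified 80/20 hold-out. The
learned μ is directly interpretable: it says how much each representation
contributes to the margin. The neural counterpart is an ensemble of small
per-view networks (depth 1–4, width {0.5, 1, 1.5} × input dimension)
merged by a shared layer.

Because the original corpus-scale study needs external annotators,
curated terminology services and pretrained embeddings, this package
ships a first-class synthetic corpus generator that plants the class
signal in exactly one view (e.g. every true entity ends in `-ase`),
making weight recovery and end-to-end behaviour testable offline.

## Worked example

```python
import multirep_ner as m

fx = m.generate_fixture(m.FixtureConfig(seed=7, n_documents=40))
train_docs, test_docs, gold_train, gold_test = fx.split(32)
result = m.run_experiment(
    train_docs, test_docs, gold_train, gold_test,
    fx.lexicon, fx.representation_config(),
    m.ModelSelectionConfig(seed=1),
    scheme="combination", learner="mkl",
)
r = result.report
print(f"entity-level P/R/F1: {r.precision:.3f} / {r.recall:.3f} / {r.f1:.3f}")
print(f"selected lambda: {result.model.lam}")
for name, w in sorted(result.model.weight_by_representation().items(),
                      key=lambda kv: -kv[1])[:4]:
    print(f"  {name:<14s} {w:.3f}")
```

prints

```
entity-level P/R/F1: 1.000 / 1.000 / 1.000
selected lambda: 0.1
  affixes        0.819
  embed_domain   0.060
  embed_general  0.054
  spectrum_2     0.017
```

The fixture plants its signal in the suffixes of the positive terms, the
corpus is cleanly separable, and EasyMKL recovers that: 82% of the weight
mass lands on the five affix-derived kernels, and the filter reaches
perfect entity-level F1 on the held-out documents.

The same pipeline is available from the shell: `multirep-ner synth`
writes a synthetic study to disk, `multirep-ner candidates` runs the
look-up alone, and `multirep-ner run` trains under a chosen scheme and
writes a JSON evaluation report.

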