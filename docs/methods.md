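# Methods

## Pipeline model and assumptions

The package implements a two-stage candidate-filter architecture for
entity recognition. Stage one is a dictionary look-up: a trie matcher
emits every leftmost-longest, non-overlapping lexicon match whose span
ends on a word boundary (a boundary is the text edge or a position
adjacent to a non-alphanumeric character). The model assumption behind
the whole design is that the lexicon's recall is high: the classifier in
stage two can only re-rank what the dictionary proposes, so entity-level
recall is bounded above by dictionary recall. Gold mentions the look-up
never proposes are excluded from training (they cannot be candidate rows)
and charged as false negatives in evaluation; this bound is asserted by
the tests.

Candidate labels come from exact span + type agreement with the gold
standoff annotations — the strictest defensible matching rule, chosen
because the positive/negative split of the training set presupposes a
crisp criterion. Matching is case-exact by default (case carries signal:
"CAT" the acronym is not "cat" the animal); a casefold mode exists.

## Base representations

Ten feature maps are computed per candidate surface:

| name | width | content |
|---|---|---|
| orthographic | 12 | length, case flags, Greek letters, dashes, digits, trailing digit, capitals flag, per-class counts, spaces, symbols |
| affixes | 20 | occurrence score of the candidate's 2/3-char prefixes and suffixes in 5 resources, max-rescaled to [0, 1] |
| word_norm | 16 | per symbol class (`a A 0 -`): total count, longest/shortest run, count in the run-compressed token |
| spectrum_1..5 | 4^p | binary presence of every length-p string over the 4-symbol alphabet in the compressed normalized token |
| embed_domain, embed_general | table dim | mean word-vector of the whitespace tokens |

Decisions the feature definitions leave open were resolved as follows.
The normalization alphabet has no space class, so spaces map to `-`
together with all other non-alphanumeric characters. The case flags
quantify over alphabetic characters only and are false for strings
without letters; a dash increments both the dash count and the symbol
count. Greek detection covers the Unicode Greek block plus spelled-out
letter names as whole tokens. Affixes are proper affixes: a length-k
affix exists only when the token is strictly longer than k, so short
tokens produce zero entries; for multi-word candidates prefixes come from
the first token and suffixes from the last, since affixes are token-level
morphology. Affix rescaling divides by the maximum count of the
(resource, kind) list, which keeps absent affixes at exactly 0. The
spectrum's repetition removal is run compression (the same operation the
word-shape features use); a global-deduplication variant is exposed as a
non-default flag. Embedding lookup tries the exact surface token first
and falls back to its casefold; out-of-vocabulary tokens contribute zero
vectors to the mean.

## Kernels and EasyMKL

The combination scheme builds 30 Gram matrices from the 10-entry bank:
each non-spectrum view in linear form and homogeneous polynomial form
k(x, z) = ⟨x, z⟩^d for d = 2..5, plus one linear kernel per spectrum
view (the spectrum is already an explicit string-kernel feature map, and
its binary features make higher degrees redundant). All kernels are
cosine-normalized before combination — mixing degree-5 polynomials with
binary presence features without normalization would let scale, not
information, decide the weights. Normalization is switchable for users
who want raw kernels.

EasyMKL maximizes the regularized margin between the class distributions
on the bi-simplex. The implementation follows the standard relaxation:
the inner quadratic problem is solved once on the unweighted sum of the
normalized base kernels, each kernel's weight is then its margin
contribution d_r = γᵀ Y K_r Y γ (non-negative because K_r is PSD), and
μ = d / ‖d‖₁. The L1 normalization resolves the scale degeneracy of the
printed objective and makes μ directly readable as shares. λ ∈ [0, 1]
trades the convex-hull margin (λ = 0) against the centroid distance
(λ = 1); it is selected on validation over {0.1, …, 0.9, 1}.

The inner QP — minimize (1−λ) γᵀYKYγ + λ‖γ‖² over a product of two
probability simplices — is solved by FISTA with exact Euclidean simplex
projections, step 1/L with L = 2 λ_max(Q) from a dense symmetric
eigendecomposition (training sets here are a few hundred candidates).
The solver starts from the uniform-per-class point, which makes the λ = 1
closed form exact (it is the fixed point of the first projection), and is
fully deterministic. Convergence is declared when the fixed-point
residual max_i |γ_i − proj(γ − step·∇f(γ))_i| drops below 1e-8, checked
every 20 iterations; 50 000 iterations without convergence raise a
numeric error carrying the residual. On problems with four training
points the solution matches exhaustive grid search over the feasible set
to 1e-4 in objective value (tested).

The combined kernel feeds a "hard-margin" SVM realized as a
precomputed-kernel SVC with C = 10^6 — a true hard margin is infeasible
on non-separable data, and the surrogate coincides with it when the data
separate. All near-hard-margin fits carry a solver iteration cap
(1–2 × 10^5) so that non-separable grid cells terminate; such cells lose
validation anyway.

## Neural combiner

The plain network is a rectifier MLP with a logistic output and
cross-entropy loss, trained with Adam (learning rate 1e-3 by default),
mini-batches of 32, at most 200 epochs, early stopping with patience 10
on validation loss, best-state restore. The architecture grid is depth
{1, 2, 3, 4} × width {0.5, 1, 1.5} × input dimension (half-up rounding,
floored at one unit) — 12 cells. Training is deterministic given the
seed; the seed drives initialization and batch shuffling and nothing
else.

The ensemble combiner trains one local network per representation on its
own view, drops each local's output unit, concatenates the final hidden
activations, and trains a shared rectified layer plus logistic head on
top with the locals frozen. Freezing is the default reading of
"train locals first, merge later"; a `fine_tune` switch performs a joint
gradient pass over the whole stack afterwards. Passing hidden states
upward (rather than the locals' probabilities) preserves information;
both choices were open and the hidden-state reading was adopted.

## Model selection

All schemes use a stratified, seeded 80/20 hold-out on the training
candidates with candidate-level F1 as the selection metric. Grids:
C ∈ {10^i, i = −5..5} (11 values) for SVMs, the 12-cell architecture
grid for networks, λ over its 10 values for MKL. Ties resolve to the
earliest grid cell — bank order first, then smaller C or shallower and
narrower network — making selection deterministic. Degenerate metric
cases use the 0-convention: precision, recall and F1 are 0 when their
denominators vanish.

## The synthetic study

The generator emulates what the pipeline actually consumes: documents
whose running text embeds lexicon terms, gold standoff spans, decoy
lexicon terms that create false-positive candidates at a configurable
rate, five affix resources bootstrapped from the lexicon, and two
embedding tables. The class signal is planted in exactly one view so that
weight attribution is unambiguous:

* `suffix_rule` (default): positives end in a planted suffix (`-ase`,
  the classic enzyme morphology; `-ism` is also shipped), decoys end in
  random consonant-vowel-consonant trigrams. Positive and decoy terms
  share the same stem construction, so length, shape and spectrum
  distributions coincide across classes and only affix-derived features
  separate them.
* `shape_rule`: positives look like `Abc-12`; shape-sensitive views
  (orthographic, word-shape, spectrum) all separate.
* `embedding_rule`: surfaces are statistically identical; the domain
  table draws positives and decoys around centers ±δ/2 along a fixed
  unit direction with unit-variance noise.
* `none`: no view separates.

Defaults: 30 documents, 4 entity placements per document, decoy rate
0.5, 100 positive and 100 decoy terms, embedding dimension 8. The term
lists are deliberately large relative to the embedding dimension so that
a δ = 0 table cannot act as a term-identity memorizer — with 200 terms in
8 dimensions a linear probe on held-out words sits at chance, which is
what "uninformative view" must mean for the recovery experiments to be
meaningful.

What the fixtures do **not** emulate: real biomedical language (no
sentence structure, no ambiguity between entity types, no nested or
overlapping gold spans), ontology structure, abbreviations, or the
distribution shift between a lexicon's vintage and a corpus. Passing
tests therefore demonstrate that the machinery is correct — matching,
labeling, feature computation, the optimization, weight attribution, the
recall bound — not that any particular F1 would transfer to a real
corpus.

## Problem sizes

Tests and the acceptance script run corpora of 30–40 documents
(≈ 120–160 candidates), chosen as the smallest sizes at which the planted
signals are reliably recoverable across seeds. The neural-ensemble runs
use the spectrum family truncated at arity 3 and 40 training epochs at
learning rate 3e-3: the wide arity-4/5 views multiply network parameter
counts without adding signal at this corpus scale. The full-width
defaults remain available and are what the kernel path uses throughout.

## Known limitations

* The gazetteer is exact (trie) matching only — no fuzzy matching,
  abbreviation expansion or normalization layers of a production
  annotator.
* One binary model per entity type; no shared multiclass head and no
  cross-type candidate competition.
* Context is ignored: candidates are classified from their surface alone,
  so sense disambiguation that needs surrounding words is out of reach.
* The EasyMKL weight solve is dense (O(n²) memory in training
  candidates); it is intended for the candidate-filter regime (10³–10⁴
  rows), not for corpus-scale kernel learning.
* Embedding tables are consumed, never trained or fine-tuned.
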