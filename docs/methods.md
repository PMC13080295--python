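# Methods

This note documents the models, conventions and numerical choices behind
`aekit`, in the spirit of a statistical software methods appendix. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Report model and text normalization

An adverse-event report carries a narrative and a six-field element map:
three core fields (`occurrence_date`, `abnormal_condition`,
`follow_up_measures`, weight 1.0), two secondary fields (`failure_cause`,
`triggered_risk`, weight 0.8), and one supplementary field
(`additional_information`) that never counts toward coverage.

Normalization applies, in order: Unicode NFKC folding (full-width digits,
letters and punctuation to half-width), user regex rules, dictionary
substitution of variant terms, and whitespace collapsing. Substitution is
idempotent by construction: canonical terms participate in the scan and map
to themselves, so a variant embedded in an already-canonical span is never
rewritten. Longest-match-first is realized by ordering the regex
alternation by key length. Element spans are stored as verbatim substrings,
not offsets, because matching operates on normalized text and offsets would
not survive normalization.

## Dataset splitting

Splits are assigned at the report level: all items derived from one report
share a partition. Target sizes follow round-half-away-from-zero on the
train (0.6·N) and test (0.3·N) counts with the remainder to validation —
the only convention that reproduces both published allocation triples
(2457/1229/409 at N=4095 and 893/446/149 at N=1488), which is why it is
hard-coded as the default. Groups are placed greedily, largest first after
a seeded shuffle, into the partition with the greatest remaining need; with
singleton groups this hits the targets exactly, and it needs no solver.

## Matching and metrics

Hierarchical matching tries exact containment of the normalized reference
in the prediction first, then a fuzzy branch: edit-distance similarity
`1 − Lev/max(|a|,|b|)` must *strictly* exceed the threshold (default 0.8);
the boundary value is a non-match. A two-sided ratio
(`1 − Lev/(|a|+|b|)`) is available as a config option. Edit distance is
computed character-wise (unicode-aware), which matters for Chinese text.
An empty reference is an error (match semantics undefined); a missing
predicted field is a non-match, not an error, so ERR remains computable
for models that omit elements.

IDIAE uses coverage over the m = 5 required fields. Two normalizations are
implemented because the denominator is genuinely ambiguous in the source
material: `weight_sum` (default; a perfect clean report scores exactly 1.0)
divides by `(Σ w_j)·β = 4.6·β`, and `field_count` divides by `m·β = 5·β`.
The correction factor is exact arithmetic:
`β = 1 + α·(N_red/10) + γ·M_error` with defaults α = 0.1, γ = 0.2 (the
grid-search optimum; see Calibration). `N_red` counts characters of the
free text assignable to no recognized field span, counted *after*
normalization; `M_error` counts tokens fuzzy-similar (>0.8) but not
identical to a canonical lexicon term. Both detectors are heuristics; the
synthetic generator records the injected ground-truth counts, and scoring
accepts them directly so that calibration work does not inherit detector
noise.

Risk recall divides the number of identified core-safety items by the fixed
list size 6, so the mean recall equals the mean item count over 6 exactly —
an identity the tests assert. Relative improvement and attenuation are
reported to one decimal with half-up rounding, matching how such
percentages are conventionally printed.

BLEU-4 (uniform 1–4-gram weights, brevity penalty, optional add-one
smoothing on zero higher-order counts) and ROUGE-L (LCS F1) are implemented
from their standard published definitions since no pre-installed package
provides them; they are surface-metric plumbing, not a contribution of this
package.

## Calibration statistics

The ICC is fixed to the two-way random-effects, single-measure,
absolute-agreement form (McGraw & Wong's ICC(A,1)), the standard choice for
blinded multi-rater scoring, computed from ANOVA mean squares with an
F-distribution confidence interval; the form is recorded in the result
object. Zero between-subject variance returns 0 with a degenerate flag.
The implementation is cross-checked in the tests against an independent
statistical library.

The alpha/gamma grid search re-scores every report at each grid cell
(coverage and penalty counts held fixed per report), stacks the re-scored
index against the expert columns, and reports the ICC matrix and its argmax
cell. Grades for kappa-style comparisons derive from continuous scores by
tertile cuts by default (configurable fixed cuts), since no canonical cut
points exist.

The QC gate releases a batch iff the arbitrated significant-drift rate is
≤ 5% (boundary inclusive: 5/100 releases, 6/100 holds) and reports
inter-annotator kappa against the 0.78 training floor.

## Micro-transformer and dual adapters

Because adapter *algebra* — not scale — is the point, the base model is a
2-layer pre-norm causal transformer (d_model 16, 2 heads, FFN width 32,
vocabulary 32) written on a minimal reverse-mode autograd engine over
float64 numpy arrays. LoRA attaches to the attention query and value
projections as `ΔW = B·A` with rank 4 at micro scale (the full-scale
default of 32 is kept on the config); A is seeded small Gaussian and B is
zeros, so `ΔW = 0` at initialization. (IA)^3 attaches to the FFN
intermediate activations as a ones-initialized scaling vector; its `l`
vectors are counted and audited as trainable parameters (they are
parameters, whatever the marketing says). No α/r rescaling is applied to
LoRA. With both adapters at initialization, the composite model is
*bitwise* identical to the frozen base — adding an exactly-zero matrix and
multiplying by exactly-one scalars are exact in IEEE arithmetic — and the
tests assert logit equality, not closeness.

The training objective is `λ_d·mean(domain NLL) + λ_g·mean(general NLL)`
with λ_d : λ_g fixed at 3:1 (defaults 0.75/0.25), per-sample loss
`Σ_t −log p(y_t | y_<t)` via log-sum-exp. Sampling interleaves the corpora
deterministically D,D,D,G (a stochastic seeded mode exists).

The two-stage schedule trains only LoRA in stage 1 (base frozen), then
carries the stage-1 LoRA weights over frozen and trains only the (IA)^3
vectors in stage 2. "Carrying attention patterns as initialization priors"
is operationalized as freeze-and-carry; a joint mode trains both families
simultaneously for comparison. Because the (IA)^3 vectors start at the
identity, the stage-2 initial loss on a fixed evaluation group equals the
stage-1 final loss exactly — asserted as equality. Before adapter training
the base is pretrained on the general corpus and then frozen (that is what
a foundation model is); the frozen-base audit checks bit-identity of all
base tensors after any adapter training.

Problem sizes for the packaged experiments: 96 domain / 32 general training
sequences of length 24, 150 pretraining steps, 120+60 adapter steps at
lr 2e-2 (Adam), held-out accuracy on 48 fresh domain sequences. These sizes
were chosen as the smallest at which base < single-adapter < dual-adapter
separations are visible above seed noise.

## Token-task generator

Domain sequences run a drifting Markov chain over symbols 0–25 and, with
probability 0.9, embed the deterministic causal chain A→B→C (symbols
26/27/28) at gap 4 — a long-range dependency a bigram learner cannot
capture; rare "terminology" symbols 29/30 appear as adjacent pairs (15% of
sequences). The terminology pair is inserted before the motif so the motif
always survives and the realized motif fraction matches its nominal
probability. General sequences use a different drift and only symbols 0–25,
so they contain no domain motifs by construction.

## Contrastive embedder

InfoNCE over cosine similarity with temperature τ = 0.15; the denominator
includes the positive term, so the uniform-similarity case is exactly
ln(K+1). The loss is computed via log-sum-exp and is invariant to positive
rescaling of any embedding.

The packaged encoder hashes character trigrams (CRC32) into 1024 buckets,
L2-normalizes the counts, and applies a trainable *diagonal* feature
reweighting initialized at the identity — so the untuned encoder scores raw
trigram cosine, and training can only amplify discriminative buckets and
suppress boilerplate shared between positives and negatives. A dense linear
mode exists but memorizes small triplet sets instead of generalizing; the
diagonal parameterization is the deliberate default for the toy scale. The
projection head `LayerNorm(W2·GELU(W1x+b1)+b2)` is optional and, when
enabled, applied consistently at training and retrieval time.

On the packaged corpus, temperature has little leverage: every τ in
{0.05, 0.15, 0.3} solves the task within one epoch, so the convergence-speed
ordering reported for large embedders on real corpora does not reproduce at
this scale; the `tau_sweep` helper measures steps-to-threshold anyway.

## Regulatory corpus generator

Documents contain numbered clauses ("Article N"; the reader also parses
"第N条"). Each clause is a shared scaffold sentence plus a *unique*
content-word subset from a 48-word theme vocabulary; each query paraphrases
exactly one clause by shuffling its content words into a different
scaffold. Shared scaffolds make surface matching deliberately ambiguous
(the untuned encoder is imperfect); unique word subsets make the task
separable, so fine-tuning has both room and signal. Default: 5 documents ×
20 clauses, 80 QA pairs (50 train / 30 held out).

What the generators do *not* emulate: linguistic variety, real reporting
distributions, OCR noise, cross-field ambiguity, or annotator disagreement
structure. Passing tests therefore demonstrate correctness of the
machinery and recoverability under controlled conditions — not performance
on real monitoring-system data.

## Retrieval scaffold

Chunking slides a character window (size 512, overlap 80 ⇒ stride 432,
0-based half-open offsets) clipped at the document end; characters are the
unit because the target corpora are Chinese regulatory prose and token
counts would depend on an external tokenizer. The cosine threshold (0.72)
gates candidates *before* the top-k cut (5); ties break by
(doc_id, chunk_id). Exact search is the default; an IVF mode
(k-means coarse quantization, `nlist` cells, engaged when the corpus holds
≥ 4·nlist chunks) trades recall for speed and is validated against exact
search as oracle. For the toy embedder the 0.72 gate is evaluated at
threshold 0 in end-to-end experiments, since that constant was tuned for a
production-scale embedder whose score distribution the toy encoder does not
share.

Prompts embed three constraint rules verbatim (no vague article references;
mandatory "insufficient basis" declarations; verbatim-citation/
interpretation alternation with `[Ref-N]` tags). The auditor segments on
terminal punctuation outside quotation marks (。！？.!?, configurable),
treats a sentence that is essentially one verbatim quotation as a citation
(no tag obligation), verifies quoted spans verbatim against the cited
chunk, resolves `[Ref-N]` tags against the hit list, and flags clause
numbers absent from all retrieved text as fabricated. Generation itself is
an injected callable; the built-in extractive responder exists for
pipeline tests, not answer quality.

## Expert-panel simulator

Each report's latent quality is its ground-truth information-density score;
a rater's score is latent plus independent Gaussian noise, giving the
analytic single-measure ICC σ²_latent/(σ²_latent+σ²_noise). The
equal-variance recovery experiment uses 500 subjects and 4 raters: with 2
raters the ANOVA estimator's sampling standard deviation (~0.05) would be
as large as the tolerance band, while 4 raters bring it to ~0.01. The
80-report calibration study is stratified 26/28/26 into high/medium/low
quality via dropout and noise levels.

## Known limitations

- All neural components are micro-scale by design; nothing here speaks to
  7B-parameter behaviour (convergence pathologies, saddle points, batch
  statistics) beyond the algebra being exercised.
- N_red/M_error detection is heuristic; calibration relies on ground-truth
  counts from the generator.
- The citation auditor's quotation heuristic (≥60% of a sentence quoted ⇒
  citation sentence) is a documented convention, not a linguistic model.
- Retrieval F1 is the harmonic mean of top-1 accuracy and top-k recall — a
  package convention recorded in output metadata, chosen because no
  operational definition accompanies the published table it mirrors.
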