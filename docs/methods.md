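# Methods

## Data model

A corpus is a set of annotated documents, each a title and abstract with
character-offset mention annotations.  A *mention* is one surface
occurrence of an entity; mentions sharing a normalized identifier are
coreferent.  Relations are undirected triples (entity pair, relation type,
novelty) with at most one relation per unordered pair; novelty marks
whether the document newly asserts the relation (`Novel`) or repeats
background knowledge (`No`).  Offsets are 0-based half-open over
`title + " " + abstract` (the PubTator convention); documents are not
sentence-segmented because no downstream step consumes sentence
boundaries.  Mention lines carrying comma-separated composite identifiers
are expanded into one mention record per identifier.  A relation file
writing `None` in the novelty column is read as `No` with a warning.

## Sample construction

For a document with entities E, every unordered pair — C(|E|, 2) of them —
yields one sample.  All mentions of the two focal entities are wrapped in
the atomic marker strings `@\E` and `E/@`; non-focal mentions are left
untouched.  The marked text is word-tokenized (whitespace split,
punctuation split off, markers and frame tokens atomic), framed by
`[CLS]`/`[SEP]`, and truncated to the configured maximum length keeping
the prefix (titles and early abstract text carry most focal mentions).  A
mention survives truncation only if both its markers fit; a sample in
which one focal entity loses all mentions is flagged degenerate and is
excluded from the coreference loss while remaining in the document-level
heads.

The *constraint map* — unordered entity-type pair → relation types ever
observed in the training split — filters out samples whose type pair can
carry no relation.  It is learned from the training split only.  At
inference the same filter applies and filtered pairs are predicted None
without a model call.

Labels per sample: coreference labels for all unordered pairs of surviving
focal mentions (positive iff same entity id, pairs ordered by document
position of the opening marker); the unordered entity-type pair; the gold
relation type or None; the gold novelty or None (relation is None iff
novelty is None).

## Model

The encoder is pluggable behind the contract "token ids in, one
h-dimensional contextual vector per token out".  The bundled encoder is a
pre-layer-norm transformer with learned token and absolute position
embeddings plus a per-head learned relative-position attention bias
(distances clipped to ±8).  The relative bias lets a small model express
position-invariant local patterns — "a cue word directly between two
marked mentions" — which absolute embeddings alone generalize poorly at
small data scale.  Defaults: 2 layers, 2 heads, hidden size 64,
feed-forward 256, ReLU, initialization N(0, 0.02²).  All tensors are
float64 numpy arrays differentiated by the package's reverse-mode autodiff
engine (`jtis._autograd`), whose operator gradients are tested against
central finite differences.

Heads:

* CR: bilinear tensor A of shape (2, h, h) and bias b over the two
  opening-marker vectors, `logit_c = mᵢᵀ A_c mⱼ + b_c`, softmax over the
  two classes.  The form is asymmetric in (i, j); pairs are fed in
  document order for reproducibility.
* EPT / RE / TNT: affine maps of the `[CLS]` vector followed by softmax.
  Class counts come from the label schema: all unordered entity-type
  pairs; relation types plus None; {Novel, No, None}.

Cross-entropy is the loss everywhere.  The CR loss of a sample is the
unweighted mean over its mention pairs (avoiding bias toward
mention-heavy samples), then averaged over the non-degenerate samples of
the batch.  The TNT head includes a None class: by default no-relation
samples train TNT with label None, and at inference the None column is
dropped and the remaining two probabilities renormalized.  Setting
`tnt_uses_none_negatives=False` instead excludes no-relation samples from
the TNT loss entirely; both behaviors are defensible readings of the
two-stage design and the default keeps the TNT model exposed to every
sample.

## Training

The joint objective is `L = L_primary + Σ_t η_t L_t` with η = 0.1 for
every auxiliary task.  Two models are trained separately: one with RE
primary, one with TNT primary.

Each optimizer step runs a clean forward/backward pass, then (when ε > 0)
an FGM adversarial pass: the token-embedding table is perturbed by
`r_adv = ε · g / ‖g‖₂` (g = accumulated embedding gradient of the clean
pass; r_adv = 0 when g = 0), the joint loss is recomputed and
back-propagated so gradients accumulate, and the table is restored
exactly from a saved copy.  ε = 0 skips the adversarial pass, making the
step bit-identical to plain fine-tuning.  The accumulated gradient is
clipped to global norm 1 and applied by AdamW (decoupled weight decay
0.01 on matrices only) in two parameter groups — encoder and heads — under
a piecewise-linear schedule: 0 → peak over the first 6% of steps, then
peak → 0.

Reference defaults (`TrainConfig`) follow the recipe for fine-tuning a
pretrained biomedical encoder: 100 epochs, batch 2, encoder LR 2e-5, head
LR 1e-4, ε = 1.  For the from-scratch tiny encoder these are far off
scale, so desk-scale runs use `tiny_train_config()`: 40 epochs, batch 8,
both LRs 3e-3, everything else unchanged.  Batches keep samples of one
document contiguous; document order is reshuffled per epoch from the run
seed, and a fixed seed reproduces final parameters exactly.  The returned
checkpoint is the best-dev one (pair+type F1 for RE-primary, novelty
accuracy for TNT-primary); last-epoch selection is available.

## Inference and ensembling

Prediction is two-stage per document: the RE model classifies every
constraint-admissible pair; pairs predicted related are passed to the TNT
model (never the others — an invariant the tests count), giving triples
(pair, relation, novelty).  The k-fold ensemble partitions the training
documents into k balanced document-level folds, trains an (RE, TNT) model
pair per held-out fold, predicts the test set with each, and votes per
pair over relation labels with None votable.  Ties break by highest mean
predicted probability among tied labels, then by schema label order;
novelty is the majority among models that voted the winning relation,
with `No` winning ties.  The tie-break chain is stated explicitly so the
vote is a deterministic, permutation-invariant function of the model
outputs.

## Evaluation

Micro P/R/F1 pooled over documents at three nested tiers: predicted pair
exists in gold (any type); plus equal relation type; plus equal novelty.
Matching is on unordered entity-id pairs, so endpoint order never matters,
and tier scores are non-increasing by construction.  0/0 precision,
recall or F1 is reported as 0.

## Synthetic corpora

The generator emulates the structural features the pipeline depends on:
six entity types, eight undirected relation labels, a symmetric type-pair
→ allowed-relations schema that generated relations always respect,
multi-mention entities (alias surfaces sharing one id), relation cue
phrases emitted with probability `cue_strength`, and novelty cue phrases
emitted independently of the relation cue.  Entity names are drawn from a
fixed per-type pool so identifiers recur across documents, as database
identifiers do in real corpora.  Cue phrases are single underscore-joined
tokens so word-level tokenizers keep them atomic.  Text is templated
filler, not natural prose: passing tests demonstrate that the mechanisms
(marking, multitask supervision, gating, voting, scoring) work end to end,
not that the tiny encoder would score well on real PubMed language.

The learnability fixture defines the desk-scale study conditions: 600
training and 60 validation documents over the four relation-bearing
entity types, two entities (one candidate pair) per document, one-to-two
mentions per entity, relation density 0.7, novelty probability 0.5.  With
`cue_strength = 1` ("separable") the labels are deterministic functions
of the surface cues and a bag-of-cue-words oracle scores perfectly; with
0.7 ("noisy") some relations are surface-invisible.  Documents with a
single candidate pair were chosen because attributing a cue to one of
several marked pairs in the same document demands more capacity and data
than a CPU-minutes budget affords; the single-pair condition isolates
what the fixture is meant to show — that the full multitask loop with
adversarial training learns the task — while the multi-pair regime
remains available through `SynthConfig`.

## Numerical choices and degenerate inputs

Softmax subtracts a gradient-free row maximum; probabilities sum to 1
within 1e-6 (tested).  Cross-entropy over an empty instance set is an
error — degenerate CR samples are excluded upstream.  `lr_at` is
continuous and peaks exactly once; total_steps = 0 is an error.  Empty
training sets, k-fold with fewer documents than folds, voting over zero
models, overlapping focal mentions, out-of-vocabulary token ids, and
non-finite losses all raise immediately with context.

## Known limitations

* The tiny encoder is word-level with a training-corpus vocabulary;
  unseen tokens map to `[UNK]`.  No subword segmentation.
* Long documents are prefix-truncated; no sliding windows.
* CR pairs cover focal mentions only (only they carry markers); the
  marker scheme does not distinguish the two focal entities.
* Single-label RE per pair; relations are undirected by construction.
* The ensemble is hard voting; probability-averaging is out of scope.
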