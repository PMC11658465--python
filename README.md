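# jtis

Joint multitask document-level relation extraction for biomedical
literature, with triplet-novelty typing, adversarial fine-tuning, and
k-fold ensemble voting.

## The problem

Biomedical facts are rarely stated in one sentence: an abstract may
introduce a gene by its full name, later call it by an acronym, and only
then relate it to a chemical.  Document-level relation extraction (DocRE)
over BioRED-style corpora asks, for every pair of normalized entities in a
title+abstract, (i) whether a relation holds and of which type
(association, positive/negative correlation, binding, …, undirected), and
(ii) whether that relation is a *novel* finding of the document or
background knowledge.

`jtis` trains a single shared text encoder with four supervised heads:

* **CR** (coreference resolution) — for two mentions marked in the text,
  a bilinear scorer `P = softmax(mᵢ A mⱼ + b)` over their opening-marker
  representations decides whether they normalize to the same entity;
* **EPT** (entity-pair typing) — classifies the unordered entity-type pair
  of a sample from the classifier-token vector;
* **RE** (relation extraction) — relation type or None, same vector;
* **TNT** (triplet novelty typing) — Novel / No / None, same vector.

Each (document, entity pair) becomes one sample: every mention of the two
focal entities is wrapped in atomic markers (`@\E … E/@`), the sequence is
framed by classifier/separator tokens, and pairs whose entity-type pair
never carries a relation in training are filtered out.  Training minimizes

```
L = L_primary + Σ_t η_t · L_t        (η_t = 0.1 by default)
```

with FGM adversarial steps (`r_adv = ε·g/‖g‖₂` added to the embedding
table, gradients of clean + adversarial passes accumulated, embeddings
restored exactly) and a linear warmup/decay schedule.  Two models are
trained — one RE-primary, one TNT-primary.  At inference the RE model
proposes relations; only predicted-related pairs reach the TNT model.  A
10-fold document-level ensemble votes per-pair relation labels, breaking
ties by mean predicted probability, then schema order.

Evaluation is micro P/R/F1 at three nested tiers: entity pair, pair +
relation type, pair + type + novelty.

## Worked example

```bash
jtis synth --n-docs 20 --seed 3 --out corpus.pubtator
jtis stats corpus.pubtator
```

prints

```json
{
  "n_docs": 20,
  "n_mentions": 218,
  "n_entities": 56,
  "n_relations": 19,
  "n_novel_pairs": 10
}
```

i.e. 20 synthetic title+abstract documents with 56 normalized entities
carrying 218 mentions (entities average ~4 mentions, so coreference is
non-trivial), 19 gold relation triples of which 10 are flagged Novel.
Train a relation model and a novelty model, predict, and score:

```bash
jtis train --corpus corpus.pubtator --dev corpus.pubtator \
     --config cfg.yaml --primary-task RE  --out re.npz
jtis train --corpus corpus.pubtator --dev corpus.pubtator \
     --config cfg.yaml --primary-task TNT --out tnt.npz
jtis predict --re re.npz --tnt tnt.npz --corpus corpus.pubtator --out pred.pubtator
jtis evaluate --gold corpus.pubtator --pred pred.pubtator
```

The evaluate command prints the three tiers, e.g. a perfectly recovered
corpus gives `"pair": {"f1": 1.0, …}` down through
`"pair+type+novelty"`; scores are non-increasing across tiers by
construction.

The same workflow runs on real BioRED-format PubTator files; use
`jtis ensemble --corpus train.pubtator --test test.pubtator --k 10` for the
voted ensemble.

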