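# msgddi

Bipartite skip-gram embeddings of adverse-event reports for drug–drug
interaction (DDI) signal detection.

Spontaneous-report databases (FAERS-style) record, per report, the set of
drugs a patient took and the set of adverse reactions observed.  `msgddi`
embeds drug and reaction concept IDs into a common low-dimensional space
with a *modified skip-gram*: instead of a sliding ±n word window, the
context of a drug is **every reaction in the same report**, and the context
of a reaction is every drug.  Training maximises

```
Σ_{(w,c)∈D} Σ_{w_j∈c} log P(w | w_j)
```

with `P(w | w_j)` factorised by hierarchical softmax over a Huffman tree
built from token frequencies: each internal node on `w`'s root-to-leaf path
contributes `σ(±⟨v_node, e(w_j)⟩)`, the sign given by the branch taken.

On top of the embeddings the package provides, end to end:

- **CM-TF-IDF baseline** — drug/reaction × report cooccurrence matrix with
  `tfidf_{i,j} = (n_{ij}/Σ_k n_{kj}) · ln(|D|/df_i)` weights, reduced by PCA
  to fixed-length term vectors;
- **pair classification** — drug pairs labeled positive for an
  adverse-event class by three reference strategies (curated drug lists,
  toxicity-keyword records, interaction-keyword records), featurised by the
  additive pair embedding `e(a)+e(b)` and scored with stratified 10-fold
  logistic-regression AUROC;
- **description enrichment** — candidate reactions ranked by
  `cos(e(a)+e(b), e(r))`; an enrichment is *valid* if any top-20 reaction
  falls under the class's MedDRA System Organ Class, and per-class accuracy
  is the fraction of valid enrichments;
- **synthetic data** — a generator that emits every input file (report
  corpus, DDI/toxicity/drug-list/SOC/event-class tables) with planted class
  structure and controllable signal/noise, so the whole pipeline is testable
  without access to FAERS, DrugBank, SIDER or MedDRA.

The intended audience is pharmacovigilance and cheminformatics researchers
who want a transparent, fully reproducible reference implementation of this
embedding family rather than a black-box service.

## Worked example

```sh
python examples/enrich_interactions.py
```

trains 50-dimensional embeddings on 1,500 synthetic two-drug reports
(5 planted classes, drug-signal 0.9, reaction noise 0.1) and enriches the
emitted interaction records:

```
pair ('100020', '100024'), class class0 — top 5 of 20:
  1. reaction 900026  cosine 0.9174  SOC: Class 0 disorders
  2. reaction 900020  cosine 0.9165  SOC: Class 0 disorders
  ...
  -> enrichment valid

class   n_ddis  n_valid accuracy
class0  40      40      1.000000
...
Total   193     193     1.000000
```

Accuracy is the fraction of interactions whose top-20 cosine-ranked
reactions contain at least one reaction under the class's organ system —
here every planted interaction is recovered.  `examples/classify_pairs.py`
prints the companion classification table (per-class 10-fold AUROC ≈ 0.97–1.00
for both feature sources at this signal strength), and
`examples/generate_bundle.py` / `examples/train_embeddings.py` show the
generator and the raw embedding geometry.

A thin CLI mirrors the library (`msgddi gen | train-msg | train-tfidf |
label | evaluate | enrich | run-all`); `msgddi run-all --seed 1 --out-dir
run/` executes the whole workflow and writes embeddings, CV tables,
enrichment rankings and the accuracy table, byte-identically for a given
seed.

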