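# Methods

## The model

Each adverse-event report is a pair of token sets: drug concept IDs and
reaction concept IDs.  The modified skip-gram discards word order and the
sliding window entirely and uses the report's bipartite structure as the
context rule: every in-vocabulary reaction is a context of every
in-vocabulary drug in the same report, and vice versa.  Drug–drug and
reaction–reaction pairs are never emitted.  The training objective is the
usual skip-gram log-likelihood

    L = Σ_{reports} Σ_{(input, target)} log P(target | input),

where the sum runs over both directions of every drug–reaction pair in the
report.  `P(target | input)` is a softmax over the joint drug+reaction
vocabulary, computed in its hierarchical form: a Huffman tree is built over
token frequencies, and

    P(w | c) = Π_{nodes n on w's path} σ(s_n · ⟨v_n, e(c)⟩),

with `s_n = +1` when the path takes the left (0) branch at `n` and `−1` for
the right branch.  Because `σ(x) + σ(−x) = 1`, these probabilities sum to 1
over the vocabulary exactly, which the tests verify to 1e-9.

Optimisation is plain sequential SGD, one (input, target) pair at a time in
corpus order, with the learning rate decaying linearly from `alpha0` to
`min_alpha` over the total number of pair updates.  No threading, negative
sampling, or frequent-word subsampling is used; sequential updates make the
trained model a pure function of (corpus, parameters), and two runs with
the same seed are bit-identical.

### Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `dim` | 100 | embedding dimensionality; the reference setting for real-scale corpora.  The synthetic studies use 50, matching their smaller vocabulary |
| `alpha0` | 0.025 | starting learning rate, the standard value for this model family |
| `min_alpha` | 1e-4 | floor of the linear decay |
| `epochs` | 5 | passes over the corpus; common practice where a source does not state one |
| `min_count` | 10 | minimum number of reports a token must appear in; the conventional threshold for statistically supportable drug concepts at database scale.  The synthetic experiments use 5 because a 2,000-report corpus supports planted drugs at ~14 expected occurrences, and a threshold of 10 would discard a third of them |
| `seed` | — | drives initialisation; input vectors start uniform in [−0.5/dim, 0.5/dim], internal-node vectors at zero |

Frequency is document frequency (reports containing the token).  Within a
report duplicate tokens collapse to one occurrence — contexts are sets —
so document frequency and raw multiplicity coincide.

### Huffman construction

The two lowest-count nodes are merged repeatedly; ties are broken by
creation index (leaves in vocabulary order, then internal nodes in creation
order), making the tree deterministic.  The first node popped becomes the
left (0) child.  Tests check Kraft equality (Σ 2^−len = 1) and, against an
independent exhaustive search over all full-binary-tree depth profiles,
optimality of the weighted code length for vocabularies up to 8 tokens.

## Two embeddings per token, and which one each stage uses

Skip-gram with hierarchical softmax learns *input* vectors `e(w)` for
tokens and vectors `v_n` for tree nodes.  The target side of the model has
no per-token vector, but its linearisation

    e'(w) = Σ_n s_n · v_n   (over w's path)

acts as the output embedding: `⟨e'(w), e(c)⟩` accumulates the per-node
logits of `P(w | c)`.

- **Pair classification** uses input vectors only.  Drugs of the same class
  share reaction contexts, so their input vectors cluster — a first-order
  effect — and the additive pair feature `e(a)+e(b)` separates classes.
- **Enrichment** scores drug→reaction affinity, which crosses the bipartite
  divide.  Nothing in the objective ties the *input* vectors of the two
  sides together: a drug's input vector aligns with the signed path nodes
  of its reactions, and the sign pattern is an artifact of where the
  Huffman tree happens to place them.  Empirically, ranking reactions by
  input–input cosine recovers some planted classes perfectly and others
  not at all (the per-class sign is effectively a coin flip), and more
  epochs do not change this.  The pipeline therefore ranks reactions by
  cosine between the additive pair embedding (input side) and the
  reaction's target-side embedding `e'(r)` — the quantity the trained
  model actually uses to score reactions — which recovers every planted
  class.  The enrichment API itself is agnostic: it takes any token→vector
  map.

## CM-TF-IDF baseline

Rows are all vocabulary terms (drugs and reactions jointly), columns are
reports, and a cell holds `(n_ij / Σ_k n_kj) · ln(|D| / df_i)`, zero
exactly where the term is absent.  The logarithm base is immaterial (any
base rescales all weights uniformly); natural log is used.  PCA runs on
the centered (not variance-scaled) term rows with a full SVD; the
per-component sign is fixed by making each component's largest-magnitude
loading positive, so the reduction is deterministic.  The output dimension
defaults to the skip-gram dimension so both feature sources feed the same
evaluation path.

## Labeling, classification, enrichment

A drug pair is positive for an event class when any of three strategies
fires: (1) either drug is in the class's curated drug list; (2) either
drug has a toxicity record whose text contains a class keyword
(case-insensitive substring); (3) the pair has an interaction record whose
description contains a class keyword.  The union defines the default
label; per-strategy labeling is available for source-wise counts.
Candidate pairs are those observed in two-drug reports whose drugs both
sit in the reference drug list (vocabulary drugs that also occur in the
interaction resource).  Negatives are all non-positive candidates,
subsampled (seeded) to match the positive count when balancing is on.

Classification is L2-regularised logistic regression (C = 1.0, lbfgs)
under stratified 10-fold cross-validation; AUROC is the Mann–Whitney rank
statistic with average ranks for ties, verified in tests against
brute-force concordant-pair counting.  Interaction dedup treats the pair
as unordered and the description case-insensitively, so mirrored records
collapse while genuinely different descriptions are kept.

Enrichment ranks all in-vocabulary reactions by cosine to the pair
embedding, truncates to the top 20 (ties broken lexicographically for
reproducibility), and calls the result valid if any ranked reaction maps
to the class's System Organ Class; reactions missing from the SOC map
never match.  Per-class accuracy is `n_valid / n_ddis`; the pooled row is
`Σ n_valid / Σ n_ddis` (a weighted average, not the mean of ratios),
reported to six decimals.

## Synthetic generator

The generator emulates a preprocessed two-drug report corpus with planted
class structure: `n_classes` classes each own a drug pool and a reaction
pool; each report picks a class (or background with probability 0.2),
fills its two drug slots from the class pool with probability `signal`
(else background), and draws 2–6 reactions from the class pool with a
per-reaction background substitution at `noise_rate`.  Resource files are
derived from the same ground truth: drug lists are the class pools;
toxicity records embed the class keyword for half of each pool; 40
keyword-bearing interaction records per class name class-drug pairs, plus
40 neutral background records so every labeling strategy has negatives;
the SOC map sends class reactions to the class's organ label and
background reactions to "Background disorders".

Defaults (5 classes × 40 drugs, 60 background drugs, 30 reactions/class,
100 background reactions, 2,000 reports) give every planted drug ~14
expected report occurrences — enough to survive frequency filtering at
threshold 5 while leaving realistic sampling noise.  The generator does
*not* model reporting biases, duplicate submissions, demographic fields,
free-text reaction strings, or Zipf-skewed token frequencies; passing
tests therefore show that the machinery recovers planted co-occurrence
structure under sampling noise, not that it would attain the same numbers
on a real spontaneous-report database.

### What the scaled-down study does and does not reproduce

At the study conditions (signal 0.9, noise 0.1, dim 50, 5 epochs) the
skip-gram features recover every planted class with mean 10-fold AUROC
≥ 0.99 and the enrichment accuracy over emitted interactions is 1.0.  The
TF-IDF baseline, however, is *not* worse here: a 510-term × 2,000-report
matrix is essentially low-rank and PCA to 50 components loses nothing, so
the baseline also reaches AUROC 1.0 (occasionally a hair above the
skip-gram mean).  The baseline's real-data weakness — the dimensionality
crush of projecting hundreds of thousands of report columns to ~100
components — only bites at corpus scales this desk-sized study does not
reach.  The comparison is retained and reported as measured.

## Numerical conventions and degenerate inputs

- Embedding files are plain text, 6-decimal fixed precision; round-trips
  agree to < 1e-6.
- All output files use fixed float formatting and deterministic ordering;
  the run log carries no timestamps, so identical seeded runs are
  byte-identical.
- Empty report sides are legal and contribute no pairs; an empty corpus,
  a single-token vocabulary, a zero vector in a cosine, out-of-range PCA
  dimensions, and folds with a single class all raise informative errors.
- Tokens appearing as drug in one report and reaction in another are a
  hard error (ambiguous kind); within one report this is rejected at
  parse time.  Whether a real corpus could contain such tokens is a
  format-level question; the strict reading was chosen because silent
  reclassification would corrupt the bipartite context rule.
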