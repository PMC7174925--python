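"""Drug-pair labeling, pair featurisation and cross-validated AUROC.

A drug pair is a *positive* for an adverse-event class when any of three
strategies fires:

1. SIDER list — either drug sits in the class's curated drug list;
2. toxicity — either drug has a toxicity record whose text contains a
   class keyword (case-insensitive substring);
3. DDI — the pair itself has an interaction record whose description
   contains a class keyword.

Pairs are featurised by elementwise addition of the two drug embeddings
(so features are symmetric in pair order) and scored with an
L2-regularised logistic regression under stratified 10-fold
cross-validation.  AUROC is the Mann-Whitney rank statistic with
average ranks for ties, i.e. the probability that a random positive
outscores a random negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .corpus_io import EventClass, LabelResources, ReportCorpus

__all__ = [
    "STRATEGIES",
    "Pair",
    "LabeledPairSet",
    "CVResult",
    "canonical_pair",
    "candidate_pairs",
    "label_pairs",
    "balance_negatives",
    "pair_features",
    "auroc_score",
    "crossval_auroc",
]

Pair = Tuple[str, str]

STRATEGIES = ("SIDER", "Toxicity", "DDI")


def canonical_pair(a: str, b: str) -> Pair:
    if a == b:
        raise ValueError(f"degenerate pair ({a!r}, {a!r})")
    return (a, b) if a < b else (b, a)


@dataclass
class LabeledPairSet:
    """Canonical pairs with labels and per-pair strategy provenance."""

    pairs: List[Pair]
    labels: Dict[Pair, int]  # 1 positive, 0 negative
    event_class: EventClass
    provenance: Dict[Pair, FrozenSet[str]] = field(default_factory=dict)

    @property
    def n_positive(self) -> int:
        return sum(self.labels[p] for p in self.pairs)

    @property
    def n_negative(self) -> int:
        return len(self.pairs) - self.n_positive


@dataclass
class CVResult:
    """Per-fold and mean AUROC plus pooled out-of-fold ROC points."""

    auroc_per_fold: List[float]
    mean_auroc: float
    roc_points: List[Tuple[float, float]]
    n_folds: int
    seed: int


def candidate_pairs(
    corpus: ReportCorpus, reference_drugs: Iterable[str]
) -> List[Pair]:
    """Unique canonical pairs from two-drug reports, restricted to a drug list.

    The reference drug list plays the role of the RDL: drugs that both
    survive frequency filtering and occur in the interaction resource.
    Order is first appearance in the corpus, for determinism.
    """
    ref = set(reference_drugs)
    seen: Dict[Pair, None] = {}
    for rep in corpus:
        if len(rep.drugs) != 2:
            continue
        a, b = rep.drugs
        if a in ref and b in ref:
            seen.setdefault(canonical_pair(a, b))
    return list(seen)


def _keyword_hit(text: str, keywords: Sequence[str]) -> bool:
    low = text.lower()
    return any(kw in low for kw in keywords)


def label_pairs(
    pairs: Sequence[Pair],
    resources: LabelResources,
    event_class: EventClass,
    strategies: Sequence[str] = STRATEGIES,
) -> LabeledPairSet:
    """Label pairs positive if ANY selected strategy fires; else negative.

    ``strategies`` restricts the union (e.g. ``("SIDER",)`` for
    per-strategy counts); provenance records which strategies fired for
    each positive.
    """
    unknown = set(strategies) - set(STRATEGIES)
    if unknown:
        raise ValueError(f"unknown strategies {sorted(unknown)}")
    sider = resources.sider_lists.get(event_class.name, frozenset())
    tox_drugs = {
        drug
        for drug, text in resources.toxicity_records
        if _keyword_hit(text, event_class.keywords)
    }
    ddi_pairs = {
        rec.pair
        for rec in resources.ddi_records
        if _keyword_hit(rec.description, event_class.keywords)
    }

    labels: Dict[Pair, int] = {}
    provenance: Dict[Pair, FrozenSet[str]] = {}
    uniq: Dict[Pair, None] = {}
    for p in pairs:
        p = canonical_pair(*p)
        if p in uniq:
            continue
        uniq.setdefault(p)
        fired = []
        if "SIDER" in strategies and (p[0] in sider or p[1] in sider):
            fired.append("SIDER")
        if "Toxicity" in strategies and (p[0] in tox_drugs or p[1] in tox_drugs):
            fired.append("Toxicity")
        if "DDI" in strategies and p in ddi_pairs:
            fired.append("DDI")
        labels[p] = 1 if fired else 0
        provenance[p] = frozenset(fired)
    return LabeledPairSet(
        pairs=list(uniq), labels=labels, event_class=event_class, provenance=provenance
    )


def balance_negatives(labelset: LabeledPairSet, seed: int) -> LabeledPairSet:
    """Subsample negatives (seeded) to match the number of positives."""
    positives = [p for p in labelset.pairs if labelset.labels[p] == 1]
    negatives = [p for p in labelset.pairs if labelset.labels[p] == 0]
    if len(negatives) > len(positives):
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(negatives), size=len(positives), replace=False)
        negatives = [negatives[i] for i in sorted(keep)]
    pairs = positives + negatives
    return LabeledPairSet(
        pairs=pairs,
        labels={p: labelset.labels[p] for p in pairs},
        event_class=labelset.event_class,
        provenance={p: labelset.provenance.get(p, frozenset()) for p in pairs},
    )


def pair_features(vectors: Mapping[str, np.ndarray], pair: Pair) -> np.ndarray:
    """Additive pair embedding: e(a) + e(b); symmetric in pair order."""
    a, b = pair
    for tok in (a, b):
        if tok not in vectors:
            raise KeyError(f"no embedding for drug {tok!r}")
    return np.asarray(vectors[a]) + np.asarray(vectors[b])


def auroc_score(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-statistic AUROC: P(score_pos > score_neg) with ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both classes present")
    ranks = rankdata(scores)
    u = np.sum(ranks[labels == 1]) - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def crossval_auroc(
    featureset: Mapping[Pair, np.ndarray],
    labelset: LabeledPairSet,
    n_folds: int = 10,
    seed: int = 0,
    C: float = 1.0,
) -> CVResult:
    """Stratified k-fold logistic regression, AUROC per held-out fold.

    Each fold fits on the remaining k-1 folds and is scored on the
    held-out pairs; splits are seeded and reproducible.  Raises if a
    fold ends up single-class (too few samples for the fold count).
    """
    if labelset.n_positive < 2 or labelset.n_negative < 2:
        raise ValueError("need at least 2 positives and 2 negatives")
    if min(labelset.n_positive, labelset.n_negative) < n_folds:
        raise ValueError(
            "stratification would leave a fold with a single class; "
            "use fewer folds or more data"
        )
    X = np.vstack([featureset[p] for p in labelset.pairs])
    y = np.asarray([labelset.labels[p] for p in labelset.pairs])
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_auc: List[float] = []
    oof_scores = np.zeros(len(y))
    for train_idx, test_idx in skf.split(X, y):
        if len(np.unique(y[test_idx])) < 2 or len(np.unique(y[train_idx])) < 2:
            raise ValueError(
                "a fold contains a single class; use fewer folds or more data"
            )
        clf = LogisticRegression(C=C, solver="lbfgs", max_iter=1000)
        clf.fit(X[train_idx], y[train_idx])
        scores = clf.predict_proba(X[test_idx])[:, 1]
        oof_scores[test_idx] = scores
        fold_auc.append(auroc_score(scores, y[test_idx]))
    fpr, tpr, _ = roc_curve(y, oof_scores)
    return CVResult(
        auroc_per_fold=fold_auc,
        mean_auroc=float(np.mean(fold_auc)),
        roc_points=list(zip(fpr.tolist(), tpr.tolist())),
        n_folds=n_folds,
        seed=seed,
    )
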