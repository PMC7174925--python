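"""Cosine-ranked description enrichment of drug-drug interactions.

Under the distributional hypothesis the additive pair embedding
e(a) + e(b) lies near the reactions the pair co-occurs with, so ranking
candidate reactions by

    cos(e(a) + e(b), e(r)) = sum_i (a_i + b_i) r_i / (||a + b|| ||r||)

surfaces reactions that plausibly describe the interaction.  An
enrichment is *valid* for an adverse-event class when at least one of
the top-K (default 20) reactions maps to the class's System Organ
Class; per-class accuracy is the fraction of evaluated interactions
with a valid enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np

from .corpus_io import EventClass
from .eval_classify import Pair, pair_features

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "AccuracyTable",
    "cosine",
    "rank_reactions",
    "validate_enrichment",
    "enrich_pair",
    "accuracy_table",
]


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity of two nonzero vectors of equal length."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"shape mismatch {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


@dataclass
class EnrichmentResult:
    """Top-K reactions for one pair with the SOC validity verdict."""

    pair: Pair
    ranked: List[Tuple[str, float]]  # (reaction, cosine), non-increasing
    valid: bool
    event_class: EventClass


@dataclass
class AccuracyTable:
    """Per-class (n_ddis, n_valid) with a pooled total row.

    The pooled accuracy is sum(n_valid) / sum(n_ddis) — a weighted
    average over classes, not the mean of per-class accuracies.
    """

    rows: Dict[str, Tuple[int, int]]  # class -> (n_ddis, n_valid)

    def accuracy(self, name: str) -> float:
        n, v = self.rows[name]
        return v / n

    @property
    def total_ddis(self) -> int:
        return sum(n for n, _ in self.rows.values())

    @property
    def total_valid(self) -> int:
        return sum(v for _, v in self.rows.values())

    @property
    def total_accuracy(self) -> float:
        return self.total_valid / self.total_ddis

    def format_tsv(self) -> str:
        lines = ["class\tn_ddis\tn_valid\taccuracy"]
        for name, (n, v) in self.rows.items():
            lines.append(f"{name}\t{n}\t{v}\t{v / n:.6f}")
        lines.append(
            f"Total\t{self.total_ddis}\t{self.total_valid}\t{self.total_accuracy:.6f}"
        )
        return "\n".join(lines) + "\n"


def rank_reactions(
    vectors: Mapping[str, np.ndarray],
    pair: Pair,
    reactions: Iterable[str],
    k: int = 20,
) -> List[Tuple[str, float]]:
    """Candidate reactions sorted by cosine to the pair embedding, top k.

    Ties are broken by token lexicographic order so rankings are
    reproducible.  An empty candidate set yields an empty ranking.
    """
    pv = pair_features(vectors, pair)
    scored = [(r, cosine(pv, vectors[r])) for r in reactions]
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored[:k]


def validate_enrichment(
    ranked: Sequence[Tuple[str, float]],
    soc_map: Mapping[str, str],
    event_class: EventClass,
) -> bool:
    """True iff any ranked reaction falls under the class's SOC label.

    Reactions absent from the SOC map never match (partial maps are
    expected, not an error).
    """
    return any(soc_map.get(r) == event_class.soc_label for r, _ in ranked)


def enrich_pair(
    vectors: Mapping[str, np.ndarray],
    pair: Pair,
    reactions: Iterable[str],
    soc_map: Mapping[str, str],
    event_class: EventClass,
    k: int = 20,
) -> EnrichmentResult:
    ranked = rank_reactions(vectors, pair, reactions, k)
    return EnrichmentResult(
        pair=pair,
        ranked=ranked,
        valid=validate_enrichment(ranked, soc_map, event_class),
        event_class=event_class,
    )


def accuracy_table(
    results_by_class: Mapping[str, Sequence[EnrichmentResult] | Tuple[int, int]],
) -> AccuracyTable:
    """Tabulate per-class enrichment accuracy with a pooled total.

    Each value is either the list of per-pair results for the class or a
    precomputed ``(n_ddis, n_valid)`` count pair (so externally tallied
    tables can be re-checked).  Classes with zero evaluated interactions
    are omitted with a warning.
    """
    rows: Dict[str, Tuple[int, int]] = {}
    for name, val in results_by_class.items():
        if isinstance(val, tuple):
            n, v = val
        else:
            n, v = len(val), sum(1 for r in val if r.valid)
        if not (0 <= v <= n):
            raise ValueError(f"class {name!r}: n_valid={v} outside [0, n_ddis={n}]")
        if n == 0:
            logger.warning("class %s has zero evaluated DDIs; omitted", name)
            continue
        rows[name] = (n, v)
    return AccuracyTable(rows=rows)
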