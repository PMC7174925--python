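"""Frequency-filtered vocabulary and the Huffman tree for hierarchical softmax.

Token frequency is *document* frequency: the number of reports a token
appears in (within-report duplicates are already collapsed, so this
coincides with raw multiplicity).  Tokens below ``min_count`` are
dropped from the vocabulary and ignored during training.

The Huffman tree assigns short codes to frequent tokens, so the
hierarchical-softmax path product is cheapest exactly where it is
evaluated most often.  Construction is the classical greedy merge of
the two lowest-count nodes; ties are broken by creation index (leaves
in vocabulary order first, then internal nodes in creation order) so
the tree is fully deterministic.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Dict, List, Tuple

from .corpus_io import ReportCorpus

__all__ = ["Vocabulary", "HuffmanTree", "build_vocab", "build_huffman"]

DRUG = "drug"
REACTION = "reaction"


@dataclass
class Vocabulary:
    """Retained tokens with counts, side-of-origin and dense indices."""

    tokens: List[str]
    counts: Dict[str, int]
    kind: Dict[str, str]  # token -> "drug" | "reaction"
    index: Dict[str, int]

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self.index

    @property
    def drugs(self) -> List[str]:
        return [t for t in self.tokens if self.kind[t] == DRUG]

    @property
    def reactions(self) -> List[str]:
        return [t for t in self.tokens if self.kind[t] == REACTION]

    def dump_tsv(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for tok in self.tokens:
                fh.write(f"{tok}\t{self.counts[tok]}\t{self.kind[tok]}\n")


@dataclass
class HuffmanTree:
    """Per-leaf binary codes and root-first internal-node paths.

    ``codes[token][i]`` is the branch taken at the i-th internal node of
    ``paths[token]``: 0 = left, 1 = right.  A full binary tree over
    ``n_leaves`` leaves has exactly ``n_leaves - 1`` internal nodes.
    """

    n_leaves: int
    codes: Dict[str, Tuple[int, ...]]
    paths: Dict[str, Tuple[int, ...]]

    @property
    def n_internal(self) -> int:
        return self.n_leaves - 1


def build_vocab(corpus: ReportCorpus, min_count: int) -> Vocabulary:
    """Count document frequencies and drop tokens seen in < min_count reports.

    A token observed as a drug in one report and as a reaction in another
    is ambiguous and raises ``ValueError``.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts: Dict[str, int] = {}
    kind: Dict[str, str] = {}
    for rep in corpus:
        for tok in rep.drugs:
            counts[tok] = counts.get(tok, 0) + 1
            if kind.setdefault(tok, DRUG) != DRUG:
                raise ValueError(
                    f"token {tok!r} appears as both drug and reaction across reports"
                )
        for tok in rep.reactions:
            counts[tok] = counts.get(tok, 0) + 1
            if kind.setdefault(tok, REACTION) != REACTION:
                raise ValueError(
                    f"token {tok!r} appears as both drug and reaction across reports"
                )
    tokens = [t for t in counts if counts[t] >= min_count]
    return Vocabulary(
        tokens=tokens,
        counts={t: counts[t] for t in tokens},
        kind={t: kind[t] for t in tokens},
        index={t: i for i, t in enumerate(tokens)},
    )


def build_huffman(vocab: Vocabulary) -> HuffmanTree:
    """Greedy optimal prefix code over the vocabulary counts.

    The two lowest-count nodes are merged repeatedly; the first node
    popped becomes the left (0) child.  Equal counts are resolved by
    creation index, making the tree a pure function of the vocabulary.
    """
    n = len(vocab)
    if n < 2:
        raise ValueError(
            "hierarchical softmax needs a vocabulary of at least 2 tokens"
        )
    # heap entries: (count, creation_index); leaves 0..n-1, internal n..2n-2
    heap: List[Tuple[int, int]] = [
        (vocab.counts[tok], i) for i, tok in enumerate(vocab.tokens)
    ]
    heapq.heapify(heap)
    children: Dict[int, Tuple[int, int]] = {}
    next_id = n
    while len(heap) > 1:
        ca, a = heapq.heappop(heap)
        cb, b = heapq.heappop(heap)
        children[next_id] = (a, b)
        heapq.heappush(heap, (ca + cb, next_id))
        next_id += 1
    root = heap[0][1]

    codes: Dict[str, Tuple[int, ...]] = {}
    paths: Dict[str, Tuple[int, ...]] = {}
    # iterative DFS from the root, accumulating the branch bits and the
    # internal-node indices (0-based: internal node id minus n_leaves)
    stack: List[Tuple[int, Tuple[int, ...], Tuple[int, ...]]] = [(root, (), ())]
    while stack:
        node, code, path = stack.pop()
        if node < n:
            codes[vocab.tokens[node]] = code
            paths[vocab.tokens[node]] = path
        else:
            left, right = children[node]
            stack.append((left, code + (0,), path + (node - n,)))
            stack.append((right, code + (1,), path + (node - n,)))
    return HuffmanTree(n_leaves=n, codes=codes, paths=paths)
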