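"""Modified skip-gram trainer with hierarchical softmax.

Standard skip-gram slides a +-n word window over running text.  Adverse
event reports have no word order worth preserving, but they do have a
bipartite structure: a set of drugs and a set of reactions.  The
modified context rule replaces the window with that structure — the
contexts of a drug are *all* reactions in the same report, and the
contexts of a reaction are all drugs.  Training maximises

    sum_{(w, c) in D} sum_{w_j in c} log P(w | w_j)

where P(w | w_j) is factorised over w's root-to-leaf path in a Huffman
tree: each internal node contributes sigma(<v_node, v_input>) when the
path branches left (bit 0) and sigma(-<v_node, v_input>) when it
branches right.  Optimisation is plain sequential SGD with a linearly
decaying learning rate, which makes training a pure function of the
corpus and the parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from .corpus_io import Report, ReportCorpus
from .vocab_huffman import HuffmanTree, Vocabulary, build_huffman, build_vocab

logger = logging.getLogger(__name__)

__all__ = [
    "TrainParams",
    "MSGModel",
    "enumerate_pairs",
    "hs_probability",
    "hs_log_prob_grad",
    "corpus_log_likelihood",
    "train",
]


@dataclass(frozen=True)
class TrainParams:
    """Hyperparameters of the embedding model.

    dim : embedding dimensionality (100 in the reference setting)
    alpha0 : starting learning rate, decayed linearly per pair update
    min_alpha : learning-rate floor
    epochs : full passes over the corpus
    min_count : minimum report frequency for a token to enter the vocabulary
    seed : seed for the embedding initialisation
    """

    dim: int = 100
    alpha0: float = 0.025
    min_alpha: float = 1e-4
    epochs: int = 5
    min_count: int = 10
    seed: int = 1

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if not (0 < self.min_alpha <= self.alpha0):
            raise ValueError("need 0 < min_alpha <= alpha0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")


@dataclass
class MSGModel:
    """Trained model: token input vectors plus Huffman internal-node vectors."""

    vocab: Vocabulary
    tree: HuffmanTree
    input_vectors: np.ndarray  # (n_tokens, dim)
    node_vectors: np.ndarray  # (n_internal, dim)
    params: TrainParams

    def vector(self, token: str) -> np.ndarray:
        return self.input_vectors[self.vocab.index[token]]

    def embeddings(self) -> Dict[str, np.ndarray]:
        """Token → input vector map (the downstream feature source)."""
        return {tok: self.input_vectors[i] for i, tok in enumerate(self.vocab.tokens)}

    def output_vector(self, token: str) -> np.ndarray:
        """Target-side embedding: the signed sum of the token's path-node vectors.

        Hierarchical softmax has no per-token output vector; its analogue
        is e'(w) = sum_i s_i * v_node_i over w's root-to-leaf path, with
        s_i = +1 for a left (0) branch and -1 for a right (1) branch, so
        that <e'(w), e(c)> accumulates the per-node logits of P(w | c).
        On a strictly bipartite corpus this is the representation that
        carries drug-to-reaction affinity; the input-input cosine between
        the two sides has an arbitrary per-cluster sign (see the methods
        note).
        """
        path = list(self.tree.paths[token])
        signs = 1.0 - 2.0 * np.asarray(self.tree.codes[token], dtype=float)
        return signs @ self.node_vectors[path]

    def enrichment_vectors(self) -> Dict[str, np.ndarray]:
        """Token → vector map for cosine enrichment.

        Drugs carry their input vectors (summed into the pair embedding);
        reactions carry their target-side embeddings, so the cosine ranks
        reactions the way the trained model scores them.
        """
        out: Dict[str, np.ndarray] = {}
        for tok in self.vocab.tokens:
            if self.vocab.kind[tok] == "reaction":
                out[tok] = self.output_vector(tok)
            else:
                out[tok] = self.vector(tok)
        return out


def enumerate_pairs(report: Report, vocab: Vocabulary) -> List[Tuple[str, str]]:
    """Directed (input, target) pairs for one report under the bipartite rule.

    Every in-vocabulary drug is paired with every in-vocabulary reaction
    in both directions; drug-drug and reaction-reaction pairs are never
    emitted.  Order is deterministic: all drug-input pairs first, then
    all reaction-input pairs, each side in report order.
    """
    drugs = [d for d in report.drugs if d in vocab]
    reactions = [r for r in report.reactions if r in vocab]
    pairs = [(d, r) for d in drugs for r in reactions]
    pairs += [(r, d) for r in reactions for d in drugs]
    return pairs


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


def hs_probability(model: MSGModel, target: str, input_token: str) -> float:
    """P(target | input) as the product of per-node sigmoids along the path."""
    h = model.vector(input_token)
    path = model.tree.paths[target]
    code = np.asarray(model.tree.codes[target], dtype=float)
    x = model.node_vectors[list(path)] @ h
    signs = 1.0 - 2.0 * code  # bit 0 -> +1, bit 1 -> -1
    return float(np.prod(_sigmoid(signs * x)))


def hs_log_prob_grad(
    model: MSGModel, target: str, input_token: str
) -> Tuple[float, np.ndarray, Dict[int, np.ndarray]]:
    """log P(target | input) with its analytic gradients.

    Returns (logp, d logp / d input_vector, {node index: d logp / d node_vector}).
    """
    h = model.vector(input_token)
    path = list(model.tree.paths[target])
    code = np.asarray(model.tree.codes[target], dtype=float)
    nodes = model.node_vectors[path]
    x = nodes @ h
    f = _sigmoid(x)
    logp = float(np.sum(np.log(np.where(code == 0, f, 1.0 - f))))
    g = (1.0 - code) - f  # d logp / d x at each node
    grad_h = g @ nodes
    grad_nodes = {p: g[i] * h for i, p in enumerate(path)}
    return logp, grad_h, grad_nodes


def corpus_log_likelihood(model: MSGModel, corpus: ReportCorpus) -> float:
    """Mean log P over all training pairs of the corpus (the SGD objective)."""
    total = 0.0
    n = 0
    for rep in corpus:
        for inp, tgt in enumerate_pairs(rep, model.vocab):
            total += float(np.log(hs_probability(model, tgt, inp)))
            n += 1
    if n == 0:
        raise ValueError("corpus yields no training pairs")
    return total / n


@dataclass
class _CompiledCorpus:
    """Index-form training pairs plus per-token path/code arrays."""

    inputs: np.ndarray  # (n_pairs,) token indices
    targets: np.ndarray  # (n_pairs,) token indices
    paths: List[np.ndarray] = field(default_factory=list)
    signs: List[np.ndarray] = field(default_factory=list)  # +1 for bit 0, -1 for bit 1
    codes: List[np.ndarray] = field(default_factory=list)


def _compile(corpus: ReportCorpus, vocab: Vocabulary, tree: HuffmanTree) -> _CompiledCorpus:
    inputs: List[int] = []
    targets: List[int] = []
    for rep in corpus:
        for inp, tgt in enumerate_pairs(rep, vocab):
            inputs.append(vocab.index[inp])
            targets.append(vocab.index[tgt])
    paths = [np.asarray(tree.paths[tok], dtype=np.intp) for tok in vocab.tokens]
    codes = [np.asarray(tree.codes[tok], dtype=np.float64) for tok in vocab.tokens]
    signs = [1.0 - 2.0 * c for c in codes]
    return _CompiledCorpus(
        inputs=np.asarray(inputs, dtype=np.intp),
        targets=np.asarray(targets, dtype=np.intp),
        paths=paths,
        signs=signs,
        codes=codes,
    )


def train(corpus: ReportCorpus, params: TrainParams) -> MSGModel:
    """Fit the model by sequential SGD over all (input, target) pairs.

    Input vectors start uniform in [-0.5/dim, 0.5/dim] from the seeded
    generator; internal-node vectors start at zero.  The learning rate
    decays linearly from ``alpha0`` to ``min_alpha`` over the total
    number of pair updates (pairs x epochs).  Updates are applied one
    pair at a time in corpus order, so the result is bit-reproducible
    from (corpus, params).
    """
    vocab = build_vocab(corpus, params.min_count)
    if len(vocab) < 2:
        raise ValueError(
            f"only {len(vocab)} token(s) survive min_count={params.min_count}; "
            "no trainable vocabulary"
        )
    tree = build_huffman(vocab)
    comp = _compile(corpus, vocab, tree)
    n_pairs = len(comp.inputs)
    if n_pairs == 0:
        raise ValueError(
            "corpus yields zero training pairs after frequency filtering; "
            f"min_count={params.min_count} is the likely cause"
        )

    rng = np.random.default_rng(params.seed)
    syn0 = (rng.random((len(vocab), params.dim)) - 0.5) / params.dim
    syn1 = np.zeros((tree.n_internal, params.dim))

    total_updates = n_pairs * params.epochs
    alpha_span = params.alpha0 - params.min_alpha
    t = 0
    for epoch in range(params.epochs):
        obj = 0.0
        for inp, tgt in zip(comp.inputs, comp.targets):
            alpha = params.alpha0 - alpha_span * (t / total_updates)
            t += 1
            path = comp.paths[tgt]
            code = comp.codes[tgt]
            h = syn0[inp].copy()
            nodes = syn1[path]
            f = 1.0 / (1.0 + np.exp(-(nodes @ h)))
            # objective bookkeeping: log sigma(sign * x) summed over the path
            obj += float(np.sum(np.log(np.where(code == 0.0, f, 1.0 - f))))
            g = ((1.0 - code) - f) * alpha
            syn0[inp] += g @ nodes
            syn1[path] += g[:, None] * h
        logger.info(
            "epoch %d/%d: mean log-likelihood %.4f, alpha %.5f",
            epoch + 1,
            params.epochs,
            obj / n_pairs,
            alpha,
        )
    return MSGModel(
        vocab=vocab, tree=tree, input_vectors=syn0, node_vectors=syn1, params=params
    )
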