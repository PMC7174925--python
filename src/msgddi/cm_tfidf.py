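"""Cooccurrence-matrix baseline: TF-IDF weighted term x report matrix + PCA.

The baseline featurises drugs and reactions jointly: each vocabulary
term is a row, each report a column, and the entry is

    tfidf(i, j) = (n_ij / sum_k n_kj) * ln(|D| / df_i)

with n_ij the number of times term i appears in report j (0 or 1 after
within-report duplicate collapse), |D| the number of reports and df_i
the number of reports containing term i.  Absent terms score exactly
zero.  PCA on the centered term rows compresses the report dimension to
fixed-length feature vectors comparable with the skip-gram embeddings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA

from .corpus_io import ReportCorpus
from .vocab_huffman import Vocabulary

__all__ = ["TfidfMatrix", "ReducedFeatures", "tfidf_weight", "build_matrix", "reduce_pca"]


def tfidf_weight(n_ij: int, report_total: int, n_reports: int, doc_freq: int) -> float:
    """TF-IDF of one (term, report) cell; zero when the term is absent."""
    if n_ij == 0:
        return 0.0
    if report_total == 0:
        raise ZeroDivisionError("report_total is 0 but n_ij > 0")
    if doc_freq < 1:
        raise ValueError("doc_freq must be >= 1 when the term occurs")
    return (n_ij / report_total) * math.log(n_reports / doc_freq)


@dataclass
class TfidfMatrix:
    """Sparse term x report TF-IDF weights with the raw counts behind them."""

    terms: List[str]
    n_reports: int
    term_counts: sp.csr_matrix  # raw n_ij (binary under set semantics)
    report_totals: np.ndarray  # (n_reports,) column sums of term_counts
    doc_freq: Dict[str, int]
    weights: sp.csr_matrix  # (n_terms, n_reports)


@dataclass
class ReducedFeatures:
    """PCA-compressed term vectors of length k."""

    vectors: Dict[str, np.ndarray]
    k: int
    explained_variance: np.ndarray
    # retained for reconstruction: centered_row ~= coords @ components
    components: np.ndarray = None  # type: ignore[assignment]
    mean: np.ndarray = None  # type: ignore[assignment]


def build_matrix(corpus: ReportCorpus, vocab: Vocabulary) -> TfidfMatrix:
    """Assemble the TF-IDF matrix over the vocabulary terms of a corpus.

    Counts follow set semantics (a term occurs 0 or 1 times per report);
    the general TF-IDF formula is kept so multiplicity corpora would
    also be handled.
    """
    if len(corpus) == 0:
        raise ValueError("cannot build a cooccurrence matrix from an empty corpus")
    n_terms, n_reports = len(vocab.tokens), len(corpus)
    rows: List[int] = []
    cols: List[int] = []
    for j, rep in enumerate(corpus):
        for tok in (*rep.drugs, *rep.reactions):
            i = vocab.index.get(tok)
            if i is not None:
                rows.append(i)
                cols.append(j)
    counts = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n_terms, n_reports)
    )
    report_totals = np.asarray(counts.sum(axis=0)).ravel()
    df = np.asarray((counts > 0).sum(axis=1)).ravel()

    weights = counts.tocoo(copy=True)
    idf = np.log(n_reports / df)
    weights.data = (
        weights.data / report_totals[weights.col] * idf[weights.row]
    )
    return TfidfMatrix(
        terms=list(vocab.tokens),
        n_reports=n_reports,
        term_counts=counts,
        report_totals=report_totals,
        doc_freq={tok: int(df[i]) for i, tok in enumerate(vocab.tokens)},
        weights=weights.tocsr(),
    )


def reduce_pca(matrix: TfidfMatrix, k: int) -> ReducedFeatures:
    """Project centered term rows onto the top-k principal axes.

    The per-component sign ambiguity is fixed by making each component's
    largest-magnitude loading positive, so the reduction is fully
    deterministic.
    """
    n_terms = len(matrix.terms)
    if not (1 <= k <= min(n_terms, matrix.n_reports)):
        raise ValueError(
            f"k={k} outside [1, min(n_terms={n_terms}, n_reports={matrix.n_reports})]"
        )
    X = matrix.weights.toarray()
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(X)
    # deterministic sign convention
    flip = np.sign(
        pca.components_[np.arange(k), np.argmax(np.abs(pca.components_), axis=1)]
    )
    flip[flip == 0] = 1.0
    coords *= flip
    components = pca.components_ * flip[:, None]
    return ReducedFeatures(
        vectors={tok: coords[i] for i, tok in enumerate(matrix.terms)},
        k=k,
        explained_variance=pca.explained_variance_.copy(),
        components=components,
        mean=pca.mean_.copy(),
    )
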