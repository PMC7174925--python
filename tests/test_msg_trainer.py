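import math

import numpy as np
import pytest

from msgddi.corpus_io import Report, ReportCorpus
from msgddi.msg_trainer import (
    MSGModel,
    TrainParams,
    corpus_log_likelihood,
    enumerate_pairs,
    hs_log_prob_grad,
    hs_probability,
    train,
)
from msgddi.vocab_huffman import build_huffman, build_vocab


def random_model(tokens, dim=6, seed=0):
    """A model with random parameters over an artificial vocabulary."""
    from msgddi.vocab_huffman import Vocabulary

    rng = np.random.default_rng(seed)
    vocab = Vocabulary(
        tokens=list(tokens),
        counts={t: int(rng.integers(1, 20)) for t in tokens},
        kind={t: "drug" for t in tokens},
        index={t: i for i, t in enumerate(tokens)},
    )
    tree = build_huffman(vocab)
    return MSGModel(
        vocab=vocab,
        tree=tree,
        input_vectors=rng.normal(size=(len(tokens), dim)),
        node_vectors=rng.normal(size=(tree.n_internal, dim)),
        params=TrainParams(dim=dim, min_count=1),
    )


def oracle_path_probability(model, target, input_token):
    """Independent scalar-loop recomputation of the path product."""
    h = model.input_vectors[model.vocab.index[input_token]]
    prob = 1.0
    for node, bit in zip(model.tree.paths[target], model.tree.codes[target]):
        x = float(np.dot(model.node_vectors[node], h))
        sig = 1.0 / (1.0 + math.exp(-x))
        prob *= sig if bit == 0 else (1.0 - sig)
    return prob


class TestEnumeratePairs:
    def test_single_drug_three_reactions(self):
        corpus = ReportCorpus((Report(("D1",), ("R1", "R2", "R3")),))
        vocab = build_vocab(corpus, 1)
        pairs = enumerate_pairs(corpus[0], vocab)
        assert len(pairs) == 6
        assert {t for i, t in pairs if i == "D1"} == {"R1", "R2", "R3"}

    def test_no_cross_side_pairs_without_reactions(self):
        corpus = ReportCorpus((Report(("D1", "D2"), ()), Report(("D1", "D2"), ("R",))))
        vocab = build_vocab(corpus, 1)
        assert enumerate_pairs(corpus[0], vocab) == []

    def test_two_by_two_gives_eight_directed_pairs(self):
        corpus = ReportCorpus((Report(("D1", "D2"), ("R1", "R2")),))
        vocab = build_vocab(corpus, 1)
        pairs = enumerate_pairs(corpus[0], vocab)
        assert len(pairs) == 8
        assert len(set(pairs)) == 8
        assert all(
            (i.startswith("D")) != (t.startswith("D")) for i, t in pairs
        )

    def test_out_of_vocab_tokens_skipped(self, tiny_corpus):
        vocab = build_vocab(tiny_corpus, min_count=2)  # D3, R3, R5 etc. dropped
        for rep in tiny_corpus:
            for i, t in enumerate_pairs(rep, vocab):
                assert i in vocab and t in vocab


class TestHSProbability:
    @pytest.mark.parametrize("n_tokens", [2, 5, 17, 64])
    def test_distribution_sums_to_one(self, n_tokens):
        model = random_model([f"w{i}" for i in range(n_tokens)], seed=n_tokens)
        total = sum(hs_probability(model, w, "w0") for w in model.vocab.tokens)
        assert abs(total - 1.0) < 1e-9

    def test_zero_vectors_two_leaves_gives_half(self):
        model = random_model(["a", "b"], dim=4)
        model.input_vectors[:] = 0.0
        model.node_vectors[:] = 0.0
        assert hs_probability(model, "a", "b") == pytest.approx(0.5)
        assert hs_probability(model, "b", "b") == pytest.approx(0.5)

    def test_matches_independent_path_product(self):
        model = random_model(["a", "b", "c", "d"], seed=3)
        for tgt in model.vocab.tokens:
            assert hs_probability(model, tgt, "c") == pytest.approx(
                oracle_path_probability(model, tgt, "c"), rel=1e-12
            )

    def test_unknown_token_raises(self):
        model = random_model(["a", "b"])
        with pytest.raises(KeyError):
            hs_probability(model, "zzz", "a")


class TestGradients:
    def test_analytic_gradients_match_central_differences(self):
        """HS log-probability gradients agree with finite differences to 1e-5."""
        model = random_model([f"w{i}" for i in range(6)], dim=5, seed=11)
        target, inp = "w3", "w1"
        eps = 1e-6
        logp, grad_h, grad_nodes = hs_log_prob_grad(model, target, inp)
        i_inp = model.vocab.index[inp]
        for d in range(5):
            model.input_vectors[i_inp][d] += eps
            up = math.log(hs_probability(model, target, inp))
            model.input_vectors[i_inp][d] -= 2 * eps
            down = math.log(hs_probability(model, target, inp))
            model.input_vectors[i_inp][d] += eps
            fd = (up - down) / (2 * eps)
            assert grad_h[d] == pytest.approx(fd, rel=1e-5, abs=1e-8)
        for node, g in grad_nodes.items():
            for d in range(5):
                model.node_vectors[node][d] += eps
                up = math.log(hs_probability(model, target, inp))
                model.node_vectors[node][d] -= 2 * eps
                down = math.log(hs_probability(model, target, inp))
                model.node_vectors[node][d] += eps
                fd = (up - down) / (2 * eps)
                assert g[d] == pytest.approx(fd, rel=1e-5, abs=1e-8)


class TestTrain:
    def test_objective_improves_after_training(self, tiny_corpus):
        params = TrainParams(dim=8, epochs=1, min_count=1, seed=5)
        trained = train(tiny_corpus, params)
        untrained = MSGModel(
            vocab=trained.vocab,
            tree=trained.tree,
            input_vectors=(
                np.random.default_rng(5).random((len(trained.vocab), 8)) - 0.5
            )
            / 8,
            node_vectors=np.zeros_like(trained.node_vectors),
            params=params,
        )
        assert corpus_log_likelihood(trained, tiny_corpus) > corpus_log_likelihood(
            untrained, tiny_corpus
        )

    def test_same_seed_is_bit_identical(self, tiny_corpus):
        params = TrainParams(dim=8, epochs=2, min_count=1, seed=42)
        m1 = train(tiny_corpus, params)
        m2 = train(tiny_corpus, params)
        assert np.array_equal(m1.input_vectors, m2.input_vectors)
        assert np.array_equal(m1.node_vectors, m2.node_vectors)

    def test_zero_pairs_names_min_count(self):
        corpus = ReportCorpus((Report(("D",), ()), Report((), ("R",))))
        with pytest.raises(ValueError, match="min_count|vocabulary"):
            train(corpus, TrainParams(dim=4, min_count=5))

    def test_objective_non_decreasing_over_epochs(self, tiny_corpus):
        """With a small learning rate the SGD objective rises epoch over
        epoch in at least 95% of seeded runs."""
        ok = 0
        seeds = range(20)
        for seed in seeds:
            base = TrainParams(
                dim=6, epochs=1, min_count=1, seed=seed, alpha0=0.01, min_alpha=0.009
            )
            values = []
            for epochs in (1, 2, 3):
                m = train(
                    tiny_corpus,
                    TrainParams(
                        dim=6,
                        epochs=epochs,
                        min_count=1,
                        seed=seed,
                        alpha0=0.01,
                        min_alpha=0.009,
                    ),
                )
                values.append(corpus_log_likelihood(m, tiny_corpus))
            if values[0] <= values[1] <= values[2]:
                ok += 1
        assert ok >= 0.95 * len(list(seeds))

    def test_token_relabeling_permutes_embeddings(self, tiny_corpus):
        params = TrainParams(dim=6, epochs=2, min_count=1, seed=9)
        m1 = train(tiny_corpus, params)
        mapping = {t: f"x_{t}" for r in tiny_corpus for t in (*r.drugs, *r.reactions)}
        relabeled = ReportCorpus(
            tuple(
                Report(
                    tuple(mapping[d] for d in r.drugs),
                    tuple(mapping[x] for x in r.reactions),
                )
                for r in tiny_corpus
            )
        )
        m2 = train(relabeled, params)
        for tok in m1.vocab.tokens:
            assert np.array_equal(m1.vector(tok), m2.vector(mapping[tok]))

    def test_planted_cooccurrence_is_recovered(self):
        """A drug that only ever co-occurs with one reaction ends up closer
        to it (cosine of input vs target-side embedding) than to the 95th
        percentile of non-co-occurring reactions."""
        rng = np.random.default_rng(123)
        reports = [Report(("D*",), ("R*",)) for _ in range(200)]
        noise_drugs = [f"d{i}" for i in range(10)]
        noise_reactions = [f"r{i}" for i in range(20)]
        for _ in range(200):
            ds = rng.choice(noise_drugs, size=2, replace=False)
            rs = rng.choice(noise_reactions, size=3, replace=False)
            reports.append(Report(tuple(ds), tuple(rs)))
        corpus = ReportCorpus(tuple(reports))
        model = train(corpus, TrainParams(dim=20, epochs=5, min_count=1, seed=7))

        def cos(u, v):
            return float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))

        d = model.vector("D*")
        target = cos(d, model.output_vector("R*"))
        others = sorted(cos(d, model.output_vector(r)) for r in noise_reactions)
        assert target > others[int(0.95 * len(others))]
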