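"""Featurization, classifier scoring, prior seeding and the screening loop."""

import math
import warnings

import numpy as np
import pytest

from screensim import (
    MetricConfig,
    PriorSet,
    SimulationConfig,
    fit_features,
    run_batch,
    select_priors,
    separable_config,
    simulate_screening,
    train_and_score,
    generate_corpus,
    wss,
)
from screensim.al_engine import _trace_rng
from screensim.corpus_io import Corpus, Record
from screensim.exceptions import (
    ConfigurationError,
    FeaturizationError,
    InfeasibleSimulationError,
)


def make_corpus(texts, labels, column="label_fulltext"):
    records = [
        Record(f"r{i}", f"title {i}", text, {column: lab})
        for i, (text, lab) in enumerate(zip(texts, labels))
    ]
    return Corpus(records, [column])


class TestFitFeatures:
    def test_matches_hand_computed_tfidf(self):
        texts = ["apple banana apple", "banana cherry", "cherry cherry dates"]
        matrix, vocab = fit_features(texts)
        # independent hand evaluation: tf * (ln((1+D)/(1+df)) + 1), l2 rows
        docs = [t.split() for t in texts]
        terms = sorted({w for d in docs for w in d})
        df = {t: sum(t in d for d in docs) for t in terms}
        expected = np.zeros((3, len(terms)))
        for i, doc in enumerate(docs):
            for j, term in enumerate(terms):
                tf = doc.count(term)
                expected[i, j] = tf * (math.log((1 + 3) / (1 + df[term])) + 1)
            expected[i] /= np.linalg.norm(expected[i])
        got = np.zeros_like(expected)
        for j, term in enumerate(terms):
            got[:, j] = matrix[:, vocab[term]].toarray().ravel()
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_disjoint_vocabularies_are_orthogonal(self):
        matrix, _ = fit_features(["aa bb cc", "dd ee ff"])
        dot = (matrix[0] @ matrix[1].T).toarray()[0, 0]
        assert dot == 0.0

    def test_ubiquitous_term_gets_unit_idf(self):
        # one-term documents: weight is tf * idf, then l2-normalized to 1;
        # with the term in every document the smoothed idf factor is 1, so
        # the un-normalized weight equals the raw term count
        matrix, vocab = fit_features(["common common", "common"])
        assert matrix.shape[1] == 1
        np.testing.assert_allclose(matrix.toarray().ravel(), [1.0, 1.0])

    def test_no_valid_tokens_raises(self):
        with pytest.raises(FeaturizationError):
            fit_features(["a b c", "x y"])  # all tokens shorter than 2 chars

    def test_empty_input_raises(self):
        with pytest.raises(FeaturizationError):
            fit_features(["", "   "])


class TestTrainAndScore:
    def setup_method(self):
        self.texts = [
            "blue blue blue",  # relevant prior
            "red red red",  # irrelevant prior
            "blue blue blue",  # candidate twin of relevant
            "red red red",  # candidate twin of irrelevant
            "red red red",  # identical to previous candidate
        ]
        self.matrix, _ = fit_features(self.texts)
        self.config = SimulationConfig()

    def test_relevant_twin_outscores_irrelevant_twin(self):
        scores = train_and_score(self.matrix, [0, 1], [1, 0], self.config, [2, 3])
        assert scores[0] > scores[1]

    def test_identical_rows_get_identical_scores(self):
        scores = train_and_score(self.matrix, [0, 1], [1, 0], self.config, [3, 4])
        assert scores[0] == scores[1]

    def test_empty_candidate_set(self):
        scores = train_and_score(self.matrix, [0, 1], [1, 0], self.config, [])
        assert scores.size == 0

    def test_single_class_training_raises(self):
        with pytest.raises(InfeasibleSimulationError):
            train_and_score(self.matrix, [0, 2], [1, 1], self.config, [3])


class TestSelectPriors:
    def _corpus(self, n_rel, n_irr):
        labels = [1] * n_rel + [0] * n_irr
        texts = [f"token{i} filler" for i in range(len(labels))]
        return make_corpus(texts, labels)

    def test_one_relevant_plus_ten_irrelevant(self):
        prior = select_priors(self._corpus(5, 20), "label_fulltext", seed=1)
        assert len(prior.irrelevant_ids) == 10
        assert prior.relevant_id not in prior.irrelevant_ids
        assert len(set(prior.irrelevant_ids)) == 10

    def test_single_relevant_is_infeasible(self):
        with pytest.raises(InfeasibleSimulationError, match="relevant"):
            select_priors(self._corpus(1, 20), "label_fulltext", seed=1)

    def test_nine_irrelevant_is_infeasible(self):
        with pytest.raises(InfeasibleSimulationError):
            select_priors(self._corpus(5, 9), "label_fulltext", seed=1)

    def test_prior_set_rejects_overlap(self):
        with pytest.raises(ConfigurationError):
            PriorSet("a", ("a", "b"), seed=0)


class TestSimulateScreening:
    def test_separable_corpus_finds_all_relevant_first(self, separable_corpus):
        stage = "label_fulltext"
        config = SimulationConfig(stage=stage, seed=11)
        prior = select_priors(separable_corpus, stage, seed=11)
        trace = simulate_screening(separable_corpus, stage, prior, config)
        r = trace.r_pool
        assert r >= 2
        assert trace.labels_in_order[:r].all()
        assert not trace.labels_in_order[r:].any()

    def test_trace_is_permutation_of_pool(self, noisy_corpus):
        stage = "label_fulltext"
        config = SimulationConfig(stage=stage, seed=5)
        prior = select_priors(noisy_corpus, stage, seed=5)
        trace = simulate_screening(noisy_corpus, stage, prior, config)
        pool_ids = set(noisy_corpus.ids()) - set(prior.all_ids)
        assert set(trace.ordered_ids) == pool_ids
        assert len(trace.ordered_ids) == len(pool_ids)
        labels = dict(zip(noisy_corpus.ids(), noisy_corpus.labels(stage)))
        assert trace.r_pool == sum(labels[i] for i in pool_ids)

    def test_deterministic_under_fixed_inputs(self, noisy_corpus):
        stage = "label_fulltext"
        config = SimulationConfig(stage=stage, seed=9)
        prior = select_priors(noisy_corpus, stage, seed=9)
        t1 = simulate_screening(noisy_corpus, stage, prior, config)
        t2 = simulate_screening(noisy_corpus, stage, prior, config)
        assert t1.ordered_ids == t2.ordered_ids
        assert np.array_equal(t1.labels_in_order, t2.labels_in_order)

    def test_identical_texts_follow_seeded_shuffle_order(self):
        n = 30
        labels = [1, 1] + [0] * (n - 2)
        corpus = Corpus(
            [
                Record(f"r{i}", "same title", "same words everywhere", {"label_fulltext": lab})
                for i, lab in enumerate(labels)
            ],
            ["label_fulltext"],
        )
        config = SimulationConfig(stage="label_fulltext", seed=3)
        prior = select_priors(corpus, "label_fulltext", seed=3)
        trace = simulate_screening(corpus, "label_fulltext", prior, config)
        # reconstruct the tie-break permutation the engine used
        ids = corpus.ids()
        pool_pos = [i for i, rid in enumerate(ids) if rid not in set(prior.all_ids)]
        rng = _trace_rng(prior, config)
        tiebreak = dict(zip(pool_pos, rng.permutation(len(pool_pos))))
        expected = [ids[p] for p in sorted(pool_pos, key=tiebreak.get)]
        assert trace.ordered_ids == expected

    def test_random_scorer_matches_order_statistic_expectation(self):
        """With a uniform-random scorer the screening order is a uniform
        permutation, so mean WSS@95 must match the closed-form
        negative-hypergeometric expectation of the m-th relevant position."""
        n = 71  # pool of 60 after removing 1 relevant + 10 irrelevant priors
        labels = [1] * 6 + [0] * (n - 6)
        corpus = make_corpus([f"word{i} tok{i % 7}" for i in range(n)], labels)
        stage = "label_fulltext"
        prior = select_priors(corpus, stage, seed=0)
        features, _ = fit_features(corpus.texts())
        rng = np.random.default_rng(123)

        def random_scorer(feats, tr_idx, tr_lab, cfg, cand):
            return rng.random(len(cand))

        values = []
        for seed in range(250):
            config = SimulationConfig(stage=stage, seed=seed)
            trace = simulate_screening(
                corpus, stage, prior, config, features=features, score_fn=random_scorer
            )
            values.append(wss(trace, MetricConfig()))
        n_pool, r_pool = 60, 5
        m = math.ceil(0.95 * r_pool)
        expected = 100 * (1 - (m * (n_pool + 1) / (r_pool + 1)) / n_pool - 0.05)
        sem = np.std(values, ddof=1) / math.sqrt(len(values))
        assert np.mean(values) == pytest.approx(expected, abs=4 * sem + 0.5)


class TestRunBatch:
    def test_all_runs_vary_relevant_and_share_irrelevant(self, separable_corpus):
        stage = "label_fulltext"
        config = SimulationConfig(stage=stage, seed=2)
        traces = run_batch(separable_corpus, stage, config, n_runs="all")
        labels = dict(zip(separable_corpus.ids(), separable_corpus.labels(stage)))
        n_rel = sum(v == 1 for v in labels.values())
        assert len(traces) == n_rel
        rel_priors = {t.prior.relevant_id for t in traces}
        assert len(rel_priors) == n_rel
        irr_sets = {t.prior.irrelevant_ids for t in traces}
        assert len(irr_sets) == 1
        assert [t.run_index for t in traces] == list(range(n_rel))

    def test_single_run(self, separable_corpus):
        config = SimulationConfig(stage="label_fulltext", seed=2)
        traces = run_batch(separable_corpus, "label_fulltext", config, n_runs=1)
        assert len(traces) == 1

    def test_excess_runs_clamped_with_warning(self, separable_corpus):
        config = SimulationConfig(stage="label_fulltext", seed=2)
        with pytest.warns(UserWarning, match="clamp"):
            traces = run_batch(separable_corpus, "label_fulltext", config, n_runs=10**6)
        labels = separable_corpus.labels("label_fulltext")
        assert len(traces) == sum(v == 1 for v in labels)


class TestSeparableEveryRunNearMax:
    def test_wss_at_least_ninety_percent_of_theoretical_max(self):
        corpus = generate_corpus(
            separable_config(n_records=120, prevalence=0.07, seed=8)
        )
        config = SimulationConfig(stage="label_fulltext", seed=8)
        traces = run_batch(corpus, "label_fulltext", config, n_runs=3)
        for trace in traces:
            m = math.ceil(0.95 * trace.r_pool)
            theoretical_max = 100 * (1 - m / trace.n_pool - 0.05)
            assert wss(trace) >= 0.9 * theoretical_max
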