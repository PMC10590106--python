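import numpy as np
import pytest

from patternwalk import (
    EmbeddingMatrix,
    KnowledgeGraph,
    SplitSpec,
    evaluate,
    hadamard_features,
    predict_links,
    rank_auc,
    replicate_overlap,
    sample_negatives,
    split_positive_edges,
    train_classifier,
)
from patternwalk.linkpred import (
    DegenerateTrainingError,
    ExhaustionError,
    LinkExample,
    LinkPredictionError,
    MetricError,
    OneVsRestModel,
    SplitError,
    build_examples,
)


def emb_of(vectors: dict) -> EmbeddingMatrix:
    vocab = sorted(vectors)
    return EmbeddingMatrix(vocab, np.array([vectors[w] for w in vocab], dtype=float))


@pytest.fixture
def bipartite_graph():
    nodes = {f"p{i}": "Protein" for i in range(6)} | {f"w{i}": "Pathway" for i in range(3)}
    triples = [(f"p{i}", "hasPathway", f"w{i % 3}") for i in range(6)]
    return KnowledgeGraph(nodes, triples)


class TestHadamard:
    def test_elementwise_product(self):
        emb = emb_of({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert list(hadamard_features(emb, "a", "b")) == [4, 10, 18]

    def test_zeros_annihilate(self):
        emb = emb_of({"a": [1, 2, 3], "z": [0, 0, 0]})
        assert list(hadamard_features(emb, "a", "z")) == [0, 0, 0]

    def test_ones_identity(self):
        emb = emb_of({"a": [1.5, -2, 3], "one": [1, 1, 1]})
        assert list(hadamard_features(emb, "a", "one")) == [1.5, -2, 3]


class TestSplit:
    def test_half_split_disjoint(self, bipartite_graph):
        train, test = split_positive_edges(bipartite_graph, "hasPathway", SplitSpec(0.5, seed=0))
        assert len(train) == 3 and len(test) == 3
        assert not (set(train) & set(test))
        assert sorted(train + test) == sorted(
            t for t in bipartite_graph.triples if t[1] == "hasPathway"
        )

    def test_same_seed_same_split(self, bipartite_graph):
        s = SplitSpec(0.5, seed=42)
        assert split_positive_edges(bipartite_graph, "hasPathway", s) == split_positive_edges(
            bipartite_graph, "hasPathway", s
        )

    def test_single_edge_cannot_split(self):
        g = KnowledgeGraph({"p": "Protein", "w": "Pathway"}, [("p", "hasPathway", "w")])
        with pytest.raises(SplitError):
            split_positive_edges(g, "hasPathway", SplitSpec(0.5, seed=0))

    def test_absent_relation_is_error(self, bipartite_graph):
        with pytest.raises(LinkPredictionError):
            split_positive_edges(bipartite_graph, "nope", SplitSpec(0.5, seed=0))


class TestNegatives:
    def test_only_two_non_edges(self):
        g = KnowledgeGraph(
            {"p1": "Protein", "p2": "Protein", "w1": "Pathway", "w2": "Pathway"},
            [("p1", "hasPathway", "w1"), ("p2", "hasPathway", "w2")],
        )
        neg = sample_negatives(g, "hasPathway", "Protein", "Pathway", 2, seed=0)
        assert sorted(neg) == [("p1", "w2"), ("p2", "w1")]

    def test_exhaustion_error(self):
        g = KnowledgeGraph(
            {"p1": "Protein", "w1": "Pathway", "w2": "Pathway"},
            [("p1", "hasPathway", "w1"), ("p1", "hasPathway", "w2")],
        )
        with pytest.raises(ExhaustionError):
            sample_negatives(g, "hasPathway", "Protein", "Pathway", 1, seed=0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_sampled_negatives_never_positive(self, bipartite_graph, seed):
        positives = {(h, t) for h, r, t in bipartite_graph.triples if r == "hasPathway"}
        neg = sample_negatives(bipartite_graph, "hasPathway", "Protein", "Pathway", 8, seed=seed)
        assert len(neg) == 8
        assert len(set(neg)) == 8
        assert not (set(neg) & positives)

    def test_forbidden_pairs_excluded(self, bipartite_graph):
        forbidden = {("p0", "w1"), ("p0", "w2")}
        neg = sample_negatives(
            bipartite_graph, "hasPathway", "Protein", "Pathway", 5, seed=3, forbidden=forbidden
        )
        assert not (set(neg) & forbidden)


class TestClassifier:
    def _separable_examples(self, n=40, d=6, seed=0):
        rng = np.random.default_rng(seed)
        pos = rng.normal(2, 0.3, size=(n, d))
        neg = rng.normal(-2, 0.3, size=(n, d))
        exs = [LinkExample(f"p{i}", "w", 1, pos[i]) for i in range(n)]
        exs += [LinkExample(f"q{i}", "w", 0, neg[i]) for i in range(n)]
        return exs

    def test_separable_training_accuracy(self):
        exs = self._separable_examples()
        clf = train_classifier(exs, seed=0)
        X = np.array([e.feature for e in exs])
        y = np.array([e.label for e in exs])
        assert (clf.predict(X) == y).all()

    def test_single_label_is_degenerate(self):
        exs = [LinkExample("a", "w", 1, np.ones(3))] * 4
        with pytest.raises(DegenerateTrainingError):
            train_classifier(exs, seed=0)

    def test_null_features_give_chance_auc(self):
        """Labels independent of features: CV AUC stays near 0.5."""
        from patternwalk.linkpred import cross_validate

        rng = np.random.default_rng(7)
        exs = [
            LinkExample(f"n{i}", "w", int(rng.random() < 0.5), rng.normal(size=8))
            for i in range(400)
        ]
        res = cross_validate(exs, folds=5, seed=7)
        assert 0.4 <= res["auc"] <= 0.6

    def test_ovr_one_model_per_class(self):
        rng = np.random.default_rng(1)
        exs = []
        for ci, cls in enumerate(["w1", "w2", "w3"]):
            for i in range(10):
                exs.append(LinkExample(f"p{ci}_{i}", cls, 1, rng.normal(ci, 0.2, size=4)))
        for i in range(30):
            exs.append(LinkExample(f"n{i}", "w1", 0, rng.normal(-3, 0.2, size=4)))
        model = train_classifier(exs, mode="one-vs-rest", seed=0)
        assert isinstance(model, OneVsRestModel)
        assert len(model) == 3


class TestPredict:
    @pytest.fixture
    def fitted(self):
        exs = TestClassifier()._separable_examples()
        clf = train_classifier(exs, seed=0)
        emb = emb_of({"hi": [2.0] * 6, "lo": [-2.0] * 6, "one": [1.0] * 6})
        return clf, emb

    def test_cutoff_one_empty(self, fitted):
        clf, emb = fitted
        assert predict_links(clf, emb, [("hi", "one")], cutoff=1.0) == []

    def test_cutoff_zero_returns_all(self, fitted):
        clf, emb = fitted
        recs = predict_links(clf, emb, [("hi", "one"), ("lo", "one")], cutoff=0.0)
        assert len(recs) == 2
        assert recs[0].confidence >= recs[1].confidence

    def test_strict_cutoff_boundary(self):
        class Fixed:
            def __init__(self, probs):
                self.probs = probs
                self.i = 0

            def predict_proba(self, X):
                p = self.probs[self.i]
                self.i += 1
                return np.array([[1 - p, p]])

        emb = emb_of({"a": [1.0], "b": [1.0], "c": [1.0], "w": [1.0]})
        clf = Fixed([0.96, 0.95, 0.10])
        recs = predict_links(clf, emb, [("a", "w"), ("b", "w"), ("c", "w")], cutoff=0.95)
        assert [(r.protein, round(r.confidence, 2)) for r in recs] == [("a", 0.96)]


class TestEvaluate:
    def _examples(self, scores, labels):
        # classifier stub scoring by first feature coordinate
        exs = [
            LinkExample(f"n{i}", "w", lab, np.array([s]))
            for i, (s, lab) in enumerate(zip(scores, labels))
        ]

        class ByFeature:
            def predict_proba(self, X):
                return np.column_stack([1 - X[:, 0], X[:, 0]])

        return ByFeature(), exs

    def test_perfect_separation(self):
        clf, exs = self._examples([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        res = evaluate(clf, exs, folds=2)
        assert res["auc"] == 1.0
        assert res["f1"] == 1.0

    def test_all_tied_scores_auc_half(self):
        clf, exs = self._examples([0.4] * 6, [1, 1, 1, 0, 0, 0])
        assert evaluate(clf, exs, folds=2)["auc"] == 0.5

    def test_hand_computed_inversion(self):
        clf, exs = self._examples([0.9, 0.8, 0.7, 0.2], [1, 1, 0, 0])
        assert evaluate(clf, exs, folds=2)["auc"] == 1.0
        clf, exs = self._examples([0.9, 0.7, 0.8, 0.2], [1, 1, 0, 0])
        assert evaluate(clf, exs, folds=2)["auc"] == 0.75

    def test_single_label_test_set_is_metric_error(self):
        clf, exs = self._examples([0.9, 0.8], [1, 1])
        with pytest.raises(MetricError):
            evaluate(clf, exs, folds=2)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_auc_equals_pairwise_ordering_oracle(self, seed):
        """rank_auc equals the brute-force fraction of correctly ordered
        positive-negative pairs (ties half) on random sets of <= 50."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 51))
        scores = np.round(rng.random(n), 2)  # rounding forces ties
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        correct = 0.0
        pairs = 0
        for sp in scores[labels == 1]:
            for sn in scores[labels == 0]:
                pairs += 1
                correct += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
        assert rank_auc(scores, labels) == pytest.approx(correct / pairs, abs=1e-12)


class TestOverlap:
    def test_intersection_counts(self):
        sets = [{("A", "w"), ("B", "w")}, {("A", "w"), ("C", "w")}, {("A", "w")}]
        res = replicate_overlap(sets)
        assert res["all_overlap"] == [("A", "w")]
        assert res["all_overlap_count"] == 1
        assert res["per_protein"]["A"]["overlap_pct"] == 100.0

    def test_identical_sets_100_percent(self):
        s = {("A", "w1"), ("A", "w2"), ("B", "w1")}
        res = replicate_overlap([set(s), set(s), set(s)])
        assert all(v["overlap_pct"] == 100.0 for v in res["per_protein"].values())
        assert res["all_overlap_count"] == 3

    def test_disjoint_sets_zero(self):
        res = replicate_overlap([{("A", "w1")}, {("A", "w2")}])
        assert res["all_overlap_count"] == 0
        assert res["per_protein"]["A"]["overlap_pct"] == 0.0

    def test_fewer_than_two_sets_rejected(self):
        with pytest.raises(LinkPredictionError):
            replicate_overlap([{("A", "w1")}])


class TestBuildExamples:
    def test_labels_and_features(self):
        emb = emb_of({"p": [1, 2], "w": [3, 4], "q": [0, 1]})
        exs = build_examples(emb, [("p", "w")], [("q", "w")])
        assert [e.label for e in exs] == [1, 0]
        assert list(exs[0].feature) == [3, 8]
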