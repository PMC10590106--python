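"""Link prediction from node embeddings.

A candidate protein-pathway pair is featurized as the Hadamard
(elementwise) product of the two node vectors and scored by logistic
regression.  Negatives are sampled under the closed-world assumption:
a typed pair with no edge of the relation of interest is treated as a
true negative, and as many negatives are drawn as there are positives.

Two formulations are provided: a single binary classifier over pair
features (default) and a one-vs-rest variant with one binary model per
pathway class, where each class's negative count matches its positive
count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score

from .embedding import EmbeddingMatrix
from .kg import KnowledgeGraph


class LinkPredictionError(Exception):
    pass


class SplitError(LinkPredictionError):
    pass


class ExhaustionError(LinkPredictionError):
    """The typed non-edge space is smaller than the requested sample."""


class DegenerateTrainingError(LinkPredictionError):
    pass


class MetricError(LinkPredictionError):
    pass


@dataclass(frozen=True)
class SplitSpec:
    holdout_fraction: float = 0.5
    seed: int = 0
    folds: int = 10

    def __post_init__(self):
        if not 0.0 < self.holdout_fraction < 1.0:
            raise SplitError("holdout_fraction must be in (0, 1)")
        if self.folds < 2:
            raise SplitError("folds must be >= 2")


@dataclass(frozen=True)
class LinkExample:
    head: str
    tail: str
    label: int  # 1 positive, 0 negative
    feature: np.ndarray

    def __post_init__(self):
        if self.label not in (0, 1):
            raise LinkPredictionError("label must be 0 or 1")


@dataclass(frozen=True)
class PredictionRecord:
    protein: str
    pathway: str
    confidence: float
    metadata: dict = field(default_factory=dict, compare=False)


def hadamard_features(emb: EmbeddingMatrix, head: str, tail: str) -> np.ndarray:
    """Elementwise product of the two node vectors."""
    return emb[head] * emb[tail]


def split_positive_edges(
    graph: KnowledgeGraph, relation: str, spec: SplitSpec
) -> tuple[list[tuple[str, str, str]], list[tuple[str, str, str]]]:
    """Seeded disjoint (train, test) partition of the relation's edges.

    Test edges must be removed from the graph before walking so the
    embedding never sees them (use ``graph.without_edges(test)``).
    """
    edges = sorted(t for t in graph.triples if t[1] == relation)
    if not edges:
        raise LinkPredictionError(f"relation {relation!r} absent from graph")
    if len(edges) < 2:
        raise SplitError("need >= 2 edges to hold any out")
    n_test = round(spec.holdout_fraction * len(edges))
    n_test = min(max(n_test, 1), len(edges) - 1)
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(edges))
    test = [edges[i] for i in sorted(order[:n_test])]
    train = [edges[i] for i in sorted(order[n_test:])]
    return train, test


def sample_negatives(
    graph: KnowledgeGraph,
    relation: str,
    head_type: str,
    tail_type: str,
    count: int,
    seed: int,
    forbidden: Optional[set[tuple[str, str]]] = None,
) -> list[tuple[str, str]]:
    """Seeded typed non-edges under the closed-world assumption.

    ``forbidden`` extends the positive set (e.g. held-out test edges that
    the graph no longer contains but that must not be sampled).
    """
    heads = graph.nodes_of_type(head_type)
    tails = graph.nodes_of_type(tail_type)
    positives = {(h, t) for h, r, t in graph.triples if r == relation}
    positives |= {(t, h) for h, t in positives}
    if forbidden:
        positives |= set(forbidden)
        positives |= {(t, h) for h, t in forbidden}
    pool = [(h, t) for h in heads for t in tails if h != t and (h, t) not in positives]
    if len(pool) < count:
        raise ExhaustionError(f"only {len(pool)} typed non-edges available, {count} requested")
    pool.sort()
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=count, replace=False)
    return [pool[i] for i in sorted(idx)]


def build_examples(
    emb: EmbeddingMatrix,
    positives: Sequence[tuple[str, str]],
    negatives: Sequence[tuple[str, str]],
) -> list[LinkExample]:
    out = []
    for h, t in positives:
        out.append(LinkExample(h, t, 1, hadamard_features(emb, h, t)))
    for h, t in negatives:
        out.append(LinkExample(h, t, 0, hadamard_features(emb, h, t)))
    return out


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------


def train_classifier(
    examples: Sequence[LinkExample],
    mode: str = "binary",
    seed: int = 0,
):
    """Fit logistic regression on Hadamard features.

    ``binary``: one model over all examples.  ``one-vs-rest``: one binary
    model per pathway (tail) class; each class uses its own positives
    plus an equal-sized seeded draw from the negative pool, so the
    negative count tracks the class's positive count.
    """
    examples = list(examples)
    if mode == "binary":
        labels = {e.label for e in examples}
        if len(labels) < 2:
            raise DegenerateTrainingError("binary training needs both labels")
        X = np.array([e.feature for e in examples])
        y = np.array([e.label for e in examples])
        clf = LogisticRegression(max_iter=2000, random_state=seed)
        clf.fit(X, y)
        return clf
    if mode == "one-vs-rest":
        pos_by_class: dict[str, list[LinkExample]] = {}
        for e in examples:
            if e.label == 1:
                pos_by_class.setdefault(e.tail, []).append(e)
        if len(pos_by_class) < 2:
            raise DegenerateTrainingError("one-vs-rest needs >= 2 pathway classes")
        neg_pool = [e for e in examples if e.label == 0]
        if not neg_pool:
            raise DegenerateTrainingError("one-vs-rest needs a negative pool")
        rng = np.random.default_rng(seed)
        models: dict[str, LogisticRegression] = {}
        for cls in sorted(pos_by_class):
            pos = pos_by_class[cls]
            k = min(len(pos), len(neg_pool))
            idx = rng.choice(len(neg_pool), size=k, replace=False)
            neg = [neg_pool[i] for i in sorted(idx)]
            X = np.array([e.feature for e in pos + neg])
            y = np.array([1] * len(pos) + [0] * len(neg))
            clf = LogisticRegression(max_iter=2000, random_state=seed)
            clf.fit(X, y)
            models[cls] = clf
        return OneVsRestModel(models)
    raise LinkPredictionError(f"unknown mode {mode!r}")


class OneVsRestModel:
    """One logistic-regression model per pathway class."""

    def __init__(self, models: dict):
        self.models = dict(models)

    def __len__(self):
        return len(self.models)

    def predict_proba_pair(self, feature: np.ndarray, pathway: str) -> float:
        if pathway in self.models:
            clf = self.models[pathway]
        else:  # unseen class: fall back to the mean over class models
            ps = [m.predict_proba(feature[None, :])[0, 1] for m in self.models.values()]
            return float(np.mean(ps))
        return float(clf.predict_proba(feature[None, :])[0, 1])


def _pair_probability(classifier, feature: np.ndarray, pathway: str) -> float:
    if isinstance(classifier, OneVsRestModel):
        return classifier.predict_proba_pair(feature, pathway)
    return float(classifier.predict_proba(feature[None, :])[0, 1])


def predict_links(
    classifier,
    emb: EmbeddingMatrix,
    candidates: Sequence[tuple[str, str]],
    cutoff: float = 0.95,
    metadata: Optional[dict] = None,
) -> list[PredictionRecord]:
    """Score candidates; keep records with confidence strictly over the cutoff."""
    records = []
    for protein, pathway in candidates:
        feature = hadamard_features(emb, protein, pathway)
        p = _pair_probability(classifier, feature, pathway)
        if p > cutoff:
            records.append(PredictionRecord(protein, pathway, p, dict(metadata or {})))
    records.sort(key=lambda r: (-r.confidence, r.protein, r.pathway))
    return records


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def rank_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC as the Mann-Whitney rank statistic (ties count half)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise MetricError("AUC needs both labels")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def evaluate(classifier, test_examples: Sequence[LinkExample], folds: int = 10, seed: int = 0) -> dict:
    """Holdout AUC (rank statistic) + f1 at the 0.5 threshold, with per-fold values.

    The folds partition the test set (seeded); each fold is scored by the
    given classifier, giving a dispersion estimate around the overall
    metrics.
    """
    test_examples = list(test_examples)
    labels = np.array([e.label for e in test_examples])
    if len(set(labels.tolist())) < 2:
        raise MetricError("test set needs both labels")
    scores = np.array(
        [_pair_probability(classifier, e.feature, e.tail) for e in test_examples]
    )
    auc = rank_auc(scores, labels)
    f1 = float(f1_score(labels, (scores > 0.5).astype(int)))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(test_examples))
    fold_aucs, fold_f1s = [], []
    for chunk in np.array_split(order, folds):
        yl, sc = labels[chunk], scores[chunk]
        if len(set(yl.tolist())) < 2:
            continue
        fold_aucs.append(rank_auc(sc, yl))
        fold_f1s.append(float(f1_score(yl, (sc > 0.5).astype(int))))
    return {
        "auc": auc,
        "f1": f1,
        "fold_aucs": fold_aucs,
        "fold_f1s": fold_f1s,
        "n": len(test_examples),
    }


def cross_validate(
    examples: Sequence[LinkExample], folds: int = 10, seed: int = 0, mode: str = "binary"
) -> dict:
    """Refitting k-fold cross-validation on the training examples."""
    examples = list(examples)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(examples))
    fold_aucs, fold_f1s = [], []
    for i, chunk in enumerate(np.array_split(order, folds)):
        test = [examples[j] for j in chunk]
        train = [examples[j] for j in order if j not in set(chunk.tolist())]
        if len({e.label for e in test}) < 2 or len({e.label for e in train}) < 2:
            continue
        clf = train_classifier(train, mode=mode, seed=seed)
        res = evaluate(clf, test, folds=2, seed=seed)
        fold_aucs.append(res["auc"])
        fold_f1s.append(res["f1"])
    return {
        # None when every fold was single-label (tiny inputs)
        "auc": float(np.mean(fold_aucs)) if fold_aucs else None,
        "f1": float(np.mean(fold_f1s)) if fold_f1s else None,
        "fold_aucs": fold_aucs,
        "fold_f1s": fold_f1s,
    }


def dark_recovery_rate(
    classifier,
    emb: EmbeddingMatrix,
    membership: Mapping[str, str],
    dark_proteins: Sequence[str],
    pathways: Sequence[str],
) -> float:
    """Fraction of dark proteins scoring their planted pathway above the
    median of the non-planted pathways.

    Dark proteins have no direct pathway edge in the graph, so any signal
    comes from shared context picked up by the walks — the understudied-
    kinase use case in miniature.
    """
    wins = 0
    total = 0
    for p in dark_proteins:
        if p not in emb or membership.get(p) not in pathways:
            continue
        scores = {
            w: _pair_probability(classifier, hadamard_features(emb, p, w), w) for w in pathways
        }
        planted = membership[p]
        others = [scores[w] for w in pathways if w != planted]
        if not others:
            continue
        total += 1
        if scores[planted] > float(np.median(others)):
            wins += 1
    if total == 0:
        raise MetricError("no scorable dark proteins")
    return wins / total


# ---------------------------------------------------------------------------
# replicate overlap (robustness metric)
# ---------------------------------------------------------------------------


def replicate_overlap(prediction_sets: Sequence[set], cutoff: Optional[float] = None) -> dict:
    """Per-protein overlap of (protein, pathway) predictions across replicates.

    For each protein: the pathways predicted in every replicate
    (intersection) versus the union across replicates, reported as a
    count and a percentage.  The global ``all_overlap`` is the
    intersection of the full pair sets across every replicate.
    """
    sets = [set(s) for s in prediction_sets]
    if len(sets) < 2:
        raise LinkPredictionError("replicate overlap needs >= 2 prediction sets")
    all_overlap = set.intersection(*sets)
    proteins = sorted({p for s in sets for p, _ in s})
    per_protein = {}
    for protein in proteins:
        path_sets = [{w for p, w in s if p == protein} for s in sets]
        inter = set.intersection(*path_sets)
        union = set.union(*path_sets)
        per_protein[protein] = {
            "overlap_count": len(inter),
            "union_count": len(union),
            "overlap_pct": 100.0 * len(inter) / len(union) if union else 0.0,
        }
    return {
        "per_protein": per_protein,
        "all_overlap": sorted(all_overlap),
        "all_overlap_count": len(all_overlap),
    }
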