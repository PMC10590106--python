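"""Skip-gram node embeddings trained on walk corpora.

Walks are treated as sentences: each node predicts its neighbors within
a window, trained by skip-gram with negative sampling (SGNS).  Training
is single-threaded and fully seeded, so identical corpora and configs
give byte-identical matrices.

The heterogeneous variant restricts negative sampling to the coarse
type group of the context node — for protein-pathway prediction the
groups are Protein, Pathway and Others — so negatives are drawn from
the same part of the type space as the observed context.  The variant
is opt-in (``type_coarsening=True``); the default objective is plain
SGNS.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .walker import WalkCorpus

COARSE_GROUPS = ("Protein", "Pathway", "Others")


class EmbeddingError(Exception):
    pass


class TrainingError(EmbeddingError):
    pass


class EmbeddingParseError(EmbeddingError):
    pass


class OutOfVocabularyError(EmbeddingError, KeyError):
    pass


@dataclass(frozen=True)
class EmbeddingConfig:
    """SGNS hyperparameters.

    Defaults follow the metapath2vec lineage: d=128, window 5, 5
    negatives, 5 epochs, min_count 1, initial learning rate 0.025
    decaying linearly to 1e-4.
    """

    dimension: int = 128
    window: int = 5
    negative_samples: int = 5
    epochs: int = 5
    min_count: int = 1
    seed: int = 0
    type_coarsening: bool = False
    alpha: float = 0.025
    min_alpha: float = 1e-4

    def __post_init__(self):
        if self.dimension < 2:
            raise EmbeddingError("dimension must be >= 2")
        if self.window < 1:
            raise EmbeddingError("window must be >= 1")
        if self.negative_samples < 1:
            raise EmbeddingError("negative_samples must be >= 1")


class EmbeddingMatrix:
    """node-id -> d-vector with a deterministic vocabulary order."""

    def __init__(self, vocab: Sequence[str], vectors: np.ndarray):
        if len(vocab) != vectors.shape[0]:
            raise EmbeddingError("vocabulary and matrix row count differ")
        self.vocab = list(vocab)
        self.vectors = np.asarray(vectors, dtype=np.float64)
        self._index = {w: i for i, w in enumerate(self.vocab)}

    @property
    def dimension(self) -> int:
        return self.vectors.shape[1]

    def __len__(self) -> int:
        return len(self.vocab)

    def __contains__(self, node: str) -> bool:
        return node in self._index

    def __getitem__(self, node: str) -> np.ndarray:
        try:
            return self.vectors[self._index[node]]
        except KeyError:
            raise OutOfVocabularyError(f"node {node!r} not in embedding vocabulary") from None

    def items(self):
        for w in self.vocab:
            yield w, self.vectors[self._index[w]]


def coarsen_label(label: str, hierarchy=None) -> str:
    """Collapse a node-type label to Protein / Pathway / Others."""
    lineage = hierarchy.ancestors(label) if hierarchy is not None else (label,)
    if "Protein" in lineage:
        return "Protein"
    if "Pathway" in lineage:
        return "Pathway"
    return "Others"


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))


def train_skipgram(
    corpus: WalkCorpus,
    config: EmbeddingConfig,
    node_types: Optional[Mapping[str, str]] = None,
    hierarchy=None,
) -> EmbeddingMatrix:
    """Train SGNS embeddings over the corpus walks.

    ``node_types`` (node-id -> type label) is only needed when
    ``type_coarsening`` is on, to group the negative-sampling tables.
    """
    sentences = corpus.sentences()
    sentences = [s for s in sentences if s]
    if not sentences:
        raise TrainingError("cannot train on an empty corpus")

    # vocabulary: frequency-descending, ties broken by id, min_count applied
    freq: dict[str, int] = {}
    for sent in sentences:
        for w in sent:
            freq[w] = freq.get(w, 0) + 1
    vocab = [w for w in sorted(freq, key=lambda w: (-freq[w], w)) if freq[w] >= config.min_count]
    if not vocab:
        raise TrainingError("min_count leaves an empty vocabulary")
    index = {w: i for i, w in enumerate(vocab)}
    V, d = len(vocab), config.dimension

    rng = np.random.default_rng(config.seed)
    w_in = (rng.random((V, d)) - 0.5) / d
    w_out = np.zeros((V, d))

    # unigram^(3/4) negative-sampling distribution, optionally split by
    # the coarse group of the OUTPUT (context) node
    counts = np.array([freq[w] for w in vocab], dtype=np.float64)
    noise = counts**0.75
    if config.type_coarsening:
        if node_types is None:
            raise TrainingError("type_coarsening requires node_types")
        groups = np.array(
            [COARSE_GROUPS.index(coarsen_label(node_types[w], hierarchy)) for w in vocab]
        )
        group_cum = {}
        for g in range(len(COARSE_GROUPS)):
            mask = groups == g
            if mask.any():
                p = np.where(mask, noise, 0.0)
                group_cum[g] = np.cumsum(p / p.sum())
    else:
        groups = None
        noise_cum = np.cumsum(noise / noise.sum())

    encoded = [np.array([index[w] for w in sent if w in index], dtype=np.int64) for sent in sentences]
    encoded = [s for s in encoded if len(s) >= 1]
    total_tokens = sum(len(s) for s in encoded) * config.epochs
    seen = 0
    neg = config.negative_samples

    for _epoch in range(config.epochs):
        for sent in encoded:
            n = len(sent)
            for pos in range(n):
                alpha = config.alpha - (config.alpha - config.min_alpha) * (seen / max(total_tokens, 1))
                seen += 1
                center = sent[pos]
                b = int(rng.integers(1, config.window + 1))  # dynamic window
                lo, hi = max(0, pos - b), min(n, pos + b + 1)
                for cpos in range(lo, hi):
                    if cpos == pos:
                        continue
                    context = sent[cpos]
                    cum = group_cum[int(groups[context])] if config.type_coarsening else noise_cum
                    negatives = np.searchsorted(cum, rng.random(neg), side="right")
                    np.clip(negatives, 0, V - 1, out=negatives)
                    negatives = negatives[negatives != context]  # never push the true pair apart
                    targets = np.concatenate(([context], negatives))
                    labels = np.zeros(len(targets))
                    labels[0] = 1.0
                    out = w_out[targets]  # (1+neg, d)
                    score = _sigmoid(out @ w_in[center])
                    grad = (labels - score) * alpha  # (1+neg,)
                    delta_in = grad @ out
                    w_out[targets] += np.outer(grad, w_in[center])
                    w_in[center] += delta_in
    # input+output sum: keeps first-order (direct co-occurrence) as well as
    # second-order (shared-context) similarity in one vector per node
    return EmbeddingMatrix(vocab, w_in + w_out)


# ---------------------------------------------------------------------------
# word2vec text serialization
# ---------------------------------------------------------------------------


def save_embeddings(emb: EmbeddingMatrix, path) -> None:
    """word2vec text format: header ``vocab_size d`` then one row per node."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(emb)} {emb.dimension}\n")
        for word, vec in emb.items():
            fh.write(word + " " + " ".join(f"{x:.8g}" for x in vec) + "\n")


def load_embeddings(path) -> EmbeddingMatrix:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise EmbeddingParseError("malformed word2vec header")
        try:
            n, d = int(header[0]), int(header[1])
        except ValueError:
            raise EmbeddingParseError("malformed word2vec header") from None
        vocab, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            if len(parts) != d + 1:
                raise EmbeddingParseError(f"row for {parts[0]!r} has {len(parts) - 1} values, expected {d}")
            vocab.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    if len(vocab) != n:
        raise EmbeddingParseError(f"header claims {n} rows, file has {len(vocab)}")
    return EmbeddingMatrix(vocab, np.array(rows))


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def pca_projection(emb: EmbeddingMatrix, components: int = 2) -> dict[str, np.ndarray]:
    """Project embeddings on the top principal components (centered)."""
    if components > emb.dimension:
        raise EmbeddingError(f"components={components} exceeds dimension {emb.dimension}")
    if len(emb) < 2:
        raise EmbeddingError("need at least 2 nodes for a projection")
    from sklearn.decomposition import PCA

    X = emb.vectors - emb.vectors.mean(axis=0)
    if np.allclose(X, 0):  # zero variance: all points coincide at the origin
        proj = np.zeros((len(emb), components))
    else:
        proj = PCA(n_components=components, random_state=0).fit_transform(X)
        if proj.shape[1] < components:
            proj = np.hstack([proj, np.zeros((len(emb), components - proj.shape[1]))])
    return {w: proj[i] for i, w in enumerate(emb.vocab)}


def type_separation_score(
    emb: EmbeddingMatrix,
    node_types: Mapping[str, str],
    hierarchy=None,
    components: int = 2,
) -> float:
    """Silhouette of the coarse type groups in PCA space (diagnostic only)."""
    from sklearn.metrics import silhouette_score

    proj = pca_projection(emb, components)
    X = np.array([proj[w] for w in emb.vocab])
    y = [coarsen_label(node_types[w], hierarchy) for w in emb.vocab]
    if len(set(y)) < 2:
        raise EmbeddingError("need >= 2 coarse groups for a separation score")
    return float(silhouette_score(X, y))


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(u @ v / (nu * nv))
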