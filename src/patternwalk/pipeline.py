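"""End-to-end orchestration: walk -> embed -> train -> predict -> evaluate.

A single RunConfig drives one seeded run; replicate_sweep repeats runs
over a grid of (num_walks, replicate-seed) settings and measures the
overlap of cutoff-filtered prediction sets across replicates — the
robustness protocol used to pick the walk-count hyperparameter.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict, replace
from typing import Optional, Sequence

import numpy as np

from . import linkpred, walker
from .embedding import EmbeddingConfig, save_embeddings, train_skipgram
from .kg import KnowledgeGraph
from .pattern import DEFAULT_PATTERN_TEXT, compile_dfa, parse_pattern
from .walker import WalkConfig

log = logging.getLogger("patternwalk")


class StageError(Exception):
    """A pipeline stage failed; the stage name prefixes the message."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    pattern: str = DEFAULT_PATTERN_TEXT
    relation: str = "hasPathway"
    walk: WalkConfig = field(default_factory=WalkConfig)
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    split: linkpred.SplitSpec = field(default_factory=linkpred.SplitSpec)
    cutoff: float = 0.95
    classifier_mode: str = "binary"
    head_type: str = "Protein"
    tail_type: str = "Pathway"


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run(
    config: RunConfig,
    graph: KnowledgeGraph,
    out_dir: str,
    candidates: Optional[Sequence[tuple[str, str]]] = None,
) -> dict:
    """Execute one seeded run and return a manifest of artifacts + metrics.

    Stages: split (holdout of known links, removed from the walking
    graph), walk, embed, train (with closed-world negatives), evaluate
    on the holdout, predict over the candidate universe.  The default
    candidate universe is {dark proteins without any known link} x
    {pathways} minus known positives.
    """
    os.makedirs(out_dir, exist_ok=True)
    manifest: dict = {"config": _config_dict(config), "out_dir": out_dir, "files": {}}

    # -- split ---------------------------------------------------------
    stage = "split"
    try:
        train_edges, test_edges = linkpred.split_positive_edges(
            graph, config.relation, config.split
        )
        walk_graph = graph.without_edges(test_edges)
    except Exception as exc:  # noqa: BLE001 - stage context wrapper
        raise StageError(stage, exc) from exc
    log.info("split: %d train / %d test edges", len(train_edges), len(test_edges))

    # -- walk ----------------------------------------------------------
    stage = "walk"
    try:
        alphabet = set(walk_graph.schema_view().node_types) | {
            a for t in walk_graph.schema_view().node_types
            for a in walk_graph.hierarchy.ancestors(t)
        }
        pattern = parse_pattern(config.pattern, alphabet)
        dfa = compile_dfa(pattern, alphabet, walk_graph.hierarchy)
        corpus = walker.generate_corpus(walk_graph, dfa, config.walk)
        corpus_path = os.path.join(out_dir, "corpus.txt")
        walker.write_corpus(corpus, corpus_path)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc
    manifest["files"]["corpus"] = {"path": corpus_path, "sha256": _checksum(corpus_path)}
    log.info("walk: %d walks", len(corpus))

    # -- embed ---------------------------------------------------------
    stage = "embed"
    try:
        node_types = {n: walk_graph.node_type(n) for n in walk_graph.nodes}
        emb = train_skipgram(
            corpus, config.embedding, node_types=node_types, hierarchy=walk_graph.hierarchy
        )
        emb_path = os.path.join(out_dir, "embeddings.w2v")
        save_embeddings(emb, emb_path)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc
    manifest["files"]["embeddings"] = {"path": emb_path, "sha256": _checksum(emb_path)}

    # -- train ---------------------------------------------------------
    stage = "train"
    try:
        train_pos = [(h, t) for h, _r, t in train_edges if h in emb and t in emb]
        test_pos = [(h, t) for h, _r, t in test_edges if h in emb and t in emb]
        neg_seed = config.split.seed + 1
        train_neg = linkpred.sample_negatives(
            walk_graph,
            config.relation,
            config.head_type,
            config.tail_type,
            len(train_pos),
            neg_seed,
            forbidden={(h, t) for h, _r, t in test_edges},
        )
        test_neg = linkpred.sample_negatives(
            walk_graph,
            config.relation,
            config.head_type,
            config.tail_type,
            len(test_pos),
            neg_seed + 1,
            forbidden={(h, t) for h, _r, t in test_edges} | set(train_neg),
        )
        train_examples = linkpred.build_examples(emb, train_pos, [p for p in train_neg if p[0] in emb and p[1] in emb])
        test_examples = linkpred.build_examples(emb, test_pos, [p for p in test_neg if p[0] in emb and p[1] in emb])
        clf = linkpred.train_classifier(train_examples, mode=config.classifier_mode, seed=config.split.seed)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # -- evaluate --------------------------------------------------------
    stage = "evaluate"
    try:
        metrics = linkpred.evaluate(clf, test_examples, folds=config.split.folds, seed=config.split.seed)
        cv = linkpred.cross_validate(
            train_examples, folds=config.split.folds, seed=config.split.seed, mode="binary"
        )
        metrics["train_cv"] = {"auc": cv["auc"], "f1": cv["f1"]}
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc
    manifest["metrics"] = metrics
    log.info("evaluate: auc=%.3f f1=%.3f", metrics["auc"], metrics["f1"])

    # -- predict ---------------------------------------------------------
    stage = "predict"
    try:
        if candidates is None:
            known = {(h, t) for h, r, t in graph.triples if r == config.relation}
            linked = {h for h, _t in known}
            darks = [
                p
                for p in graph.nodes_of_type("DarkKinase", resolve=False)
                if p not in linked and p in emb
            ]
            pathways = [w for w in graph.nodes_of_type(config.tail_type) if w in emb]
            candidates = [(p, w) for p in darks for w in pathways if (p, w) not in known]
        meta = {
            "seed": config.walk.seed,
            "num_walks": config.walk.num_walks,
            "cutoff": config.cutoff,
        }
        records = linkpred.predict_links(clf, emb, candidates, config.cutoff, metadata=meta)
        pred_path = os.path.join(out_dir, "predictions.tsv")
        with open(pred_path, "w", encoding="utf-8") as fh:
            for k, v in sorted(meta.items()):
                fh.write(f"# {k}={v}\n")
            fh.write("protein\tpathway\tconfidence\n")
            for r in records:
                fh.write(f"{r.protein}\t{r.pathway}\t{r.confidence:.6f}\n")
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc
    manifest["files"]["predictions"] = {"path": pred_path, "sha256": _checksum(pred_path)}
    manifest["n_predictions"] = len(records)
    manifest["predictions"] = [(r.protein, r.pathway, round(r.confidence, 6)) for r in records]

    manifest_path = os.path.join(out_dir, "manifest.json")
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    manifest["files"]["manifest"] = {"path": manifest_path}
    return manifest


def end_to_end_recovery(config: RunConfig, kg_config, out_dir: str) -> dict:
    """Full recovery experiment on the synthetic KG.

    Generates the graph, runs the pipeline with half the known
    protein-pathway links held out, and additionally scores every dark
    protein against every pathway to measure how often the planted
    pathway outranks the median non-planted one.
    """
    from .embedding import load_embeddings
    from .synthetic import generate

    graph, truth = generate(kg_config)
    manifest = run(config, graph, out_dir)
    emb = load_embeddings(manifest["files"]["embeddings"]["path"])

    # refit the run's classifier from its own artifacts for the dark ranking
    train_edges, test_edges = linkpred.split_positive_edges(graph, config.relation, config.split)
    walk_graph = graph.without_edges(test_edges)
    train_pos = [(h, t) for h, _r, t in train_edges if h in emb and t in emb]
    train_neg = linkpred.sample_negatives(
        walk_graph,
        config.relation,
        config.head_type,
        config.tail_type,
        len(train_pos),
        config.split.seed + 1,
        forbidden={(h, t) for h, _r, t in test_edges},
    )
    examples = linkpred.build_examples(
        emb, train_pos, [p for p in train_neg if p[0] in emb and p[1] in emb]
    )
    clf = linkpred.train_classifier(examples, mode=config.classifier_mode, seed=config.split.seed)
    pathways = [w for w in graph.nodes_of_type(config.tail_type) if w in emb]
    dark_rate = linkpred.dark_recovery_rate(
        clf, emb, truth.membership, truth.dark_proteins, pathways
    )
    manifest["metrics"]["dark_recovery_rate"] = dark_rate
    manifest["n_dark_proteins"] = len(truth.dark_proteins)
    return manifest


def replicate_sweep(
    config: RunConfig,
    graph: KnowledgeGraph,
    out_dir: str,
    num_walks_values: Sequence[int] = (10, 20, 30, 40, 50, 60, 70, 80),
    replicate_seeds: Sequence[int] = (0, 1, 2),
) -> dict:
    """Run every (NW, seed) replicate and report prediction overlap.

    Per NW value: the per-protein overlap across that value's replicates.
    Globally: the "all overlap" intersection across every dataset in the
    sweep.
    """
    if len(replicate_seeds) < 2:
        raise ValueError("need >= 2 replicate seeds")
    os.makedirs(out_dir, exist_ok=True)
    all_sets: list[set] = []
    per_nw: dict[int, dict] = {}
    for nw in num_walks_values:
        nw_sets = []
        for rep, seed in enumerate(replicate_seeds):
            run_cfg = replace(
                config,
                walk=replace(config.walk, num_walks=nw, seed=seed),
                embedding=replace(config.embedding, seed=seed),
            )
            sub = os.path.join(out_dir, f"nw{nw}_rep{rep}")
            manifest = run(run_cfg, graph, sub)
            preds = {(p, w) for p, w, _c in manifest["predictions"]}
            nw_sets.append(preds)
            all_sets.append(preds)
        overlap = linkpred.replicate_overlap(nw_sets)
        pcts = [v["overlap_pct"] for v in overlap["per_protein"].values()]
        per_nw[nw] = {
            "mean_overlap_pct": float(np.mean(pcts)) if pcts else 0.0,
            "all_overlap_count": overlap["all_overlap_count"],
            "n_replicates": len(nw_sets),
        }
    if len(all_sets) >= 2:
        global_overlap = linkpred.replicate_overlap(all_sets)
        all_count = global_overlap["all_overlap_count"]
        all_pairs = global_overlap["all_overlap"]
    else:
        all_count, all_pairs = 0, []
    if all(len(s) == 0 for s in all_sets):
        log.warning("every replicate produced an empty prediction set at cutoff %.2f", config.cutoff)
    report = {
        "per_nw": per_nw,
        "all_overlap_count": all_count,
        "all_overlap": all_pairs,
        "n_datasets": len(all_sets),
    }
    with open(os.path.join(out_dir, "sweep.json"), "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    return report


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    walk = d["walk"]
    if walk.get("start_types") is not None:
        walk["start_types"] = sorted(walk["start_types"])
    return d
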