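"""Seeded synthetic heterogeneous knowledge graphs with planted structure.

The generator emulates the shape of a kinase-centric biological KG:
proteins (some subtyped as understudied DarkKinases or well-studied
LightKinases) belong to pathways, and co-pathway proteins share context
nodes — GO terms (split into MolecularFunction / CellularComponent /
BiologicalProcess), functional domains, PTM sites, chemicals, diseases —
plus within-pathway protein-protein interactions.  Dark proteins keep
their context and PPI edges but their direct hasPathway edge is
withheld from the emitted graph and recorded in the ground truth: they
are the recovery targets.  A power-law layer of promiscuous hub nodes
reproduces the scale-free degree skew that motivates the inverse-degree
walk bias.

The generator also emits raw source-export-style association tables
with evidence codes and scores that straddle each curation threshold,
so every filter has boundary cases by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kg import KnowledgeGraph, TypeHierarchy


class SyntheticConfigError(Exception):
    pass


CONTEXT_TYPES = {
    # type label -> (relation, default count per pathway, edges per protein)
    "MolecularFunction": ("hasMolecularFunction", 5, 2),
    "CellularComponent": ("hasCellularComponent", 4, 2),
    "BiologicalProcess": ("hasBiologicalProcess", 5, 2),
    "FunctionalDomain": ("hasFunctionalDomain", 4, 2),
    "PTM": ("hasPTM", 3, 1),
    "Chemical": ("associatedWithChemical", 3, 1),
    "Disease": ("associatedWithDisease", 2, 1),
}

HIERARCHY = TypeHierarchy({"DarkKinase": "Protein", "LightKinase": "Protein"})


@dataclass(frozen=True)
class SyntheticKGConfig:
    """Study conditions for the synthetic KG.

    Defaults: 3 pathways x 30 proteins, a fifth of each pathway's
    proteins dark, within-pathway PPI density 0.15 with 1% cross-pathway
    noise, and 6 decoy hubs with power-law (exponent 2.5) attachment.
    """

    n_pathways: int = 3
    proteins_per_pathway: int = 30
    dark_fraction: float = 0.2
    light_fraction: float = 0.3
    context_per_pathway: dict = field(
        default_factory=lambda: {t: c for t, (_, c, _) in CONTEXT_TYPES.items()}
    )
    context_edges_per_protein: dict = field(
        default_factory=lambda: {t: k for t, (_, _, k) in CONTEXT_TYPES.items()}
    )
    ppi_within_pathway_prob: float = 0.15
    ppi_noise_prob: float = 0.01
    n_hubs: int = 6
    hub_exponent: float = 2.5
    go_generality_cap: int = 5000
    seed: int = 17

    def __post_init__(self):
        if not 0.0 <= self.dark_fraction < 1.0:
            raise SyntheticConfigError("dark_fraction must be in [0, 1)")
        for p in (self.ppi_within_pathway_prob, self.ppi_noise_prob):
            if not 0.0 <= p <= 1.0:
                raise SyntheticConfigError("probabilities must be in [0, 1]")
        if self.n_pathways < 1 or self.proteins_per_pathway < 1:
            raise SyntheticConfigError("need >= 1 pathway and >= 1 protein per pathway")


@dataclass(frozen=True)
class GroundTruth:
    """Planted memberships, including the withheld (dark) edges."""

    membership: dict  # protein -> pathway (all proteins)
    dark_proteins: tuple[str, ...]
    withheld_edges: tuple[tuple[str, str, str], ...]


def generate(config: SyntheticKGConfig) -> tuple[KnowledgeGraph, GroundTruth]:
    """Build the synthetic graph and its ground truth, fully seeded."""
    rng = np.random.default_rng(config.seed)
    node_types: dict[str, str] = {}
    triples: list[tuple[str, str, str]] = []

    pathways = [f"pw{i:02d}" for i in range(config.n_pathways)]
    for w in pathways:
        node_types[w] = "Pathway"

    membership: dict[str, str] = {}
    dark: list[str] = []
    withheld: list[tuple[str, str, str]] = []
    proteins_by_pathway: dict[str, list[str]] = {}

    for pi, w in enumerate(pathways):
        members = [f"p{pi:02d}_{j:02d}" for j in range(config.proteins_per_pathway)]
        proteins_by_pathway[w] = members
        n_dark = int(round(config.dark_fraction * len(members)))
        n_light = int(round(config.light_fraction * len(members)))
        if n_dark >= len(members):
            raise SyntheticConfigError("dark_fraction leaves no anchored proteins in a pathway")
        order = rng.permutation(len(members))
        dark_idx = set(order[:n_dark].tolist())
        light_idx = set(order[n_dark : n_dark + n_light].tolist())
        for j, p in enumerate(members):
            membership[p] = w
            if j in dark_idx:
                node_types[p] = "DarkKinase"
                dark.append(p)
                withheld.append((p, "hasPathway", w))
            else:
                node_types[p] = "LightKinase" if j in light_idx else "Protein"
                triples.append((p, "hasPathway", w))

        # pathway-specific context nodes shared by co-members
        for type_label, (relation, _dc, _de) in CONTEXT_TYPES.items():
            n_ctx = config.context_per_pathway.get(type_label, 0)
            k = config.context_edges_per_protein.get(type_label, 1)
            ctx_nodes = [f"{type_label.lower()}_{pi:02d}_{c:02d}" for c in range(n_ctx)]
            for c in ctx_nodes:
                node_types[c] = type_label
            if not ctx_nodes:
                continue
            for p in members:
                picks = rng.choice(len(ctx_nodes), size=min(k, len(ctx_nodes)), replace=False)
                for c in sorted(picks.tolist()):
                    triples.append((p, relation, ctx_nodes[c]))

    # protein-protein interactions: dense within a pathway, sparse across
    all_proteins = [p for w in pathways for p in proteins_by_pathway[w]]
    for i, a in enumerate(all_proteins):
        for b in all_proteins[i + 1 :]:
            prob = (
                config.ppi_within_pathway_prob
                if membership[a] == membership[b]
                else config.ppi_noise_prob
            )
            if rng.random() < prob:
                triples.append((a, "interactsWith", b))

    # decoy hubs with power-law attachment (exercise the inverse-degree bias)
    if config.n_hubs > 0:
        max_deg = max(2, len(all_proteins))
        raw = rng.pareto(config.hub_exponent - 1.0, size=config.n_hubs) + 1.0
        hub_degrees = np.clip((raw * 10).astype(int), 2, max_deg)
        hub_degrees = np.sort(hub_degrees)[::-1]
        for hi, deg in enumerate(hub_degrees):
            hub = f"hub_bp_{hi:02d}"
            node_types[hub] = "BiologicalProcess"
            picks = rng.choice(len(all_proteins), size=int(deg), replace=False)
            for j in sorted(picks.tolist()):
                triples.append((all_proteins[j], "hasBiologicalProcess", hub))

    graph = KnowledgeGraph(node_types, triples, HIERARCHY)
    truth = GroundTruth(membership, tuple(sorted(dark)), tuple(sorted(withheld)))
    return graph, truth


# ---------------------------------------------------------------------------
# raw source-table fixtures for the curation filters
# ---------------------------------------------------------------------------


def emit_source_tables(config: SyntheticKGConfig) -> dict[str, pd.DataFrame]:
    """Association tables with boundary rows for every curation rule.

    Emitted tables (keyed by provenance tag): ``reactome`` (evidence
    TAS/IEA), ``reactome_hierarchy`` (child, parent), ``go`` (term sizes
    straddling the generality cap), ``string`` (experimental scores
    straddling 700), ``iptmnet`` (confidences straddling 1.0) and
    ``pfam`` (kinase + non-kinase domains).
    """
    rng = np.random.default_rng(config.seed + 1)
    graph, truth = generate(config)
    proteins = sorted(truth.membership)
    pathways = sorted(set(truth.membership.values()))

    reactome = pd.DataFrame(
        {
            "subject": proteins,
            "object": [truth.membership[p] for p in proteins],
            "evidence": [("TAS" if rng.random() < 0.7 else "IEA") for _ in proteins],
        }
    )
    # hierarchy with the excluded-root / kept-root pattern
    hier_rows = [
        ("Disease", "TopLevel"),
        ("InfectiousDisease", "Disease"),
        ("pw_infectious_leaf", "InfectiousDisease"),
        ("pw_disease_leaf", "Disease"),
    ] + [(w, "TopLevel") for w in pathways]
    hierarchy = pd.DataFrame(hier_rows, columns=["child", "parent"])
    extra = pd.DataFrame(
        {
            "subject": [proteins[0], proteins[1]],
            "object": ["pw_disease_leaf", "pw_infectious_leaf"],
            "evidence": ["TAS", "TAS"],
        }
    )
    reactome = pd.concat([reactome, extra], ignore_index=True)

    # GO: one oversized term (cap + 1 rows), one at the cap, plus per-pathway terms
    cap = config.go_generality_cap
    go_rows = []
    big_pool = [f"x_{i:04d}" for i in range(cap + 1)]
    for s in big_pool:
        go_rows.append((s, "go_overly_general"))
    for s in big_pool[:cap]:
        go_rows.append((s, "go_at_cap"))
    for p in proteins[:10]:
        go_rows.append((p, f"go_{truth.membership[p]}"))
    go = pd.DataFrame(go_rows, columns=["subject", "object"])
    go["namespace"] = "BiologicalProcess"

    n_ppi = min(60, len(proteins) * 2)
    partners = rng.choice(proteins, size=(n_ppi, 2))
    scores = rng.integers(300, 1000, size=n_ppi)
    string = pd.DataFrame(
        {"subject": partners[:, 0], "object": partners[:, 1], "experimental_score": scores}
    )
    boundary = pd.DataFrame(
        {
            "subject": [proteins[0]] * 3,
            "object": [proteins[1], proteins[2], proteins[3]],
            "experimental_score": [650, 700, 701],
        }
    )
    string = pd.concat([string, boundary], ignore_index=True)

    iptmnet = pd.DataFrame(
        {
            "subject": rng.choice(proteins, size=20),
            "object": [f"ptm_site_{i:02d}" for i in range(20)],
            "confidence": np.round(rng.uniform(0.5, 3.0, size=20), 2),
        }
    )
    iptmnet = pd.concat(
        [
            iptmnet,
            pd.DataFrame(
                {
                    "subject": [proteins[0]] * 3,
                    "object": ["ptm_b1", "ptm_b2", "ptm_b3"],
                    "confidence": [0.9, 1.0, 1.5],
                }
            ),
        ],
        ignore_index=True,
    )

    domains = ["Pkinase", "Pkinase_Tyr", "SH2", "SH3", "PH", "WD40"]
    pfam = pd.DataFrame(
        {
            "subject": rng.choice(proteins, size=24),
            "object": rng.choice(domains, size=24),
        }
    )

    return {
        "reactome": reactome,
        "reactome_hierarchy": hierarchy,
        "go": go,
        "string": string,
        "iptmnet": iptmnet,
        "pfam": pfam,
    }
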