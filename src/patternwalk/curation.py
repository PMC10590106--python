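"""Source-specific filtering of raw association tables.

Each public source export is reduced before graph construction:

- pathway memberships keep only manually curated rows (evidence TAS);
- pathways under excluded high-level roots are pruned, with explicit
  keep-roots overriding the exclusion (the shipped default excludes the
  Reactome "Disease" subtree, R-HSA-1643685, but keeps "Infectious
  disease", R-HSA-5663205);
- overly general GO terms (more than 5000 associations) are dropped;
- protein-protein interactions need an experimental score over 700 and
  at least one kinase endpoint;
- PTM rows need a confidence over 1.0;
- the kinase domains themselves (Pkinase, Pkinase_Tyr) are removed from
  domain annotations, since they carry no discriminating signal in a
  kinase-only protein set.

All thresholds are strict inequalities.  Filters are pure, idempotent
row predicates (plus the hierarchy closure), so output row counts equal
a brute-force scan with the same predicate.
"""

from __future__ import annotations

from typing import Iterable, Optional

import pandas as pd

DEFAULT_EVIDENCE = frozenset({"TAS"})
DEFAULT_EXCLUDED_DOMAINS = frozenset({"Pkinase", "Pkinase_Tyr"})
DEFAULT_EXCLUDE_ROOTS = frozenset({"R-HSA-1643685"})  # Disease
DEFAULT_KEEP_ROOTS = frozenset({"R-HSA-5663205"})  # Infectious disease
DEFAULT_GO_CAP = 5000
DEFAULT_MIN_STRING_SCORE = 700
DEFAULT_MIN_PTM_CONFIDENCE = 1.0


class CurationError(Exception):
    pass


class SchemaError(CurationError):
    """A required attribute column is missing."""


class HierarchyError(CurationError):
    """The pathway hierarchy contains a cycle."""


def _require(table: pd.DataFrame, column: str) -> None:
    if column not in table.columns:
        raise SchemaError(f"table lacks required column {column!r}")


def filter_reactome_evidence(
    table: pd.DataFrame, allowed: Iterable[str] = DEFAULT_EVIDENCE
) -> pd.DataFrame:
    """Keep only rows whose evidence code is in ``allowed`` (default {TAS})."""
    _require(table, "evidence")
    allowed = set(allowed)
    return table[table["evidence"].isin(allowed)].reset_index(drop=True)


def descendant_closure(hierarchy: pd.DataFrame, roots: Iterable[str]) -> set[str]:
    """All ids at or below any root in a (child, parent) table.

    Raises HierarchyError on cyclic input.
    """
    children: dict[str, list[str]] = {}
    for child, parent in zip(hierarchy["child"], hierarchy["parent"]):
        children.setdefault(str(parent), []).append(str(child))
    # cycle check over the full table
    state: dict[str, int] = {}

    def visit(node: str, trail: set[str]) -> None:
        if node in trail:
            raise HierarchyError(f"pathway hierarchy contains a cycle through {node!r}")
        if state.get(node) == 2:
            return
        trail.add(node)
        for ch in children.get(node, ()):
            visit(ch, trail)
        trail.discard(node)
        state[node] = 2

    for parent in list(children):
        visit(parent, set())

    out: set[str] = set()
    stack = [str(r) for r in roots]
    while stack:
        node = stack.pop()
        if node in out:
            continue
        out.add(node)
        stack.extend(children.get(node, ()))
    return out


def prune_pathway_hierarchy(
    table: pd.DataFrame,
    hierarchy: pd.DataFrame,
    exclude_roots: Iterable[str] = DEFAULT_EXCLUDE_ROOTS,
    keep_roots: Iterable[str] = DEFAULT_KEEP_ROOTS,
) -> pd.DataFrame:
    """Drop rows whose pathway lies under an excluded root, unless it also
    lies under (or is) a keep root; keep overrides exclude."""
    _require(table, "object")
    exclude_roots = set(exclude_roots)
    keep_roots = set(keep_roots)
    excluded = descendant_closure(hierarchy, exclude_roots) if exclude_roots else set()
    kept = descendant_closure(hierarchy, keep_roots) if keep_roots else set()
    kept |= keep_roots
    drop = excluded - kept
    return table[~table["object"].astype(str).isin(drop)].reset_index(drop=True)


def filter_go_generality(
    table: pd.DataFrame, max_associations: int = DEFAULT_GO_CAP
) -> pd.DataFrame:
    """Remove every GO term with more than ``max_associations`` rows (all its rows)."""
    _require(table, "object")
    sizes = table["object"].value_counts()
    too_general = set(sizes[sizes > max_associations].index)
    return table[~table["object"].isin(too_general)].reset_index(drop=True)


def filter_string_ppi(
    table: pd.DataFrame,
    min_experimental_score: float = DEFAULT_MIN_STRING_SCORE,
    kinase_ids: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Keep rows with experimental score strictly over the threshold AND at
    least one kinase endpoint."""
    _require(table, "experimental_score")
    kinases = set(kinase_ids or ())
    mask = table["experimental_score"] > min_experimental_score
    mask &= table["subject"].isin(kinases) | table["object"].isin(kinases)
    return table[mask].reset_index(drop=True)


def filter_ptm_confidence(
    table: pd.DataFrame, min_confidence: float = DEFAULT_MIN_PTM_CONFIDENCE
) -> pd.DataFrame:
    """Keep rows with confidence strictly over the threshold (default 1.0)."""
    _require(table, "confidence")
    return table[table["confidence"] > min_confidence].reset_index(drop=True)


def filter_pfam_domains(
    table: pd.DataFrame, excluded_domains: Iterable[str] = DEFAULT_EXCLUDED_DOMAINS
) -> pd.DataFrame:
    """Drop rows whose domain is excluded (default: Pkinase, Pkinase_Tyr)."""
    _require(table, "object")
    excluded = set(excluded_domains)
    return table[~table["object"].isin(excluded)].reset_index(drop=True)


def curation_report(before: pd.DataFrame, after: pd.DataFrame, rule: str) -> dict:
    return {"rule": rule, "rows_in": int(len(before)), "rows_out": int(len(after))}
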