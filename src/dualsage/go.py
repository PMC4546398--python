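"""GO DAG annotation propagation and node scores.

Sequences are annotated to GO terms; annotations propagate to every
ancestor along is_a/part_of edges (the true-path rule).  A term's node
score aggregates annotation instances at or below it, optionally
distance-discounted:

    S_t = sum over directly annotated (seq, term) pairs of w^d,

where d is the shortest directed distance from the annotated term up to t
and w in (0, 1] the discount.  With w = 1 the score is simply the number of
annotation instances in the term's subtree, so the namespace root conserves
the total instance count.  This is an explicit, reproducible stand-in for
the proprietary Blast2GO "combined graph" node score; the comparison logic
(score cut-off, per-namespace level listings) mirrors how such graphs are
read side by side for two species.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import obonet
import pandas as pd

from .tags import InputError

logger = logging.getLogger(__name__)

DEFAULT_EDGE_TYPES = ("is_a", "part_of")
DEFAULT_CUTOFF = 20.0


class FormatError(ValueError):
    """Malformed ontology input."""


@dataclass
class GOGraph:
    """Ontology DAG: edges run child -> parent; obsolete terms excluded."""

    graph: nx.DiGraph
    alt_ids: dict[str, str] = field(default_factory=dict)

    def resolve(self, term: str) -> str | None:
        if term in self.graph:
            return term
        return self.alt_ids.get(term)

    def namespace(self, term: str) -> str | None:
        return self.graph.nodes[term].get("namespace")

    def name(self, term: str) -> str | None:
        return self.graph.nodes[term].get("name")

    def ancestors(self, term: str) -> set[str]:
        """Ancestors-or-self of a term along the configured edge types."""
        return {term} | nx.descendants(self.graph, term)

    def roots(self) -> list[str]:
        return [n for n in self.graph.nodes if self.graph.out_degree(n) == 0]

    def levels(self) -> dict[str, int]:
        """Shortest directed distance from each term up to its namespace root."""
        out = {}
        for term in self.graph.nodes:
            best = math.inf
            for root, d in nx.single_source_shortest_path_length(
                self.graph, term
            ).items():
                if self.graph.out_degree(root) == 0:
                    best = min(best, d)
            out[term] = int(best) if best < math.inf else 0
        return out


def parse_obo(
    source, edge_types: Iterable[str] = DEFAULT_EDGE_TYPES
) -> GOGraph:
    """Parse an OBO 1.2/1.4 ontology into a GOGraph.

    Obsolete terms are excluded from the graph (obonet drops them);
    alt_ids map to their primary term.  A cyclic ontology is rejected,
    naming one term on a cycle.
    """
    multi = obonet.read_obo(source, ignore_obsolete=True)
    edge_types = set(edge_types)
    g = nx.DiGraph()
    alt_ids: dict[str, str] = {}
    for node, data in multi.nodes(data=True):
        g.add_node(node, name=data.get("name"), namespace=data.get("namespace"))
        for alt in data.get("alt_id", []):
            alt_ids[alt] = node
    for child, parent, rel in multi.edges(keys=True):
        if rel in edge_types:
            g.add_edge(child, parent, relation=rel)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise FormatError(f"ontology contains a cycle through {cycle[0][0]}")
    return GOGraph(g, alt_ids)


def propagate_annotations(
    go: GOGraph, annotations: Mapping[str, Iterable[str]]
) -> dict[str, set[str]]:
    """True-path propagation: term -> set of sequences annotated at-or-below.

    Annotations to unknown terms are skipped with a warning; alt_ids are
    resolved to their primary term first.
    """
    propagated: dict[str, set[str]] = {}
    for seq, terms in annotations.items():
        for term in terms:
            primary = go.resolve(term)
            if primary is None:
                logger.warning("sequence %s: unknown/obsolete GO term %s", seq, term)
                continue
            for anc in go.ancestors(primary):
                propagated.setdefault(anc, set()).add(seq)
    return propagated


def node_score(
    go: GOGraph,
    annotations: Mapping[str, Iterable[str]],
    weight: float = 1.0,
) -> pd.DataFrame:
    """Distance-discounted annotation-instance score per GO term.

    Each direct (sequence, term) annotation contributes weight**d to every
    ancestor at shortest directed distance d (d=0 at the annotated term).
    Returns one row per scored term: term, name, namespace, level, score,
    n_sequences (distinct propagated sequences).
    """
    if not 0 < weight <= 1:
        raise InputError("weight must be in (0, 1]")
    # multiplicity of direct annotation instances per term
    direct: dict[str, int] = {}
    for seq, terms in annotations.items():
        for term in terms:
            primary = go.resolve(term)
            if primary is None:
                logger.warning("sequence %s: unknown/obsolete GO term %s", seq, term)
                continue
            direct[primary] = direct.get(primary, 0) + 1
    scores: dict[str, float] = {}
    for term, mult in direct.items():
        for anc, d in nx.single_source_shortest_path_length(go.graph, term).items():
            scores[anc] = scores.get(anc, 0.0) + mult * weight**d
    propagated = propagate_annotations(go, annotations)
    levels = go.levels()
    rows = [
        (
            term,
            go.name(term),
            go.namespace(term),
            levels[term],
            score,
            len(propagated.get(term, ())),
        )
        for term, score in scores.items()
    ]
    df = pd.DataFrame(
        rows, columns=["term", "name", "namespace", "level", "score", "n_sequences"]
    )
    return df.sort_values(
        ["score", "term"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


def filter_and_compare(
    host_scores: pd.DataFrame,
    symbiont_scores: pd.DataFrame,
    cutoff: float = DEFAULT_CUTOFF,
    level: int | None = None,
) -> pd.DataFrame:
    """Side-by-side host/symbiont node scores above the cut-off.

    A term is retained when its score reaches ``cutoff`` (inclusive) in
    either species; a term absent from one table scores 0 there.  With
    ``level`` set, only terms at that shortest-distance-from-root level are
    listed.  Sorted by the larger of the two scores, descending.
    """
    h = host_scores.set_index("term")
    s = symbiont_scores.set_index("term")
    merged = h[["name", "namespace", "level", "score"]].join(
        s[["score"]], how="outer", lsuffix="_host", rsuffix="_symbiont"
    )
    for col in ("name", "namespace", "level"):
        missing = merged[col].isna()
        if missing.any():
            fill = s.reindex(merged.index[missing])[col]
            merged.loc[missing, col] = fill
    merged = merged.rename(
        columns={"score_host": "score_host", "score_symbiont": "score_symbiont"}
    )
    for col in ("score_host", "score_symbiont"):
        merged[col] = pd.to_numeric(merged[col], errors="coerce").fillna(0.0)
    keep = (merged["score_host"] >= cutoff) | (merged["score_symbiont"] >= cutoff)
    merged = merged[keep]
    if level is not None:
        merged = merged[merged["level"] == level]
    merged["score_max"] = merged[["score_host", "score_symbiont"]].max(axis=1)
    merged = merged.sort_values(
        ["score_max", "term"], ascending=[False, True], kind="stable"
    ).drop(columns="score_max")
    return merged.reset_index()


def read_annotation_map(path) -> dict[str, set[str]]:
    """Read a two-column TSV (sequence/tag id, GO term) into a mapping."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["seq", "term"], dtype=str)
    out: dict[str, set[str]] = {}
    for seq, term in zip(df["seq"], df["term"]):
        out.setdefault(seq, set()).add(term)
    return out
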