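"""Minimal is_a ontology DAG for context-term queries.

Experimental contexts are annotated with terms from anatomy/cell ontologies
(UBERON, CL, CLO, BTO, EFO). For stratifying interactions by anatomical
system, only descendant queries against named roots are needed — the central
nervous system (UBERON:0001017) and the eye (UBERON:0000970) — so the DAG is
consumed as a child/parent edge list rather than a full OBO release.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import networkx as nx
import pandas as pd

CNS_ROOT = "UBERON:0001017"
EYE_ROOT = "UBERON:0000970"

__all__ = ["OntologyDag", "CNS_ROOT", "EYE_ROOT"]


@dataclass
class OntologyDag:
    """is_a hierarchy over term CURIEs, queried by descendant-of-root.

    Edges point child -> parent. The graph must be acyclic and every parent
    must itself be a known term.
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "OntologyDag":
        g = nx.DiGraph()
        g.add_edges_from(edges)
        dag = cls(graph=g)
        dag._check()
        return dag

    @classmethod
    def from_edgelist_tsv(cls, source: str | IO[str]) -> "OntologyDag":
        """Read a two-column TSV (child_curie, parent_curie)."""
        df = pd.read_csv(source, sep="\t", dtype=str)
        for col in ("child_curie", "parent_curie"):
            if col not in df.columns:
                raise ValueError(f"ontology edge list missing column {col!r}")
        return cls.from_edges(
            (str(r.child_curie), str(r.parent_curie)) for r in df.itertuples()
        )

    def to_edgelist_tsv(self, sink: IO[str]) -> None:
        sink.write("child_curie\tparent_curie\n")
        for child, parent in sorted(self.graph.edges()):
            sink.write(f"{child}\t{parent}\n")

    def _check(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("ontology is_a links contain a cycle")

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes())

    def descendants(self, root: str) -> set[str]:
        """The root itself plus all transitive is_a children."""
        if root not in self.graph:
            raise KeyError(f"unknown ontology term {root!r}")
        # edges run child -> parent, so descendants of root are its ancestors
        # in the child->parent digraph
        return {root} | nx.ancestors(self.graph, root)

    def is_descendant(self, term: str, root: str) -> bool:
        if term not in self.graph or root not in self.graph:
            return False
        return term == root or root in nx.descendants(self.graph, term)
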