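"""Core data model for signed, weighted, directed gene-regulation graphs.

A regulatory network links transcription factors (TFs) to the genes they
regulate.  Each directed edge carries a real interaction strength: positive
for activation, negative for repression.  Source databases often report
several strengths for the same ordered gene pair (one per promoter region);
this module collapses them to a single edge carrying the largest value, so
the stored graph is always simple (at most one edge per ordered pair).

Operationally a TF is any node with positive out-degree; a gene with zero
out-degree is an *effector* (regulated, but regulating nothing).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import networkx as nx

__all__ = [
    "GeneNode",
    "SignedInteraction",
    "DegreeRecord",
    "RegulatoryNetwork",
    "InvalidInteractionError",
    "UnknownGeneError",
    "SIGN_CATEGORY_WEIGHTS",
]

#: Categorical regulatory effects (RegulonDB-style) and the weight each
#: materializes to.  "dual" edges count toward degree but carry no sign.
SIGN_CATEGORY_WEIGHTS = {"positive": 1.0, "negative": -1.0, "dual": 0.0}


class InvalidInteractionError(ValueError):
    """Raised for malformed interaction records (bad symbol or weight)."""


class UnknownGeneError(KeyError):
    """Raised when an operation references a gene absent from the network."""

    def __init__(self, symbol: str):
        super().__init__(symbol)
        self.symbol = symbol

    def __str__(self) -> str:  # KeyError quotes its arg; keep message readable
        return f"gene symbol not in network: {self.symbol!r}"


def _clean_symbol(symbol: str) -> str:
    if not isinstance(symbol, str):
        raise InvalidInteractionError(f"gene symbol must be a string, got {type(symbol).__name__}")
    sym = symbol.strip()
    if not sym:
        raise InvalidInteractionError("empty gene symbol")
    return sym


@dataclass(frozen=True)
class GeneNode:
    """A gene, identified by its (case-sensitive) symbol.

    Annotations hold optional per-gene metadata such as the average
    transcript count observed at the start of a time course.
    """

    id: str
    annotations: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "id", _clean_symbol(self.id))

    def __hash__(self):
        return hash(self.id)


@dataclass(frozen=True)
class SignedInteraction:
    """One directed regulatory edge candidate.

    Exactly one of ``weight`` (real interaction strength, Z-score units)
    or ``sign_category`` ("positive" / "negative" / "dual") must be given;
    categorical effects are materialized to weights +1 / -1 / 0 at
    construction.  ``promoter_id`` distinguishes promoter-level duplicate
    records for the same gene pair.
    """

    source: str
    target: str
    weight: Optional[float] = None
    promoter_id: Optional[str] = None
    sign_category: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "source", _clean_symbol(self.source))
        object.__setattr__(self, "target", _clean_symbol(self.target))
        if (self.weight is None) == (self.sign_category is None):
            raise InvalidInteractionError(
                "exactly one of weight / sign_category must be set "
                f"(got weight={self.weight!r}, sign_category={self.sign_category!r})"
            )
        if self.sign_category is not None:
            if self.sign_category not in SIGN_CATEGORY_WEIGHTS:
                raise InvalidInteractionError(
                    f"unknown sign category {self.sign_category!r}; "
                    f"expected one of {sorted(SIGN_CATEGORY_WEIGHTS)}"
                )
            object.__setattr__(self, "weight", SIGN_CATEGORY_WEIGHTS[self.sign_category])
        w = float(self.weight)
        if not math.isfinite(w):
            raise InvalidInteractionError(f"non-finite interaction weight: {self.weight!r}")
        object.__setattr__(self, "weight", w)


@dataclass(frozen=True)
class DegreeRecord:
    """Distinct-regulator / distinct-target counts for one gene."""

    gene: str
    in_deg: int
    out_deg: int


class RegulatoryNetwork:
    """Simple directed graph of regulatory interactions.

    At most one edge is stored per ordered gene pair; submitting further
    records for an existing pair keeps the *biggest* value.  Two
    aggregation modes exist:

    ``"signed-max"`` (default)
        keep the largest signed weight (so +2.0 beats -3.0);
    ``"abs-max"``
        keep the record of largest magnitude, sign preserved.

    Parameters
    ----------
    aggregation : {"signed-max", "abs-max"}
        Duplicate-record resolution rule.
    """

    AGGREGATIONS = ("signed-max", "abs-max")

    def __init__(self, aggregation: str = "signed-max"):
        if aggregation not in self.AGGREGATIONS:
            raise ValueError(f"unknown aggregation mode {aggregation!r}; expected one of {self.AGGREGATIONS}")
        self.aggregation = aggregation
        self._g = nx.DiGraph()

    # ---------------------------------------------------------------- nodes
    def add_gene(self, symbol: str, **annotations) -> None:
        """Register a gene (idempotent); annotations are merged in."""
        sym = _clean_symbol(symbol)
        self._g.add_node(sym)
        if annotations:
            self._g.nodes[sym].update(annotations)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._g

    @property
    def genes(self) -> list[str]:
        return sorted(self._g.nodes)

    def annotations(self, symbol: str) -> dict:
        if symbol not in self._g:
            raise UnknownGeneError(symbol)
        return dict(self._g.nodes[symbol])

    @property
    def n_genes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    # ---------------------------------------------------------------- edges
    def add_interaction(self, rec: SignedInteraction) -> "RegulatoryNetwork":
        """Submit one interaction record, applying the max-weight rule.

        Both endpoints are created if absent.  If the ordered pair already
        has an edge, its weight is replaced only when the incoming record
        wins under the network's aggregation mode.  Returns ``self`` for
        chaining.
        """
        if not isinstance(rec, SignedInteraction):
            raise InvalidInteractionError(f"expected SignedInteraction, got {type(rec).__name__}")
        s, t, w = rec.source, rec.target, rec.weight
        self._g.add_node(s)
        self._g.add_node(t)
        if self._g.has_edge(s, t):
            old = self._g[s][t]["weight"]
            if self.aggregation == "signed-max":
                new = max(old, w)
            else:  # abs-max, sign preserved
                new = w if abs(w) > abs(old) else old
            self._g[s][t]["weight"] = new
        else:
            self._g.add_edge(s, t, weight=w)
        return self

    def add_interactions(self, records: Iterable[SignedInteraction]) -> "RegulatoryNetwork":
        for rec in records:
            self.add_interaction(rec)
        return self

    def weight(self, source: str, target: str) -> float:
        if not self._g.has_edge(source, target):
            raise UnknownGeneError(f"{source}->{target}")
        return self._g[source][target]["weight"]

    def has_edge(self, source: str, target: str) -> bool:
        return self._g.has_edge(source, target)

    def edges(self) -> Iterator[tuple[str, str, float]]:
        """Iterate (source, target, weight), sorted by (source, target)."""
        for s, t in sorted(self._g.edges):
            yield s, t, self._g[s][t]["weight"]

    def out_edges(self, source: str) -> Iterator[tuple[str, float]]:
        """Iterate (target, weight) over a gene's outgoing edges, sorted."""
        if source not in self._g:
            raise UnknownGeneError(source)
        for t in sorted(self._g.successors(source)):
            yield t, self._g[source][t]["weight"]

    # -------------------------------------------------------------- degrees
    def degrees(self) -> list[DegreeRecord]:
        """Per-gene distinct in/out neighbor counts, sorted by symbol.

        A self-loop contributes one to each count.  Degree conservation
        holds on every network: sum of in-degrees = sum of out-degrees =
        number of edges.
        """
        return [
            DegreeRecord(gene=n, in_deg=self._g.in_degree(n), out_deg=self._g.out_degree(n))
            for n in sorted(self._g.nodes)
        ]

    def tfs(self) -> set[str]:
        """Genes with positive out-degree (the transcription factors)."""
        return {n for n in self._g.nodes if self._g.out_degree(n) > 0}

    def effectors(self) -> set[str]:
        """Genes with zero out-degree (regulated, regulating nothing)."""
        return {n for n in self._g.nodes if self._g.out_degree(n) == 0}

    # ---------------------------------------------------------- subnetworks
    def tf_subnetwork(self) -> "RegulatoryNetwork":
        """Drop all effector genes in a single pass.

        Membership is decided by out-degree in *this* network only (no
        iteration): the result may itself contain new zero-out-degree
        nodes when a TF's only targets were effectors.  The original
        network is left untouched.
        """
        keep = self.tfs()
        sub = RegulatoryNetwork(aggregation=self.aggregation)
        for n in keep:
            sub.add_gene(n, **self._g.nodes[n])
        for s, t in self._g.edges:
            if s in keep and t in keep:
                sub._g.add_edge(s, t, weight=self._g[s][t]["weight"])
        return sub

    def subnetwork_of_targets(self, sources: Iterable[str]) -> "RegulatoryNetwork":
        """Subgraph of ``sources`` plus their direct targets.

        Only edges *leaving* a source are kept, so each such edge appears
        exactly once and edges between two non-source targets are dropped.
        """
        srcs = set(sources)
        for s in srcs:
            if s not in self._g:
                raise UnknownGeneError(s)
        sub = RegulatoryNetwork(aggregation=self.aggregation)
        for s in srcs:
            sub.add_gene(s, **self._g.nodes[s])
            for t in self._g.successors(s):
                sub.add_gene(t, **self._g.nodes[t])
                sub._g.add_edge(s, t, weight=self._g[s][t]["weight"])
        return sub

    # ------------------------------------------------------------ plumbing
    def copy(self) -> "RegulatoryNetwork":
        out = RegulatoryNetwork(aggregation=self.aggregation)
        out._g = self._g.copy()
        return out

    def to_networkx(self) -> nx.DiGraph:
        """A defensive copy of the underlying :class:`networkx.DiGraph`."""
        return self._g.copy()

    @classmethod
    def from_networkx(cls, g: nx.DiGraph, aggregation: str = "signed-max") -> "RegulatoryNetwork":
        net = cls(aggregation=aggregation)
        net._g = g.copy()
        return net

    @classmethod
    def from_interactions(
        cls, records: Iterable[SignedInteraction], aggregation: str = "signed-max"
    ) -> "RegulatoryNetwork":
        """Bulk-load a record stream through the max-weight rule."""
        return cls(aggregation=aggregation).add_interactions(records)

    def __eq__(self, other) -> bool:
        if not isinstance(other, RegulatoryNetwork):
            return NotImplemented
        if set(self._g.nodes) != set(other._g.nodes):
            return False
        if set(self._g.edges) != set(other._g.edges):
            return False
        return all(self._g[s][t]["weight"] == other._g[s][t]["weight"] for s, t in self._g.edges)

    def __repr__(self) -> str:
        return f"<RegulatoryNetwork: {self.n_genes} genes, {self.n_edges} interactions, {self.aggregation}>"
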