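"""Readers, writers, and the breadth-first database crawler.

Edge tables are UTF-8 delimited text with a header row and '#' comments.
Two dialects cover the common curated sources: quantitative tables with a
real ``weight`` column (Z-score interaction strengths, optionally one row
per promoter region) and categorical tables with an ``effect`` column
(activation / repression / dual), which materialize to weights +1 / -1 / 0.

The crawler reconstructs a network from a gene-centric edge database: a
provider answering "who regulates gene X?" and "what does X regulate?".
Starting from a seed gene it walks the database breadth-first, submitting
every reported interaction through the max-weight aggregation rule, and
stops when no unexplored gene remains — recovering exactly the weakly
connected component of the seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Protocol, runtime_checkable

import networkx as nx

from .network import (
    InvalidInteractionError,
    RegulatoryNetwork,
    SignedInteraction,
)

__all__ = [
    "EdgeTableSpec",
    "FANTOM_STYLE",
    "REGULONDB_STYLE",
    "EdgeTableFormatError",
    "EdgeTableRowError",
    "EdgeProvider",
    "CrawlError",
    "read_edge_table",
    "crawl",
    "crawl_all",
    "write_network",
    "read_network",
    "FORMATS",
]

_EFFECT_ALIASES = {
    "positive": "positive", "activation": "positive", "activator": "positive", "+": "positive",
    "negative": "negative", "repression": "negative", "repressor": "negative", "-": "negative",
    "dual": "dual", "+-": "dual", "-+": "dual",
}

#: Node directive used in edge-TSV files to carry zero-degree genes, which
#: a plain edge list cannot represent.  Still a '#' comment for other tools.
_NODE_DIRECTIVE = "#!node"

FORMATS = ("edge-tsv", "sif", "graphml")


class EdgeTableFormatError(ValueError):
    """Header/spec-level problem with an edge table."""


class EdgeTableRowError(ValueError):
    """A single bad data row; carries the 1-based line number."""

    def __init__(self, line_no: int, message: str):
        super().__init__(f"line {line_no}: {message}")
        self.line_no = line_no


@dataclass(frozen=True)
class EdgeTableSpec:
    """Column mapping and dialect for a delimited edge table.

    Exactly one of ``weight_col`` / ``effect_col`` must be set: a table is
    either quantitative or categorical, never both.
    """

    source_col: str = "source"
    target_col: str = "target"
    weight_col: Optional[str] = "weight"
    effect_col: Optional[str] = None
    promoter_col: Optional[str] = None
    sep: str = "\t"
    comment: str = "#"

    def __post_init__(self):
        if (self.weight_col is None) == (self.effect_col is None):
            raise EdgeTableFormatError(
                "exactly one of weight_col / effect_col must be set "
                f"(got weight_col={self.weight_col!r}, effect_col={self.effect_col!r})"
            )


#: Quantitative promoter-level tables (FANTOM4-style).
FANTOM_STYLE = EdgeTableSpec(promoter_col="promoter")
#: Categorical TF-gene tables (RegulonDB-style).
REGULONDB_STYLE = EdgeTableSpec(weight_col=None, effect_col="effect")


def read_edge_table(path, spec: EdgeTableSpec = FANTOM_STYLE) -> Iterator[SignedInteraction]:
    """Stream one :class:`SignedInteraction` per data row.

    Rows are validated as they stream: missing endpoints, unparseable
    weights and unknown effect categories raise :class:`EdgeTableRowError`
    naming the offending line.  Comment lines and blank lines are skipped.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        line_no = 0
        header = None
        reader = csv.reader(fh, delimiter=spec.sep)
        for row in reader:
            line_no += 1
            if not row or (row[0].startswith(spec.comment)):
                continue
            header = row
            break
        if header is None:
            raise EdgeTableFormatError(f"{path}: no header row found")
        idx = {name.strip(): i for i, name in enumerate(header)}
        needed = [spec.source_col, spec.target_col, spec.weight_col or spec.effect_col]
        for col in needed:
            if col not in idx:
                raise EdgeTableFormatError(f"{path}: missing mandatory column {col!r} (header: {header})")

        for row in reader:
            line_no += 1
            if not row or row[0].startswith(spec.comment):
                continue
            def cell(col):
                i = idx[col]
                return row[i].strip() if i < len(row) else ""

            source, target = cell(spec.source_col), cell(spec.target_col)
            if not source or not target:
                raise EdgeTableRowError(line_no, f"missing endpoint (source={source!r}, target={target!r})")
            promoter = None
            if spec.promoter_col and spec.promoter_col in idx:
                promoter = cell(spec.promoter_col) or None
            try:
                if spec.weight_col is not None:
                    raw = cell(spec.weight_col)
                    try:
                        weight = float(raw)
                    except ValueError:
                        raise EdgeTableRowError(line_no, f"unparseable weight {raw!r}") from None
                    yield SignedInteraction(source=source, target=target, weight=weight, promoter_id=promoter)
                else:
                    raw = cell(spec.effect_col).lower()
                    if raw not in _EFFECT_ALIASES:
                        raise EdgeTableRowError(line_no, f"unknown effect category {raw!r}")
                    yield SignedInteraction(
                        source=source, target=target,
                        sign_category=_EFFECT_ALIASES[raw], promoter_id=promoter,
                    )
            except InvalidInteractionError as exc:
                raise EdgeTableRowError(line_no, str(exc)) from exc


# --------------------------------------------------------------------- crawl

@runtime_checkable
class EdgeProvider(Protocol):
    """Gene-centric edge database interface.

    Both queries may return duplicate gene pairs with different weights
    (promoter-level records) and must be pure: repeated calls within a
    session return the same answer, and every symbol they return is
    itself queryable.
    """

    def regulators_of(self, gene: str) -> list[tuple[str, float]]:
        """(regulator symbol, weight) pairs for edges INTO ``gene``."""
        ...

    def targets_of(self, gene: str) -> list[tuple[str, float]]:
        """(target symbol, weight) pairs for edges OUT of ``gene``."""
        ...


class CrawlError(RuntimeError):
    """Provider failure mid-crawl; carries the partial network."""

    def __init__(self, symbol: str, partial: RegulatoryNetwork, cause: BaseException):
        super().__init__(f"provider query failed for gene {symbol!r}: {cause}")
        self.symbol = symbol
        self.partial = partial
        self.__cause__ = cause


def crawl(
    provider: EdgeProvider, seed: str, aggregation: str = "signed-max",
    _net: Optional[RegulatoryNetwork] = None,
) -> RegulatoryNetwork:
    """Breadth-first walk of an edge database from a seed gene.

    Maintains a FIFO queue of genes to explore and a registry of explored
    genes; each dequeued gene is queried once for regulators and once for
    targets, and every reported interaction is submitted through
    :meth:`RegulatoryNetwork.add_interaction` (max-weight rule).  The
    result equals the weakly connected component of the seed in the
    provider's union graph, independent of exploration order.
    """
    from collections import deque

    net = _net if _net is not None else RegulatoryNetwork(aggregation=aggregation)
    seed = seed.strip()
    net.add_gene(seed)
    queue = deque([seed])
    explored = {seed}
    while queue:
        gene = queue.popleft()
        try:
            incoming = provider.regulators_of(gene)
            outgoing = provider.targets_of(gene)
        except Exception as exc:  # noqa: BLE001 - provider contract is opaque
            raise CrawlError(gene, net, exc) from exc
        for regulator, w in incoming:
            net.add_interaction(SignedInteraction(source=regulator, target=gene, weight=w))
            if regulator not in explored:
                explored.add(regulator)
                queue.append(regulator)
        for target, w in outgoing:
            net.add_interaction(SignedInteraction(source=gene, target=target, weight=w))
            if target not in explored:
                explored.add(target)
                queue.append(target)
    return net


def crawl_all(
    provider: EdgeProvider, seeds: Iterable[str], aggregation: str = "signed-max"
) -> RegulatoryNetwork:
    """Union of crawls from several seeds (covers disconnected databases).

    Duplicate discoveries across seeds resolve through the same max-weight
    rule; crawling the same component twice is a no-op.
    """
    net = RegulatoryNetwork(aggregation=aggregation)
    for seed in seeds:
        crawl(provider, seed, aggregation=aggregation, _net=net)
    return net


# --------------------------------------------------------------- serialization

def _fmt_weight(w: float) -> str:
    return format(w, ".9g")


def write_network(net: RegulatoryNetwork, path, fmt: str = "edge-tsv") -> None:
    """Write a network as edge-TSV, SIF, or GraphML.

    edge-TSV rows are sorted by (source, target) and weights printed with
    9 significant digits; zero-degree genes are carried as ``#!node``
    directive lines so a read-back reproduces the network exactly.  SIF
    uses interaction type ``reg`` and drops weights (lossy).  GraphML
    stores the weight as an edge attribute and node annotations as node
    attributes.
    """
    path = Path(path)
    if fmt == "edge-tsv":
        lines = ["source\ttarget\tweight"]
        connected = set()
        for s, t, w in net.edges():
            connected.add(s)
            connected.add(t)
            lines.append(f"{s}\t{t}\t{_fmt_weight(w)}")
        for g in net.genes:
            if g not in connected:
                lines.append(f"{_NODE_DIRECTIVE} {g}")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif fmt == "sif":
        lines = [f"{s}\treg\t{t}" for s, t, _ in net.edges()]
        connected = {x for s, t, _ in net.edges() for x in (s, t)}
        lines += [g for g in net.genes if g not in connected]
        path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
    elif fmt == "graphml":
        nx.write_graphml(net.to_networkx(), path)
    else:
        raise ValueError(f"unknown network format {fmt!r}; expected one of {FORMATS}")


def read_network(path, fmt: str = "edge-tsv", aggregation: str = "signed-max") -> RegulatoryNetwork:
    """Read a network written by :func:`write_network`.

    SIF carries no weights; its edges are read back with weight +1.0.
    """
    path = Path(path)
    net = RegulatoryNetwork(aggregation=aggregation)
    if fmt == "edge-tsv":
        with path.open(encoding="utf-8") as fh:
            lines = fh.read().splitlines()
        for raw in lines:
            if raw.startswith(_NODE_DIRECTIVE):
                net.add_gene(raw[len(_NODE_DIRECTIVE):].strip())
        net.add_interactions(read_edge_table(path, EdgeTableSpec()))
    elif fmt == "sif":
        with path.open(encoding="utf-8") as fh:
            for raw in fh:
                parts = raw.split()
                if not parts:
                    continue
                if len(parts) == 1:
                    net.add_gene(parts[0])
                elif len(parts) >= 3:
                    for target in parts[2:]:
                        net.add_interaction(SignedInteraction(source=parts[0], target=target, weight=1.0))
                else:
                    raise EdgeTableFormatError(f"{path}: malformed SIF line {raw!r}")
    elif fmt == "graphml":
        g = nx.read_graphml(path)
        for n in g.nodes:
            net.add_gene(str(n), **g.nodes[n])
        for s, t, data in g.edges(data=True):
            net.add_interaction(SignedInteraction(source=str(s), target=str(t), weight=float(data["weight"])))
    else:
        raise ValueError(f"unknown network format {fmt!r}; expected one of {FORMATS}")
    return net
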