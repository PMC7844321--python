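"""Bipartite miRNA->mRNA networks.

The reference map (a global catalogue of regulator/target pairs) and the
condition-specific subnetworks extracted from it share one container,
:class:`BipartiteNetwork`.  A condition-specific network is the subgraph of
the reference induced by the differentially expressed miRNAs and mRNAs of one
contrast, with zero-degree nodes dropped; the reference itself may carry
isolated nodes.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

#: column names recognised as a header row when reading edge lists
_HEADER_TOKENS = {
    "mirna", "mirna_id", "mir", "source", "regulator",
    "mrna", "mrna_id", "gene", "gene_id", "target",
}


class BipartitenessError(ValueError):
    """An identifier occurs both as a miRNA and as an mRNA."""


class EdgeListParseError(ValueError):
    """A malformed line in an edge-list file."""


@dataclass(frozen=True)
class BipartiteNetwork:
    """Directed bipartite graph from miRNAs to their target mRNAs.

    Parameters
    ----------
    edges
        Set of ``(mirna_id, mrna_id)`` pairs, duplicates removed.
    mirna_nodes, mrna_nodes
        Node sets; may contain isolated nodes (reference maps do).
    """

    edges: frozenset = field(default_factory=frozenset)
    mirna_nodes: frozenset = field(default_factory=frozenset)
    mrna_nodes: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        overlap = self.mirna_nodes & self.mrna_nodes
        if overlap:
            raise BipartitenessError(
                f"ids present in both partitions: {sorted(overlap)[:5]}"
            )
        for m, g in self.edges:
            if m not in self.mirna_nodes or g not in self.mrna_nodes:
                raise ValueError(f"edge ({m!r}, {g!r}) has an endpoint missing from its node set")

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        mirna_nodes: Iterable[str] = (),
        mrna_nodes: Iterable[str] = (),
    ) -> "BipartiteNetwork":
        """Build a network from an edge iterable, inferring node sets.

        Extra (possibly isolated) nodes may be supplied explicitly.
        """
        edges = frozenset(edges)
        mirnas = frozenset(m for m, _ in edges) | frozenset(mirna_nodes)
        mrnas = frozenset(g for _, g in edges) | frozenset(mrna_nodes)
        return cls(edges=edges, mirna_nodes=mirnas, mrna_nodes=mrnas)

    @cached_property
    def _targets(self) -> Mapping[str, frozenset]:
        adj: dict[str, set] = {m: set() for m in self.mirna_nodes}
        for m, g in self.edges:
            adj[m].add(g)
        return {m: frozenset(v) for m, v in adj.items()}

    @cached_property
    def _regulators(self) -> Mapping[str, frozenset]:
        adj: dict[str, set] = {g: set() for g in self.mrna_nodes}
        for m, g in self.edges:
            adj[g].add(m)
        return {g: frozenset(v) for g, v in adj.items()}

    def targets_of(self, mirna: str) -> frozenset:
        if mirna not in self.mirna_nodes:
            raise KeyError(f"unknown miRNA id: {mirna!r}")
        return self._targets[mirna]

    def regulators_of(self, mrna: str) -> frozenset:
        if mrna not in self.mrna_nodes:
            raise KeyError(f"unknown mRNA id: {mrna!r}")
        return self._regulators[mrna]

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def __contains__(self, node: str) -> bool:
        return node in self.mirna_nodes or node in self.mrna_nodes


def read_edge_list(path, header: bool | str = "auto", sep: str = "\t") -> BipartiteNetwork:
    """Read a two-column miRNA/mRNA edge list.

    ``header`` may be True, False or ``"auto"`` (skip the first line when its
    fields look like column names).  Duplicate edges are dropped with a logged
    count; a line with other than two fields raises
    :class:`EdgeListParseError` naming the line number.
    """
    rows: list[tuple[str, str]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=sep)
        for lineno, fields in enumerate(reader, start=1):
            if not fields or (len(fields) == 1 and not fields[0].strip()):
                continue  # blank line
            if len(fields) != 2:
                raise EdgeListParseError(
                    f"{path}: line {lineno}: expected 2 tab-separated fields, got {len(fields)}"
                )
            rows.append((fields[0].strip(), fields[1].strip()))
    if rows and header != False:  # noqa: E712 - header may be the string "auto"
        first = rows[0]
        is_header = header is True or (
            header == "auto" and any(f.lower() in _HEADER_TOKENS for f in first)
        )
        if is_header:
            rows = rows[1:]
    n_dup = len(rows) - len(set(rows))
    if n_dup:
        logger.warning("%s: %d duplicate edge line(s) dropped", path, n_dup)
    return BipartiteNetwork.from_edges(rows)


def write_edge_list(network: BipartiteNetwork, path, header: bool = False) -> None:
    """Write the network as a sorted two-column TSV edge list."""
    with open(path, "w") as fh:
        if header:
            fh.write("mirna\tmrna\n")
        for m, g in sorted(network.edges):
            fh.write(f"{m}\t{g}\n")


def extract_condition_network(
    reference: BipartiteNetwork,
    de_mirnas: Iterable[str],
    de_mrnas: Iterable[str],
) -> BipartiteNetwork:
    """Induce the condition-specific subnetwork on DE feature sets.

    Keeps exactly the reference edges whose miRNA is in ``de_mirnas`` and whose
    mRNA is in ``de_mrnas``; nodes left with zero degree are dropped.  DE ids
    absent from the reference are ignored (logged).
    """
    de_mirnas = set(de_mirnas)
    de_mrnas = set(de_mrnas)
    unknown = (de_mirnas - reference.mirna_nodes) | (de_mrnas - reference.mrna_nodes)
    if unknown:
        logger.info("%d DE id(s) absent from the reference network ignored", len(unknown))
    edges = frozenset(
        (m, g) for m, g in reference.edges if m in de_mirnas and g in de_mrnas
    )
    return BipartiteNetwork.from_edges(edges)


def to_graphml(network: BipartiteNetwork, path) -> None:
    """Export for visualization; node attribute ``kind`` marks the partition."""
    import networkx as nx

    g = nx.DiGraph()
    for m in sorted(network.mirna_nodes):
        g.add_node(m, kind="miRNA")
    for t in sorted(network.mrna_nodes):
        g.add_node(t, kind="mRNA")
    g.add_edges_from(sorted(network.edges))
    nx.write_graphml(g, path)
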