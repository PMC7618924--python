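"""Lineage forest: nuclei over time connected by continuation/division edges.

Nodes are ``(frame, label)`` pairs.  Invariants: in-degree ≤ 1, out-degree
≤ 2, out-degree-2 nodes are divisions, the graph is acyclic (edges only go
forward in time).
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .core import DataFormatError

Node = tuple[int, int]


class LineageForest:
    """Forest of nucleus tracks with typed edges and derived events."""

    def __init__(self, n_frames: int | None = None):
        self.graph = nx.DiGraph()
        self._n_frames = n_frames

    # -- construction -------------------------------------------------
    def add_node(self, frame: int, label: int, **attrs) -> None:
        self.graph.add_node((int(frame), int(label)), **attrs)

    def add_edge(self, src: Node, dst: Node, kind: str = "continuation") -> None:
        src = (int(src[0]), int(src[1]))
        dst = (int(dst[0]), int(dst[1]))
        if dst[0] <= src[0]:
            raise DataFormatError(f"edge {src}->{dst} does not advance in time")
        self.graph.add_edge(src, dst, kind=kind)
        if self.graph.out_degree(src) > 2:
            self.graph.remove_edge(src, dst)
            raise DataFormatError(f"node {src} would exceed out-degree 2")
        if self.graph.in_degree(dst) > 1:
            self.graph.remove_edge(src, dst)
            raise DataFormatError(f"node {dst} would exceed in-degree 1")

    # -- queries ------------------------------------------------------
    @property
    def n_frames(self) -> int:
        if self._n_frames is not None:
            return self._n_frames
        if not self.graph:
            return 0
        return max(f for f, _ in self.graph.nodes) + 1

    def nodes_at(self, frame: int) -> list[Node]:
        return sorted(n for n in self.graph.nodes if n[0] == frame)

    def roots(self) -> list[Node]:
        return sorted(n for n in self.graph.nodes if self.graph.in_degree(n) == 0)

    def leaves(self) -> list[Node]:
        return sorted(n for n in self.graph.nodes if self.graph.out_degree(n) == 0)

    def division_nodes(self) -> list[Node]:
        return sorted(n for n in self.graph.nodes if self.graph.out_degree(n) == 2)

    def edges(self, kind: str | None = None) -> list[tuple[Node, Node, str]]:
        out = [(u, v, d.get("kind", "continuation"))
               for u, v, d in self.graph.edges(data=True)]
        if kind is not None:
            out = [e for e in out if e[2] == kind]
        return sorted(out)

    def appearances(self) -> list[Node]:
        """Nodes with no predecessor after the first frame."""
        first = min((f for f, _ in self.graph.nodes), default=0)
        return sorted(n for n in self.graph.nodes
                      if self.graph.in_degree(n) == 0 and n[0] > first)

    def disappearances(self) -> list[Node]:
        """Nodes with no successor before the last frame."""
        last = self.n_frames - 1
        return sorted(n for n in self.graph.nodes
                      if self.graph.out_degree(n) == 0 and n[0] < last)

    def counts(self) -> pd.Series:
        """Live-node count per frame (index = frame)."""
        nf = self.n_frames
        c = np.zeros(nf, dtype=int)
        for f, _ in self.graph.nodes:
            c[f] += 1
        return pd.Series(c, index=pd.RangeIndex(nf, name="frame"), name="n_nuclei")

    def tracks(self) -> list[list[Node]]:
        """Maximal unbranched chains (between roots/divisions and
        leaves/divisions), each sorted by frame."""
        out = []
        starts = list(self.roots())
        for d in self.division_nodes():
            starts.extend(self.graph.successors(d))
        for s in sorted(set(starts)):
            chain = [s]
            cur = s
            while self.graph.out_degree(cur) == 1:
                nxt = next(iter(self.graph.successors(cur)))
                chain.append(nxt)
                cur = nxt
            out.append(chain)
        return out

    def validate(self) -> None:
        for n in self.graph.nodes:
            if self.graph.in_degree(n) > 1:
                raise DataFormatError(f"node {n} has in-degree > 1")
            if self.graph.out_degree(n) > 2:
                raise DataFormatError(f"node {n} has out-degree > 2")
        if not nx.is_directed_acyclic_graph(self.graph):
            raise DataFormatError("lineage graph has a cycle")

    def edge_set(self) -> set[tuple[Node, Node]]:
        return set(self.graph.edges())

    def __eq__(self, other) -> bool:
        if not isinstance(other, LineageForest):
            return NotImplemented
        return (set(self.graph.nodes) == set(other.graph.nodes)
                and self.edge_set() == other.edge_set())
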