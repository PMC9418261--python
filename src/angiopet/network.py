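"""Lattice-anchored microvascular network container.

Nodes are lattice sites (row ``i``, column ``j``) stored as flat indices
``i * n_side + j``; every segment joins two 4-adjacent sites, so its length
is always one grid spacing.  Segments carry diameter (um), length (um),
hematocrit, flow (m^3/s) and blood viscosity (Pa s); the flow state proper
lives in :class:`angiopet.hemodynamics.NetworkFlowState`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = ["VesselNetwork"]


@dataclass
class VesselNetwork:
    n_side: int                 # lattice nodes per side
    grid_spacing_m: float       # h in metres (segment length)
    nodes: set[int] = field(default_factory=set)
    segments: list[tuple[int, int]] = field(default_factory=list)
    diameters_um: list[float] = field(default_factory=list)
    parent_nodes: list[int] = field(default_factory=list)
    _seg_set: set[tuple[int, int]] = field(default_factory=set, repr=False)

    # --- lattice addressing ----------------------------------------------
    def flat(self, i: int, j: int) -> int:
        return i * self.n_side + j

    def ij(self, node: int) -> tuple[int, int]:
        return divmod(node, self.n_side)

    def xy_m(self, node: int) -> tuple[float, float]:
        i, j = self.ij(node)
        return j * self.grid_spacing_m, i * self.grid_spacing_m

    @property
    def length_um(self) -> float:
        return self.grid_spacing_m * 1e6

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    # --- construction -----------------------------------------------------
    def add_segment(self, a: int, b: int, d_um: float) -> bool:
        """Add a segment between 4-adjacent lattice nodes; returns False if
        the segment already exists."""
        ia, ja = self.ij(a)
        ib, jb = self.ij(b)
        if abs(ia - ib) + abs(ja - jb) != 1:
            raise ValueError(f"segment endpoints {a}-{b} are not 4-adjacent")
        key = (a, b) if a < b else (b, a)
        if key in self._seg_set:
            return False
        self._seg_set.add(key)
        self.segments.append(key)
        self.diameters_um.append(float(d_um))
        self.nodes.add(a)
        self.nodes.add(b)
        return True

    def has_segment(self, a: int, b: int) -> bool:
        return ((a, b) if a < b else (b, a)) in self._seg_set

    # --- queries ------------------------------------------------------------
    def degree(self, node: int) -> int:
        return sum(1 for a, b in self.segments if a == node or b == node)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for k, (a, b) in enumerate(self.segments):
            g.add_edge(a, b, index=k, d_um=self.diameters_um[k])
        return g

    def cycle_rank(self) -> int:
        """Number of independent loops (first Betti number)."""
        g = self.to_graph()
        return g.number_of_edges() - g.number_of_nodes() + nx.number_connected_components(g)

    def segment_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(a, b, d_um) as numpy arrays."""
        if not self.segments:
            return (np.empty(0, dtype=int), np.empty(0, dtype=int), np.empty(0))
        ab = np.asarray(self.segments, dtype=int)
        return ab[:, 0], ab[:, 1], np.asarray(self.diameters_um)

    def node_list(self) -> np.ndarray:
        return np.asarray(sorted(self.nodes), dtype=int)

    def copy(self) -> "VesselNetwork":
        return VesselNetwork(
            self.n_side, self.grid_spacing_m,
            set(self.nodes), list(self.segments), list(self.diameters_um),
            list(self.parent_nodes), set(self._seg_set),
        )

    def subnetwork(self, keep: np.ndarray) -> "VesselNetwork":
        """Network restricted to segments where ``keep`` is True; nodes and
        parent markers pruned accordingly."""
        sub = VesselNetwork(self.n_side, self.grid_spacing_m)
        for k, (a, b) in enumerate(self.segments):
            if keep[k]:
                sub.add_segment(a, b, self.diameters_um[k])
        sub.parent_nodes = [p for p in self.parent_nodes if p in sub.nodes]
        return sub

    def validate(self) -> None:
        """Check the structural invariants (adjacency, positivity, parent
        connectivity)."""
        for k, (a, b) in enumerate(self.segments):
            ia, ja = self.ij(a)
            ib, jb = self.ij(b)
            if abs(ia - ib) + abs(ja - jb) != 1:
                raise ValueError(f"segment {k} endpoints not 4-adjacent")
            if self.diameters_um[k] <= 0:
                raise ValueError(f"segment {k} has non-positive diameter")
        if self.segments and self.parent_nodes:
            g = self.to_graph()
            reach = set()
            for p in self.parent_nodes:
                if p in g and p not in reach:
                    reach |= nx.node_connected_component(g, p)
            if not set(self.nodes) <= reach:
                raise ValueError("network has nodes disconnected from the parent vessel")
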