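"""Exhaustive verification oracle for the grid computations.

Enumerates every simple cycle of the (subdivided) network, so per-edge
shortest round paths are exact minima over all cycles, and the minimum
cycle basis is selected by matroid-greedy over the *complete* cycle set —
independent of the Horton candidate construction used by the fast path.
Guarded to small instances (<= 15 interaction edges by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .network import EdgeRef, ThermoringNetwork, gf2_insert

MAX_INTERACTION_EDGES = 15


@dataclass
class OracleResult:
    per_edge_sizes: dict[EdgeRef, int | None]
    basis_sizes: list[int]

    @property
    def total_s(self) -> int:
        return sum(self.basis_sizes)


def brute_force_grid_oracle(
    net: ThermoringNetwork,
    max_interaction_edges: int = MAX_INTERACTION_EDGES,
) -> OracleResult:
    """Exact per-edge grid sizes and minimum-basis weight by enumeration.

    Refuses instances above the size guard rather than running forever.
    """
    if net.n_interactions > max_interaction_edges:
        raise ValueError(
            f"{net.n_interactions} interaction edges exceed the oracle "
            f"guard of {max_interaction_edges}"
        )
    sg, eid_map = net._simple_graph()
    edge_w = {tuple(sorted(e)): sg.edges[e]["weight"] for e in sg.edges}
    edge_j = {tuple(sorted(e)): sg.edges[e]["j"] for e in sg.edges}
    edge_eid = {tuple(sorted(e)): sg.edges[e]["eid"] for e in sg.edges}

    cycles = []  # (true weight, sorted node tuple, edge set, eid set)
    for nodes in nx.simple_cycles(sg):
        ring = list(nodes) + [nodes[0]]
        edges = {tuple(sorted((a, b))) for a, b in zip(ring, ring[1:])}
        weight = sum(edge_w[e] for e in edges)
        eids = {edge_eid[e] for e in edges}
        cycles.append((weight, tuple(sorted(nodes)), edges, eids))
    cycles.sort(key=lambda c: (c[0], c[1]))

    per_edge: dict[EdgeRef, int | None] = {}
    for eid, ref in eid_map.items():
        if ref.kind != "interaction":
            continue
        hits = [w for w, _, _, eids in cycles if eid in eids]
        per_edge[ref] = min(hits) if hits else None

    mu = (sg.number_of_edges() - sg.number_of_nodes()
          + nx.number_connected_components(sg))
    basis_masks: dict[int, int] = {}
    basis_sizes: list[int] = []
    for weight, _, edges, _ in cycles:
        mask = 0
        for e in edges:
            mask |= 1 << edge_j[e]
        if gf2_insert(basis_masks, mask):
            basis_sizes.append(weight)
            if len(basis_sizes) == mu:
                break
    return OracleResult(per_edge_sizes=per_edge,
                        basis_sizes=sorted(basis_sizes))
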