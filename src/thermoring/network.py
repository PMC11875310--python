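"""The grid-like thermoring network and its cycle ("grid") analysis.

Nodes are the *engaged* residues of a pathway (those taking part in at
least one intra-pathway noncovalent interaction), ordered by author
number.  Consecutive engaged residues are joined by a *sequence edge*
whose integer weight counts the free (silent) residues between them;
every detected interaction contributes an *interaction edge* of weight 0.

A *grid* is one independent cycle of this mesh.  Its size ``s`` is the
number of free residues along the cycle, i.e. the cycle's total weight.
Two quantities summarise a state:

* ``N`` — the number of interaction edges, and
* ``S`` — the total weight of a minimum-weight cycle basis,

from which the systematic thermal instability ``T_i = S/N`` follows.

The per-edge "shortest round path" (the smallest grid closing over a
given interaction) is the shortest path between the edge's endpoints in
the network with that edge removed.  The minimum-weight cycle basis is
computed with Horton's algorithm: candidate cycles are built from
single-source shortest-path trees, then a basis is selected greedily by
weight under GF(2) independence.  Edge weights are made unique by a
power-of-two perturbation so shortest paths, and hence the Horton set,
are well defined even with ties.

Parallel edges (a sequence edge next to an interaction edge between
adjacent engaged residues, or two interaction types on one pair) are
legitimate and close 2-cycles of size 0 — the "smallest Grid_0" cases.
Internally every parallel edge beyond the first is subdivided with a
virtual node so both the basis algorithm and the exhaustive oracle run
on a simple graph; virtual nodes are stripped from all reported cycles.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx

from .interactions import Interaction, InteractionSet
from .structure import PathwaySelection

logger = logging.getLogger(__name__)

SEQUENCE = "sequence"
INTERACTION = "interaction"


@dataclass(frozen=True)
class EdgeRef:
    """Stable identity of one network edge."""

    u: int
    v: int
    key: int  # multigraph key
    kind: str
    itype: str | None = None

    @property
    def pair(self) -> tuple[int, int]:
        return tuple(sorted((self.u, self.v)))


@dataclass
class Grid:
    """One round path (cycle) of the mesh with its free-residue size."""

    label: str
    cycle: list[int]  # residue numbers in cycle order
    size_s: int
    interaction_edges: list[EdgeRef]
    controlled: list[EdgeRef]  # least-stable member interaction(s)
    n_equiv: float  # basic-H-bond equivalents of the controlled bridge(s)

    def __post_init__(self) -> None:
        if self.size_s < 0:
            raise ValueError("grid size cannot be negative")


@dataclass
class NetworkSummary:
    """Per-state totals: N, S, the grid list, biggest and smallest grids."""

    n_interactions: int
    total_grid_sizes: int
    grids: list[Grid]
    biggest_grid: Grid | None
    smallest_grids: list[Grid]
    per_edge_sizes: dict[EdgeRef, int | None]
    controlling_grid: dict[EdgeRef, str] = field(default_factory=dict)


class ThermoringNetwork:
    """Sequence-ordered engaged residues plus weighted sequence/interaction
    edges, wrapped around a ``networkx.MultiGraph``."""

    def __init__(self, graph: nx.MultiGraph,
                 pathway: PathwaySelection | None = None,
                 grid_energy_overrides: dict | None = None):
        self.graph = graph
        self.pathway = pathway
        self.grid_energy_overrides = grid_energy_overrides or {}
        self._assign_edge_ids()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_interactions(
        cls,
        iset: InteractionSet,
        selection: PathwaySelection | None = None,
        count_unmodeled_as_free: bool = True,
    ) -> "ThermoringNetwork":
        """Build the network from detected interactions.

        Interactions naming residues outside the selection are excluded with
        a warning.  Sequence-edge weights come from author-numbering gaps;
        with ``count_unmodeled_as_free`` (default) unmodelled positions count
        as free residues, otherwise only modelled ones do.
        """
        selection = selection or iset.pathway
        intra = iset.intra()
        if not intra:
            raise ValueError("cannot build a network from an empty "
                             "interaction set")
        kept: list[Interaction] = []
        for ia in intra:
            a, b = ia.pair
            if selection is not None and (a not in selection
                                          or b not in selection):
                logger.warning("interaction %s-%s outside pathway "
                               "[%d, %d]: excluded", a, b,
                               selection.start, selection.end)
                continue
            kept.append(ia)
        if not kept:
            raise ValueError("no interaction lies inside the pathway")
        gaps = set(selection.gaps) if selection is not None else set()
        pairs = [(ia.pair, ia.itype.value, ia.energy_equiv) for ia in kept]
        return cls._assemble(pairs, gaps if not count_unmodeled_as_free
                             else None, selection,
                             iset.grid_energy_overrides)

    @classmethod
    def from_pairs(
        cls,
        pairs: list[tuple[int, int]],
        energies: dict[tuple[int, int], float] | None = None,
    ) -> "ThermoringNetwork":
        """Build an abstract network from residue-number pairs (all
        intervening residues free, default energy 1)."""
        if not pairs:
            raise ValueError("cannot build a network from an empty pair list")
        energies = {tuple(sorted(k)): v for k, v in (energies or {}).items()}
        triples = []
        for p in pairs:
            key = tuple(sorted(p))
            if key[0] == key[1]:
                raise ValueError(f"self-pair {p}")
            triples.append((key, INTERACTION, energies.get(key, 1.0)))
        return cls._assemble(triples, None, None, None)

    @classmethod
    def _assemble(cls, triples, modeled_free_filter, selection, grid_ov):
        engaged = sorted({n for pair, _, _ in triples for n in pair})
        g = nx.MultiGraph()
        g.add_nodes_from(engaged)
        for a, b in itertools.pairwise(engaged):
            between = range(a + 1, b)
            if modeled_free_filter is None:
                w = b - a - 1
            else:  # count only modelled free residues
                w = sum(1 for n in between if n not in modeled_free_filter)
            g.add_edge(a, b, kind=SEQUENCE, weight=int(w), itype=None,
                       energy=None)
        seen = set()
        for (a, b), itype, energy in sorted(triples):
            if ((a, b), itype) in seen:
                continue
            seen.add(((a, b), itype))
            g.add_edge(a, b, kind=INTERACTION, weight=0, itype=itype,
                       energy=float(energy))
        return cls(g, pathway=selection, grid_energy_overrides=grid_ov)

    def _assign_edge_ids(self) -> None:
        """Deterministic integer ids over all multigraph edges."""
        edges = sorted(
            self.graph.edges(keys=True, data=True),
            key=lambda e: (min(e[0], e[1]), max(e[0], e[1]),
                           e[3]["kind"], str(e[3]["itype"]), e[2]),
        )
        self._edges: list[EdgeRef] = []
        self._edge_data: dict[EdgeRef, dict] = {}
        for u, v, k, data in edges:
            u, v = min(u, v), max(u, v)
            ref = EdgeRef(u, v, k, data["kind"], data["itype"])
            self._edges.append(ref)
            self._edge_data[ref] = data

    # -- views ------------------------------------------------------------

    @property
    def nodes(self) -> list[int]:
        return sorted(self.graph.nodes)

    @property
    def sequence_edges(self) -> list[EdgeRef]:
        return [e for e in self._edges if e.kind == SEQUENCE]

    @property
    def interaction_edges(self) -> list[EdgeRef]:
        return [e for e in self._edges if e.kind == INTERACTION]

    @property
    def n_interactions(self) -> int:
        return len(self.interaction_edges)

    def edge_weight(self, ref: EdgeRef) -> int:
        return self._edge_data[ref]["weight"]

    def edge_energy(self, ref: EdgeRef) -> float | None:
        return self._edge_data[ref]["energy"]

    def find_interaction_edge(self, a: int, b: int,
                              itype: str | None = None) -> EdgeRef:
        a, b = min(a, b), max(a, b)
        hits = [e for e in self.interaction_edges
                if e.pair == (a, b) and (itype is None or e.itype == itype)]
        if not hits:
            raise KeyError(f"no interaction edge {a}-{b}")
        return hits[0]

    # -- simple-graph transform -------------------------------------------

    def _simple_graph(self) -> tuple[nx.Graph, dict[int, EdgeRef]]:
        """Subdivide parallel edges; return (simple graph, edge-id map).

        Simple-graph nodes are the residue numbers plus negative integers
        for virtual subdivision nodes.  Every simple edge carries ``eid``
        (index into the original edge list) and its true integer ``weight``.
        """
        sg = nx.Graph()
        sg.add_nodes_from(self.graph.nodes)
        next_virtual = -1
        eid_map: dict[int, EdgeRef] = {}
        for eid, ref in enumerate(self._edges):
            eid_map[eid] = ref
            w = self.edge_weight(ref)
            if not sg.has_edge(ref.u, ref.v):
                sg.add_edge(ref.u, ref.v, weight=w, eid=eid)
            else:
                vn = next_virtual
                next_virtual -= 1
                sg.add_node(vn)
                sg.add_edge(ref.u, vn, weight=w, eid=eid)
                sg.add_edge(vn, ref.v, weight=0, eid=eid)
        # unique perturbed weights: pw = w * 2^m + 2^j
        m = sg.number_of_edges()
        for j, (u, v) in enumerate(sorted(sg.edges())):
            sg[u][v]["pw"] = sg[u][v]["weight"] * (1 << m) + (1 << j)
            sg[u][v]["j"] = j
        return sg, eid_map

    # -- shortest round path per edge --------------------------------------

    def grid_size_of_edge(self, edge: EdgeRef | tuple) -> int | None:
        """Free-residue count of the smallest grid closing over *edge*.

        Equals the weight of the shortest path between the edge's endpoints
        in the network with that edge removed (interaction edges weigh 0).
        Returns ``None`` when no round path exists (acyclic marker).
        """
        if not isinstance(edge, EdgeRef):
            edge = self.find_interaction_edge(*edge)
        if edge not in self._edge_data:
            raise KeyError(f"edge {edge} not in network")
        h = self.graph.copy()
        h.remove_edge(edge.u, edge.v, key=edge.key)
        try:
            span = nx.dijkstra_path_length(h, edge.u, edge.v, weight="weight")
        except nx.NetworkXNoPath:
            return None
        return int(span) + self.edge_weight(edge)


# --------------------------------------------------------------------------
# GF(2) cycle-space helpers (shared with the brute-force oracle).

def gf2_insert(basis: dict[int, int], mask: int) -> bool:
    """Gaussian elimination over GF(2) with bitmask rows.

    *basis* maps pivot bit -> reduced mask.  Returns True (and updates the
    basis) when *mask* is independent of it."""
    while mask:
        pivot = mask.bit_length() - 1
        if pivot in basis:
            mask ^= basis[pivot]
        else:
            basis[pivot] = mask
            return True
    return False


def cycle_nodes_in_order(edge_set: set[tuple[int, int]]) -> list[int]:
    """Order the nodes of a simple cycle given as an edge set; virtual
    (negative) nodes are dropped.  Deterministic: starts at the smallest
    node and proceeds toward its smaller neighbour."""
    adj: dict[int, list[int]] = {}
    for u, v in edge_set:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    start = min(adj)
    ordered = [start]
    prev, cur = None, start
    while True:
        nxt = sorted(n for n in adj[cur] if n != prev)
        step = nxt[0] if nxt else prev
        if step == start:
            break
        ordered.append(step)
        prev, cur = cur, step
    return [n for n in ordered if n >= 0]


def _is_simple_cycle(edge_set: set[tuple[int, int]]) -> bool:
    deg: dict[int, int] = {}
    for u, v in edge_set:
        deg[u] = deg.get(u, 0) + 1
        deg[v] = deg.get(v, 0) + 1
    if any(d != 2 for d in deg.values()):
        return False
    # connectivity walk
    nodes = set(deg)
    adj: dict[int, list[int]] = {n: [] for n in nodes}
    for u, v in edge_set:
        adj[u].append(v)
        adj[v].append(u)
    seen = {next(iter(nodes))}
    stack = list(seen)
    while stack:
        for n in adj[stack.pop()]:
            if n not in seen:
                seen.add(n)
                stack.append(n)
    return seen == nodes


def _path_edges(path: list[int]) -> set[tuple[int, int]]:
    return {(min(a, b), max(a, b)) for a, b in itertools.pairwise(path)}


def minimum_cycle_basis_horton(
    sg: nx.Graph,
) -> list[tuple[set[tuple[int, int]], int]]:
    """Minimum-weight cycle basis of a simple weighted graph.

    Horton candidate cycles (shortest-path tree through every node x every
    edge) are screened for simplicity, sorted by perturbed weight and
    selected greedily under GF(2) independence.  Returns ``(edge set, true
    weight)`` per basis cycle.  Perturbed weights make shortest paths unique,
    which keeps the greedy selection exact.
    """
    m = sg.number_of_edges()
    n = sg.number_of_nodes()
    ncomp = nx.number_connected_components(sg)
    mu = m - n + ncomp
    if mu == 0:
        return []
    edge_j = {tuple(sorted(e)): sg.edges[e]["j"] for e in sg.edges}
    edge_w = {tuple(sorted(e)): sg.edges[e]["weight"] for e in sg.edges}
    edge_pw = {tuple(sorted(e)): sg.edges[e]["pw"] for e in sg.edges}

    candidates: dict[frozenset, int] = {}
    for v in sg.nodes:
        _, paths = nx.single_source_dijkstra(sg, v, weight="pw")
        for x, y in sg.edges:
            if x not in paths or y not in paths:
                continue
            cyc = _path_edges(paths[x]) ^ _path_edges(paths[y])
            cyc ^= {(min(x, y), max(x, y))}
            if not cyc or not _is_simple_cycle(cyc):
                continue
            key = frozenset(cyc)
            if key not in candidates:
                candidates[key] = sum(edge_pw[e] for e in cyc)

    ordered = sorted(candidates.items(), key=lambda kv: kv[1])
    basis_masks: dict[int, int] = {}
    chosen: list[tuple[set, int]] = []
    for cyc, _pw in ordered:
        mask = 0
        for e in cyc:
            mask |= 1 << edge_j[e]
        if gf2_insert(basis_masks, mask):
            chosen.append((set(cyc), sum(edge_w[e] for e in cyc)))
            if len(chosen) == mu:
                break
    if len(chosen) < mu:  # cannot happen for a Horton set; guard anyway
        raise RuntimeError("incomplete cycle basis")
    return chosen


# --------------------------------------------------------------------------
# Grid enumeration and summary.

def _grid_n_equiv(net: ThermoringNetwork, controlled: list[EdgeRef]) -> float:
    key = frozenset(e.pair for e in controlled)
    if key in net.grid_energy_overrides:
        return net.grid_energy_overrides[key]
    return sum(net.edge_energy(e) or 1.0 for e in controlled)


def enumerate_grids(net: ThermoringNetwork) -> list[Grid]:
    """Minimum-weight cycle basis of the network, one :class:`Grid` per
    basis cycle.  An acyclic network yields an empty list (S = 0)."""
    sg, eid_map = net._simple_graph()
    basis = minimum_cycle_basis_horton(sg)
    grids: list[Grid] = []
    raw = []
    for edge_set, weight in basis:
        eids = {sg.edges[e]["eid"] for e in edge_set}
        inter = [eid_map[i] for i in sorted(eids)
                 if eid_map[i].kind == INTERACTION]
        cycle = cycle_nodes_in_order(edge_set)
        raw.append((weight, cycle, inter))
    raw.sort(key=lambda t: (-t[0], t[1]))
    primes_seen: dict[int, int] = {}
    for weight, cycle, inter in raw:
        count = primes_seen.get(weight, 0)
        primes_seen[weight] = count + 1
        label = f"Grid_{weight}" + "'" * count
        if inter:
            emin = min(net.edge_energy(e) or 1.0 for e in inter)
            controlled = [e for e in inter
                          if (net.edge_energy(e) or 1.0) == emin]
        else:
            controlled = []
        grids.append(Grid(label=label, cycle=cycle, size_s=weight,
                          interaction_edges=inter, controlled=controlled,
                          n_equiv=_grid_n_equiv(net, controlled)
                          if controlled else 0.0))
    return grids


def summarize(net: ThermoringNetwork,
              grids: list[Grid] | None = None) -> NetworkSummary:
    """N, S, the biggest grid (with its least-stable controlled bridge),
    the size-0 grids, per-edge shortest round paths, and each interaction
    edge's controlling grid (the smallest basis grid containing it)."""
    if grids is None:
        grids = enumerate_grids(net)
    total_s = sum(g.size_s for g in grids)
    biggest = grids[0] if grids else None
    smallest = [g for g in grids if g.size_s == 0]
    per_edge = {e: net.grid_size_of_edge(e) for e in net.interaction_edges}
    controlling: dict[EdgeRef, str] = {}
    for e in net.interaction_edges:
        holding = [g for g in grids if e in g.interaction_edges]
        if holding:
            controlling[e] = min(holding, key=lambda g: (g.size_s, g.cycle)).label
    return NetworkSummary(
        n_interactions=net.n_interactions,
        total_grid_sizes=total_s,
        grids=grids,
        biggest_grid=biggest,
        smallest_grids=smallest,
        per_edge_sizes=per_edge,
        controlling_grid=controlling,
    )


def export_edge_list(net: ThermoringNetwork, path) -> None:
    """Plain-text edge list: ``u v kind weight itype energy`` per line."""
    lines = ["# u\tv\tkind\tweight\titype\tenergy"]
    for ref in net._edges:
        lines.append(
            f"{ref.u}\t{ref.v}\t{ref.kind}\t{net.edge_weight(ref)}"
            f"\t{ref.itype or '-'}\t{net.edge_energy(ref) or '-'}"
        )
    from pathlib import Path
    Path(path).write_text("\n".join(lines) + "\n")
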