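"""Exact contig ordering via a traveling-salesman reduction.

Edge weights are flipped into distances (``m - w`` with ``m`` the maximum
adjacency weight) and an intermediate node is added between each contig's
two connectors so that every Hamiltonian cycle traverses each contig exactly
once, in one orientation.  A branch-and-bound search over signed contig
permutations (which is equivalent to the cycle search on the enlarged
graph, because the zero-distance intermediate edges force the
``l - v - r`` traversal) finds a minimum-distance cycle, i.e. a
maximum-total-weight circular contig order.  The cycle is cut at its
lowest-weight realized adjacency to report a linear order.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .adjacency import AdjacencyGraph, Connector

__all__ = ["TspInstance", "SignedOrdering", "to_tsp", "solve_exact"]


class TspTimeout(RuntimeError):
    """Raised when the exact solver exceeds its time limit."""


@dataclass
class TspInstance:
    """TSP form of an adjacency graph.

    ``nodes`` are the 2n connectors plus one intermediate node per contig;
    adjacency distances are ``max_weight - w``; the two edges via each
    intermediate node have distance 0; intra edges are removed (absent).
    """

    contig_ids: List[str]
    max_weight: float
    # distance[(connector, connector)] for adjacency edges only
    distances: Dict[Tuple[Connector, Connector], float]

    @property
    def n(self) -> int:
        return len(self.contig_ids)

    @property
    def nodes(self) -> List:
        out: List = []
        for c in self.contig_ids:
            out.extend([(c, "L"), (c, "mid"), (c, "R")])
        return out

    def distance(self, u: Connector, v: Connector) -> float:
        if u[0] == v[0]:
            raise KeyError("intra contig edges are removed from the instance")
        return self.distances[(u, v)]

    def weight(self, u: Connector, v: Connector) -> float:
        return self.max_weight - self.distance(u, v)


@dataclass
class SignedOrdering:
    """A signed permutation of the contigs with its realized cycle weight.

    ``sequence`` holds ``(contig_id, '+'|'-')`` pairs; ``total_weight`` is
    the sum of adjacency weights realized along the circular tour (n edges).
    """

    sequence: List[Tuple[str, str]]
    total_weight: float
    cut_weight: float = 0.0

    def write_tsv(self, path, weights_to_next: Optional[List[float]] = None) -> None:
        with open(path, "w") as fh:
            fh.write("rank\tcontig_id\torientation\tweight_to_next\n")
            for rank, (cid, orient) in enumerate(self.sequence):
                w = ""
                if weights_to_next is not None and rank < len(weights_to_next):
                    w = f"{weights_to_next[rank]:.10g}"
                fh.write(f"{rank}\t{cid}\t{orient}\t{w}\n")


def to_tsp(graph: AdjacencyGraph) -> TspInstance:
    """Flip weights into distances and add intermediate nodes."""
    m = graph.max_adjacency_weight()
    distances: Dict[Tuple[Connector, Connector], float] = {}
    for e in graph.adjacency_edges():
        u, v = tuple(e)
        d = m - graph.weight(u, v)
        distances[(u, v)] = d
        distances[(v, u)] = d
    return TspInstance(contig_ids=list(graph.contig_ids), max_weight=m,
                       distances=distances)


def _out_connector(cid: str, orient: str) -> Connector:
    return (cid, "R" if orient == "+" else "L")


def _in_connector(cid: str, orient: str) -> Connector:
    return (cid, "L" if orient == "+" else "R")


def solve_exact(
    instance: TspInstance,
    time_limit: Optional[float] = None,
    exact_limit: int = 14,
) -> SignedOrdering:
    """Optimal signed contig order by depth-first branch and bound.

    Contigs are explored in lexicographic id order with ``+`` before ``-``
    so that, among equally good tours, the first (lexicographically least)
    one found is kept; the search is deterministic.  Raises
    :class:`TspTimeout` when ``time_limit`` seconds elapse, advising the
    layout heuristic for large instances.
    """
    ids = sorted(instance.contig_ids)
    n = len(ids)
    if n > exact_limit:
        raise ValueError(
            f"{n} contigs exceed the exact-solver bound ({exact_limit}); "
            "use the layout heuristic instead"
        )
    if n == 1:
        return SignedOrdering(sequence=[(ids[0], "+")], total_weight=0.0)

    dist = instance.distances
    min_dist = min(dist.values()) if dist else 0.0
    start = time.monotonic()

    # Seed the upper bound with a nearest-neighbour tour.
    best_cost, best_seq = _nearest_neighbour(ids, dist)

    # Reflection symmetry: fix the first contig and its orientation.
    first = (ids[0], "+")
    path: List[Tuple[str, str]] = [first]
    used = {ids[0]}

    def dfs(cost: float) -> None:
        nonlocal best_cost, best_seq
        if time_limit is not None and time.monotonic() - start > time_limit:
            raise TspTimeout(
                "exact TSP time limit exceeded; consider the layout "
                "heuristic (build_layout) for this instance"
            )
        k = len(path)
        if k == n:
            closing = dist[(_out_connector(*path[-1]), _in_connector(*first))]
            total = cost + closing
            if total < best_cost:
                best_cost = total
                best_seq = list(path)
            return
        remaining_edges = n - k  # edges still to add (incl. closing edge)
        if cost + remaining_edges * min_dist >= best_cost:
            return
        out = _out_connector(*path[-1])
        for cid in ids:
            if cid in used:
                continue
            for orient in ("+", "-"):
                step = dist[(out, _in_connector(cid, orient))]
                path.append((cid, orient))
                used.add(cid)
                dfs(cost + step)
                used.remove(cid)
                path.pop()

    dfs(0.0)

    total_weight = n * instance.max_weight - best_cost
    return _linearize(best_seq, instance, total_weight)


def _nearest_neighbour(ids, dist) -> Tuple[float, List[Tuple[str, str]]]:
    seq: List[Tuple[str, str]] = [(ids[0], "+")]
    used = {ids[0]}
    cost = 0.0
    while len(seq) < len(ids):
        out = _out_connector(*seq[-1])
        best = None
        for cid in ids:
            if cid in used:
                continue
            for orient in ("+", "-"):
                d = dist[(out, _in_connector(cid, orient))]
                if best is None or d < best[0]:
                    best = (d, cid, orient)
        cost += best[0]
        seq.append((best[1], best[2]))
        used.add(best[1])
    cost += dist[(_out_connector(*seq[-1]), _in_connector(*seq[0]))]
    return cost, seq


def _linearize(
    cycle: List[Tuple[str, str]], instance: TspInstance, total_weight: float
) -> SignedOrdering:
    """Cut the circular tour at its lowest-weight realized adjacency.

    Ties are broken by choosing, over all minimum-weight cut points and both
    traversal directions, the lexicographically least linear sequence
    (``+`` sorting before ``-``)."""
    n = len(cycle)
    weights = []
    for i in range(n):
        u = _out_connector(*cycle[i])
        v = _in_connector(*cycle[(i + 1) % n])
        weights.append(instance.weight(u, v))
    w_min = min(weights)
    orient_rank = {"+": 0, "-": 1}

    def key(seq):
        return [(cid, orient_rank[o]) for cid, o in seq]

    best_seq = None
    for i, w in enumerate(weights):
        if w != w_min:
            continue
        fwd = cycle[i + 1 :] + cycle[: i + 1]
        rev = [(cid, "+" if o == "-" else "-") for cid, o in reversed(fwd)]
        for cand in (fwd, rev):
            if best_seq is None or key(cand) < key(best_seq):
                best_seq = cand
    return SignedOrdering(sequence=best_seq, total_weight=total_weight,
                          cut_weight=w_min)
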