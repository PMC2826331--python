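"""Conflict-tolerant layout graph via a relaxed multi-fragment heuristic.

The classical multi-fragment TSP heuristic inserts edges best-first while
keeping every node's degree at most two and avoiding premature cycles.  Two
relaxations make the result informative on real draft genomes: cycles are
*not* checked (so repeating contigs can close loops), and one — but not
both — of an edge's endpoints may exceed degree two (so conflicting
adjacency evidence stays visible).  The result is a subgraph of the
adjacency graph, possibly disconnected, showing the most promising contig
adjacencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

from .adjacency import AdjacencyGraph, Connector

Edge = FrozenSet[Connector]

__all__ = ["LayoutGraph", "build_layout", "annotate", "to_dot", "default_min_weight"]


@dataclass
class ContigAnnotation:
    label: str
    size_bp: int
    small: bool = False
    repeat: bool = False


@dataclass
class LayoutGraph:
    """Subset of the adjacency edges (plus the structural intra edges)."""

    contig_ids: List[str]
    edges: List[Tuple[Edge, float]]
    per_reference: Dict[Edge, Dict[str, float]] = field(default_factory=dict)
    annotations: Dict[str, ContigAnnotation] = field(default_factory=dict)

    def edge_set(self) -> set:
        return {e for e, _ in self.edges}

    def degree(self, v: Connector) -> int:
        return sum(1 for e, _ in self.edges if v in e)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("contig_a\tside_a\tcontig_b\tside_b\tweight\tper_reference\n")
            for e, w in self.edges:
                (c1, s1), (c2, s2) = sorted(e)
                breakdown = ";".join(
                    f"{r}={v:.6g}"
                    for r, v in sorted(self.per_reference.get(e, {}).items())
                )
                fh.write(f"{c1}\t{s1}\t{c2}\t{s2}\t{w:.10g}\t{breakdown}\n")


def default_min_weight(graph: AdjacencyGraph, fraction: float = 0.5) -> float:
    """Default layout threshold: a fraction of the strongest adjacency.

    Absolute weights scale with 1/tau and with the number of references, so
    a fixed cutoff is meaningless across runs; anchoring it to the maximum
    keeps only edges whose evidence is comparable to the best signal."""
    return fraction * graph.max_adjacency_weight()


def build_layout(graph: AdjacencyGraph, min_weight: float = 0.0) -> LayoutGraph:
    """Greedy best-connection-first layout under the relaxed degree rule.

    Adjacency edges are processed in order of decreasing weight (ties broken
    lexicographically by endpoints).  An edge is inserted iff its weight
    exceeds ``min_weight`` and at least one endpoint currently has
    adjacency-degree below two (intra edges are structural and not
    counted).  No cycle check is performed.  All edges are processed, so the
    result may contain conflicting or cyclic adjacencies by design.
    """
    order = sorted(
        ((e, w) for e, w in graph.nonzero_edges() if w > min_weight),
        key=lambda ew: (-ew[1], sorted(ew[0])),
    )
    degree: Dict[Connector, int] = {}
    chosen: List[Tuple[Edge, float]] = []
    per_ref: Dict[Edge, Dict[str, float]] = {}
    for e, w in order:
        u, v = tuple(e)
        if degree.get(u, 0) < 2 or degree.get(v, 0) < 2:
            chosen.append((e, w))
            degree[u] = degree.get(u, 0) + 1
            degree[v] = degree.get(v, 0) + 1
            per_ref[e] = graph.per_reference(u, v)
    return LayoutGraph(
        contig_ids=list(graph.contig_ids), edges=chosen, per_reference=per_ref
    )


def annotate(
    layout: LayoutGraph,
    contigs: Sequence,
    matches: Optional[Mapping[Tuple[str, str], Sequence]] = None,
    ref_order=None,
    small_cutoff: int = 3500,
    repeat_fraction: float = 0.95,
) -> LayoutGraph:
    """Attach display annotations to the layout in place (and return it).

    Node labels are reference-order ranks when ``ref_order`` is given, else
    contig ids; contigs shorter than ``small_cutoff`` are flagged small
    (drawn gray), and contigs of which at least ``repeat_fraction`` of the
    bases are covered by two or more matches on some single reference are
    flagged as repeats (drawn as boxes).
    """
    ranks = {}
    if ref_order is not None:
        for rank, entry in enumerate(ref_order.entries):
            ranks[entry.contig_id] = rank
    by_id = {c.id: c for c in contigs}
    genomes = sorted({g for (_, g) in matches}) if matches else []
    for cid in layout.contig_ids:
        size = len(by_id[cid].seq) if cid in by_id else 0
        repeat = False
        if matches is not None and cid in by_id:
            for g in genomes:
                cov = _multi_coverage_fraction(by_id[cid], matches.get((cid, g), ()))
                if cov >= repeat_fraction:
                    repeat = True
                    break
        layout.annotations[cid] = ContigAnnotation(
            label=str(ranks[cid]) if cid in ranks else cid,
            size_bp=size,
            small=size < small_cutoff,
            repeat=repeat,
        )
    return layout


def _multi_coverage_fraction(contig, matches) -> float:
    """Fraction of contig bases covered by >= 2 matches on one reference."""
    n = len(contig.seq)
    if n == 0 or len(matches) < 2:
        return 0.0
    delta = [0] * (n + 2)
    for m in matches:
        lo, hi = min(m.sb, m.se), max(m.sb, m.se)
        delta[lo] += 1
        delta[hi + 1] -= 1
    covered2 = 0
    depth = 0
    for pos in range(1, n + 1):
        depth += delta[pos]
        if depth >= 2:
            covered2 += 1
    return covered2 / n


def to_dot(layout: LayoutGraph) -> str:
    """Graphviz DOT rendering of an (annotated) layout graph.

    One node per contig; connector sides appear as head/tail port labels;
    small contigs are filled gray, repeats drawn as boxes; edge labels are
    log10 of the adjacency weight.
    """
    lines = ["graph layout {", "  node [style=filled, fillcolor=white];"]
    for cid in layout.contig_ids:
        ann = layout.annotations.get(cid)
        attrs = []
        if ann is not None:
            label = f"{ann.label}\\n{ann.size_bp / 1000.0:.1f} kb"
            attrs.append(f'label="{label}"')
            attrs.append(f'shape={"box" if ann.repeat else "ellipse"}')
            if ann.small:
                attrs.append('fillcolor="gray"')
        else:
            attrs.append(f'label="{cid}"')
        lines.append(f'  "{cid}" [{", ".join(attrs)}];')
    for e, w in layout.edges:
        (c1, s1), (c2, s2) = sorted(e)
        logw = math.log10(w) if w > 0 else float("-inf")
        lines.append(
            f'  "{c1}" -- "{c2}" [taillabel="{s1}", headlabel="{s2}", '
            f'label="{logw:.2f}"];'
        )
    lines.append("}")
    return "\n".join(lines) + "\n"
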