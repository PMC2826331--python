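"""Override adjacency evidence with expert knowledge.

Mate pairs, fosmid ends or wet-lab results sometimes contradict or confirm
the comparative evidence.  Such knowledge enters as edge-weight overrides:
a forbidden adjacency is set to weight zero (it disappears from the
layout), a forced one to the graph's maximum weight (it is inserted first).
"""

from phyloscaffold import (
    SimParams,
    apply_constraints,
    build_layout,
    default_min_weight,
    scaffold,
    simulate,
)

sim = simulate(SimParams(genome_length=100_000, n_contigs=5, seed=4))
res = scaffold(sim.contigs, sim.references, sim.tree, "target")

strongest_edge, w = res.graph.nonzero_edges()[0]
u, v = sorted(strongest_edge)
print(f"strongest adjacency: {u} -- {v} (weight {w:.3f})")

constrained = apply_constraints(res.graph, [(u, v, "forbid")])
layout = build_layout(constrained, min_weight=default_min_weight(constrained))
print(f"after forbidding it, the layout has {len(layout.edges)} edges and")
print(f"the forbidden pair is present: {strongest_edge in layout.edge_set()}")

# force a connection the comparative evidence does not support
far_u, far_v = (u[0], u[1]), ("contig5", "R" if v != ("contig5", "R") else "L")
if far_u[0] != far_v[0]:
    forced = apply_constraints(res.graph, [(far_u, far_v, "force")])
    print(f"forcing {far_u} -- {far_v} raises its weight to the graph maximum: "
          f"{forced.weight(far_u, far_v):.3f}")
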