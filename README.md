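# phyloscaffold

Phylogeny-weighted comparative scaffolding of bacterial draft genomes.

After shotgun assembly a bacterial genome typically remains in dozens of
contigs, and closing the gaps by primer walking is only affordable when the
relative order and orientation of the contigs is known.  `phyloscaffold`
estimates that order from *several* related finished genomes at once: the
contigs are matched against every reference, candidate adjacencies are
scored with a likelihood that discounts distant relatives (where
rearrangements are more likely), and the result is reported either as an
optimal linear order or — more usefully on real data with repeats — as a
conflict-tolerant *layout graph* that shows unique adjacencies where
possible and the best alternatives where necessary.

## The model

Each contig `c_i` contributes two connector vertices `l_i`, `r_i` (its two
ends) to a fully connected graph.  A match of a contig on a reference is
extended to a projection of the whole contig; two projections on the same
replicon have a signed displacement `d` (0 = abutting, negative =
overlapping).  For a reference at patristic tree distance `τ` from the
contig species, a supporting projection pair scores

    s(d, τ) = (1/τ) · [ (1−φ) · exp(−d² / 2σ₁(τ)²) + φ · exp(−(d−μ)² / 2σ₂²) ]

with σ₁ = 10 000 (insertion/deletion displacement), μ = 2 000 and
σ₂ = 1 000 (lost sequencing fragments), φ = 0.1, and σ₁(τ) growing
proportionally with τ: a distant reference tolerates larger displacements
but counts for less.  Per reference the best supporting pair is taken; the
edge weight is the sum over references.  Matching uses a q-gram filter
(q = 11) with seed chaining and edit-distance verification; matches must be
≥ 64 bases long with ≤ 8% errors.

Orders are derived from the graph in two ways:

* **exact** — flip weights to distances, add an intermediate node per
  contig, and solve the resulting TSP by branch and bound (small instances);
* **layout** — a relaxed multi-fragment greedy: edges enter best-first
  while at most one endpoint exceeds adjacency-degree two and cycles are
  allowed, so repeats and conflicting evidence stay visible.

Predictions are evaluated against a reference order (contigs mapped onto
their own finished genome) as TP/FP, sensitivity TPR = TP/P and precision
PPV = TP/(TP+FP).

## Worked example

`python examples/simulate_and_scaffold.py` simulates a 200 kb genome along
a four-species tree, fragments the target leaf into 10 contigs (lost
fragments ~2 kb), scaffolds them against the three other leaves and scores
the layout against the known truth:

```
simulated 10 contigs, N50 = 17816 bp, references: refA, refB, refC
adjacency graph has 45 scored edges; layout keeps 9 above the threshold (1.105 = half the strongest edge)
  contig09:L -- contig10:L   weight 2.209
  contig05:R -- contig06:R   weight 2.205
  ...
  contig04:R -- contig05:L   weight 1.943
against the true order: TP=9 FP=0 TPR=1.00 PPV=1.00
```

The nine kept edges are exactly the nine true neighbour pairs, with the
correct facing ends (`contig09:L -- contig10:L` means contig 10 continues
contig 9's left end — one of the two is reverse-complemented in the draft).
The other examples show the score surface (`score_curve.py`), the exact TSP
order (`exact_ordering.py`) and expert forbid/force overrides
(`expert_constraints.py`).

The same pipeline is available from the shell:

```
phyloscaffold simulate --length 200000 --n-contigs 10 --outdir sim
phyloscaffold pipeline --contigs sim/contigs.fasta \
    --reference refA=sim/ref_refA.fasta --reference refB=sim/ref_refB.fasta \
    --reference refC=sim/ref_refC.fasta --tree sim/tree.nwk \
    --species target --finished-genome sim/target.fasta --outdir out
```

writing `matches.tsv`, `adjacency_graph.tsv`, `layout.tsv`, `layout.dot`
(Graphviz) and `evaluation.tsv`.  Precomputed BLAST `-outfmt 6` or nucmer
`show-coords -rclT` tables can substitute for the built-in matcher.

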