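# Methods

## Problem and overall procedure

Given a set of contigs `C = {c_1 … c_n}` of one bacterial species, a set of
finished reference genomes `R = {g_1 … g_m}` of related species (each
possibly several replicons), and a phylogenetic tree with branch lengths
containing all species, the package estimates which contig ends are
adjacent in the unknown genome.  The pipeline has three stages: (1) local
matching of every contig against every reference replicon, (2) construction
of the contig adjacency graph with phylogeny-weighted edge weights, and
(3) derivation of either an optimal linear order (exact TSP) or a
conflict-tolerant layout graph (greedy heuristic).

## Matching

Matches are local alignments of a contig substring to a reference substring
with length ≥ `min_length` (measured on the reference, default 64 bases)
and unit-cost edit-error rate ≤ `max_error` (default 8%).  The
implementation is a q-gram filter: an index of all `q = 11`-mers of the
reference is probed with every contig q-mer (both strands), seed hits are
binned by alignment diagonal with a band tolerance of
⌈`max_error` · `min_length`⌉ bases (indels within a candidate), chained
along the reference with a maximum seed gap (default 1 000 bases, the point
at which locally unalignable stretches split a candidate in two), extended
outwards while the sequences agree exactly, and verified with a global
edit-distance alignment (edlib).  The number of distinct seeding q-grams is
reported as `qhits`.  Overlapping candidates from neighbouring bands are
deduplicated keeping larger `qhits`, then longer matches, then smaller
reference start — a fixed tie-break that makes output deterministic.

Note on q: at 64 bases and 8% error the q-gram lemma guarantees no seed for
q = 11, so the filter runs with a seed threshold of one and relies on the
verification alignment; q, the band width and the seed gap are exposed as
parameters.  With substitution rates up to ~6% the chance that a 2 kb
homologous region contains no clean q-gram run is negligible, which the
planted-homology tests exercise.  Coordinates are 1-based inclusive;
reverse-strand matches carry `sb > se` on the contig and ascending
reference coordinates always.  N bases never seed and count as mismatches.

## Projection and displacement

A match extends to a *projection* of its whole contig: for a forward match
`pb = tb − sb + 1`, `pe = te + |c| − se`, so that a full-length match
projects exactly onto its own interval (the +1 keeps the identity under
1-based inclusive coordinates; the uncorrected variant is available behind
`raw=True`).  Reverse matches are handled symmetrically.  Projections may
run off the ends of a replicon.  The displacement of two projections on the
same replicon is `d = start_later − end_earlier − 1`: abutting intervals
give 0, overlapping give negative values.  Across different genomes or
different replicons the displacement is undefined and the pair contributes
nothing (bacterial references may carry plasmids; adjacency evidence never
crosses replicons).

## Adjacency score

Two superimposed Gaussian kernels score a displacement at tree distance τ
(patristic path length between the contig species and the reference):

    s(d, τ) = (1/τ) [ (1−φ) e^{−d²/2σ₁(τ)²} + φ e^{−(d−μ)²/2σ₂²} ]

* σ₁ (default 10 000 bases) — scale of insertion/deletion displacement
  between related genomes.  With τ-scaling on (default),
  σ₁(τ) = σ₁ · τ/τ_min where τ_min is the smallest contig-to-reference
  distance of the run: a more distant reference tolerates proportionally
  larger displacements, while the 1/τ prefactor down-weights its vote.
  The normalisation by τ_min makes the printed σ₁ apply to the closest
  reference.
* μ = 2 000, σ₂ = 1 000 bases — size distribution of lost sequencing
  fragments, which shift truly adjacent contigs to positive displacement.
* φ = 0.1 — mixture weight of the lost-fragment component (the rarer
  event).

The components are unnormalised kernels (value 1 at their mean), not
densities: mixing densities of different σ would re-weight the two branches
behind φ's back; a flag restores density normalisation.  The edge weight
for a connector pair is, per reference, the *maximum* over supporting
projection pairs (a sum would let repeat-induced multiplicity inflate one
adjacency), summed over references.  Which connector pair a projection pair
supports follows from orientation: the earlier interval contributes its
rightward-facing connector (R for forward, L for reverse projections), the
later its leftward-facing one.  Pairs farther apart than `d_cutoff`
(default 200 000 bases, where both kernels are numerically zero) are
skipped to prune the quadratic enumeration.

`qhits` is not part of the score; match quality is enforced by the matching
thresholds.  Expert knowledge enters as overrides: *forbid* sets an edge
weight to zero, *force* to the current maximum adjacency weight (after all
forbids), which makes a forced edge enter the layout first without
distorting the weight scale.

## Exact ordering

Weights flip to distances (`m − w`, `m` = maximum weight) and an
intermediate node between each contig's connectors forces `l−v−r`
traversal, so a shortest Hamiltonian cycle is a maximum-weight circular
contig order.  The solver is a depth-first branch and bound over signed
permutations (equivalent by construction), with a nearest-neighbour upper
bound and the admissible bound `cost + remaining · min_edge_distance`;
contigs are explored in lexicographic order with `+` before `−`, making the
result deterministic and, under total degeneracy, lexicographically least.
Bacterial chromosomes are circular, so the tour is a cycle; the linear
report cuts it at the lowest-weight realized adjacency (ties resolved
toward the lexicographically least sequence).  The exact solver is bounded
at 14 contigs by default and raises a timeout error pointing at the layout
heuristic.

## Layout graph

The layout heuristic processes adjacency edges best-first (decreasing
weight, lexicographic tie-break) and inserts an edge iff its weight exceeds
`min_weight` and at least one endpoint currently has adjacency-degree < 2.
Cycles are not checked (repeats may legitimately close loops) and one
endpoint may exceed degree two (conflicting evidence stays visible); intra
edges are structural and excluded from degree counting.  All edges above
the threshold are processed; no cap on conflict-star sizes is imposed.

Because every connector binds at most one partner in a clean path, the
degree rule alone cannot reject weak spurious edges — after the true path
is built, *any* remaining edge has a free endpoint.  The pipeline therefore
defaults `min_weight` to half the maximum adjacency weight.  This is
deliberately relative: absolute weights scale with 1/τ and with the number
of references, so no fixed cutoff is portable across runs, whereas true
adjacencies concentrate near the maximum (displacements within ~σ₂ of μ)
and skip-over pairs fall below half of it once contigs are larger than
~1.5 σ₁.  `build_layout` itself takes an absolute threshold, and the
fraction is configurable.

Annotations follow the conventions used for published layout figures: node
label = reference-order rank (or contig id), second line = size in kb,
gray fill below 3.5 kb, rectangular shape when ≥ 95% of a contig's bases
are covered twice or more by its matches on some single reference, edge
labels in log₁₀ scale.  DOT output renders with Graphviz.

## Evaluation

The reference order maps each contig onto its own finished genome and
places it where it gains the most matches: matches are clustered along each
replicon (cluster gap = contig length), the winning cluster maximizes
summed `qhits` (ties: summed match length, then leftmost), and orientation
follows the strand with the majority of matched bases.  Unmatched contigs
are excluded and reported.  A predicted connector pair is a TP iff its
contigs are consecutive in the reference order *and* the connector sides
match the reference orientations; a correct pair with wrong facing is an FP
(flagged separately).  P = included contigs − 1 (or the count itself with
`circular`).  Edges touching excluded contigs are dropped, not counted as
FP.  PPV is reported as undefined when nothing was predicted.  N50 is the
largest L such that contigs ≥ L cover half the total length.

## Synthetic data generator

The generator emulates the data situation the method addresses: a random
ancestral genome (default 200 kb — a scaled-down bacterial chromosome that
keeps the full pipeline in seconds) evolves independently down each branch
of a default four-leaf tree
`((target:0.5,refA:0.5):0.25,(refB:0.5,refC:0.75):0.25)`, giving
contig-to-reference distances of 1.0, 1.5 and 1.75.  Substitutions are
Poisson at 0.02/base per unit branch (≈ 2–4% divergence to the references,
typical for congeneric bacteria); inversions, translocations and indels are
Poisson events with geometric sizes (means 10 kb and 500 bases) and default
rate zero — the clean study condition; degradation experiments switch them
on.  Structural events precede substitutions within a branch (a fixed order
chosen for determinism; at these rates the difference is negligible).

The target leaf is cut into `n_contigs` = 10 pieces separated by lost
fragments of size N(2 000, 1 000) clamped at zero, matching the score's
lost-fragment component — this is a model-consistency choice, not a fit to
data.  Piece sizes are Dirichlet-proportional with concentration 400,
i.e. near-uniform (~18 kb ± 1 kb): the generator models a well-covered
assembly broken chiefly by lost fragments, not the heavy-tailed size
distributions of repeat-broken real drafts (a smaller concentration
produces those, but then short contigs make skip-over adjacencies
genuinely ambiguous and perfect recovery is not the expected outcome).
Each contig is reverse-complemented with probability ½.  All randomness
flows from one integer seed; outputs are byte-identical across runs.

What passing the clean-recovery test shows: matching, projection, scoring,
facing logic, threshold and greedy rule compose correctly on data the model
describes.  What it does not show: robustness to repeats, horizontal
transfer, misassemblies or contaminated contigs — real drafts will produce
conflict stars and false adjacencies, which is why the layout graph (not a
single linear order) is the primary output.

## Numerical and degenerate-input choices

Tie-breaks are lexicographic everywhere (match dedup, layout insertion,
TSP exploration, cycle cutting), so all outputs are deterministic.  Score
comparisons in the graph use exact floats; the brute-force test oracles
compare to 1e−12.  Degenerate inputs: contigs shorter than `min_length`
match nothing (warning); an empty match map yields an all-zero graph
(warning) whose layout is empty; a single contig gives a trivial order;
τ ≤ 0 (contig species used as its own reference) is an error.

## Known limitations

Rearrangement breakpoints inside a reference produce misleading adjacency
evidence by construction; the phylogenetic weighting only dilutes, never
detects them.  Matching is exhaustive per q-gram (no repeat masking), so
highly repetitive references inflate candidate pairs within `d_cutoff`.
The exact solver is practical only to ~14 contigs.  Mate pairs and fosmid
ends are supported only via the generic constraint file, not parsed from
read data.
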