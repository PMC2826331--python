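"""The contig adjacency graph and its phylogeny-weighted scoring.

Every contig contributes two *connector* vertices — ``L`` (its 5' end) and
``R`` (its 3' end) — joined by a zero-weight *intra* edge.  All remaining
connector pairs are *adjacency* edges whose weight scores the likelihood of
the two contigs being neighbours with those ends facing each other.

The weight of an adjacency edge is accumulated over the reference genomes:
for each reference ``r`` with tree distance ``tau_r`` to the contig species,
every pair of matches (one per contig, same replicon) is projected onto the
reference, their signed displacement ``d`` is taken, and the pair's support

    s(d, tau) = (1/tau) * [ (1-phi) * exp(-d^2 / (2*sigma1(tau)^2))
                            + phi   * exp(-(d-mu)^2 / (2*sigma2^2)) ]

scores the edge, where the first Gaussian models insertions/deletions
between the genomes and the second models lost sequencing fragments of
typical size ``mu``.  With tau-scaling enabled, ``sigma1(tau) = sigma1 *
tau/tau_min``: more distant references tolerate larger displacements but are
down-weighted overall by ``1/tau``.  Per reference the best supporting pair
is taken (max), and the per-reference scores are summed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

from .matching import Match

logger = logging.getLogger(__name__)

__all__ = [
    "Connector",
    "ProjectedContig",
    "ScoringParams",
    "AdjacencyGraph",
    "project",
    "displacement",
    "score",
    "build_graph",
    "apply_constraints",
]

# A connector vertex: (contig_id, "L" | "R")
Connector = Tuple[str, str]
Edge = FrozenSet[Connector]


def connector(contig_id: str, side: str) -> Connector:
    if side not in ("L", "R"):
        raise ValueError("side must be 'L' or 'R'")
    return (contig_id, side)


@dataclass(frozen=True)
class ProjectedContig:
    """Placement interval implied for a whole contig on a reference replicon.

    ``pb <= pe`` always; the interval may run off the ends of the record
    (``pb < 1`` or ``pe`` beyond the record length).
    """

    contig_id: str
    ref_genome: str
    ref_record: str
    pb: int
    pe: int
    orientation: str  # "forward" | "reverse"
    source_match: Match

    @property
    def is_reverse(self) -> bool:
        return self.orientation == "reverse"


@dataclass(frozen=True)
class ScoringParams:
    """Parameters of the two-Gaussian adjacency score.

    sigma1
        standard deviation (bases) of insertion/deletion displacement
        between related genomes; default 10 000.
    mu, sigma2
        mean and standard deviation (bases) of the lost-fragment size that
        produces systematically positive displacements; defaults 2 000 and
        1 000.
    phi
        mixture weight of the lost-fragment component, in [0, 1];
        default 0.1.
    tau_scaling
        when on, sigma1 grows proportionally with the tree distance
        (normalised so the printed sigma1 applies to the closest
        reference).
    gaussian_kernels
        when on (default), both components are unnormalised kernels with
        value 1 at their mean, so phi alone sets their relative influence;
        when off, proper normal densities are mixed instead.
    """

    sigma1: float = 10_000.0
    mu: float = 2_000.0
    sigma2: float = 1_000.0
    phi: float = 0.1
    tau_scaling: bool = True
    gaussian_kernels: bool = True

    def __post_init__(self) -> None:
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError("sigma1 and sigma2 must be positive")
        if not (0.0 <= self.phi <= 1.0):
            raise ValueError("phi must lie in [0, 1]")


def project(match: Match, contig_length: int, raw: bool = False) -> ProjectedContig:
    """Extend a match to the placement interval of the whole contig.

    Under 1-based inclusive coordinates a full-length forward match projects
    exactly onto its own reference interval: ``pb = tb - sb + 1``,
    ``pe = te + |c| - se``.  With ``raw=True`` the uncorrected textbook form
    ``pb = tb - sb`` is used instead (off by one base at the left end).
    """
    off = 0 if raw else 1
    if not match.is_reverse:
        pb = match.tb - match.sb + off
        pe = match.te + contig_length - match.se
        orientation = "forward"
    else:
        pb = match.tb - (contig_length - match.sb) - (1 - off)
        pe = match.te + (match.se - 1)
        orientation = "reverse"
    return ProjectedContig(
        contig_id=match.contig_id,
        ref_genome=match.ref_genome,
        ref_record=match.ref_record,
        pb=pb,
        pe=pe,
        orientation=orientation,
        source_match=match,
    )


def displacement(p: ProjectedContig, p2: ProjectedContig) -> Optional[int]:
    """Signed gap between two projections on the same reference replicon.

    Abutting intervals give 0; overlapping intervals give a negative value.
    Returns ``None`` (undefined) when the projections lie on different
    reference genomes or different replicons.
    """
    if p.ref_genome != p2.ref_genome or p.ref_record != p2.ref_record:
        return None
    first, second = (p, p2) if (p.pb, p.pe) <= (p2.pb, p2.pe) else (p2, p)
    return second.pb - first.pe - 1


def score(
    d: float,
    tau: float,
    params: ScoringParams = ScoringParams(),
    tau_min: Optional[float] = None,
) -> float:
    """Adjacency likelihood score for displacement ``d`` at tree distance
    ``tau``.

    ``tau_min`` is the smallest contig-to-reference distance of the run and
    anchors the tau-scaling of sigma1; when omitted it defaults to ``tau``
    (i.e. the printed sigma1 applies as-is).
    """
    if tau <= 0:
        raise ValueError(
            "tree distance must be positive; the contig species cannot "
            "serve as its own reference"
        )
    if tau_min is None:
        tau_min = tau
    sigma1 = params.sigma1 * (tau / tau_min) if params.tau_scaling else params.sigma1
    g1 = math.exp(-(d * d) / (2.0 * sigma1 * sigma1))
    g2 = math.exp(-((d - params.mu) ** 2) / (2.0 * params.sigma2 ** 2))
    if not params.gaussian_kernels:
        g1 /= sigma1 * math.sqrt(2.0 * math.pi)
        g2 /= params.sigma2 * math.sqrt(2.0 * math.pi)
    return (1.0 / tau) * ((1.0 - params.phi) * g1 + params.phi * g2)


class AdjacencyGraph:
    """Fully connected graph on the 2n connector vertices.

    Intra edges carry weight 0 by definition; adjacency edges default to
    weight 0 unless explicitly set.  Per-edge, per-reference score
    decompositions are kept for reporting.
    """

    def __init__(self, contig_ids: Sequence[str]):
        if len(set(contig_ids)) != len(contig_ids):
            raise ValueError("contig ids must be unique")
        self.contig_ids: List[str] = list(contig_ids)
        self._weights: Dict[Edge, float] = {}
        self._per_ref: Dict[Edge, Dict[str, float]] = {}

    # -- structure ---------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.contig_ids)

    def vertices(self) -> List[Connector]:
        return [(c, s) for c in self.contig_ids for s in ("L", "R")]

    def is_intra(self, e: Edge) -> bool:
        (c1, _), (c2, _) = tuple(e)
        return c1 == c2

    def intra_edges(self) -> List[Edge]:
        return [frozenset(((c, "L"), (c, "R"))) for c in self.contig_ids]

    def adjacency_edges(self) -> List[Edge]:
        out = []
        for u, v in combinations(self.vertices(), 2):
            if u[0] != v[0]:
                out.append(frozenset((u, v)))
        return out

    # -- weights -----------------------------------------------------------
    def weight(self, u: Connector, v: Connector) -> float:
        e = frozenset((u, v))
        if self.is_intra(e):
            return 0.0
        return self._weights.get(e, 0.0)

    def set_weight(
        self, u: Connector, v: Connector, w: float,
        per_ref: Optional[Dict[str, float]] = None,
    ) -> None:
        e = frozenset((u, v))
        if self.is_intra(e):
            raise ValueError("intra contig edges have fixed weight 0")
        if w < 0:
            raise ValueError("edge weights must be nonnegative")
        self._weights[e] = w
        if per_ref is not None:
            self._per_ref[e] = dict(per_ref)

    def per_reference(self, u: Connector, v: Connector) -> Dict[str, float]:
        return dict(self._per_ref.get(frozenset((u, v)), {}))

    def max_adjacency_weight(self) -> float:
        return max(self._weights.values(), default=0.0)

    def nonzero_edges(self) -> List[Tuple[Edge, float]]:
        return sorted(
            ((e, w) for e, w in self._weights.items() if w > 0),
            key=lambda ew: (-ew[1], sorted(ew[0])),
        )

    def copy(self) -> "AdjacencyGraph":
        g = AdjacencyGraph(self.contig_ids)
        g._weights = dict(self._weights)
        g._per_ref = {e: dict(d) for e, d in self._per_ref.items()}
        return g

    def write_tsv(self, path) -> None:
        """Edge list with per-reference breakdown (nonzero edges only)."""
        with open(path, "w") as fh:
            fh.write("contig_a\tside_a\tcontig_b\tside_b\tweight\tper_reference\n")
            for e, w in self.nonzero_edges():
                (c1, s1), (c2, s2) = sorted(e)
                breakdown = ";".join(
                    f"{r}={v:.6g}" for r, v in sorted(self._per_ref.get(e, {}).items())
                )
                fh.write(f"{c1}\t{s1}\t{c2}\t{s2}\t{w:.10g}\t{breakdown}\n")


def _facing(p: ProjectedContig, direction: str) -> Connector:
    """The connector of ``p``'s contig that faces ``direction`` on the
    reference.  For a forward projection R faces rightward (greater
    coordinates) and L leftward; for a reverse projection the two swap."""
    if direction == "right":
        side = "R" if not p.is_reverse else "L"
    else:
        side = "L" if not p.is_reverse else "R"
    return (p.contig_id, side)


def supported_edge(p: ProjectedContig, p2: ProjectedContig) -> Optional[Edge]:
    """Which adjacency edge a projection pair supports, by the facing rule:
    the earlier interval contributes its rightward-facing connector and the
    later interval its leftward-facing connector."""
    if p.contig_id == p2.contig_id:
        return None
    first, second = (p, p2) if (p.pb, p.pe) <= (p2.pb, p2.pe) else (p2, p)
    return frozenset((_facing(first, "right"), _facing(second, "left")))


def build_graph(
    matches: Mapping[Tuple[str, str], Sequence[Match]],
    tree,
    contig_species: str,
    contig_lengths: Mapping[str, int],
    params: ScoringParams = ScoringParams(),
    d_cutoff: int = 200_000,
) -> AdjacencyGraph:
    """Construct the contig adjacency graph from a match map.

    ``matches`` maps ``(contig_id, genome)`` to that contig's matches on the
    genome; ``tree`` provides patristic distances and must contain
    ``contig_species`` and every reference genome name as leaves.  Pairs of
    projections farther apart than ``d_cutoff`` are ignored.
    """
    contig_ids = sorted(contig_lengths)
    genomes = sorted({g for (_, g) in matches})
    leaf_names = set(tree.leaf_names)
    if contig_species not in leaf_names:
        raise ValueError(f"species not in tree: {contig_species}")
    for g in genomes:
        if g not in leaf_names:
            raise ValueError(f"species not in tree: {g}")
        if g == contig_species:
            raise ValueError(
                "the contig species cannot be one of its own references"
            )
    taus = {g: tree.distance(contig_species, g) for g in genomes}
    for g, t in taus.items():
        if t <= 0:
            raise ValueError(f"tree distance to reference {g} is not positive")
    tau_min = min(taus.values()) if taus else 1.0

    graph = AdjacencyGraph(contig_ids)
    if not any(matches.values()):
        logger.warning("no matches at all; adjacency graph has all-zero weights")
        return graph

    # Pre-project all matches once per (contig, genome).
    projections: Dict[Tuple[str, str], List[ProjectedContig]] = {}
    for (cid, g), ms in matches.items():
        projections[(cid, g)] = [project(m, contig_lengths[cid]) for m in ms]

    accum: Dict[Edge, Dict[str, float]] = {}
    for g in genomes:
        tau = taus[g]
        for ci, cj in combinations(contig_ids, 2):
            for p in projections.get((ci, g), ()):  # matches of contig i on g
                for p2 in projections.get((cj, g), ()):
                    d = displacement(p, p2)
                    if d is None or abs(d) > d_cutoff:
                        continue
                    e = supported_edge(p, p2)
                    if e is None:
                        continue
                    s = score(d, tau, params, tau_min=tau_min)
                    ref_scores = accum.setdefault(e, {})
                    if s > ref_scores.get(g, 0.0):
                        ref_scores[g] = s
    for e, ref_scores in accum.items():
        u, v = tuple(e)
        graph.set_weight(u, v, sum(ref_scores.values()), per_ref=ref_scores)
    return graph


def apply_constraints(
    graph: AdjacencyGraph,
    constraints: Iterable[Tuple[Connector, Connector, str]],
) -> AdjacencyGraph:
    """Apply expert knowledge: ``forbid`` zeroes an edge weight, ``force``
    raises it to the current maximum adjacency weight of the graph.  All
    forbids are applied before any force, so a forced edge ties with the
    strongest remaining evidence.  Returns a modified copy."""
    g = graph.copy()
    known = set(g.vertices())
    parsed = []
    for u, v, action in constraints:
        if u not in known or v not in known:
            raise ValueError(f"constraint references unknown connector: {u} -- {v}")
        if u[0] == v[0]:
            raise ValueError("constraints on intra contig edges are not allowed")
        if action not in ("forbid", "force"):
            raise ValueError(f"unknown constraint action: {action!r}")
        parsed.append((u, v, action))
    for u, v, action in parsed:
        if action == "forbid":
            g.set_weight(u, v, 0.0, per_ref={"override": 0.0})
    max_w = g.max_adjacency_weight()
    for u, v, action in parsed:
        if action == "force":
            g.set_weight(u, v, max_w, per_ref={"override": max_w})
    return g
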