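"""Scoring predicted contig adjacencies against a reference order.

The *reference order* is the ground-truth signed contig permutation obtained
by mapping the contigs onto their own finished genome and placing each
contig where it gathers the most matches.  A predicted connector pair is a
true positive iff the two contigs are consecutive in the reference order
*and* the connector sides agree with the reference orientations; everything
else is a false positive.  Sensitivity (TPR) divides by the number of
connections in the reference order, precision (PPV) by the number of
predictions — and is undefined when nothing was predicted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

from .adjacency import Connector
from .matching import Match, MatchParams, match_all

logger = logging.getLogger(__name__)

Edge = FrozenSet[Connector]

__all__ = [
    "PlacedContig",
    "ReferenceOrder",
    "EvalResult",
    "build_reference_order",
    "reference_order_from_truth",
    "evaluate",
    "n50",
]


@dataclass(frozen=True)
class PlacedContig:
    contig_id: str
    orientation: str  # "+" | "-"
    start: int
    end: int


@dataclass
class ReferenceOrder:
    """Ground-truth contig placements, sorted by start coordinate."""

    entries: List[PlacedContig]
    excluded: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.entries = sorted(self.entries, key=lambda p: (p.start, p.end))
        seen = set()
        for p in self.entries:
            if p.contig_id in seen:
                raise ValueError(f"contig placed twice: {p.contig_id}")
            seen.add(p.contig_id)

    @property
    def contig_ids(self) -> List[str]:
        return [p.contig_id for p in self.entries]

    def true_edges(self, circular: bool = False) -> Set[Edge]:
        """Connector pairs of consecutive contigs, orientation-resolved:
        a ``+`` contig exposes R to its successor and L to its predecessor,
        a ``-`` contig the opposite."""
        edges: Set[Edge] = set()
        pairs = list(zip(self.entries, self.entries[1:]))
        if circular and len(self.entries) > 1:
            pairs.append((self.entries[-1], self.entries[0]))
        for a, b in pairs:
            ca = (a.contig_id, "R" if a.orientation == "+" else "L")
            cb = (b.contig_id, "L" if b.orientation == "+" else "R")
            edges.add(frozenset((ca, cb)))
        return edges

    def n_connections(self, circular: bool = False) -> int:
        n = len(self.entries)
        if n < 2:
            return 0
        return n if circular else n - 1

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("rank\tcontig_id\torientation\tstart\tend\n")
            for rank, p in enumerate(self.entries):
                fh.write(f"{rank}\t{p.contig_id}\t{p.orientation}\t{p.start}\t{p.end}\n")
            for cid in self.excluded:
                fh.write(f"excluded\t{cid}\t\t\t\n")


@dataclass
class EvalResult:
    """Adjacency prediction counts; ``ppv`` is None when nothing scored."""

    tp: int
    fp: int
    p: int
    dropped: int = 0
    orientation_wrong: int = 0

    @property
    def tpr(self) -> float:
        return self.tp / self.p if self.p > 0 else 0.0

    @property
    def ppv(self) -> Optional[float]:
        total = self.tp + self.fp
        return self.tp / total if total > 0 else None

    def write_tsv(self, path) -> None:
        ppv = "undef." if self.ppv is None else f"{self.ppv:.4f}"
        with open(path, "w") as fh:
            fh.write("TP\tFP\tP\tTPR\tPPV\tdropped\tpair_correct_orientation_wrong\n")
            fh.write(
                f"{self.tp}\t{self.fp}\t{self.p}\t{self.tpr:.4f}\t{ppv}"
                f"\t{self.dropped}\t{self.orientation_wrong}\n"
            )


def build_reference_order(
    contigs: Sequence,
    finished_genome: Sequence,
    params: MatchParams = MatchParams(),
    cluster_gap: Optional[int] = None,
) -> ReferenceOrder:
    """Place each contig on the region of its finished genome where it
    gains the most matches.

    Matches of a contig are clustered along each replicon (split when the
    gap between projected placements exceeds ``cluster_gap``, default the
    contig length); the winning cluster maximizes summed qhits, with ties
    broken by summed match length and then by the leftmost position.
    Orientation follows the strand carrying the majority of matched bases
    in the winning cluster.  Contigs with no matches at all are excluded.
    """
    from .adjacency import project

    matches = match_all(contigs, {"__finished__": list(finished_genome)}, params)
    entries: List[PlacedContig] = []
    excluded: List[str] = []
    for contig in contigs:
        ms = matches.get((contig.id, "__finished__"), [])
        if not ms:
            excluded.append(contig.id)
            continue
        gap = cluster_gap if cluster_gap is not None else len(contig.seq)
        best = None  # (qhits, sum_len, -pb) maximized
        projected = sorted(
            (project(m, len(contig.seq)) for m in ms),
            key=lambda p: (p.ref_record, p.pb, p.pe),
        )
        cluster: List = []

        def flush(cluster):
            nonlocal best
            if not cluster:
                return
            qh = sum(p.source_match.qhits for p in cluster)
            ln = sum(p.source_match.length for p in cluster)
            pb = min(p.pb for p in cluster)
            pe = max(p.pe for p in cluster)
            fwd = sum(p.source_match.length for p in cluster if not p.is_reverse)
            rev = sum(p.source_match.length for p in cluster if p.is_reverse)
            orient = "+" if fwd >= rev else "-"
            record = cluster[0].ref_record
            key = (qh, ln, -pb, record)
            if best is None or key > best[0]:
                best = (key, PlacedContig(contig.id, orient, pb, pe))

        for p in projected:
            if cluster and (
                p.ref_record != cluster[-1].ref_record
                or p.pb > max(c.pe for c in cluster) + gap
            ):
                flush(cluster)
                cluster = []
            cluster.append(p)
        flush(cluster)
        entries.append(best[1])
    if excluded:
        logger.info("contigs excluded from the reference order: %s", excluded)
    return ReferenceOrder(entries=entries, excluded=excluded)


def reference_order_from_truth(truth) -> ReferenceOrder:
    """Reference order taken directly from a simulation's ground truth."""
    entries = [
        PlacedContig(cid, orient, start, end)
        for cid, orient, start, end in truth.placements
    ]
    return ReferenceOrder(entries=entries)


def evaluate(
    predicted_edges: Set[Edge] | Sequence[Edge],
    ref_order: ReferenceOrder,
    circular: bool = False,
) -> EvalResult:
    """Count TP/FP of predicted connector pairs against the reference order.

    Edges touching contigs that are not part of the reference order are
    dropped (with a warning), not counted as false positives.  An edge
    joining the right contig pair with the wrong connector sides is a false
    positive, counted separately in ``orientation_wrong``.
    """
    known = set(ref_order.contig_ids)
    truth = ref_order.true_edges(circular=circular)
    consecutive_pairs = {
        frozenset((tuple(e)[0][0], tuple(e)[1][0])) for e in truth
    }
    tp = fp = dropped = orientation_wrong = 0
    for e in set(predicted_edges):
        (c1, _), (c2, _) = tuple(e)
        if c1 not in known or c2 not in known:
            dropped += 1
            logger.warning("prediction involves contig outside reference order: %s", sorted(e))
            continue
        if e in truth:
            tp += 1
        else:
            fp += 1
            if frozenset((c1, c2)) in consecutive_pairs:
                orientation_wrong += 1
    return EvalResult(
        tp=tp,
        fp=fp,
        p=ref_order.n_connections(circular=circular),
        dropped=dropped,
        orientation_wrong=orientation_wrong,
    )


def n50(lengths: Sequence[int]) -> int:
    """Largest L such that sequences of length >= L sum to at least half
    the total length."""
    if not lengths:
        raise ValueError("n50 of an empty length list is undefined")
    total = sum(lengths)
    acc = 0
    for L in sorted(lengths, reverse=True):
        acc += L
        if 2 * acc >= total:
            return L
    return min(lengths)  # unreachable
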