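"""Synthetic evolution and fragmentation fixtures with full ground truth.

A random ancestral genome is evolved independently down every branch of a
given phylogeny (structural events and substitutions, Poisson in branch
length x rate).  One designated leaf is the *target*: its genome is cut into
contigs separated by *lost fragments* whose sizes follow a truncated normal
(mean 2 000, sd 1 000 by default — the same scale the adjacency score's
second Gaussian models).  Every other leaf becomes a finished reference
genome.  Contigs are independently reverse-complemented with probability
one half; the true signed order, gap sizes and per-branch event log are
returned alongside the sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np

from .io_formats import PhyloTree, SequenceRecord, revcomp, write_fasta

__all__ = ["SimParams", "GroundTruth", "SimulationResult", "simulate"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimParams:
    """Study conditions for the simulator.

    Rates are per unit branch length: ``sub_rate`` per base, the structural
    rates in expected events.  Structural rates default to zero (the clean
    condition); sizes are geometric with the given means.  Fragment-size
    spread of the contigs is controlled by ``contig_alpha`` (Dirichlet
    concentration; large values give near-uniform pieces).
    """

    genome_length: int = 200_000
    newick: str = (
        "((target:0.5,refA:0.5):0.25,(refB:0.5,refC:0.75):0.25);"
    )
    target_leaf: str = "target"
    sub_rate: float = 0.02        # substitutions per base per unit branch
    inv_rate: float = 0.0         # inversions per unit branch
    transloc_rate: float = 0.0    # translocations per unit branch
    indel_rate: float = 0.0       # indels per unit branch
    inv_size: int = 10_000        # mean inversion size (geometric)
    indel_size: int = 500         # mean indel size (geometric)
    lost_fragment_mean: float = 2_000.0
    lost_fragment_sd: float = 1_000.0
    n_contigs: int = 10
    contig_alpha: float = 400.0
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.sub_rate, self.inv_rate, self.transloc_rate, self.indel_rate):
            if r < 0:
                raise ValueError("rates must be nonnegative")
        if (self.inv_rate > 0 or self.transloc_rate > 0) and self.inv_size >= self.genome_length:
            raise ValueError("event sizes must be smaller than the genome")
        if self.indel_rate > 0 and self.indel_size >= self.genome_length:
            raise ValueError("event sizes must be smaller than the genome")
        if self.n_contigs < 1:
            raise ValueError("need at least one contig")


@dataclass
class GroundTruth:
    """True layout of the simulated contigs on the target genome.

    ``placements`` holds (contig_id, orientation, start, end) in genomic
    order with 1-based inclusive coordinates on the target sequence;
    ``gap_sizes`` are the lost fragments between consecutive contigs;
    ``event_log`` records the structural events applied per branch.
    """

    placements: List[Tuple[str, str, int, int]]
    gap_sizes: List[int]
    event_log: List[Tuple[str, str, int, int]] = field(default_factory=list)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("contig_id\torientation\tstart\tend\tgap_after\n")
            for i, (cid, orient, start, end) in enumerate(self.placements):
                gap = self.gap_sizes[i] if i < len(self.gap_sizes) else ""
                fh.write(f"{cid}\t{orient}\t{start}\t{end}\t{gap}\n")


@dataclass
class SimulationResult:
    contigs: List[SequenceRecord]
    references: Dict[str, List[SequenceRecord]]
    tree: PhyloTree
    truth: GroundTruth
    target_genome: SequenceRecord

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.contigs, outdir / "contigs.fasta")
        for name, records in self.references.items():
            write_fasta(records, outdir / f"ref_{name}.fasta")
        write_fasta([self.target_genome], outdir / "target.fasta")
        with open(outdir / "tree.nwk", "w") as fh:
            fh.write(self.tree._tree.as_string(schema="newick").strip() + "\n")
        self.truth.write_tsv(outdir / "truth.tsv")


def _random_genome(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _geometric_size(rng: np.random.Generator, mean: int) -> int:
    return int(rng.geometric(1.0 / max(mean, 1)))


def _substitute(seq: list, rng: np.random.Generator, n_events: int) -> None:
    if n_events <= 0:
        return
    n_events = min(n_events, len(seq))
    positions = rng.choice(len(seq), size=n_events, replace=False)
    for pos in positions:
        old = seq[pos]
        choices = [b for b in "ACGT" if b != old]
        seq[pos] = choices[rng.integers(0, 3)]


def _evolve_branch(
    seq: str, branch_length: float, params: SimParams,
    rng: np.random.Generator, log: List, branch_name: str,
) -> str:
    s = list(seq)
    # structural events first, then substitutions
    for _ in range(rng.poisson(params.inv_rate * branch_length)):
        size = min(_geometric_size(rng, params.inv_size), len(s) - 1)
        start = int(rng.integers(0, len(s) - size))
        s[start : start + size] = list(revcomp("".join(s[start : start + size])))
        log.append((branch_name, "inversion", start + 1, size))
    for _ in range(rng.poisson(params.transloc_rate * branch_length)):
        size = min(_geometric_size(rng, params.inv_size), len(s) // 2)
        start = int(rng.integers(0, len(s) - size))
        segment = s[start : start + size]
        del s[start : start + size]
        dest = int(rng.integers(0, len(s)))
        s[dest:dest] = segment
        log.append((branch_name, "translocation", start + 1, size))
    for _ in range(rng.poisson(params.indel_rate * branch_length)):
        size = _geometric_size(rng, params.indel_size)
        if rng.random() < 0.5 and len(s) > size + 1:
            start = int(rng.integers(0, len(s) - size))
            del s[start : start + size]
            log.append((branch_name, "deletion", start + 1, size))
        else:
            start = int(rng.integers(0, len(s)))
            s[start:start] = list(_random_genome(rng, size))
            log.append((branch_name, "insertion", start + 1, size))
    n_subs = rng.poisson(params.sub_rate * branch_length * len(s))
    _substitute(s, rng, n_subs)
    return "".join(s)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> int:
    if sd == 0:
        return max(0, int(round(mean)))
    return max(0, int(round(rng.normal(mean, sd))))


def simulate(params: SimParams) -> SimulationResult:
    """Run the full simulation; byte-identical output for a fixed seed."""
    rng = np.random.default_rng(params.seed)
    tree = PhyloTree.from_newick(params.newick)
    if params.target_leaf not in tree.leaf_names:
        raise ValueError(f"target leaf {params.target_leaf!r} not in tree")

    ancestor = _random_genome(rng, params.genome_length)
    log: List[Tuple[str, str, int, int]] = []
    leaf_seqs: Dict[str, str] = {}

    internal_counter = [0]

    def descend(node, seq: str) -> None:
        for child in node.child_nodes():
            if child.is_leaf():
                name = child.taxon.label
            else:
                internal_counter[0] += 1
                name = f"internal{internal_counter[0]}"
            child_seq = _evolve_branch(
                seq, child.edge.length or 0.0, params, rng, log, name
            )
            if child.is_leaf():
                leaf_seqs[child.taxon.label] = child_seq
            else:
                descend(child, child_seq)

    descend(tree._tree.seed_node, ancestor)

    target_seq = leaf_seqs[params.target_leaf]
    references = {
        name: [SequenceRecord(id=name, seq=seq)]
        for name, seq in sorted(leaf_seqs.items())
        if name != params.target_leaf
    }

    # fragmentation: n contigs, n-1 lost fragments
    n = params.n_contigs
    L = len(target_seq)
    gaps = [
        _truncated_normal(rng, params.lost_fragment_mean, params.lost_fragment_sd)
        for _ in range(n - 1)
    ]
    remaining = L - sum(gaps)
    if remaining < n:
        raise ValueError(
            "contigs plus lost fragments exceed the genome length; lower "
            "n_contigs or the lost-fragment size"
        )
    props = rng.dirichlet([params.contig_alpha] * n)
    lengths = np.maximum(1, np.floor(props * remaining).astype(int))
    # distribute the rounding remainder deterministically
    deficit = remaining - int(lengths.sum())
    for i in range(abs(deficit)):
        lengths[i % n] += 1 if deficit > 0 else -1

    width = len(str(n))
    placements: List[Tuple[str, str, int, int]] = []
    contigs: List[SequenceRecord] = []
    pos = 0
    for i in range(n):
        cid = f"contig{i + 1:0{width}d}"
        start, end = pos + 1, pos + int(lengths[i])
        piece = target_seq[start - 1 : end]
        orient = "+" if rng.random() < 0.5 else "-"
        contigs.append(
            SequenceRecord(id=cid, seq=piece if orient == "+" else revcomp(piece))
        )
        placements.append((cid, orient, start, end))
        pos = end + (gaps[i] if i < n - 1 else 0)

    truth = GroundTruth(placements=placements, gap_sizes=gaps, event_log=log)
    return SimulationResult(
        contigs=contigs,
        references=references,
        tree=tree,
        truth=truth,
        target_genome=SequenceRecord(id=params.target_leaf, seq=target_seq),
    )
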