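"""End-to-end orchestration: match -> adjacency graph -> layout/order.

:func:`run_pipeline` is the library entry point the CLI wraps.  It accepts
either file paths (via :class:`RunConfig`) or in-memory objects (via
:func:`scaffold`), caches match tables, and writes every artifact as TSV or
DOT under an output directory.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from . import io_formats
from .adjacency import (
    AdjacencyGraph,
    ScoringParams,
    apply_constraints,
    build_graph,
)
from .evaluation import EvalResult, build_reference_order, evaluate
from .io_formats import PhyloTree, SequenceRecord, read_constraints
from .layout import LayoutGraph, annotate, build_layout, default_min_weight, to_dot
from .matching import MatchParams, match_all
from .ordering import SignedOrdering, solve_exact, to_tsp

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ScaffoldResult", "run_pipeline", "scaffold", "load_config"]


@dataclass
class RunConfig:
    """All inputs and options of one scaffolding run."""

    contigs_path: str
    reference_paths: Dict[str, str]  # species name -> FASTA path
    tree_path: str
    contig_species: str
    output_dir: str = "phyloscaffold_out"
    cache_dir: Optional[str] = None
    match_params: MatchParams = field(default_factory=MatchParams)
    scoring_params: ScoringParams = field(default_factory=ScoringParams)
    d_cutoff: int = 200_000
    min_weight: Optional[float] = None  # None -> 0.5 * max adjacency weight
    min_weight_fraction: float = 0.5
    small_cutoff: int = 3500
    repeat_fraction: float = 0.95
    compute_order: bool = False
    exact_limit: int = 14
    time_limit: Optional[float] = None
    circular: bool = False
    constraints_path: Optional[str] = None
    finished_genome_path: Optional[str] = None
    log_level: str = "INFO"


@dataclass
class ScaffoldResult:
    matches: Dict[Tuple[str, str], list]
    graph: AdjacencyGraph
    layout: LayoutGraph
    ordering: Optional[SignedOrdering] = None
    evaluation: Optional[EvalResult] = None
    min_weight: float = 0.0


def scaffold(
    contigs: Sequence[SequenceRecord],
    references: Mapping[str, Sequence[SequenceRecord]],
    tree: PhyloTree,
    contig_species: str,
    match_params: MatchParams = MatchParams(),
    scoring_params: ScoringParams = ScoringParams(),
    d_cutoff: int = 200_000,
    min_weight: Optional[float] = None,
    min_weight_fraction: float = 0.5,
    cache_dir=None,
    constraints=None,
    compute_order: bool = False,
    exact_limit: int = 14,
    time_limit: Optional[float] = None,
) -> ScaffoldResult:
    """In-memory pipeline: matching, graph construction, layout (+order).

    ``min_weight=None`` uses the relative default, a fraction of the maximum
    adjacency weight (see :func:`phyloscaffold.layout.default_min_weight`).
    """
    matches = match_all(contigs, references, match_params, cache_dir=cache_dir)
    graph = build_graph(
        matches,
        tree,
        contig_species,
        {c.id: len(c.seq) for c in contigs},
        scoring_params,
        d_cutoff=d_cutoff,
    )
    if constraints:
        graph = apply_constraints(graph, constraints)
    mw = (
        default_min_weight(graph, min_weight_fraction)
        if min_weight is None
        else min_weight
    )
    layout = build_layout(graph, min_weight=mw)
    annotate(layout, contigs, matches)
    ordering = None
    if compute_order and graph.n <= exact_limit:
        ordering = solve_exact(to_tsp(graph), time_limit=time_limit,
                               exact_limit=exact_limit)
    return ScaffoldResult(
        matches=matches, graph=graph, layout=layout, ordering=ordering,
        min_weight=mw,
    )


def run_pipeline(config: RunConfig) -> ScaffoldResult:
    """File-based pipeline run; writes all artifacts to the output dir."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    t0 = time.monotonic()
    contigs = io_formats.read_fasta(config.contigs_path)
    references = {
        name: io_formats.read_fasta(path)
        for name, path in sorted(config.reference_paths.items())
    }
    tree = io_formats.read_newick(config.tree_path)
    for species in [config.contig_species, *references]:
        if species not in tree.leaf_names:
            raise ValueError(f"species not in tree: {species}")
    constraints = None
    if config.constraints_path:
        constraints = [
            (u, v, action)
            for u, v, action in read_constraints(config.constraints_path)
        ]
    logger.info("inputs loaded in %.2f s", time.monotonic() - t0)

    t1 = time.monotonic()
    result = scaffold(
        contigs,
        references,
        tree,
        config.contig_species,
        match_params=config.match_params,
        scoring_params=config.scoring_params,
        d_cutoff=config.d_cutoff,
        min_weight=config.min_weight,
        min_weight_fraction=config.min_weight_fraction,
        cache_dir=config.cache_dir,
        constraints=constraints,
        compute_order=config.compute_order,
        exact_limit=config.exact_limit,
        time_limit=config.time_limit,
    )
    logger.info(
        "matching + graph + layout finished in %.2f s (min_weight=%.4g)",
        time.monotonic() - t1, result.min_weight,
    )

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    all_matches = [m for ms in result.matches.values() for m in ms]
    all_matches.sort(key=lambda m: (m.contig_id, m.ref_genome, m.ref_record, m.tb))
    io_formats.write_matches(all_matches, outdir / "matches.tsv")
    result.graph.write_tsv(outdir / "adjacency_graph.tsv")
    result.layout.write_tsv(outdir / "layout.tsv")

    ref_order = None
    if config.finished_genome_path:
        finished = io_formats.read_fasta(config.finished_genome_path)
        ref_order = build_reference_order(contigs, finished, config.match_params)
        ref_order.write_tsv(outdir / "reference_order.tsv")
        result.evaluation = evaluate(
            result.layout.edge_set(), ref_order, circular=config.circular
        )
        result.evaluation.write_tsv(outdir / "evaluation.tsv")
    annotate(
        result.layout, contigs, result.matches, ref_order=ref_order,
        small_cutoff=config.small_cutoff, repeat_fraction=config.repeat_fraction,
    )
    (outdir / "layout.dot").write_text(to_dot(result.layout))
    if result.ordering is not None:
        result.ordering.write_tsv(outdir / "order.tsv")
    logger.info("pipeline done in %.2f s", time.monotonic() - t0)
    return result


def load_config(path: str | Path) -> dict:
    """Flat key = value config file; '#' starts a comment line."""
    out: dict = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {line!r}")
            key, _, value = line.partition("=")
            out[key.strip()] = value.strip()
    return out
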