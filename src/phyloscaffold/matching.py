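"""Contig-to-reference matching with a q-gram filter (seed and extend).

A *match* is a local alignment between a contig substring and a reference
substring that is at least ``min_length`` bases long (measured on the
reference) and has an edit-error rate of at most ``max_error`` over the
matched region.  Candidate regions are found with a q-gram index on the
reference: exact q-mer seed hits are binned by alignment diagonal, chained
within a diagonal band, extended outwards while the sequences agree exactly,
and finally verified by a global edit-distance alignment of the delimited
substrings.  The number of seed hits supporting a match is reported as
``qhits`` and can serve as a quality estimate.

Both strands are searched; reverse-strand matches are reported with
``sb > se`` on the contig, and reference coordinates are always ascending.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import edlib

logger = logging.getLogger(__name__)

__all__ = ["Match", "MatchParams", "find_matches", "match_all"]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Match:
    """One matching region between a contig and one reference replicon.

    Coordinates are 1-based inclusive.  ``sb > se`` encodes a reverse-strand
    match; ``tb < te`` always holds.  The match length ``|m|`` is defined on
    the reference: ``te - tb + 1``.
    """

    contig_id: str
    ref_genome: str
    ref_record: str
    sb: int
    se: int
    tb: int
    te: int
    qhits: int

    def __post_init__(self) -> None:
        if not (1 <= min(self.sb, self.se)):
            raise ValueError(f"contig coordinates must be >= 1: {self}")
        if not (1 <= self.tb < self.te):
            raise ValueError(f"reference coordinates must satisfy 1 <= tb < te: {self}")
        if self.qhits < 1:
            raise ValueError("qhits must be >= 1")

    @property
    def is_reverse(self) -> bool:
        return self.sb > self.se

    @property
    def length(self) -> int:
        """Length of the covered substring on the reference."""
        return self.te - self.tb + 1


@dataclass(frozen=True)
class MatchParams:
    """Thresholds for the q-gram matcher.

    ``min_length`` and ``max_error`` follow the published defaults (64 bases,
    8% errors); ``q`` and the chaining parameters are implementation knobs.
    ``max_seed_gap`` bounds the reference-position gap between consecutive
    seeds chained into one candidate; ``band_width`` is the diagonal
    tolerance within a chain (indels up to this size stay in one candidate).
    """

    q: int = 11
    min_length: int = 64
    max_error: float = 0.08
    max_seed_gap: int = 1000
    band_width: int = 0  # 0 -> ceil(max_error * min_length)

    def __post_init__(self) -> None:
        if self.q < 4:
            raise ValueError("q must be >= 4")
        if not (0 < self.max_error < 1):
            raise ValueError("max_error must be in (0, 1)")
        if self.min_length < self.q:
            raise ValueError("min_length must be >= q")

    @property
    def effective_band_width(self) -> int:
        import math

        if self.band_width > 0:
            return self.band_width
        return math.ceil(self.max_error * self.min_length)


def _qgram_index(seq: str, q: int) -> Dict[str, List[int]]:
    """Positions (0-based) of every q-gram over {A,C,G,T}; N-grams skipped."""
    index: Dict[str, List[int]] = {}
    for j in range(len(seq) - q + 1):
        gram = seq[j : j + q]
        if "N" in gram:
            continue
        index.setdefault(gram, []).append(j)
    return index


def _chain_seeds(
    seeds: List[Tuple[int, int]], band_width: int, max_gap: int
) -> List[List[Tuple[int, int]]]:
    """Group (i, j) seeds into chains within one diagonal band.

    Seeds are sorted by diagonal; runs of diagonals closer than
    ``band_width`` form a band, and within a band seeds are chained along
    the reference, splitting whenever the gap exceeds ``max_gap``.
    """
    if not seeds:
        return []
    by_diag = sorted(seeds, key=lambda s: (s[1] - s[0], s[1]))
    bands: List[List[Tuple[int, int]]] = []
    cur = [by_diag[0]]
    for s in by_diag[1:]:
        if (s[1] - s[0]) - (cur[-1][1] - cur[-1][0]) <= band_width:
            cur.append(s)
        else:
            bands.append(cur)
            cur = [s]
    bands.append(cur)

    chains: List[List[Tuple[int, int]]] = []
    for band in bands:
        band.sort(key=lambda s: (s[1], s[0]))
        chain = [band[0]]
        for s in band[1:]:
            if s[1] - chain[-1][1] <= max_gap:
                chain.append(s)
            else:
                chains.append(chain)
                chain = [s]
        chains.append(chain)
    return chains


def _extend_exact(
    contig: str, ref: str, ci: int, cj: int, ri: int, rj: int
) -> Tuple[int, int, int, int]:
    """Extend [ci,cj) x [ri,rj) outwards while bases agree exactly."""
    while ci > 0 and ri > 0 and contig[ci - 1] == ref[ri - 1] and contig[ci - 1] != "N":
        ci -= 1
        ri -= 1
    n, m = len(contig), len(ref)
    while cj < n and rj < m and contig[cj] == ref[rj] and contig[cj] != "N":
        cj += 1
        rj += 1
    return ci, cj, ri, rj


def _verify(contig_sub: str, ref_sub: str) -> int:
    """Unit-cost edit distance between the two delimited substrings."""
    if contig_sub == ref_sub:
        return 0
    return edlib.align(contig_sub, ref_sub, mode="NW", task="distance")["editDistance"]


def find_matches(
    contig, reference, params: MatchParams = MatchParams()
) -> List[Match]:
    """All matching regions of ``contig`` on ``reference`` (both strands).

    Parameters are :class:`SequenceRecord`-like objects with ``id`` and
    ``seq`` attributes.  ``reference.id`` is recorded as both the genome and
    the record name; callers that distinguish multi-replicon genomes should
    use :func:`match_all`.  Returns an empty list when nothing passes the
    thresholds.
    """
    return _find_matches_indexed(
        contig, reference.id, reference.id, reference.seq,
        _qgram_index(reference.seq, params.q), params,
    )


def _find_matches_indexed(
    contig,
    ref_genome: str,
    ref_record: str,
    ref_seq: str,
    index: Dict[str, List[int]],
    params: MatchParams,
) -> List[Match]:
    q = params.q
    cseq = contig.seq
    n = len(cseq)
    if n < params.min_length:
        return []
    candidates: List[Tuple[int, Match]] = []  # (sort key built later)
    results: List[Match] = []
    for strand in ("+", "-"):
        query = cseq if strand == "+" else _revcomp(cseq)
        seeds: List[Tuple[int, int]] = []
        for i in range(n - q + 1):
            gram = query[i : i + q]
            if "N" in gram:
                continue
            for j in index.get(gram, ()):
                seeds.append((i, j))
        for chain in _chain_seeds(seeds, params.effective_band_width, params.max_seed_gap):
            ci = min(s[0] for s in chain)
            cj = max(s[0] for s in chain) + q
            ri = min(s[1] for s in chain)
            rj = max(s[1] for s in chain) + q
            ci, cj, ri, rj = _extend_exact(query, ref_seq, ci, cj, ri, rj)
            length = rj - ri
            if length < params.min_length:
                continue
            errors = _verify(query[ci:cj], ref_seq[ri:rj])
            if errors / length > params.max_error:
                continue
            qhits = len({s[0] for s in chain})
            tb, te = ri + 1, rj
            if strand == "+":
                sb, se = ci + 1, cj
            else:
                # query position p (0-based) maps to contig position n - p
                sb, se = n - ci, n - cj + 1
            results.append(
                Match(
                    contig_id=contig.id,
                    ref_genome=ref_genome,
                    ref_record=ref_record,
                    sb=sb,
                    se=se,
                    tb=tb,
                    te=te,
                    qhits=qhits,
                )
            )
    return _dedupe(results)


def _dedupe(matches: List[Match]) -> List[Match]:
    """Merge overlapping candidates: keep larger qhits, then longer, then
    smaller tb.  Two matches are duplicates when they share orientation and
    overlap on both the contig and the reference."""
    ordered = sorted(
        matches, key=lambda m: (-m.qhits, -(m.te - m.tb), m.tb, min(m.sb, m.se))
    )
    kept: List[Match] = []
    for m in ordered:
        dup = False
        for k in kept:
            if m.is_reverse != k.is_reverse:
                continue
            c_ov = min(max(m.sb, m.se), max(k.sb, k.se)) - max(
                min(m.sb, m.se), min(k.sb, k.se)
            )
            r_ov = min(m.te, k.te) - max(m.tb, k.tb)
            if c_ov >= 0 and r_ov >= 0:
                dup = True
                break
        if not dup:
            kept.append(m)
    kept.sort(key=lambda m: (m.ref_record, m.tb, m.te, min(m.sb, m.se)))
    return kept


# ---------------------------------------------------------------------------
# Whole-run matching with a cache
# ---------------------------------------------------------------------------


def _run_digest(contigs, records, params: MatchParams) -> str:
    h = hashlib.sha256()
    h.update(repr((params.q, params.min_length, params.max_error,
                   params.max_seed_gap, params.band_width)).encode())
    for c in sorted(contigs, key=lambda r: r.id):
        h.update(c.id.encode())
        h.update(hashlib.sha256(c.seq.encode()).digest())
    for r in sorted(records, key=lambda r: r.id):
        h.update(r.id.encode())
        h.update(hashlib.sha256(r.seq.encode()).digest())
    return h.hexdigest()[:16]


def match_all(
    contigs: Sequence,
    references: Mapping[str, Sequence],
    params: MatchParams = MatchParams(),
    cache_dir: str | Path | None = None,
) -> Dict[Tuple[str, str], List[Match]]:
    """Match every contig against every reference genome.

    ``references`` maps a genome (species) name to its list of replicon
    records.  Returns a dict keyed by ``(contig_id, genome)``; entries may
    be empty lists.  With ``cache_dir`` set, per-genome match tables are
    cached as native TSV keyed by a digest of sequences and parameters; a
    warm cache returns byte-identical tables without recomputation.
    """
    from . import io_formats  # deferred: io_formats imports Match from here

    ids = [c.id for c in contigs]
    if len(set(ids)) != len(ids):
        raise ValueError("contig ids must be unique")
    for c in contigs:
        if len(c.seq) < params.min_length:
            logger.warning(
                "contig %s is shorter than min_length=%d; it cannot match",
                c.id, params.min_length,
            )
    out: Dict[Tuple[str, str], List[Match]] = {
        (c.id, g): [] for c in contigs for g in references
    }
    for genome in sorted(references):
        records = references[genome]
        cache_file = None
        if cache_dir is not None:
            digest = _run_digest(contigs, records, params)
            cache_file = Path(cache_dir) / f"matches.{genome}.{digest}.tsv"
            if cache_file.exists():
                try:
                    cached = io_formats.read_match_table(cache_file, "native-tsv")
                    for m in cached:
                        out[(m.contig_id, genome)].append(m)
                    continue
                except (ValueError, KeyError) as exc:
                    logger.warning(
                        "match cache %s is corrupt (%s); recomputing", cache_file, exc
                    )
                    for key in out:
                        if key[1] == genome:
                            out[key] = []
        genome_matches: List[Match] = []
        for record in records:
            index = _qgram_index(record.seq, params.q)
            for contig in contigs:
                found = _find_matches_indexed(
                    contig, genome, record.id, record.seq, index, params
                )
                out[(contig.id, genome)].extend(found)
                genome_matches.extend(found)
        if cache_file is not None:
            cache_file.parent.mkdir(parents=True, exist_ok=True)
            genome_matches.sort(
                key=lambda m: (m.contig_id, m.ref_record, m.tb, m.te, min(m.sb, m.se))
            )
            io_formats.write_matches(genome_matches, cache_file)
    for key in out:
        out[key].sort(key=lambda m: (m.ref_record, m.tb, m.te, min(m.sb, m.se)))
    return out
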