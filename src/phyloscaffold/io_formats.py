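"""Readers and writers for the external formats used by the scaffolder.

Sequences are plain nucleotide strings over ``{A, C, G, T, N}``; FASTA input
is uppercased on read and validated.  Phylogenies are Newick trees with
branch lengths, wrapped in :class:`PhyloTree` which exposes patristic
(leaf-to-leaf path length) distances.  Match tables can be read from three
dialects: BLAST tabular ``-outfmt 6``, ``nucmer``/``show-coords -rclT``
output, and the package's own TSV.

Coordinate convention: 1-based, inclusive at both ends, on both the contig
and the reference.  A reverse-strand match is encoded by ``sb > se`` on the
contig; reference coordinates always satisfy ``tb < te``.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
from Bio import SeqIO

from .matching import Match

__all__ = [
    "SequenceRecord",
    "PhyloTree",
    "read_fasta",
    "write_fasta",
    "read_newick",
    "tree_distance",
    "read_match_table",
    "write_matches",
    "read_constraints",
]

_VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence (contig or reference replicon)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.seq) - _VALID_BASES
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid characters: "
                f"{sorted(bad)!r} (allowed: A,C,G,T,N)"
            )

    def __len__(self) -> int:
        return len(self.seq)


class PhyloTree:
    """A rooted phylogeny with named leaves and branch lengths.

    Thin wrapper around a :class:`dendropy.Tree` that precomputes the full
    patristic distance matrix between leaves.  All scoring in this package
    uses patristic path-length distances.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._leaves = []
        for leaf in tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise ValueError("Newick tree contains an unnamed leaf")
            self._leaves.append(leaf.taxon.label)
        if len(set(self._leaves)) != len(self._leaves):
            raise ValueError("leaf names in the tree are not unique")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                raise ValueError(
                    "branch lengths are required on every edge of the tree"
                )
            if edge.length < 0:
                raise ValueError("negative branch length in tree")
        pdm = tree.phylogenetic_distance_matrix()
        self._dist: dict[frozenset[str], float] = {}
        taxa = [t for t in tree.taxon_namespace]
        for i, t1 in enumerate(taxa):
            for t2 in taxa[i + 1 :]:
                self._dist[frozenset((t1.label, t2.label))] = float(
                    pdm.patristic_distance(t1, t2)
                )

    @property
    def leaf_names(self) -> list[str]:
        return list(self._leaves)

    def distance(self, leaf_a: str, leaf_b: str) -> float:
        """Patristic distance (sum of branch lengths on the path)."""
        for name in (leaf_a, leaf_b):
            if name not in self._leaves:
                raise KeyError(f"unknown leaf name: {name!r}")
        if leaf_a == leaf_b:
            return 0.0
        return self._dist[frozenset((leaf_a, leaf_b))]

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
        return cls(tree)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (multi-)FASTA file into ordered :class:`SequenceRecord` s.

    Ids are the first whitespace-delimited token of the header.  Lowercase
    bases are uppercased; any character outside ``{A,C,G,T,N}`` raises.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id in {path}: {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(id=rec.id, seq=str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no records found in FASTA file {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_newick(path: str | Path) -> PhyloTree:
    """Parse a Newick file; branch lengths are mandatory on every edge."""
    with open(path) as fh:
        return PhyloTree.from_newick(fh.read())


def tree_distance(tree: PhyloTree, leaf_a: str, leaf_b: str) -> float:
    """Patristic distance between two leaves; symmetric, zero on identity."""
    return tree.distance(leaf_a, leaf_b)


# ---------------------------------------------------------------------------
# Match tables
# ---------------------------------------------------------------------------

_NATIVE_HEADER = [
    "contig_id",
    "ref_genome",
    "ref_record",
    "sb",
    "se",
    "tb",
    "te",
    "qhits",
]


def _normalize_coords(qs: int, qe: int, ss: int, se: int) -> tuple[int, int, int, int]:
    """Map arbitrary query/subject coordinates onto the package convention.

    The reference interval is always ascending (tb < te); a reverse-strand
    match is carried entirely on the contig side (sb > se).  A row with the
    subject descending is flipped on both sides, which encodes the same
    alignment.
    """
    if ss > se:
        qs, qe = qe, qs
        ss, se = se, ss
    return qs, qe, ss, se


def _synth_qhits(identity_fraction: float, aligned_length: int, q: int = 11) -> int:
    """Surrogate q-gram hit count for imported BLAST/nucmer matches."""
    return max(0, round(identity_fraction * aligned_length) - q + 1)


def read_match_table(
    path: str | Path,
    dialect: str = "native-tsv",
    ref_genome: str | None = None,
    q: int = 11,
) -> list[Match]:
    """Read a match table in one of three dialects.

    ``blast-tab6``
        standard 12-column BLAST tabular output; query = contig, subject =
        reference record.  ``ref_genome`` names the genome the table refers
        to (defaults to the subject id).
    ``nucmer-coords``
        ``show-coords -rclT`` output (tab separated, reference first);
        header lines are skipped.
    ``native-tsv``
        this package's own table, written by :func:`write_matches`.

    qhits is synthesized from identity x aligned length for the two foreign
    dialects, which do not carry q-gram counts.
    """
    matches: list[Match] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if dialect == "native-tsv":
        for ln, line in enumerate(lines, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields == _NATIVE_HEADER:
                continue
            if len(fields) != 8:
                raise ValueError(f"{path}:{ln}: expected 8 columns, got {len(fields)}")
            try:
                matches.append(
                    Match(
                        contig_id=fields[0],
                        ref_genome=fields[1],
                        ref_record=fields[2],
                        sb=int(fields[3]),
                        se=int(fields[4]),
                        tb=int(fields[5]),
                        te=int(fields[6]),
                        qhits=int(fields[7]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: malformed row: {exc}") from exc
    elif dialect == "blast-tab6":
        for ln, line in enumerate(lines, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{ln}: expected 12 BLAST columns, got {len(f)}")
            try:
                qid, sid = f[0], f[1]
                pident = float(f[2])
                length = int(f[3])
                qs, qe, ss, se_ = int(f[6]), int(f[7]), int(f[8]), int(f[9])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: malformed row: {exc}") from exc
            sb, se_c, tb, te = _normalize_coords(qs, qe, ss, se_)
            matches.append(
                Match(
                    contig_id=qid,
                    ref_genome=ref_genome or sid,
                    ref_record=sid,
                    sb=sb,
                    se=se_c,
                    tb=tb,
                    te=te,
                    qhits=max(1, _synth_qhits(pident / 100.0, length, q)),
                )
            )
    elif dialect == "nucmer-coords":
        for ln, line in enumerate(lines, 1):
            f = line.rstrip("\n").split("\t")
            # show-coords -rclT: S1 E1 S2 E2 LEN1 LEN2 %IDY LENR LENQ COVR COVQ R Q
            if len(f) < 13:
                continue  # headers / separators
            try:
                s1, e1, s2, e2 = int(f[0]), int(f[1]), int(f[2]), int(f[3])
                idy = float(f[6])
            except ValueError:
                continue  # column header line
            rid, qid = f[11], f[12]
            # reference columns first in -r sorted output
            sb, se_c, tb, te = _normalize_coords(s2, e2, s1, e1)
            matches.append(
                Match(
                    contig_id=qid,
                    ref_genome=ref_genome or rid,
                    ref_record=rid,
                    sb=sb,
                    se=se_c,
                    tb=tb,
                    te=te,
                    qhits=max(1, _synth_qhits(idy / 100.0, te - tb + 1, q)),
                )
            )
    else:
        raise ValueError(f"unknown match-table dialect: {dialect!r}")
    return matches


def write_matches(matches: Sequence[Match], path: str | Path) -> None:
    """Write matches as the native TSV (stable column order, header line)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_NATIVE_HEADER) + "\n")
        for m in matches:
            fh.write(
                f"{m.contig_id}\t{m.ref_genome}\t{m.ref_record}\t"
                f"{m.sb}\t{m.se}\t{m.tb}\t{m.te}\t{m.qhits}\n"
            )


def read_constraints(path: str | Path) -> list[tuple[tuple[str, str], tuple[str, str], str]]:
    """Read an expert-constraint TSV: contig_id, side, contig_id, side, action.

    ``side`` is L or R, ``action`` is ``forbid`` or ``force``.
    """
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 5:
                raise ValueError(f"{path}:{ln}: expected 5 columns")
            c1, s1, c2, s2, action = f
            if s1 not in ("L", "R") or s2 not in ("L", "R"):
                raise ValueError(f"{path}:{ln}: side must be L or R")
            if action not in ("forbid", "force"):
                raise ValueError(f"{path}:{ln}: action must be forbid or force")
            out.append(((c1, s1), (c2, s2), action))
    return out
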