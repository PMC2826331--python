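import random

import pytest

from phyloscaffold import PhyloTree, SequenceRecord


@pytest.fixture
def write_fasta_file(tmp_path):
    def _write(records, name="seqs.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in records:
                fh.write(f">{rid}\n{seq}\n")
        return path

    return _write


@pytest.fixture
def two_leaf_tree():
    return PhyloTree.from_newick("(S:1.0,R:1.0);")


@pytest.fixture
def three_ref_tree():
    return PhyloTree.from_newick("((S:0.5,R1:0.5):0.25,(R2:0.5,R3:0.75):0.25);")


def random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))
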