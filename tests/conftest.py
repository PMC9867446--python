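import numpy as np
import pytest

from clckit.phylo import PhyloTree, load_jtt
from clckit.seqio import ProteinRecord


@pytest.fixture(scope="session")
def jtt():
    return load_jtt()


@pytest.fixture()
def rng():
    return np.random.default_rng(20230104)


@pytest.fixture()
def write_fasta_file(tmp_path):
    def _write(entries, name="input.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in entries:
                fh.write(f">{rid}\n{seq}\n")
        return path

    return _write


def make_protein(seq: str, rid: str = "p1") -> ProteinRecord:
    return ProteinRecord(id=rid, sequence=seq)


@pytest.fixture()
def balanced_quartet() -> PhyloTree:
    return PhyloTree.from_newick("((A:0.1,B:0.1):0.2,(C:0.1,D:0.1):0.2);")
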