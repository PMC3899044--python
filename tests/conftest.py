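import numpy as np
import pytest

from parsimotif.io import SequenceRecord
from parsimotif.markov import fit_homogeneous_mm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_fasta(tmp_path):
    p = tmp_path / "toy.fa"
    p.write_text(">s1\nACGTACGT\n>s2\nacgt\n>s3\nTTTTCCCCAAAA\n")
    return p


@pytest.fixture
def toy_genome():
    """Plain dict genome: 100 bp chromosome plus a short one with an N run."""
    rng = np.random.default_rng(7)
    chr1 = "".join("ACGT"[c] for c in rng.integers(0, 4, 100))
    return {"chr1": chr1, "chr2": "ACGTACGTAC" + "N" * 5 + "GGGCCC"}


@pytest.fixture
def toy_flank():
    """Small order-1 flanking model fitted to fixed sequences."""
    return fit_homogeneous_mm(["ACGTACGGTACGATCCTTGACA", "GGATCCAATTGGCC"], order=1, ess=4)


@pytest.fixture
def records_factory():
    def make(seqs):
        return [SequenceRecord(id=f"r{i}", seq=s) for i, s in enumerate(seqs)]

    return make
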