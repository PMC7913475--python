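import numpy as np
import pytest

from cystakit import SequenceRecord, load_basal_repertoire, load_basal_tree
from cystakit.simulate import (
    TOY_ATYP_50,
    TOY_SIGNAL_PEPTIDE,
    TOY_STEFIN_50,
    TOY_TYPE2_MATURE,
)


@pytest.fixture
def toy_stefin():
    return SequenceRecord(id="toy_stefin", residues=TOY_STEFIN_50)


@pytest.fixture
def toy_atypical():
    return SequenceRecord(id="toy_atyp", residues=TOY_ATYP_50)


@pytest.fixture
def toy_type2():
    return SequenceRecord(id="toy_type2", residues=TOY_SIGNAL_PEPTIDE + TOY_TYPE2_MATURE)


@pytest.fixture(scope="session")
def basal_tree():
    return load_basal_tree()


@pytest.fixture(scope="session")
def basal_matrix():
    return load_basal_repertoire()


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def write_fasta_text(path, entries):
    """Write raw (id, sequence) pairs without validation."""
    with open(path, "w") as fh:
        for rid, seq in entries:
            fh.write(f">{rid}\n{seq}\n")
    return path


@pytest.fixture
def fasta_writer(tmp_path):
    def _write(name, entries):
        return write_fasta_text(tmp_path / name, entries)

    return _write
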