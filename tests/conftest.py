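import pytest

from lcrmap import DNA, SequenceRecord, generate_random, write_fasta

#: 24-nt sequence with a homopolymer run at 8..17 and an inverted repeat
#: (positions 1..7 are the reverse complement of 18..24).
WORKED_EXAMPLE = "ATGCTCGAAAAAAAAAACGAGCAT"


@pytest.fixture
def worked_example() -> SequenceRecord:
    return SequenceRecord("example", WORKED_EXAMPLE)


@pytest.fixture
def random_record() -> SequenceRecord:
    return SequenceRecord("rand", generate_random(2000, 42, DNA))


@pytest.fixture
def fasta_writer(tmp_path):
    """Write records to a temp FASTA file and return its path."""

    counter = {"n": 0}

    def _write(records, line_width: int = 80):
        counter["n"] += 1
        path = tmp_path / f"fixture{counter['n']}.fa"
        write_fasta(records, path, line_width=line_width)
        return path

    return _write
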