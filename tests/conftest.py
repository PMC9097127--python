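import pytest

from primercover.fasta_io import SequenceRecord
from primercover.synth import FixtureSpec, make_records


def rec(seq_id, sequence, header=None):
    return SequenceRecord(seq_id, header or f"s{seq_id}", sequence)


@pytest.fixture
def family_records():
    """10 mutated copies of each of 2 ancestors, 200 bp, 2% substitutions."""
    return make_records(
        FixtureSpec(
            n_sequences=20,
            bases_per_sequence=200,
            mode="family",
            n_ancestors=2,
            substitution_rate=0.02,
            seed=11,
        )
    )


@pytest.fixture
def fasta_file(tmp_path):
    def _write(text, name="input.fasta"):
        p = tmp_path / name
        p.write_text(text)
        return p

    return _write
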