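import numpy as np
import pytest

from viromarker.io_core import SequenceRecord

BASES = "ACGT"


def random_record(rng: np.random.Generator, length: int, rec_id: str = "seq") -> SequenceRecord:
    return SequenceRecord(
        id=rec_id, residues="".join(rng.choice(list(BASES), size=length))
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240417)


@pytest.fixture
def small_study():
    """One small coupled synthetic study, shared by pipeline-level tests."""
    from viromarker.simulate import generate_study

    return generate_study(
        seed=101,
        n_pairs=600,
        virus_length=20_000,
        dtr_len=2_500,
        host_genome_length=12_000,
    )
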