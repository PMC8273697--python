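import pytest

from pkat.seq_io import SeqRecord
from pkat.simulate import gen_pkat_protein, gen_rpt


@pytest.fixture
def clean_rpt():
    """Ten identical 13-mers with planted TS/DE ladders."""
    record, truth = gen_rpt(13, 10, 0.0, ladder_spec={"TS": (2,), "DE": (9,)},
                            seed=1)
    return record, truth


@pytest.fixture
def noisy_rpt():
    record, truth = gen_rpt(13, 10, 0.05, ladder_spec={"TS": (2,), "DE": (9,)},
                            seed=1)
    return record, truth


@pytest.fixture
def pkat_protein():
    record, truth = gen_pkat_protein(seed=7)
    return record, truth


@pytest.fixture
def protein_record():
    return SeqRecord(id="p1", seq="MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ",
                     moltype="protein")
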