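import pytest
from hypothesis import settings

from mtseq import Alphabet, SequenceRecord, uniform_model

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def iid_genome_1mb():
    """One i.i.d. uniform 1 Mb genome, shared across tests."""
    from mtseq import simulate_sequence

    return simulate_sequence(uniform_model(), 1_000_000, seed=42, record_id="g")


@pytest.fixture
def dna(request):
    def make(seq, rid="t1"):
        return SequenceRecord(rid, seq, Alphabet.DNA)

    return make
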