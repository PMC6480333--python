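import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from chimeranet.reconstruction import ExonRecord, TranscriptModel

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def plus_transcript():
    """Two-exon plus-strand transcript: exons (101-150) and (201-250)."""
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), size=100))
    exons = [
        ExonRecord("chr1", 101, 150, "+", "tx_plus"),
        ExonRecord("chr1", 201, 250, "+", "tx_plus"),
    ]
    return TranscriptModel("tx_plus", "geneA", "+", exons, seq)


@pytest.fixture
def minus_transcript():
    """Two-exon minus-strand transcript: exons (201-250) then (101-150) in transcript order."""
    rng = np.random.default_rng(43)
    seq = "".join(rng.choice(list("ACGT"), size=100))
    exons = [
        ExonRecord("chr1", 201, 250, "-", "tx_minus"),
        ExonRecord("chr1", 101, 150, "-", "tx_minus"),
    ]
    return TranscriptModel("tx_minus", "geneB", "-", exons, seq)


@pytest.fixture(scope="session")
def toy_genome():
    from chimeranet.simulate import generate_toy_genome

    return generate_toy_genome(n_genes=6, seed=7)


@pytest.fixture(scope="session")
def motif_dataset():
    from chimeranet.simulate import SyntheticSpec, generate_motif_dataset

    return generate_motif_dataset(SyntheticSpec(n_per_class=60, n_genes=48, seed=11))
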