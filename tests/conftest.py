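import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from phagetools import CodonBiasSpec, generate_genome, generate_pair


@pytest.fixture(scope="session")
def small_genome():
    """Small synthetic phage genome with one TGG-anticodon tRNA."""
    spec = CodonBiasSpec(n_cds=8, cds_length_codons=(10, 30), seed=11)
    return generate_genome(spec, trna_anticodons=["TGG"], genome_id="fixphage")


@pytest.fixture(scope="session")
def enriched_pair():
    """Host/phage pair with CCA and AGA enriched in the phage, plus truth."""
    host_spec = CodonBiasSpec(n_cds=40, cds_length_codons=(80, 200), seed=5)
    return generate_pair(
        host_spec, {"CCA": 1.8, "AGA": 2.5}, phage_trnas=["TGG"], seed=5
    )
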