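import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from motifhotspot.simulate import SyntheticDatasetSpec, generate_catalog, generate_reference

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_dataset():
    """Small synthetic dataset with planted GTA clustering."""
    spec = SyntheticDatasetSpec(
        seq_length=600,
        n_planted=4,
        n_mutations=40,
        enrichment_beta=8.0,
        recurrence_rate=0.2,
        seed=7,
    )
    ref, planted = generate_reference(spec)
    records, truth = generate_catalog(ref, planted, spec)
    return spec, ref, planted, records, truth


@pytest.fixture
def tsv_catalog(tmp_path):
    """Write a 3-row TSV catalogue: SNV, 2-bp deletion, recurrent duplicate SNV."""
    path = tmp_path / "catalog.tsv"
    path.write_text(
        "id\tcontig\tposition\tref\talt\tclass\tannotation\tinheritance\tsex\tsource\n"
        "v1\tchr9\t100\tA\tG\tSNV\tsplicing\tDE_NOVO\tF\tstudyA\n"
        "v2\tchr9\t150\tTAC\tT\tINDEL\tframeshift\tRARE_INHERITED\tM\tstudyB\n"
        "v3\tchr9\t100\tA\tG\tSNV\tsplicing\tDE_NOVO\tM\tstudyC\n"
    )
    return path


def rng_for(*entropy) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy))
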