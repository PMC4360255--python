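import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import polyamap as pm
from polyamap.simulate import (
    OrfSpec,
    SyntheticSpec,
    animal_like_template,
    simulate_dataset,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def toy_genome():
    """Small handcrafted genome with one gene on each strand."""
    rng = np.random.default_rng(42)
    bases = np.array(list("ACGT"))
    seq = "".join(rng.choice(bases, size=10_000))
    return pm.GenomeIndex({"toy": seq})


@pytest.fixture(scope="session")
def plant_dataset():
    """Plant-like synthetic dataset at recovery scale: 2000 genes, AATAAA
    planted at -21 in 55% of genes (generator defaults)."""
    spec = SyntheticSpec(seed=20, n_genes=2000)
    genome, transcripts, truth = simulate_dataset(spec)
    return spec, genome, transcripts, truth


@pytest.fixture(scope="session")
def plant_run(plant_dataset):
    spec, genome, transcripts, truth = plant_dataset
    result = pm.run_pipeline(pm.RunConfig(), transcripts=transcripts, genome=genome)
    return spec, truth, result


@pytest.fixture(scope="session")
def animal_run():
    """Animal-like template (A peak -18, U peak -9), no motif planting."""
    spec = SyntheticSpec(seed=21, n_genes=2000, template=animal_like_template(), plantings=())
    genome, transcripts, truth = simulate_dataset(spec)
    result = pm.run_pipeline(
        pm.RunConfig(profile_motifs=()), transcripts=transcripts, genome=genome
    )
    return spec, truth, result


@pytest.fixture(scope="session")
def small_run():
    """Small end-to-end run for fast structural checks."""
    spec = SyntheticSpec(seed=5, n_genes=200, redundancy_rate=0.25)
    genome, transcripts, truth = simulate_dataset(spec)
    result = pm.run_pipeline(pm.RunConfig(), transcripts=transcripts, genome=genome)
    return spec, genome, transcripts, truth, result


@pytest.fixture(scope="session")
def utr_dataset():
    """ORF-bearing genes with planted UTR lengths including -1/-2 overlaps."""
    spec = SyntheticSpec(
        seed=9,
        n_genes=50,
        orf=OrfSpec(aa_length=120, utr_lengths=(150, 240, 30, 0, -1, -2)),
    )
    return spec, *simulate_dataset(spec)
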