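import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from synologs.records import DetectionConfig
from synologs.simulate import (
    PlantedGroup,
    SUBCATEGORIES,
    SyntheticDesign,
    generate_genome,
    standard_design,
)


@pytest.fixture(scope="session")
def standard_fixture():
    """Standard synthetic genome (seed 1): 300 background genes, 12 planted
    groups at copy identity 0.97, 3 truncated decoys."""
    design = standard_design(rng_seed=1)
    records, truth = generate_genome(design)
    return design, records, truth


@pytest.fixture(scope="session")
def denovo_config():
    return DetectionConfig(mode="denovo", kmer_prescreen=True)


def small_design(seed: int, n_background: int = 60, sizes=(2, 3, 2),
                 target_identity: float = 0.97, n_contigs: int = 1):
    """A desk-size design for tests that need many full all-vs-all runs."""
    groups = tuple(
        PlantedGroup(
            size=s,
            target_identity=target_identity,
            subcategory=SUBCATEGORIES[i % len(SUBCATEGORIES)],
            arrangement="tandem" if i % 2 == 0 else "dispersed",
        )
        for i, s in enumerate(sizes)
    )
    return SyntheticDesign(
        n_background=n_background,
        length_range=(60, 120),
        planted_groups=groups,
        n_contigs=n_contigs,
        rng_seed=seed,
        genome_id=f"small{seed}",
        min_dispersed_gap=10,
    )
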