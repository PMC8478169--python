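import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from cuprome import ModelCatalog, default_catalog
from cuprome.simulate import PlantedCluster, RepliconSpec, simulate_annotated_genome


@pytest.fixture
def catalog() -> ModelCatalog:
    return default_catalog()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture
def hit_table() -> pd.DataFrame:
    """A small constructed hit table with multi-model duplicates and ties."""
    rows = [
        # P1 hit by two models: smaller e-value wins
        ("P1", "COG2217", 150.0, 1e-45, 1, 120),
        ("P1", "TIGR01480", 130.0, 1e-38, 5, 110),
        # P2 exact tie: lexicographically smaller accession wins
        ("P2", "TIGR01386", 120.0, 1e-40, 1, 100),
        ("P2", "COG3696", 120.0, 1e-40, 1, 100),
        # singles at varied e-values for sweep tests
        ("P3", "COG0845", 90.0, 1e-25, 1, 90),
        ("P4", "TIGR02044", 60.0, 1e-15, 1, 80),
        ("P5", "COG2372", 40.0, 1e-11, 1, 70),
        ("P6", "COG2217", 200.0, 1e-60, 1, 130),
    ]
    return pd.DataFrame(
        rows,
        columns=["protein_id", "model_accession", "bit_score", "evalue", "ali_start", "ali_end"],
    )


@pytest.fixture
def planted_genome():
    """Two replicons carrying 2 full + 3 partial clusters, some on islands."""
    replicons = [
        RepliconSpec(
            replicon_id="chrom_1",
            replicon_class="chromosome",
            length=80000,
            n_background_genes=24,
            clusters=(
                PlantedCluster(on_genomic_island=True),  # full, on GI
                PlantedCluster(roles=("copA", "cupredoxin", "duf2933_hypothetical", "icmt")),
            ),
        ),
        RepliconSpec(
            replicon_id="plasmid_1",
            replicon_class="plasmid",
            length=70000,
            n_background_genes=18,
            clusters=(
                PlantedCluster(strand="-"),  # full, minus strand
                PlantedCluster(roles=("merR", "copA", "icmt"), on_genomic_island=True),
                PlantedCluster(roles=("merR", "copA", "cupredoxin")),
            ),
        ),
    ]
    sequences, features, gi, truth = simulate_annotated_genome(replicons, seed=7)
    return replicons, sequences, features, gi, truth
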