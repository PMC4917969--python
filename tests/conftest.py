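import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from plasmacnv.genome import Chromosome, CopyNumberEvent, CopyNumberStateMap, GenomeModel
from plasmacnv.profiles import BinnedProfile, ControlPanel, gc_correct
from plasmacnv.simulate import SimulationConfig, simulate_controls, simulation_grid

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_genome():
    """Compact male genome: three 50-Mb autosomes plus a 30-Mb X."""
    return GenomeModel(
        [
            Chromosome("chr1", 50_000_000, 2),
            Chromosome("chr2", 50_000_000, 2),
            Chromosome("chr3", 50_000_000, 2),
            Chromosome("chrX", 30_000_000, 1),
        ]
    )


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_bins=3600, total_coverage=120.0, seed=11)


@pytest.fixture(scope="session")
def small_grid(small_genome, small_config):
    return simulation_grid(small_genome, small_config)


@pytest.fixture(scope="session")
def small_panel(small_genome, small_config, small_grid):
    controls = simulate_controls(small_genome, 10, small_config, grid=small_grid)
    return ControlPanel.from_profiles(
        [
            gc_correct(BinnedProfile.from_counts(small_grid, c.counts, c.sample_id))
            for c in controls
        ]
    )


@pytest.fixture()
def synthetic_genes():
    """Gene track on the compact genome with driver and deletion-gene flags."""
    genes = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr2", "chr2", "chr3", "chrX"],
            "start": [10_000_000, 30_000_000, 5_000_000, 20_000_000, 12_000_000, 15_000_000],
            "end": [10_150_000, 30_200_000, 5_100_000, 20_080_000, 12_300_000, 15_200_000],
            "name": ["GENE_A", "DRV1", "GENE_B", "DELG1", "GENE_C", "DRVX"],
        }
    )
    from plasmacnv.focal import GeneAnnotation

    return GeneAnnotation(genes, drivers={"DRV1", "DRVX"}, deletion_genes={"DELG1"})
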