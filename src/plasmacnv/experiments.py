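"""Reproducible in-silico experiments built from the pipeline stages.

The dilution experiment mirrors the wet-lab control for focal-amplification
sensitivity: a cell-line-like genome carrying a high-level AR amplicon
(13 copies on the single-copy male X, pure log2 ratio log2(13) = 3.70) is
mixed into normal cell-free DNA at decreasing tumour fractions and the
full pipeline (GC correction, control-panel normalization, CBS, focal
caller with AR flagged as a driver) is run at each level.  A level counts
as detectable when the amplicon is called in at least half the replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calls import call_states
from .focal import FocalCriteria, GeneAnnotation, call_focal_amplifications, empty_track
from .genome import CopyNumberEvent, CopyNumberStateMap, GenomeModel
from .profiles import BinnedProfile, ControlPanel, gc_correct, to_log2
from .segmentation import segment_profile
from .simulate import SimulationConfig, simulate_controls, simulate_sample, simulation_grid

__all__ = ["DilutionResult", "run_dilution_experiment", "AR_AMPLICON"]

#: 2-Mb amplicon over the AR locus (Xq12) at 13 copies: pure log2 = 3.70
AR_AMPLICON = CopyNumberEvent("chrX", 66_000_000, 68_000_000, 13.0)


@dataclass
class DilutionResult:
    levels: list[float]  # tumour fractions, descending
    n_replicates: int
    detected: dict[float, int]  # replicates in which the amplicon was called
    lowest_detectable: float | None  # lowest fraction with >= majority detection
    majority: float = 0.5

    @property
    def lowest_detectable_pct(self) -> float | None:
        return None if self.lowest_detectable is None else 100.0 * self.lowest_detectable


def run_dilution_experiment(
    seed: int = 1,
    levels: tuple[float, ...] = (0.20, 0.10, 0.05, 0.01),
    n_replicates: int = 25,
    n_bins: int = 50_000,
    coverage: float = 120.0,
    n_controls: int = 10,
    majority: float = 0.5,
    amplicon: CopyNumberEvent = AR_AMPLICON,
) -> DilutionResult:
    """Detection limit of a focal AR amplification across a dilution series.

    Returns per-level detection counts and the lowest tumour fraction at
    which the amplicon was called in at least ``majority`` of replicates.
    One control panel (``n_controls`` tumour-free samples) is shared by all
    replicates, as a single panel would be in practice.
    """
    genome = GenomeModel.male_hg19()
    base_cfg = SimulationConfig(n_bins=n_bins, total_coverage=coverage, seed=seed)
    grid = simulation_grid(genome, base_cfg)
    states = CopyNumberStateMap([amplicon])

    controls = simulate_controls(genome, n_controls, base_cfg, grid=grid)
    panel = ControlPanel.from_profiles(
        [gc_correct(BinnedProfile.from_counts(grid, c.counts, c.sample_id)) for c in controls]
    )

    genes = GeneAnnotation.packaged_default()
    criteria = FocalCriteria()
    segdup = empty_track()
    dgv = empty_track()
    ar = genes.genes[genes.genes["name"] == "AR"].iloc[0]

    detected: dict[float, int] = {}
    rng = np.random.default_rng(seed)
    for li, f in enumerate(levels):
        hits = 0
        for rep in range(n_replicates):
            rep_seed = seed + 10_000 * (li + 1) + rep
            cfg = SimulationConfig(
                n_bins=n_bins,
                total_coverage=coverage,
                tumour_fraction=f,
                seed=rep_seed,
            )
            sim = simulate_sample(genome, states, cfg, grid=grid)
            prof = BinnedProfile.from_counts(grid, sim.counts, f"f{f:g}_r{rep}")
            prof = to_log2(gc_correct(prof), panel)
            seg = segment_profile(
                prof, seed=int(rng.integers(1, 2**31 - 1))
            )
            events, _ = call_focal_amplifications(seg, genes, segdup, dgv, criteria)
            hit = (
                (events["chrom"] == ar["chrom"])
                & (events["start"] < ar["end"])
                & (events["end"] > ar["start"])
            ).any()
            hits += int(hit)
        detected[f] = hits

    need = majority * n_replicates
    detectable = [f for f in levels if detected[f] >= need]
    lowest = min(detectable) if detectable else None
    return DilutionResult(
        levels=list(levels),
        n_replicates=n_replicates,
        detected=detected,
        lowest_detectable=lowest,
        majority=majority,
    )
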