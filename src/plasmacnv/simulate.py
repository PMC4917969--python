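"""Synthetic shallow-WGS plasma profiles with known copy-number truth.

The generator emulates the measurement process the pipeline is built for:
cell-free DNA from a male donor sequenced to ~0.1x, reads counted in
~50,000 equal-mappability bins.  A tumour contributing a fraction *f* of the
cell-free DNA with absolute copy number *c* over a region shifts that
region's expected relative coverage to ``(baseline*(1-f) + c*f) / baseline``.
Coverage is modulated by a smooth unimodal GC-bias curve and counts are
drawn from a Poisson (optionally negative-binomial) distribution.

Every sample records its per-bin expected log2 ratio so downstream stages
can be tested against exact truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .genome import CopyNumberEvent, CopyNumberStateMap, GenomeModel
from .profiles import BinGrid, build_bin_grid

__all__ = [
    "SimulationConfig",
    "SimulatedSample",
    "expected_log2",
    "make_gc_track",
    "simulation_grid",
    "simulate_sample",
    "simulate_dilution_series",
    "simulate_serial_scenario",
    "simulate_controls",
]

#: log2 value reported when the mixture mean is exactly zero
LOG2_FLOOR = -10.0


@dataclass(frozen=True)
class GCBias:
    """Smooth unimodal coverage bias over GC fraction.

    ``bias(gc) = max(floor, 1 - curvature * (gc - peak)**2)``: coverage is
    highest at ``peak`` and falls off quadratically, mimicking the
    GC-dependent amplification/sequencing efficiency seen in real libraries.
    """

    peak: float = 0.45
    curvature: float = 16.0
    floor: float = 0.05

    def __call__(self, gc: np.ndarray) -> np.ndarray:
        gc = np.asarray(gc, dtype=float)
        return np.maximum(self.floor, 1.0 - self.curvature * (gc - self.peak) ** 2)

    @classmethod
    def flat(cls) -> "GCBias":
        return cls(curvature=0.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated sample or series."""

    n_bins: int = 50_000
    total_coverage: float = 120.0  # mean reads per autosomal bin (~0.1x)
    tumour_fraction: float = 0.0
    gc_bias: GCBias = field(default_factory=GCBias)
    noise_model: Literal["poisson", "negative_binomial"] = "poisson"
    nb_dispersion: float = 0.0  # extra-Poisson dispersion; var = mu*(1+d*mu)
    seed: int = 0
    gc_seed: int = 1234  # GC landscape is a grid property, fixed across samples

    def __post_init__(self) -> None:
        if not 0.0 <= self.tumour_fraction <= 1.0:
            raise ValueError("tumour fraction must lie in [0, 1]")
        if self.total_coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.noise_model not in ("poisson", "negative_binomial"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.noise_model == "negative_binomial" and self.nb_dispersion <= 0:
            raise ValueError("negative-binomial noise needs dispersion > 0")


@dataclass
class SimulatedSample:
    """Bin counts plus the truth that generated them."""

    grid: BinGrid
    counts: np.ndarray
    truth_log2: np.ndarray  # per-bin expected log2 ratio
    truth_copies: np.ndarray  # per-bin bp-weighted tumour copy number
    states: CopyNumberStateMap
    config: SimulationConfig
    seed: int
    sample_id: str = "sim"


def expected_log2(c: float, f: float, baseline: int) -> float:
    """Expected log2 ratio of a region at tumour copy number ``c``.

    The cell-free DNA is a mixture: a fraction ``f`` of tumour DNA at ``c``
    copies and ``1 - f`` of normal DNA at the baseline copy number, so the
    relative coverage is ``(baseline*(1-f) + c*f) / baseline``.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError("tumour fraction must lie in [0, 1]")
    if c < 0:
        raise ValueError("tumour copy number must be >= 0")
    if baseline not in (1, 2):
        raise ValueError("baseline copy number must be 1 or 2")
    mix = baseline * (1.0 - f) + c * f
    if mix == 0.0:
        return LOG2_FLOOR
    return math.log2(mix / baseline)


def make_gc_track(n_bins: int, seed: int = 1234) -> np.ndarray:
    """Smooth synthetic GC landscape: mean ~0.42, SD ~0.05, clipped [0.28, 0.62].

    A white-noise series is smoothed with a Gaussian kernel (~40 bins wide)
    so neighbouring bins share GC composition, as they do in real genomes.
    """
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal(n_bins + 400)
    width = 40
    xs = np.arange(-3 * width, 3 * width + 1)
    kernel = np.exp(-0.5 * (xs / width) ** 2)
    kernel /= kernel.sum()
    smooth = np.convolve(raw, kernel, mode="same")[200:-200]
    smooth /= max(smooth.std(), 1e-12)
    return np.clip(0.42 + 0.05 * smooth, 0.28, 0.62)


def simulation_grid(genome: GenomeModel, config: SimulationConfig) -> BinGrid:
    """Equal-mappability grid with the synthetic GC landscape attached.

    Deterministic in (genome, n_bins, gc_seed), so samples, controls and
    dilution series generated from the same config share one grid.
    """
    grid = build_bin_grid(genome, config.n_bins)
    return grid.with_gc(make_gc_track(len(grid), seed=config.gc_seed))


def _bin_copies(
    grid: BinGrid, genome: GenomeModel, states: CopyNumberStateMap
) -> np.ndarray:
    """bp-weighted mean tumour copy number per bin."""
    chroms = grid.chrom
    starts = grid.start
    ends = grid.end
    copies = np.empty(len(grid), dtype=float)
    for chrom, sl in grid.chrom_slices():
        base = float(genome.baseline(chrom))
        copies[sl] = base
        s = starts[sl]
        e = ends[sl]
        span = (e - s).astype(float)
        for ev in states.events_on(chrom):
            ov = np.clip(np.minimum(e, ev.end) - np.maximum(s, ev.start), 0, None)
            copies[sl] += (ev.copies - base) * ov / span
    return copies


def _draw_counts(
    rng: np.random.Generator, mean: np.ndarray, config: SimulationConfig
) -> np.ndarray:
    if config.noise_model == "poisson":
        return rng.poisson(mean)
    # negative binomial with var = mu * (1 + d * mu)
    d = config.nb_dispersion
    r = 1.0 / d
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_sample(
    genome: GenomeModel,
    states: CopyNumberStateMap,
    config: SimulationConfig,
    grid: BinGrid | None = None,
    sample_id: str = "sim",
) -> SimulatedSample:
    """Draw one sample: per-bin mean = coverage * gc_bias * mixture ratio.

    The expected count of an autosomal copy-neutral bin is
    ``total_coverage * gc_bias(gc)``; regions with tumour copy number ``c``
    are scaled by the mixture ratio and single-copy (X/Y) chromosomes get
    half the autosomal coverage, as in a male reference sample.
    """
    states.validate_against(genome)
    if grid is None:
        grid = simulation_grid(genome, config)
    f = config.tumour_fraction
    copies = _bin_copies(grid, genome, states)
    baseline = np.empty(len(grid), dtype=float)
    for chrom, sl in grid.chrom_slices():
        baseline[sl] = float(genome.baseline(chrom))
    mix = baseline * (1.0 - f) + copies * f
    with np.errstate(divide="ignore"):
        truth = np.where(mix > 0, np.log2(np.maximum(mix, 1e-300) / baseline), LOG2_FLOOR)
    mean = config.total_coverage * config.gc_bias(grid.gc) * mix / 2.0
    rng = np.random.default_rng(config.seed)
    counts = _draw_counts(rng, mean, config)
    return SimulatedSample(
        grid=grid,
        counts=counts,
        truth_log2=truth,
        truth_copies=copies,
        states=states,
        config=config,
        seed=config.seed,
        sample_id=sample_id,
    )


def simulate_dilution_series(
    genome: GenomeModel,
    pure: CopyNumberStateMap,
    fractions: Sequence[float],
    config: SimulationConfig,
    grid: BinGrid | None = None,
) -> list[SimulatedSample]:
    """One sample per tumour fraction, sharing grid and GC bias.

    Per-fraction seeds are ``config.seed + index`` so the series is
    reproducible but each dilution level is an independent draw.
    """
    if len(fractions) == 0:
        raise ValueError("empty fraction list")
    for f in fractions:
        if not 0.0 < f <= 1.0:
            raise ValueError("dilution fractions must lie in (0, 1]")
    if grid is None:
        grid = simulation_grid(genome, config)
    out = []
    for i, f in enumerate(fractions):
        cfg = replace(config, tumour_fraction=float(f), seed=config.seed + i)
        out.append(
            simulate_sample(
                genome, pure, cfg, grid=grid, sample_id=f"dilution_{f:g}"
            )
        )
    return out


def simulate_serial_scenario(
    genome: GenomeModel,
    base: CopyNumberStateMap,
    changes: Sequence[tuple[str, CopyNumberEvent, int]],
    n_timepoints: int,
    config: SimulationConfig,
    grid: BinGrid | None = None,
    fractions: Sequence[float] | None = None,
) -> list[SimulatedSample]:
    """Serial samples from an evolving tumour genome.

    ``changes`` is a list of ``(op, event, time_index)`` with op ``"add"`` or
    ``"remove"``; each time point's state map is ``base`` with all changes up
    to and including that index applied.  Removing an event that is not
    present raises.  ``fractions`` optionally sets a per-time-point tumour
    fraction (ctDNA content varies between draws); otherwise the config's
    fraction applies throughout.  Differential truth between consecutive
    time points is implied by the recorded state maps.
    """
    indices = [t for _, _, t in changes]
    if any(b <= a for a, b in zip(indices, indices[1:])):
        raise ValueError("change time indices must be strictly increasing")
    if any(t < 0 or t >= n_timepoints for t in indices):
        raise ValueError("change time index outside the sampled time points")
    if fractions is not None and len(fractions) != n_timepoints:
        raise ValueError("need one tumour fraction per time point")
    if grid is None:
        grid = simulation_grid(genome, config)
    out = []
    states = base
    pending = list(changes)
    for t in range(n_timepoints):
        while pending and pending[0][2] <= t:
            op, ev, _ = pending.pop(0)
            if op == "add":
                states = states.with_event(ev)
            elif op == "remove":
                states = states.without_event(ev)
            else:
                raise ValueError(f"unknown serial change op {op!r}")
        f_t = config.tumour_fraction if fractions is None else float(fractions[t])
        cfg = replace(config, seed=config.seed + t, tumour_fraction=f_t)
        out.append(
            simulate_sample(genome, states, cfg, grid=grid, sample_id=f"t{t}")
        )
    return out


def simulate_controls(
    genome: GenomeModel,
    n: int,
    config: SimulationConfig,
    grid: BinGrid | None = None,
) -> list[SimulatedSample]:
    """``n`` tumour-free samples (f = 0) with independent derived seeds."""
    if n < 2:
        raise ValueError("need >= 2 controls (SD undefined otherwise)")
    if grid is None:
        grid = simulation_grid(genome, config)
    empty = CopyNumberStateMap()
    out = []
    for i in range(n):
        cfg = replace(config, tumour_fraction=0.0, seed=config.seed + 1_000 + i)
        out.append(
            simulate_sample(genome, empty, cfg, grid=grid, sample_id=f"control_{i}")
        )
    return out
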