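"""End-to-end orchestration: simulate/normalize/segment/call/focal/serial.

A :class:`RunConfig` (flat YAML file or keyword arguments) drives one run;
outputs are plain TSV tables plus a manifest recording the package version,
the configuration hash and the seed, which together suffice to reproduce
the run bit for bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .calls import (
    StateCallingConfig,
    altered_fractions,
    call_states,
    classify_aberrant,
    control_aberrance_stats,
)
from .focal import (
    FocalCriteria,
    GeneAnnotation,
    call_focal_amplifications,
    call_focal_deletions,
    empty_track,
    read_bed,
)
from .genome import CopyNumberEvent, CopyNumberStateMap, GenomeModel
from .io import write_bin_counts, write_log2_profile, write_manifest, write_seg, write_truth_bed
from .profiles import BinnedProfile, ControlPanel, gc_correct, to_log2
from .segmentation import segment_profile, segment_values
from .serial import SerialConfig, cluster_profiles, compare_serial, linkage_to_newick
from .simulate import SimulationConfig, simulate_controls, simulate_sample, simulation_grid

__all__ = ["RunConfig", "run_sample_pipeline", "run_serial_pipeline"]


@dataclass
class RunConfig:
    """Parameters for one pipeline run (defaults are the published values)."""

    out_dir: str = "run_out"
    seed: int = 0
    n_bins: int = 50_000
    total_coverage: float = 120.0
    tumour_fraction: float = 0.0
    n_controls: int = 10
    # events as (chrom, start, end, copies) tuples; one list per sample
    events: list = field(default_factory=list)
    serial_events: list = field(default_factory=list)  # list of per-timepoint lists
    serial_fractions: list = field(default_factory=list)
    cbs_alpha: float = 0.01
    cbs_min_width: int = 3
    cbs_n_perm: int = 1000
    cbs_merge_tol: float = 0.05
    gain_threshold: float = 0.2
    loss_threshold: float = -0.2
    min_rho: float = 0.85
    genes_bed: str | None = None
    drivers_txt: str | None = None
    deletion_genes_txt: str | None = None
    segdup_bed: str | None = None
    dgv_bed: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _annotation(config: RunConfig) -> GeneAnnotation:
    if config.genes_bed is None:
        return GeneAnnotation.packaged_default()
    genes = read_bed(config.genes_bed)
    drivers = _load_list(config.drivers_txt)
    dels = _load_list(config.deletion_genes_txt)
    return GeneAnnotation(genes, drivers=drivers, deletion_genes=dels)


def _load_list(path: str | None) -> set[str]:
    if path is None:
        return set()
    with open(path) as fh:
        return {ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")}


def _track(path: str | None):
    return read_bed(path) if path else empty_track()


def _state_map(events: list) -> CopyNumberStateMap:
    return CopyNumberStateMap(
        [CopyNumberEvent(str(c), int(s), int(e), float(cn)) for c, s, e, cn in events]
    )


def _normalize_one(grid, counts, panel, sample_id):
    prof = BinnedProfile.from_counts(grid, counts, sample_id)
    return to_log2(gc_correct(prof), panel)


def run_sample_pipeline(config: RunConfig) -> Path:
    """Simulate one sample plus controls and run it through every stage.

    Writes bin counts, truth, log2 profile, SEG, labelled SEG, focal events
    and rejections, a per-sample summary and a manifest into ``out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = GenomeModel.male_hg19()
    sim_cfg = SimulationConfig(
        n_bins=config.n_bins,
        total_coverage=config.total_coverage,
        tumour_fraction=config.tumour_fraction,
        seed=config.seed,
    )
    grid = simulation_grid(genome, sim_cfg)
    states = _state_map(config.events)
    sim = simulate_sample(genome, states, sim_cfg, grid=grid, sample_id="sample")
    write_bin_counts(sim, out / "bin_counts.tsv")
    write_truth_bed(sim, out / "truth.bed")

    controls = simulate_controls(genome, config.n_controls, sim_cfg, grid=grid)
    panel = ControlPanel.from_profiles(
        [gc_correct(BinnedProfile.from_counts(grid, c.counts, c.sample_id)) for c in controls]
    )
    prof = _normalize_one(grid, sim.counts, panel, "sample")
    write_log2_profile(prof, out / "log2.tsv")

    rng = np.random.default_rng(config.seed)
    seg_kwargs = dict(
        alpha=config.cbs_alpha,
        min_width=config.cbs_min_width,
        n_perm=config.cbs_n_perm,
        merge_tol=config.cbs_merge_tol,
    )
    seg = segment_profile(prof, seed=int(rng.integers(1, 2**31 - 1)), **seg_kwargs)
    write_seg(seg, out / "segments.seg")

    state_cfg = StateCallingConfig(config.gain_threshold, config.loss_threshold)
    labelled = call_states(seg, state_cfg)
    write_seg(labelled, out / "segments_labelled.seg")

    control_segs = []
    for c in controls:
        cp = _normalize_one(grid, c.counts, panel, c.sample_id)
        cs = segment_profile(cp, seed=int(rng.integers(1, 2**31 - 1)), **seg_kwargs)
        control_segs.append(call_states(cs, state_cfg))
    stats = control_aberrance_stats(control_segs, state_cfg)
    fractions = altered_fractions(labelled)
    aberrant, _ = classify_aberrant(fractions, stats)

    genes = _annotation(config)
    criteria = FocalCriteria()
    segdup = _track(config.segdup_bed)
    dgv = _track(config.dgv_bed)
    amps, amp_rej = call_focal_amplifications(labelled, genes, segdup, dgv, criteria)
    dels, del_rej = call_focal_deletions(labelled, genes, segdup, dgv, criteria)
    import pandas as pd

    def _concat(frames):
        frames = [f for f in frames if len(f)]
        return pd.concat(frames, ignore_index=True) if frames else amps.iloc[0:0]

    events = _concat([amps, dels])
    events.to_csv(out / "focal_events.tsv", sep="\t", index=False)
    rej = [f for f in (amp_rej, del_rej) if len(f)]
    (pd.concat(rej, ignore_index=True) if rej else amp_rej).to_csv(
        out / "focal_rejections.tsv", sep="\t", index=False
    )

    summary = {
        "sample": "sample",
        "pct_gain": round(fractions["pct_gain"], 4),
        "pct_loss": round(fractions["pct_loss"], 4),
        "mb_gain": round(fractions["mb_gain"], 3),
        "mb_loss": round(fractions["mb_loss"], 3),
        "aberrant": int(aberrant),
        "n_focal_amplifications": len(amps),
        "n_focal_deletions": len(dels),
    }
    pd.DataFrame([summary]).to_csv(out / "summary.tsv", sep="\t", index=False)
    write_manifest(
        {
            "version": __version__,
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "stage": "sample_pipeline",
        },
        out / "manifest.tsv",
    )
    return out


def run_serial_pipeline(config: RunConfig) -> Path:
    """Simulate and compare serial samples; also writes the clustering tree."""
    if len(config.serial_events) < 2:
        raise ValueError("serial pipeline needs >= 2 configured time points")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = GenomeModel.male_hg19()
    sim_cfg = SimulationConfig(
        n_bins=config.n_bins,
        total_coverage=config.total_coverage,
        tumour_fraction=config.tumour_fraction,
        seed=config.seed,
    )
    grid = simulation_grid(genome, sim_cfg)
    controls = simulate_controls(genome, config.n_controls, sim_cfg, grid=grid)
    panel = ControlPanel.from_profiles(
        [gc_correct(BinnedProfile.from_counts(grid, c.counts, c.sample_id)) for c in controls]
    )

    rng = np.random.default_rng(config.seed)
    fracs = config.serial_fractions or [config.tumour_fraction] * len(config.serial_events)
    import pandas as pd
    from dataclasses import replace as dc_replace

    seg_values_list = []
    names = []
    for t, ev_list in enumerate(config.serial_events):
        cfg_t = dc_replace(sim_cfg, tumour_fraction=float(fracs[t]), seed=config.seed + t)
        sim = simulate_sample(genome, _state_map(ev_list), cfg_t, grid=grid, sample_id=f"t{t}")
        prof = _normalize_one(grid, sim.counts, panel, f"t{t}")
        seg = segment_profile(prof, seed=int(rng.integers(1, 2**31 - 1)))
        write_seg(seg, out / f"segments_t{t}.seg")
        seg_values_list.append(segment_values(prof, seg))
        names.append(f"t{t}")

    serial_cfg = SerialConfig(min_rho=config.min_rho)
    reports = []
    for t in range(len(names) - 1):
        comp = compare_serial(
            grid,
            seg_values_list[t],
            seg_values_list[t + 1],
            sample_a=names[t],
            sample_b=names[t + 1],
            config=serial_cfg,
        )
        reports.append(
            {
                "pair": f"{comp.sample_a}->{comp.sample_b}",
                "rho": round(comp.rho, 4),
                "eligible": int(comp.eligible),
                "ratio": comp.ratio if comp.ratio is not None else "",
                "pct_differential": (
                    round(comp.pct_differential, 3)
                    if comp.pct_differential is not None
                    else ""
                ),
                "skipped_reason": comp.skipped_reason or "",
            }
        )
        if comp.regions is not None:
            comp.regions.to_csv(
                out / f"differential_{comp.sample_a}_{comp.sample_b}.bed",
                sep="\t",
                index=False,
                header=False,
            )
    pd.DataFrame(reports).to_csv(out / "serial_report.tsv", sep="\t", index=False)

    if len(names) >= 2:
        mat = np.vstack(seg_values_list)
        link = cluster_profiles(mat)
        (out / "clusters.nwk").write_text(linkage_to_newick(link, names) + "\n")

    write_manifest(
        {
            "version": __version__,
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "stage": "serial_pipeline",
        },
        out / "manifest.tsv",
    )
    return out
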