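"""Plain-text table formats used by the pipeline.

All tables are tab-separated with a header, coordinates 0-based half-open:

* bin-count TSV: ``chrom start end gc mappable_bp count``
* log2 profile TSV: ``chrom start end log2 masked``
* SEG TSV: ``sample chrom start end n_bins mean_log2`` (+ optional columns);
  externally segmented data (e.g. array-derived tables) enter here
* truth BED: ``chrom start end copy_number expected_log2``
* manifest: ``key<TAB>value`` lines
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .profiles import BinGrid, BinnedProfile
from .segmentation import SegmentedProfile
from .simulate import SimulatedSample

__all__ = [
    "write_bin_counts",
    "read_bin_counts",
    "write_log2_profile",
    "read_log2_profile",
    "write_seg",
    "read_seg",
    "write_truth_bed",
    "write_manifest",
    "read_manifest",
]


def write_bin_counts(sample: SimulatedSample | BinnedProfile, path: str | Path) -> None:
    grid = sample.grid
    df = pd.DataFrame(
        {
            "chrom": grid.chrom,
            "start": grid.start,
            "end": grid.end,
            "gc": np.round(grid.gc, 6),
            "mappable_bp": grid.bins["mappable_bp"].to_numpy(),
            "count": np.asarray(sample.counts, dtype=np.int64),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_bin_counts(path: str | Path) -> tuple[BinGrid, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "gc", "mappable_bp", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"bin-count table missing columns: {sorted(missing)}")
    grid = BinGrid(df[["chrom", "start", "end", "gc", "mappable_bp"]].copy())
    return grid, df["count"].to_numpy(dtype=np.int64)


def write_log2_profile(profile: BinnedProfile, path: str | Path) -> None:
    if profile.log2 is None:
        raise ValueError("profile has no log2 values")
    grid = profile.grid
    df = pd.DataFrame(
        {
            "chrom": grid.chrom,
            "start": grid.start,
            "end": grid.end,
            "log2": np.round(profile.log2, 6),
            "masked": profile.mask.astype(int),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_log2_profile(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "log2", "masked"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"log2 table missing columns: {sorted(missing)}")
    return df


def write_seg(profiles: SegmentedProfile | Sequence[SegmentedProfile], path: str | Path) -> None:
    if isinstance(profiles, SegmentedProfile):
        profiles = [profiles]
    frames = []
    for prof in profiles:
        df = prof.segments.copy()
        df.insert(0, "sample", prof.sample_id)
        df["mean_log2"] = np.round(df["mean_log2"].astype(float), 6)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_seg(path: str | Path) -> list[SegmentedProfile]:
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "chrom", "start", "end", "mean_log2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"SEG table missing columns: {sorted(missing)}")
    out = []
    for sample, grp in df.groupby("sample", sort=False):
        out.append(
            SegmentedProfile.from_table(
                grp.drop(columns="sample"), sample_id=str(sample)
            )
        )
    return out


def write_truth_bed(sample: SimulatedSample, path: str | Path) -> None:
    grid = sample.grid
    df = pd.DataFrame(
        {
            "chrom": grid.chrom,
            "start": grid.start,
            "end": grid.end,
            "copy_number": np.round(sample.truth_copies, 4),
            "expected_log2": np.round(sample.truth_log2, 6),
        }
    )
    df.to_csv(path, sep="\t", index=False, header=False)


def write_manifest(entries: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        for key in sorted(entries):
            fh.write(f"{key}\t{entries[key]}\n")


def read_manifest(path: str | Path) -> dict[str, str]:
    out = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            key, _, value = line.rstrip("\n").partition("\t")
            out[key] = value
    return out
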