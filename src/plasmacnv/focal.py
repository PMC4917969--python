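"""Focal amplification and deletion calling on segmented profiles.

A focal amplification is a segment that satisfies all of: span < 20 Mb;
mean log2 ratio > 0.2; contains at least one and at most 100 genes; exceeds
the length-weighted mean log2 of the neighbouring 20 Mb on both sides by
more than 0.2 if it contains a known amplification driver gene and by more
than 0.58 (about three copies at diploid baseline) otherwise; is not covered
more than 50% by segmental duplications; and is not disqualified by
germline copy-number variants.  Focal deletions mirror these rules below
-0.2 and additionally require a gene from the known deletion-gene list.

Every candidate above the base log2 threshold that is rejected records the
first rule it failed, so calls are auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .segmentation import SegmentedProfile

__all__ = [
    "FocalCriteria",
    "GeneAnnotation",
    "flank_weighted_mean",
    "log2_to_copies",
    "call_focal_amplifications",
    "call_focal_deletions",
    "count_focal_per_sample",
    "interval_union_overlap",
]

AMP_RULES = ("size", "log2", "no_gene", "too_many_genes", "flank_delta", "segdup", "germline_cnv")
DEL_RULES = ("size", "log2", "no_deletion_gene", "too_many_genes", "flank_delta", "segdup", "germline_cnv")


@dataclass(frozen=True)
class FocalCriteria:
    """Thresholds of the focal-event definition (defaults as published)."""

    max_size_bp: float = 20e6
    amp_log2: float = 0.2
    del_log2: float = -0.2
    flank_bp: float = 20e6
    driver_delta: float = 0.2  # flank excess needed when a driver gene is contained
    nondriver_delta: float = 0.58  # ~three copies at diploid baseline
    max_genes: int = 100
    segdup_max_frac: float = 0.5
    germline_max_frac: float = 0.5  # coverage-based DGV disqualification

    def __post_init__(self) -> None:
        if self.nondriver_delta <= self.driver_delta:
            raise ValueError("non-driver flank delta must exceed driver delta")
        for name in ("max_size_bp", "amp_log2", "flank_bp", "driver_delta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class GeneAnnotation:
    """Gene bodies plus driver and deletion-gene flags.

    ``genes`` needs columns chrom, start, end, name; ``drivers`` and
    ``deletion_genes`` are gene-name sets gating the lenient (0.2) versus
    strict (0.58) flank threshold and the deletion-gene requirement.
    """

    def __init__(
        self,
        genes: pd.DataFrame,
        drivers: set[str] | Sequence[str] = (),
        deletion_genes: set[str] | Sequence[str] = (),
    ) -> None:
        required = {"chrom", "start", "end", "name"}
        missing = required - set(genes.columns)
        if missing:
            raise ValueError(f"gene table missing columns: {sorted(missing)}")
        if (genes["end"] <= genes["start"]).any():
            raise ValueError("gene intervals must have end > start")
        self.genes = genes.reset_index(drop=True)
        self.drivers = set(drivers)
        self.deletion_genes = set(deletion_genes)

    def overlapping(self, chrom: str, start: float, end: float) -> pd.DataFrame:
        g = self.genes
        sel = (g["chrom"] == chrom) & (g["start"] < end) & (g["end"] > start)
        return g[sel]

    @classmethod
    def packaged_default(cls) -> "GeneAnnotation":
        """Gene track and driver/deletion lists shipped with the package.

        Coordinates are approximate hg19 gene bodies for a small set of
        recurrent prostate-cancer genes; intended for simulations and demos,
        not as a production annotation.
        """
        data = resources.files("plasmacnv").joinpath("data")
        genes = read_bed(str(data.joinpath("genes_hg19.bed")))
        drivers = _read_list(str(data.joinpath("driver_genes.txt")))
        dels = _read_list(str(data.joinpath("deletion_genes.txt")))
        return cls(genes, drivers=drivers, deletion_genes=dels)


def read_bed(path: str) -> pd.DataFrame:
    """Minimal BED reader: chrom, start, end and an optional name column."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    df.columns = cols[: len(df.columns)]
    if "name" not in df.columns:
        df["name"] = [f"entry_{i}" for i in range(len(df))]
    return df[["chrom", "start", "end", "name"]]


def _read_list(path: str) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip() and not line.startswith("#")}


def interval_union_overlap(
    track: pd.DataFrame, chrom: str, start: float, end: float
) -> float:
    """Total bp of [start, end) covered by the union of track entries."""
    t = track[(track["chrom"] == chrom) & (track["start"] < end) & (track["end"] > start)]
    if len(t) == 0:
        return 0.0
    ivls = sorted(
        (max(float(s), start), min(float(e), end))
        for s, e in zip(t["start"], t["end"])
    )
    covered = 0.0
    cur_s, cur_e = ivls[0]
    for s, e in ivls[1:]:
        if s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            covered += cur_e - cur_s
            cur_s, cur_e = s, e
    covered += cur_e - cur_s
    return covered


def flank_weighted_mean(
    profile: SegmentedProfile, target_index: int, window_bp: float = 20e6
) -> float:
    """Length-weighted mean log2 of the 20 Mb flanking the target segment.

    Both windows are truncated at the chromosome's segmented extent; when
    one side is empty the other alone is used, and 0 is returned when both
    are.
    """
    df = profile.segments
    if target_index not in df.index:
        raise KeyError(f"segment index {target_index} not in profile")
    target = df.loc[target_index]
    chrom_segs = df[(df["chrom"] == target["chrom"]) & (df.index != target_index)]
    windows = (
        (target["start"] - window_bp, target["start"]),
        (target["end"], target["end"] + window_bp),
    )
    wsum = 0.0
    vsum = 0.0
    for ws, we in windows:
        for _, seg in chrom_segs.iterrows():
            ov = min(float(seg["end"]), we) - max(float(seg["start"]), ws)
            if ov > 0:
                wsum += ov
                vsum += ov * float(seg["mean_log2"])
    if wsum == 0:
        return 0.0
    return vsum / wsum


def log2_to_copies(log2_ratio: float, baseline: int = 2) -> float:
    """Absolute copies implied by a log2 ratio at a given baseline ploidy."""
    if baseline not in (1, 2):
        raise ValueError("baseline ploidy must be 1 or 2")
    return baseline * 2.0 ** log2_ratio


def _call_focal(
    profile: SegmentedProfile,
    genes: GeneAnnotation,
    segdup: pd.DataFrame,
    germline_cnv: pd.DataFrame,
    criteria: FocalCriteria,
    kind: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    if segdup is None or germline_cnv is None:
        raise ValueError(
            "segdup and germline-CNV tracks are required (pass empty tables "
            "to disable the filters explicitly)"
        )
    amp = kind == "amplification"
    events = []
    rejections = []
    df = profile.segments
    for idx, seg in df.iterrows():
        chrom, start, end = seg["chrom"], float(seg["start"]), float(seg["end"])
        mean = float(seg["mean_log2"])
        span = end - start
        passes_base = mean > criteria.amp_log2 if amp else mean < criteria.del_log2

        overlapping = genes.overlapping(chrom, start, end)
        names = list(overlapping["name"])
        has_driver = any(n in genes.drivers for n in names)
        has_del_gene = any(n in genes.deletion_genes for n in names)
        flank = flank_weighted_mean(profile, idx, criteria.flank_bp)
        delta = mean - flank
        segdup_frac = (
            interval_union_overlap(segdup, chrom, start, end) / span if span > 0 else 0.0
        )
        germ_frac = (
            interval_union_overlap(germline_cnv, chrom, start, end) / span
            if span > 0
            else 0.0
        )

        failed = None
        if span >= criteria.max_size_bp:
            failed = "size"
        elif not passes_base:
            failed = "log2"
        elif amp and len(names) < 1:
            failed = "no_gene"
        elif not amp and not has_del_gene:
            failed = "no_deletion_gene"
        elif len(names) > criteria.max_genes:
            failed = "too_many_genes"
        elif amp and delta <= (
            criteria.driver_delta if has_driver else criteria.nondriver_delta
        ):
            failed = "flank_delta"
        elif not amp and delta >= -criteria.driver_delta:
            failed = "flank_delta"
        elif segdup_frac > criteria.segdup_max_frac:
            failed = "segdup"
        elif germ_frac >= criteria.germline_max_frac:
            failed = "germline_cnv"

        record = {
            "sample": profile.sample_id,
            "chrom": chrom,
            "start": int(start),
            "end": int(end),
            "class": kind,
            "mean_log2": mean,
            "flank_mean": flank,
            "delta": delta,
            "genes": ",".join(names),
            "n_genes": len(names),
            "has_driver": has_driver if amp else has_del_gene,
        }
        if failed is None:
            events.append(record)
        elif passes_base:
            rejections.append({**record, "failed_rule": failed})

    ev_cols = [
        "sample", "chrom", "start", "end", "class", "mean_log2",
        "flank_mean", "delta", "genes", "n_genes", "has_driver",
    ]
    ev = pd.DataFrame(events, columns=ev_cols)
    rej = pd.DataFrame(rejections, columns=ev_cols + ["failed_rule"])
    return ev, rej


def call_focal_amplifications(
    profile: SegmentedProfile,
    genes: GeneAnnotation,
    segdup: pd.DataFrame,
    germline_cnv: pd.DataFrame,
    criteria: FocalCriteria | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Focal amplification events and the audited rejections."""
    return _call_focal(
        profile, genes, segdup, germline_cnv, criteria or FocalCriteria(), "amplification"
    )


def call_focal_deletions(
    profile: SegmentedProfile,
    genes: GeneAnnotation,
    segdup: pd.DataFrame,
    germline_cnv: pd.DataFrame,
    criteria: FocalCriteria | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Focal deletion events and the audited rejections."""
    return _call_focal(
        profile, genes, segdup, germline_cnv, criteria or FocalCriteria(), "deletion"
    )


def empty_track() -> pd.DataFrame:
    """An explicitly empty annotation track (disables a filter)."""
    return pd.DataFrame(columns=["chrom", "start", "end", "name"])


def count_focal_per_sample(
    events: pd.DataFrame,
    one_per_patient: bool = False,
    patient_map: pd.DataFrame | None = None,
    n_samples: int | None = None,
) -> dict:
    """Per-sample focal-event counts and the cohort mean.

    ``n_samples`` sets the cohort denominator explicitly (samples without
    events otherwise would not be counted).  With ``one_per_patient`` a
    designated sample per patient is used: the one flagged ``use`` in
    ``patient_map`` (columns sample, patient[, use]), else the first listed
    per patient; the mean is then events per patient.
    """
    if one_per_patient:
        if patient_map is None:
            raise ValueError("one_per_patient requires a patient map")
        pm = patient_map.copy()
        missing = set(events["sample"]) - set(pm["sample"])
        if missing:
            raise ValueError(f"patient map missing samples: {sorted(missing)}")
        if "use" in pm.columns:
            chosen = pm[pm["use"].astype(bool)]
        else:
            chosen = pm.drop_duplicates("patient", keep="first")
        keep = set(chosen["sample"])
        events = events[events["sample"].isin(keep)]
        units = patient_map["patient"].nunique()
    else:
        units = n_samples if n_samples is not None else events["sample"].nunique()

    per_sample = (
        events.groupby(["sample", "class"]).size().unstack(fill_value=0)
        if len(events)
        else pd.DataFrame()
    )
    total = int(len(events))
    mean = total / units if units else 0.0
    return {
        "per_sample": per_sample,
        "n_events": total,
        "n_units": int(units),
        "mean_per_unit": mean,
    }
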