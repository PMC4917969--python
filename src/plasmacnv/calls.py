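"""Gain/loss labelling, altered genome fractions and the aberrance classifier.

Segments are labelled gained when their mean log2 ratio exceeds +0.2 and
lost below -0.2 (strict inequalities).  A sample is classified copy-number
aberrant when its cumulative gained length or cumulative lost length exceeds
the corresponding control mean by more than k (default 3) standard
deviations, with the control statistics taken from non-tumour samples run
through the identical pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .profiles import BinGrid
from .segmentation import SegmentedProfile

__all__ = [
    "StateCallingConfig",
    "AberranceStats",
    "call_states",
    "altered_fractions",
    "classify_aberrant",
    "control_aberrance_stats",
]

GAIN, LOSS, BALANCED = "gain", "loss", "balanced"


@dataclass(frozen=True)
class StateCallingConfig:
    gain_threshold: float = 0.2
    loss_threshold: float = -0.2

    def __post_init__(self) -> None:
        if not self.gain_threshold > 0 > self.loss_threshold:
            raise ValueError("need gain threshold > 0 > loss threshold")


@dataclass(frozen=True)
class AberranceStats:
    """Control-cohort cumulative gained/lost length statistics (bp)."""

    gain_mean: float
    gain_sd: float
    loss_mean: float
    loss_sd: float
    n_controls: int
    k: float = 3.0

    def __post_init__(self) -> None:
        if self.n_controls < 2:
            raise ValueError("aberrance statistics require >= 2 controls")
        if self.gain_sd < 0 or self.loss_sd < 0:
            raise ValueError("standard deviations must be >= 0")


def call_states(
    profile: SegmentedProfile, config: StateCallingConfig | None = None
) -> SegmentedProfile:
    """Label every segment gain / loss / balanced (strict thresholds)."""
    config = config or StateCallingConfig()
    df = profile.segments.copy()
    means = df["mean_log2"].to_numpy(dtype=float)
    label = np.where(
        means > config.gain_threshold,
        GAIN,
        np.where(means < config.loss_threshold, LOSS, BALANCED),
    )
    df["label"] = label
    return SegmentedProfile(
        sample_id=profile.sample_id, segments=df, grid=profile.grid
    )


def altered_fractions(
    profile: SegmentedProfile, grid: BinGrid | None = None
) -> dict[str, float]:
    """Percent and Mb of the unmasked genome gained and lost.

    With a grid, lengths are recounted per bin (sum of spans of bins whose
    covering segment is labelled); without one, segment ``bp`` totals are
    used.  The two agree exactly when the segments came from that grid.
    """
    df = profile.segments
    if "label" not in df.columns:
        raise ValueError("segments are unlabelled; run call_states first")
    grid = grid if grid is not None else profile.grid
    if grid is not None:
        spans = grid.span
        mid = (grid.start + grid.end) / 2.0
        chroms = grid.chrom
        covered = np.zeros(len(grid), dtype=bool)
        gained = 0.0
        lost = 0.0
        total = 0.0
        for _, seg in df.iterrows():
            sel = (chroms == seg["chrom"]) & (mid >= seg["start"]) & (mid < seg["end"])
            bp = float(spans[sel].sum())
            covered |= sel
            total += bp
            if seg["label"] == GAIN:
                gained += bp
            elif seg["label"] == LOSS:
                lost += bp
    else:
        bp = df["bp"].to_numpy(dtype=float)
        total = float(bp.sum())
        gained = float(bp[df["label"] == GAIN].sum())
        lost = float(bp[df["label"] == LOSS].sum())
    if total <= 0:
        raise ValueError("zero-length genome: no unmasked segment span")
    return {
        "pct_gain": 100.0 * gained / total,
        "pct_loss": 100.0 * lost / total,
        "mb_gain": gained / 1e6,
        "mb_loss": lost / 1e6,
        "bp_gain": gained,
        "bp_loss": lost,
        "bp_total": total,
    }


def classify_aberrant(
    fractions: dict[str, float], stats: AberranceStats
) -> tuple[bool, dict[str, float]]:
    """Copy-number aberrant iff gained or lost length exceeds control mean + k*SD."""
    gain_cut = stats.gain_mean + stats.k * stats.gain_sd
    loss_cut = stats.loss_mean + stats.k * stats.loss_sd
    gained = fractions["bp_gain"]
    lost = fractions["bp_loss"]
    aberrant = bool(gained > gain_cut or lost > loss_cut)
    report = {
        "bp_gain": gained,
        "bp_loss": lost,
        "gain_cutoff_bp": gain_cut,
        "loss_cutoff_bp": loss_cut,
        "gain_exceeds": float(gained > gain_cut),
        "loss_exceeds": float(lost > loss_cut),
    }
    return aberrant, report


def control_aberrance_stats(
    control_profiles: Sequence[SegmentedProfile],
    config: StateCallingConfig | None = None,
    k: float = 3.0,
) -> AberranceStats:
    """Gain/loss cumulative-length statistics from labelled control samples."""
    if len(control_profiles) < 2:
        raise ValueError("aberrance statistics require >= 2 controls")
    gains = []
    losses = []
    for prof in control_profiles:
        labelled = prof if "label" in prof.segments.columns else call_states(prof, config)
        fr = altered_fractions(labelled)
        gains.append(fr["bp_gain"])
        losses.append(fr["bp_loss"])
    gains_arr = np.asarray(gains, dtype=float)
    losses_arr = np.asarray(losses, dtype=float)
    return AberranceStats(
        gain_mean=float(gains_arr.mean()),
        gain_sd=float(gains_arr.std(ddof=1)),
        loss_mean=float(losses_arr.mean()),
        loss_sd=float(losses_arr.std(ddof=1)),
        n_controls=len(control_profiles),
        k=k,
    )
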