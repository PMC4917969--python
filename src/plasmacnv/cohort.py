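"""Cohort-level summaries and statistical tests.

Per-bin gain/loss frequency tracks across a cohort, two-group comparisons
of focal-event counts (Mann-Whitney U), 2x2 contingency tests (Fisher
exact) and a per-group report of focal counts, altered fractions and
driver-aberration frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calls import GAIN, LOSS
from .profiles import BinGrid
from .segmentation import SegmentedProfile

__all__ = [
    "FrequencyTrack",
    "GroupComparison",
    "frequency_tracks",
    "mann_whitney_u",
    "fisher_exact_2x2",
    "cohort_report",
    "share_pct",
]

#: largest combined sample size for which the Mann-Whitney p-value is
#: computed by exact enumeration (ties force the normal approximation)
EXACT_MW_MAX_N = 12

# chr21 interval spanned by the TMPRSS2:ERG fusion deletion (hg19, gene bodies)
TMPRSS2_ERG_REGION = ("chr21", 39_751_949, 42_903_043)


@dataclass
class GroupComparison:
    test: str
    groups: tuple[str, str]
    n: tuple[int, int]
    statistic: float
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


@dataclass
class FrequencyTrack:
    grid: BinGrid
    gain_frac: np.ndarray
    loss_frac: np.ndarray
    n_samples: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.grid.chrom,
                "start": self.grid.start,
                "end": self.grid.end,
                "gain_frac": self.gain_frac,
                "loss_frac": self.loss_frac,
            }
        )


def frequency_tracks(
    profiles: Sequence[SegmentedProfile], grid: BinGrid
) -> FrequencyTrack:
    """Fraction of samples gained / lost per bin across labelled profiles."""
    if not profiles:
        raise ValueError("empty cohort")
    gain = np.zeros(len(grid))
    loss = np.zeros(len(grid))
    mid = (grid.start + grid.end) / 2.0
    chroms = grid.chrom
    for prof in profiles:
        df = prof.segments
        if "label" not in df.columns:
            raise ValueError(f"{prof.sample_id}: segments unlabelled")
        for _, seg in df.iterrows():
            if seg["label"] not in (GAIN, LOSS):
                continue
            sel = (chroms == seg["chrom"]) & (mid >= seg["start"]) & (mid < seg["end"])
            if seg["label"] == GAIN:
                gain[sel] += 1
            else:
                loss[sel] += 1
    n = len(profiles)
    return FrequencyTrack(
        grid=grid, gain_frac=gain / n, loss_frac=loss / n, n_samples=n
    )


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    labels: tuple[str, str] = ("x", "y"),
) -> GroupComparison:
    """Two-sided Mann-Whitney U test.

    Exact enumeration of the U distribution for combined n <= 12 without
    ties; normal approximation with tie correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    no_ties = len(np.unique(combined)) == len(combined)
    exact = no_ties and len(combined) <= EXACT_MW_MAX_N
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return GroupComparison(
        test="mann-whitney-u",
        groups=labels,
        n=(len(x), len(y)),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method=method,
    )


def fisher_exact_2x2(
    table: Sequence[Sequence[int]], labels: tuple[str, str] = ("rows", "cols")
) -> GroupComparison:
    """Two-sided Fisher exact test on a 2x2 table.

    The two-sided p sums hypergeometric probabilities of all tables with the
    observed margins that are no more likely than the observed one.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 integer table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin: test undefined")
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return GroupComparison(
        test="fisher-exact",
        groups=labels,
        n=(int(t[0].sum()), int(t[1].sum())),
        statistic=float(odds),
        p_value=float(p),
        method="exact",
    )


def share_pct(k: int, n: int) -> float:
    """Percentage k/n, the unit used for cohort frequency statements."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    return 100.0 * k / n


def _fusion_deletion_patients(
    events: pd.DataFrame, sample_to_patient: dict[str, str]
) -> set[str]:
    chrom, rs, re_ = TMPRSS2_ERG_REGION
    dels = events[
        (events["class"] == "deletion")
        & (events["chrom"] == chrom)
        & (events["start"] < re_)
        & (events["end"] > rs)
    ]
    return {sample_to_patient[s] for s in dels["sample"]}


def cohort_report(
    events: pd.DataFrame,
    fractions: pd.DataFrame | None = None,
    metadata: pd.DataFrame | None = None,
    group_col: str | None = None,
) -> dict:
    """Cohort report: focal counts per group, altered fractions, driver table.

    ``events`` is a focal-event table (columns as written by the focal
    caller).  ``fractions`` optionally carries per-sample altered-fraction
    summaries; ``metadata`` maps samples to patients and grouping variables
    (columns: sample, patient, and any group columns).  The driver table
    counts, per patient over all their samples, TMPRSS2:ERG-type fusion
    deletions, driver focal deletions and driver focal amplifications.
    """
    report: dict = {}
    if len(events) == 0:
        report["n_events"] = 0
        report["focal_counts"] = pd.DataFrame()
        return report
    report["n_events"] = int(len(events))

    if metadata is not None:
        unmatched = sorted(set(events["sample"]) - set(metadata["sample"]))
        if unmatched:
            raise ValueError(f"samples missing from metadata: {unmatched}")
        sample_to_patient = dict(zip(metadata["sample"], metadata["patient"]))
        patients = sorted(set(metadata["patient"]))
        n_patients = len(patients)

        amp_driver = events[(events["class"] == "amplification") & events["has_driver"]]
        del_driver = events[(events["class"] == "deletion") & events["has_driver"]]
        fusion_pat = _fusion_deletion_patients(events, sample_to_patient)
        amp_pat = {sample_to_patient[s] for s in amp_driver["sample"]}
        del_pat = {sample_to_patient[s] for s in del_driver["sample"]}
        any_pat = fusion_pat | amp_pat | del_pat
        report["driver_table"] = pd.DataFrame(
            {
                "aberration": [
                    "fusion_deletion",
                    "driver_focal_deletion",
                    "driver_amplification",
                    "any_driver",
                ],
                "n_patients": [
                    len(fusion_pat),
                    len(del_pat),
                    len(amp_pat),
                    len(any_pat),
                ],
                "pct_patients": [
                    share_pct(len(fusion_pat), n_patients),
                    share_pct(len(del_pat), n_patients),
                    share_pct(len(amp_pat), n_patients),
                    share_pct(len(any_pat), n_patients),
                ],
            }
        )

        if group_col is not None:
            per_sample = events.groupby("sample").size()
            counts = metadata.set_index("sample").join(
                per_sample.rename("n_focal"), how="left"
            )
            counts["n_focal"] = counts["n_focal"].fillna(0)
            report["focal_counts"] = (
                counts.groupby(group_col)["n_focal"]
                .describe()[["count", "mean", "25%", "50%", "75%"]]
                .rename(columns={"25%": "q1", "50%": "median", "75%": "q3"})
            )

    if fractions is not None:
        report["altered_fractions"] = fractions.describe()

    return report
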