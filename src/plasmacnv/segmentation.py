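"""Circular binary segmentation of per-bin log2 profiles.

Each chromosome is partitioned recursively: the pair of cut points
maximizing the two-sample t statistic between the enclosed arc and the rest
of the segment (arcs may wrap, hence "circular") is accepted when its
permutation p-value falls below ``alpha``, and the search recurses into the
resulting sub-segments.  Adjacent segments whose means differ by less than a
merge tolerance are re-merged at the end.

The max-t scan and the permutation test are compiled with numba; the
permutation loop stops early once the outcome is decided (exceedances
already guarantee p > alpha, or zero exceedances after ceil(1/alpha)
permutations guarantee p < alpha), which keeps the test exact in level while
avoiding the full permutation budget on clear-cut segments.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from numba import njit

from .profiles import BinGrid, BinnedProfile

__all__ = ["SegmentedProfile", "segment_profile", "segment_values"]


@njit(cache=True)
def _max_arc(S, n, min_w):
    """Max arc t statistic over prefix sums S of mean-centred values.

    t(i, j) = |S_j - S_i| * sqrt(n / (L * (n - L))) with L = j - i; the arc
    [i, j) is tested against its (possibly wrapped) complement.  Returns
    (t_max, i, j); the split cuts before bin i and before bin j.
    """
    best = -1.0
    bi = 0
    bj = 0
    smin = S[0]
    smax = S[0]
    for k in range(1, n + 1):
        if S[k] < smin:
            smin = S[k]
        if S[k] > smax:
            smax = S[k]
    srange = smax - smin  # |S_j - S_i| can never exceed this
    for L in range(min_w, n - min_w + 1):
        w = np.sqrt(n / (L * (n - L)))
        if srange * w <= best:
            continue
        for i in range(0, n - L + 1):
            d = S[i + L] - S[i]
            if d < 0.0:
                d = -d
            t = d * w
            if t > best:
                best = t
                bi = i
                bj = i + L
    return best, bi, bj


@njit(cache=True)
def _arc_exceeds(S, n, min_w, thresh):
    """True as soon as some arc's t statistic reaches ``thresh``."""
    smin = S[0]
    smax = S[0]
    for k in range(1, n + 1):
        if S[k] < smin:
            smin = S[k]
        if S[k] > smax:
            smax = S[k]
    srange = smax - smin
    for L in range(min_w, n - min_w + 1):
        w = np.sqrt(n / (L * (n - L)))
        lim = thresh / w
        if srange < lim:
            continue
        for i in range(0, n - L + 1):
            d = S[i + L] - S[i]
            if d < 0.0:
                d = -d
            if d >= lim:
                return True
    return False


@njit(cache=True)
def _perm_pvalue(xc, obs_t, min_w, n_perm, alpha, seed):
    """Permutation p-value of the observed max arc statistic.

    Early stop: once exceedances c satisfy (c + 1) / (n_perm + 1) > alpha
    the split can never be accepted; once c == 0 after ceil(3/alpha)
    permutations the upper confidence bound on p is below alpha, so the
    split is accepted (the factor 3 keeps the extra type-I probability of
    the early accept near exp(-3) at p = alpha, preserving the test level).
    """
    np.random.seed(seed)
    n = xc.shape[0]
    c_reject = int(alpha * (n_perm + 1))  # c > c_reject - 1  =>  p > alpha
    m_accept = int(np.ceil(3.0 / alpha))
    c = 0
    m = 0
    x = xc.copy()
    S = np.empty(n + 1)
    while m < n_perm:
        np.random.shuffle(x)
        S[0] = 0.0
        for k in range(n):
            S[k + 1] = S[k] + x[k]
        if _arc_exceeds(S, n, min_w, obs_t):
            c += 1
        m += 1
        if c >= c_reject:
            return (c + 1.0) / (m + 1.0)
        if c == 0 and m >= m_accept:
            return 1.0 / (m + 1.0)
    return (c + 1.0) / (n_perm + 1.0)


def _segment_array(
    x: np.ndarray,
    alpha: float,
    min_width: int,
    n_perm: int,
    rng: np.random.Generator,
) -> list[int]:
    """Recursive CBS on one chromosome's unmasked values.

    Returns interior breakpoint indices (a breakpoint at k separates bins
    k-1 and k).
    """
    n = len(x)
    breaks: list[int] = []
    stack = [(0, n)]
    while stack:
        lo, hi = stack.pop()
        m = hi - lo
        if m < 2 * min_width:
            continue
        seg = x[lo:hi]
        xc = seg - seg.mean()
        if np.all(np.abs(xc) < 1e-15):
            continue
        S = np.concatenate([[0.0], np.cumsum(xc)])
        t, i, j = _max_arc(S, m, min_width)
        if t <= 0:
            continue
        seed = int(rng.integers(1, 2**31 - 1))
        p = _perm_pvalue(xc, t, min_width, n_perm, alpha, seed)
        if p < alpha:
            cuts = [k for k in (i, j) if 0 < k < m]
            if not cuts:
                continue
            pieces = [lo] + [lo + k for k in cuts] + [hi]
            breaks.extend(pieces[1:-1])
            for a, b in zip(pieces[:-1], pieces[1:]):
                stack.append((a, b))
    return sorted(breaks)


def _merge_segments(
    x: np.ndarray, boundaries: list[int], merge_tol: float
) -> list[int]:
    """Re-merge adjacent segments whose means differ by < merge_tol.

    Closest pair first, iterated to a fixed point.
    """
    bounds = list(boundaries)
    while len(bounds) > 2:
        means = [x[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])]
        diffs = [abs(means[k + 1] - means[k]) for k in range(len(means) - 1)]
        k = int(np.argmin(diffs))
        if diffs[k] >= merge_tol:
            break
        del bounds[k + 1]
    return bounds


@dataclass
class SegmentedProfile:
    """Ordered copy-number segments for one sample.

    ``segments`` columns: chrom, start, end, n_bins, bp, mean_log2 and
    (after state calling) label.  ``bp`` is the cumulative unmasked genomic
    span of the member bins; for externally supplied segment tables it
    defaults to end - start.
    """

    sample_id: str
    segments: pd.DataFrame
    grid: BinGrid | None = None

    def __len__(self) -> int:
        return len(self.segments)

    @classmethod
    def from_table(
        cls, segments: pd.DataFrame, sample_id: str = "sample"
    ) -> "SegmentedProfile":
        df = segments.copy()
        required = {"chrom", "start", "end", "mean_log2"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"segment table missing columns: {sorted(missing)}")
        if "n_bins" not in df.columns:
            df["n_bins"] = 1
        if "bp" not in df.columns:
            df["bp"] = df["end"] - df["start"]
        return cls(sample_id=sample_id, segments=df.reset_index(drop=True))

    def bin_values(self, grid: BinGrid) -> np.ndarray:
        """Per-bin expansion of segment means (NaN where no segment covers).

        Assignment is by coordinate midpoint, so it works identically for
        internally segmented and externally loaded tables.
        """
        out = np.full(len(grid), np.nan)
        mid = (grid.start + grid.end) / 2.0
        chroms = grid.chrom
        for _, seg in self.segments.iterrows():
            sel = (chroms == seg["chrom"]) & (mid >= seg["start"]) & (mid < seg["end"])
            out[sel] = seg["mean_log2"]
        return out


def segment_profile(
    profile: BinnedProfile,
    alpha: float = 0.01,
    min_width: int = 3,
    n_perm: int = 1000,
    merge_tol: float = 0.05,
    seed: int = 0,
) -> SegmentedProfile:
    """Segment a log2 profile chromosome by chromosome.

    Masked bins contribute no values; a segment may bridge them in genomic
    span but its ``bp`` counts member-bin spans only.  Deterministic for a
    fixed seed.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if profile.log2 is None:
        raise ValueError("profile has no log2 values; run normalization first")
    rng = np.random.default_rng(seed)
    grid = profile.grid
    rows = []
    for chrom, sl in grid.chrom_slices():
        keep = ~profile.mask[sl] & np.isfinite(profile.log2[sl])
        idx = np.flatnonzero(keep) + sl.start
        x = profile.log2[idx]
        if len(x) == 0:
            continue
        if len(x) < min_width:
            warnings.warn(
                f"{chrom}: fewer than min_width={min_width} unmasked bins; "
                "emitting a single segment"
            )
            bounds = [0, len(x)]
        else:
            breaks = _segment_array(x, alpha, min_width, n_perm, rng)
            bounds = _merge_segments(x, [0] + breaks + [len(x)], merge_tol)
        starts = grid.start
        ends = grid.end
        spans = grid.span
        for a, b in zip(bounds[:-1], bounds[1:]):
            members = idx[a:b]
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(starts[members[0]]),
                    "end": int(ends[members[-1]]),
                    "n_bins": int(b - a),
                    "bp": int(spans[members].sum()),
                    "mean_log2": float(x[a:b].mean()),
                }
            )
    segments = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_bins", "bp", "mean_log2"]
    )
    return SegmentedProfile(
        sample_id=profile.sample_id, segments=segments, grid=grid
    )


def segment_values(profile: BinnedProfile, segmented: SegmentedProfile) -> np.ndarray:
    """Per-bin segmented log2 values on the profile's grid (NaN on masked bins)."""
    vals = segmented.bin_values(profile.grid)
    vals[profile.mask] = np.nan
    return vals
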