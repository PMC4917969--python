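"""Serial plasma-sample comparison and profile clustering.

Two samples from the same patient are compared on their per-bin segmented
log2 values.  A pair is eligible when the Spearman correlation of the two
profiles exceeds 0.85 (high tumour-content variability otherwise biases the
comparison).  Because the ctDNA fraction varies between draws, a tumour
content ratio r is fitted by grid search over 0..10 in steps of 0.01,
minimizing the sum of squared differences between r times the earlier
profile and the later one; bins where the adjusted difference
``d = s_B - r * s_A`` exceeds 0.2 in magnitude are flagged and merged into
directional differential regions.

Profiles are clustered with Manhattan distances and average linkage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist

from .profiles import BinGrid

__all__ = [
    "SerialConfig",
    "SerialComparison",
    "profile_spearman",
    "fit_tumor_ratio",
    "differential_regions",
    "compare_serial",
    "cluster_profiles",
    "linkage_to_newick",
    "tissue_plasma_pearson",
]


@dataclass(frozen=True)
class SerialConfig:
    min_rho: float = 0.85
    ratio_min: float = 0.0
    ratio_max: float = 10.0
    ratio_step: float = 0.01
    diff_threshold: float = 0.2
    min_run_bins: int = 5  # 1 reproduces the literal bin-wise rule

    def __post_init__(self) -> None:
        if not 0.0 < self.min_rho < 1.0:
            raise ValueError("eligibility rho must lie in (0, 1)")
        if self.ratio_step <= 0:
            raise ValueError("ratio grid step must be > 0")
        if self.diff_threshold <= 0:
            raise ValueError("differential threshold must be > 0")


@dataclass
class SerialComparison:
    sample_a: str
    sample_b: str
    rho: float
    eligible: bool
    ratio: float | None = None
    analytic_slope: float | None = None
    regions: pd.DataFrame | None = None
    pct_differential: float | None = None
    skipped_reason: str | None = None


def _shared_finite(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles are not on the same grid")
    return np.isfinite(a) & np.isfinite(b)


def profile_spearman(a: np.ndarray, b: np.ndarray, min_bins: int = 10) -> float:
    """Spearman rank correlation over shared unmasked bins."""
    keep = _shared_finite(a, b)
    if keep.sum() < min_bins:
        raise ValueError(f"need >= {min_bins} shared unmasked bins")
    x, y = np.asarray(a)[keep], np.asarray(b)[keep]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant profile: Spearman correlation undefined")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


def fit_tumor_ratio(
    a: np.ndarray, b: np.ndarray, config: SerialConfig | None = None
) -> tuple[float, float]:
    """Grid-search tumour content ratio between two segmented profiles.

    Returns ``(r, slope)``: r minimizes ``sum((r*a - b)**2)`` over the grid
    (ties toward smaller r) and ``slope`` is the closed-form least-squares
    slope through the origin, reported for audit.
    """
    config = config or SerialConfig()
    keep = _shared_finite(a, b)
    x, y = np.asarray(a, dtype=float)[keep], np.asarray(b, dtype=float)[keep]
    sxx = float(np.dot(x, x))
    if sxx == 0.0:
        raise ValueError("first profile is all zero: ratio unidentifiable")
    sxy = float(np.dot(x, y))
    syy = float(np.dot(y, y))
    n_steps = int(round((config.ratio_max - config.ratio_min) / config.ratio_step))
    grid = config.ratio_min + config.ratio_step * np.arange(n_steps + 1)
    sse = grid**2 * sxx - 2.0 * grid * sxy + syy
    r = float(grid[int(np.argmin(sse))])
    return r, sxy / sxx


def differential_regions(
    grid: BinGrid,
    a: np.ndarray,
    b: np.ndarray,
    ratio: float,
    config: SerialConfig | None = None,
) -> tuple[pd.DataFrame, float]:
    """Directional regions where the adjusted difference exceeds the threshold.

    ``d = s_B - r * s_A`` per bin; runs of consecutive same-direction flagged
    bins within a chromosome shorter than ``min_run_bins`` are dropped.
    Returns the regions and the percent of unmasked autosomal bp flagged.
    """
    config = config or SerialConfig()
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(grid) or len(b) != len(grid):
        raise ValueError("profiles are not on the grid")
    d = b - ratio * a
    keep = np.isfinite(d)
    direction = np.zeros(len(d), dtype=int)
    direction[keep & (d > config.diff_threshold)] = 1
    direction[keep & (d < -config.diff_threshold)] = -1

    rows = []
    spans = grid.span
    starts = grid.start
    ends = grid.end
    flagged_bins = np.zeros(len(d), dtype=bool)
    for chrom, sl in grid.chrom_slices():
        dirs = direction[sl]
        i = 0
        n = sl.stop - sl.start
        while i < n:
            if dirs[i] == 0:
                i += 1
                continue
            j = i
            while j < n and dirs[j] == dirs[i]:
                j += 1
            if j - i >= config.min_run_bins:
                lo, hi = sl.start + i, sl.start + j
                flagged_bins[lo:hi] = True
                rows.append(
                    {
                        "chrom": chrom,
                        "start": int(starts[lo]),
                        "end": int(ends[hi - 1]),
                        "direction": "gain" if dirs[i] > 0 else "loss",
                        "n_bins": int(j - i),
                        "mean_delta": float(np.nanmean(d[lo:hi])),
                    }
                )
            i = j
    regions = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "direction", "n_bins", "mean_delta"]
    )
    auto = grid.autosomal() & keep
    denom = float(spans[auto].sum())
    pct = 100.0 * float(spans[auto & flagged_bins].sum()) / denom if denom else 0.0
    return regions, pct


def compare_serial(
    grid: BinGrid,
    a: np.ndarray,
    b: np.ndarray,
    sample_a: str = "A",
    sample_b: str = "B",
    config: SerialConfig | None = None,
    force: bool = False,
) -> SerialComparison:
    """Full serial comparison: eligibility gate, ratio fit, differential regions."""
    config = config or SerialConfig()
    rho = profile_spearman(a, b)
    eligible = rho > config.min_rho
    if not eligible and not force:
        return SerialComparison(
            sample_a=sample_a,
            sample_b=sample_b,
            rho=rho,
            eligible=False,
            skipped_reason="low correlation",
        )
    r, slope = fit_tumor_ratio(a, b, config)
    regions, pct = differential_regions(grid, a, b, r, config)
    return SerialComparison(
        sample_a=sample_a,
        sample_b=sample_b,
        rho=rho,
        eligible=eligible,
        ratio=r,
        analytic_slope=slope,
        regions=regions,
        pct_differential=pct,
    )


def cluster_profiles(profiles: np.ndarray, labels: list[str] | None = None):
    """Average-linkage clustering of profiles on Manhattan distances.

    ``profiles`` is samples x bins; bins with a missing value in any sample
    are dropped so every pairwise distance uses the same bins.  Returns the
    scipy linkage matrix.
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2 or profiles.shape[0] < 2:
        raise ValueError("need >= 2 profiles on a shared grid")
    keep = np.isfinite(profiles).all(axis=0)
    if not keep.any():
        raise ValueError("no shared unmasked bins")
    dists = pdist(profiles[:, keep], metric="cityblock")
    return linkage(dists, method="average")


def linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a newick string with branch lengths."""
    tree = to_tree(link)

    def render(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left = render(node.left)
        right = render(node.right)
        bl_l = node.dist - node.left.dist
        bl_r = node.dist - node.right.dist
        return f"({left}:{bl_l:g},{right}:{bl_r:g})"

    return render(tree) + ";"


def tissue_plasma_pearson(grid: BinGrid, a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two profiles over autosomal unmasked bins only.

    Sex chromosomes are excluded: tissue controls may mix sexes, which
    biases their sex-chromosome baselines.
    """
    keep = _shared_finite(a, b) & grid.autosomal()
    if keep.sum() < 2:
        raise ValueError("too few shared autosomal bins")
    x, y = np.asarray(a)[keep], np.asarray(b)[keep]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant profile: Pearson correlation undefined")
    r, _ = stats.pearsonr(x, y)
    return float(r)
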