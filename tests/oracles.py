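"""Independent brute-force oracles the implementation is checked against.

Everything here is written as plainly as possible -- nested loops, explicit
enumeration, per-bp counting -- and shares no code with the package beyond
its public data structures.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import hypergeom


# -- Mann-Whitney by exhaustive enumeration --------------------------------

def mann_whitney_enumerated(x, y):
    """Two-sided exact p by enumerating every assignment of labels."""
    x = list(x)
    y = list(y)
    pooled = x + y
    nx = len(x)

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b) + 0.5 * sum(
            1 for a in xs for b in ys if a == b
        )

    u_obs = u_stat(x, y)
    us = []
    for idx in combinations(range(len(pooled)), nx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(u_stat(xs, ys))
    us = np.asarray(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge))


# -- Fisher exact by enumerating tables with fixed margins -----------------

def fisher_enumerated(table):
    """Two-sided p: sum of hypergeometric probabilities <= that of the table."""
    a, b = table[0]
    c, d = table[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    p_obs = hypergeom.pmf(a, n, r1, c1)
    total = 0.0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        p_k = hypergeom.pmf(k, n, r1, c1)
        if p_k <= p_obs * (1 + 1e-9):
            total += p_k
    return min(1.0, total)


# -- focal criteria, rule by rule ------------------------------------------

def focal_check_brute(
    segments: pd.DataFrame,
    target_row: int,
    genes: pd.DataFrame,
    drivers: set,
    deletion_genes: set,
    segdup: pd.DataFrame,
    germline: pd.DataFrame,
    kind: str,
    max_size=20e6,
    base=0.2,
    flank_bp=20e6,
    driver_delta=0.2,
    nondriver_delta=0.58,
    max_genes=100,
    segdup_frac=0.5,
    germline_frac=0.5,
):
    """Accept/reject one segment by walking every rule with dumb loops."""
    seg = segments.iloc[target_row]
    span = seg["end"] - seg["start"]
    if span >= max_size:
        return False
    if kind == "amplification" and not seg["mean_log2"] > base:
        return False
    if kind == "deletion" and not seg["mean_log2"] < -base:
        return False

    contained = []
    for _, g in genes.iterrows():
        if g["chrom"] == seg["chrom"] and g["start"] < seg["end"] and g["end"] > seg["start"]:
            contained.append(g["name"])
    if kind == "amplification" and len(contained) < 1:
        return False
    if kind == "deletion" and not any(n in deletion_genes for n in contained):
        return False
    if len(contained) > max_genes:
        return False

    # flank weighted mean by explicit per-segment overlap accumulation
    wsum = vsum = 0.0
    for win in [(seg["start"] - flank_bp, seg["start"]), (seg["end"], seg["end"] + flank_bp)]:
        for i, other in segments.iterrows():
            if i == target_row or other["chrom"] != seg["chrom"]:
                continue
            ov = min(other["end"], win[1]) - max(other["start"], win[0])
            if ov > 0:
                wsum += ov
                vsum += ov * other["mean_log2"]
    flank = vsum / wsum if wsum > 0 else 0.0
    delta = seg["mean_log2"] - flank
    if kind == "amplification":
        has_driver = any(n in drivers for n in contained)
        need = driver_delta if has_driver else nondriver_delta
        if not delta > need:
            return False
    else:
        if not delta < -driver_delta:
            return False

    def union_cov(track):
        positions = set()
        for _, t in track.iterrows():
            if t["chrom"] != seg["chrom"]:
                continue
            lo = max(int(t["start"]), int(seg["start"]))
            hi = min(int(t["end"]), int(seg["end"]))
            # coarse per-kb coverage walk keeps the loop honest but bounded
            step = 1000
            for p in range(lo, hi, step):
                positions.add(p // step)
        return len(positions) * 1000

    if union_cov(segdup) / span > segdup_frac:
        return False
    if union_cov(germline) / span >= germline_frac:
        return False
    return True


# -- max-t breakpoint search, exhaustively ---------------------------------

def max_arc_t_brute(x, min_width):
    """Best circular-arc split of x by trying every (i, j) pair."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    xc = x - x.mean()
    S = np.concatenate([[0.0], np.cumsum(xc)])
    best = (-1.0, 0, 0)
    for i in range(n + 1):
        for j in range(i + 1, n + 1):
            L = j - i
            if L < min_width or n - L < min_width:
                continue
            t = abs(S[j] - S[i]) * np.sqrt(n / (L * (n - L)))
            if t > best[0]:
                best = (t, i, j)
    return best


# -- per-bp flank mean ------------------------------------------------------

def flank_mean_per_bp(segments: pd.DataFrame, target_row: int, window=20e6):
    """Flank mean by brute-force accumulation over 1-kb positions."""
    seg = segments.iloc[target_row]
    total = 0.0
    weight = 0
    step = 1000
    for win_lo, win_hi in [
        (seg["start"] - window, seg["start"]),
        (seg["end"], seg["end"] + window),
    ]:
        for i, other in segments.iterrows():
            if i == target_row or other["chrom"] != seg["chrom"]:
                continue
            lo = max(int(other["start"]), int(win_lo))
            hi = min(int(other["end"]), int(win_hi))
            for _ in range(lo, hi, step):
                total += other["mean_log2"] * step
                weight += step
    return total / weight if weight else 0.0
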