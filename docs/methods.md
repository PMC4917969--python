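# Methods

## The measurement model

Plasma cell-free DNA is a mixture of normal DNA (germline copy number
*b* = 2 on autosomes, 1 on the male X and Y) and tumour DNA at absolute
copy number *c* over altered regions, with tumour fraction *f*.  Relative
coverage over a region is `(b(1−f) + cf)/b`, and its base-2 logarithm is
the quantity every stage of the pipeline works with.  Two consequences
shape the design: amplitudes attenuate linearly in *f* for small effects,
so shallow sequencing detects high-level amplifications at much lower
tumour fractions than single-copy losses; and total-count normalization
measures every bin against the sample's overall DNA mass, so genome-wide
gains depress the apparent baseline slightly (profiles are interpreted
relative to their median, which is the copy-neutral level in practice).

## Synthetic data: what it emulates and what it does not

The generator reproduces the measurement process on a male hg19 genome
(X/Y at one copy, Y pseudo-autosomal regions masked): ~50,000
equal-mappability bins, mean 120 reads per autosomal bin (~0.1×), a smooth
unimodal GC-bias curve `max(0.05, 1 − κ(GC − 0.45)²)` applied to expected
counts, and Poisson sampling (negative-binomial with a dispersion
parameter is available).  The GC landscape is a smoothed Gaussian field
(mean 0.42, SD 0.05, ~40-bin correlation length), fixed per grid so
samples, controls and dilutions share it.  Defaults: κ = 16 gives a raw
count–GC Spearman correlation of ~0.38 on null samples, the strength we
consider representative of real sWGS libraries; per-level seeds in series
are derived as `seed + index` so series are reproducible yet independent.

Not emulated: fragment-length biology, mappability artefacts, germline
CNVs, duplicate reads, batch effects between samples, and the pervasive
low-amplitude autocorrelated waviness of real cfDNA coverage.  The last
omission matters: real non-tumour plasma profiles carry ~0.1–0.5% of the
genome beyond the calling thresholds, whereas clean Poisson nulls carry
almost none.  Tests passing on synthetic data therefore demonstrate the
correctness of the algorithms under the stated noise model, not the
end-to-end false-positive behaviour on real libraries (see Limitations).

## GC correction

Counts are divided by the sample total and the count-versus-GC trend is
divided out, fitted on unmasked autosomal bins only (the male X would
drag the fit down; it is corrected by evaluation, then re-levelled by the
control panel).  The trend estimate is two-stage: a quadratic backbone
iterated to a fixed point (three degrees of freedom, so almost no
estimation noise is imprinted on the data), then a single robust LOESS
pass (span 0.5, two robustness iterations, statsmodels `lowess` with a
small `delta`) for non-quadratic structure.  A single wide-span linear
LOESS cannot flatten a strongly curved bias — its residual decays only
harmonically under iteration — which is why the backbone exists.  The fit
support is trimmed to the central [0.5%, 99.5%] GC quantiles; bins outside
it are masked, as local fits are unstable where GC values are sparse.
Robustness matters because large copy-number events contaminate the fit;
the bisquare weighting suppresses them.  The correction is idempotent to
well below 1e-3 relative RMS (verified at high simulated coverage, where
the check is not drowned by the smoother's Poisson-noise imprint).

Control-panel normalization divides the corrected values by the per-bin
mean of ≥ 2 (by default 10) non-tumour controls processed identically;
bins whose panel mean falls below 10% of the genome median are masked.
For tumour tissue the same operation runs against a constitutional-DNA
panel — a configuration change, not code.

## Segmentation

Circular binary segmentation, implemented natively.  Within a chromosome
the statistic for cut points (i, j) is `|S_j − S_i|·sqrt(n/(L(n−L)))` on
mean-centred prefix sums — the two-sample t statistic up to the common
scale factor, which cancels in the permutation comparison.  The maximizing
arc is accepted when its permutation p-value (1,000 shuffles) is below
α = 0.01, and the search recurses into the three resulting pieces;
adjacent segments with means closer than 0.05 are re-merged afterwards
(closest pair first).  Minimum arc width is 3 bins.  Numerical choices:
the O(n²) scan is numba-compiled and prunes arc lengths whose best
possible score (prefix-sum range × length weight) cannot beat the current
best; the permutation loop stops early once the exceedance count already
forces p > α, or accepts once zero exceedances persist for ⌈3/α⌉ shuffles
(the upper confidence bound on p is then below α; the factor 3 keeps the
extra acceptance probability near e⁻³ at the boundary, so the realized
test level stays ≈ 1.3% at α = 1%).  Everything is deterministic under a
fixed seed.  A profile segmented to a constant reconstructs exactly:
the bin-weighted mean of segment means equals the mean of the input.

## Calling and the aberrance classifier

Segments are labelled gained above +0.2 and lost below −0.2, strict
inequalities (the focal criteria are phrased as strict; ties at the
threshold stay balanced).  Cumulative gained/lost lengths are measured in
unmasked genomic bp of the member bins.  A sample is copy-number aberrant
when either cumulative length exceeds the control mean by more than
3 SD — one-sided, per the rule's "higher than" phrasing.

## Focal events

Candidates are segments as emitted by the segmenter (no sub-segment
refitting).  Gene containment means ≥ 1 bp overlap with a gene body.
Flank context is the length-weighted mean of segment log2 values over the
20 Mb on each side, truncated at chromosome ends; an empty side simply
contributes no weight.  The germline-CNV filter disqualifies a segment
when known variant entries cover ≥ 50% of it (mirroring the
segmental-duplication rule; a literal any-overlap rule would disqualify
essentially every segment given how much of the genome known germline
CNVs touch).  Every candidate beyond the base ±0.2 threshold that is not
emitted records the first rule it failed.  The packaged driver list
contains 30 recurrently amplified cancer genes and the deletion list 42
recurrently deleted genes; the gene-coordinate track shipped for
simulations covers a small set of well-known loci with approximate hg19
coordinates and is not a production annotation — callers accept arbitrary
BED tracks.

## Serial analysis

Comparisons run on per-bin expansions of segment means, so bins weight
segments implicitly.  Pairs must correlate (Spearman > 0.85) to be
compared — at low shared structure the ratio fit is meaningless.  The
tumour-content ratio r minimizes Σ(r·s_A − s_B)² over the grid 0–10 in
0.01 steps, ties toward smaller r; the closed-form slope Σs_As_B/Σs_A² is
reported alongside, and the grid point chosen is always the one nearest
the clamped slope.  Scaling acts on log2 values (an approximation for
tumour-content variation that is exact in the small-amplitude limit), and
the earlier sample is scaled: d = s_B − r·s_A.  Bins with |d| > 0.2 merge
into directional runs; runs shorter than 5 bins are dropped by default
(1 reproduces the literal bin-wise rule).  The flagged fraction is
reported over unmasked autosomal bp.  Fitting on segmented rather than
raw bin values is essential: raw-bin fits suffer errors-in-variables
attenuation (at ~0.1× the per-bin noise SD ≈ 0.14 rivals the signal),
whereas segment means average it away.  Clustering uses Manhattan
distances and average linkage on the shared unmasked bins; ties follow
scipy's deterministic ordering.  Plasma–tissue correlations are Pearson,
autosomes only, since mixed-sex tissue controls bias sex-chromosome
baselines.

## Cohort statistics

Two-sided tests throughout, no multiple-testing correction.  Mann–Whitney
U is computed by exact enumeration for combined n ≤ 12 without ties and
by the tie-corrected normal approximation otherwise; Fisher's exact
two-sided p sums hypergeometric probabilities no larger than the observed
table's.  Both are delegated to scipy and verified against exhaustive
enumeration in the test suite.  TMPRSS2:ERG fusion status is inferred
from a focal deletion overlapping the chr21 interval between the two gene
bodies.  Driver-aberration frequency counts, per patient over all their
samples, fusion deletions, driver focal deletions and driver focal
amplifications.

## Problem sizes used in the tests

The dilution experiment runs at full production scale (50,000 bins, 25
replicates at each of 20/10/5/1% tumour fraction, one shared 10-control
panel).  Properties that only need the per-stage behaviour run on a
four-chromosome 180-Mb genome with 3,600 bins at the same per-bin depth.
The classifier-specificity property keeps all 23 relevant chromosomes (the
number of independent segmentation tests drives the spurious-call rate)
at 11,500 bins, again at production depth.

## Known limitations

- The aberrance classifier's false-positive rate on *clean Poisson* null
  simulations is ~5–8%, not the ~2% a Gaussian reading of the 3-SD rule
  suggests.  Under the clean noise model, control cumulative altered
  lengths are zero-inflated with heavy-tailed exceptions (every accepted
  spurious CBS arc shorter than ~11 bins necessarily exceeds |0.2|), and
  mean + 3·SD is a poor quantile estimate for such a distribution.  Real
  control profiles, with their continuous Mb-scale background of apparent
  alteration, match the rule's assumptions better.  The corresponding
  acceptance test is left failing deliberately rather than tuning the
  generator or the classifier to pass.
- CBS is the sole segmenter; no consensus with a second gain/loss
  analysis, and no HMM or wavelet alternative.
- No read-level simulation, fragmentomics or mutation calling; bin counts
  are the unit of everything.
- The ratio grid search caps r at 10; serial pairs with a more extreme
  tumour-content swing saturate at the boundary.
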