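# Methods

## The measurement problem

Meiotic recombination starts with DNA double-strand breaks (DSBs) made by
SPO11 at hotspots. The 5′ strands at each break are nucleolytically degraded
(resected), exposing 3′ ssDNA tails. End-sequencing assays (S1-seq,
Exo7/T-seq, END-seq) blunt the ssDNA/dsDNA junction and sequence from a
ligated adapter, so each read marks one resection endpoint: top-strand reads
mark rightward-moving tracts, bottom-strand reads leftward ones. Unresected
DSBs produce reads at the cut sites themselves, and recombination
intermediates (RIs, e.g. D-loops) produce a "central" signal near hotspot
centers. `resectseq` turns such strand-specific endpoint maps into the
standard genome-average statistics of resection, and ships a mechanistic
simulator so that every estimator can be validated by parameter recovery.

## Analysis pipeline

All constants live in `AnalysisConfig`, in bp, and are logged on every run:

| parameter | default | meaning |
|---|---|---|
| `half_width` | 3000 | window around each hotspot center, offsets −W..+W |
| `smooth_plot` | 151 | Hann window for plotted/modal profiles |
| `smooth_central` | 51 | Hann window for the near-center strand profiles |
| `background_offset` / `background_half_width` | 2500 / 75 | background estimate location |
| `resection_window` | (100, 2500) | resection-endpoint statistics window |
| `central_window` | (−300, 100) | RI (central-peak) window |
| `length_bin` | 100 | bin size for the mean-length estimator |
| `heatmap_bin` / `heatmap_window` | 40 / 4001 | heatmap binning |
| `area_window` | (−1000, 2500) | area normalization for coverage profiles |

Pipeline order: raw counts → RPM (both strands scaled by the same
library-wide total) → per-hotspot windows → co-orientation (bottom-strand
offsets mirrored about the center so left and right tracts superimpose) →
unweighted mean over all 2N strand-rows → background subtraction →
statistics.

**Background.** The estimate is the mean over a 151-bp window centered at
+2500 bp rather than the single +2500 value: endpoint maps are sparse at
single-bp resolution and the windowed mean matches the point value in
expectation while being far less noisy. Negative values after subtraction
are set to zero. Background is subtracted from the *unsmoothed* profile;
smoothing afterwards is the default order (the alternative order is one
config change away).

**Mean resection length.** Signal at offsets <100 bp or >2500 bp is zeroed;
the remaining [100, 2500) range is split into 24 bins of 100 bp; the
estimate is Σ fᵢ·mᵢ with fᵢ the bin's fraction of windowed signal and mᵢ its
midpoint (150, 250, …, 2450 nt). Midpoints, not left edges, represent the
bins — using left edges would shift every mean by −50 nt. The estimator is
scale-invariant and, because the within-hotspot cut-position spread is
symmetric around the center, recovers the simulator's true mean tract length
with <5 nt bias at the default study conditions.

**Modal resection length.** Argmax of the 151-bp-Hann-smoothed profile over
[100, 2500], ties toward the smaller offset. The mode is defined on the
smoothed profile (it is the peak of the plotted curve), unlike the mean and
ratio which use the unsmoothed profile. Convolving the tract distribution
with the cut-position spread shifts the observed mode upward by ~10–20 nt
relative to the tract-distribution mode; this is inherent to the observable,
not an estimator artifact.

**Central:resection ratio.** AUC over [−300, +100) divided by AUC over
[+100, +2500]; the shared +100 boundary belongs to the resection window only,
so nothing is double-counted. Computed on the background-subtracted profile
by default (a raw-profile variant is a flag away, since the subtraction
convention for this ratio is not canonical).

**Replicate CV.** 100 × sample SD / mean over per-replicate statistics.
Replicates can also be combined by averaging RPM maps position-wise before
any statistic (`average_tracks`); both paths are provided because they
answer different questions (variability vs. a pooled estimate).

**Hann smoothing.** Kernel ∝ 0.5·(1 − cos(2πk/(w−1))) normalized to sum 1;
at array edges the kernel is truncated and renormalized, which preserves
constants exactly and total mass to <0.5% for signal ≥ w from the edge.

**Heatmaps.** Strand-specific 40-bp bin sums over a 4001-bp window; each
hotspot's bins are divided by its own combined-strand window total, so every
row sums to 1 and strand asymmetry (the double-cut signature) survives
normalization. 4001 is not a multiple of 40: the single leftover +2000
position is absorbed into the last bin. Rows are ordered strongest hotspot
first; zero-total hotspots are flagged and left as zero rows. Decile classes
are assigned over the pooled nonzero values of the whole heatmap (global,
not per-row; a per-row variant can be had by classifying row slices), ties
going to the higher class, zeros to class 1.

**Strand offset (double-cut signature).** Genome-average top and bottom
profiles (not co-oriented), 51-bp Hann smoothed; the statistic is
centroid(top) − centroid(bottom) over ±400 bp. Double cutting exposes only
the outermost ends of a multiply-cut molecule, so the offset equals the mean
outermost-cut spacing (positive); RI signal displaces the strands the
opposite way (negative). The centroid form is chosen because it is robust
and equals the simulator's configured spacing exactly in expectation.

**Oligo statistics.** Size classes split at the 34-nt marker (fraction below
= "fast"). Periodicity: unit-binned length histogram, detrended by a 21-nt
moving average (≈ two periods, edge-renormalized so constant baselines cancel
exactly), then the lag in 5–15 nt maximizing the residual autocorrelation.

## Synthetic data generator

The simulator emulates the statistical structure the analysis assumes, per
molecule:

1. hotspot ∝ exponential strength, on a 30-Mb chromosome with 1000 centers
   ≥10 kb apart (windows disjoint), optionally plus a flagged sex chromosome;
2. cut position from a trimodal kernel: central normal (sd 60 bp, weight
   0.8) plus subsidiary clusters at ±200 bp (weight 0.1 each), matching the
   "strong central cluster with weaker flanking clusters" of SPO11-oligo
   maps;
3. with probability `p_double_cut`, a second cut spaced by
   round(33 + 10·Geometric(0.4) + N(0, 1)) bp, placed symmetrically around
   the first draw — double-cut molecules carry exactly two cuts, so the
   observable outermost spacing equals the drawn spacing;
4. fate: RI (one read at center + d, d ~ N(−100, 80) truncated to
   [−300, 100] co-oriented, strand chosen 50:50 and mirrored); unresected
   (endpoints at the outermost cuts); or resected (endpoints pushed outward
   by independent left/right tracts from a truncated gamma);
5. uniform background, 30 reads/Mb/strand by default.

**Tract model.** Truncated gamma on [200, 2450] nt.
`calibrate_tract_distribution` fixes the interior mode (k−1)θ exactly and
solves the scale by root-finding so the truncated mean hits its target
within 1 nt (initialized from the untruncated identities θ = mean − mode,
k = mean/θ). The gamma family and bounds are modeling choices — real
mammalian tract-length distributions are only characterized by their means
and modes — and the bounds sit inside the analysis windows so recovery is
well-posed.

**Fate-fraction calibration.** An RI molecule emits 1 read, a resected
molecule 2, so the central:resection read-mass ratio is
ρ = r / (2(1−r)(1−u)) with r the RI fraction and u the unresected fraction.
Preset tables store the scientific target ρ; the loader inverts to
r = 2ρ(1−u) / (1 + 2ρ(1−u)).

**Preset table** (`presets.yaml`): wt (mean 1100 / mode 1015 nt, ρ = 0.40),
HN-Het (1040), Mre11-cHN (672, small unresected fraction), Mre11-cKO (all
unresected, 75% double cut, double-cut-dominated oligos),
Mre11-cKO-juvenile-resected (mode 897), Nbs1dB and Nbs1dB-14.5dpp (627,
ρ = 0.275), Nbs1dB-16.5dpp (ρ = 0.347), Nbs1dB-Exo1DA (516, ρ = 0.288),
Exo1DA (974), Mre11-ATLD1 (583), Rad50-L1237F (1000) and Rad50-D69Y (900)
— placed between wild type and Nbs1dB so the allelic series of estimated
means is reproduced — and Atm-null (mixed fates and oligo classes). Where a
genotype's mode is not separately characterized, the target mode defaults to
mean − 85 nt (the wild-type mean−mode gap). Left and right tracts are
independent (no within-DSB correlation estimate exists to condition on).

**Randomness.** One seed per simulate call; hotspot layout, molecule draws
and background use independent child streams of a single `SeedSequence`, so
adding background does not perturb molecule draws and fixed seeds give
bit-identical output.

## What the simulator does and does not emulate

It reproduces: strand-specific endpoint geometry, RPM bookkeeping,
hotspot-strength heterogeneity, unresected/double-cut/RI signal classes,
uniform background, and SPO11-oligo class structure. It does not model:
sequence-level reads (no FASTQ, alignment error or PCR duplicates),
chromatin- or sequence-dependent background structure, inter-hotspot signal
spillover (windows are disjoint by construction), within-DSB left/right
tract correlation, or cell-population heterogeneity. Passing recovery tests
therefore validate the estimators against the stated generative model, not
against every artifact of real libraries.

## Numerical choices and degenerate inputs

Coordinates are 0-based half-open everywhere; bedGraph values are
per-position counts (wider intervals are expanded, lossless for the
package's own width-1 output). Endpoint assignment takes read 1 as the
adapter-proximal mate: forward mates mark top-strand endpoints at their
leftmost base, reverse mates mark bottom-strand endpoints at their rightmost
base; the simulator's alignment writer mirrors the identical convention.
Degenerate inputs raise typed errors rather than returning NaNs: empty
resection windows (`DegenerateProfileError`), even smoothing windows, zero
library totals, infeasible calibration targets, flat oligo histograms
(detected with a scale-relative 1e-9 tolerance because edge-renormalized
detrending leaves float dust on exactly flat histograms). Overlapping
hotspot windows are allowed to double-count signal (no deduplication rule is
canonical); sex-chromosome hotspots are included by default and every
profile operation takes a hotspot mask so X/Y-only analyses are subset
calls.

## Known limitations

- Central-ratio recovery carries a small upward bias (up to ~+1.7 percentage
  points for the shortest-tract preset, Nbs1dB-Exo1DA): endpoints drawn
  under the left subsidiary cut cluster with near-minimal tracts can land
  below +100 bp and be counted in the central window. This is a property of
  the generative geometry, not of the ratio estimator.
- The observed modal length sits ~10–20 nt above the tract-distribution mode
  because of the cut-position spread (see above).
- The mean-length estimator is only defined for signal inside
  [100, 2500] bp; tracts truncated at the window edges would bias it, which
  is why the tract model's support is kept inside the window.

## Problem sizes

Recovery tests and the acceptance script use 1000 hotspots on a 30-Mb
chromosome with 5×10⁵ molecules per library (10⁶ for the replicate-CV
study, 10 libraries), chosen so each statistic's sampling error is an order
of magnitude below its tolerance; a full acceptance run takes about half a
minute on one CPU.
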