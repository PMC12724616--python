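# Methods

## The measurement being modelled

Each nucleus carries `ploidy` alleles of a genomic domain.  Two DNA FISH
channels mark the domain's 5′ and 3′ boundary loci; a third FISH channel
marks nascent transcripts of a gene inside the domain, so a transcription
site appears only at alleles that are actively transcribing at fixation.
The quantities of interest per allele are the 5′–3′ boundary
center-to-center distance, the allele's activity state, and — at the
population level — the fraction of alleles whose boundary distance falls
below an interaction threshold.

Imaging geometry follows the high-throughput spinning-disk configuration
this analysis targets: 152 nm lateral pixels and Z-stacks of 8 planes at
1 μm spacing (7 μm depth).  Primary distance measurements are made on 2D
maximum-intensity projections; the 3D distance (z in μm via the plane
spacing) is carried alongside.

## Generative model of the synthetic scenes

The simulator is the package's source of ground truth; its structure is the
statistical structure the analysis assumes.

* **Nuclei** are non-overlapping spheres (default radius 3 μm) placed in
  the field by rejection sampling with an attempt cap of 100 × `n_cells`;
  exceeding the cap raises an error naming the achieved density.  All
  nuclei sit at mid-stack, so non-overlap is a 2D condition.
* **Allele anchors** (the 5′ boundary positions) are uniform in a sphere
  shrunk by a margin of 3× the largest displacement scale, and are
  rejection-sampled to be at least `min_allele_separation_um` (default
  1.5 μm) apart — a coarse stand-in for chromosome territories that also
  realizes the well-separated regime in which closest-neighbor pairing is
  provably near-optimal.
* **Boundary displacement** is a two-state mixture: with probability
  `p_pair` the boundaries are paired and the 3D displacement is isotropic
  Gaussian with per-axis sd `paired_scale_um` (default 0.08 μm); otherwise
  `unpaired_scale_um` (default 0.40 μm) applies.  The 3D distance is then
  scale·χ (3 df) and its 2D projection scale·χ (2 df), giving closed-form
  medians and threshold probabilities used as test oracles.  Defaults were
  chosen so the 2D-projected population median (0.41 μm) and the 250 nm
  interaction fraction (0.30) lie in the range reported for human TAD
  boundaries by high-throughput FISH; `p_pair` = 0.15 reflects the
  published 5–20% single-allele pairing frequencies.  The mixture is a
  modelling convenience, not a claim about the true distance law of any
  locus.
* **Activity** is Bernoulli(`p_active`, default 0.3), independent of the
  pairing state by default.  Setting `p_pair_active` decouples the two
  Bernoulli rates, generating the *coupled* alternative in which active
  alleles pair more often — the effect the analysis must be able to detect.
  Active alleles carry an RNA site at the 5′ anchor plus an isotropic
  Gaussian offset (`rna_offset_scale_um`, default 0.2 μm; >99.9% of sites
  fall within the 1 μm activity radius under this default, consistent with
  the calibration experiments that motivated the radius).
* **Detection degradation** retains each true spot with its channel's
  `detect_eff` (default 0.99, which reproduces ">95% of cells with the
  correct DNA signal count"), adds isotropic localization noise
  (`loc_noise_um`, default 0.02 μm), and shifts the RNA channel by
  `channel_shift_px` to emulate an unregistered sequential acquisition.
* **Rendering** draws each FISH spot as a 3D Gaussian — lateral sd
  `spot_sigma_px` (1.3 px ≈ 0.2 μm, diffraction-limited) and axial sd
  `spot_sigma_z_um` (0.6 μm, the typical ~3× lateral axial extent of a
  spinning-disk confocal PSF; an axial width much smaller than the 1 μm
  plane spacing would make spots between planes invisible) — of amplitude
  `spot_amplitude` (200 photons) on `background` (25 photons), DAPI as
  PSF-blurred filled spheres, and Poisson shot noise throughout.  Peak SNR
  under the defaults is ≈ 40.

Seeding: one root seed; nucleus packing, each cell's geometry, each cell's
detection draws and the render noise use fixed counter-derived sub-streams,
so enlarging `n_cells` extends a scene without reshuffling existing cells,
and a fixed config is bit-reproducible.

## Analysis operators

* **Segmentation** is a transparent classical pipeline (Otsu threshold,
  hole filling, distance-transform watershed, minimum area, border
  exclusion).  It is adequate for the smooth synthetic nuclei and carries
  the same I/O contract as the learned segmenters used on real screens; it
  is not intended to match them on real images.  Border-touching nuclei are
  excluded by default because distances near crops are unreliable.
* **Spot detection** uses the scale-normalized negative
  Laplacian-of-Gaussian response; maxima above `min_snr` × the robust
  background spread (MAD × 1.4826) are kept, with intensity-weighted
  subpixel centroids in a ±⌈σ⌉ window and lexicographic tie-breaking on
  plateaus.  One tunable threshold, robust to the background level.
* **Registration** estimates the rigid DAPI-to-DAPI shift by phase
  cross-correlation with subpixel upsampling.  The reported shift is the
  displacement of the moving acquisition relative to the reference;
  applying it to a spot table subtracts the shift and recomputes physical
  coordinates.  Re-applying a shift to an already-registered table is an
  error (the operation is deliberately not idempotent).  In spot-table
  pipeline runs there are no images, so the configured shift is inverted
  directly (ideal registration); image-mode runs estimate it.
* **QC** keeps diploid cells with exactly 2+2 DNA signals and ≤2 RNA
  signals, triploid cells with 2–3 of each DNA signal and ≤3 RNA; every
  failure carries a reason code and the QC report counts unmatched signals
  in passing cells.
* **Pairing** interprets "closest neighbors" as greedy globally-closest
  matching: repeatedly take the unmatched (5′, 3′) pair at minimum
  Euclidean distance; ties resolve by ascending index.  In the
  QC-enforced regime (alleles separated by ≫ the intra-allele distance)
  this coincides with the optimal bipartite assignment, which the
  acceptance suite verifies by exhaustive enumeration.  Pairing uses 3D
  coordinates when z is available (configurable); reported distances
  always include the 2D projected value, which is the primary statistic.
* **Activity** assigns RNA signals to alleles in ascending order of the
  minimum distance to the allele's two boundary spots, only below the
  activity radius (default 1 μm, strict `<`), at most one RNA per allele;
  surplus signals stay unassigned and are logged.  How a shared RNA signal
  should be attributed is genuinely ambiguous; minimum-distance assignment
  is the declared convention.
* **Interaction fraction** uses strict `<` at the 250 nm threshold (a
  measure-zero convention, fixed for bit-exactness).  Both thresholds are
  config fields with the standard values as defaults.

## Statistics

Quantiles use linear interpolation between order statistics (medians and
IQRs are convention-sensitive at small n; this is the declared rule).
Mann–Whitney uses exact enumeration when n₁·n₂ ≤ 400 and the pooled sample
is tie-free, otherwise the tie-corrected normal approximation; the
crossover is configurable.  Dunn's pairwise z statistics follow
Kruskal–Wallis with the tie-corrected rank variance and Bonferroni
multiplication capped at 1.  Experiment-level comparisons aggregate each
experiment to its median, then run a two-way fixed-effects ANOVA
(condition × locus, experiments as replicates — the minimal design
consistent with mean-of-medians reporting) with Bonferroni-corrected
condition contrasts per locus on the pooled residual mean square; both SEM
and SD dispersion of the medians are exposed.  Within-nucleus allele-pair
correlation randomizes the (arbitrary) allele order with a seeded generator
and reports Pearson and Spearman coefficients.  Sums of squares below
numerical round-off are treated as structurally zero so that degenerate
designs (all medians equal; zero noise) produce p = 1 / p = 0 rather than
float noise.

## What the synthetic tests do and do not show

Passing tests establish that the operators are mutually consistent and
recover the generative model's parameters: pairing is optimal, distances
are exact to floating precision, activity calls agree with ground truth,
the tests hold their nominal size, and the active-vs-inactive comparison
stays null under independence while detecting a `p_pair` shift of +0.3 at
n = 2,000 alleles.  They do not validate segmentation or detection on real
micrographs (irregular nuclei, autofluorescence, probe variability,
replication-dependent spot doubling and chromatic aberration are all
outside the generative model), and the mixture distance law is an
assumption, not an inference about any real locus.

## Problem sizes and numerical choices

The verification suite uses 1,000 cells for the pairing-optimality check,
10,000 alleles for parameter recovery (bootstrap 99% CI of the median,
2,000 resamples), 200 rendered cells (10 fields of 20, 512×512×8) for the
detection round trip, 5,000 cells for activity fidelity and expression-state
fractions, 2,000 Monte-Carlo replicates for test calibration (groups of
100, where the normal approximation's size is nominal), and 200 runs of
2,000 alleles each for the null/alternative sensitivity check — sizes at
which the binomial three-standard-error bands used in the assertions are
decisive while a full run stays in the minutes range on one CPU.

Known limitations: nuclei are ideal spheres at a common focal depth; the
renderer has no photobleaching, blinking or aberration model; triploid
scenes use the same anchor model as diploid; the pipeline treats spot
tables as already cell-assigned when they come from the simulator's
degradation path.
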