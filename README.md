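# tadfish

Allele-level quantification of chromatin-domain boundary proximity and gene
activity from high-throughput DNA/RNA FISH imaging.

Topologically associating domains (TADs) are flanked by boundary regions
whose physical pairing can be visualized by labelling the 5′ and 3′ boundary
loci with DNA FISH probes, while a nascent-RNA FISH probe against a gene in
the domain reports which alleles are transcribing at the moment of fixation.
`tadfish` implements the single-allele analysis for this kind of experiment:

- **image front end** — calibrated 4-channel OME-TIFF stacks (DAPI, 5′
  boundary, 3′ boundary, nascent RNA; 152 nm XY pixels, 1 μm Z steps),
  maximum-intensity projections, Otsu/watershed nucleus segmentation,
  Laplacian-of-Gaussian spot detection with subpixel centroids, and phase
  cross-correlation registration of sequential DNA/RNA acquisitions;
- **allele calling** — ploidy-aware QC (diploid: exactly two 5′ and two 3′
  signals and ≤2 RNA signals per cell; triploid: 2–3 DNA signals and ≤3
  RNA), greedy closest-neighbor matching of 5′/3′ signals into boundary
  pairs, center-to-center distances *d* in μm (2D projected and 3D), an
  allele called **active** when an RNA signal lies within 1 μm of either of
  its boundary signals, and the **interaction fraction**
  P(*d* < 250 nm);
- **statistics** — median ± IQR summaries, Mann–Whitney *U* (exact
  enumeration for small samples), two-sample Kolmogorov–Smirnov,
  Kruskal–Wallis with Dunn–Bonferroni post hocs, two-way ANOVA on
  per-experiment medians (mean-of-medians aggregation), within-nucleus
  allele-pair correlation, and the usual significance categories
  (\*\*\* p<0.001, \*\* p<0.01, \* p<0.05, ns p≥0.05);
- **synthetic scenes** — a ground-truthed generator in which the 5′→3′
  boundary displacement follows a two-state mixture (paired with probability
  `p_pair`, isotropic Gaussian scales `paired_scale_um` /
  `unpaired_scale_um`, so the 3D distance is scale·χ₃), activity is
  Bernoulli(`p_active`) with RNA placed near the 5′ boundary, and imaging is
  emulated either as a degraded spot table (detection efficiency,
  localization noise, inter-acquisition channel shift) or as rendered
  Poisson-noise image stacks.  Every stage of the pipeline is therefore
  testable against exact ground truth and closed-form χ-distribution
  oracles, with no external data.

## Worked example

A full simulated experiment — 2,000 diploid cells, boundary pairing in 15%
of alleles, transcription at 30% of alleles, independent of pairing:

```sh
cat > demo.yaml <<EOF
seed: 7
simulate:
  n_cells: 2000
EOF
tadfish run --config demo.yaml --out demo/
```

`demo/stats.csv` then contains (abridged):

```
summary,n_alleles,3834
summary,median_um,0.4184260780997028
summary,iqr_um,0.4233051314097033
summary,interaction_fraction,0.29473135106937925
activity,mw_p,0.8365687776068003
activity,mw_category,ns
activity,median_active_um,0.42013442493503356
activity,median_inactive_um,0.4171761670262209
allele_correlation,pearson_r,0.012884243687150815
```

Reading: 3,834 alleles passed QC; the 2D boundary distance distribution has
median 0.42 μm (IQR 0.42 μm) with 29% of alleles inside the 250 nm
interaction threshold; active and inactive alleles have indistinguishable
distance distributions (Mann–Whitney p = 0.84, "ns"), and the two alleles of
a nucleus are uncorrelated (r ≈ 0.01) — the structure the generator was
asked to produce.  The run also writes `spots.csv`, `alleles.csv`,
`qc_report.csv` and `provenance.json` (config hash, seeds, record counts
surviving each filter); the same config and seed reproduce all five files
byte-for-byte.

Other entry points: `tadfish simulate` (ground truth + spot table),
`tadfish detect` (stack → spot table), `tadfish alleles`, `tadfish stats`,
or the library API (`tadfish.simulate_ground_truth`,
`tadfish.build_alleles`, `tadfish.mann_whitney`, ...).

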