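# Table and file formats

All tables are plain CSV with a header row; coordinates are physical
micrometers unless the column name says `_px`.  Channel labels are
`dapi`, `dna5` (5′ boundary DNA FISH), `dna3` (3′ boundary DNA FISH),
`rna` (nascent RNA FISH).

## spots.csv

One row per detected (or simulated-detected) FISH signal.

| column | meaning |
| --- | --- |
| channel | `dna5`, `dna3` or `rna` |
| cell_id | nucleus label; 0 = unassigned (excluded from allele analyses) |
| true_allele_id | ground-truth allele (simulation only) |
| x_um, y_um, z_um | centroid in physical units |
| x_px, y_px, z_px | centroid in pixels / planes (`_um` = `_px` × calibration) |
| peak_intensity, quality | detector outputs (image mode) |
| registered | whether the channel shift has been applied |

## ground_truth.csv / nuclei.csv (simulation)

Per allele: `cell_id`, `allele_id`, `x5_um..z5_um`, `x3_um..z3_um`,
`true_distance_um`, `paired_state`, `active`, `rna_x_um..rna_z_um` (empty
when inactive).  Per nucleus: `cell_id`, `cx_um`, `cy_um`, `cz_um`,
`radius_um`.

## alleles.csv

One row per matched 5′/3′ boundary pair.

| column | meaning |
| --- | --- |
| cell_id, allele_id | nucleus label and within-cell allele counter |
| spot5_index, spot3_index | row indices into spots.csv |
| distance_2d_um | projected center-to-center distance |
| distance_3d_um | 3D distance (empty without z) |
| active | nascent RNA within the activity radius of either boundary |
| rna_spot_index | assigned RNA row (empty if inactive) |
| rna_boundary_distance_um | RNA-to-nearest-boundary distance |

## qc_report.csv

Per cell: `cell_id`, `n_dna5`, `n_dna3`, `n_rna`, `reason` (empty or
`dna5_count` / `dna3_count` / `rna_count`), `qc_pass`, `ploidy_class`,
`n_alleles`, `n_unmatched_dna`.

## stats.csv

Tidy `section,name,value` rows: distribution summary (n, median, IQR,
interaction fraction at the configured threshold), active-vs-inactive
Mann–Whitney results, expression-state fractions (silent / mono / bi /
≥3), and within-nucleus allele correlation.

## provenance.json

Package version, full normalized config, SHA-256 of the config, seed,
per-stage record counts, and any notices (skipped comparisons, applied
registration).  No timestamps, so identical runs are byte-identical.

## Images

Stacks are OME-TIFF, axes C×Z×Y×X, with `PhysicalSizeX/Y/Z` metadata and
channel names.  Plain TIFF is accepted when `--pixel-size-um` /
`--z-step-um` overrides are given.  Label images are integer TIFF.
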