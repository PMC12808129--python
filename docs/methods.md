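# Methods

## Problem and model

Nanoparticle (NP) enrichment workflows for plasma proteomics capture
low-abundance proteins through protein-corona formation, but they also
amplify blood-cell contamination: residual platelets, hemolysed
erythrocytes, or partial coagulation inflate protein identifications and
distort quantification. `plasmaqc` assesses three contamination types per
sample through a single statistic, the **contamination index**

```
index(sample, panel) = sum of detected marker intensities
                       ---------------------------------
                       sum of all detected intensities
```

computed on linear intensities. The index lies in [0, 1], is invariant to
rescaling a sample by a positive constant, and — on an ideal volumetric
mixture — is non-decreasing in the contaminant fraction. The denominator
includes the markers themselves: the formula is a mass share of the
detected proteome, and excluding markers would break the [0, 1] bound.
A sample is flagged when its index strictly exceeds a per-type threshold.
Indices are not comparable across different NP chemistries; no
cross-workflow normalisation is attempted.

## Marker discovery

**Gradient designs (platelet, erythrocyte).** Protein groups missing in
strictly more than 50% of samples are removed (a protein exactly at the
threshold is kept). Each remaining protein's Spearman rank correlation
(rho) with the design gradient is computed pairwise-complete over the
samples where the protein is detected, with average ranks for ties; rho is
undefined below three complete pairs. Proteins are ranked by *signed* rho
descending — contamination markers must rise with contamination, and
strongly negatively correlated proteins (displaced plasma proteins) must
not enter the panel — the top 100 form the correlation pool, and the 30
most abundant pool members form the panel. Abundance here is the mean over
gradient levels of the per-level mean of detected intensities, so unequal
replication cannot bias the ranking. Ties break deterministically: higher
abundance, then lexicographic identifier. The discovery gradient is the
design-level mixing fraction (or group rank), not measured cell counts;
counts enter only at threshold calibration.

**Contamination-independent proteins** are those detected in the
zero-contamination samples whose signed rho is strictly below 0.7.
Undefined rho counts as independent (no evidence of association).

**Paired designs (coagulation).** Per protein and donor, the condition
value is the mean of detected replicate intensities; proteins testable in
at least two donors in both conditions get a plasma/serum fold change on
linear condition means and a two-sided paired Student's t-test on log2
donor means (fold change on linear scale, test on log scale — the data are
log-normal, but the field reports linear fold changes). P-values are
Benjamini–Hochberg adjusted across all tested proteins. Survivors need
fold change strictly greater than 5 *and* adjusted p below 0.05; the 20
most abundant survivors form the panel. All-zero paired differences give
p = 1 by convention (no evidence), zero-variance non-zero differences
give p = 0.

**Trend clustering.** An exploratory fuzzy c-means view of per-level mean
trends (z-scored per protein) with 8 clusters and fuzzifier m = 2 is
provided; it visualises rising/falling archetypes but is not on the
selection path. The implementation is the classic Bezdek alternating
update with seed-controlled initial centroids (random distinct proteins),
stopping when the largest centroid movement falls below 1e-6 or after 300
iterations. Memberships row-normalise to 1; points coinciding with a
centroid get full membership there.

## Threshold calibration

The index-versus-cell-count relationship is fit with a single-knot
continuous broken-stick model on x = log10(count + 1) (the +1 admits the
zero counts of clean samples): flat at a baseline up to the knot, linear
rise after. For each candidate knot — the observed transformed counts plus
a 201-point uniform refinement grid — baseline and slope are solved by
ordinary least squares under the continuity constraint, and the knot with
minimal residual sum of squares wins (ties to the smallest knot). All
points participate in the fit: the flat segment is estimated jointly with
the rise rather than pre-trimming a visually flat region, which would
presuppose the answer. R² is 1 − RSS/TSS over all points. Zero variance in
the indices yields a degenerate flat fit (R² = 1 by convention, knot at
the upper boundary) which is refused for flagging; a knot pinned to either
end of the count range is marked as a boundary solution. The flagging
threshold is the fitted index at the knot — flags are defined on indices,
so a threshold on the index scale is directly applicable to cohorts
without cell counts. A single-knot model (rather than cubic splines or
multiple knots) matches the observed flat-then-rising shape; knot
uncertainty intervals are out of scope.

## QC metrics

Replicate precision is the per-protein CV (100·sd/mean, n−1 standard
deviation) on linear intensities over biological replicates, skipping
proteins missing in any replicate of a group; summarised by the median.
Spike-in accuracy compares per-feature log2 fold changes of
contaminant-specific features between design groups against the known
mixing ratios. Intensities are log2-transformed and optionally per-sample
median-centred (global median normalisation) first. Median centring is a
faithful technical-variation correction when samples share composition,
but on strong volumetric mixtures the background itself is diluted by
(1 − f) and the median shifts with composition, biasing spike ratios;
the exactness checks therefore run with normalisation off, where the
observed ratios equal f1/f2 identically.

## Synthetic spike-in generator

The generator emulates the statistical structure of contaminant mixing
experiments, not their biochemistry.

* **Base proteome:** 2000 protein groups with log-normal abundances,
  log10-intensity mean 5 and sd 1 — a realistic plasma dynamic range and
  rank structure.
* **Mixing design:** 7 levels (clean, then a geometric ladder 0.01 → 1 of
  contaminant volume fractions) in triplicate; the exact published ratios
  of such designs are rarely printed, so a two-decade geometric ladder is
  the default and fully configurable. Cell counts map linearly to the
  mixing fraction with 2.5e8 cells at full contamination (a typical
  platelet concentrate scale).
* **Contaminant profile:** 200 planted markers enriched 50-fold in the
  contaminant; 30% of them are contaminant-specific (absent from clean
  plasma — hemoglobin-like behaviour, rarely detected without
  contamination); planted markers draw their clean-plasma abundance one
  decade below the base distribution (contaminant-cell proteins are scarce
  in clean plasma, keeping the clean-sample index near zero); 20% of the
  non-planted plasma proteins are absent from the contaminant and hence
  decline with contamination (the falling trend archetype).
* **Noise and censoring:** mean-one multiplicative log-normal noise with
  CV 0.2 (replicate CVs below ~20%, as quantitative plasma workflows
  achieve), then left-censoring at the 5% quantile of the pooled intensity
  distribution (missing-not-at-random at the low end). Zeros, blanks and
  NaN are all "missing".
* **Paired design:** 10 donors, 800 proteins, 40 planted coagulation
  proteins depleted 8-fold in serum, donor-level biological CV 0.3,
  technical CV 0.1.

Every draw is governed by one integer seed. What passing tests on this
generator do **not** show: real NP data have correlated protein covariance
(shared corona affinity), peptide-level effects, batch structure, and
contaminant profiles that overlap plasma far less cleanly; panel purity
and index separation on real cohorts will be lower than on the simulator.

## Problem sizes and numerical choices

Tests and the acceptance script use the study-scale defaults: 2000
proteins × 21 samples for discovery, 20 seeded repetitions for recovery,
50 seeds for noisy change-point recovery on 33-point curves (chosen so the
default suite and script complete in well under a minute each on a single
CPU). The change-point candidate grid resolution is (range/200) log10
units; knot-recovery claims are made to within one grid step. Marker
matching is case-insensitive on gene symbols (with DIA-NN "A;B" multi-gene
annotations split), falling back to protein-group identifiers; unmatched
markers are reported and reduce the numerator silently, failing only when
an entire panel is unmatched. Ranking ties break by abundance then
identifier, making every selection deterministic.

## Known limitations

* The index quantifies contamination severity; it cannot correct
  contamination-induced quantitative bias.
* Default shipped panels contain only a handful of canonical markers per
  type and are placeholders for properly discovered 30/30/20 panels.
* Thresholds calibrated on one NP workflow do not transfer to another.
* The broken-stick model assumes one change point; gradual onsets are
  approximated, not modelled.
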