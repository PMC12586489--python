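# protconcord

Cross-platform plasma-proteomics concordance analysis: in-depth TMT-based
LC-MS/MS relative quantification versus proximity-extension affinity assays
(Olink-style NPX readout) on the same cohort.

Plasma proteomics studies increasingly mix the two technology families, and
they frequently disagree protein by protein. This package implements, as a
reusable and tested pipeline, the full concordance-analysis stack a platform
comparison needs — and a synthetic dual-platform cohort generator with known
ground truth, so that every stage is verifiable without access to a deposited
cohort. It is written for proteomics methodologists and analysts choosing or
combining platforms.

## What it computes

**Precision.** Technical CVs from duplicate measurements on the log2 scale via
the log-normal back-transform

    CV% = 100 · sqrt(exp((ln 2 · SD)²) − 1),  capped at 100%,

where SD = |a − b|/√2 per duplicate pair and the feature CV is the mean over
its pairs. MS CVs are inter-assay (duplicate aliquots across TMT sets);
affinity CVs are intra-assay (a pooled control measured twice) — the asymmetry
is preserved and labelled.

**Quantification roll-up.** PSM-level log2 reporter intensities are rolled up
as the median of channel/internal-standard log2 ratios per peptide and per
protein, after excluding PSMs that map to more than one protein group or miss
a value in any channel of their TMT set, followed by per-channel median
centering. The internal standard models the master pool built from every
sample and split across sets.

**Coverage and missingness.** Per-feature missing fractions (with below-LOD
values either retained or censored), and reference-proteome coverage binned by
estimated blood concentration (right-closed intervals), with a generic
hypergeometric over-representation test for annotation sets.

**Protein-level concordance.** Spearman ρ (average ranks) and Pearson r per
matched protein on pairwise-complete samples, requiring ≥ 8 overlapping
points, under three dataset variants — *full* (below-LOD and QC-warned values
retained), *clean* (those set to missing) and *complete* (no missing or
flagged values on either platform) — with the standard category bins
(ρ ∈ [−1, 0.3) none, [0.3, 0.5) weak, [0.5, 0.7) moderate, [0.7, 1.0] strong),
isoform-resolved correlations for genes where the platforms quantify different
UniProt IDs, and alignment with external cross-platform correlation tables
(median over reagent pairs, per-confidence-tier medians).

**Differential abundance.** Two-sided Welch's *t* (female − male, males as
reference) per platform, BH-FDR < 0.05, then significant-set overlap,
directional agreement, Pearson R of paired log2 fold changes, and replication
rates against external DAA tables (same-direction significance among proteins
tested in both studies).

**Technical factors.** Univariable OLS of the per-protein cross-platform ρ on
each candidate factor (missingness, below-LOD fraction, PSM/peptide depth,
sequence coverage, precursor mass error, CVs, NPX margin above LOD, QC
warnings, panel version, protein properties, concentration) with 95% CIs,
adjusted R² and BH adjustment across factors.

**Peptide-level agreement.** Per-peptide Spearman ρ against the gene's assay
(≥ 15 samples, ≥ 2 peptides per gene), exact-substring localization on isoform
sequences (1-based inclusive, leftmost occurrence, multi-hit flagged),
per-region median correlations, non-overlapping display-track layout
(first-fit), and per-residue median ρ painted into a PDB temperature-factor
column — the machinery behind sequence/structure views that reveal which
proteoform an affinity assay actually tracks.

## Worked example

The numbered drivers under `analysis/` run the whole study on the synthetic
cohort (88 samples, ~500 proteins spanning ten orders of magnitude, six MS
duplicate pairs, MNAR missingness, LOD noise-floor censoring, two
multi-proteoform genes):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_precision_coverage.py
python analysis/03_protein_concordance.py
python analysis/04_differential_abundance.py
python analysis/05_technical_factors.py
python analysis/06_peptide_agreement.py
```

Selected output (seed 20250927):

```
MS technical CV: median 12.0% over 480 proteins (95% computable)
affinity technical CV: median 12.9% over 502 assays
MS proteins with >=1 missing value: 59%; assays with >=1 below-LOD value: 25%

full     : N= 502  median rho=0.75 (IQR 0.67-0.79); moderate+strong 80%
clean    : N= 412  median rho=0.77 (IQR 0.72-0.80); moderate+strong 97%
complete : N=  75  median rho=0.78 (IQR 0.73-0.81); moderate+strong 100%
isoform resolution: GMASPX assay agrees best with P90001-2 (rho=0.73)

DAPs (FDR<0.05): MS 45, affinity 41, both 37 of 502 overlapping proteins
directional agreement (significant in >=1 platform): 100%; fold-change R=0.96

  GMASPX   iso1_unique  n= 6  median rho=0.07
  GMASPX   iso2_unique  n= 6  median rho=0.66
  GAMBPX   product_a    n= 6  median rho=0.71
  GAMBPX   product_b    n= 6  median rho=0.17
```

Reading this: both platforms are precise (CV ≈ 12%) yet agree only moderately
per protein (median ρ 0.75 here; below-LOD fraction and MS missingness explain
most of the variance in ρ — see `results/factor_fits.tsv`). They call largely
the same sex-differential proteins with near-perfect directional agreement.
At the peptide level, the two-isoform gene GMASPX shows strong correlations
only in the isoform-2-unique region — recovering the generator's truth that
the assay targets isoform 2 — and the cleaved-precursor gene GAMBPX shows the
assay tracking product A, not product B.

The same pipeline is available as a CLI (`protconcord run --seed 1 --outdir
results/run`) driven by a JSON config; thresholds default to ≥ 8 overlap
points, ≥ 15 peptide samples, FDR 0.05 and a 100% CV cap, and every run writes
a manifest with the resolved configuration and seed.

## Layout

```
src/protconcord/    library: synthetic, ingest, precision, concordance,
                    daa, factors, peptides, experiments, pipeline, cli
analysis/           numbered narrative drivers over the library
tests/              pytest suite incl. oracle-based acceptance checks
scripts/            acceptance.py
docs/methods.md     model assumptions, parameter choices, limitations
```
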