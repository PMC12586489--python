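# Methods

This note documents the models behind `protconcord`: what the synthetic
dual-platform cohort emulates, the quantitative rules each analysis stage
implements, the parameter defaults and why, numerical choices, and the limits
of what passing tests demonstrate about real data.

## The latent cohort model

Each protein (or proteoform) *p* has a latent log2 abundance per sample *s*

    L[s, p] = b_p + e_p · 1{s female} + ε_{s,p},   ε ~ N(0, σ_bio²)

with the baseline `b_p` drawn from a uniform log10 blood concentration over
`conc_log10_range` (default (−3, 7) log10 ng/mL — ten orders of magnitude,
down to pg/mL) converted to log2. A subset of `n_sex_affected` proteins
(default 50 of 500) carries a sex effect of magnitude `sex_effect_log2`
(default 0.5) with a random sign per protein, so directional-agreement
statistics are non-trivial. Defaults: 88 samples, 42% female, σ_bio = 0.5
log2 units, six duplicate aliquot pairs. Duplicate aliquots share latent
values exactly and differ only by technical noise.

Multi-proteoform genes have one latent trajectory per isoform, drawn jointly
with correlation `proteoform_corr` (default 0.2) and a shared baseline.
Biological variation is independent across proteins — plasma co-regulation
structure is not modelled; this is a deliberate simplification, and any
analysis that depends on between-protein correlation structure (e.g. network
inference) is outside what these simulations validate.

Plain proteins receive a random amino-acid sequence (150–400 residues) and
are represented internally as single-isoform proteoforms with one region
covering the whole sequence, so peptide generation, localization and region
summaries treat every gene uniformly.

## The MS observation layer

PSM-level log2 intensities per TMT channel are

    I[psm, c] = L[s(c), p] + batch[p, set] + offset_psm + ν,   ν ~ N(0, σ_tech²)

with σ_tech = 0.3, per-(protein, set) batch effects of SD 0.2, and a per-PSM
intensity offset (SD 1.0) that cancels in ratio formation. The internal
standard emulates the master pool made from every sample and split across
sets: its latent value is the global per-protein **median** of the samples'
latent log2 values, identical in every set, and batch effects perturb sample
channels only (a per-set pool would cancel batch structure and break cross-set
comparability). The median rather than the mean makes the all-noise-off
configuration produce exactly two-valued centered ratios, so the noise-free
identity checks hold bitwise rather than approximately.

Missingness is missing-not-at-random at the (protein, TMT set) level: a
protein drops out of an entire set with probability
`logistic(logit(base_rate) − slope · z_p)` where `z_p` standardizes the
protein's mean latent abundance. Defaults `base_rate = 0.1`, `slope = 1.0`
yield ≈ 55–60% of proteins with at least one missing value over eight sets,
matching the observed granularity (set-specific missingness) and magnitude of
deep TMT plasma data. Small rates of multi-mapped PSMs (2%) and per-channel
intensity dropout (0.5%) exercise the roll-up exclusion rules.

Peptides are fixed-length substrings (8–16 aa) sampled inside declared
regions; tryptic termini are available as an option but localization never
depends on cleavage rules. Each peptide follows the latent trajectory of the
isoform its region belongs to, which is what propagates proteoform structure
to the peptide level.

The roll-up itself — exclusion of multi-group PSMs and PSMs missing any
channel, median of log2(channel) − log2(IS) per feature, per-channel median
centering — is the production code path (`ingest.roll_up_psms`); the
simulator emits raw PSMs and calls it, so tests of the simulator also
exercise the roll-up.

## The affinity observation layer

Each gene gets one assay:

    NPX[s, a] = offset_a + Σ_i w_i · L[s, isoform_i] + ν,  ν ~ N(0, σ_npx²)

with σ_npx = 0.3 NPX units (one NPX unit = one doubling), per-assay offsets
(SD 1.0), and mixture weights `w` over the gene's isoforms describing what
the antibody pair actually binds. The assay LOD is the assay offset plus a
global latent-concentration quantile (`lod_quantile`, default 0.2).
Measurements whose signal falls below the LOD lose that signal: they are
redrawn from a noise floor hugging the LOD from below (background dominates a
proximity-extension readout under its detection limit), flagged `below_lod`,
and retained — analyses then choose to keep or censor them. About a quarter
of assays end up with at least one below-LOD value at the defaults. Sample
QC warnings are Bernoulli (1%) per measurement, assay QC warnings 1% per
assay. A pooled control (mean latent) measured twice supplies the intra-assay
CV, mirroring how affinity control duplicates are produced on-plate.

A consequence worth stating: masking below-LOD values *per protein* does not
raise its correlation under this model — the floor values still sit at the
bottom of the rank order, and removing them restricts the biological range.
The improvement of the "clean" variant is compositional: heavily censored,
poorly correlating proteins lose eligibility (< 8 points) and drop out,
raising the median over surviving records. The tests assert exactly that
observable.

## Analysis conventions

* Correlations: Spearman with average ranks (the conventional tie treatment),
  pairwise-complete observations, ≥ 8 overlapping points, zero-variance
  vectors excluded with a reason rather than emitted as NaN. Coefficients are
  reported unfiltered by significance. Category bins are left-closed with the
  top bin closed: [−1, 0.3), [0.3, 0.5), [0.5, 0.7), [0.7, 1.0].
* Duplicate aliquots and control samples never enter correlations or DAA;
  only samples measured by both platforms do (the first aliquot carries the
  sample ID, so the shared-sample intersection enforces this).
* Technical CV: per-pair SD uses the sample (n−1) denominator, |a−b|/√2 for a
  pair — the choice is isolated in one function. The cap at 100% is applied
  to the final feature CV.
* Welch's t with Satterthwaite df; features with fewer than two non-missing
  values per group are excluded *before* BH so the number of tests reflects
  testable features (restricting the universe therefore changes significance,
  as it should). Zero-variance degenerate cases are defined explicitly:
  equal means → (t=0, p=1), unequal → (±∞, p=0).
* log2 fold change = difference of group means on the log2/NPX scale;
  fold-change agreement uses Pearson R; directional agreement counts
  sign(fc_MS) = sign(fc_affinity), with 0 = 0 agreeing, over either all
  overlapping proteins or those significant in ≥ 1 platform (both scopes are
  emitted; neither is privileged).
* Identifier matching: per assay, the first UniProt ID, then gene name;
  isoform-suffixed IDs ("P48740-2") never match at the UniProt level.
  Gene-basis matches are labelled so downstream outputs can stratify by match
  basis, and UniProt-matched pairs are preferred for full-variant reporting.
* External correlation tables are aggregated by the median over reagent
  pairs per (study, protein) before joining (UniProt first, gene fallback);
  replication-rate denominators are the DAPs tested in both studies.
* Peptide-level filters: ≥ 15 samples per peptide, ≥ 2 surviving peptides per
  gene. Localization is exact substring search, leftmost occurrence, 1-based
  inclusive coordinates (UniProt feature convention), multi-hit flagged;
  unplaceable peptides are reported, not fatal. Boundary-spanning peptides
  count in every region they touch (a majority-overlap rule is available).
  Track layout is first-fit greedy by ascending (start, end, sequence) —
  deterministic and order-invariant. Structure annotation writes raw ρ at two
  decimals into the temperature-factor field (lossless round-trip; rescaling
  is the viewer's job), with −9.99 for uncovered residues and a residue-
  identity cross-check that errors above 5% mismatch.
* Factor regressions: univariable OLS, 95% CIs from the t distribution,
  adjusted R², BH across factors; binary group factors enter as indicators,
  and per-set PSM/peptide medians count detected sets only (a set where the
  protein is absent contributes no zero). A two-sided Wilcoxon rank-sum
  utility covers group-style panels.

## Problem sizes and calibration experiments

The packaged experiments use 88 samples throughout — the cohort scale the
design emulates — with 200–500 proteins per run, which is sufficient for
stable medians and regression slopes while keeping the full suite around a
minute. The calibration battery:

* **Null DAA** (no sex effect, 500 proteins): Welch rejections at p < 0.05
  within the 99% binomial interval of 0.05; BH false-discovery proportion
  averaged over 20 independent cohorts. Computed on the affinity matrix,
  which is complete with independent noise — a clean null; the MS matrix
  deliberately carries TMT batch structure and is not one.
* **Proteoform recovery**: a two-isoform gene (trajectory correlation 0.2,
  observation noise 0.3, ≥ 5 peptides per region, n = 88) with the assay on
  isoform 2; the targeted region's median peptide ρ exceeds the other's by
  ≥ 0.3 in ≥ 95 of 100 seeds. LOD censoring is off here: the experiment
  concerns targeting of a well-detected gene (an assay below LOD in all
  samples would be excluded from analysis as not detected).
* **Degradation**: median protein ρ is non-increasing over observation-noise
  SD {0, 0.2, 0.5, 1.0}, and the fitted slope of ρ on MS missingness is
  negative under MNAR generation — the mechanism being the shared abundance
  link between MS dropout and affinity LOD censoring.

## Synthetic demo proteoform genes

`GMASPX` (two isoforms, assay on isoform 2) and `GAMBPX` (a cleaved precursor
modelled as its two circulating products with distinct sequences, assay on
product A) are synthetic stand-ins generated from a seed: sequences, regions
and coordinates are generator truth, not curated annotations of any real
protein. Region tables for real proteins are accepted as user input in the
same format (gene, region, isoform, start, end).

## What passing tests do and do not show

The generator reproduces the *statistical* structure that drives concordance
analyses — abundance-dependent missingness, LOD censoring at a noise floor,
batch effects, duplicate designs, proteoform mixtures — but not antibody
cross-reactivity, epitope masking, post-translational modifications, sample
handling artifacts, plate/bridging effects, or correlated biology across
proteins. Passing the suite shows the statistics and bookkeeping are correct
and that known signal is recovered under realistic noise; it does not certify
any particular real platform pairing, where additional, unmodelled error
modes lower agreement further. Numbers printed by the drivers (median ρ
≈ 0.75 at the defaults) are properties of these idealized conditions, not
predictions for real cohorts.
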