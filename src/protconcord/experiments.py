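"""Focused simulation experiments over the generator + analysis stack.

Each experiment builds a small, purpose-specific synthetic cohort, runs the
relevant analysis path, and returns the measured quantities.  They back the
calibration and recovery checks (type-I error of the Welch pathway, proteoform
region separation, correlation degradation under observation noise and MNAR
missingness) and are reused by the analysis drivers and the acceptance script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import concordance, daa, factors, ingest, peptides, precision, synthetic


# ---------------------------------------------------------------------------
# proteoform recovery (peptide-level region separation)
# ---------------------------------------------------------------------------

def proteoform_recovery(
    seed: int,
    n_samples: int = 88,
    proteoform_corr: float = 0.2,
    noise_sd: float = 0.3,
    peptides_per_region: int = 6,
    n_background: int = 20,
) -> dict:
    """One seed of the two-isoform recovery experiment.

    A gene with two isoforms (latent trajectory correlation
    ``proteoform_corr``) is measured by an affinity assay targeting isoform 2
    only; MS peptides cover an isoform-1-unique and an isoform-2-unique
    region.  Returns the median peptide-assay Spearman correlation of the
    targeted and non-targeted regions.  LOD censoring is disabled: the
    experiment concerns proteoform targeting of a well-detected gene, and
    assays below LOD in all samples would be excluded from such an analysis
    anyway.
    """
    cohort = synthetic.CohortSpec(
        n_samples=n_samples, n_proteins=n_background, n_sex_affected=0,
        biological_sd_log2=0.5, n_duplicate_pairs=2, seed=seed,
    )
    demo = synthetic.demo_proteoforms(seed=seed + 101)
    gene_spec = next(pf for pf in demo if pf.gene == "GMASPX")
    gene_spec = synthetic.ProteoformSpec(
        gene=gene_spec.gene,
        isoform_sequences=gene_spec.isoform_sequences,
        region_map=gene_spec.region_map,
        assay_targets=gene_spec.assay_targets,
        proteoform_corr=proteoform_corr,
    )
    truth = synthetic.generate_cohort(cohort, proteoforms=[gene_spec])
    design = synthetic.generate_peptides(
        truth.proteoforms.values(), peptides_per_region=peptides_per_region,
        seed=seed + 202,
    )
    ms_spec = synthetic.MsNoiseSpec(
        n_tmt_sets=8, set_size=16, tech_sd_log2=noise_sd, batch_sd_log2=0.0,
        missing_base_rate=0.0, multi_map_rate=0.0, channel_dropout_rate=0.0,
        psm_per_peptide_mean=0.0,
    )
    aff_spec = synthetic.AffinityNoiseSpec(
        tech_sd_npx=noise_sd, lod_quantile=0.0, qc_warning_rate=0.0, assay_qc_rate=0.0,
    )
    _, peptide_qm, _, _ = synthetic.simulate_ms(
        truth, ms_spec, peptide_design=design, seed=seed + 1
    )
    npx = synthetic.simulate_affinity(truth, aff_spec, seed=seed + 2)

    pep_corr = peptides.peptide_correlations(peptide_qm, npx)
    fasta = {g: dict(pf.isoform_sequences) for g, pf in truth.proteoforms.items()}
    placed = peptides.locate_peptides(pep_corr, fasta)
    regions = pd.DataFrame(
        [
            {"gene": gene_spec.gene, "region": name, "isoform_id": iso,
             "start": s, "end": e}
            for name, iso, s, e in gene_spec.region_map
        ]
    )
    summ = peptides.summarize_regions(placed, regions).set_index("region")
    return {
        "targeted_median_rho": float(summ.loc["iso2_unique", "median_rho"]),
        "nontargeted_median_rho": float(summ.loc["iso1_unique", "median_rho"]),
        "n_targeted_peptides": int(summ.loc["iso2_unique", "n_peptides"]),
        "n_nontargeted_peptides": int(summ.loc["iso1_unique", "n_peptides"]),
    }


def proteoform_recovery_rate(
    n_seeds: int = 100, min_separation: float = 0.3, base_seed: int = 0, **kwargs
) -> dict:
    """Fraction of seeds in which the targeted region wins by ``min_separation``."""
    seps = []
    for i in range(n_seeds):
        r = proteoform_recovery(seed=base_seed + i, **kwargs)
        seps.append(r["targeted_median_rho"] - r["nontargeted_median_rho"])
    seps = np.asarray(seps)
    return {
        "n_seeds": n_seeds,
        "success_rate": float(np.mean(seps >= min_separation)),
        "median_separation": float(np.median(seps)),
        "min_separation_observed": float(seps.min()),
    }


# ---------------------------------------------------------------------------
# type-I error calibration of the differential-abundance pathway
# ---------------------------------------------------------------------------

def null_daa_calibration(
    seed: int,
    n_seeds: int = 20,
    n_proteins: int = 500,
    n_samples: int = 88,
    alpha: float = 0.05,
) -> dict:
    """Null simulation (no sex effect): Welch rejection rate and BH FDP.

    The Welch rejection rate at p < alpha is measured on the first seed's
    affinity matrix (complete data, independent noise — a clean null);
    the false discovery proportion of BH at FDR < alpha is averaged over
    ``n_seeds`` independent cohorts.  Every discovery is false by
    construction, so per-seed FDP is 1 if BH rejects anything, else 0.
    """
    rates = []
    fdps = []
    for i in range(n_seeds):
        cohort = synthetic.CohortSpec(
            n_samples=n_samples, n_proteins=n_proteins,
            n_sex_affected=0, sex_effect_log2=0.0,
            n_duplicate_pairs=0, seed=seed + i,
        )
        truth = synthetic.generate_cohort(cohort)
        aff = synthetic.simulate_affinity(
            truth,
            synthetic.AffinityNoiseSpec(lod_quantile=0.0, qc_warning_rate=0.0,
                                        assay_qc_rate=0.0),
            seed=seed + i + 1,
        )
        mat = concordance.npx_matrix(aff)[list(truth.sample_ids)]
        res = daa.run_daa(mat, truth.sex, "affinity", fdr_threshold=alpha)
        rates.append(float((res["p"] < alpha).mean()))
        n_disc = int(res["significant"].sum())
        fdps.append(1.0 if n_disc > 0 else 0.0)
    return {
        "rejection_rate_first_seed": rates[0],
        "mean_rejection_rate": float(np.mean(rates)),
        "mean_fdp": float(np.mean(fdps)),
        "n_seeds": n_seeds,
        "n_tests_per_seed": n_proteins,
    }


# ---------------------------------------------------------------------------
# degradation of cross-platform correlation
# ---------------------------------------------------------------------------

def noise_degradation_curve(
    seed: int,
    noise_grid: tuple[float, ...] = (0.0, 0.2, 0.5, 1.0),
    n_proteins: int = 200,
    n_samples: int = 88,
) -> pd.DataFrame:
    """Median protein-level Spearman rho across an observation-noise grid.

    The same latent cohort is observed at each noise level (applied to both
    platforms symmetrically); missingness and censoring are off so the curve
    isolates observation noise.
    """
    cohort = synthetic.CohortSpec(
        n_samples=n_samples, n_proteins=n_proteins, n_sex_affected=0,
        n_duplicate_pairs=2, seed=seed,
    )
    truth = synthetic.generate_cohort(cohort)
    rows = []
    for noise in noise_grid:
        ms_spec = synthetic.MsNoiseSpec(
            tech_sd_log2=noise, batch_sd_log2=0.0, missing_base_rate=0.0,
            multi_map_rate=0.0, channel_dropout_rate=0.0, psm_per_peptide_mean=0.0,
            psm_offset_sd=0.0 if noise == 0 else 1.0,
        )
        aff_spec = synthetic.AffinityNoiseSpec(
            tech_sd_npx=noise, lod_quantile=0.0, qc_warning_rate=0.0, assay_qc_rate=0.0,
        )
        protein_qm, _, _, _ = synthetic.simulate_ms(truth, ms_spec, seed=seed + 1)
        npx = synthetic.simulate_affinity(truth, aff_spec, seed=seed + 2)
        ms_meta = pd.DataFrame(
            {"protein_id": truth.feature_ids, "gene": truth.gene_of.to_numpy()}
        )
        overlap = ingest.build_overlap(
            ms_meta[ms_meta["protein_id"].isin(protein_qm.feature_ids)],
            npx.drop_duplicates("olink_id")[["olink_id", "uniprot_ids", "gene"]],
        )
        recs = concordance.run_variants(protein_qm, npx, overlap, variants=("full",))
        rows.append(
            {"noise_sd": noise, "median_rho": float(recs["rho"].median()),
             "n_proteins": len(recs)}
        )
    return pd.DataFrame(rows)


def mnar_missingness_slope(
    seed: int,
    n_proteins: int = 200,
    n_samples: int = 88,
) -> dict:
    """Slope of per-protein cross-platform rho on MS missingness under MNAR.

    Generated with abundance-dependent (MNAR) protein-by-set dropout and LOD
    censoring at the generator defaults, so low-abundance proteins carry both
    more missing MS values and noise-floor affinity values; the fitted
    univariable slope is the directionality check.
    """
    cohort = synthetic.CohortSpec(
        n_samples=n_samples, n_proteins=n_proteins, n_sex_affected=0,
        n_duplicate_pairs=2, seed=seed,
    )
    truth = synthetic.generate_cohort(cohort)
    protein_qm, _, psm_table, _ = synthetic.simulate_ms(
        truth, synthetic.MsNoiseSpec(), seed=seed + 1
    )
    npx = synthetic.simulate_affinity(truth, synthetic.AffinityNoiseSpec(), seed=seed + 2)
    ms_meta = pd.DataFrame(
        {"protein_id": truth.feature_ids, "gene": truth.gene_of.to_numpy()}
    )
    overlap = ingest.build_overlap(
        ms_meta[ms_meta["protein_id"].isin(protein_qm.feature_ids)],
        npx.drop_duplicates("olink_id")[["olink_id", "uniprot_ids", "gene"]],
    )
    recs = concordance.run_variants(protein_qm, npx, overlap, variants=("full",))
    table = factors.build_factor_table(recs, protein_qm, psm_table, npx)
    fit = factors.univariable_fit(table["rho"], table["ms_missing_frac"],
                                  name="ms_missing_frac")
    # MNAR structure check: missingness fraction vs latent abundance
    miss_frac = protein_qm.values.isna().mean(axis=1)
    latent_mean = truth.latent.mean(axis=1).reindex(miss_frac.index)
    rho_mnar = concordance.correlate_pair(
        miss_frac.to_numpy(), latent_mean.to_numpy(), "spearman"
    )
    return {
        "slope_rho_on_missingness": fit.slope,
        "slope_p": fit.p,
        "mnar_spearman_missing_vs_abundance": rho_mnar[0] if rho_mnar else float("nan"),
        "n_proteins": fit.n,
    }
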