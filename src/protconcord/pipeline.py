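"""End-to-end orchestration of the synthetic concordance study.

``run_pipeline`` executes simulate -> ingest/match -> precision ->
protein-concordance -> differential abundance -> technical factors ->
peptide-level agreement against one :class:`RunConfig`, writing every stage's
tables under the output directory plus a manifest echoing the resolved
configuration and seed.  Stages are plain functions over the library modules
so the numbered analysis drivers, the CLI and the acceptance script all share
one code path.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import concordance, daa, factors, ingest, peptides, precision, synthetic


class Thresholds(BaseModel):
    min_overlap: int = 8
    min_peptide_samples: int = 15
    fdr: float = 0.05
    cv_cap: float = 100.0


class RunConfig(BaseModel):
    """Resolved configuration of one pipeline run.

    ``cohort``, ``ms_noise`` and ``affinity`` override fields of the
    generator's default specifications; thresholds default to the analysis
    conventions (>=8 overlapping points, >=15 peptide samples, FDR 0.05,
    CV cap 100%).
    """

    outdir: str = "results/pipeline"
    seed: int = 0
    cohort: dict[str, Any] = Field(default_factory=dict)
    ms_noise: dict[str, Any] = Field(default_factory=dict)
    affinity: dict[str, Any] = Field(default_factory=dict)
    thresholds: Thresholds = Field(default_factory=Thresholds)
    include_demo_proteoforms: bool = True
    peptides_per_region: int = 6


@dataclasses.dataclass
class PipelineResult:
    """In-memory handles to everything a run produced."""

    config: RunConfig
    truth: synthetic.TruthTables
    protein_qm: ingest.QuantMatrix
    peptide_qm: ingest.QuantMatrix
    psm_table: pd.DataFrame
    set_layout: dict
    npx: pd.DataFrame
    overlap: ingest.OverlapMap
    cv_ms: pd.DataFrame
    cv_affinity: pd.DataFrame
    records: pd.DataFrame
    daa_ms: pd.DataFrame
    daa_affinity: pd.DataFrame
    concordance_all: daa.ConcordanceSummary
    concordance_complete: daa.ConcordanceSummary
    factor_fits: pd.DataFrame
    factor_table: pd.DataFrame
    peptide_corr: pd.DataFrame
    placed: pd.DataFrame
    region_summaries: pd.DataFrame


def simulate_stage(cfg: RunConfig):
    spec = synthetic.CohortSpec(**{"seed": cfg.seed, **cfg.cohort})
    demo = synthetic.demo_proteoforms(seed=cfg.seed + 101) if cfg.include_demo_proteoforms else []
    truth = synthetic.generate_cohort(spec, proteoforms=demo)
    ms_spec = synthetic.MsNoiseSpec(**cfg.ms_noise)
    aff_spec = synthetic.AffinityNoiseSpec(**cfg.affinity)
    design = synthetic.generate_peptides(
        truth.proteoforms.values(),
        peptides_per_region=cfg.peptides_per_region,
        seed=cfg.seed + 202,
    )
    protein_qm, peptide_qm, psm_table, layout = synthetic.simulate_ms(
        truth, ms_spec, peptide_design=design, seed=cfg.seed + 1
    )
    npx = synthetic.simulate_affinity(truth, aff_spec, seed=cfg.seed + 2)
    return truth, protein_qm, peptide_qm, psm_table, layout, npx


def run_pipeline(cfg: RunConfig, write: bool = True) -> PipelineResult:
    out = Path(cfg.outdir)
    if write:
        out.mkdir(parents=True, exist_ok=True)

    truth, protein_qm, peptide_qm, psm_table, layout, npx = simulate_stage(cfg)

    ms_meta = pd.DataFrame(
        {"protein_id": truth.feature_ids, "gene": truth.gene_of.to_numpy()}
    )
    ms_detected = ms_meta[ms_meta["protein_id"].isin(protein_qm.feature_ids)]
    assays = npx.drop_duplicates("olink_id")[["olink_id", "uniprot_ids", "gene"]]
    overlap = ingest.build_overlap(ms_detected, assays)

    # precision: MS inter-set duplicate pairs; affinity intra-plate control pair
    cv_ms = precision.cv_table(
        protein_qm.values, truth.duplicate_pairs, "ms", cap=cfg.thresholds.cv_cap
    )
    aff_mat = concordance.npx_matrix(npx)
    control_cols = [c for c in aff_mat.columns if str(c).startswith("CONTROL_")]
    cv_aff = precision.cv_table(
        aff_mat, [(control_cols[0], control_cols[1])], "affinity",
        cap=cfg.thresholds.cv_cap,
    ) if len(control_cols) >= 2 else pd.DataFrame(columns=["platform", "n_pairs", "cv_percent"])

    records = concordance.run_variants(
        protein_qm, npx, overlap, min_overlap=cfg.thresholds.min_overlap
    )
    iso_records = concordance.isoform_correlations(protein_qm, npx, overlap)

    # differential abundance on the shared cohort
    samples = concordance.shared_samples(protein_qm, aff_mat)
    daa_ms = daa.run_daa(
        protein_qm.values[samples], truth.sex, "ms", cfg.thresholds.fdr
    )
    # key affinity results by matched MS protein for cross-platform joins
    assay_to_ms = records[records["variant"] == "full"].set_index("olink_id")["ms_id"]
    aff_vals = aff_mat.loc[aff_mat.index.isin(assay_to_ms.index), samples]
    daa_aff = daa.run_daa(aff_vals, truth.sex, "affinity", cfg.thresholds.fdr)
    daa_aff.index = daa_aff.index.map(assay_to_ms)

    conc_all = daa.concordance(daa_ms, daa_aff, scope="significant_any")
    complete_ids = records.loc[records["variant"] == "complete", "ms_id"].unique()
    try:
        conc_complete = daa.concordance(
            daa_ms, daa_aff, scope="significant_any", restrict_to=complete_ids
        )
    except ValueError:
        conc_complete = conc_all

    factor_table = factors.build_factor_table(
        records, protein_qm, psm_table, npx,
        cv_ms=cv_ms, cv_affinity=cv_aff,
        conc_log10=truth.latent.mean(axis=1) / synthetic.LOG2_10,
        proteoforms=truth.proteoforms,
        shared_samples=samples,
    )
    usable = [c for c in factors.DEFAULT_FACTORS if c in factor_table.columns]
    factor_fits = factors.fit_factors(
        factor_table, y_col="rho", factor_cols=usable,
        log10_cols=("median_psms", "median_unique_peptides"),
    )

    pep_corr = peptides.peptide_correlations(
        peptide_qm, npx, min_samples=cfg.thresholds.min_peptide_samples
    )
    fasta_genes = {
        g: dict(pf.isoform_sequences) for g, pf in truth.proteoforms.items()
    }
    placed = peptides.locate_peptides(pep_corr, fasta_genes)
    regions = pd.DataFrame(
        [
            {"gene": pf.gene, "region": name, "isoform_id": iso, "start": s, "end": e}
            for pf in truth.proteoforms.values()
            for name, iso, s, e in pf.region_map
            if len(pf.isoform_sequences) > 1 or len(pf.region_map) > 1
        ]
    )
    region_summaries = (
        peptides.summarize_regions(placed, regions) if len(regions) else pd.DataFrame()
    )

    result = PipelineResult(
        config=cfg, truth=truth, protein_qm=protein_qm, peptide_qm=peptide_qm,
        psm_table=psm_table, set_layout=layout, npx=npx, overlap=overlap,
        cv_ms=cv_ms, cv_affinity=cv_aff, records=records,
        daa_ms=daa_ms, daa_affinity=daa_aff,
        concordance_all=conc_all, concordance_complete=conc_complete,
        factor_fits=factor_fits, factor_table=factor_table,
        peptide_corr=pep_corr, placed=placed, region_summaries=region_summaries,
    )

    if write:
        ingest.write_quant(protein_qm, out / "ms_protein_quant.tsv")
        ingest.write_quant(peptide_qm, out / "ms_peptide_quant.tsv")
        ingest.write_npx(npx, out / "npx.csv")
        synthetic.write_fasta(truth.proteoforms.values(), out / "proteome.fasta")
        synthetic.write_truth(truth, out / "truth")
        overlap.pairs.to_csv(out / "overlap_pairs.tsv", sep="\t", index=False)
        cv_ms.to_csv(out / "cv_ms.tsv", sep="\t")
        cv_aff.to_csv(out / "cv_affinity.tsv", sep="\t")
        records.to_csv(out / "correlation_records.tsv", sep="\t", index=False)
        iso_records.to_csv(out / "isoform_correlations.tsv", sep="\t", index=False)
        daa_ms.to_csv(out / "daa_ms.tsv", sep="\t")
        daa_aff.to_csv(out / "daa_affinity.tsv", sep="\t")
        with (out / "concordance.json").open("w") as fh:
            json.dump(
                {"overlap_all": conc_all.to_dict(),
                 "overlap_complete": conc_complete.to_dict()},
                fh, indent=2, default=float,
            )
        factor_table.to_csv(out / "factor_table.tsv", sep="\t")
        factor_fits.to_csv(out / "factor_fits.tsv", sep="\t")
        pep_corr.to_csv(out / "peptide_correlations.tsv", sep="\t", index=False)
        placed.to_csv(out / "peptide_placements.tsv", sep="\t", index=False)
        if len(region_summaries):
            region_summaries.to_csv(out / "region_summaries.tsv", sep="\t", index=False)
        synthetic.write_manifest(
            out / "manifest.json",
            config=json.loads(cfg.model_dump_json()),
            cohort_spec=synthetic.CohortSpec(**{"seed": cfg.seed, **cfg.cohort}),
            ms_noise_spec=synthetic.MsNoiseSpec(**cfg.ms_noise),
            affinity_noise_spec=synthetic.AffinityNoiseSpec(**cfg.affinity),
        )
    return result


def summary_quantities(res: PipelineResult) -> dict[str, dict]:
    """The run's headline quantities as ``{name: {"value", "n"}}``."""
    full = res.records[res.records["variant"] == "full"]
    clean = res.records[res.records["variant"] == "clean"]
    complete = res.records[res.records["variant"] == "complete"]
    q = {}

    def put(name, value, n):
        q[name] = {"value": float(np.round(value, 4)), "n": int(n)}

    put("n_overlapping_proteins", len(res.overlap.pairs), len(res.overlap.pairs))
    put("median_rho_full", full["rho"].median(), len(full))
    put("iqr_low_rho_full", full["rho"].quantile(0.25), len(full))
    put("iqr_high_rho_full", full["rho"].quantile(0.75), len(full))
    put("median_rho_clean", clean["rho"].median(), len(clean))
    put("median_rho_complete", complete["rho"].median(), len(complete))
    frac_mod_strong = float(full["category"].isin(["moderate", "strong"]).mean()) * 100
    put("pct_moderate_or_strong_full", frac_mod_strong, len(full))
    put("median_cv_ms_percent", res.cv_ms["cv_percent"].median(),
        res.cv_ms["cv_percent"].notna().sum())
    if len(res.cv_affinity):
        put("median_cv_affinity_percent", res.cv_affinity["cv_percent"].median(),
            res.cv_affinity["cv_percent"].notna().sum())
    c = res.concordance_all
    put("n_dap_ms", c.n_sig_ms, c.n_tested)
    put("n_dap_affinity", c.n_sig_affinity, c.n_tested)
    put("n_dap_both", c.n_sig_both, c.n_tested)
    put("directional_agreement_percent", c.directional_agreement_percent, c.n_tested)
    put("fc_correlation_R", c.fc_correlation, c.n_tested)
    if len(res.region_summaries):
        tgt = res.region_summaries.set_index(["gene", "region"])
        if ("GMASPX", "iso2_unique") in tgt.index:
            put("targeted_region_median_rho",
                tgt.loc[("GMASPX", "iso2_unique"), "median_rho"],
                tgt.loc[("GMASPX", "iso2_unique"), "n_peptides"])
            put("nontargeted_region_median_rho",
                tgt.loc[("GMASPX", "iso1_unique"), "median_rho"],
                tgt.loc[("GMASPX", "iso1_unique"), "n_peptides"])
    if "ms_missing_frac" in res.factor_fits.index:
        fit = res.factor_fits.loc["ms_missing_frac"]
        put("missingness_slope", fit["slope"], fit["n"])
    return q
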