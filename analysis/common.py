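"""Shared loading helpers for the numbered analysis drivers."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from protconcord import ingest

DATA = Path("results/data")
RESULTS = Path("results")


def load_dataset():
    """Read the simulated dual-platform dataset written by 01_simulate_cohort."""
    protein_qm = ingest.read_quant(DATA / "ms_protein_quant.tsv")
    peptide_qm = ingest.read_quant(DATA / "ms_peptide_quant.tsv")
    meta = pd.read_csv(DATA / "ms_peptide_meta.tsv", sep="\t", index_col=0)
    peptide_qm.feature_meta = meta.reindex(peptide_qm.feature_ids)
    npx = ingest.read_npx(DATA / "npx.csv")
    sex = pd.read_csv(DATA / "truth" / "sex_labels.tsv", sep="\t", index_col=0)["sex"]
    gene_of = pd.read_csv(DATA / "truth" / "gene_map.tsv", sep="\t", index_col=0)["gene"]
    dup = pd.read_csv(DATA / "truth" / "duplicate_pairs.tsv", sep="\t")
    duplicate_pairs = list(dup.itertuples(index=False, name=None))
    latent = pd.read_csv(DATA / "truth" / "latent_log2.tsv", sep="\t", index_col=0)
    return dict(
        protein_qm=protein_qm, peptide_qm=peptide_qm, npx=npx, sex=sex,
        gene_of=gene_of, duplicate_pairs=duplicate_pairs, latent=latent,
    )


def build_overlap(data) -> ingest.OverlapMap:
    ms = pd.DataFrame(
        {"protein_id": data["gene_of"].index, "gene": data["gene_of"].to_numpy()}
    )
    ms = ms[ms["protein_id"].isin(data["protein_qm"].feature_ids)]
    assays = data["npx"].drop_duplicates("olink_id")[["olink_id", "uniprot_ids", "gene"]]
    return ingest.build_overlap(ms, assays)
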