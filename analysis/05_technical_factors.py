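"""Which technical factors drive cross-platform agreement?

Builds the per-protein factor table (missingness, below-LOD fraction, PSM
and unique-peptide depth, sequence coverage, precursor mass error, CVs, NPX
margin above LOD, QC warnings, panel version, protein properties, estimated
concentration) and fits univariable OLS of the full-variant Spearman rho on
each factor, BH-adjusted.  Writes factor_table.tsv and factor_fits.tsv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

import pandas as pd

from common import RESULTS, build_overlap, load_dataset
from protconcord import concordance, factors, precision, synthetic


def main() -> None:
    data = load_dataset()
    overlap = build_overlap(data)
    protein_qm, npx = data["protein_qm"], data["npx"]
    psm_table = pd.read_csv("results/data/psm_table.tsv", sep="\t")

    records = concordance.run_variants(protein_qm, npx, overlap)
    cv_ms = precision.cv_table(protein_qm.values, data["duplicate_pairs"], "ms")
    mat = concordance.npx_matrix(npx)
    controls = [c for c in mat.columns if str(c).startswith("CONTROL_")]
    cv_aff = precision.cv_table(mat, [(controls[0], controls[1])], "affinity")

    conc_log10 = data["latent"].mean(axis=1) / synthetic.LOG2_10
    table = factors.build_factor_table(
        records, protein_qm, psm_table, npx,
        cv_ms=cv_ms, cv_affinity=cv_aff, conc_log10=conc_log10,
    )
    usable = [c for c in factors.DEFAULT_FACTORS if c in table.columns]
    fits = factors.fit_factors(table, factor_cols=usable,
                               log10_cols=("median_psms", "median_unique_peptides"))
    table.to_csv(RESULTS / "factor_table.tsv", sep="\t")
    fits.to_csv(RESULTS / "factor_fits.tsv", sep="\t")

    tested = fits[fits["testable"].fillna(False)].sort_values("adj_r2",
                                                              ascending=False)
    print("univariable fits of cross-platform rho (top by variance explained):")
    for factor, row in tested.head(6).iterrows():
        sig = "*" if row["fdr"] < 0.05 else " "
        print(f"  {factor:24s} slope {row['slope']:+.3f}  "
              f"adjR2 {row['adj_r2']:.2f}  FDR {row['fdr']:.2g} {sig}")

    ranks = factors.rank_sum_by_group(
        table.assign(qc_warned=table["assay_qc_warn"].astype(bool)),
        "rho", ["panel_version", "qc_warned"],
    )
    ranks.to_csv(RESULTS / "factor_rank_sums.tsv", sep="\t")
    print("rank-sum comparisons (rho by group):")
    print(ranks[["median_low", "median_high", "p", "fdr"]].round(3).to_string())


if __name__ == "__main__":
    main()
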