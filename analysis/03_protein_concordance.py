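"""Protein-level cross-platform correlation under the three dataset variants.

Correlates every matched protein between the MS and affinity platforms
(Spearman + Pearson, pairwise-complete, >= 8 overlapping points), under the
full / clean / complete variants, bins the correlations into the standard
categories, resolves isoform-level correlations for multi-proteoform genes,
and aligns the estimates with a synthetic external study stratified into
confidence tiers.  Writes correlation_records.tsv, isoform_correlations.tsv
and external_alignment tables under results/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

import numpy as np
import pandas as pd

from common import RESULTS, build_overlap, load_dataset
from protconcord import concordance


def main() -> None:
    data = load_dataset()
    overlap = build_overlap(data)
    records = concordance.run_variants(data["protein_qm"], data["npx"], overlap)
    records.to_csv(RESULTS / "correlation_records.tsv", sep="\t", index=False)

    iso = concordance.isoform_correlations(data["protein_qm"], data["npx"], overlap)
    iso.to_csv(RESULTS / "isoform_correlations.tsv", sep="\t", index=False)

    for variant in ("full", "clean", "complete"):
        sub = records[records["variant"] == variant]
        q1, q3 = sub["rho"].quantile([0.25, 0.75])
        cats = sub["category"].value_counts(normalize=True)
        print(f"{variant:9s}: N={len(sub):4d}  median rho={sub['rho'].median():.2f} "
              f"(IQR {q1:.2f}-{q3:.2f}); moderate+strong "
              f"{cats.get('moderate', 0) + cats.get('strong', 0):.0%}")

    best = iso[iso["best_isoform"] & (iso["gene"] == "GMASPX")]
    if len(best):
        print(f"isoform resolution: GMASPX assay agrees best with "
              f"{best.iloc[0]['ms_id']} (rho={best.iloc[0]['rho']:.2f}), "
              "matching the generator's isoform-2 targeting")

    # synthetic external study: own correlations + study-level noise, tiered
    rng = np.random.default_rng(404)
    full = records[records["variant"] == "full"]
    ext = pd.DataFrame(
        {
            "study": "external-panel-study",
            "uniprot": full["ms_id"].to_numpy(),
            "gene": full["gene"].to_numpy(),
            "corr": np.clip(full["rho"].to_numpy()
                            + rng.normal(0, 0.15, len(full)), -1, 1),
        }
    )
    ext["tier"] = np.where(ext["corr"] > 0.5, 1,
                           np.where(rng.random(len(ext)) < 0.5, 2, 3))
    joined, tier_medians = concordance.align_external(records, ext)
    joined.to_csv(RESULTS / "external_alignment.tsv", sep="\t", index=False)
    tier_medians.to_csv(RESULTS / "external_tier_medians.tsv", sep="\t")
    print("per-tier median rho (own vs external):")
    for (study, tier), row in tier_medians.iterrows():
        print(f"  tier {tier}: {row['median_own_rho']:.2f} vs "
              f"{row['median_external_corr']:.2f} (n={int(row['n_proteins'])})")


if __name__ == "__main__":
    main()
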