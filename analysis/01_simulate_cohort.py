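"""Simulate the dual-platform plasma cohort at the default study conditions.

88 samples (42% female), 500 proteins spanning ten orders of magnitude of
blood concentration plus two multi-proteoform demo genes, six MS duplicate
aliquot pairs across TMT sets, one affinity control pair, MNAR
protein-by-set dropout and LOD noise-floor censoring.  Writes the platform
data files and the ground-truth tables under results/data/.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

from protconcord import ingest, synthetic
from protconcord.pipeline import RunConfig, simulate_stage

SEED = 20250927
OUT = Path("results/data")


def main() -> None:
    cfg = RunConfig(outdir=str(OUT), seed=SEED)
    truth, protein_qm, peptide_qm, psm_table, layout, npx = simulate_stage(cfg)
    OUT.mkdir(parents=True, exist_ok=True)

    ingest.write_quant(protein_qm, OUT / "ms_protein_quant.tsv")
    ingest.write_quant(peptide_qm, OUT / "ms_peptide_quant.tsv")
    peptide_qm.feature_meta.to_csv(OUT / "ms_peptide_meta.tsv", sep="\t")
    psm_table.to_csv(OUT / "psm_table.tsv", sep="\t", index=False)
    ingest.write_npx(npx, OUT / "npx.csv")
    synthetic.write_fasta(truth.proteoforms.values(), OUT / "proteome.fasta")
    synthetic.write_truth(truth, OUT / "truth")
    (OUT / "set_layout.json").write_text(json.dumps(layout, indent=2))
    synthetic.write_manifest(
        OUT / "manifest.json",
        config=json.loads(cfg.model_dump_json()),
        cohort_spec=synthetic.CohortSpec(seed=SEED),
        ms_noise_spec=synthetic.MsNoiseSpec(),
        affinity_noise_spec=synthetic.AffinityNoiseSpec(),
    )

    n_ms = protein_qm.n_features
    n_assays = npx["olink_id"].nunique()
    any_missing = protein_qm.values.isna().any(axis=1).mean()
    any_lod = npx.groupby("olink_id")["below_lod"].any().mean()
    print(f"wrote {OUT}/: {n_ms} MS protein groups, {n_assays} affinity assays, "
          f"{peptide_qm.n_features} peptides")
    print(f"  MS proteins with >=1 missing value: {any_missing:.0%}; "
          f"assays with >=1 below-LOD value: {any_lod:.0%}")
    print(f"  duplicate pairs: {truth.duplicate_pairs}")


if __name__ == "__main__":
    main()
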