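"""Generator contracts: determinism, latent-layer truth, MNAR structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from protconcord import synthetic
from protconcord.synthetic import (
    AffinityNoiseSpec, CohortSpec, InvalidSpecError, MsNoiseSpec, ProteoformSpec,
)


def test_identical_seed_gives_identical_outputs():
    spec = CohortSpec(n_samples=30, n_proteins=40, n_sex_affected=8, seed=42)
    demo = synthetic.demo_proteoforms(seed=9)
    t1 = synthetic.generate_cohort(spec, proteoforms=demo)
    t2 = synthetic.generate_cohort(spec, proteoforms=demo)
    pd.testing.assert_frame_equal(t1.latent, t2.latent)
    pd.testing.assert_series_equal(t1.sex, t2.sex)
    p1 = synthetic.simulate_ms(t1, MsNoiseSpec(n_tmt_sets=4), seed=7)
    p2 = synthetic.simulate_ms(t2, MsNoiseSpec(n_tmt_sets=4), seed=7)
    pd.testing.assert_frame_equal(p1[0].values, p2[0].values)
    pd.testing.assert_frame_equal(p1[2], p2[2])
    a1 = synthetic.simulate_affinity(t1, AffinityNoiseSpec(), seed=8)
    a2 = synthetic.simulate_affinity(t2, AffinityNoiseSpec(), seed=8)
    pd.testing.assert_frame_equal(a1, a2)


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(n_samples=0),
        dict(n_proteins=-1),
        dict(frac_female=1.5),
        dict(n_sex_affected=1000),
        dict(biological_sd_log2=-0.1),
        dict(conc_log10_range=(3.0, -3.0)),
        dict(n_duplicate_pairs=99),
    ],
)
def test_invalid_cohort_specs_rejected(kwargs):
    with pytest.raises(InvalidSpecError):
        CohortSpec(**kwargs)


def test_sex_labels_match_requested_fraction():
    truth = synthetic.generate_cohort(CohortSpec(n_samples=88, n_proteins=10, n_sex_affected=2, seed=1))
    assert (truth.sex == "F").sum() == round(37 / 88 * 88)


def test_noise_free_latent_group_difference_is_exact():
    spec = CohortSpec(n_samples=40, n_proteins=50, biological_sd_log2=0.0,
                      sex_effect_log2=1.0, n_sex_affected=20, seed=3)
    truth = synthetic.generate_cohort(spec)
    f = truth.sex[truth.sex == "F"].index
    m = truth.sex[truth.sex == "M"].index
    diffs = truth.latent[f].mean(axis=1) - truth.latent[m].mean(axis=1)
    affected = truth.effects
    assert np.allclose(diffs.loc[affected.index], affected, atol=1e-12)
    unaffected = diffs.drop(affected.index)
    assert np.allclose(unaffected, 0.0, atol=1e-12)


def test_null_sex_effect_latent_rejection_rate_is_nominal():
    spec = CohortSpec(n_samples=88, n_proteins=400, sex_effect_log2=0.0,
                      n_sex_affected=0, seed=17)
    truth = synthetic.generate_cohort(spec)
    f = truth.sex[truth.sex == "F"].index
    m = truth.sex[truth.sex == "M"].index
    p = stats.ttest_ind(truth.latent[f], truth.latent[m], axis=1, equal_var=False).pvalue
    rate = (p < 0.05).mean()
    ci = 2.576 * np.sqrt(0.05 * 0.95 / 400)
    assert abs(rate - 0.05) < ci


def test_duplicate_aliquots_share_latent_and_land_in_different_sets():
    spec = CohortSpec(n_samples=40, n_proteins=30, n_sex_affected=5, n_duplicate_pairs=4, seed=2)
    truth = synthetic.generate_cohort(spec)
    _, _, _, layout = synthetic.simulate_ms(truth, MsNoiseSpec(n_tmt_sets=4), seed=3)
    set_of = {m: s for s, ms in layout.items() for m in ms}
    for a, b in truth.duplicate_pairs:
        assert set_of[a] != set_of[b]
        # aliquots are the same latent sample by construction
        assert b == f"{a}_B"


def test_duplicate_observed_differences_have_sqrt2_tech_sd():
    spec = CohortSpec(n_samples=30, n_proteins=400, n_duplicate_pairs=6,
                      biological_sd_log2=0.5, seed=4)
    truth = synthetic.generate_cohort(spec)
    ms_spec = MsNoiseSpec(n_tmt_sets=4, batch_sd_log2=0.0, tech_sd_log2=0.1,
                          missing_base_rate=0.0, psm_per_peptide_mean=0.0,
                          peptides_per_protein_mean=0.0,
                          multi_map_rate=0.0, channel_dropout_rate=0.0)
    qm, _, _, _ = synthetic.simulate_ms(truth, ms_spec, seed=5)
    diffs = np.concatenate(
        [(qm.values[a] - qm.values[b]).dropna().to_numpy()
         for a, b in truth.duplicate_pairs]
    )
    assert abs(diffs.mean()) < 0.02
    assert np.isclose(diffs.std(), 0.1 * np.sqrt(2), rtol=0.10)


def test_mnar_missingness_decreases_with_abundance_deciles():
    spec = CohortSpec(n_samples=30, n_proteins=300, seed=6)
    truth = synthetic.generate_cohort(spec)
    ms_spec = MsNoiseSpec(n_tmt_sets=4, missing_base_rate=0.3,
                          missing_abundance_slope=1.5)
    qm, _, _, _ = synthetic.simulate_ms(truth, ms_spec, seed=7)
    miss = qm.values.reindex(truth.feature_ids).isna().mean(axis=1)
    abundance = truth.latent.mean(axis=1)
    deciles = pd.qcut(abundance, 10, labels=False)
    per_decile = miss.groupby(deciles).mean()
    # overall trend: top-decile proteins far less missing, negative rank corr
    rho = stats.spearmanr(per_decile.index, per_decile.to_numpy()).statistic
    assert rho < -0.8
    assert per_decile.iloc[0] > per_decile.iloc[-1]


def test_noise_free_ms_matrix_equals_centered_latent():
    spec = CohortSpec(n_samples=20, n_proteins=60, n_duplicate_pairs=0,
                      biological_sd_log2=0.4, seed=8)
    truth = synthetic.generate_cohort(spec)
    ms_spec = MsNoiseSpec(n_tmt_sets=2, set_size=12, batch_sd_log2=0.0,
                          tech_sd_log2=0.0, missing_base_rate=0.0,
                          psm_offset_sd=0.0, multi_map_rate=0.0,
                          channel_dropout_rate=0.0)
    qm, _, _, _ = synthetic.simulate_ms(truth, ms_spec, seed=9)
    # oracle: latent minus the global per-protein pool median, median-centered per sample
    expected = truth.latent.sub(truth.latent.median(axis=1), axis=0)
    expected = expected.sub(expected.median(axis=0), axis=1)
    got = qm.values.reindex(index=expected.index, columns=expected.columns)
    assert np.allclose(got, expected, atol=1e-10)


class TestAffinity:
    def test_zero_lod_quantile_gives_no_flags(self):
        truth = synthetic.generate_cohort(CohortSpec(n_samples=20, n_proteins=30, n_sex_affected=5, seed=1))
        npx = synthetic.simulate_affinity(truth, AffinityNoiseSpec(lod_quantile=0.0), seed=2)
        assert not npx["below_lod"].any()

    def test_noise_free_npx_equals_latent(self):
        truth = synthetic.generate_cohort(CohortSpec(n_samples=20, n_proteins=30, n_sex_affected=5, seed=1))
        spec = AffinityNoiseSpec(tech_sd_npx=0.0, lod_quantile=0.0,
                                 qc_warning_rate=0.0, assay_qc_rate=0.0,
                                 assay_offset_sd=0.0)
        npx = synthetic.simulate_affinity(truth, spec, seed=2)
        mat = npx.pivot(index="olink_id", columns="sample_id", values="npx")
        gene_assay = npx.drop_duplicates("olink_id").set_index("olink_id")["uniprot_ids"]
        for oid, uid in gene_assay.items():
            got = mat.loc[oid, truth.sample_ids].to_numpy(dtype=float)
            assert np.array_equal(got, truth.latent.loc[uid].to_numpy())

    def test_below_lod_flag_is_consistent_and_censored_at_noise_floor(self):
        truth = synthetic.generate_cohort(CohortSpec(n_samples=40, n_proteins=200, n_sex_affected=20, seed=3))
        npx = synthetic.simulate_affinity(truth, AffinityNoiseSpec(lod_quantile=0.3), seed=4)
        assert ((npx["npx"] < npx["lod"]) == npx["below_lod"]).all()
        flagged = npx[npx["below_lod"]]
        assert len(flagged) > 0
        # the noise floor hugs the LOD from below
        assert ((flagged["lod"] - flagged["npx"]) < 5.0).all()

    def test_assay_targets_select_the_measured_isoform(self):
        # assay weights (1, 0) on a two-isoform gene: NPX tracks isoform 1
        demo = synthetic.demo_proteoforms(seed=11)
        pf = demo[1]  # GAMBPX targets its first proteoform
        truth = synthetic.generate_cohort(
            CohortSpec(n_samples=88, n_proteins=10, n_sex_affected=0, seed=12), proteoforms=[pf]
        )
        npx = synthetic.simulate_affinity(
            truth, AffinityNoiseSpec(tech_sd_npx=0.3, lod_quantile=0.0), seed=13
        )
        assay = npx[npx["gene"] == pf.gene].set_index("sample_id")["npx"]
        vals = assay.loc[truth.sample_ids].to_numpy(dtype=float)
        rho1 = stats.spearmanr(vals, truth.latent.loc["P90002"]).statistic
        rho2 = stats.spearmanr(vals, truth.latent.loc["P90002-2"]).statistic
        assert rho1 - rho2 >= 0.3


class TestGeneratePeptides:
    def test_peptides_lie_inside_their_region_and_sequence(self):
        demo = synthetic.demo_proteoforms(seed=20)
        design = synthetic.generate_peptides(demo, peptides_per_region=8,
                                             length_range=(8, 12), seed=21)
        seqs = {iso: seq for pf in demo for iso, seq in pf.isoform_sequences}
        regions = {(pf.gene, name): (iso, s, e)
                   for pf in demo for name, iso, s, e in pf.region_map}
        for _, row in design.iterrows():
            iso, rs, re_ = regions[(row["gene"], row["region"])]
            assert rs <= row["start"] <= row["end"] <= re_
            assert 8 <= row["end"] - row["start"] + 1 <= 12
            assert seqs[iso][row["start"] - 1:row["end"]] == row["peptide"]

    def test_zero_peptides_per_region_gives_empty_table(self):
        demo = synthetic.demo_proteoforms(seed=20)
        design = synthetic.generate_peptides(demo, peptides_per_region=0)
        assert len(design) == 0

    def test_short_region_skipped_with_warning(self):
        pf = ProteoformSpec(
            gene="GX", isoform_sequences=(("PX", "ACDEFGHIKLMNPQRSTVWY"),),
            region_map=(("tiny", "PX", 1, 4), ("ok", "PX", 1, 20)),
            assay_targets=(1.0,),
        )
        with pytest.warns(UserWarning, match="tiny"):
            design = synthetic.generate_peptides([pf], peptides_per_region=3,
                                                 length_range=(8, 10), seed=1)
        assert set(design["region"]) == {"ok"}

    def test_tryptic_option_ends_on_k_or_r_when_available(self):
        seq = "AAAKAAARAAAKAAARAAAKAAARAAAKAAAR"
        pf = ProteoformSpec(
            gene="GT", isoform_sequences=(("PT", seq),),
            region_map=(("full", "PT", 1, len(seq)),), assay_targets=(1.0,),
        )
        design = synthetic.generate_peptides([pf], peptides_per_region=10,
                                             length_range=(6, 10), seed=2, tryptic=True)
        ends_kr = [seq[e - 1] in "KR" for e in design["end"]]
        assert np.mean(ends_kr) > 0.5


def test_ms_capacity_validation():
    truth = synthetic.generate_cohort(CohortSpec(n_samples=50, n_proteins=10, n_sex_affected=0, seed=1))
    with pytest.raises(InvalidSpecError, match="capacity"):
        synthetic.simulate_ms(truth, MsNoiseSpec(n_tmt_sets=2, set_size=10), seed=2)
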