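"""Protein-level correlation: filters, categories, variants, isoforms, externals."""

import numpy as np
import pandas as pd
import pytest

from protconcord import concordance, synthetic
from protconcord.concordance import (
    align_external, categorize, correlate_pair, isoform_correlations, run_variants,
)
from protconcord.pipeline import RunConfig, run_pipeline

from oracles import brute_pearson, brute_spearman


class TestCorrelatePair:
    def test_perfect_positive_and_negative(self):
        x = np.arange(10, dtype=float)
        rho, n = correlate_pair(x, x, "spearman")
        assert rho == pytest.approx(1.0, abs=1e-12) and n == 10
        assert correlate_pair(x, 2 * x + 3, "pearson")[0] == pytest.approx(1.0)
        assert correlate_pair(x, -x, "spearman")[0] == pytest.approx(-1.0, abs=1e-12)

    def test_fewer_than_eight_overlapping_points_excluded(self):
        x = np.arange(10, dtype=float)
        y = x.copy()
        y[:3] = np.nan  # 7 overlapping points
        assert correlate_pair(x, y) is None
        y[2] = 2.0      # 8 points: eligible again
        assert correlate_pair(x, y) is not None

    def test_zero_variance_excluded(self):
        x = np.ones(10)
        y = np.arange(10, dtype=float)
        assert correlate_pair(x, y) is None
        assert correlate_pair(y, x) is None

    @pytest.mark.parametrize("trial", range(30))
    def test_matches_longhand_formulas_with_ties(self, trial):
        rng = np.random.default_rng(300 + trial)
        n = 20
        x = rng.integers(0, 6, size=n).astype(float)  # heavy ties
        y = rng.normal(size=n) + x
        rho, _ = correlate_pair(x, y, "spearman")
        r, _ = correlate_pair(x, y, "pearson")
        assert rho == pytest.approx(brute_spearman(x, y), abs=1e-12)
        assert r == pytest.approx(brute_pearson(x, y), abs=1e-12)

    def test_spearman_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=50)
        y = rng.normal(size=50) + 0.5 * x
        base = correlate_pair(x, y, "spearman")[0]
        assert correlate_pair(np.exp(x), y, "spearman")[0] == pytest.approx(base)
        assert correlate_pair(x, y**3 + 10 * y, "spearman")[0] == pytest.approx(base)


class TestCategorize:
    @pytest.mark.parametrize(
        "rho,expected",
        [(0.5, "moderate"), (1.0, "strong"), (0.299999, "none"), (0.3, "weak"),
         (0.7, "strong"), (-1.0, "none"), (0.69999, "moderate")],
    )
    def test_bin_boundaries(self, rho, expected):
        assert categorize(rho) == expected

    def test_nan_has_no_category(self):
        assert categorize(float("nan")) is None

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            categorize(1.5)


class TestVariants:
    def test_variant_sets_are_nested(self, small_result):
        recs = small_result.records
        by = {v: set(recs.loc[recs["variant"] == v, "ms_id"]) for v in
              ("full", "clean", "complete")}
        assert by["complete"] <= by["clean"] <= by["full"]

    def test_complete_membership_equals_brute_force_scan(self, small_result):
        res = small_result
        recs = res.records
        complete_ids = set(recs.loc[recs["variant"] == "complete", "ms_id"])
        full_m = concordance.npx_matrix(res.npx)
        samples = concordance.shared_samples(res.protein_qm, full_m)
        flags = res.npx.set_index(["olink_id", "sample_id"])[
            ["below_lod", "sample_qc_warn", "assay_qc_warn"]
        ].any(axis=1).unstack("sample_id")
        brute = set()
        for _, pair in res.overlap.pairs.iterrows():
            pid, oid = pair["ms_id"], pair["olink_id"]
            if pid not in res.protein_qm.values.index or oid not in full_m.index:
                continue
            x = res.protein_qm.values.loc[pid, samples]
            y = full_m.loc[oid, samples]
            f = flags.loc[oid, samples]
            if not x.isna().any() and not y.isna().any() and not f.any():
                if x.nunique() > 1 and y.nunique() > 1:
                    brute.add(pid)
        assert complete_ids == brute

    def test_noise_free_data_gives_rho_one_in_all_variants(self, noise_free_result):
        recs = noise_free_result.records
        assert len(recs) > 0
        assert (recs["rho"] == 1.0).all()
        assert (recs["category"] == "strong").all()

    def test_clean_variant_median_improves_by_dropping_censored_proteins(self):
        # heavily below-LOD proteins correlate poorly in the full variant and
        # lose eligibility (<8 points) once censored values are masked, so the
        # clean variant's median over its surviving records is at least the
        # full variant's median — the cohort-level improvement seen in
        # practice; masking is not a paired per-protein gain, because removing
        # the noise-floor points also restricts the biological range
        cfg = RunConfig(
            outdir="unused", seed=21,
            cohort=dict(n_proteins=200, n_sex_affected=0),
            affinity=dict(lod_quantile=0.3),
            include_demo_proteoforms=False,
        )
        res = run_pipeline(cfg, write=False)
        recs = res.records
        full = recs[recs["variant"] == "full"]
        clean = recs[recs["variant"] == "clean"]
        assert len(full) >= 100
        assert len(clean) < len(full)  # censored proteins dropped
        assert clean["rho"].median() >= full["rho"].median()
        # the dropped proteins are indeed the poorly correlating ones
        dropped = set(full["ms_id"]) - set(clean["ms_id"])
        assert full[full["ms_id"].isin(dropped)]["rho"].median() < full["rho"].median()


class TestIsoforms:
    def test_assay_targeted_isoform_ranks_first(self, small_result):
        iso = small_result.isoform_records if hasattr(small_result, "isoform_records") \
            else isoform_correlations(small_result.protein_qm, small_result.npx,
                                      small_result.overlap)
        gm = iso[iso["gene"] == "GMASPX"]
        assert len(gm) == 2
        best = gm[gm["best_isoform"]].iloc[0]
        assert best["ms_id"] == "P90001-2"  # the assay targets isoform 2

    def test_single_isoform_group_degenerates_to_one_record(self):
        truth = synthetic.generate_cohort(
            synthetic.CohortSpec(n_samples=30, n_proteins=20, n_sex_affected=0, seed=41)
        )
        qm, _, _, _ = synthetic.simulate_ms(truth, seed=42)
        npx = synthetic.simulate_affinity(truth, seed=43)
        import protconcord.ingest as ingest

        ms = pd.DataFrame({"protein_id": truth.feature_ids,
                           "gene": truth.gene_of.to_numpy()})
        om = ingest.build_overlap(
            ms, npx.drop_duplicates("olink_id")[["olink_id", "uniprot_ids", "gene"]]
        )
        # force one single-member group
        om.isoform_groups = {truth.gene_of.iloc[0]: [truth.feature_ids[0]]}
        iso = isoform_correlations(qm, npx, om)
        assert len(iso) <= 1
        if len(iso):
            assert bool(iso.iloc[0]["best_isoform"])

    def test_exact_ties_are_flagged_and_broken_deterministically(self):
        # two isoforms with identical trajectories -> identical rho; the
        # lexicographically first ID wins and both are flagged tied
        rng = np.random.default_rng(44)
        samples = [f"S{i:03d}" for i in range(20)]
        traj = rng.normal(size=20)
        vals = pd.DataFrame([traj, traj], index=["P1", "P1-2"], columns=samples)
        import protconcord.ingest as ingest

        qm = ingest.QuantMatrix(vals, pd.Series("set1", index=samples))
        npx = pd.DataFrame(
            {"sample_id": samples, "olink_id": "OID1", "uniprot_ids": "P1",
             "gene": "G1", "panel": "x", "panel_version": "I",
             "npx": traj + rng.normal(0, 0.1, 20), "lod": -99.0,
             "below_lod": False, "sample_qc_warn": False, "assay_qc_warn": False}
        )
        om = ingest.OverlapMap(
            pairs=pd.DataFrame([{"ms_id": "P1", "olink_id": "OID1", "gene": "G1",
                                 "match_basis": "uniprot"}]),
            isoform_groups={"G1": ["P1", "P1-2"]},
        )
        iso = isoform_correlations(qm, npx, om)
        assert list(iso["ms_id"]) == ["P1", "P1-2"]
        assert iso["tied"].all()


class TestExternal:
    def test_reagent_pairs_aggregated_by_median(self):
        own = pd.DataFrame({"ms_id": ["P1"], "gene": ["G1"], "rho": [0.6]})
        ext = pd.DataFrame(
            {"study": ["s"] * 3, "uniprot": ["P1"] * 3, "gene": ["G1"] * 3,
             "corr": [0.2, 0.5, 0.9], "tier": [1, 1, 1]}
        )
        joined, medians = align_external(own, ext)
        assert joined["external_corr"].iloc[0] == 0.5

    def test_gene_fallback_and_unmatched_count(self):
        own = pd.DataFrame({"ms_id": ["P1"], "gene": ["G1"], "rho": [0.6]})
        ext = pd.DataFrame(
            {"study": ["s", "s"], "uniprot": ["P999", "P888"],
             "gene": ["G1", "G404"], "corr": [0.4, 0.5]}
        )
        with pytest.warns(UserWarning, match="no match"):
            joined, _ = align_external(own, ext)
        assert list(joined["matched_by"]) == ["gene"]
        assert joined.attrs["n_unmatched"] == 1

    def test_per_tier_medians_equal_brute_force_group_by(self):
        rng = np.random.default_rng(50)
        own = pd.DataFrame(
            {"ms_id": [f"P{i}" for i in range(30)],
             "gene": [f"G{i}" for i in range(30)],
             "rho": rng.uniform(-1, 1, 30)}
        )
        ext = pd.DataFrame(
            {"study": "eldjarn-like",
             "uniprot": [f"P{i}" for i in range(30)],
             "gene": [f"G{i}" for i in range(30)],
             "corr": rng.uniform(-1, 1, 30),
             "tier": rng.integers(1, 4, 30)}
        )
        joined, medians = align_external(own, ext)
        for tier in (1, 2, 3):
            sub = joined[joined["tier"] == tier]
            if len(sub):
                assert medians.loc[("eldjarn-like", tier), "median_own_rho"] == \
                    pytest.approx(float(np.median(sub["own_rho"])))
                assert medians.loc[("eldjarn-like", tier), "median_external_corr"] == \
                    pytest.approx(float(np.median(sub["external_corr"])))


def test_monotone_degradation_in_observation_noise():
    from protconcord.experiments import noise_degradation_curve

    curve = noise_degradation_curve(seed=61, n_proteins=100)
    med = curve["median_rho"].to_numpy()
    assert np.all(np.diff(med) <= 0)
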