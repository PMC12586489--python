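"""Peptide-assay correlations, sequence localization, layout and structures."""

import json

import numpy as np
import pandas as pd
import pytest

from protconcord import synthetic
from protconcord.ingest import QuantMatrix
from protconcord.peptides import (
    UNCOVERED_SENTINEL, annotate_structure, export_sequence_plot, layout_tracks,
    locate_peptide, locate_peptides, peptide_correlations, read_isoform_fasta,
    read_structure_bfactors, summarize_regions, write_synthetic_structure,
)

from oracles import brute_first_fit


# ---------------------------------------------------------------------------
# correlations and filters
# ---------------------------------------------------------------------------

def _pep_inputs(n_samples=30, missing_for=None):
    rng = np.random.default_rng(7)
    samples = [f"S{i:03d}" for i in range(n_samples)]
    traj = rng.normal(size=n_samples)
    peptides = ["PEPTIDEA", "PEPTIDEB", "LONELYPEP"]
    vals = pd.DataFrame(
        [traj + rng.normal(0, 0.2, n_samples) for _ in peptides],
        index=peptides, columns=samples,
    )
    if missing_for:
        vals.loc[missing_for, samples[:-14]] = np.nan  # leaves 14 observations
    meta = pd.DataFrame(
        {"protein_id": ["P1", "P1", "P2"], "gene": ["G1", "G1", "G2"]},
        index=pd.Index(peptides, name="peptide"),
    )
    qm = QuantMatrix(vals, pd.Series("set1", index=samples), feature_meta=meta)
    npx = pd.DataFrame(
        {"sample_id": samples, "olink_id": "OID1", "uniprot_ids": "P1",
         "gene": "G1", "panel": "x", "panel_version": "I",
         "npx": traj, "lod": -99.0, "below_lod": False,
         "sample_qc_warn": False, "assay_qc_warn": False}
    )
    return qm, npx


def test_peptides_below_15_samples_are_excluded():
    qm, npx = _pep_inputs(missing_for="PEPTIDEB")
    out = peptide_correlations(qm, npx)
    assert "PEPTIDEB" not in set(out["peptide"])


def test_gene_with_single_surviving_peptide_is_dropped():
    qm, npx = _pep_inputs(missing_for="PEPTIDEB")
    # G1 keeps only PEPTIDEA -> the whole gene is dropped
    out = peptide_correlations(qm, npx)
    assert len(out) == 0


def test_gene_without_assay_is_counted_not_fatal():
    qm, npx = _pep_inputs()
    out = peptide_correlations(qm, npx)
    assert out.attrs["n_genes_without_assay"] == 1  # G2 has no assay
    assert set(out["gene"]) == {"G1"}


def test_targeted_isoform_peptides_correlate_higher():
    from protconcord.experiments import proteoform_recovery

    r = proteoform_recovery(seed=3)
    assert r["n_targeted_peptides"] >= 5
    assert r["n_nontargeted_peptides"] >= 5
    assert r["targeted_median_rho"] - r["nontargeted_median_rho"] >= 0.3


# ---------------------------------------------------------------------------
# localization
# ---------------------------------------------------------------------------

class TestLocate:
    def test_simple_placement(self):
        pl = locate_peptide("PEPTIDE", {"ISO1": "MKPEPTIDER"})
        assert (pl.start, pl.end) == (3, 9)
        assert not pl.multi_hit and pl.isoform_specific

    def test_overlapping_occurrences_flag_multi_hit(self):
        pl = locate_peptide("AA", {"ISO1": "AAAA"})
        assert (pl.start, pl.end) == (1, 2)
        assert pl.multi_hit

    def test_absent_peptide_returns_none(self):
        assert locate_peptide("WWWWW", {"ISO1": "MKPEPTIDER"}) is None

    def test_canonical_isoform_preferred_and_specificity(self):
        isoforms = {"P1": "XXPEPTIDEXX", "P1-2": "PEPTIDE"}
        pl = locate_peptide("PEPTIDE", isoforms)
        assert pl.isoform_id == "P1"
        assert not pl.isoform_specific and pl.n_isoforms_hit == 2
        pl2 = locate_peptide("XXPEP", isoforms)
        assert pl2.isoform_id == "P1" and pl2.isoform_specific

    def test_generator_round_trip_recovers_true_coordinates(self):
        demo = synthetic.demo_proteoforms(seed=30)
        design = synthetic.generate_peptides(demo, peptides_per_region=10,
                                             length_range=(8, 14), seed=31)
        seqs = {pf.gene: dict(pf.isoform_sequences) for pf in demo}
        for _, row in design.iterrows():
            pl = locate_peptide(row["peptide"], seqs[row["gene"]])
            assert pl is not None
            if not pl.multi_hit and pl.isoform_id == row["isoform_id"]:
                assert (pl.start, pl.end) == (row["start"], row["end"])

    def test_fasta_round_trip(self, tmp_path):
        demo = synthetic.demo_proteoforms(seed=32)
        path = tmp_path / "demo.fasta"
        synthetic.write_fasta(demo, path)
        genes = read_isoform_fasta(path)
        assert set(genes) == {pf.gene for pf in demo}
        for pf in demo:
            for iso, seq in pf.isoform_sequences:
                assert genes[pf.gene][iso] == seq


# ---------------------------------------------------------------------------
# region summaries
# ---------------------------------------------------------------------------

class TestRegions:
    def _placed(self):
        return pd.DataFrame(
            {
                "peptide": ["A", "B", "C"],
                "gene": "G1", "isoform_id": "P1",
                "start": [1, 20, 35], "end": [10, 30, 45],
                "rho": [0.1, 0.5, 0.9],
                "category": ["none", "moderate", "strong"],
                "placed": True,
            }
        )

    def _regions(self, rows):
        return pd.DataFrame(rows, columns=["gene", "region", "isoform_id",
                                           "start", "end"])

    def test_median_over_covering_peptides(self):
        out = summarize_regions(
            self._placed(), self._regions([("G1", "all", "P1", 1, 50)])
        )
        assert out.iloc[0]["median_rho"] == 0.5
        assert out.iloc[0]["n_peptides"] == 3
        assert json.loads(out.iloc[0]["category_mix"]) == {
            "none": 1, "moderate": 1, "strong": 1}

    def test_disjoint_region_has_zero_peptides(self):
        out = summarize_regions(
            self._placed(), self._regions([("G1", "far", "P1", 100, 120)])
        )
        assert out.iloc[0]["n_peptides"] == 0
        assert np.isnan(out.iloc[0]["median_rho"])

    def test_boundary_spanning_peptide_counts_in_both_regions(self):
        regions = self._regions([("G1", "left", "P1", 1, 25),
                                 ("G1", "right", "P1", 26, 50)])
        out = summarize_regions(self._placed(), regions).set_index("region")
        # peptide B (20-30) spans the boundary
        assert out.loc["left", "n_peptides"] == 2
        assert out.loc["right", "n_peptides"] == 2
        # majority rule assigns B to the left region only (6 vs 5 residues)
        out2 = summarize_regions(self._placed(), regions,
                                 overlap_rule="majority").set_index("region")
        assert out2.loc["left", "n_peptides"] == 2
        assert out2.loc["right", "n_peptides"] == 1


# ---------------------------------------------------------------------------
# track layout
# ---------------------------------------------------------------------------

class TestLayout:
    def test_non_overlapping_peptides_share_one_row(self):
        df = pd.DataFrame({"start": [1, 11, 21], "end": [10, 20, 30],
                           "peptide": ["a", "b", "c"]})
        out = layout_tracks(df)
        assert set(out["row"]) == {0}

    def test_adjacent_intervals_may_share_a_row(self):
        df = pd.DataFrame({"start": [1, 11], "end": [10, 20],
                           "peptide": ["a", "b"]})
        assert set(layout_tracks(df)["row"]) == {0}

    def test_mutually_overlapping_clique_needs_k_rows(self):
        k = 5
        df = pd.DataFrame({"start": [1] * k, "end": [50] * k,
                           "peptide": list("abcde")})
        assert sorted(layout_tracks(df)["row"]) == list(range(k))

    @pytest.mark.parametrize("trial", range(25))
    def test_random_layouts_valid_and_match_first_fit_oracle(self, trial):
        rng = np.random.default_rng(500 + trial)
        n = int(rng.integers(2, 40))
        starts = rng.integers(1, 200, size=n)
        lengths = rng.integers(5, 30, size=n)
        df = pd.DataFrame({"start": starts, "end": starts + lengths,
                           "peptide": [f"p{i}" for i in range(n)]})
        out = layout_tracks(df)
        # no within-row overlap
        for _, grp in out.groupby("row"):
            g = grp.sort_values("start")
            assert (g["start"].to_numpy()[1:] > g["end"].to_numpy()[:-1]).all()
        # equals the brute-force first-fit oracle
        oracle = brute_first_fit(
            [(r["start"], r["end"], r["peptide"]) for _, r in df.iterrows()]
        )
        assert list(out["row"]) == oracle

    def test_layout_invariant_to_input_order(self):
        rng = np.random.default_rng(9)
        starts = rng.integers(1, 100, size=20)
        df = pd.DataFrame({"start": starts, "end": starts + 10,
                           "peptide": [f"p{i}" for i in range(20)]})
        base = layout_tracks(df).set_index("peptide")["row"]
        shuffled = df.sample(frac=1, random_state=1)
        again = layout_tracks(shuffled).set_index("peptide")["row"]
        assert base.sort_index().equals(again.sort_index())


# ---------------------------------------------------------------------------
# structure annotation
# ---------------------------------------------------------------------------

class TestStructure:
    SEQ = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"

    def _placed(self):
        return pd.DataFrame(
            {
                "peptide": ["MKTAYIAK", "AYIAKQRQ", "SHFSRQLE"],
                "gene": "G1", "isoform_id": "P1",
                "start": [1, 4, 17], "end": [8, 11, 24],
                "rho": [0.2, 0.8, 0.5],
                "category": ["none", "strong", "moderate"],
                "placed": True, "multi_hit": False,
            }
        )

    def test_median_and_sentinel_and_round_trip(self, tmp_path):
        pdb_in = tmp_path / "model.pdb"
        pdb_out = tmp_path / "annotated.pdb"
        write_synthetic_structure(self.SEQ, pdb_in)
        values = annotate_structure(self._placed(), pdb_in, "P1", self.SEQ, pdb_out)
        # residue 5 covered by peptides with rho (0.2, 0.8) -> median 0.50
        assert values.loc[5] == 0.50
        # residue 1 covered only by the first peptide
        assert values.loc[1] == 0.20
        # uncovered residue gets the sentinel
        assert values.loc[30] == UNCOVERED_SENTINEL
        back = read_structure_bfactors(pdb_out)
        assert np.allclose(back.to_numpy(), values.to_numpy(), atol=1e-9)

    def test_sequence_mismatch_raises(self, tmp_path):
        pdb_in = tmp_path / "model.pdb"
        write_synthetic_structure(self.SEQ, pdb_in)
        wrong = "W" * len(self.SEQ)
        with pytest.raises(ValueError, match="mismatch"):
            annotate_structure(self._placed(), pdb_in, "P1", wrong,
                               tmp_path / "x.pdb")


def test_sequence_plot_export_round_trip(tmp_path):
    placed = pd.DataFrame(
        {
            "peptide": ["AAA", "BBB"], "gene": "G1", "isoform_id": "P1",
            "start": [1, 2], "end": [3, 4], "rho": [0.4, 0.9],
            "category": ["weak", "strong"], "placed": True, "multi_hit": False,
        }
    )
    regions = pd.DataFrame([{"gene": "G1", "region": "dom", "isoform_id": "P1",
                             "start": 1, "end": 10}])
    path = tmp_path / "plot.json"
    payload = export_sequence_plot("G1", "P1", 10, placed, regions, path)
    loaded = json.loads(path.read_text())
    assert loaded == json.loads(json.dumps(payload))
    assert len(loaded["peptides"]) == 2
    rows = {p["peptide"]: p["row"] for p in loaded["peptides"]}
    assert rows["AAA"] != rows["BBB"]  # overlapping -> different tracks
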