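"""Protein-level cross-platform correlation under the three dataset variants.

Variants:

* ``full``    — below-LOD values and QC-warned measurements retained;
* ``clean``   — below-LOD and QC-warned affinity values set to missing;
* ``complete``— restricted to proteins with no missing, below-LOD or QC-warned
  values on either platform over the shared samples.

Per matched protein, Spearman's rho (average ranks for ties) and Pearson's r
are computed on pairwise-complete observations; proteins with fewer than
``min_overlap`` (default 8) overlapping points, or zero variance on either
platform, are excluded rather than emitted.  Duplicate aliquots and control
samples never enter correlations: only samples measured by both platforms do.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ingest import OverlapMap, QuantMatrix

#: category bins: [-1, 0.3) none, [0.3, 0.5) weak, [0.5, 0.7) moderate, [0.7, 1] strong
CATEGORY_EDGES = (0.3, 0.5, 0.7)
CATEGORIES = ("none", "weak", "moderate", "strong")

MIN_OVERLAP = 8


@dataclass(frozen=True)
class PairCorrelation:
    rho: float
    r: float
    n_overlap: int


def categorize(rho: float) -> str | None:
    """Map a correlation to its category; half-open bins, top bin closed."""
    if rho is None or np.isnan(rho):
        return None
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"correlation {rho} outside [-1, 1]")
    if rho < CATEGORY_EDGES[0]:
        return "none"
    if rho < CATEGORY_EDGES[1]:
        return "weak"
    if rho < CATEGORY_EDGES[2]:
        return "moderate"
    return "strong"


def correlate_pair(
    x, y, method: str = "spearman", min_overlap: int = MIN_OVERLAP
) -> tuple[float, int] | None:
    """Correlation on pairwise-complete observations.

    Returns ``(coefficient, n_overlap)`` or None when fewer than
    ``min_overlap`` points overlap or either vector has zero variance over the
    overlap (coefficient undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < min_overlap:
        return None
    xs, ys = x[ok], y[ok]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return None
    if method == "spearman":
        coef = stats.spearmanr(xs, ys).statistic
    elif method == "pearson":
        coef = stats.pearsonr(xs, ys).statistic
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(coef), n


def _both(x, y, min_overlap: int) -> PairCorrelation | None:
    sp = correlate_pair(x, y, "spearman", min_overlap)
    if sp is None:
        return None
    pe = correlate_pair(x, y, "pearson", min_overlap)
    return PairCorrelation(rho=sp[0], r=pe[0], n_overlap=sp[1])


# ---------------------------------------------------------------------------
# NPX pivots and shared-sample handling
# ---------------------------------------------------------------------------

def npx_matrix(npx: pd.DataFrame, clean: bool = False) -> pd.DataFrame:
    """Pivot a long NPX table to an assay x sample matrix.

    With ``clean=True``, below-LOD values and QC-warned measurements are set
    to missing (the cleaned dataset variant).
    """
    df = npx.copy()
    if clean:
        mask = df["below_lod"] | df["sample_qc_warn"] | df["assay_qc_warn"]
        df.loc[mask, "npx"] = np.nan
    return df.pivot(index="olink_id", columns="sample_id", values="npx")


def shared_samples(ms: QuantMatrix, npx_mat: pd.DataFrame) -> list[str]:
    """Samples measured on both platforms (duplicates/controls drop out here)."""
    return [s for s in ms.sample_ids if s in npx_mat.columns]


# ---------------------------------------------------------------------------
# dataset variants
# ---------------------------------------------------------------------------

def run_variants(
    protein_qm: QuantMatrix,
    npx: pd.DataFrame,
    overlap: OverlapMap,
    min_overlap: int = MIN_OVERLAP,
    variants: tuple[str, ...] = ("full", "clean", "complete"),
) -> pd.DataFrame:
    """Correlation records per matched protein under each dataset variant.

    Returns one row per (ms_id, olink_id, variant) that survives the overlap
    and variance filters, with columns ``gene, match_basis, variant, rho, r,
    n_overlap, category``.
    """
    full_m = npx_matrix(npx, clean=False)
    clean_m = npx_matrix(npx, clean=True)
    samples = shared_samples(protein_qm, full_m)

    flags = npx.set_index(["olink_id", "sample_id"])[
        ["below_lod", "sample_qc_warn", "assay_qc_warn"]
    ].any(axis=1).unstack("sample_id")

    records: list[dict] = []
    for _, pair in overlap.pairs.iterrows():
        ms_id, oid = pair["ms_id"], pair["olink_id"]
        if ms_id not in protein_qm.values.index or oid not in full_m.index:
            continue
        x = protein_qm.values.loc[ms_id, samples].to_numpy(dtype=float)
        y_full = full_m.loc[oid, samples].to_numpy(dtype=float)
        y_clean = clean_m.loc[oid, samples].to_numpy(dtype=float)

        is_complete = (
            not np.isnan(x).any()
            and not np.isnan(y_full).any()
            and oid in flags.index
            and not flags.loc[oid, samples].fillna(True).to_numpy().any()
        )
        per_variant = {
            "full": y_full,
            "clean": y_clean,
            "complete": y_full if is_complete else None,
        }
        for variant in variants:
            y = per_variant.get(variant)
            if y is None:
                continue
            res = _both(x, y, min_overlap)
            if res is None:
                continue
            records.append(
                {
                    "ms_id": ms_id, "olink_id": oid, "gene": pair["gene"],
                    "match_basis": pair["match_basis"], "variant": variant,
                    "rho": res.rho, "r": res.r, "n_overlap": res.n_overlap,
                    "category": categorize(res.rho),
                }
            )
    return pd.DataFrame(
        records,
        columns=["ms_id", "olink_id", "gene", "match_basis", "variant",
                 "rho", "r", "n_overlap", "category"],
    )


# ---------------------------------------------------------------------------
# isoform-resolved correlations
# ---------------------------------------------------------------------------

def isoform_correlations(
    protein_qm: QuantMatrix,
    npx: pd.DataFrame,
    overlap: OverlapMap,
    min_overlap: int = MIN_OVERLAP,
) -> pd.DataFrame:
    """Per-isoform correlations for genes whose platforms quantify several IDs.

    For each isoform group, every MS protein ID is correlated against the
    gene's assay; records are ranked by rho (ties broken by higher n_overlap,
    then lexicographic ID) and the top record is flagged ``best_isoform``.
    Exact rho-and-n ties are additionally flagged.
    """
    full_m = npx_matrix(npx, clean=False)
    samples = shared_samples(protein_qm, full_m)
    assay_of_gene = overlap.pairs.drop_duplicates("gene").set_index("gene")["olink_id"]

    rows: list[dict] = []
    for gene, members in overlap.isoform_groups.items():
        oid = assay_of_gene.get(gene)
        if oid is None or oid not in full_m.index:
            continue
        y = full_m.loc[oid, samples].to_numpy(dtype=float)
        for ms_id in members:
            if ms_id not in protein_qm.values.index:
                continue
            x = protein_qm.values.loc[ms_id, samples].to_numpy(dtype=float)
            res = _both(x, y, min_overlap)
            if res is None:
                continue
            rows.append(
                {"gene": gene, "ms_id": ms_id, "olink_id": oid,
                 "rho": res.rho, "r": res.r, "n_overlap": res.n_overlap,
                 "category": categorize(res.rho)}
            )
    df = pd.DataFrame(
        rows, columns=["gene", "ms_id", "olink_id", "rho", "r", "n_overlap", "category"]
    )
    if not len(df):
        df["rank"] = []
        df["best_isoform"] = []
        df["tied"] = []
        return df
    df = df.sort_values(
        ["gene", "rho", "n_overlap", "ms_id"],
        ascending=[True, False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df["rank"] = df.groupby("gene").cumcount() + 1
    df["best_isoform"] = df["rank"] == 1
    top = df[df["rank"] <= 2].groupby("gene").agg(
        n=("rho", "size"), r1=("rho", "first"),
        r2=("rho", "last"), n1=("n_overlap", "first"), n2=("n_overlap", "last"),
    )
    tied_genes = set(top.index[(top["n"] > 1) & (top["r1"] == top["r2"]) & (top["n1"] == top["n2"])])
    df["tied"] = df["gene"].isin(tied_genes) & (df["rank"] <= 2)
    return df


# ---------------------------------------------------------------------------
# alignment with external correlation tables
# ---------------------------------------------------------------------------

def align_external(
    records: pd.DataFrame,
    external: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join own correlation records with an external cross-platform table.

    ``external`` has one row per (study, protein, reagent pair) with columns
    ``study, uniprot, gene, corr`` and optional ``tier``; multi-reagent
    proteins are first aggregated by the median of their reagent-pair
    correlations.  Matching is by UniProt ID, falling back to gene name.
    Returns ``(joined, tier_medians)``; unmatched external rows are counted in
    ``joined.attrs['n_unmatched']``.
    """
    own = records.copy()
    if "variant" in own.columns:
        own = own[own["variant"] == "full"]
    own = own[["ms_id", "gene", "rho"]].rename(columns={"rho": "own_rho"})

    agg_cols = ["study", "uniprot", "gene"] + (["tier"] if "tier" in external.columns else [])
    ext = (
        external.groupby(agg_cols, dropna=False)["corr"].median().reset_index()
        .rename(columns={"corr": "external_corr"})
    )

    by_uid = own.set_index("ms_id")["own_rho"]
    by_gene = own.groupby("gene")["own_rho"].median()
    own_vals = ext["uniprot"].map(by_uid)
    fallback = ext["gene"].map(by_gene)
    matched_by = np.where(own_vals.notna(), "uniprot",
                          np.where(fallback.notna(), "gene", "unmatched"))
    ext["own_rho"] = own_vals.fillna(fallback)
    ext["matched_by"] = matched_by

    joined = ext[ext["matched_by"] != "unmatched"].reset_index(drop=True)
    n_unmatched = int((matched_by == "unmatched").sum())
    if n_unmatched:
        import warnings

        warnings.warn(f"{n_unmatched} external rows had no match", stacklevel=2)
    joined.attrs["n_unmatched"] = n_unmatched

    group_cols = ["study"] + (["tier"] if "tier" in joined.columns else [])
    tier_medians = joined.groupby(group_cols, dropna=False)[
        ["own_rho", "external_corr"]
    ].median().rename(columns={"own_rho": "median_own_rho",
                               "external_corr": "median_external_corr"})
    tier_medians["n_proteins"] = joined.groupby(group_cols, dropna=False).size()
    return joined, tier_medians
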