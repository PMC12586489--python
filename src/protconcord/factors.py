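"""Technical factors behind cross-platform agreement.

Univariable ordinary least squares of the per-protein MS-affinity Spearman
correlation on one technical factor at a time (missingness fractions, PSM and
unique-peptide depth, sequence coverage, precursor mass error, technical CVs,
NPX margin above LOD, QC-warning counts, panel/panel-version indicators,
protein mass/length/isoform count, estimated blood concentration).  Slopes,
95% CIs, p values and adjusted R-squared are reported, with BH adjustment
across all tested factors.  A two-sided Wilcoxon rank-sum utility covers
group-style comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .daa import bh_fdr
from .ingest import QuantMatrix


@dataclass(frozen=True)
class RegressionResult:
    factor: str
    slope: float
    ci_low: float
    ci_high: float
    p: float
    adj_r2: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


class UntestableFactor(ValueError):
    """Raised for a constant factor (slope undefined)."""


def univariable_fit(correlations, factor, name: str = "factor") -> RegressionResult:
    """OLS of correlation on one factor over complete pairs.

    Requires >= 3 complete (correlation, factor) pairs; a constant factor
    raises :class:`UntestableFactor`.
    """
    y = np.asarray(correlations, dtype=float)
    x = np.asarray(factor, dtype=float)
    ok = np.isfinite(y) & np.isfinite(x)
    y, x = y[ok], x[ok]
    if len(y) < 3:
        raise ValueError(f"{name}: need >= 3 complete pairs, got {len(y)}")
    if np.ptp(x) == 0:
        raise UntestableFactor(f"{name}: constant factor, slope undefined")
    if np.ptp(y) == 0:
        raise UntestableFactor(f"{name}: constant response, fit degenerate")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=0.05)
    return RegressionResult(
        factor=name,
        slope=float(model.params[1]),
        ci_low=float(ci[1, 0]),
        ci_high=float(ci[1, 1]),
        p=float(model.pvalues[1]),
        adj_r2=float(model.rsquared_adj),
        n=int(len(y)),
    )


def fit_factors(
    table: pd.DataFrame,
    y_col: str = "rho",
    factor_cols: list[str] | None = None,
    log10_cols: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Fit every factor column univariably with BH adjustment across factors.

    ``log10_cols`` are log10-transformed before fitting (count-style factors
    such as median unique peptides).  Constant or underpowered factors are
    reported with NaN statistics and ``testable = False``.
    """
    if factor_cols is None:
        factor_cols = [c for c in table.columns if c != y_col]
    rows = []
    for col in factor_cols:
        x = table[col]
        if x.dtype == bool:
            x = x.astype(float)
        elif x.dtype == object:
            levels = sorted(x.dropna().unique())
            if len(levels) != 2:
                rows.append({"factor": col, "testable": False})
                continue
            x = (x == levels[1]).astype(float).where(x.notna())
        x = pd.to_numeric(x, errors="coerce")
        if col in log10_cols:
            x = np.log10(x.where(x > 0))
        try:
            res = univariable_fit(table[y_col], x, name=col)
        except (UntestableFactor, ValueError):
            rows.append({"factor": col, "testable": False})
            continue
        d = res.to_dict()
        d["testable"] = True
        rows.append(d)
    out = pd.DataFrame(rows).set_index("factor")
    tested = out.index[out["testable"].fillna(False)] if "testable" in out else []
    out["fdr"] = np.nan
    if len(tested):
        out.loc[tested, "fdr"] = bh_fdr(out.loc[tested, "p"].to_numpy())
    return out


def rank_sum_by_group(
    table: pd.DataFrame,
    y_col: str,
    group_cols: list[str],
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum per binary grouping column, BH-adjusted."""
    rows = []
    for col in group_cols:
        g = table[[y_col, col]].dropna()
        levels = sorted(g[col].unique())
        if len(levels) != 2:
            rows.append({"factor": col, "p": np.nan, "testable": False})
            continue
        a = g.loc[g[col] == levels[0], y_col]
        b = g.loc[g[col] == levels[1], y_col]
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append(
            {"factor": col, "group_low": levels[0], "group_high": levels[1],
             "median_low": float(a.median()), "median_high": float(b.median()),
             "u_stat": float(stat), "p": float(p), "testable": True}
        )
    out = pd.DataFrame(rows).set_index("factor")
    tested = out.index[out["testable"]]
    out["fdr"] = np.nan
    if len(tested):
        out.loc[tested, "fdr"] = bh_fdr(out.loc[tested, "p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# factor-table assembly
# ---------------------------------------------------------------------------

def _protein_mass(seq: str) -> float:
    from Bio.SeqUtils import molecular_weight

    try:
        return float(molecular_weight(seq, seq_type="protein"))
    except (ValueError, KeyError):
        return float("nan")


def build_factor_table(
    records: pd.DataFrame,
    protein_qm: QuantMatrix,
    psm_table: pd.DataFrame,
    npx: pd.DataFrame,
    cv_ms: pd.DataFrame | None = None,
    cv_affinity: pd.DataFrame | None = None,
    conc_log10: pd.Series | None = None,
    proteoforms: dict | None = None,
    shared_samples: list[str] | None = None,
) -> pd.DataFrame:
    """One row per correlated protein with its candidate technical factors.

    Medians of per-set PSM / unique-peptide counts are taken over the TMT sets
    in which the protein was detected (sets without the protein do not count
    as zero).  ``records`` supplies the dependent variable (full-variant
    Spearman rho) and the MS-to-assay pairing.
    """
    recs = records
    if "variant" in recs.columns:
        recs = recs[recs["variant"] == "full"]
    recs = recs.drop_duplicates("ms_id").set_index("ms_id")

    samples = shared_samples
    if samples is None:
        samples = [s for s in protein_qm.sample_ids if s in set(npx["sample_id"])]

    out = pd.DataFrame(index=recs.index)
    out["rho"] = recs["rho"]
    out["olink_id"] = recs["olink_id"]
    out["gene"] = recs["gene"]

    # MS missingness over the shared cohort
    vals = protein_qm.values.reindex(index=recs.index, columns=samples)
    out["ms_missing_frac"] = vals.isna().mean(axis=1)

    # per-set PSM and unique-peptide depth over detected sets
    single = ~psm_table["proteins"].astype(str).str.contains(";", regex=False)
    psm1 = psm_table.loc[single & (psm_table["channel"] != "IS")]
    per_set_psms = psm1.groupby(["proteins", "set"])["psm_id"].nunique()
    per_set_peps = psm1.groupby(["proteins", "set"])["peptide"].nunique()
    out["median_psms"] = per_set_psms.groupby("proteins").median().reindex(recs.index)
    out["median_unique_peptides"] = (
        per_set_peps.groupby("proteins").median().reindex(recs.index)
    )
    if "precursor_ppm" in psm_table.columns:
        ppm = psm1.groupby("proteins")["precursor_ppm"].apply(lambda s: s.abs().median())
        out["precursor_mass_error"] = ppm.reindex(recs.index)

    # affinity-side factors, keyed by matched assay
    npx_cohort = npx[npx["sample_id"].isin(set(samples))]
    grp = npx_cohort.groupby("olink_id")
    below = grp["below_lod"].mean()
    margin = grp.apply(lambda g: float((g["npx"] - g["lod"]).median()), include_groups=False)
    warns = grp["sample_qc_warn"].sum()
    assay_warn = grp["assay_qc_warn"].first()
    assay_meta = npx.drop_duplicates("olink_id").set_index("olink_id")
    for col, series in [
        ("below_lod_frac", below), ("median_npx_minus_lod", margin),
        ("sample_qc_warn_count", warns), ("assay_qc_warn", assay_warn),
        ("panel", assay_meta["panel"]), ("panel_version", assay_meta["panel_version"]),
    ]:
        out[col] = out["olink_id"].map(series)

    if cv_ms is not None:
        out["cv_ms"] = cv_ms["cv_percent"].reindex(recs.index)
    if cv_affinity is not None:
        out["cv_affinity"] = out["olink_id"].map(cv_affinity["cv_percent"])
    if conc_log10 is not None:
        out["conc_log10"] = conc_log10.reindex(recs.index)

    # sequence-derived properties and coverage
    if proteoforms is not None:
        seq_of: dict[str, str] = {}
        iso_count: dict[str, int] = {}
        for pf in proteoforms.values():
            for iso, seq in pf.isoform_sequences:
                seq_of[iso] = seq
                iso_count[iso] = len(pf.isoform_sequences)
        lengths = {pid: len(seq_of[pid]) for pid in recs.index if pid in seq_of}
        out["protein_length"] = pd.Series(lengths).reindex(recs.index)
        out["protein_mass"] = pd.Series(
            {pid: _protein_mass(seq_of[pid]) for pid in lengths}
        ).reindex(recs.index)
        out["n_isoforms"] = pd.Series(iso_count).reindex(recs.index)

        meta = getattr(protein_qm, "feature_meta", None)
        # sequence coverage from observed peptides when positions are known
        pep_meta = psm1.drop_duplicates("peptide")
        if {"peptide"}.issubset(pep_meta.columns):
            cov: dict[str, float] = {}
            peps_by_prot = pep_meta.groupby("proteins")["peptide"].apply(list)
            for pid in lengths:
                seq = seq_of[pid]
                covered = np.zeros(len(seq), dtype=bool)
                for pep in peps_by_prot.get(pid, []):
                    pos = seq.find(pep)
                    if pos >= 0:
                        covered[pos:pos + len(pep)] = True
                cov[pid] = float(covered.mean())
            out["sequence_coverage"] = pd.Series(cov).reindex(recs.index)
    return out


DEFAULT_FACTORS = [
    "ms_missing_frac", "below_lod_frac", "median_psms", "median_unique_peptides",
    "sequence_coverage", "precursor_mass_error", "cv_ms", "cv_affinity",
    "median_npx_minus_lod", "sample_qc_warn_count", "assay_qc_warn",
    "panel_version", "protein_length", "protein_mass", "n_isoforms", "conc_log10",
]
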