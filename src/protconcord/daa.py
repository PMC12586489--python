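"""Per-platform differential abundance (female vs male) and its concordance.

Each feature is tested with a two-sided Welch's t test (males as the reference
group, so the reported effect is mean(female) - mean(male) on the log2/NPX
scale), p values are adjusted per platform with Benjamini-Hochberg, and
significance is called at FDR < 0.05.  Concordance statistics follow:
significant-set overlap, directional agreement of the log2 fold changes,
Pearson R of the paired fold changes, and replication rates against external
differential-abundance tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

FDR_THRESHOLD = 0.05


# ---------------------------------------------------------------------------
# Welch's t
# ---------------------------------------------------------------------------

def welch_test(group_a, group_b) -> tuple[float, float, float, float]:
    """Two-sided Welch's t test: returns ``(t, df, p, mean_diff)``.

    ``mean_diff`` = mean(group_a) - mean(group_b) (call with the female group
    first to match the males-as-reference convention).  Requires >= 2
    non-missing values per group.  Degenerate zero-variance groups are handled
    explicitly: equal means give (0, nan, 1, 0); unequal means give
    (+/-inf, nan, 0, diff).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("Welch's t test needs >= 2 non-missing values per group")
    diff = float(a.mean() - b.mean())
    va, vb = a.var(ddof=1), b.var(ddof=1)
    sa, sb = va / len(a), vb / len(b)
    se2 = sa + sb
    if se2 == 0.0:
        if diff == 0.0:
            return 0.0, float("nan"), 1.0, 0.0
        return float(np.sign(diff) * np.inf), float("nan"), 0.0, diff
    t = diff / np.sqrt(se2)
    df = se2**2 / (sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return float(t), float(df), p, diff


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# per-platform DAA
# ---------------------------------------------------------------------------

def run_daa(
    values: pd.DataFrame,
    sex: pd.Series,
    platform: str = "",
    fdr_threshold: float = FDR_THRESHOLD,
) -> pd.DataFrame:
    """Vectorized Welch DAA over a feature x sample matrix.

    ``sex`` maps sample IDs to 'F'/'M'; only samples present in both inputs
    are used.  Features with fewer than 2 non-missing values in either group
    are excluded before FDR (so the number of tests reflects testable features
    only); the number skipped is recorded in ``result.attrs['n_skipped']``.
    """
    samples = [s for s in values.columns if s in sex.index]
    lab = sex.reindex(samples)
    f_cols = [s for s in samples if lab[s] == "F"]
    m_cols = [s for s in samples if lab[s] == "M"]
    fa = values[f_cols].to_numpy(dtype=float)
    ma = values[m_cols].to_numpy(dtype=float)

    nf = (~np.isnan(fa)).sum(axis=1)
    nm = (~np.isnan(ma)).sum(axis=1)
    testable = (nf >= 2) & (nm >= 2)

    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mf = np.nanmean(np.where(np.isnan(fa), np.nan, fa), axis=1)
        mm = np.nanmean(np.where(np.isnan(ma), np.nan, ma), axis=1)
        vf = np.nanvar(fa, axis=1, ddof=1)
        vm = np.nanvar(ma, axis=1, ddof=1)
        diff = mf - mm
        sa = vf / nf
        sb = vm / nm
        se2 = sa + sb
        t = diff / np.sqrt(se2)
        df = se2**2 / (sa**2 / (nf - 1) + sb**2 / (nm - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)

    with np.errstate(invalid="ignore"):
        zero_se = se2 == 0.0
        t = np.where(zero_se & (diff == 0.0), 0.0, t)
        p = np.where(zero_se & (diff == 0.0), 1.0, p)
        t = np.where(zero_se & (diff != 0.0), np.sign(diff) * np.inf, t)
        p = np.where(zero_se & (diff != 0.0), 0.0, p)
        df = np.where(zero_se, np.nan, df)

    out = pd.DataFrame(
        {
            "platform": platform,
            "log2fc": diff,
            "t_stat": t,
            "df": df,
            "p": p,
            "n_female": nf,
            "n_male": nm,
        },
        index=values.index,
    )
    out = out.loc[testable]
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = out["fdr"] < fdr_threshold
    out.attrs["n_skipped"] = int((~testable).sum())
    return out


# ---------------------------------------------------------------------------
# concordance between platforms
# ---------------------------------------------------------------------------

@dataclass
class ConcordanceSummary:
    n_tested: int
    n_sig_ms: int
    n_sig_affinity: int
    n_sig_both: int
    directional_agreement_percent: float
    fc_correlation: float
    scope: str
    replication_rates: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def concordance(
    results_ms: pd.DataFrame,
    results_affinity: pd.DataFrame,
    scope: str = "significant_any",
    restrict_to=None,
) -> ConcordanceSummary:
    """Cross-platform agreement of the differential-abundance results.

    ``scope`` chooses the directional-agreement/fold-change universe:
    ``"all"`` uses every feature tested on both platforms, whereas
    ``"significant_any"`` restricts to features significant in at least one.
    ``restrict_to`` optionally limits the whole analysis to a feature subset
    (e.g. the overlapping-and-complete proteins); an empty restriction is an
    error.  Zero fold changes on both platforms count as directionally
    agreeing.
    """
    common = results_ms.index.intersection(results_affinity.index)
    if restrict_to is not None:
        common = common.intersection(pd.Index(restrict_to))
    if len(common) == 0:
        raise ValueError("empty feature restriction for concordance analysis")
    ms = results_ms.loc[common]
    aff = results_affinity.loc[common]

    sig_ms = set(ms.index[ms["significant"]])
    sig_aff = set(aff.index[aff["significant"]])

    if scope == "all":
        universe = common
    elif scope == "significant_any":
        universe = pd.Index(sorted(sig_ms | sig_aff))
    else:
        raise ValueError(f"unknown scope {scope!r}")

    if len(universe):
        s_ms = np.sign(ms.loc[universe, "log2fc"].to_numpy())
        s_aff = np.sign(aff.loc[universe, "log2fc"].to_numpy())
        agreement = 100.0 * float(np.mean(s_ms == s_aff))
    else:
        agreement = float("nan")
    if len(universe) >= 2 and ms.loc[universe, "log2fc"].nunique() > 1 \
            and aff.loc[universe, "log2fc"].nunique() > 1:
        fc_r = float(stats.pearsonr(ms.loc[universe, "log2fc"],
                                    aff.loc[universe, "log2fc"]).statistic)
    elif len(universe) >= 2 and (ms.loc[universe, "log2fc"]
                                 == aff.loc[universe, "log2fc"]).all():
        fc_r = 1.0  # identical (possibly degenerate) fold changes
    else:
        fc_r = float("nan")

    return ConcordanceSummary(
        n_tested=len(common),
        n_sig_ms=len(sig_ms),
        n_sig_affinity=len(sig_aff),
        n_sig_both=len(sig_ms & sig_aff),
        directional_agreement_percent=agreement,
        fc_correlation=fc_r,
        scope=scope,
    )


def replication_rate(
    own: pd.DataFrame,
    external: pd.DataFrame,
) -> dict:
    """Replication of own DAPs in an external differential-abundance table.

    ``own`` is a DAA result (index = feature, columns ``significant, log2fc``);
    ``external`` needs index/column ``feature`` plus ``significant`` and a sign
    column (``sign`` or ``log2fc``).  The denominator is the set of own DAPs
    also tested externally; the numerator requires external significance with
    the same direction.  Returns ``{"rate", "n_tested_both", "n_replicated"}``.
    """
    ext = external.copy()
    if "feature" in ext.columns:
        ext = ext.set_index("feature")
    if "sign" in ext.columns:
        ext_sign = np.sign(ext["sign"].astype(float))
    elif "log2fc" in ext.columns:
        ext_sign = np.sign(ext["log2fc"].astype(float))
    else:
        raise ValueError("external table must carry a 'sign' or 'log2fc' column")
    if "significant" not in ext.columns:
        raise ValueError("external table must carry a 'significant' column")

    daps = own.index[own["significant"]]
    tested_both = daps.intersection(ext.index)
    if len(tested_both) == 0:
        return {"rate": float("nan"), "n_tested_both": 0, "n_replicated": 0}
    own_sign = np.sign(own.loc[tested_both, "log2fc"].to_numpy())
    replicated = (
        ext.loc[tested_both, "significant"].to_numpy().astype(bool)
        & (ext_sign.loc[tested_both].to_numpy() == own_sign)
    )
    return {
        "rate": float(replicated.mean()),
        "n_tested_both": int(len(tested_both)),
        "n_replicated": int(replicated.sum()),
    }
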