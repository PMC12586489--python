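"""Technical precision, missingness and coverage summaries.

The technical CV of a feature measured on the log2 scale uses the log-normal
back-transform

    CV% = 100 * sqrt(exp((ln 2 * SD)^2) - 1)

where SD is the log2-scale standard deviation of a duplicate pair (sample
denominator, n-1: SD = |a - b| / sqrt(2)).  The final feature CV is the mean
over its available duplicate pairs, capped at 100%.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

LN2 = math.log(2.0)


# ---------------------------------------------------------------------------
# technical CVs
# ---------------------------------------------------------------------------

def cv_from_sd_log2(sd_log2: float | np.ndarray) -> float | np.ndarray:
    """Uncapped CV%% of a log-normal variable with log2-scale SD ``sd_log2``."""
    sd = np.asarray(sd_log2, dtype=float)
    out = 100.0 * np.sqrt(np.expm1((LN2 * sd) ** 2))
    return float(out) if out.ndim == 0 else out


def cv_log2(pairs: Sequence[Sequence[float]], cap: float = 100.0) -> float:
    """Technical CV%% from duplicate log2 measurements.

    ``pairs`` is an iterable of (a, b) duplicate log2 values; pairs with a
    missing member are dropped.  Per pair SD = |a-b|/sqrt(2) (n-1 denominator),
    the pair CVs are averaged, and the result is capped at ``cap``.  Returns
    NaN when no complete pair is available (CV not computable).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim == 1:
        arr = arr.reshape(1, -1)
    if arr.shape[1] != 2:
        raise ValueError("each duplicate pair must have exactly 2 values")
    ok = ~np.isnan(arr).any(axis=1)
    if not ok.any():
        return float("nan")
    sd = np.abs(arr[ok, 0] - arr[ok, 1]) / math.sqrt(2.0)
    return float(min(cap, np.mean(cv_from_sd_log2(sd))))


def cv_table(
    values: pd.DataFrame,
    duplicate_pairs: Sequence[tuple[str, str]],
    platform: str,
    cap: float = 100.0,
) -> pd.DataFrame:
    """Per-feature technical CVs over the duplicate pairs present in ``values``.

    Returns columns ``platform, n_pairs, cv_percent``; features with no
    complete pair get ``n_pairs = 0`` and NaN CV (the paper-style "CV not
    computable" fraction follows directly from this).
    """
    pairs = [(a, b) for a, b in duplicate_pairs if a in values.columns and b in values.columns]
    if not pairs:
        raise ValueError("no duplicate pair is present in the value matrix")
    a = values.loc[:, [p[0] for p in pairs]].to_numpy()
    b = values.loc[:, [p[1] for p in pairs]].to_numpy()
    ok = ~(np.isnan(a) | np.isnan(b))
    sd = np.abs(a - b) / math.sqrt(2.0)
    cv = cv_from_sd_log2(sd)
    with np.errstate(invalid="ignore"):
        mean_cv = np.where(ok.any(axis=1), np.nansum(np.where(ok, cv, 0.0), axis=1)
                           / ok.sum(axis=1), np.nan)
    return pd.DataFrame(
        {
            "platform": platform,
            "n_pairs": ok.sum(axis=1),
            "cv_percent": np.minimum(mean_cv, cap),
        },
        index=values.index,
    )


# ---------------------------------------------------------------------------
# missingness
# ---------------------------------------------------------------------------

def missingness_profile(
    values: pd.DataFrame,
    intervals: Sequence[float] = (0, 10, 20, 30, 40, 50, 60, 70, 80, 90, 100),
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-feature missing fraction plus an interval histogram.

    Returns ``(fractions, histogram)`` where fractions are in [0, 1] and the
    histogram counts features per missingness interval (percent scale,
    right-closed except the first interval which includes 0) together with the
    cumulative feature count at each interval's upper bound.
    """
    frac = values.isna().mean(axis=1)
    pct = frac * 100.0
    edges = list(intervals)
    cats = pd.cut(pct, bins=edges, right=True, include_lowest=True)
    hist = cats.value_counts().sort_index().rename("n_features").to_frame()
    hist["cumulative"] = hist["n_features"].cumsum()
    return frac, hist


def npx_missingness(
    npx: pd.DataFrame,
    treat_below_lod_as_missing: bool = False,
    samples: Sequence[str] | None = None,
) -> pd.Series:
    """Per-assay missing fraction of an NPX table.

    With ``treat_below_lod_as_missing`` the below-LOD flags count as missing
    (the "cleaned" convention); otherwise only truly absent measurements do.
    """
    df = npx
    if samples is not None:
        df = df[df["sample_id"].isin(set(samples))]
        n = len(set(samples))
    else:
        n = df["sample_id"].nunique()
    present = df.groupby("olink_id")["npx"].apply(lambda s: s.notna().sum())
    if treat_below_lod_as_missing:
        flagged = df.groupby("olink_id")["below_lod"].sum()
        present = present - flagged
    return 1.0 - present / n


# ---------------------------------------------------------------------------
# coverage by concentration
# ---------------------------------------------------------------------------

def coverage_by_concentration(
    detected_ms: Iterable[str],
    detected_affinity: Iterable[str],
    reference: "pd.DataFrame | object",
    bin_edges_log10: Sequence[float] = (-5, -3, -1, 1, 3, 5, 7),
) -> pd.DataFrame:
    """Classify every reference protein into a concentration bin x detection class.

    Bins are right-closed intervals on log10 ng/mL; proteins without a
    concentration estimate fall into an ``unknown`` bin.  Detection classes are
    ``both / ms_only / affinity_only / not_detected`` against the reference
    set, and each protein lands in exactly one (bin, class) cell.
    """
    table = reference.table if hasattr(reference, "table") else reference
    ms = set(detected_ms)
    aff = set(detected_affinity)

    conc = table["conc_ng_ml"]
    log10c = np.log10(conc.where(conc > 0))
    cats = pd.cut(log10c, bins=list(bin_edges_log10), right=True)
    labels = cats.astype(object).where(cats.notna(), "unknown")

    idx = table.index
    in_ms = idx.isin(ms)
    in_aff = idx.isin(aff)
    klass = np.select(
        [in_ms & in_aff, in_ms & ~in_aff, ~in_ms & in_aff],
        ["both", "ms_only", "affinity_only"],
        default="not_detected",
    )
    df = pd.DataFrame({"bin": labels, "class": klass}, index=idx)
    out = (
        df.groupby(["bin", "class"], observed=False).size().unstack("class", fill_value=0)
    )
    for c in ("both", "ms_only", "affinity_only", "not_detected"):
        if c not in out.columns:
            out[c] = 0
    out = out[["both", "ms_only", "affinity_only", "not_detected"]]
    out["total"] = out.sum(axis=1)
    return out


# ---------------------------------------------------------------------------
# overrepresentation (hypergeometric)
# ---------------------------------------------------------------------------

def ora_hypergeom(
    hits: Iterable[str],
    annotated: Iterable[str],
    background: Iterable[str],
) -> tuple[float, float]:
    """Upper-tail hypergeometric overrepresentation test.

    Returns ``(p, fold_enrichment)`` for the overlap of ``hits`` with
    ``annotated`` against ``background``; fold enrichment is
    (|hits∩annot|/|hits|) / (|annot|/|background|).  Both input sets must be
    subsets of the background.
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background")
    h = set(hits)
    a = set(annotated)
    if not h <= bg or not a <= bg:
        raise ValueError("hits and annotated must be subsets of the background")
    N, K, n = len(bg), len(a), len(h)
    k = len(h & a)
    p = float(hypergeom.sf(k - 1, N, K, n))
    if n == 0 or K == 0:
        fold = float("nan")
    else:
        fold = (k / n) / (K / N)
    return p, fold


def ora_table(
    hits: Iterable[str],
    annotation_sets: Mapping[str, Iterable[str]],
    background: Iterable[str],
) -> pd.DataFrame:
    """Run :func:`ora_hypergeom` per annotation term with BH adjustment."""
    bg = set(background)
    h = set(hits)
    rows = []
    for term, members in annotation_sets.items():
        a = set(members) & bg
        p, fold = ora_hypergeom(h, a, bg)
        rows.append({"term": term, "n_annotated": len(a),
                     "overlap": len(h & a), "p": p, "fold_enrichment": fold})
    df = pd.DataFrame(rows).set_index("term")
    if len(df):
        df["fdr"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    else:
        df["fdr"] = []
    return df.sort_values("p")
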