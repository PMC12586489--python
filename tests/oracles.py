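"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive: explicit loops, sort-based medians, textbook formulas.
They never call the library code paths they verify.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd


def brute_median(values) -> float:
    vals = sorted(values)
    n = len(vals)
    if n == 0:
        return float("nan")
    if n % 2:
        return float(vals[n // 2])
    return (vals[n // 2 - 1] + vals[n // 2]) / 2.0


def brute_average_ranks(x) -> list[float]:
    """Average ranks (1-based) with explicit tie handling."""
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def brute_pearson(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sx = math.sqrt(sum((a - mx) ** 2 for a in x))
    sy = math.sqrt(sum((b - my) ** 2 for b in y))
    return cov / (sx * sy)


def brute_spearman(x, y) -> float:
    return brute_pearson(brute_average_ranks(list(x)), brute_average_ranks(list(y)))


def brute_bh(p) -> list[float]:
    """Benjamini-Hochberg by the definition: sort, scale, cumulative min, unsort."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    scaled = [p[order[i]] * m / (i + 1) for i in range(m)]
    for i in range(m - 2, -1, -1):
        scaled[i] = min(scaled[i], scaled[i + 1])
    out = [0.0] * m
    for i, idx in enumerate(order):
        out[idx] = min(1.0, scaled[i])
    return out


def brute_hypergeom_sf(k, N, K, n) -> float:
    """P(X >= k) by exhaustive summation over all achievable overlaps."""
    total = math.comb(N, n)
    p = 0.0
    for kk in range(k, min(K, n) + 1):
        if n - kk <= N - K:
            p += math.comb(K, kk) * math.comb(N - K, n - kk) / total
    return p


def brute_welch(a, b):
    """Longhand Welch t and Satterthwaite df."""
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    t = (ma - mb) / math.sqrt(va / na + vb / nb)
    df = (va / na + vb / nb) ** 2 / (
        (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    )
    return t, df


def brute_ols(x, y):
    """Closed-form simple least squares: slope, intercept, r2, adj_r2."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    slope = sxy / sxx
    intercept = my - slope * mx
    ss_res = sum((b - (intercept + slope * a)) ** 2 for a, b in zip(x, y))
    ss_tot = sum((b - my) ** 2 for b in y)
    r2 = 1.0 - ss_res / ss_tot
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return slope, intercept, r2, adj


def brute_first_fit(intervals) -> list[int]:
    """First-fit interval layout; input is a list of (start, end, label)."""
    order = sorted(range(len(intervals)), key=lambda i: intervals[i])
    rows_end: list[float] = []
    assignment = [0] * len(intervals)
    for idx in order:
        s, e = intervals[idx][0], intervals[idx][1]
        placed = False
        for ri in range(len(rows_end)):
            if rows_end[ri] < s:
                assignment[idx] = ri
                rows_end[ri] = e
                placed = True
                break
        if not placed:
            assignment[idx] = len(rows_end)
            rows_end.append(e)
    return assignment


def brute_rollup(psm: pd.DataFrame, set_layout: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Loop-based PSM roll-up re-implementation (exclusions, medians, centering)."""
    all_samples = [s for samples in set_layout.values() for s in samples]

    # group rows per (set, psm_id)
    groups: dict[tuple, list] = {}
    for _, row in psm.iterrows():
        groups.setdefault((row["set"], row["psm_id"]), []).append(row)

    ratios = []  # (protein, peptide, sample, ratio)
    for (set_name, _), rows in groups.items():
        expected = len(set_layout[set_name]) + 1
        present = [r for r in rows if not pd.isna(r["log2_intensity"])]
        if len(present) != expected:
            continue  # missing value in some channel
        prot = str(rows[0]["proteins"])
        if ";" in prot:
            continue  # multi protein group
        is_val = next(r["log2_intensity"] for r in rows if r["channel"] == "IS")
        for r in rows:
            if r["channel"] == "IS":
                continue
            ratios.append((prot, r["peptide"], r["channel"],
                           r["log2_intensity"] - is_val))

    def build(key_idx):
        per_cell: dict[tuple, list] = {}
        for prot, pep, sample, ratio in ratios:
            key = (prot, pep)[key_idx]
            per_cell.setdefault((key, sample), []).append(ratio)
        features = sorted({k for k, _ in per_cell})
        mat = pd.DataFrame(np.nan, index=features, columns=all_samples)
        for (feat, sample), vals in per_cell.items():
            mat.loc[feat, sample] = brute_median(vals)
        for sample in all_samples:
            col = [v for v in mat[sample] if not pd.isna(v)]
            if col:
                mat[sample] = mat[sample] - brute_median(col)
        return mat

    return build(0), build(1)
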