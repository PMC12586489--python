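"""Reading, validation and matching of the two platforms' quantification tables.

The MS side arrives as PSM-level log2 reporter intensities that are rolled up to
peptide- and protein-level relative quantities (median of channel/internal-standard
log2 ratios, then per-channel median centering).  The affinity side arrives as a
long NPX table with per-assay limits of detection and QC flags.  Cross-platform
identity is resolved primarily by UniProt ID and secondarily by gene name.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: channel label reserved for the pooled internal standard of a TMT set
IS_CHANNEL = "IS"

#: NA tokens accepted in TSV quantification matrices
NA_TOKENS = ("", "NA")

NPX_COLUMNS = [
    "sample_id", "olink_id", "uniprot_ids", "gene", "panel", "panel_version",
    "npx", "lod", "below_lod", "sample_qc_warn", "assay_qc_warn",
]


class DataFormatError(ValueError):
    """Raised for malformed input tables (duplicate rows, bad tokens, ...)."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class QuantMatrix:
    """Feature x sample matrix of log2 relative abundances with batch labels.

    ``values`` holds log2 ratios to the internal standard (median-centered per
    channel); missing entries are NaN.  ``tmt_sets`` maps every sample column to
    its TMT set.  ``feature_meta`` optionally carries per-feature annotation
    (peptide sequence -> protein/gene for peptide-level matrices).
    """

    values: pd.DataFrame
    tmt_sets: pd.Series
    feature_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise DataFormatError(f"duplicate feature IDs: {dups[:5]}")
        missing = [c for c in self.values.columns if c not in self.tmt_sets.index]
        if missing:
            raise DataFormatError(f"samples without a TMT set label: {missing[:5]}")
        self.tmt_sets = self.tmt_sets.reindex(self.values.columns)
        vals = self.values.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise DataFormatError("non-finite (inf) quantification values")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_features(self) -> int:
        return len(self.values.index)

    @property
    def n_samples(self) -> int:
        return len(self.values.columns)


@dataclass
class OverlapMap:
    """Resolved matching between MS protein groups and affinity assays.

    ``pairs`` has one row per (ms_id, olink_id) with ``match_basis`` in
    {"uniprot", "gene"}; UniProt matches take precedence per assay.
    ``isoform_groups`` maps genes for which the platforms quantify more than a
    single UniProt ID to the list of MS protein IDs sharing that gene.
    """

    pairs: pd.DataFrame
    isoform_groups: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pairs.duplicated(subset=["ms_id", "olink_id"]).any():
            raise DataFormatError("duplicate (ms_id, olink_id) pair in OverlapMap")


@dataclass
class ReferenceProteome:
    """Union of supplied reference plasma-proteome ID lists.

    ``table`` is indexed by UniProt ID with membership flags per source list and
    an estimated blood concentration (ng/mL) whose ``conc_source`` follows the
    precedence ms_based > immunoassay.
    """

    table: pd.DataFrame

    @property
    def uniprot_ids(self) -> set[str]:
        return set(self.table.index)

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# PSM roll-up
# ---------------------------------------------------------------------------

def roll_up_psms(
    psm: pd.DataFrame,
    set_layout: Mapping[str, Sequence[str]],
) -> tuple[QuantMatrix, QuantMatrix]:
    """Roll PSM-level log2 intensities up to protein and peptide matrices.

    ``psm`` is long-form with columns ``set, psm_id, peptide, proteins, gene,
    channel, log2_intensity`` (one row per PSM x channel; ``proteins`` is a
    ';'-joined protein-group string; the internal standard uses channel "IS").
    ``set_layout`` maps each TMT set to its ordered sample channels (excluding
    the internal standard).

    Rules applied, in order:

    1. PSMs with a missing value in any channel of their set are excluded
       (absent rows count as missing).
    2. PSMs mapping to more than one protein group are excluded.
    3. ratio = log2(channel) - log2(internal standard), per PSM and channel.
    4. Peptide / protein value = median of its PSM ratios within each channel.
    5. Each channel is centered by subtracting its median value (separately for
       the protein- and peptide-level matrices).
    """
    required = {"set", "psm_id", "peptide", "proteins", "channel", "log2_intensity"}
    if not required.issubset(psm.columns):
        raise DataFormatError(f"PSM table missing columns: {sorted(required - set(psm.columns))}")
    for s, samples in set_layout.items():
        chans = set(psm.loc[psm["set"] == s, "channel"].unique())
        if len(chans) and IS_CHANNEL not in chans:
            raise DataFormatError(f"TMT set {s!r} has no internal-standard channel")

    psm = psm.copy()
    key = psm["set"].astype(str) + "\x00" + psm["psm_id"].astype(str)
    psm["_key"] = key

    # 1. completeness: a PSM needs a non-missing intensity in every channel of its set
    expected = {s: len(samples) + 1 for s, samples in set_layout.items()}
    ok_rows = psm["log2_intensity"].notna()
    n_present = psm.loc[ok_rows].groupby("_key")["log2_intensity"].size()
    n_expected = psm.groupby("_key")["set"].first().map(lambda s: expected[s])
    complete_keys = n_present.reindex(n_expected.index, fill_value=0) == n_expected
    complete_keys = set(complete_keys.index[complete_keys])

    # 2. unique protein group
    single = ~psm["proteins"].astype(str).str.contains(";", regex=False)

    keep = psm["_key"].isin(complete_keys) & single
    kept = psm.loc[keep]

    # 3. log2 ratio to the internal standard of the same PSM
    is_vals = (
        kept.loc[kept["channel"] == IS_CHANNEL]
        .set_index("_key")["log2_intensity"]
    )
    rows = kept.loc[kept["channel"] != IS_CHANNEL].copy()
    rows["ratio"] = rows["log2_intensity"].to_numpy() - is_vals.reindex(rows["_key"]).to_numpy()

    all_samples = [s for samples in set_layout.values() for s in samples]
    sets = pd.Series(
        {s: set_name for set_name, samples in set_layout.items() for s in samples},
        name="tmt_set",
    )

    # 4. medians per feature x channel
    prot = (
        rows.groupby(["proteins", "channel"], sort=True)["ratio"].median().unstack("channel")
    )
    pep = (
        rows.groupby(["peptide", "channel"], sort=True)["ratio"].median().unstack("channel")
    )
    prot = prot.reindex(columns=all_samples)
    pep = pep.reindex(columns=all_samples)

    # 5. per-channel median centering (protein and peptide levels separately)
    prot = prot.sub(prot.median(axis=0, skipna=True), axis=1)
    pep = pep.sub(pep.median(axis=0, skipna=True), axis=1)

    meta_cols = [c for c in ("proteins", "gene") if c in rows.columns]
    pep_meta = rows.groupby("peptide")[meta_cols].first()
    pep_meta = pep_meta.rename(columns={"proteins": "protein_id"}).reindex(pep.index)

    prot.index.name = "protein_id"
    pep.index.name = "peptide"
    return (
        QuantMatrix(values=prot, tmt_sets=sets),
        QuantMatrix(values=pep, tmt_sets=sets, feature_meta=pep_meta),
    )


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def write_quant(qm: QuantMatrix, path: str | Path) -> None:
    """Write the TSV dialect: row 1 sample IDs, row 2 TMT-set labels, then features."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("feature_id\t" + "\t".join(map(str, qm.sample_ids)) + "\n")
        fh.write("set\t" + "\t".join(qm.tmt_sets.astype(str)) + "\n")
        for fid, row in qm.values.iterrows():
            cells = ["" if pd.isna(v) else format(v, ".10g") for v in row]
            fh.write(str(fid) + "\t" + "\t".join(cells) + "\n")


def read_quant(path: str | Path) -> QuantMatrix:
    """Read a quantification matrix written by :func:`write_quant`."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        setrow = fh.readline().rstrip("\n").split("\t")
    if not header or header[0] != "feature_id" or not setrow or setrow[0] != "set":
        raise DataFormatError(f"{path}: expected 'feature_id' and 'set' header rows")
    samples = header[1:]
    sets = pd.Series(setrow[1:], index=samples, name="tmt_set")
    df = pd.read_csv(
        path, sep="\t", skiprows=[1], index_col=0,
        na_values=list(NA_TOKENS), keep_default_na=False,
    )
    df.columns = samples
    return QuantMatrix(values=df.astype(float), tmt_sets=sets)


def write_npx(npx: pd.DataFrame, path: str | Path) -> None:
    npx.loc[:, NPX_COLUMNS].to_csv(path, index=False)


def read_npx(path: str | Path) -> pd.DataFrame:
    """Read and validate a long NPX CSV.

    Checks: unique (sample, assay) rows, numeric NPX (declared NA tokens only),
    and recomputes ``below_lod`` as npx < lod.  Malformed rows are reported with
    their file line numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, na_values=list(NA_TOKENS), keep_default_na=False)
    missing = [c for c in NPX_COLUMNS if c not in df.columns]
    if missing:
        raise DataFormatError(f"{path}: missing NPX columns {missing}")
    dup = df.duplicated(subset=["sample_id", "olink_id"], keep=False)
    if dup.any():
        lines = (df.index[dup] + 2).tolist()  # +2: header + 1-based
        raise DataFormatError(
            f"{path}: duplicate (sample_id, olink_id) rows at lines {lines[:10]}"
        )
    npx_numeric = pd.to_numeric(df["npx"], errors="coerce")
    bad = npx_numeric.isna() & df["npx"].notna()
    if bad.any():
        lines = (df.index[bad] + 2).tolist()
        raise DataFormatError(f"{path}: non-numeric NPX values at lines {lines[:10]}")
    df["npx"] = npx_numeric
    df["lod"] = pd.to_numeric(df["lod"], errors="coerce")
    for c in ("below_lod", "sample_qc_warn", "assay_qc_warn"):
        df[c] = df[c].astype(bool)
    df["below_lod"] = df["npx"] < df["lod"]
    return df


# ---------------------------------------------------------------------------
# identifier matching
# ---------------------------------------------------------------------------

def split_uniprot_ids(value: str | Sequence[str]) -> list[str]:
    """Normalize an ordered UniProt ID list (';'-joined string or sequence)."""
    if isinstance(value, str):
        return [v.strip() for v in value.split(";") if v.strip()]
    return list(value)


def base_accession(uniprot_id: str) -> str:
    """Strip an isoform suffix: 'P48740-2' -> 'P48740'."""
    return uniprot_id.split("-")[0]


def build_overlap(ms_proteins: pd.DataFrame, assays: pd.DataFrame) -> OverlapMap:
    """Match MS protein groups to affinity assays.

    ``ms_proteins`` needs columns ``protein_id, gene``; ``assays`` needs
    ``olink_id, uniprot_ids, gene`` (``uniprot_ids`` is the assay's ordered ID
    list).  For each assay the first UniProt ID is tried against the MS IDs;
    unmatched assays fall back to gene name, which may yield several MS protein
    groups (isoform groups).  Isoform suffixes never match at the UniProt level.
    """
    ms_ids = set(ms_proteins["protein_id"])
    by_gene: dict[str, list[str]] = {}
    for pid, gene in zip(ms_proteins["protein_id"], ms_proteins["gene"]):
        by_gene.setdefault(str(gene), []).append(str(pid))

    rows: list[dict] = []
    for _, assay in assays.iterrows():
        uids = split_uniprot_ids(assay["uniprot_ids"])
        gene = str(assay["gene"])
        first = uids[0] if uids else None
        if first is not None and first in ms_ids:
            rows.append(
                {"ms_id": first, "olink_id": assay["olink_id"], "gene": gene,
                 "match_basis": "uniprot"}
            )
        else:
            for pid in sorted(by_gene.get(gene, [])):
                rows.append(
                    {"ms_id": pid, "olink_id": assay["olink_id"], "gene": gene,
                     "match_basis": "gene"}
                )

    pairs = pd.DataFrame(rows, columns=["ms_id", "olink_id", "gene", "match_basis"])

    # genes where the two platforms quantify different or multiple UniProt IDs
    isoform_groups: dict[str, list[str]] = {}
    assay_first = {
        str(a["gene"]): (split_uniprot_ids(a["uniprot_ids"]) or [None])[0]
        for _, a in assays.iterrows()
    }
    for gene in sorted(set(pairs["gene"])):
        members = sorted(by_gene.get(gene, []))
        if not members:
            continue
        first = assay_first.get(gene)
        if len(members) > 1 or (first is not None and members != [first]):
            isoform_groups[gene] = members
    return OverlapMap(pairs=pairs, isoform_groups=isoform_groups)


def compile_reference(
    hppp_ids: Iterable[str],
    hpa_conc: pd.DataFrame,
    hpa_secreted_ids: Iterable[str],
) -> ReferenceProteome:
    """Compile the reference plasma proteome from supplied ID lists.

    ``hpa_conc`` needs columns ``uniprot, conc_ng_ml, source`` with ``source``
    in {"ms_based", "immunoassay"}.  The reference set is the union of the three
    sources; when both concentration sources exist for a protein the MS-based
    estimate wins.  Duplicate concentrations within one source keep the first
    occurrence with a warning.
    """
    hppp = {str(x) for x in hppp_ids}
    secreted = {str(x) for x in hpa_secreted_ids}

    conc = hpa_conc.copy()
    bad_source = ~conc["source"].isin(["ms_based", "immunoassay"])
    if bad_source.any():
        raise DataFormatError(
            f"unknown concentration source(s): {sorted(conc.loc[bad_source, 'source'].unique())}"
        )
    if (conc["conc_ng_ml"] <= 0).any():
        raise DataFormatError("non-positive concentration in HPA table")
    dup = conc.duplicated(subset=["uniprot", "source"], keep="first")
    if dup.any():
        warnings.warn(
            f"{int(dup.sum())} duplicate (uniprot, source) concentration rows; keeping first",
            stacklevel=2,
        )
        conc = conc.loc[~dup]

    all_ids = sorted(hppp | secreted | set(conc["uniprot"].astype(str)))
    table = pd.DataFrame(index=pd.Index(all_ids, name="uniprot"))
    table["in_hppp"] = table.index.isin(hppp)
    table["in_hpa_conc"] = table.index.isin(set(conc["uniprot"]))
    table["in_hpa_secreted"] = table.index.isin(secreted)

    conc_wide = conc.pivot(index="uniprot", columns="source", values="conc_ng_ml")
    ms = conc_wide.get("ms_based", pd.Series(dtype=float))
    ia = conc_wide.get("immunoassay", pd.Series(dtype=float))
    table["conc_ng_ml"] = ms.reindex(table.index)
    table["conc_source"] = np.where(table["conc_ng_ml"].notna(), "ms_based", None)
    use_ia = table["conc_ng_ml"].isna() & ia.reindex(table.index).notna()
    table.loc[use_ia, "conc_ng_ml"] = ia.reindex(table.index)[use_ia]
    table.loc[use_ia, "conc_source"] = "immunoassay"
    return ReferenceProteome(table=table)


def read_id_list(path: str | Path) -> list[str]:
    """Read a plain-text ID list, one UniProt ID per line."""
    with Path(path).open() as fh:
        return [line.strip() for line in fh if line.strip()]
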