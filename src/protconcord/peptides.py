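"""Peptide-level cross-platform agreement along the protein sequence.

MS peptides are matched to affinity assays by gene name and correlated
(Spearman) per peptide; peptides quantified in fewer than ``MIN_PEPTIDE_SAMPLES``
(15) samples and genes with fewer than two surviving peptides are excluded.
Peptides are localized on isoform sequences by exact substring search
(1-based inclusive coordinates, leftmost occurrence, multi-hit flagged),
summarized per user-supplied sequence region, laid out into non-overlapping
display tracks, and painted onto a structure file's temperature-factor column
for 3D inspection.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .concordance import categorize, correlate_pair, npx_matrix, shared_samples
from .ingest import QuantMatrix

MIN_PEPTIDE_SAMPLES = 15
MIN_PEPTIDES_PER_GENE = 2

#: temperature-factor sentinel for residues not covered by any peptide
UNCOVERED_SENTINEL = -9.99


# ---------------------------------------------------------------------------
# peptide-assay correlations
# ---------------------------------------------------------------------------

def peptide_correlations(
    peptide_qm: QuantMatrix,
    npx: pd.DataFrame,
    min_samples: int = MIN_PEPTIDE_SAMPLES,
    min_peptides_per_gene: int = MIN_PEPTIDES_PER_GENE,
) -> pd.DataFrame:
    """Spearman correlation of every MS peptide with its gene's affinity assay.

    Requires ``peptide_qm.feature_meta`` with a ``gene`` column.  Returns one
    row per surviving peptide (``gene, olink_id, rho, n_overlap, category``);
    genes without an assay are skipped and counted in
    ``result.attrs['n_genes_without_assay']``.
    """
    meta = peptide_qm.feature_meta
    if meta is None or "gene" not in meta.columns:
        raise ValueError("peptide matrix needs feature_meta with a 'gene' column")
    mat = npx_matrix(npx, clean=False)
    samples = shared_samples(peptide_qm, mat)
    assay_of_gene = (
        npx.drop_duplicates("olink_id").groupby("gene")["olink_id"].first()
    )

    rows: list[dict] = []
    n_no_assay = 0
    for pep in peptide_qm.feature_ids:
        gene = meta.loc[pep, "gene"]
        oid = assay_of_gene.get(gene)
        if oid is None or oid not in mat.index:
            n_no_assay += 1
            continue
        x = peptide_qm.values.loc[pep, samples].to_numpy(dtype=float)
        y = mat.loc[oid, samples].to_numpy(dtype=float)
        res = correlate_pair(x, y, "spearman", min_overlap=min_samples)
        if res is None:
            continue
        rho, n = res
        rows.append(
            {"peptide": pep, "gene": gene, "olink_id": oid, "rho": rho,
             "n_overlap": n, "category": categorize(rho)}
        )
    df = pd.DataFrame(
        rows, columns=["peptide", "gene", "olink_id", "rho", "n_overlap", "category"]
    )
    counts = df.groupby("gene")["peptide"].transform("size") if len(df) else pd.Series(dtype=int)
    df = df[counts >= min_peptides_per_gene].reset_index(drop=True)
    df.attrs["n_genes_without_assay"] = n_no_assay
    return df


# ---------------------------------------------------------------------------
# localization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Placement:
    peptide: str
    isoform_id: str
    start: int  # 1-based inclusive
    end: int
    multi_hit: bool           # occurs more than once in this isoform
    isoform_specific: bool    # found in exactly one isoform
    n_isoforms_hit: int


def _occurrences(needle: str, haystack: str) -> list[int]:
    """All (possibly overlapping) 0-based occurrence positions."""
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def locate_peptide(
    peptide: str,
    isoforms: Mapping[str, str] | Sequence[tuple[str, str]],
) -> Placement | None:
    """Exact substring placement of a peptide on a set of isoform sequences.

    Returns the leftmost occurrence on the preferred isoform (canonical
    accession without isoform suffix first, then lexicographic), with
    ``multi_hit`` flagging repeated occurrences within that isoform.  Returns
    None when the peptide is absent from every isoform (variant peptide,
    modification, or sequence mismatch — not fatal).
    """
    items = list(isoforms.items()) if isinstance(isoforms, Mapping) else list(isoforms)
    hits = {iso: _occurrences(peptide, seq) for iso, seq in items if _occurrences(peptide, seq)}
    if not hits:
        return None

    def pref(iso: str) -> tuple[int, str]:
        return (0 if "-" not in iso else 1, iso)

    iso = min(hits, key=pref)
    pos = hits[iso][0]
    return Placement(
        peptide=peptide,
        isoform_id=iso,
        start=pos + 1,
        end=pos + len(peptide),
        multi_hit=len(hits[iso]) > 1,
        isoform_specific=len(hits) == 1,
        n_isoforms_hit=len(hits),
    )


def read_isoform_fasta(path: str | Path) -> dict[str, dict[str, str]]:
    """Read UniProt-style FASTA (``sp|ID|GENE_HUMAN``) grouped by gene.

    Returns ``{gene: {isoform_id: sequence}}``.
    """
    from Bio import SeqIO

    genes: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) >= 3:
            iso = parts[1]
            gene = parts[2].rsplit("_", 1)[0]
        else:
            iso, gene = rec.id, rec.id
        genes.setdefault(gene, {})[iso] = str(rec.seq)
    return genes


def locate_peptides(
    pepcorr: pd.DataFrame,
    fasta_genes: Mapping[str, Mapping[str, str]],
) -> pd.DataFrame:
    """Place every correlated peptide on its gene's isoforms.

    Adds ``isoform_id, start, end, multi_hit, isoform_specific`` columns;
    unplaceable peptides are returned with NaN coordinates and a ``placed``
    flag of False.
    """
    rows = []
    for _, rec in pepcorr.iterrows():
        isoforms = fasta_genes.get(rec["gene"], {})
        placement = locate_peptide(rec["peptide"], isoforms) if isoforms else None
        d = dict(rec)
        if placement is None:
            d.update({"isoform_id": None, "start": np.nan, "end": np.nan,
                      "multi_hit": False, "isoform_specific": False, "placed": False})
        else:
            d.update(
                {"isoform_id": placement.isoform_id, "start": placement.start,
                 "end": placement.end, "multi_hit": placement.multi_hit,
                 "isoform_specific": placement.isoform_specific, "placed": True}
            )
        rows.append(d)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# region summaries
# ---------------------------------------------------------------------------

def summarize_regions(
    placed: pd.DataFrame,
    regions: pd.DataFrame,
    overlap_rule: str = "any",
) -> pd.DataFrame:
    """Median peptide correlation per sequence region.

    ``regions`` has columns ``gene, region, isoform_id, start, end`` (1-based
    inclusive).  With ``overlap_rule="any"`` a peptide counts in every region
    it touches by >= 1 residue (boundary-spanning peptides count in all);
    ``"majority"`` assigns it only to regions holding more than half of its
    residues.  Regions without peptides are emitted with ``n_peptides = 0``
    and NaN median.
    """
    if overlap_rule not in ("any", "majority"):
        raise ValueError("overlap_rule must be 'any' or 'majority'")
    rows = []
    pl = placed[placed.get("placed", True) & placed["start"].notna()]
    for _, reg in regions.iterrows():
        sub = pl[(pl["gene"] == reg["gene"]) & (pl["isoform_id"] == reg["isoform_id"])]
        ov = np.minimum(sub["end"], reg["end"]) - np.maximum(sub["start"], reg["start"]) + 1
        if overlap_rule == "any":
            inside = ov >= 1
        else:
            inside = ov > (sub["end"] - sub["start"] + 1) / 2.0
        sel = sub[inside]
        cat_mix = sel["category"].value_counts().to_dict() if len(sel) else {}
        rows.append(
            {
                "gene": reg["gene"], "region": reg["region"],
                "isoform_id": reg["isoform_id"],
                "start": int(reg["start"]), "end": int(reg["end"]),
                "n_peptides": int(len(sel)),
                "median_rho": float(sel["rho"].median()) if len(sel) else float("nan"),
                "category_mix": json.dumps(cat_mix, sort_keys=True),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# track layout
# ---------------------------------------------------------------------------

def layout_tracks(intervals: pd.DataFrame) -> pd.DataFrame:
    """First-fit greedy layout of peptide intervals into non-overlapping rows.

    Peptides are processed by ascending ``(start, end, peptide)``; each goes
    to the lowest-index row whose last interval ends before its start
    (adjacency allowed with 1-based inclusive coordinates: previous end <
    start).  Deterministic and invariant to input order.  Returns the input
    with a ``row`` column (0-based).
    """
    cols = ["start", "end"]
    if not set(cols).issubset(intervals.columns):
        raise ValueError("layout needs 'start' and 'end' columns")
    tie = "peptide" if "peptide" in intervals.columns else None
    order_cols = ["start", "end"] + ([tie] if tie else [])
    df = intervals.sort_values(order_cols, kind="mergesort")
    row_ends: list[float] = []
    assigned = []
    for _, rec in df.iterrows():
        s, e = rec["start"], rec["end"]
        for ri, last_end in enumerate(row_ends):
            if last_end < s:
                assigned.append(ri)
                row_ends[ri] = e
                break
        else:
            assigned.append(len(row_ends))
            row_ends.append(e)
    df = df.assign(row=assigned)
    return df.sort_index()


# ---------------------------------------------------------------------------
# structure annotation
# ---------------------------------------------------------------------------

def annotate_structure(
    placed: pd.DataFrame,
    structure_path: str | Path,
    isoform_id: str,
    sequence: str,
    out_path: str | Path,
    mismatch_threshold: float = 0.05,
) -> pd.Series:
    """Write per-residue median peptide correlations into a PDB's B-factor column.

    Residue numbering in the structure must align to the 1-based isoform
    sequence; the residue identities are cross-checked against ``sequence``
    and more than ``mismatch_threshold`` disagreement is an error listing the
    mismatched positions.  Covered residues receive the median rho of the
    peptides spanning them (2 decimals); uncovered residues receive the
    sentinel -9.99.  Coordinates are untouched.  Returns the per-residue
    value series (1-based index).
    """
    from Bio.PDB import PDBParser, PDBIO
    from Bio.PDB.Polypeptide import protein_letters_3to1

    sub = placed[
        (placed.get("placed", True))
        & (placed["isoform_id"] == isoform_id)
        & placed["start"].notna()
    ]
    per_residue_vals: dict[int, list[float]] = {}
    for _, rec in sub.iterrows():
        for pos in range(int(rec["start"]), int(rec["end"]) + 1):
            per_residue_vals.setdefault(pos, []).append(rec["rho"])
    values = pd.Series(
        {pos: round(float(np.median(v)), 2) for pos, v in per_residue_vals.items()}
    )
    values = values.reindex(range(1, len(sequence) + 1), fill_value=UNCOVERED_SENTINEL)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tolerate minimal synthetic PDB records
        structure = PDBParser(QUIET=True).get_structure("model", str(structure_path))

    mismatches: list[int] = []
    n_checked = 0
    for residue in structure.get_residues():
        if residue.id[0] != " ":
            continue
        pos = residue.id[1]
        if 1 <= pos <= len(sequence):
            n_checked += 1
            one = protein_letters_3to1.get(residue.get_resname().strip().upper())
            if one is not None and one != sequence[pos - 1]:
                mismatches.append(pos)
    if n_checked and len(mismatches) / n_checked > mismatch_threshold:
        raise ValueError(
            f"structure/sequence mismatch at {len(mismatches)}/{n_checked} residues: "
            f"{mismatches[:10]}"
        )

    for residue in structure.get_residues():
        pos = residue.id[1]
        val = float(values.get(pos, UNCOVERED_SENTINEL))
        for atom in residue.get_atoms():
            atom.set_bfactor(val)
    io = PDBIO()
    io.set_structure(structure)
    io.save(str(out_path))
    return values


def read_structure_bfactors(path: str | Path) -> pd.Series:
    """Per-residue temperature-factor values of a PDB file (1-based index)."""
    from Bio.PDB import PDBParser

    structure = PDBParser(QUIET=True).get_structure("model", str(path))
    vals = {}
    for residue in structure.get_residues():
        atoms = list(residue.get_atoms())
        if atoms:
            vals[residue.id[1]] = float(atoms[0].get_bfactor())
    return pd.Series(vals).sort_index()


def write_synthetic_structure(sequence: str, path: str | Path) -> None:
    """Write a minimal synthetic C-alpha-only PDB for a sequence.

    Coordinates trace an idealized helix — a synthetic stand-in used to
    exercise structure annotation, not a predicted structure.
    """
    from Bio.SeqUtils import seq3

    lines = []
    for i, aa in enumerate(sequence):
        theta = i * 100.0 * np.pi / 180.0
        x, y, z = 2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i
        resname = seq3(aa).upper()
        lines.append(
            f"ATOM  {i + 1:5d}  CA  {resname:>3s} A{i + 1:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}           C"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# sequence-plot data export
# ---------------------------------------------------------------------------

def export_sequence_plot(
    gene: str,
    isoform_id: str,
    sequence_length: int,
    placed: pd.DataFrame,
    regions: pd.DataFrame | None,
    path: str | Path,
) -> dict:
    """JSON export of one gene's sequence-plot data (peptide tracks + regions)."""
    sub = placed[
        (placed["gene"] == gene) & (placed["isoform_id"] == isoform_id)
        & placed["start"].notna()
    ]
    laid = layout_tracks(sub) if len(sub) else sub.assign(row=[])
    payload = {
        "gene": gene,
        "isoform_id": isoform_id,
        "sequence_length": int(sequence_length),
        "peptides": [
            {
                "peptide": r["peptide"], "start": int(r["start"]), "end": int(r["end"]),
                "rho": None if pd.isna(r["rho"]) else round(float(r["rho"]), 4),
                "category": r["category"], "row": int(r["row"]),
                "multi_hit": bool(r["multi_hit"]),
            }
            for _, r in laid.iterrows()
        ],
        "regions": [
            {"region": r["region"], "start": int(r["start"]), "end": int(r["end"])}
            for _, r in regions.iterrows()
            if r["gene"] == gene and r["isoform_id"] == isoform_id
        ]
        if regions is not None
        else [],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
    return payload
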