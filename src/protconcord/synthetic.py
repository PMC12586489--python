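"""Synthetic dual-platform plasma cohort with known ground truth.

Generates a latent log2-abundance layer (protein baselines spanning ~10 orders of
magnitude of blood concentration, sex effects, between-sample biological
variation, multi-isoform genes with correlated proteoform trajectories) and two
observation layers on top of it:

* an MS layer — PSM-level log2 reporter intensities per TMT channel, batch
  effects per TMT set, abundance-dependent (MNAR) protein-by-set dropout, and
  technical replicate noise; rolled up through the real
  :func:`protconcord.ingest.roll_up_psms` code path so the roll-up rules are
  exercised, not emulated;
* an affinity layer — long NPX records (log2 scale, +1 NPX = doubling) with a
  per-assay offset, isoform-weighted targeting, a limit of detection derived
  from the latent concentration distribution, and QC-warning flags.  Below-LOD
  values are flagged but retained.

Every random draw flows from explicit integer seeds, so identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import ingest
from .ingest import IS_CHANNEL, QuantMatrix, roll_up_psms

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
LOG2_10 = float(np.log2(10.0))

PANELS = [
    ("Cardiometabolic", "I"), ("Inflammation", "I"),
    ("Neurology", "I"), ("Oncology", "I"),
    ("Cardiometabolic_II", "II"), ("Inflammation_II", "II"),
    ("Neurology_II", "II"), ("Oncology_II", "II"),
]


class InvalidSpecError(ValueError):
    """Raised when a generator specification violates its invariants."""


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Latent cohort layer: who the samples are and what the proteins do.

    Defaults mirror the emulated study design: 88 samples (42% female), six
    duplicate aliquot pairs, baseline blood concentrations drawn uniformly over
    10 orders of magnitude (log10 ng/mL in [-3, 7]).
    """

    n_samples: int = 88
    n_proteins: int = 500
    frac_female: float = 37 / 88
    n_sex_affected: int = 50
    sex_effect_log2: float = 0.5
    conc_log10_range: tuple[float, float] = (-3.0, 7.0)
    biological_sd_log2: float = 0.5
    n_duplicate_pairs: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_proteins <= 0:
            raise InvalidSpecError("n_samples and n_proteins must be positive")
        if not 0.0 <= self.frac_female <= 1.0:
            raise InvalidSpecError("frac_female must lie in [0, 1]")
        if self.n_sex_affected > self.n_proteins or self.n_sex_affected < 0:
            raise InvalidSpecError("need 0 <= n_sex_affected <= n_proteins")
        if self.biological_sd_log2 < 0 or self.sex_effect_log2 < 0:
            raise InvalidSpecError("SDs and effect magnitudes must be >= 0")
        if self.conc_log10_range[0] > self.conc_log10_range[1]:
            raise InvalidSpecError("conc_log10_range must be (min, max)")
        if self.n_duplicate_pairs < 0 or self.n_duplicate_pairs > self.n_samples:
            raise InvalidSpecError("0 <= n_duplicate_pairs <= n_samples required")


@dataclass(frozen=True)
class MsNoiseSpec:
    """MS observation layer: TMT design, batch/technical noise, MNAR dropout.

    ``missing_base_rate`` is the protein-by-set dropout probability for a
    protein of average abundance; ``missing_abundance_slope`` steepens dropout
    for low-abundance proteins (logistic on the standardized latent mean).
    PSM counts per peptide and peptides per protein are 1 + Poisson draws.
    """

    n_tmt_sets: int = 8
    set_size: int = 16
    batch_sd_log2: float = 0.2
    tech_sd_log2: float = 0.3
    missing_base_rate: float = 0.1
    missing_abundance_slope: float = 1.0
    psm_per_peptide_mean: float = 1.0
    peptides_per_protein_mean: float = 1.5
    psm_offset_sd: float = 1.0
    multi_map_rate: float = 0.02
    channel_dropout_rate: float = 0.005

    def __post_init__(self) -> None:
        if self.n_tmt_sets <= 0 or self.set_size <= 1:
            raise InvalidSpecError("need n_tmt_sets >= 1 and set_size >= 2")
        for name in ("batch_sd_log2", "tech_sd_log2", "psm_per_peptide_mean",
                     "peptides_per_protein_mean", "psm_offset_sd"):
            if getattr(self, name) < 0:
                raise InvalidSpecError(f"{name} must be >= 0")
        for name in ("missing_base_rate", "multi_map_rate", "channel_dropout_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise InvalidSpecError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class AffinityNoiseSpec:
    """Affinity (PEA/NPX) observation layer."""

    tech_sd_npx: float = 0.3
    lod_quantile: float = 0.2
    qc_warning_rate: float = 0.01
    assay_qc_rate: float = 0.01
    assay_offset_sd: float = 1.0

    def __post_init__(self) -> None:
        for name in ("lod_quantile", "qc_warning_rate", "assay_qc_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise InvalidSpecError(f"{name} must lie in [0, 1]")
        if self.tech_sd_npx < 0 or self.assay_offset_sd < 0:
            raise InvalidSpecError("SDs must be >= 0")


@dataclass(frozen=True)
class ProteoformSpec:
    """A gene whose protein product exists as several measurable proteoforms.

    ``assay_targets`` are the affinity assay's mixture weights over the
    isoforms; ``proteoform_corr`` is the latent correlation between isoform
    abundance trajectories across samples.  ``region_map`` rows are
    (region_name, isoform_id, start, end), 1-based inclusive.
    """

    gene: str
    isoform_sequences: tuple[tuple[str, str], ...]
    region_map: tuple[tuple[str, str, int, int], ...]
    assay_targets: tuple[float, ...]
    proteoform_corr: float = 0.2

    def __post_init__(self) -> None:
        if not self.isoform_sequences:
            raise InvalidSpecError(f"{self.gene}: needs at least one isoform")
        if len(self.assay_targets) != len(self.isoform_sequences):
            raise InvalidSpecError(f"{self.gene}: one assay weight per isoform required")
        w = np.asarray(self.assay_targets, dtype=float)
        if (w < 0).any() or not np.isclose(w.sum(), 1.0):
            raise InvalidSpecError(f"{self.gene}: assay weights must be >= 0 and sum to 1")
        if not -1.0 <= self.proteoform_corr <= 1.0:
            raise InvalidSpecError(f"{self.gene}: proteoform_corr must lie in [-1, 1]")
        lengths = {iso: len(seq) for iso, seq in self.isoform_sequences}
        for name, iso, start, end in self.region_map:
            if iso not in lengths:
                raise InvalidSpecError(f"{self.gene}: region {name} on unknown isoform {iso}")
            if not 1 <= start <= end <= lengths[iso]:
                raise InvalidSpecError(f"{self.gene}: region {name} outside isoform {iso}")

    @property
    def isoform_ids(self) -> list[str]:
        return [iso for iso, _ in self.isoform_sequences]

    def sequence_of(self, isoform_id: str) -> str:
        for iso, seq in self.isoform_sequences:
            if iso == isoform_id:
                return seq
        raise KeyError(isoform_id)


@dataclass
class TruthTables:
    """Ground truth: the latent layer every observation is generated from."""

    latent: pd.DataFrame              # isoform UniProt ID x distinct sample
    sex: pd.Series                    # sample -> 'F' / 'M'
    effects: pd.Series                # affected feature -> signed log2 effect
    duplicate_pairs: list[tuple[str, str]]
    proteoforms: dict[str, ProteoformSpec] = field(default_factory=dict)
    gene_of: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
    spec: CohortSpec | None = None

    @property
    def sample_ids(self) -> pd.Index:
        return self.latent.columns

    @property
    def feature_ids(self) -> pd.Index:
        return self.latent.index


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def generate_cohort(
    spec: CohortSpec,
    proteoforms: Sequence[ProteoformSpec] = (),
) -> TruthTables:
    """Draw the latent cohort layer.

    Plain proteins get a synthetic sequence and are wrapped as single-isoform
    :class:`ProteoformSpec` objects with one region covering the whole
    sequence, so peptide generation and localization treat every gene
    uniformly.  Extra multi-isoform genes are appended after the plain block.
    Sex effects (random sign per protein) are applied to the female group of
    plain proteins only.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_samples, spec.n_proteins

    samples = [f"S{i + 1:03d}" for i in range(n)]
    n_female = int(round(spec.frac_female * n))
    sex = np.array(["M"] * n, dtype=object)
    sex[rng.permutation(n)[:n_female]] = "F"
    sex = pd.Series(sex, index=samples, name="sex")

    # plain proteins
    plain_ids = [f"P{i + 1:05d}" for i in range(p)]
    plain_genes = [f"G{i + 1:05d}" for i in range(p)]
    lo, hi = spec.conc_log10_range
    baseline = rng.uniform(lo, hi, size=p) * LOG2_10
    latent = baseline[:, None] + rng.normal(0.0, spec.biological_sd_log2, size=(p, n))

    affected_idx = rng.choice(p, size=spec.n_sex_affected, replace=False)
    signs = rng.choice([-1.0, 1.0], size=spec.n_sex_affected)
    female_mask = (sex.to_numpy() == "F").astype(float)
    effects = pd.Series(
        signs * spec.sex_effect_log2,
        index=pd.Index([plain_ids[i] for i in affected_idx], name="feature_id"),
        name="sex_effect_log2",
    )
    for i, eff in zip(affected_idx, signs * spec.sex_effect_log2):
        latent[i] += eff * female_mask

    all_specs: dict[str, ProteoformSpec] = {}
    for pid, gene in zip(plain_ids, plain_genes):
        seq = _random_sequence(rng, int(rng.integers(150, 401)))
        all_specs[gene] = ProteoformSpec(
            gene=gene,
            isoform_sequences=((pid, seq),),
            region_map=(("full", pid, 1, len(seq)),),
            assay_targets=(1.0,),
            proteoform_corr=1.0,
        )

    rows = list(latent)
    ids = list(plain_ids)
    genes = list(plain_genes)

    # multi-isoform genes with correlated trajectories
    for pf in proteoforms:
        if pf.gene in all_specs:
            raise InvalidSpecError(f"duplicate gene {pf.gene}")
        all_specs[pf.gene] = pf
        k = len(pf.isoform_sequences)
        base = rng.uniform(lo, hi) * LOG2_10
        cov = np.full((k, k), pf.proteoform_corr, dtype=float)
        np.fill_diagonal(cov, 1.0)
        sd = spec.biological_sd_log2
        z = rng.multivariate_normal(np.zeros(k), cov, size=n, method="cholesky").T
        for j, iso in enumerate(pf.isoform_ids):
            rows.append(base + sd * z[j])
            ids.append(iso)
            genes.append(pf.gene)

    latent_df = pd.DataFrame(
        np.vstack(rows), index=pd.Index(ids, name="feature_id"), columns=samples
    )
    gene_of = pd.Series(genes, index=latent_df.index, name="gene")
    duplicate_pairs = [(samples[i], f"{samples[i]}_B") for i in range(spec.n_duplicate_pairs)]
    return TruthTables(
        latent=latent_df, sex=sex, effects=effects,
        duplicate_pairs=duplicate_pairs, proteoforms=all_specs,
        gene_of=gene_of, spec=spec,
    )


# ---------------------------------------------------------------------------
# peptide design
# ---------------------------------------------------------------------------

def generate_peptides(
    proteoforms: Iterable[ProteoformSpec],
    peptides_per_region: int = 6,
    length_range: tuple[int, int] = (8, 16),
    seed: int = 0,
    tryptic: bool = False,
) -> pd.DataFrame:
    """Sample tryptic-like substrings wholly inside each declared region.

    Returns a design table with columns ``gene, isoform_id, region, peptide,
    start, end`` (1-based inclusive); every emitted peptide occurs at its
    recorded position in the isoform sequence by construction.  Regions shorter
    than the minimum peptide length are skipped with a warning.  With
    ``tryptic=True`` peptide C-termini snap to the nearest K/R within the
    region when one exists; localization never depends on cleavage rules.
    """
    import warnings as _warnings

    rng = np.random.default_rng(seed)
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise InvalidSpecError("length_range must satisfy 1 <= min <= max")
    rows: list[dict] = []
    for pf in proteoforms:
        for region, iso, start, end in pf.region_map:
            seq = pf.sequence_of(iso)
            rlen = end - start + 1
            if rlen < lo:
                _warnings.warn(
                    f"{pf.gene}/{region}: region length {rlen} < min peptide length {lo}; skipped",
                    stacklevel=2,
                )
                continue
            seen: set[str] = set()
            for _ in range(peptides_per_region):
                length = int(rng.integers(lo, min(hi, rlen) + 1))
                s = int(rng.integers(start, end - length + 2))
                e = s + length - 1
                if tryptic:
                    # snap C-terminus to the next K/R inside the region
                    for cand in range(e - 1, min(end, s + hi - 1)):
                        if seq[cand] in "KR":
                            e = cand + 1
                            break
                pep = seq[s - 1:e]
                if pep in seen:
                    continue
                seen.add(pep)
                rows.append(
                    {"gene": pf.gene, "isoform_id": iso, "region": region,
                     "peptide": pep, "start": s, "end": e}
                )
    df = pd.DataFrame(rows, columns=["gene", "isoform_id", "region", "peptide", "start", "end"])
    # a sequence sampled from two positions keeps its first recorded placement
    return df.drop_duplicates(subset=["isoform_id", "peptide"], keep="first").reset_index(drop=True)


# ---------------------------------------------------------------------------
# MS simulation
# ---------------------------------------------------------------------------

def _assign_sets(
    measurements: list[str],
    duplicate_pairs: list[tuple[str, str]],
    n_sets: int,
    per_set: int,
    rng: np.random.Generator,
) -> dict[str, list[str]]:
    """Shuffle measurements into TMT sets, forcing aliquot pairs into different sets."""
    order = [measurements[i] for i in rng.permutation(len(measurements))]
    sets: dict[str, list[str]] = {f"set{i + 1}": [] for i in range(n_sets)}
    names = list(sets)
    for i, m in enumerate(order):
        sets[names[i % n_sets]].append(m)
    if n_sets == 1 and duplicate_pairs:
        raise InvalidSpecError("cross-set duplicate pairs require n_tmt_sets >= 2")
    set_of = {m: s for s, ms in sets.items() for m in ms}
    for a, b in duplicate_pairs:
        if set_of[a] == set_of[b]:
            # move b to the least-loaded other set
            target = min((s for s in names if s != set_of[a]), key=lambda s: len(sets[s]))
            sets[set_of[b]].remove(b)
            sets[target].append(b)
            set_of[b] = target
    if any(len(ms) > per_set for ms in sets.values()):
        raise InvalidSpecError("TMT capacity exceeded after duplicate placement")
    return {s: sorted(ms) for s, ms in sets.items()}


def simulate_ms(
    truth: TruthTables,
    spec: MsNoiseSpec = MsNoiseSpec(),
    peptide_design: pd.DataFrame | None = None,
    seed: int | None = None,
) -> tuple[QuantMatrix, QuantMatrix, pd.DataFrame, dict[str, list[str]]]:
    """Simulate the MS layer and roll it up through the real ingest path.

    Returns ``(protein_matrix, peptide_matrix, psm_table, set_layout)``.
    Duplicate aliquots (``<sample>_B``) are placed in different TMT sets from
    their first aliquot.  The internal standard emulates the master pool made
    from every sample and split across sets: its latent value is the global
    per-protein median of the samples' latent log2 values, identical in every
    set.  TMT-set batch effects perturb the sample channels only, so they
    survive ratio formation (as observed set effects do).  Each peptide's
    signal follows the latent trajectory of the isoform its region belongs
    to, so proteoform structure propagates to the peptide level.
    """
    if seed is None:
        seed = (truth.spec.seed if truth.spec is not None else 0) + 1
    rng = np.random.default_rng(seed)

    samples = list(truth.sample_ids)
    dup_ids = [b for _, b in truth.duplicate_pairs]
    measurements = samples + dup_ids
    capacity = spec.n_tmt_sets * (spec.set_size - 1)
    if capacity < len(measurements):
        raise InvalidSpecError(
            f"TMT capacity {capacity} < {len(measurements)} measurements (incl. duplicates)"
        )
    layout = _assign_sets(measurements, truth.duplicate_pairs, spec.n_tmt_sets,
                          spec.set_size - 1, rng)
    set_names = list(layout)
    base_of = {m: m.removesuffix("_B") for m in measurements}

    if peptide_design is None:
        peptide_design = generate_peptides(
            truth.proteoforms.values(), seed=rng.integers(0, 2**31 - 1),
        )
        # draw a variable number of peptides per protein
        keep_rows = []
        for iso, grp in peptide_design.groupby("isoform_id", sort=False):
            k = 1 + rng.poisson(spec.peptides_per_protein_mean)
            keep_rows.append(grp.head(k))
        peptide_design = pd.concat(keep_rows).reset_index(drop=True)

    features = list(truth.feature_ids)
    f_index = {f: i for i, f in enumerate(features)}
    latent = truth.latent.to_numpy()

    batch = rng.normal(0.0, spec.batch_sd_log2, size=(len(features), spec.n_tmt_sets))
    # master-pool internal standard: one latent value per protein, all sets
    is_latent_global = np.median(latent, axis=1)

    # MNAR protein-by-set dropout on the standardized latent mean abundance
    mean_ab = latent.mean(axis=1)
    sd_ab = mean_ab.std()
    z = (mean_ab - mean_ab.mean()) / sd_ab if sd_ab > 0 else np.zeros_like(mean_ab)
    if spec.missing_base_rate <= 0.0:
        p_miss = np.zeros((len(features), spec.n_tmt_sets))
    elif spec.missing_base_rate >= 1.0:
        p_miss = np.ones((len(features), spec.n_tmt_sets))
    else:
        eta = logit(spec.missing_base_rate) - spec.missing_abundance_slope * z
        p_miss = np.repeat(expit(eta)[:, None], spec.n_tmt_sets, axis=1)
    missing = rng.random(p_miss.shape) < p_miss

    design = peptide_design.reset_index(drop=True)
    design_iso = design["isoform_id"].to_numpy()
    design_pep = design["peptide"].to_numpy()
    design_gene = design["gene"].to_numpy()

    frames: list[pd.DataFrame] = []
    psm_counter = 0
    for si, set_name in enumerate(set_names):
        set_samples = layout[set_name]
        cols = np.array([truth.latent.columns.get_loc(base_of[m]) for m in set_samples])
        det = ~missing[[f_index[i] for i in design_iso], si]
        if not det.any():
            continue
        idx_rows = np.flatnonzero(det)
        n_psm = 1 + rng.poisson(spec.psm_per_peptide_mean, size=len(idx_rows))
        rep = np.repeat(idx_rows, n_psm)          # one entry per PSM -> design row
        n_total = len(rep)
        fi = np.array([f_index[i] for i in design_iso[rep]])

        sig = latent[np.ix_(fi, cols)] if len(cols) else np.empty((n_total, 0))
        sig = sig + batch[fi, si][:, None]
        offsets = rng.normal(0.0, spec.psm_offset_sd, size=n_total)  # per-PSM intensity offset
        noise = rng.normal(0.0, spec.tech_sd_log2, size=sig.shape)
        intens = sig + offsets[:, None] + noise
        is_col = is_latent_global[fi] + offsets

        if spec.channel_dropout_rate > 0:
            drop = rng.random(intens.shape) < spec.channel_dropout_rate
            intens = np.where(drop, np.nan, intens)

        proteins = design_iso[rep].astype(object)
        if spec.multi_map_rate > 0:
            mm = rng.random(n_total) < spec.multi_map_rate
            if mm.any():
                partners = rng.choice(features, size=int(mm.sum()))
                proteins = proteins.copy()
                proteins[mm] = [f"{a};{b}" for a, b in zip(proteins[mm], partners)]

        psm_ids = np.arange(psm_counter, psm_counter + n_total)
        psm_counter += n_total

        channels = list(set_samples) + [IS_CHANNEL]
        block = np.column_stack([intens, is_col[:, None]])
        frames.append(
            pd.DataFrame(
                {
                    "set": set_name,
                    "psm_id": np.repeat(psm_ids, len(channels)),
                    "peptide": np.repeat(design_pep[rep], len(channels)),
                    "proteins": np.repeat(proteins, len(channels)),
                    "gene": np.repeat(design_gene[rep], len(channels)),
                    "channel": np.tile(channels, n_total),
                    "log2_intensity": block.ravel(),
                }
            )
        )

    psm_table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["set", "psm_id", "peptide", "proteins", "gene", "channel", "log2_intensity"]
    )
    # synthetic precursor mass errors (ppm), a factor-model covariate
    if len(psm_table):
        per_psm = psm_table.groupby("psm_id", sort=False).ngroup()
        ppm = rng.normal(0.0, 3.0, size=per_psm.max() + 1)
        psm_table["precursor_ppm"] = ppm[per_psm]

    protein_qm, peptide_qm = roll_up_psms(psm_table, layout)
    if peptide_qm.feature_meta is not None:
        extra = design.set_index("peptide")[["isoform_id", "region", "start", "end"]]
        extra = extra[~extra.index.duplicated(keep="first")]
        peptide_qm.feature_meta = peptide_qm.feature_meta.join(extra, how="left")
    return protein_qm, peptide_qm, psm_table, layout


# ---------------------------------------------------------------------------
# affinity simulation
# ---------------------------------------------------------------------------

def simulate_affinity(
    truth: TruthTables,
    spec: AffinityNoiseSpec = AffinityNoiseSpec(),
    seed: int | None = None,
    n_control_replicates: int = 2,
) -> pd.DataFrame:
    """Simulate the affinity layer as a long NPX table (one assay per gene).

    NPX = assay offset + proteoform-weighted latent log2 abundance + noise.
    The per-assay LOD is the assay offset plus a global latent-concentration
    quantile (``lod_quantile``).  Measurements falling below the LOD lose
    their signal: they are redrawn from a noise floor just under the LOD
    (background counts dominate a PEA readout below its detection limit), are
    flagged below-LOD, and are retained in the table.  A pooled control
    sample (mean latent) is measured ``n_control_replicates`` times as
    ``CONTROL_1``, ``CONTROL_2``, ... for intra-assay CV estimation.
    """
    if seed is None:
        seed = (truth.spec.seed if truth.spec is not None else 0) + 2
    rng = np.random.default_rng(seed)

    samples = list(truth.sample_ids)
    control_ids = [f"CONTROL_{i + 1}" for i in range(n_control_replicates)]
    genes = sorted(truth.proteoforms)
    latent = truth.latent

    if spec.lod_quantile > 0.0:
        lod_latent = float(np.quantile(latent.to_numpy(), spec.lod_quantile))
    else:
        lod_latent = -np.inf

    rows: list[pd.DataFrame] = []
    for ai, gene in enumerate(genes):
        pf = truth.proteoforms[gene]
        w = np.asarray(pf.assay_targets, dtype=float)
        iso_latent = latent.loc[pf.isoform_ids].to_numpy()
        signal = w @ iso_latent
        control_signal = float(w @ iso_latent.mean(axis=1))
        offset = rng.normal(0.0, spec.assay_offset_sd)
        panel, version = PANELS[int(rng.integers(len(PANELS)))]
        assay_warn = bool(rng.random() < spec.assay_qc_rate)
        # order the assay's UniProt list by targeting weight (primary first)
        order = np.argsort(-w, kind="stable")
        uids = ";".join(pf.isoform_ids[j] for j in order)

        all_samples = samples + control_ids
        sig = np.concatenate([signal, np.full(n_control_replicates, control_signal)])
        npx = offset + sig + rng.normal(0.0, spec.tech_sd_npx, size=len(all_samples))
        lod = offset + lod_latent
        if np.isfinite(lod):
            below = npx < lod
            if below.any():
                floor_sd = spec.tech_sd_npx if spec.tech_sd_npx > 0 else 0.1
                npx[below] = lod - np.abs(
                    rng.normal(0.0, floor_sd, size=int(below.sum()))
                )
        rows.append(
            pd.DataFrame(
                {
                    "sample_id": all_samples,
                    "olink_id": f"OID{ai + 1:05d}",
                    "uniprot_ids": uids,
                    "gene": gene,
                    "panel": panel,
                    "panel_version": version,
                    "npx": npx,
                    "lod": lod,
                    "below_lod": npx < lod,
                    "sample_qc_warn": rng.random(len(all_samples)) < spec.qc_warning_rate,
                    "assay_qc_warn": assay_warn,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# demo proteoform genes (synthetic stand-ins for curated multi-region examples)
# ---------------------------------------------------------------------------

def demo_proteoforms(seed: int = 7, region_length: int = 120) -> list[ProteoformSpec]:
    """Two synthetic multi-proteoform genes.

    ``GMASPX`` emulates a two-isoform gene whose affinity assay targets isoform
    2 only; ``GAMBPX`` emulates a cleaved precursor whose assay tracks the
    first product.  Sequences and coordinates are synthetic, generated here —
    they stand in for curated examples, not for any real protein.
    """
    rng = np.random.default_rng(seed)
    L = region_length

    shared = _random_sequence(rng, L)
    unique1 = _random_sequence(rng, L)
    unique2 = _random_sequence(rng, L)
    maspx = ProteoformSpec(
        gene="GMASPX",
        isoform_sequences=(
            ("P90001", shared + unique1),
            ("P90001-2", shared + unique2),
        ),
        region_map=(
            ("shared", "P90001", 1, L),
            ("iso1_unique", "P90001", L + 1, 2 * L),
            ("iso2_unique", "P90001-2", L + 1, 2 * L),
        ),
        assay_targets=(0.0, 1.0),
        proteoform_corr=0.2,
    )

    # cleaved precursor: the two circulating products carry distinct sequences
    # and independent-ish trajectories; the assay tracks product A only
    part_a = _random_sequence(rng, L)
    part_b = _random_sequence(rng, L)
    ambpx = ProteoformSpec(
        gene="GAMBPX",
        isoform_sequences=(
            ("P90002", part_a),
            ("P90002-2", part_b),
        ),
        region_map=(
            ("product_a", "P90002", 1, L),
            ("product_b", "P90002-2", 1, L),
        ),
        assay_targets=(1.0, 0.0),
        proteoform_corr=0.2,
    )
    return [maspx, ambpx]


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def write_fasta(proteoforms: Iterable[ProteoformSpec], path: str | Path) -> None:
    """Write all isoform sequences with UniProt-style headers sp|ID|GENE_HUMAN."""
    with Path(path).open("w") as fh:
        for pf in proteoforms:
            for iso, seq in pf.isoform_sequences:
                fh.write(f">sp|{iso}|{pf.gene}_HUMAN\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i:i + 60] + "\n")


def write_truth(truth: TruthTables, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth.latent.to_csv(outdir / "latent_log2.tsv", sep="\t")
    truth.sex.to_frame().to_csv(outdir / "sex_labels.tsv", sep="\t")
    truth.effects.to_frame().to_csv(outdir / "sex_effects.tsv", sep="\t")
    truth.gene_of.to_frame().to_csv(outdir / "gene_map.tsv", sep="\t")
    pd.DataFrame(truth.duplicate_pairs, columns=["sample_a", "sample_b"]).to_csv(
        outdir / "duplicate_pairs.tsv", sep="\t", index=False
    )


def write_manifest(path: str | Path, **specs) -> None:
    """JSON manifest echoing the seeds and specifications of a simulation."""
    payload = {}
    for name, value in specs.items():
        if hasattr(value, "__dataclass_fields__"):
            payload[name] = asdict(value)
        else:
            payload[name] = value
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
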