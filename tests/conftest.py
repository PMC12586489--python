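import numpy as np
import pandas as pd
import pytest

from protconcord import synthetic
from protconcord.pipeline import RunConfig, run_pipeline


@pytest.fixture(scope="session")
def small_result():
    """One modest default-conditions pipeline run shared across tests."""
    cfg = RunConfig(outdir="unused", seed=11, cohort={"n_proteins": 120})
    return run_pipeline(cfg, write=False)


@pytest.fixture(scope="session")
def noise_free_result():
    """All observation noise and censoring off; minority sex effect."""
    cfg = RunConfig(
        outdir="unused", seed=5,
        cohort=dict(n_proteins=150, biological_sd_log2=0.0,
                    sex_effect_log2=1.0, n_sex_affected=30),
        ms_noise=dict(batch_sd_log2=0.0, tech_sd_log2=0.0, missing_base_rate=0.0,
                      psm_offset_sd=0.0, multi_map_rate=0.0, channel_dropout_rate=0.0),
        affinity=dict(tech_sd_npx=0.0, lod_quantile=0.0,
                      qc_warning_rate=0.0, assay_qc_rate=0.0),
        include_demo_proteoforms=False,
    )
    return run_pipeline(cfg, write=False)


@pytest.fixture()
def tiny_psm_table():
    """Two sets, two samples each, hand-enumerable PSMs."""
    layout = {"set1": ["A", "B"], "set2": ["C", "D"]}
    rows = []

    def psm(set_name, pid, protein, peptide, intensities):
        for chan, val in intensities.items():
            rows.append({"set": set_name, "psm_id": pid, "peptide": peptide,
                         "proteins": protein, "gene": "G1", "channel": chan,
                         "log2_intensity": val})

    psm("set1", 0, "P1", "PEPA", {"A": 1.0, "B": 2.0, "IS": 1.0})
    psm("set1", 1, "P1", "PEPA", {"A": 0.0, "B": 1.0, "IS": 1.0})
    psm("set1", 2, "P1", "PEPB", {"A": 6.0, "B": 1.0, "IS": 1.0})
    psm("set1", 3, "P2", "PEPC", {"A": 3.0, "B": np.nan, "IS": 1.0})   # incomplete
    psm("set1", 4, "P1;P2", "PEPD", {"A": 2.0, "B": 2.0, "IS": 1.0})   # multi-mapped
    psm("set2", 5, "P1", "PEPA", {"C": 4.0, "D": 2.0, "IS": 2.0})
    return pd.DataFrame(rows), layout


def random_psm_table(rng, n_proteins=6, n_sets=2, samples_per_set=3,
                     max_psms=4, missing_rate=0.1, multi_rate=0.15):
    """Random small PSM table + layout for oracle-equivalence checks."""
    layout = {
        f"set{t + 1}": [f"s{t}_{j}" for j in range(samples_per_set)]
        for t in range(n_sets)
    }
    proteins = [f"P{i}" for i in range(n_proteins)]
    rows = []
    pid = 0
    for set_name, samples in layout.items():
        for prot in proteins:
            for pep_i in range(rng.integers(1, 3)):
                pep = f"{prot}_pep{pep_i}"
                for _ in range(rng.integers(1, max_psms + 1)):
                    prot_field = prot
                    if rng.random() < multi_rate:
                        prot_field = f"{prot};{rng.choice(proteins)}"
                    for chan in samples + ["IS"]:
                        val = float(np.round(rng.normal(0, 2), 3))
                        if rng.random() < missing_rate:
                            val = np.nan
                        rows.append({"set": set_name, "psm_id": pid,
                                     "peptide": pep, "proteins": prot_field,
                                     "gene": prot, "channel": chan,
                                     "log2_intensity": val})
                    pid += 1
    return pd.DataFrame(rows), layout
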