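"""Shared simulated populations (session-scoped: each is one fixed study
design reused by many tests)."""

import numpy as np
import pandas as pd
import pytest

from lethalscan import io_formats as io
from lethalscan.mixed_models import build_A
from lethalscan.simulate import (SimulationConfig, call_genotypes,
                                 simulate_population,
                                 simulate_records_and_drp)


@pytest.fixture(scope="session")
def pop_small():
    """Tiny population for format/plumbing tests."""
    cfg = SimulationConfig(n_founders=200, n_generations=2, n_sires_per_gen=15,
                           progeny_per_sire=10, n_markers=100, seed=7)
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def pop_scan():
    """Association-scan panel: half-sib families, deletion at p = 0.08."""
    cfg = SimulationConfig(n_founders=400, n_generations=2, n_sires_per_gen=30,
                           progeny_per_sire=30, n_markers=400,
                           causative_allele_freq=0.08, seed=11)
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def scan_data(pop_scan):
    """Genotypes, QC'd panel, weighted phenotypes, pedigree and A for the
    scan population."""
    g = call_genotypes(pop_scan)
    g_qc, qc_report = io.filter_markers(g, maf_min=0.01, hwp_p_min=1e-5)
    _, drp = simulate_records_and_drp(pop_scan)
    pheno = io.prepare_phenotypes(drp, trait="SB")
    ped = pop_scan.pedigree()
    return {
        "pop": pop_scan, "g": g, "g_qc": g_qc, "qc_report": qc_report,
        "pheno": pheno, "ped": ped, "A": build_A(ped),
    }


@pytest.fixture(scope="session")
def rhm_result(scan_data):
    """Random haplotype model fitted on the deletion-spanning tag window."""
    from lethalscan.association_scan import fit_rhm

    return fit_rhm(scan_data["g"], scan_data["pheno"], scan_data["A"],
                   scan_data["pop"].tag_window_ids)


@pytest.fixture(scope="session")
def pop_lethal10k():
    """Founder-heavy panel of ~10,400 live animals with the tag haplotype at
    q ~ 0.055, for the missing-homozygote test."""
    cfg = SimulationConfig(n_founders=7000, n_generations=1, n_sires_per_gen=60,
                           progeny_per_sire=60, n_markers=120,
                           causative_allele_freq=0.055, seed=5)
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def pop_neutral():
    """Non-lethal control: the same construction with penetrance 0 plants a
    neutral haplotype at q ~ 0.2."""
    cfg = SimulationConfig(n_founders=1500, n_generations=1, n_sires_per_gen=40,
                           progeny_per_sire=40, n_markers=120,
                           causative_allele_freq=0.2, penetrance=0.0, seed=6)
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def hd_panel():
    """HD-array-like panel: ~340 bulls, ~140 markers inside the deletion, for
    intensity-based carrier calling."""
    cfg = SimulationConfig(n_founders=160, n_generations=1, n_sires_per_gen=15,
                           progeny_per_sire=12, n_markers=5600,
                           causative_allele_freq=0.08, seed=12)
    pop = simulate_population(cfg)
    return {"pop": pop, "g": call_genotypes(pop),
            "region": f"{cfg.chrom}:{cfg.deletion_start_bp}-{cfg.deletion_end_bp}"}


def _mating_fit(penetrance: float, seed: int = 21):
    from lethalscan import mating_analysis as mat

    cfg = SimulationConfig(n_founders=1200, n_generations=2, n_sires_per_gen=50,
                           progeny_per_sire=80, n_markers=60,
                           causative_allele_freq=0.125, penetrance=penetrance,
                           baseline_stillbirth=0.04, seed=seed)
    pop = simulate_population(cfg)
    calving, _ = simulate_records_and_drp(pop)
    records = mat.build_mating_records(calving, pop.carrier_truth())
    mgs_ids = sorted(set(records["mgs"]))
    ped = pop.pedigree()
    A_s = build_A(ped[ped["id"].isin(mgs_ids)]).subset(mgs_ids)
    res = mat.fit_mating_model(records, A_s)
    return {"result": res, "records": records, "p": cfg.causative_allele_freq,
            "penetrance": penetrance}


@pytest.fixture(scope="session")
def mating_fits():
    """Mating-model fits at penetrance 0, 0.5 and 1 (shared: each is a full
    gene drop plus REML fit)."""
    return {pen: _mating_fit(pen) for pen in (0.0, 0.5, 1.0)}
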