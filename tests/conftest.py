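"""Shared fixtures: small simulated cohorts and toy genotype builders."""
from __future__ import annotations

import numpy as np
import pytest

from founderpanel.core import GenotypeMatrix, Individual, Pedigree, Sites
from founderpanel import simpop as sp


def make_sites(n: int, length_cm: float = 50.0, chrom: str = "1") -> Sites:
    cm = np.arange(n, dtype=float) * (length_cm / n)
    return Sites(np.full(n, chrom, dtype=object), np.arange(1, n + 1) * 10,
                 np.full(n, "A", dtype=object), np.full(n, "G", dtype=object),
                 cm)


def make_gm(dosages, sites: Sites | None = None, samples=None,
            gq: int = 60, dp: int = 30) -> GenotypeMatrix:
    """GenotypeMatrix from a (n_samples, n_sites) dosage array; -1 = missing,
    quality fields consistent with clean calls."""
    d = np.asarray(dosages)
    n, s = d.shape
    sites = sites if sites is not None else make_sites(s)
    samples = samples or [f"S{i:03d}" for i in range(n)]
    gm = GenotypeMatrix.empty(sites, samples)
    gm.a1 = np.where(d < 0, -1, (d > 0).astype(np.int8)).astype(np.int8)
    gm.a2 = np.where(d < 0, -1, (d > 1).astype(np.int8)).astype(np.int8)
    gm.gq = np.full((n, s), gq, dtype=np.int16)
    gm.dp = np.full((n, s), dp, dtype=np.int16)
    gm.ad_alt = np.where(d == 1, dp // 2, np.where(d == 2, dp, 0)).astype(np.int16)
    gm.ad_alt[d < 0] = 0
    gm.ad_ref = (dp - gm.ad_alt).astype(np.int16)
    return gm


def engineered_qc_fixture():
    """10 engineered sites over 26 samples; exactly 3 survive default QC.

    Independent hand count: sites 0-2 fail missingness (8/26 > 25%), 3-4
    fail the trio Mendel rate (2/2 complete trios inconsistent), 5 fails
    HWE (all-het, exact p ~ 1.6e-7 < 1e-6), 6 is monomorphic, 7-9 clean.
    """
    n = 26
    d = np.ones((n, 10), dtype=int)
    mix18 = [-1] * 8 + [0] * 5 + [1] * 9 + [2] * 4
    d[:, 0] = d[:, 1] = d[:, 2] = mix18
    d[:, 5] = 1
    d[:, 6] = 0
    mix = [1] * 4 + [0] * 6 + [1] * 7 + [2] * 7 + [1] * 2
    d[:, 7] = d[:, 8] = d[:, 9] = mix
    d[:, 3] = [0] * 13 + [1] * 13
    d[:, 4] = [0] * 13 + [1] * 13
    samples = [f"S{i:03d}" for i in range(n)]
    gm = make_gm(d, samples=samples)
    inds = [Individual(s, None, None, 1) for s in samples[:24]]
    inds += [Individual("S024", "S000", "S001", 1),
             Individual("S025", "S002", "S003", 2)]
    ped = Pedigree(inds)
    for site in (3, 4):
        for row in (0, 1, 2, 3):
            gm.a1[row, site] = gm.a2[row, site] = 0
        for row in (24, 25):
            gm.a1[row, site] = gm.a2[row, site] = 1
    return gm, ped


def trio_pedigree() -> Pedigree:
    return Pedigree([
        Individual("FATHER", None, None, 1),
        Individual("MOTHER", None, None, 2),
        Individual("CHILD", "FATHER", "MOTHER", 1),
    ])


@pytest.fixture(scope="session")
def sim_cfg() -> sp.SimConfig:
    return sp.SimConfig(
        ancestral_pop_size=60, burn_in_generations=300, n_sites=1200,
        region_length_cm=60.0, mutation_rate_per_site_per_gen=3e-4,
        n_founders=20, pedigree_generations=3, mean_offspring=2.5,
        cousin_mating=0.0, seed=11)


@pytest.fixture(scope="session")
def sim_bundle(sim_cfg):
    """(ancestral panel, cohort genotypes, pedigree, truth tracks)."""
    anc = sp.simulate_ancestral(sim_cfg)
    gm, ped, truth = sp.found_and_expand(anc, sim_cfg)
    return anc, gm, ped, truth


def dense_cfg(seed: int = 11) -> sp.SimConfig:
    """Marker-dense cohort with a large outbred reference population; used
    by the IBD/HBD analyses, which need low identity-by-state noise."""
    return sp.SimConfig(
        ancestral_pop_size=250, burn_in_generations=750, n_sites=3000,
        region_length_cm=40.0, mutation_rate_per_site_per_gen=1.5e-4,
        n_founders=20, pedigree_generations=4, mean_offspring=2.5,
        cousin_mating=0.3, seed=seed)


@pytest.fixture(scope="session")
def dense_bundle():
    cfg = dense_cfg()
    anc = sp.simulate_ancestral(cfg)
    gm, ped, truth = sp.found_and_expand(anc, cfg)
    return anc, gm, ped, truth
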