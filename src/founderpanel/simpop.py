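"""Synthetic cohorts: forward Wright-Fisher ancestry, pedigree gene dropping,
genotype noise injection, array manifests, and deleteriousness scores.

The simulator produces an outbred "ancestral" population on a finite-sites
grid and a bottlenecked founder cohort expanded through a known pedigree,
together with per-haplotype founder-segment truth tracks.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import (ConfigError, GenotypeMatrix, HaplotypePanel, Individual,
                   ManifestError, Pedigree, SimulationError, Sites, MISSING,
                   substream)

_BASES = np.array(list("ACGT"))


@dataclass
class NoiseConfig:
    """Fractions of calls corrupted in each way; all in [0, 1]."""

    frac_low_gq: float = 0.0
    frac_low_dp: float = 0.0
    frac_half_calls: float = 0.0
    frac_mendel_errors: float = 0.0
    het_ab_distortion: float = 0.0

    def validate(self) -> None:
        for name in ("frac_low_gq", "frac_low_dp", "frac_half_calls",
                     "frac_mendel_errors", "het_ab_distortion"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")


@dataclass
class SimConfig:
    ancestral_pop_size: int = 200
    burn_in_generations: int = 800
    mutation_rate_per_site_per_gen: float = 2.5e-5
    n_sites: int = 20_000
    region_length_cm: float = 100.0
    n_founders: int = 20
    pedigree_generations: int = 3
    mean_offspring: float = 2.5
    cousin_mating: float = 0.0  # fraction of couples forced to be first cousins
    seed: int = 0
    noise: NoiseConfig = field(default_factory=NoiseConfig)

    def validate(self) -> None:
        for name in ("ancestral_pop_size", "burn_in_generations", "n_sites",
                     "n_founders", "pedigree_generations"):
            if getattr(self, name) <= 0 and name != "burn_in_generations":
                raise ConfigError(f"{name} must be positive")
        if self.burn_in_generations < 0:
            raise ConfigError("burn_in_generations must be >= 0")
        if self.region_length_cm <= 0:
            raise ConfigError("region_length_cm must be positive")
        if self.mean_offspring <= 0:
            raise ConfigError("mean_offspring must be positive")
        if not 0.0 <= self.mutation_rate_per_site_per_gen < 1.0:
            raise ConfigError("mutation rate must be a probability")
        if not 0.0 <= self.cousin_mating <= 1.0:
            raise ConfigError("cousin_mating must be in [0, 1]")
        self.noise.validate()


@dataclass
class TruthTracks:
    """Ground truth from gene dropping.

    ``founder_labels`` maps (sample_id, hap_index 0/1) to half-open
    site-index segments (start, end, founder_haplotype_row). Founder
    haplotype rows index into the founder slice of the cohort truth panel.
    """

    founder_labels: dict[tuple[str, int], list[tuple[int, int, int]]]
    true_haplotypes: HaplotypePanel
    ancestral_freq: np.ndarray
    cohort_freq: np.ndarray


def _site_grid(config: SimConfig) -> Sites:
    s = config.n_sites
    cm = np.arange(s, dtype=float) * (config.region_length_cm / s)
    rng = substream(config.seed, "alleles")
    ref_idx = rng.integers(0, 4, size=s)
    alt_idx = (ref_idx + rng.integers(1, 4, size=s)) % 4
    return Sites(chrom=np.full(s, "1", dtype=object), pos=np.arange(1, s + 1) * 10,
                 ref=_BASES[ref_idx], alt=_BASES[alt_idx], cm=cm)


def _meiosis_masks(rng: np.random.Generator, n_gametes: int, cm: np.ndarray,
                   length_cm: float) -> np.ndarray:
    """Per-gamete 0/1 source-haplotype choice at each site.

    Crossover count per meiosis is Poisson(length_cm/100); breakpoints are
    uniform in cM. Returns an int8 matrix (n_gametes, n_sites).
    """
    n_cross = rng.poisson(length_cm / 100.0, size=n_gametes)
    phase = rng.integers(0, 2, size=n_gametes, dtype=np.int8)
    hits = np.zeros((n_gametes, cm.shape[0]), dtype=np.int32)
    total = int(n_cross.sum())
    if total:
        gidx = np.repeat(np.arange(n_gametes), n_cross)
        bp = rng.uniform(0.0, length_cm, size=total)
        sidx = np.searchsorted(cm, bp, side="left")
        keep = sidx < cm.shape[0]
        np.add.at(hits, (gidx[keep], sidx[keep]), 1)
    return ((np.cumsum(hits, axis=1) + phase[:, None]) % 2).astype(np.int8)


def _mutate(rng: np.random.Generator, haps: np.ndarray, mu: float) -> np.ndarray:
    """Flip alleles in place at Binomial(cells, mu) distinct positions."""
    if mu <= 0:
        return np.zeros(0, dtype=np.int64)
    n_cells = haps.size
    k = rng.binomial(n_cells, mu)
    if k == 0:
        return np.zeros(0, dtype=np.int64)
    flat = rng.choice(n_cells, size=k, replace=False)
    haps.reshape(-1)[flat] ^= 1
    return flat


def simulate_ancestral(config: SimConfig) -> HaplotypePanel:
    """Forward Wright-Fisher population of 2N phased haplotypes.

    Starts monomorphic; runs ``burn_in_generations`` of random mating with
    recombination and symmetric per-site mutation. Monomorphic sites are
    retained (frequency 0) for later site-union logic.
    """
    config.validate()
    sites = _site_grid(config)
    rng = substream(config.seed, "ancestral")
    n = config.ancestral_pop_size
    haps = np.zeros((2 * n, config.n_sites), dtype=np.int8)
    for _ in range(config.burn_in_generations):
        parents = rng.integers(0, n, size=2 * n)
        masks = _meiosis_masks(rng, 2 * n, sites.cm, config.region_length_cm)
        haps = np.where(masks == 0, haps[2 * parents], haps[2 * parents + 1])
        _mutate(rng, haps, config.mutation_rate_per_site_per_gen)
    samples = [f"ANC{i:04d}" for i in range(n) for _ in range(2)]
    return HaplotypePanel(sites, haps, samples)


# ---------------------------------------------------------------------------
# pedigree expansion


def _splice_labels(track_a: list, track_b: list, mask: np.ndarray) -> list:
    """Child gamete label track from parental tracks and a meiosis mask."""
    out: list[tuple[int, int, int]] = []
    s = mask.shape[0]
    # boundaries where the source haplotype switches
    switch = np.flatnonzero(np.diff(mask.astype(np.int8)) != 0) + 1
    bounds = [0, *switch.tolist(), s]
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        src = track_a if mask[lo] == 0 else track_b
        for a, b, lab in src:
            a2, b2 = max(a, lo), min(b, hi)
            if a2 < b2:
                if out and out[-1][1] == a2 and out[-1][2] == lab:
                    out[-1] = (out[-1][0], b2, lab)
                else:
                    out.append((a2, b2, lab))
    return out


def _pair_couples(rng: np.random.Generator, members: list[str],
                  ped: dict[str, Individual], kin_grandparents: dict[str, set],
                  cousin_mating: float) -> list[tuple[str, str]]:
    """Monogamous male-female couples; sib mating avoided by construction.

    With ``cousin_mating`` > 0 a fraction of couples is preferentially drawn
    from first-cousin pairs (shared grandparent, different parents).
    """
    males = [m for m in members if ped[m].sex == 1]
    females = [f for f in members if ped[f].sex == 2]
    rng.shuffle(males)
    rng.shuffle(females)
    couples: list[tuple[str, str]] = []

    def parents_of(x):
        return (ped[x].father, ped[x].mother)

    def are_sibs(a, b):
        pa, pb = parents_of(a), parents_of(b)
        return pa != (None, None) and pa == pb

    def are_cousins(a, b):
        if are_sibs(a, b):
            return False
        return bool(kin_grandparents.get(a, set()) & kin_grandparents.get(b, set()))

    n_target = min(len(males), len(females))
    n_cousin = int(round(cousin_mating * n_target))
    if n_cousin:
        used: set[str] = set()
        for m in males:
            if len(couples) >= n_cousin:
                break
            for f in females:
                if f in used or not are_cousins(m, f):
                    continue
                couples.append((m, f))
                used.add(f)
                break
        males = [m for m in males if m not in {c[0] for c in couples}]
        females = [f for f in females if f not in used]
    remaining_f = list(females)
    for m in males:
        match = next((f for f in remaining_f if not are_sibs(m, f)), None)
        if match is not None:
            couples.append((m, match))
            remaining_f.remove(match)
    return couples


def found_and_expand(ancestral: HaplotypePanel, config: SimConfig
                     ) -> tuple[GenotypeMatrix, Pedigree, TruthTracks]:
    """Sample founders, expand through a multi-generation pedigree by gene
    dropping, and return the full cohort with truth tracks."""
    config.validate()
    n_anc = ancestral.n_haps // 2
    if config.n_founders > n_anc:
        raise ConfigError("n_founders exceeds ancestral population size")
    rng = substream(config.seed, "pedigree")
    sites = ancestral.sites
    s = len(sites)

    founder_idx = np.sort(rng.choice(n_anc, size=config.n_founders, replace=False))
    inds: dict[str, Individual] = {}
    haps: dict[str, np.ndarray] = {}   # (2, S) per individual
    labels: dict[tuple[str, int], list] = {}
    grandparents: dict[str, set] = {}

    founders: list[str] = []
    for k, ai in enumerate(founder_idx):
        iid = f"G0-{k:03d}"
        sex = 1 if k % 2 == 0 else 2
        inds[iid] = Individual(iid, None, None, sex)
        haps[iid] = np.stack([ancestral.haps[2 * ai], ancestral.haps[2 * ai + 1]])
        labels[(iid, 0)] = [(0, s, 2 * k)]
        labels[(iid, 1)] = [(0, s, 2 * k + 1)]
        founders.append(iid)

    generations = [founders]
    for g in range(1, config.pedigree_generations + 1):
        prev = generations[-1]
        couples = _pair_couples(rng, prev, inds, grandparents,
                                config.cousin_mating if g >= 3 else 0.0)
        if not couples:
            raise SimulationError(f"no couples could be formed at generation {g}")
        children: list[str] = []
        k = 0
        for father, mother in couples:
            first_sex = int(rng.integers(1, 3))
            for ci in range(rng.poisson(config.mean_offspring)):
                iid = f"G{g}-{k:03d}"
                k += 1
                # alternate within the family: keeps the sex ratio balanced
                sex = 1 + (first_sex + ci) % 2
                inds[iid] = Individual(iid, father, mother, sex)
                grandparents[iid] = {p for par in (father, mother)
                                     for p in (inds[par].father, inds[par].mother)
                                     if p is not None}
                child = np.empty((2, s), dtype=np.int8)
                for hap_i, parent in ((0, father), (1, mother)):
                    mask = _meiosis_masks(rng, 1, sites.cm,
                                          config.region_length_cm)[0]
                    gamete = np.where(mask == 0, haps[parent][0], haps[parent][1])
                    _mutate(rng, gamete, config.mutation_rate_per_site_per_gen)
                    child[hap_i] = gamete
                    labels[(iid, hap_i)] = _splice_labels(
                        labels[(parent, 0)], labels[(parent, 1)], mask)
                haps[iid] = child
                children.append(iid)
        if not children:
            raise SimulationError(f"no children born at generation {g}")
        generations.append(children)

    cohort_ids = [iid for gen in generations for iid in gen]
    ped = Pedigree(inds[i] for i in cohort_ids)
    hap_rows = np.concatenate([haps[i] for i in cohort_ids])
    panel = HaplotypePanel(sites.copy(), hap_rows,
                           [i for i in cohort_ids for _ in range(2)])
    gm = _genotypes_from_truth(panel, config.seed)
    truth = TruthTracks(founder_labels=labels, true_haplotypes=panel,
                        ancestral_freq=ancestral.alt_freq(),
                        cohort_freq=panel.alt_freq())
    return gm, ped, truth


def _genotypes_from_truth(panel: HaplotypePanel, seed: int) -> GenotypeMatrix:
    """Clean genotype calls (pass default QC) from truth haplotypes."""
    gm = panel.to_genotypes()
    rng = substream(seed, "call-quality")
    n, s = gm.a1.shape
    dp = rng.poisson(35, size=(n, s)).astype(np.int16)
    np.clip(dp, 10, None, out=dp)
    gq = rng.integers(40, 100, size=(n, s), dtype=np.int16)
    dose = gm.a1 + gm.a2
    alt_reads = np.where(dose == 0, 0, np.where(dose == 2, dp, 0)).astype(np.int16)
    het = dose == 1
    if het.any():
        raw = rng.binomial(dp[het], 0.5).astype(np.int16)
        lo = np.ceil(0.25 * dp[het]).astype(np.int16)
        hi = np.floor(0.75 * dp[het]).astype(np.int16)
        alt_reads[het] = np.clip(raw, lo, hi)
    gm.dp, gm.gq = dp, gq
    gm.ad_alt = alt_reads
    gm.ad_ref = (dp - alt_reads).astype(np.int16)
    gm.phased = np.zeros_like(gm.phased)  # cohort VCF is unphased
    return gm


# ---------------------------------------------------------------------------
# noise injection


def inject_noise(genotypes: GenotypeMatrix, noise: NoiseConfig, seed: int,
                 ped: Pedigree | None = None
                 ) -> tuple[GenotypeMatrix, dict[str, np.ndarray]]:
    """Corrupt the configured fractions of calls; returns the corrupted copy
    and a truth mask per corruption category."""
    noise.validate()
    gm = genotypes.copy()
    rng = substream(seed, "noise")
    shape = gm.a1.shape
    masks = {k: np.zeros(shape, dtype=bool)
             for k in ("low_gq", "low_dp", "half_call", "ab_distort", "mendel")}

    def pick(frac: float, eligible: np.ndarray) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        idx = np.flatnonzero(eligible.reshape(-1))
        k = int(round(frac * idx.size))
        if k:
            out.reshape(-1)[rng.choice(idx, size=k, replace=False)] = True
        return out

    called = gm.called()
    masks["low_gq"] = pick(noise.frac_low_gq, called)
    gm.gq[masks["low_gq"]] = rng.integers(0, 20, size=int(masks["low_gq"].sum()))
    masks["low_dp"] = pick(noise.frac_low_dp, called)
    ndp = rng.integers(0, 8, size=int(masks["low_dp"].sum())).astype(np.int16)
    gm.dp[masks["low_dp"]] = ndp
    # keep AD consistent with the new depth
    gm.ad_alt[masks["low_dp"]] = np.minimum(gm.ad_alt[masks["low_dp"]], ndp)
    gm.ad_ref[masks["low_dp"]] = ndp - gm.ad_alt[masks["low_dp"]]

    masks["ab_distort"] = pick(noise.het_ab_distortion, gm.het())
    if masks["ab_distort"].any():
        n_bad = int(masks["ab_distort"].sum())
        d = gm.dp[masks["ab_distort"]].astype(float)
        low_side = rng.random(n_bad) < 0.5
        frac = np.where(low_side, rng.uniform(0.0, 0.2, n_bad),
                        rng.uniform(0.8, 1.0, n_bad))
        alt = np.round(frac * d).astype(np.int16)
        # force strictly outside [0.25, 0.75]
        ab = alt / np.maximum(d, 1)
        inside = (ab >= 0.25) & (ab <= 0.75)
        alt = np.where(inside, np.where(low_side, 0, d), alt)
        gm.ad_alt[masks["ab_distort"]] = alt.astype(np.int16)
        gm.ad_ref[masks["ab_distort"]] = (d - alt).astype(np.int16)

    if noise.frac_mendel_errors > 0 and ped is not None:
        trio_children = [c for c, _, _ in ped.trios() if c in gm.samples]
        rows = np.array([gm.samples.index(c) for c in trio_children], dtype=int)
        elig = np.zeros(shape, dtype=bool)
        if rows.size:
            elig[rows] = called[rows]
        masks["mendel"] = pick(noise.frac_mendel_errors, elig)
        if masks["mendel"].any():
            dose = np.clip(gm.a1, 0, None) + np.clip(gm.a2, 0, None)
            sel = masks["mendel"]
            new_dose = np.where(dose[sel] == 0, 2,
                                np.where(dose[sel] == 2, 0,
                                         2 * rng.integers(0, 2, int(sel.sum()))))
            gm.a1[sel] = (new_dose > 0).astype(np.int8)
            gm.a2[sel] = (new_dose > 1).astype(np.int8)
            # make AD consistent so only the Mendel check can catch the flip
            d = gm.dp[sel]
            gm.ad_alt[sel] = np.where(new_dose == 0, 0, d).astype(np.int16)
            gm.ad_ref[sel] = (d - gm.ad_alt[sel]).astype(np.int16)

    masks["half_call"] = pick(noise.frac_half_calls, gm.called())
    gm.a2[masks["half_call"]] = MISSING

    return gm, masks


def make_array_manifest(genotypes: GenotypeMatrix, n_array_sites: int,
                        min_maf: float, seed: int) -> Sites:
    """Sorted random subset of common sites standing in for array content."""
    maf = genotypes.maf()
    qual = np.flatnonzero(np.nan_to_num(maf) >= min_maf)
    if qual.size < n_array_sites:
        raise ManifestError(
            f"only {qual.size} sites with MAF >= {min_maf}, need {n_array_sites}")
    rng = substream(seed, "manifest")
    chosen = np.sort(rng.choice(qual, size=n_array_sites, replace=False))
    return genotypes.sites.take(chosen)


def assign_scores(cohort_sites: Sites, reference_sites: Sites, shift: float,
                  seed: int):
    """Per-variant deleteriousness scores; cohort-specific variants are
    location-shifted by +shift. Returns a pandas DataFrame
    (chrom, pos, ref, alt, score, status)."""
    import pandas as pd

    if shift < 0:
        raise ConfigError("shift must be >= 0")
    rng = substream(seed, "scores")
    ref_keys = set(reference_sites.locus_keys())
    status = np.array(["shared" if k in ref_keys else "cohort_specific"
                       for k in cohort_sites.locus_keys()], dtype=object)
    score = rng.normal(0.0, 1.0, size=len(cohort_sites))
    score[status == "cohort_specific"] += shift
    return pd.DataFrame({"chrom": cohort_sites.chrom, "pos": cohort_sites.pos,
                         "ref": cohort_sites.ref, "alt": cohort_sites.alt,
                         "score": score, "status": status})
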