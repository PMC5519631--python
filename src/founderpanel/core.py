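"""Shared data structures: sites, genotype matrices, haplotype panels, pedigrees.

All site coordinates are 1-based (VCF convention) on a single pseudo-chromosome
unless the input says otherwise; genetic positions are in centiMorgans.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

AUTOSOMES = frozenset(str(i) for i in range(1, 23))

MISSING = -1  # allele code for an uncalled allele


class FounderPanelError(Exception):
    """Base class for package errors."""


class ConfigError(FounderPanelError):
    pass


class SimulationError(FounderPanelError):
    pass


class VcfFormatError(FounderPanelError):
    pass


class PedigreeError(FounderPanelError):
    pass


class ManifestError(FounderPanelError):
    pass


class MergeError(FounderPanelError):
    pass


def substream(seed: int, *keys: str) -> np.random.Generator:
    """Named random substream derived from one global seed.

    Every source of randomness in the package flows through here so that a
    stage can be re-run in isolation and reproduce its draws exactly.
    """
    entropy = [int(seed)] + [zlib.crc32(k.encode("utf-8")) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


@dataclass
class Sites:
    """Ordered variant sites with genetic-map positions."""

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    cm: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.cm = np.asarray(self.cm, dtype=np.float64)

    def __len__(self) -> int:
        return int(self.pos.shape[0])

    def keys(self) -> list[tuple]:
        """(chrom, pos, ref, alt) tuple per site."""
        return list(zip(self.chrom, self.pos.tolist(), self.ref, self.alt))

    def locus_keys(self) -> list[tuple]:
        """(chrom, pos) tuple per site."""
        return list(zip(self.chrom, self.pos.tolist()))

    def take(self, idx) -> "Sites":
        idx = np.asarray(idx)
        return Sites(self.chrom[idx], self.pos[idx], self.ref[idx],
                     self.alt[idx], self.cm[idx])

    def is_snv(self) -> np.ndarray:
        return np.array([len(r) == 1 and len(a) == 1 and "," not in a
                         for r, a in zip(self.ref, self.alt)], dtype=bool)

    def copy(self) -> "Sites":
        return Sites(self.chrom.copy(), self.pos.copy(), self.ref.copy(),
                     self.alt.copy(), self.cm.copy())


@dataclass
class GenotypeMatrix:
    """Diploid genotypes with per-call quality metadata.

    Allele arrays hold 0 (ref), positive ALT indices, or ``MISSING``.
    A half-call has exactly one allele equal to ``MISSING``. GQ/DP/AD use
    ``MISSING`` for "field absent".
    """

    sites: Sites
    samples: list[str]
    a1: np.ndarray  # (n_samples, n_sites) int8
    a2: np.ndarray
    phased: np.ndarray  # bool, per call
    gq: np.ndarray  # int16
    dp: np.ndarray
    ad_ref: np.ndarray
    ad_alt: np.ndarray

    @classmethod
    def empty(cls, sites: Sites, samples: Sequence[str]) -> "GenotypeMatrix":
        n, s = len(samples), len(sites)
        mk = lambda dt, v: np.full((n, s), v, dtype=dt)
        return cls(sites, list(samples), mk(np.int8, MISSING), mk(np.int8, MISSING),
                   np.zeros((n, s), dtype=bool), mk(np.int16, MISSING),
                   mk(np.int16, MISSING), mk(np.int16, MISSING), mk(np.int16, MISSING))

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.sites.copy(), list(self.samples),
                              self.a1.copy(), self.a2.copy(), self.phased.copy(),
                              self.gq.copy(), self.dp.copy(),
                              self.ad_ref.copy(), self.ad_alt.copy())

    def take_sites(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(self.sites.take(idx), list(self.samples),
                              self.a1[:, idx], self.a2[:, idx], self.phased[:, idx],
                              self.gq[:, idx], self.dp[:, idx],
                              self.ad_ref[:, idx], self.ad_alt[:, idx])

    def take_samples(self, names: Iterable[str]) -> "GenotypeMatrix":
        order = {s: i for i, s in enumerate(self.samples)}
        try:
            idx = np.array([order[n] for n in names], dtype=int)
        except KeyError as e:  # pragma: no cover - message path
            raise FounderPanelError(f"unknown sample {e.args[0]!r}") from None
        return GenotypeMatrix(self.sites.copy(), [self.samples[i] for i in idx],
                              self.a1[idx], self.a2[idx], self.phased[idx],
                              self.gq[idx], self.dp[idx],
                              self.ad_ref[idx], self.ad_alt[idx])

    # --- call-state masks -------------------------------------------------
    def called(self) -> np.ndarray:
        """Both alleles observed."""
        return (self.a1 >= 0) & (self.a2 >= 0)

    def half_called(self) -> np.ndarray:
        return (self.a1 >= 0) ^ (self.a2 >= 0)

    def fully_missing(self) -> np.ndarray:
        return (self.a1 < 0) & (self.a2 < 0)

    def het(self) -> np.ndarray:
        return self.called() & (self.a1 != self.a2)

    def dosage(self) -> np.ndarray:
        """ALT-allele dosage per call; NaN unless both alleles are called."""
        d = (np.clip(self.a1, 0, None) + np.clip(self.a2, 0, None)).astype(float)
        d[~self.called()] = np.nan
        return d

    def set_missing(self, mask: np.ndarray) -> None:
        self.a1[mask] = MISSING
        self.a2[mask] = MISSING
        self.phased[mask] = False

    # --- per-site summaries ----------------------------------------------
    def allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """(alt allele count, called allele count) per site; half-call
        contributes its known allele."""
        known1, known2 = self.a1 >= 0, self.a2 >= 0
        alt = (np.where(known1, self.a1, 0).sum(axis=0)
               + np.where(known2, self.a2, 0).sum(axis=0))
        tot = known1.sum(axis=0) + known2.sum(axis=0)
        return alt.astype(np.int64), tot.astype(np.int64)

    def alt_freq(self) -> np.ndarray:
        alt, tot = self.allele_counts()
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)

    def maf(self) -> np.ndarray:
        f = self.alt_freq()
        return np.minimum(f, 1.0 - f)

    def segregating(self) -> np.ndarray:
        """Sites where at least one called ALT allele is present."""
        alt, tot = self.allele_counts()
        return (alt > 0) & (alt < tot)


@dataclass
class HaplotypePanel:
    """Phased biallelic haplotypes over ordered sites."""

    sites: Sites
    haps: np.ndarray  # (n_haps, n_sites) int8 in {0, 1}
    samples: list[str]  # sample of origin, one entry per haplotype row
    ambiguous: np.ndarray | None = None  # bool, phase-uncertainty flags

    @property
    def n_haps(self) -> int:
        return int(self.haps.shape[0])

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def copy(self) -> "HaplotypePanel":
        amb = None if self.ambiguous is None else self.ambiguous.copy()
        return HaplotypePanel(self.sites.copy(), self.haps.copy(),
                              list(self.samples), amb)

    def take_sites(self, idx) -> "HaplotypePanel":
        idx = np.asarray(idx)
        amb = None if self.ambiguous is None else self.ambiguous[:, idx]
        return HaplotypePanel(self.sites.take(idx), self.haps[:, idx],
                              list(self.samples), amb)

    def take_samples(self, names: Iterable[str]) -> "HaplotypePanel":
        names = list(names)
        keep = np.array([s in set(names) for s in self.samples], dtype=bool)
        amb = None if self.ambiguous is None else self.ambiguous[keep]
        return HaplotypePanel(self.sites.copy(), self.haps[keep],
                              [s for s, k in zip(self.samples, keep) if k], amb)

    def sample_hap_rows(self, name: str) -> list[int]:
        return [i for i, s in enumerate(self.samples) if s == name]

    def alt_freq(self) -> np.ndarray:
        return self.haps.mean(axis=0)

    def to_genotypes(self) -> GenotypeMatrix:
        """Collapse consecutive haplotype pairs into a phased GenotypeMatrix."""
        if self.n_haps % 2:
            raise FounderPanelError("panel does not pair into diploids")
        names = self.samples[0::2]
        if names != self.samples[1::2]:
            raise FounderPanelError("haplotype rows are not paired by sample")
        gm = GenotypeMatrix.empty(self.sites, names)
        gm.a1 = self.haps[0::2].astype(np.int8).copy()
        gm.a2 = self.haps[1::2].astype(np.int8).copy()
        gm.phased = np.ones_like(gm.phased)
        return gm


@dataclass
class Individual:
    iid: str
    father: str | None
    mother: str | None
    sex: int  # 1 male, 2 female, 0 unknown
    fid: str = "FAM1"


class Pedigree:
    """Directed pedigree: parent links, trio/duo derivation, founder list."""

    def __init__(self, individuals: Iterable[Individual]):
        self.individuals: dict[str, Individual] = {}
        for ind in individuals:
            if ind.iid in self.individuals:
                raise PedigreeError(f"duplicate individual id {ind.iid!r}")
            self.individuals[ind.iid] = ind
        self._check_acyclic()

    def __len__(self) -> int:
        return len(self.individuals)

    def __contains__(self, iid: str) -> bool:
        return iid in self.individuals

    def ids(self) -> list[str]:
        return list(self.individuals)

    def parents(self, iid: str) -> tuple[str | None, str | None]:
        ind = self.individuals[iid]
        f = ind.father if ind.father in self.individuals else None
        m = ind.mother if ind.mother in self.individuals else None
        return f, m

    def founders(self) -> list[str]:
        return [i for i in self.individuals if self.parents(i) == (None, None)]

    def trios(self) -> list[tuple[str, str, str]]:
        """(child, father, mother) with both parents present."""
        out = []
        for iid in self.individuals:
            f, m = self.parents(iid)
            if f is not None and m is not None:
                out.append((iid, f, m))
        return out

    def duos(self) -> list[tuple[str, str]]:
        """(child, parent) where exactly one parent is present."""
        out = []
        for iid in self.individuals:
            f, m = self.parents(iid)
            if (f is None) != (m is None):
                out.append((iid, f if f is not None else m))
        return out

    def depth_order(self) -> list[str]:
        """Ids ordered so that parents precede children."""
        depth: dict[str, int] = {}

        def d(iid: str, stack: frozenset) -> int:
            if iid in depth:
                return depth[iid]
            if iid in stack:
                raise PedigreeError(f"pedigree cycle involving {iid!r}")
            f, m = self.parents(iid)
            val = 0 if f is None and m is None else 1 + max(
                d(p, stack | {iid}) for p in (f, m) if p is not None)
            depth[iid] = val
            return val

        for iid in self.individuals:
            d(iid, frozenset())
        return sorted(self.individuals, key=lambda i: (depth[i], i))

    def _check_acyclic(self) -> None:
        self.depth_order()
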