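"""Quality-control cascade: record normalization, genotype filters, Mendelian
masking, exact Hardy-Weinberg test, site filters, concordance, and
sensitivity-by-MAF.

QC is monotone: genotypes only ever become missing and sites are only ever
dropped, so running the cascade on its own output is a no-op.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from .core import (AUTOSOMES, FounderPanelError, GenotypeMatrix, MISSING,
                   Pedigree, Sites)


@dataclass
class QcThresholds:
    min_gq: int = 20
    min_dp: int = 8
    ab_low: float = 0.25
    ab_high: float = 0.75
    max_missing: float = 0.25
    max_mendel: float = 0.10
    hwe_p: float = 1e-6


@dataclass
class QcReport:
    """Counts removed per filter plus survival and concordance summaries."""

    input_sites: int = 0
    normalization: dict = field(default_factory=dict)
    genotype_filters: dict = field(default_factory=dict)
    mendel: dict = field(default_factory=dict)
    site_filters: dict = field(default_factory=dict)
    surviving_sites: int = 0
    concordance: dict = field(default_factory=dict)
    sensitivity: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True, default=int)

    def to_tsv(self) -> str:
        rows = [("input_sites", self.input_sites),
                ("surviving_sites", self.surviving_sites)]
        for group in ("normalization", "genotype_filters", "mendel",
                      "site_filters", "concordance"):
            for k, v in sorted(getattr(self, group).items()):
                rows.append((f"{group}.{k}", v))
        return "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"


# ---------------------------------------------------------------------------
# normalization


def _trim_variant(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Parsimonious, left-shifted representation of an allele pair."""
    # right-trim shared suffix
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # left-trim shared prefix
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def normalize_and_restrict(gm: GenotypeMatrix) -> tuple[GenotypeMatrix, dict]:
    """Drop multi-allelic and non-autosomal records, canonicalize indels,
    collapse duplicate (pos, ref, alt) records."""
    counts = {"multiallelic": 0, "non_autosomal": 0, "duplicate": 0}
    sites = gm.sites
    keep: list[int] = []
    seen: set[tuple] = set()
    new_pos = sites.pos.copy()
    new_ref = sites.ref.copy()
    new_alt = sites.alt.copy()
    for i in range(len(sites)):
        if "," in sites.alt[i]:
            counts["multiallelic"] += 1
            continue
        chrom = str(sites.chrom[i]).removeprefix("chr")
        if chrom not in AUTOSOMES:
            counts["non_autosomal"] += 1
            continue
        p, r, a = _trim_variant(int(sites.pos[i]), sites.ref[i], sites.alt[i])
        key = (chrom, p, r, a)
        if key in seen:
            counts["duplicate"] += 1
            continue
        seen.add(key)
        new_pos[i], new_ref[i], new_alt[i] = p, r, a
        keep.append(i)
    out = gm.copy()
    out.sites = Sites(sites.chrom, new_pos, new_ref, new_alt, sites.cm)
    out = out.take_sites(np.array(keep, dtype=int))
    order = np.lexsort((out.sites.pos, out.sites.chrom.astype(str)))
    out = out.take_sites(order)
    return out, counts


# ---------------------------------------------------------------------------
# genotype-level filters


def filter_genotypes(gm: GenotypeMatrix, thresholds: QcThresholds | None = None
                     ) -> tuple[GenotypeMatrix, dict]:
    """Set low-quality and half-called genotypes to missing.

    A call lacking a quality field (coded as -1) passes that specific rule;
    such passes are counted in the report.
    """
    t = thresholds or QcThresholds()
    out = gm.copy()
    has_gq, has_dp = gm.gq >= 0, gm.dp >= 0
    has_ad = (gm.ad_ref >= 0) & (gm.ad_alt >= 0)
    called_or_half = gm.called() | gm.half_called()

    low_gq = has_gq & (gm.gq < t.min_gq) & called_or_half
    low_dp = has_dp & (gm.dp < t.min_dp) & called_or_half
    ad_sum = (gm.ad_ref + gm.ad_alt).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ab = np.where(ad_sum > 0, gm.ad_alt / np.maximum(ad_sum, 1), np.nan)
    bad_ab = gm.het() & has_ad & ((ab < t.ab_low) | (ab > t.ab_high))
    half = gm.half_called()

    mask = low_gq | low_dp | bad_ab | half
    out.set_missing(mask)
    counts = {
        "low_gq": int(low_gq.sum()),
        "low_dp": int(low_dp.sum()),
        "allele_balance": int(bad_ab.sum()),
        "half_calls": int(half.sum()),
        "set_missing": int(mask.sum()),
        "missing_quality_fields": int((~(has_gq & has_dp & has_ad)
                                       & called_or_half).sum()),
    }
    return out, counts


# ---------------------------------------------------------------------------
# Mendelian consistency


def trio_inconsistent(f: np.ndarray, m: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Elementwise trio impossibility over dosage arrays (NaN = missing)."""
    ok = ~(np.isnan(f) | np.isnan(m) | np.isnan(c))
    bad = np.zeros(f.shape, dtype=bool)
    bad |= (c == 0) & ((f == 2) | (m == 2))
    bad |= (c == 2) & ((f == 0) | (m == 0))
    bad |= (c == 1) & (((f == 0) & (m == 0)) | ((f == 2) & (m == 2)))
    return bad & ok


def duo_inconsistent(p: np.ndarray, c: np.ndarray) -> np.ndarray:
    ok = ~(np.isnan(p) | np.isnan(c))
    return ok & (((p == 0) & (c == 2)) | ((p == 2) & (c == 0)))


def mendel_mask(gm: GenotypeMatrix, ped: Pedigree, use_duos: bool = True
                ) -> tuple[GenotypeMatrix, np.ndarray, dict]:
    """Mask Mendelian-impossible genotype configurations.

    All implicated members are masked (the error cannot be attributed).
    Returns the masked matrix, per-site trio error rates, and counts.
    """
    for iid in ped.ids():
        if iid not in gm.samples:
            raise FounderPanelError(f"pedigree individual {iid!r} not in cohort")
    row = {s: i for i, s in enumerate(gm.samples)}
    dose = gm.dosage()
    mask = np.zeros(dose.shape, dtype=bool)
    n_err = np.zeros(gm.n_sites, dtype=np.int64)
    n_complete = np.zeros(gm.n_sites, dtype=np.int64)
    for child, father, mother in ped.trios():
        ci, fi, mi = row[child], row[father], row[mother]
        bad = trio_inconsistent(dose[fi], dose[mi], dose[ci])
        complete = ~(np.isnan(dose[fi]) | np.isnan(dose[mi]) | np.isnan(dose[ci]))
        n_err += bad
        n_complete += complete
        mask[[fi, mi, ci]] |= bad
    n_duo_err = 0
    if use_duos:
        for child, parent in ped.duos():
            ci, pi = row[child], row[parent]
            bad = duo_inconsistent(dose[pi], dose[ci])
            n_duo_err += int(bad.sum())
            mask[[pi, ci]] |= bad
    out = gm.copy()
    out.set_missing(mask)
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(n_complete > 0, n_err / np.maximum(n_complete, 1), 0.0)
    counts = {"trio_errors": int(n_err.sum()), "duo_errors": int(n_duo_err),
              "calls_masked": int(mask.sum()), "n_trios": len(ped.trios())}
    return out, rates, counts


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_het_distribution(n_minor: int, n_ind: int
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Exact conditional distribution of the heterozygote count given the
    minor-allele count ``n_minor`` among ``n_ind`` diploids.

    Log-space recurrence: P(h+2)/P(h) = (m-h)(M-h) / ((h+1)(h+2)).
    Returns (heterozygote counts, probabilities).
    """
    m, big_m = n_minor, 2 * n_ind - n_minor
    if m > big_m:
        raise ValueError("n_minor is not the minor allele count")
    hs = np.arange(m % 2, m + 1, 2, dtype=np.int64)
    if hs.size == 0:
        return hs, np.ones(0)
    h = hs[:-1].astype(float)
    log_ratio = (np.log(m - h) + np.log(big_m - h)
                 - np.log(h + 1.0) - np.log(h + 2.0))
    logp = np.concatenate([[0.0], np.cumsum(log_ratio)])
    logp -= logsumexp(logp)
    return hs, np.exp(logp)


def hwe_exact(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact HWE p-value: total probability of heterozygote counts
    whose conditional probability does not exceed the observed one."""
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("negative genotype count")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no genotypes observed")
    m = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    hs, probs = hwe_het_distribution(m, n)
    p_obs = probs[np.searchsorted(hs, n_Aa)]
    p = probs[probs <= p_obs * (1.0 + 1e-12)].sum()
    return float(min(1.0, p))


def hwe_exact_oracle(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Independent enumeration via log-factorials (no recurrence)."""
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no genotypes observed")
    m = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    big_m = 2 * n - m
    hs = np.arange(m % 2, m + 1, 2, dtype=np.int64)
    logp = (hs * np.log(2.0) + gammaln(n + 1)
            - gammaln(hs + 1) - gammaln((m - hs) / 2 + 1)
            - gammaln((big_m - hs) / 2 + 1)
            + gammaln(m + 1) + gammaln(big_m + 1) - gammaln(2 * n + 1))
    probs = np.exp(logp - logsumexp(logp))
    p_obs = probs[np.searchsorted(hs, n_Aa)]
    return float(min(1.0, probs[probs <= p_obs * (1.0 + 1e-12)].sum()))


def hwe_pvalues(gm: GenotypeMatrix) -> np.ndarray:
    """Per-site exact HWE p-value over fully called genotypes (1.0 where no
    complete calls)."""
    dose = gm.dosage()
    out = np.ones(gm.n_sites)
    n_hom_ref = np.nansum(dose == 0, axis=0).astype(int)
    n_het = np.nansum(dose == 1, axis=0).astype(int)
    n_hom_alt = np.nansum(dose == 2, axis=0).astype(int)
    for j in range(gm.n_sites):
        if n_hom_ref[j] + n_het[j] + n_hom_alt[j] > 0:
            out[j] = hwe_exact(n_hom_ref[j], n_het[j], n_hom_alt[j])
    return out


# ---------------------------------------------------------------------------
# site-level filters


def filter_sites(gm: GenotypeMatrix, mendel_rates: np.ndarray | None = None,
                 thresholds: QcThresholds | None = None,
                 ped: Pedigree | None = None
                 ) -> tuple[GenotypeMatrix, QcReport]:
    """Drop sites failing missingness, Mendel-rate, HWE, or monomorphism
    rules (thresholds strict, as printed defaults)."""
    t = thresholds or QcThresholds()
    if mendel_rates is None:
        if ped is not None:
            _, mendel_rates, _ = mendel_mask(gm, ped)
        else:
            mendel_rates = np.zeros(gm.n_sites)
    n = gm.n_samples
    missing_rate = 1.0 - gm.called().sum(axis=0) / max(n, 1)
    hwe_p = hwe_pvalues(gm)
    alt, tot = gm.allele_counts()
    fail_missing = missing_rate > t.max_missing
    fail_mendel = np.asarray(mendel_rates) > t.max_mendel
    fail_hwe = hwe_p < t.hwe_p
    fail_mono = alt == 0
    fail = fail_missing | fail_mendel | fail_hwe | fail_mono
    report = QcReport(input_sites=gm.n_sites)
    report.site_filters = {
        "missing_rate": int(fail_missing.sum()),
        "mendel_rate": int(fail_mendel.sum()),
        "hwe": int(fail_hwe.sum()),
        "monomorphic": int(fail_mono.sum()),
        "dropped": int(fail.sum()),
    }
    out = gm.take_sites(np.flatnonzero(~fail))
    report.surviving_sites = out.n_sites
    return out, report


def run_qc(gm: GenotypeMatrix, ped: Pedigree | None = None,
           thresholds: QcThresholds | None = None
           ) -> tuple[GenotypeMatrix, QcReport]:
    """Full cascade: normalization -> genotype filters -> Mendel mask ->
    site filters. Filter order is fixed."""
    t = thresholds or QcThresholds()
    gm1, norm_counts = normalize_and_restrict(gm)
    gm2, geno_counts = filter_genotypes(gm1, t)
    if ped is not None:
        gm3, mendel_rates, mendel_counts = mendel_mask(gm2, ped)
    else:
        gm3, mendel_rates, mendel_counts = gm2, np.zeros(gm2.n_sites), {}
    gm4, report = filter_sites(gm3, mendel_rates, t)
    report.input_sites = gm.n_sites
    report.normalization = norm_counts
    report.genotype_filters = geno_counts
    report.mendel = mendel_counts
    return gm4, report


# ---------------------------------------------------------------------------
# concordance and sensitivity


def concordance(gm: GenotypeMatrix, pairs: list[tuple[str, str]]) -> dict:
    """Genotype concordance within duplicate-sample pairs, split by variant
    class; missing calls are excluded from the denominator."""
    row = {s: i for i, s in enumerate(gm.samples)}
    for a, b in pairs:
        for s in (a, b):
            if s not in row:
                raise FounderPanelError(f"unknown sample {s!r}")
    is_snv = gm.sites.is_snv()
    out = {}
    for cls, sel in (("snv", is_snv), ("indel", ~is_snv)):
        n_agree = n_total = 0
        for a, b in pairs:
            da, db = gm.dosage()[row[a], sel], gm.dosage()[row[b], sel]
            ok = ~(np.isnan(da) | np.isnan(db))
            n_total += int(ok.sum())
            n_agree += int((da[ok] == db[ok]).sum())
        out[cls] = {"rate": (n_agree / n_total) if n_total else float("nan"),
                    "n_compared": n_total}
    return out


def sensitivity_by_maf(wgs: GenotypeMatrix, array: GenotypeMatrix,
                       bins: np.ndarray) -> list[dict]:
    """Fraction of high-quality array sites (minor allele count > 0, missing
    rate < 5%, HWE p > 1e-4) that segregate in the WGS call set, per array
    MAF bin."""
    shared = set(wgs.samples) & set(array.samples)
    if not shared:
        raise FounderPanelError("no overlapping samples")
    alt, tot = array.allele_counts()
    mac = np.minimum(alt, tot - alt)
    missing_rate = 1.0 - array.called().sum(axis=0) / max(array.n_samples, 1)
    hwe_p = hwe_pvalues(array)
    good = (mac > 0) & (missing_rate < 0.05) & (hwe_p > 1e-4)
    maf = array.maf()
    wgs_keys = {k for k, seg in zip(wgs.sites.locus_keys(),
                                    (wgs.allele_counts()[0] > 0))
                if seg}
    present = np.array([k in wgs_keys for k in array.sites.locus_keys()])
    edges = np.asarray(bins, dtype=float)
    out = []
    for b in range(edges.size):
        lo = 0.0 if b == 0 else edges[b - 1]
        sel = good & (maf > lo if b else maf >= 0.0) & (maf <= edges[b])
        n = int(sel.sum())
        sens = float(present[sel].sum() / n) if n else float("nan")
        out.append({"bin_upper": float(edges[b]), "n_sites": n,
                    "sensitivity": sens})
    return out
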