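"""Population-genetic characterizations: BLUE allele frequencies,
rare-variant depletion resampling, drift enrichment, IBD/HBD segment
detection and summaries, and the frequency-binned deleteriousness
comparison."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import FounderPanelError, GenotypeMatrix, HaplotypePanel, Pedigree
from .panelbuild import inbreeding, pedigree_kinship, select_unrelated
from .simpop import TruthTracks

#: Cohort MAF bins: rare < 0.5%, low 0.5-5%, common > 5% (strict boundaries).
BIN3_LABELS = ("rare", "low", "common")


def bin3(maf: float | np.ndarray) -> np.ndarray:
    maf = np.asarray(maf, dtype=float)
    out = np.where(maf < 0.005, "rare",
                   np.where(maf > 0.05, "common", "low"))
    return out.astype(object)


# ---------------------------------------------------------------------------
# BLUE allele frequencies


def phi_star(ped: Pedigree, ids: list[str]) -> np.ndarray:
    """Kinship matrix with inbreeding-adjusted diagonal:
    Phi*_ii = (1 + F_i) / 2, Phi*_ij = phi_ij."""
    all_ids, phi = pedigree_kinship(ped)
    pos = {iid: k for k, iid in enumerate(all_ids)}
    fs = inbreeding(ped)
    idx = np.array([pos[i] for i in ids])
    m = phi[np.ix_(idx, idx)].copy()
    np.fill_diagonal(m, [(1.0 + fs[i]) / 2.0 for i in ids])
    return m


def blue_frequency(g: np.ndarray, kin: np.ndarray) -> tuple[float, float]:
    """Best linear unbiased allele-frequency estimate and standard error.

    ``g`` holds per-individual allele fractions (0, 1/2, 1; NaN = missing);
    ``kin`` is the inbreeding-adjusted kinship matrix over the same
    individuals. p = (1' K^-1 g) / (1' K^-1 1); se^2 = p(1-p) / (2 1'K^-1 1).
    """
    g = np.asarray(g, dtype=float)
    keep = ~np.isnan(g)
    if keep.sum() == 0:
        raise FounderPanelError("no called individuals")
    k = np.asarray(kin, dtype=float)[np.ix_(keep, keep)]
    ones = np.ones(int(keep.sum()))
    try:
        w = np.linalg.solve(k, ones)
    except np.linalg.LinAlgError:
        raise FounderPanelError(
            "singular kinship matrix (duplicate individuals?); deduplicate "
            "the cohort before estimating frequencies") from None
    denom = float(ones @ w)
    p = float(w @ g[keep] / denom)
    # with Phi*_ii = (1+F)/2 the unrelated case gives var = p(1-p)/(2n)
    se = float(np.sqrt(max(p * (1.0 - p), 0.0) / denom))
    return p, se


def blue_frequencies(gm: GenotypeMatrix, ped: Pedigree) -> pd.DataFrame:
    """FreqTable: naive and BLUE frequencies with SE and 3-way MAF bin.

    Individuals missing at a site are dropped for that site; the linear
    solve is cached per missingness pattern.
    """
    ids = [s for s in gm.samples if s in ped]
    sub = gm.take_samples(ids)
    kin = phi_star(ped, ids)
    dose = sub.dosage() / 2.0  # allele fractions
    naive = np.nanmean(dose, axis=0)
    p_hat = np.empty(sub.n_sites)
    se = np.empty(sub.n_sites)
    cache: dict[bytes, np.ndarray] = {}
    for j in range(sub.n_sites):
        g = dose[:, j]
        keep = ~np.isnan(g)
        key = keep.tobytes()
        if key not in cache:
            kk = kin[np.ix_(keep, keep)]
            try:
                cache[key] = np.linalg.solve(kk, np.ones(int(keep.sum())))
            except np.linalg.LinAlgError:
                raise FounderPanelError(
                    "singular kinship matrix (duplicate individuals?)"
                ) from None
        w = cache[key]
        denom = float(w.sum())
        p_hat[j] = float(w @ g[keep] / denom)
        se[j] = float(np.sqrt(max(p_hat[j] * (1 - p_hat[j]), 0.0) / denom))
    maf = np.minimum(p_hat, 1.0 - p_hat)
    return pd.DataFrame({
        "chrom": sub.sites.chrom, "pos": sub.sites.pos,
        "ref": sub.sites.ref, "alt": sub.sites.alt,
        "naive_freq": naive, "blue_freq": p_hat, "blue_se": se,
        "maf": maf, "bin3": bin3(maf)})


# ---------------------------------------------------------------------------
# rare-variant depletion


def depletion_resample(cohort: GenotypeMatrix, reference: GenotypeMatrix,
                       ped: Pedigree, n_sub: int, n_reps: int = 10,
                       bins=(0.005, 0.05, 0.5), seed: int = 0,
                       rare_inclusive: bool = True,
                       max_degree: int = 3) -> pd.DataFrame:
    """Counts of segregating SNVs per MAF bin: one unrelated cohort
    subsample vs resampled (with replacement) reference subsets.

    MAF is recomputed within each counting subsample. Bin edges are upper
    bounds; the first bin is MAF <= edge when ``rare_inclusive``.
    """
    unrelated = select_unrelated(ped, max_degree=max_degree,
                                 within=list(cohort.samples))
    if len(unrelated) < n_sub:
        raise FounderPanelError(
            f"only {len(unrelated)} unrelated cohort individuals available, "
            f"need {n_sub}")
    if reference.n_samples < n_sub:
        raise FounderPanelError("reference smaller than n_sub")
    from .core import substream
    rng_ref = substream(seed, "depletion")
    edges = np.asarray(bins, dtype=float)

    def counts(gm: GenotypeMatrix, cols: np.ndarray) -> np.ndarray:
        snv = gm.sites.is_snv()
        a1 = gm.a1[cols][:, snv]
        a2 = gm.a2[cols][:, snv]
        known1, known2 = a1 >= 0, a2 >= 0
        alt = (np.where(known1, a1, 0) + np.where(known2, a2, 0)).sum(axis=0)
        tot = (known1.sum(axis=0) + known2.sum(axis=0))
        mac = np.minimum(alt, tot - alt)
        seg = mac > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            maf = np.where(tot > 0, np.minimum(alt, tot - alt)
                           / np.maximum(tot, 1), 0.0)
        out = np.zeros(edges.size, dtype=np.int64)
        for b in range(edges.size):
            lo = 0.0 if b == 0 else edges[b - 1]
            if b == 0 and rare_inclusive:
                sel = seg & (maf <= edges[0])
            else:
                sel = seg & (maf > lo) & (maf <= edges[b])
            out[b] = int(sel.sum())
        return out

    cohort_cols = np.array([cohort.samples.index(u)
                            for u in unrelated[:n_sub]], dtype=int)
    cohort_counts = counts(cohort, cohort_cols)
    rep_counts = np.empty((n_reps, edges.size), dtype=np.int64)
    for r in range(n_reps):
        cols = rng_ref.integers(0, reference.n_samples, size=n_sub)
        rep_counts[r] = counts(reference, cols)
    return pd.DataFrame({
        "bin_upper": edges,
        "cohort_count": cohort_counts,
        "reference_mean": rep_counts.mean(axis=0),
        "reference_sd": rep_counts.std(axis=0, ddof=1) if n_reps > 1
        else np.zeros(edges.size),
    })


# ---------------------------------------------------------------------------
# drift enrichment


def drift_enrichment(cohort_freqs: pd.DataFrame,
                     reference_maf: dict[tuple, float],
                     ref_cut: float = 0.005, cohort_cut: float = 0.05
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Variants rare or absent in the reference (MAF < ref_cut, absent = 0)
    that exceed ``cohort_cut`` cohort MAF; strict inequalities.

    Returns (drifted variant table, 3x3 bin cross-table)."""
    keys = list(zip(cohort_freqs["chrom"], cohort_freqs["pos"]))
    ref = np.array([reference_maf.get(k, 0.0) for k in keys])
    coh = cohort_freqs["maf"].to_numpy(dtype=float)
    hit = (ref < ref_cut) & (coh > cohort_cut)
    drifted = cohort_freqs.loc[hit].copy()
    drifted["reference_maf"] = ref[hit]
    cross = pd.crosstab(pd.Series(bin3(coh), name="cohort_bin"),
                        pd.Series(bin3(ref), name="reference_bin"))
    return drifted, cross


# ---------------------------------------------------------------------------
# IBD / HBD segments


def _label_track_segments(track_a: list, track_b: list, cm: np.ndarray,
                          min_cm: float,
                          founder_seq: np.ndarray | None = None,
                          max_mismatch: int = 0
                          ) -> list[tuple[float, float]]:
    """cM intervals where two founder-label tracks carry the same label.

    When ``founder_seq`` is given, intervals where two differently-labelled
    founder haplotypes are sequence-identical also count: identical founder
    segments are the same ancestral haplotype for every downstream purpose.
    Contiguous intersections are merged before the length filter: sharing
    that continues across a simultaneous label switch is one segment.
    """
    raw: list[tuple[int, int]] = []
    for a0, a1, lab_a in track_a:
        for b0, b1, lab_b in track_b:
            lo, hi = max(a0, b0), min(a1, b1)
            if lo >= hi:
                continue
            if lab_a == lab_b:
                raw.append((lo, hi))
            elif founder_seq is not None:
                diff = founder_seq[lab_a, lo:hi] != founder_seq[lab_b, lo:hi]
                bounds = [lo - 1, *(np.flatnonzero(diff) + lo).tolist(), hi]
                last = len(bounds) - 1
                s = cm.shape[0]
                for i in range(last):
                    j = min(i + max_mismatch + 1, last)
                    c0, c1 = bounds[i] + 1, bounds[j]
                    # only windows long enough on their own may join the
                    # truth set, otherwise tolerant windows chain unboundedly
                    if c0 < c1 and \
                            cm[min(c1, s - 1)] - cm[c0] >= min_cm:
                        raw.append((c0, c1))
    raw.sort()
    merged: list[tuple[int, int]] = []
    for lo, hi in raw:
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    out = []
    s = cm.shape[0]
    step = cm[-1] - cm[-2] if s > 1 else 0.0
    for lo, hi in merged:
        c0 = cm[lo]
        c1 = cm[hi] if hi < s else cm[-1] + step
        if c1 - c0 >= min_cm:
            out.append((float(c0), float(c1)))
    return out


def _identity_segments(h1: np.ndarray, h2: np.ndarray, cm: np.ndarray,
                       min_cm: float, max_mismatch: int
                       ) -> list[tuple[float, float]]:
    """Maximal allele-identity runs allowing <= max_mismatch mismatches per
    segment; greedy left-to-right scan, ends trimmed to matching sites."""
    mism = np.flatnonzero(h1 != h2)
    s = h1.shape[0]
    bounds = [-1, *mism.tolist(), s]
    out: list[tuple[float, float]] = []
    i = 0
    # segments span runs of matches joined across up to max_mismatch mismatches
    while i < len(bounds) - 1:
        j = min(i + max_mismatch + 1, len(bounds) - 1)
        start, end = bounds[i] + 1, bounds[j] - 1  # trimmed to matches
        if start <= end:
            c0, c1 = cm[start], cm[min(end + 1, s - 1)]
            if end + 1 >= s and s > 1:
                c1 = cm[-1] + (cm[-1] - cm[-2])
            if c1 - c0 >= min_cm:
                if out and out[-1][0] <= c0 <= out[-1][1]:
                    out[-1] = (out[-1][0], max(out[-1][1], float(c1)))
                else:
                    out.append((float(c0), float(c1)))
        i += 1
    return out


def _merge_intervals(segs: list[tuple[float, float]]
                     ) -> list[tuple[float, float]]:
    if not segs:
        return []
    segs = sorted(segs)
    out = [segs[0]]
    for lo, hi in segs[1:]:
        if lo <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], hi))
        else:
            out.append((lo, hi))
    return out


@dataclass
class SegmentSet:
    """IBD segments keyed by sample pair, HBD segments keyed by sample.

    ``ibd`` holds the union over the four haplotype-pair combinations (a
    locus is shared if any pair of haplotypes is identical by descent);
    ``pihat`` holds the kinship-scale sharing Sum(combo fractions)/2, whose
    expectation is 2*phi.
    """

    ibd: dict[tuple[str, str], list[tuple[float, float]]]
    hbd: dict[str, list[tuple[float, float]]]
    map_length_cm: float
    pihat: dict[tuple[str, str], float] | None = None

    def ibd_fraction(self, pair: tuple[str, str]) -> float:
        segs = self.ibd.get(tuple(sorted(pair)), [])
        return sum(hi - lo for lo, hi in segs) / self.map_length_cm

    def ibd_pihat(self, pair: tuple[str, str]) -> float:
        return (self.pihat or {}).get(tuple(sorted(pair)), 0.0)

    def hbd_total(self, iid: str) -> float:
        return sum(hi - lo for lo, hi in self.hbd.get(iid, []))


def _founder_sequences(truth: TruthTracks) -> np.ndarray:
    """Founder haplotype alleles indexed by founder-haplotype label."""
    panel = truth.true_haplotypes
    n_lab = 1 + max(lab for segs in truth.founder_labels.values()
                    for _, _, lab in segs)
    out = np.zeros((n_lab, panel.n_sites), dtype=np.int8)
    seen = np.zeros(n_lab, dtype=bool)
    s = panel.n_sites
    for (iid, h), segs in truth.founder_labels.items():
        if len(segs) == 1 and segs[0][0] == 0 and segs[0][1] == s:
            lab = segs[0][2]
            row = panel.sample_hap_rows(iid)[h]
            out[lab] = panel.haps[row]
            seen[lab] = True
    if not seen.all():
        raise FounderPanelError("founder haplotypes not recoverable from "
                                "truth tracks")
    return out


def detect_segments(data: TruthTracks | HaplotypePanel, mode: str = "truth",
                    min_cm: float = 3.0, max_mismatch: int = 2,
                    samples: list[str] | None = None,
                    pairs: list[tuple[str, str]] | None = None,
                    founder_identity: bool = False) -> SegmentSet:
    """IBD (across individuals) and HBD (within) segments >= min_cm.

    Truth mode intersects founder-label tracks; haplotype mode scans allele
    identity allowing <= max_mismatch mismatches per segment. With
    ``founder_identity`` truth mode additionally counts intervals where two
    differently-labelled founder haplotypes are sequence-identical (the same
    ancestral haplotype sampled twice into the founder set).
    """
    if mode == "truth":
        if not isinstance(data, TruthTracks):
            raise FounderPanelError("truth mode requires TruthTracks")
        panel = data.true_haplotypes
    else:
        panel = data if isinstance(data, HaplotypePanel) else data.true_haplotypes
    cm = panel.sites.cm
    if np.isnan(cm).any():
        raise FounderPanelError("unmapped sites: cM positions required")
    ids = samples if samples is not None else sorted(set(panel.samples))
    rows = {iid: panel.sample_hap_rows(iid) for iid in ids}
    length = float(cm[-1] - cm[0] + (cm[-1] - cm[-2] if len(cm) > 1 else 0.0))
    founder_seq = (_founder_sequences(data)
                   if mode == "truth" and founder_identity else None)

    def hap_pair_segments(r1: int, r2: int) -> list[tuple[float, float]]:
        if mode == "truth":
            key1 = (panel.samples[r1], r1 % 2)
            key2 = (panel.samples[r2], r2 % 2)
            return _label_track_segments(data.founder_labels[key1],
                                         data.founder_labels[key2], cm, min_cm,
                                         founder_seq, max_mismatch)
        return _identity_segments(panel.haps[r1], panel.haps[r2], cm,
                                  min_cm, max_mismatch)

    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1:]]
    ibd: dict[tuple[str, str], list] = {}
    pihat: dict[tuple[str, str], float] = {}
    for a, b in pairs:
        segs: list[tuple[float, float]] = []
        combo_total = 0.0
        for r1 in rows[a]:
            for r2 in rows[b]:
                got = hap_pair_segments(r1, r2)
                combo_total += sum(hi - lo for lo, hi in got)
                segs.extend(got)
        key = tuple(sorted((a, b)))
        ibd[key] = _merge_intervals(segs)
        pihat[key] = combo_total / (2.0 * length)
    hbd: dict[str, list] = {}
    for iid in ids:
        r1, r2 = rows[iid][:2]
        hbd[iid] = _merge_intervals(hap_pair_segments(r1, r2))
    return SegmentSet(ibd=ibd, hbd=hbd, map_length_cm=length, pihat=pihat)


def sharing_summaries(segments: SegmentSet, groups: dict[str, list[str]]
                      ) -> dict:
    """Grouped IBD-fraction and HBD-length distributions.

    ``groups`` maps group name -> sample ids. Emits within-group and
    between-group IBD fraction distributions plus per-group HBD totals.
    """
    names = list(groups)
    out: dict[str, np.ndarray] = {}
    for gi, ga in enumerate(names):
        ids_a = groups[ga]
        within = [segments.ibd_fraction((a, b))
                  for i, a in enumerate(ids_a) for b in ids_a[i + 1:]
                  if tuple(sorted((a, b))) in segments.ibd]
        out[f"ibd_within_{ga}"] = np.asarray(within)
        out[f"hbd_{ga}"] = np.asarray([segments.hbd_total(i) for i in ids_a
                                       if i in segments.hbd])
        for gb in names[gi + 1:]:
            between = [segments.ibd_fraction((a, b))
                       for a in ids_a for b in groups[gb]
                       if tuple(sorted((a, b))) in segments.ibd]
            out[f"ibd_between_{ga}_{gb}"] = np.asarray(between)
    return out


# ---------------------------------------------------------------------------
# rank-sum test and deleteriousness comparison


def ranksum(x: np.ndarray, y: np.ndarray, exact_max: int = 20) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Normal approximation with continuity and tie correction; exact
    enumeration when both groups have <= ``exact_max`` observations.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        return float("nan")
    method = "exact" if (x.size <= exact_max and y.size <= exact_max) else \
        "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.pvalue)


def deleteriousness_compare(scores: pd.DataFrame, freqs: pd.DataFrame,
                            class_column: str | None = None) -> pd.DataFrame:
    """Mean score per sharing status and rank-sum p within each stratum
    (3-way cohort MAF bin x optional coding class).

    Strata with an empty group are reported with a NaN p-value rather than
    raising.
    """
    merged = scores.merge(freqs[["chrom", "pos", "maf", "bin3"]],
                          on=["chrom", "pos"], how="inner")
    if merged.empty:
        raise FounderPanelError("no scored variants with frequency bins")
    strata = ["bin3"] + ([class_column] if class_column else [])
    rows = []
    for key, grp in merged.groupby(strata, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        shared = grp.loc[grp["status"] == "shared", "score"].to_numpy()
        spec = grp.loc[grp["status"] == "cohort_specific", "score"].to_numpy()
        row = dict(zip(strata, key))
        row.update({
            "n_shared": shared.size, "n_specific": spec.size,
            "mean_shared": float(shared.mean()) if shared.size else float("nan"),
            "mean_specific": float(spec.mean()) if spec.size else float("nan"),
            "p_value": ranksum(spec, shared)
            if shared.size and spec.size else float("nan"),
            "testable": bool(shared.size and spec.size),
        })
        rows.append(row)
    return pd.DataFrame(rows)
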