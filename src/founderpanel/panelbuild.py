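"""Reference-panel construction: pedigree kinship, unrelated-subset
selection, transmission phasing, and panel assembly/merging."""
from __future__ import annotations

import numpy as np

from .core import (GenotypeMatrix, HaplotypePanel, MergeError, Pedigree,
                   PedigreeError, Sites)


def pedigree_kinship(ped: Pedigree) -> tuple[list[str], np.ndarray]:
    """Exact kinship matrix by the tabular method.

    phi(i,i) = (1 + phi(father_i, mother_i)) / 2;
    phi(i,j) = (phi(father_i, j) + phi(mother_i, j)) / 2 for i later than j;
    founders are pairwise unrelated and non-inbred.
    """
    order = ped.depth_order()  # raises on cycles
    idx = {iid: k for k, iid in enumerate(order)}
    n = len(order)
    phi = np.zeros((n, n))
    for k, iid in enumerate(order):
        f, m = ped.parents(iid)
        fi = idx[f] if f is not None else None
        mi = idx[m] if m is not None else None
        for j in range(k):
            val = 0.0
            if fi is not None:
                val += 0.5 * phi[fi, j]
            if mi is not None:
                val += 0.5 * phi[mi, j]
            phi[k, j] = phi[j, k] = val
        inb = phi[fi, mi] if (fi is not None and mi is not None) else 0.0
        phi[k, k] = 0.5 * (1.0 + inb)
    ids = ped.ids()
    perm = np.array([idx[i] for i in ids])
    return ids, phi[np.ix_(perm, perm)]


def inbreeding(ped: Pedigree) -> dict[str, float]:
    """F_i = phi(father_i, mother_i); 0 for founders."""
    ids, phi = pedigree_kinship(ped)
    pos = {iid: k for k, iid in enumerate(ids)}
    out = {}
    for iid in ids:
        f, m = ped.parents(iid)
        out[iid] = float(phi[pos[f], pos[m]]) if (f and m) else 0.0
    return out


def kinship_cutoff(max_degree: int) -> float:
    """Geometric boundary below degree ``max_degree`` relatedness: pairs with
    phi >= 2^-(d + 1.5) are considered related at degree <= d."""
    return float(2.0 ** -(max_degree + 1.5))


def select_unrelated(ped: Pedigree, max_degree: int = 3,
                     kinship: tuple[list[str], np.ndarray] | None = None,
                     within: list[str] | None = None) -> list[str]:
    """Greedy unrelated subset: repeatedly drop the individual related (at
    phi >= cutoff) to the most remaining others, ties broken by dropping the
    lexicographically last id. ``within`` restricts the candidate pool
    (kinship is still computed on the full pedigree)."""
    if len(ped) == 0:
        raise PedigreeError("empty pedigree")
    ids, phi = kinship if kinship is not None else pedigree_kinship(ped)
    if within is not None:
        keep = [k for k, iid in enumerate(ids) if iid in set(within)]
        ids = [ids[k] for k in keep]
        phi = phi[np.ix_(keep, keep)]
    cutoff = kinship_cutoff(max_degree)
    related = (phi >= cutoff)
    np.fill_diagonal(related, False)
    alive = dict.fromkeys(ids, True)
    pos = {iid: k for k, iid in enumerate(ids)}
    while True:
        alive_idx = [pos[i] for i, a in alive.items() if a]
        sub = related[np.ix_(alive_idx, alive_idx)]
        deg = sub.sum(axis=1)
        if deg.max(initial=0) == 0:
            break
        worst = max(range(len(alive_idx)),
                    key=lambda k: (deg[k], ids[alive_idx[k]]))
        alive[ids[alive_idx[worst]]] = False
    return sorted(i for i, a in alive.items() if a)


# ---------------------------------------------------------------------------
# transmission phasing


def _resolve_by_parents(dose: np.ndarray, row: dict[str, int],
                        ped: Pedigree, samples: list[str]
                        ) -> tuple[np.ndarray, np.ndarray]:
    """First pass: per sample, (2, S) haplotypes with -1 where unresolved.

    Homozygous calls resolve themselves; heterozygotes resolve when at least
    one genotyped parent is homozygous. Row 0 is paternal where a father is
    known, otherwise "transmitted-by-parent-1" by convention.
    """
    n, s = len(samples), dose.shape[1]
    haps = np.full((n, 2, s), -1, dtype=np.int8)
    for i, iid in enumerate(samples):
        d = dose[i]
        hom = (d == 0) | (d == 2)
        haps[i, 0, hom] = haps[i, 1, hom] = (d[hom] // 2).astype(np.int8)
        het = d == 1
        if iid not in ped:
            continue
        f, m = ped.parents(iid)
        for hap_i, parent in ((0, f), (1, m)):
            if parent is None or parent not in row:
                continue
            pd = dose[row[parent]]
            p_hom = het & ((pd == 0) | (pd == 2))
            haps[i, hap_i, p_hom] = (pd[p_hom] // 2).astype(np.int8)
            other = 1 - hap_i
            haps[i, other, p_hom] = 1 - haps[i, hap_i, p_hom]
    return haps, haps >= 0


def _anchor_parents_by_children(haps: np.ndarray, resolved: np.ndarray,
                                dose: np.ndarray, row: dict[str, int],
                                ped: Pedigree, samples: list[str]
                                ) -> np.ndarray:
    """Phase het sites of parents lacking genotyped parents via the gamete
    each transmitted to a child.

    Haplotype 0 is anchored to the gamete sent to the most-informative
    child; remaining sites are filled from further children in order of
    informativeness. Mutates ``haps``/``resolved``; returns flags for the
    anchored calls (the gamete is a recombined mosaic, so this phase is
    approximate and stays marked uncertain).
    """
    anchored = np.zeros(resolved.shape, dtype=bool)
    children: dict[str, list[tuple[str, int]]] = {}
    for iid in samples:
        if iid not in ped:
            continue
        f, m = ped.parents(iid)
        if f in row:
            children.setdefault(f, []).append((iid, 0))
        if m in row:
            children.setdefault(m, []).append((iid, 1))
    for iid in samples:
        if iid in ped and any(p in row for p in ped.parents(iid)):
            continue  # pass 1 already fixed this sample's orientation
        kids = children.get(iid, [])
        if not kids:
            continue
        i = row[iid]
        het = dose[i] == 1

        def informative(kid: tuple[str, int]) -> int:
            c, hap_i = kid
            return int((het & ~resolved[i, 0]
                        & resolved[row[c], hap_i]).sum())

        for c, hap_i in sorted(kids, key=informative, reverse=True):
            sel = het & ~resolved[i, 0] & resolved[row[c], hap_i]
            if not sel.any():
                continue
            transmitted = haps[row[c], hap_i, sel]
            haps[i, 0, sel] = transmitted
            haps[i, 1, sel] = 1 - transmitted
            resolved[i, 0, sel] = resolved[i, 1, sel] = True
            anchored[i, 0, sel] = anchored[i, 1, sel] = True
    return anchored


def _window_fill(haps: np.ndarray, resolved: np.ndarray, dose: np.ndarray,
                 window: int, parent_rows: list | None = None) -> np.ndarray:
    """Resolve remaining sites by copying from the best-matching resolved
    haplotype context in a sliding window. Mutates ``haps``; returns
    ambiguity flags.

    Heterozygous sites are decided jointly for the two haplotypes: the
    complementary allele pair follows whichever haplotype has the stronger
    windowed context match.
    """
    n, _, s = haps.shape
    flat = haps.reshape(n * 2, s)
    res = resolved.reshape(n * 2, s)
    ambiguous = np.zeros((n * 2, s), dtype=bool)
    ref = flat.copy()  # snapshot: every fill is based on pass-1 data only
    ref_res = res.copy()

    def windowed(x: np.ndarray) -> np.ndarray:  # box filter along sites
        c = np.cumsum(np.pad(x, ((0, 0), (window + 1, window))), axis=1)
        return c[:, 2 * window + 1:] - c[:, :-2 * window - 1]

    cnt = ref_res.sum(axis=0)
    maj = (np.where(ref_res, ref, 0).sum(axis=0) * 2 > cnt).astype(np.int8)

    for i in range(n):
        rows = (i * 2, i * 2 + 1)
        if res[rows, :].all():
            continue
        fill_allele = np.empty((2, s), dtype=np.int8)
        fill_score = np.full((2, s), np.inf)
        for hap_i, r in enumerate(rows):
            both = ref_res & res[r][None, :]
            both[i * 2:i * 2 + 2] = False  # never copy from self
            mism = both & (ref != flat[r][None, :])
            wb = windowed(both.astype(float))
            wm = windowed(mism.astype(float))
            frac = np.where(wb > 0, wm / np.maximum(wb, 1e-9), np.inf)
            cols = np.arange(s)
            # the true copy source for a child's gamete is one of that
            # parent's two haplotypes: prefer them when they are resolved
            allele = np.full(s, -1, dtype=np.int8)
            score = np.full(s, np.inf)
            if parent_rows is not None and parent_rows[i][hap_i] is not None:
                pr = parent_rows[i][hap_i]
                loc = np.argmin(frac[pr, :], axis=0)
                lbest = np.array(pr)[loc]
                lok = np.isfinite(frac[lbest, cols]) & ref_res[lbest, cols]
                allele[lok] = ref[lbest[lok], cols[lok]]
                score[lok] = frac[lbest[lok], cols[lok]] - 1e-6
            best = np.argmin(frac, axis=0)
            gok = np.isfinite(frac[best, cols]) & ref_res[best, cols]
            use_g = (allele < 0) & gok
            allele[use_g] = ref[best[use_g], cols[use_g]]
            score[use_g] = frac[best[use_g], cols[use_g]]
            none = allele < 0
            allele[none] = maj[none]
            score[none] = 1.0
            fill_allele[hap_i] = allele
            fill_score[hap_i] = score
        het = dose[i] == 1
        for hap_i, r in enumerate(rows):
            todo = ~res[r]
            other = 1 - hap_i
            # het: complementary pair follows the stronger context match
            trust_other = het & (fill_score[other] < fill_score[hap_i])
            pick = np.where(trust_other, 1 - fill_allele[other],
                            fill_allele[hap_i]).astype(np.int8)
            flat[r, todo] = pick[todo]
            ambiguous[r, todo] = True
    return ambiguous.reshape(n, 2, s)


def transmission_phase(gm: GenotypeMatrix, ped: Pedigree, window: int = 25
                       ) -> HaplotypePanel:
    """Phase by pedigree transmission plus windowed haplotype-context fill.

    Mendelian-unambiguous assignments are exact; remaining heterozygotes and
    missing calls are filled from the best-matching resolved context and
    flagged ambiguous.
    """
    samples = list(gm.samples)
    row = {iid: i for i, iid in enumerate(samples)}
    dose = gm.dosage()
    haps, resolved = _resolve_by_parents(dose, row, ped, samples)
    anchored = _anchor_parents_by_children(haps, resolved, dose, row, ped,
                                           samples)
    parent_rows = []
    for iid in samples:
        f, m = ped.parents(iid) if iid in ped else (None, None)
        parent_rows.append(tuple(
            [2 * row[p], 2 * row[p] + 1] if p in row else None
            for p in (f, m)))
    ambiguous = _window_fill(haps, resolved, dose, window, parent_rows)
    ambiguous |= anchored
    # het repair: for het genotypes the two rows must differ
    het = dose == 1
    same = haps[:, 0, :] == haps[:, 1, :]
    fix = het & same
    haps[:, 1, :][fix] = 1 - haps[:, 0, :][fix]
    haps = np.clip(haps, 0, 1).astype(np.int8)
    n, _, s = haps.shape
    out_haps = haps.reshape(n * 2, s)
    out_amb = ambiguous.reshape(n * 2, s)
    names = [iid for iid in samples for _ in range(2)]
    return HaplotypePanel(gm.sites.copy(), out_haps, names, out_amb)


def build_panel(haps: HaplotypePanel, ped: Pedigree, degree: int = 1
                ) -> HaplotypePanel:
    """Restrict a phased panel to individuals unrelated at ``degree``."""
    keep = select_unrelated(ped, max_degree=degree)
    present = [iid for iid in keep if iid in set(haps.samples)]
    return haps.take_samples(present)


# ---------------------------------------------------------------------------
# panel merging


def merge_panels(a: HaplotypePanel, b: HaplotypePanel, params=None
                 ) -> HaplotypePanel:
    """Union-site merge with reciprocal haploid Li-Stephens fill-in.

    Sites unique to one panel are imputed (posterior-mode allele) on the
    other panel's haplotypes.
    """
    from .lsimpute import LsParams, impute_haplotypes

    params = params or LsParams()
    key_a = {k: i for i, k in enumerate(a.sites.locus_keys())}
    key_b = {k: i for i, k in enumerate(b.sites.locus_keys())}
    for k in set(key_a) & set(key_b):
        ia, ib = key_a[k], key_b[k]
        if (a.sites.ref[ia], a.sites.alt[ia]) != (b.sites.ref[ib], b.sites.alt[ib]):
            raise MergeError(f"conflicting ref/alt at {k}")
    union = sorted(set(key_a) | set(key_b))
    s_u = len(union)

    def union_sites() -> Sites:
        chrom, pos, ref, alt, cm = [], [], [], [], []
        for k in union:
            src, i = (a.sites, key_a[k]) if k in key_a else (b.sites, key_b[k])
            chrom.append(src.chrom[i]); pos.append(src.pos[i])
            ref.append(src.ref[i]); alt.append(src.alt[i]); cm.append(src.cm[i])
        return Sites(np.array(chrom, dtype=object), np.array(pos),
                     np.array(ref, dtype=object), np.array(alt, dtype=object),
                     np.array(cm))

    sites_u = union_sites()
    pos_u = {k: i for i, k in enumerate(union)}

    def expanded(panel: HaplotypePanel, key: dict, other: HaplotypePanel
                 ) -> np.ndarray:
        out = np.zeros((panel.n_haps, s_u), dtype=np.int8)
        own_cols = np.array([pos_u[k] for k in key], dtype=int)
        own_src = np.array(list(key.values()), dtype=int)
        out[:, own_cols] = panel.haps[:, own_src]
        missing_keys = [k for k in union if k not in key]
        if missing_keys:
            filled = impute_haplotypes(panel, other, params)
            miss_cols = np.array([pos_u[k] for k in missing_keys], dtype=int)
            other_idx = {k: i for i, k in enumerate(other.sites.locus_keys())}
            src_cols = np.array([other_idx[k] for k in missing_keys], dtype=int)
            out[:, miss_cols] = filled[:, src_cols]
        return out

    haps_a = expanded(a, key_a, b)
    haps_b = expanded(b, key_b, a)
    return HaplotypePanel(sites_u, np.vstack([haps_a, haps_b]),
                          list(a.samples) + list(b.samples))
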