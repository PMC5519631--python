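"""Haploid Li-Stephens haplotype-copying HMM.

Hidden state: which panel haplotype is copied at each panel site. Switch
probability between adjacent sites at genetic distance d cM is
rho = 1 - exp(-4 * ne * (d/100) / K), spread uniformly over the K panel
haplotypes (stay probability 1 - rho + rho/K). Typed sites emit the target
allele with probability 1-eps on match, eps on mismatch; untyped sites emit
uniformly. Forward-backward uses per-site scaling.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ConfigError, FounderPanelError, HaplotypePanel


@dataclass
class LsParams:
    ne: float = 100.0
    eps: float = 1e-3
    min_typed_sites: int = 2

    def validate(self) -> None:
        if self.ne <= 0:
            raise ConfigError("ne must be positive")
        if not 0.0 < self.eps < 0.5:
            raise ConfigError("eps must be in (0, 0.5)")


@dataclass
class DosageMatrix:
    """Imputed ALT dosages (samples x sites) with per-site quality."""

    samples: list[str]
    sites: "object"  # Sites
    dosage: np.ndarray  # float, in [0, 2]
    quality: np.ndarray  # per-site mean max copy posterior
    typed: np.ndarray  # bool per site


def _switch_probs(cm: np.ndarray, ne: float, k: int) -> np.ndarray:
    d = np.diff(cm) / 100.0  # Morgans
    return 1.0 - np.exp(-4.0 * ne * np.maximum(d, 0.0) / k)


def ls_forward_backward(target: np.ndarray, panel: HaplotypePanel,
                        params: LsParams | None = None) -> np.ndarray:
    """Posterior copy probabilities, shape (n_sites, n_haps).

    ``target`` holds 0/1 at typed sites and -1 at untyped sites, aligned to
    the panel's site grid.
    """
    params = params or LsParams()
    params.validate()
    target = np.asarray(target)
    if target.shape[0] != panel.n_sites:
        raise FounderPanelError("target not aligned to panel sites")
    n_typed = int((target >= 0).sum())
    if n_typed < params.min_typed_sites:
        raise FounderPanelError(
            f"{n_typed} typed sites < min_typed_sites={params.min_typed_sites}")
    post = _fb_batch(target[None, :], panel.haps, panel.sites.cm, params,
                     keep_posteriors=True)
    return post[0]


def _emissions(targets: np.ndarray, haps: np.ndarray, eps: float) -> np.ndarray:
    """(B, S, K) emission weights; 1 at untyped sites."""
    t = targets[:, :, None]  # (B, S, 1)
    h = haps.T[None, :, :]  # (1, S, K)
    match = (t == h)
    em = np.where(match, 1.0 - eps, eps)
    em[np.broadcast_to(t < 0, em.shape)] = 1.0
    return em


def _fb_batch(targets: np.ndarray, haps: np.ndarray, cm: np.ndarray,
              params: LsParams, keep_posteriors: bool = False) -> np.ndarray:
    """Batched scaled forward-backward.

    Returns posteriors (B, S, K) when ``keep_posteriors`` else the per-site
    posterior ALT-allele probability (B, S) with the eps miscopy correction.
    """
    b, s = targets.shape
    k = haps.shape[0]
    rho = _switch_probs(cm, params.ne, k)
    em = _emissions(targets, haps, params.eps)

    fwd = np.empty((b, s, k))
    f = np.full((b, k), 1.0 / k) * em[:, 0, :]
    f /= f.sum(axis=1, keepdims=True)
    fwd[:, 0, :] = f
    for j in range(1, s):
        f = ((1.0 - rho[j - 1]) * f
             + rho[j - 1] / k * f.sum(axis=1, keepdims=True)) * em[:, j, :]
        f /= f.sum(axis=1, keepdims=True)
        fwd[:, j, :] = f

    out_post = np.empty((b, s, k)) if keep_posteriors else None
    out_palt = np.empty((b, s))
    bw = np.ones((b, k))
    alleles = haps.T.astype(float)  # (S, K)
    for j in range(s - 1, -1, -1):
        gamma = fwd[:, j, :] * bw
        gamma /= gamma.sum(axis=1, keepdims=True)
        if keep_posteriors:
            out_post[:, j, :] = gamma
        a = alleles[j][None, :]
        out_palt[:, j] = (gamma * (a * (1.0 - params.eps)
                                   + (1.0 - a) * params.eps)).sum(axis=1)
        if j > 0:
            tmp = bw * em[:, j, :]
            bw = ((1.0 - rho[j - 1]) * tmp
                  + rho[j - 1] / k * tmp.sum(axis=1, keepdims=True))
            bw /= bw.sum(axis=1, keepdims=True)
    return out_post if keep_posteriors else out_palt


def _hap_allele_posteriors(targets: np.ndarray, panel: HaplotypePanel,
                           params: LsParams, chunk: int = 16) -> np.ndarray:
    """(n_targets, n_sites) posterior ALT probability per target haplotype."""
    params.validate()
    out = np.empty(targets.shape)
    for lo in range(0, targets.shape[0], chunk):
        out[lo:lo + chunk] = _fb_batch(targets[lo:lo + chunk], panel.haps,
                                       panel.sites.cm, params)
    return out


def impute_haplotypes(targets: HaplotypePanel, reference: HaplotypePanel,
                      params: LsParams | None = None) -> np.ndarray:
    """Impute each target haplotype at all of ``reference``'s sites.

    Typed evidence is the shared-locus alleles; returns posterior-mode
    alleles (n_target_haps, reference.n_sites). Shared sites keep the
    observed allele.
    """
    params = params or LsParams()
    ref_idx = {key: i for i, key in enumerate(reference.sites.locus_keys())}
    shared_t, shared_r = [], []
    for i, key in enumerate(targets.sites.locus_keys()):
        if key in ref_idx:
            shared_t.append(i)
            shared_r.append(ref_idx[key])
    if len(shared_t) < params.min_typed_sites:
        raise FounderPanelError("too few shared sites between panels")
    typed = np.full((targets.n_haps, reference.n_sites), -1, dtype=np.int8)
    typed[:, np.array(shared_r)] = targets.haps[:, np.array(shared_t)]
    p_alt = _hap_allele_posteriors(typed, reference, params)
    alleles = (p_alt > 0.5).astype(np.int8)
    obs = typed >= 0
    alleles[obs] = typed[obs]
    return alleles


def impute_dosage(hap1: np.ndarray, hap2: np.ndarray, panel: HaplotypePanel,
                  params: LsParams | None = None, sample: str = "sample"
                  ) -> DosageMatrix:
    """Diploid dosages for one phased sample.

    ``hap1``/``hap2`` hold 0/1 at typed sites and -1 at untyped sites on the
    panel's grid. Typed sites pass through the observed dosage.
    """
    params = params or LsParams()
    targets = np.stack([hap1, hap2])
    p_alt = _hap_allele_posteriors(targets, panel, params)
    typed = (targets >= 0).all(axis=0)
    dosage = p_alt.sum(axis=0)
    dosage[typed] = targets[:, typed].sum(axis=0)
    certainty = np.abs(p_alt - 0.5).mean(axis=0) * 2.0
    return DosageMatrix(samples=[sample], sites=panel.sites,
                        dosage=dosage[None, :], quality=certainty,
                        typed=typed)


def impute_samples(targets: HaplotypePanel, panel: HaplotypePanel,
                   params: LsParams | None = None) -> DosageMatrix:
    """Dosages for every (paired-haplotype) sample in ``targets``, whose
    sites must be a subset of the panel's sites."""
    params = params or LsParams()
    panel_idx = {key: i for i, key in enumerate(panel.sites.locus_keys())}
    cols = []
    for key in targets.sites.locus_keys():
        if key not in panel_idx:
            raise FounderPanelError(f"target site {key} absent from panel")
        cols.append(panel_idx[key])
    typed = np.full((targets.n_haps, panel.n_sites), -1, dtype=np.int8)
    typed[:, np.array(cols, dtype=int)] = targets.haps
    p_alt = _hap_allele_posteriors(typed, panel, params)
    dosage = p_alt[0::2] + p_alt[1::2]
    obs = typed >= 0
    obs_pair = obs[0::2] & obs[1::2]
    true_dose = np.clip(typed[0::2], 0, None) + np.clip(typed[1::2], 0, None)
    dosage[obs_pair] = true_dose[obs_pair]
    typed_sites = obs_pair.all(axis=0)
    quality = (np.abs(p_alt - 0.5) * 2.0).mean(axis=0)
    names = targets.samples[0::2]
    return DosageMatrix(samples=list(names), sites=panel.sites,
                        dosage=dosage, quality=quality, typed=typed_sites)
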