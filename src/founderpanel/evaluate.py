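"""Masking/evaluation harness: hold out test individuals, mask to array
sites, impute under several panel configurations, and score aggregate r^2 by
reference-population MAF bin, with panel-sharing accounting."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import FounderPanelError, GenotypeMatrix, HaplotypePanel, Sites
from .lsimpute import LsParams, impute_samples

#: Right-closed upper bin edges, log-dense at rare frequencies.
DEFAULT_MAF_BINS = (0.0005, 0.001, 0.002, 0.005, 0.01, 0.02, 0.03,
                    0.05, 0.1, 0.15, 0.2, 0.3, 0.4, 0.5)


@dataclass
class EvalConfig:
    n_test: int = 10
    maf_bins: tuple = DEFAULT_MAF_BINS
    bin_source: str = "reference"

    def validate(self) -> None:
        if self.n_test < 1:
            raise FounderPanelError("n_test must be >= 1")
        edges = np.asarray(self.maf_bins, dtype=float)
        if edges.size == 0 or not np.all(np.diff(edges) > 0) or edges[-1] > 0.5:
            raise FounderPanelError("maf_bins must increase and cover (0, 0.5]")


@dataclass
class EvalReport:
    """Per bin x config aggregate r^2 plus variant-sharing accounting."""

    r2: pd.DataFrame = field(default_factory=pd.DataFrame)
    sharing: pd.DataFrame = field(default_factory=pd.DataFrame)
    specific_r2: float = float("nan")
    n_scored: int = 0

    def to_json(self) -> str:
        import json
        return json.dumps({
            "r2": self.r2.to_dict(orient="records"),
            "sharing": self.sharing.to_dict(orient="records"),
            "specific_r2": None if np.isnan(self.specific_r2)
            else self.specific_r2,
            "n_scored": self.n_scored,
        }, indent=2, sort_keys=True)

    def to_tsv(self) -> str:
        return self.r2.to_csv(sep="\t", index=False)


def assign_bins(maf: np.ndarray, edges) -> np.ndarray:
    """Bin index per site; right-closed upper edges, MAF 0 (absent from the
    bin-source population) goes to the lowest bin."""
    edges = np.asarray(edges, dtype=float)
    maf = np.nan_to_num(np.asarray(maf, dtype=float))
    return np.searchsorted(edges, maf, side="left").clip(0, edges.size - 1)


def mask_to_array(test: GenotypeMatrix, manifest: Sites
                  ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Split a test matrix into manifest-typed sites and masked truth
    dosages. The typed and masked site sets partition the input."""
    man = set(manifest.locus_keys())
    if not man:
        raise FounderPanelError("empty manifest")
    keys = test.sites.locus_keys()
    typed_idx = np.array([i for i, k in enumerate(keys) if k in man], dtype=int)
    if typed_idx.size == 0:
        raise FounderPanelError("manifest is disjoint from the test sites")
    masked_idx = np.setdiff1d(np.arange(len(keys)), typed_idx)
    typed = test.take_sites(typed_idx)
    truth = test.take_sites(masked_idx)
    truth_df = pd.DataFrame(truth.dosage(), index=test.samples,
                            columns=[f"{c}:{p}" for c, p in
                                     truth.sites.locus_keys()])
    return typed, truth_df


def mask_panel(test: HaplotypePanel, manifest: Sites
               ) -> tuple[HaplotypePanel, HaplotypePanel]:
    """Panel counterpart of :func:`mask_to_array` for phased targets."""
    man = set(manifest.locus_keys())
    if not man:
        raise FounderPanelError("empty manifest")
    keys = test.sites.locus_keys()
    typed_idx = np.array([i for i, k in enumerate(keys) if k in man], dtype=int)
    if typed_idx.size == 0:
        raise FounderPanelError("manifest is disjoint from the test sites")
    masked_idx = np.setdiff1d(np.arange(len(keys)), typed_idx)
    return test.take_sites(typed_idx), test.take_sites(masked_idx)


def aggregate_r2(imputed: np.ndarray, truth: np.ndarray, bins,
                 bin_maf: np.ndarray) -> pd.DataFrame:
    """Pooled-genotype aggregate r^2 per MAF bin.

    All (imputed, true) dosage pairs in a bin are pooled into two vectors;
    r^2 is their squared Pearson correlation. Zero-variance bins are
    reported as NaN (undefined), not 0.
    """
    imputed = np.asarray(imputed, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if imputed.shape != truth.shape:
        raise FounderPanelError("imputed/truth shape mismatch")
    edges = np.asarray(bins, dtype=float)
    which = assign_bins(bin_maf, edges)
    rows = []
    for b in range(edges.size):
        sel = which == b
        n_var = int(sel.sum())
        x, y = imputed[:, sel].ravel(), truth[:, sel].ravel()
        ok = ~(np.isnan(x) | np.isnan(y))
        x, y = x[ok], y[ok]
        if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
            r2 = float("nan")
        else:
            r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
        rows.append({"bin": b, "bin_upper": float(edges[b]),
                     "n_variants": n_var, "r2": r2})
    return pd.DataFrame(rows)


def pooled_r2(imputed: np.ndarray, truth: np.ndarray) -> float:
    x, y = np.asarray(imputed, float).ravel(), np.asarray(truth, float).ravel()
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def compare_configs(test: HaplotypePanel, panels: dict[str, HaplotypePanel],
                    manifest: Sites, config: EvalConfig | None = None,
                    params: LsParams | None = None,
                    bin_maf_panel: str | None = None,
                    cohort_maf: np.ndarray | None = None) -> EvalReport:
    """Impute masked test genotypes under every panel configuration and
    score aggregate r^2 per MAF bin.

    Only variants present in all panels are scored. Bin MAF comes from
    ``bin_maf_panel`` (default: the panel named "reference" if present,
    else the first panel).
    """
    config = config or EvalConfig()
    config.validate()
    params = params or LsParams()
    if not panels:
        raise FounderPanelError("no panel configurations supplied")
    typed, masked = mask_panel(test, manifest)

    masked_keys = masked.sites.locus_keys()
    in_all = set(masked_keys)
    for p in panels.values():
        in_all &= set(p.sites.locus_keys())
    scored_idx = np.array([i for i, k in enumerate(masked_keys) if k in in_all],
                          dtype=int)
    scored = masked.take_sites(scored_idx)
    truth_dose = (scored.haps[0::2] + scored.haps[1::2]).astype(float)

    if bin_maf_panel is None:
        bin_maf_panel = "reference" if "reference" in panels else next(iter(panels))
    src = panels[bin_maf_panel]
    src_freq = dict(zip(src.sites.locus_keys(), src.alt_freq()))
    f = np.array([src_freq.get(k, 0.0) for k in scored.sites.locus_keys()])
    bin_maf = np.minimum(f, 1.0 - f)

    frames = []
    dosages: dict[str, np.ndarray] = {}
    for name, panel in panels.items():
        pk = set(panel.sites.locus_keys())
        typed_p = typed.take_sites([i for i, k in
                                    enumerate(typed.sites.locus_keys())
                                    if k in pk])
        dm = impute_samples(typed_p, panel, params)
        col = {k: i for i, k in enumerate(panel.sites.locus_keys())}
        cols = np.array([col[k] for k in scored.sites.locus_keys()], dtype=int)
        imput = dm.dosage[:, cols]
        dosages[name] = imput
        df = aggregate_r2(imput, truth_dose, config.maf_bins, bin_maf)
        df.insert(0, "config", name)
        frames.append(df)
    report = EvalReport(r2=pd.concat(frames, ignore_index=True),
                        n_scored=len(scored_idx))
    report._dosages = dosages  # diagnostics for specific-variant scoring
    report._truth = truth_dose
    report._scored_sites = scored.sites
    report._bin_maf = bin_maf
    return report


def specific_variant_report(cohort_sites: Sites, cohort_maf: np.ndarray,
                            reference_panels: dict[str, HaplotypePanel],
                            bins=DEFAULT_MAF_BINS,
                            eval_report: EvalReport | None = None,
                            merged_name: str = "merged") -> pd.DataFrame:
    """Per cohort-MAF bin: proportion of cohort variants present in each
    reference panel and in none; optional aggregate r^2 of the none-category
    variants under the merged panel (stored on the report)."""
    edges = np.asarray(bins, dtype=float)
    which = assign_bins(cohort_maf, edges)
    keys = cohort_sites.locus_keys()
    panel_keys = {name: set(p.sites.locus_keys())
                  for name, p in reference_panels.items()}
    rows = []
    for b in range(edges.size):
        sel = [i for i in range(len(keys)) if which[i] == b]
        n = len(sel)
        row = {"bin": b, "bin_upper": float(edges[b]), "n_variants": n}
        none = 0
        for i in sel:
            if not any(keys[i] in pk for pk in panel_keys.values()):
                none += 1
        for name, pk in panel_keys.items():
            row[f"in_{name}"] = (sum(keys[i] in pk for i in sel) / n
                                 if n else float("nan"))
        row["specific"] = none / n if n else float("nan")
        rows.append(row)
    out = pd.DataFrame(rows)
    if eval_report is not None and merged_name in getattr(
            eval_report, "_dosages", {}):
        scored_keys = eval_report._scored_sites.locus_keys()
        spec = np.array([not any(k in pk for pk in panel_keys.values())
                         for k in scored_keys])
        if spec.any():
            eval_report.specific_r2 = pooled_r2(
                eval_report._dosages[merged_name][:, spec],
                eval_report._truth[:, spec])
        eval_report.sharing = out
    return out
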