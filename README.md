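# founderpanel

Build and evaluate population-specific haplotype reference panels for
founder populations, end to end and fully offline:

- **simpop** — forward Wright–Fisher simulation of an outbred ancestral
  population, a bottlenecked founder cohort expanded through a known
  multi-generation pedigree (gene dropping with founder-segment truth
  tracks), genotype-level noise injection, array-site manifests, and
  synthetic per-variant deleteriousness scores.
- **vcfqc** — the QC cascade: record normalization (multi-allelic and
  non-autosomal removal, indel trimming), genotype filters (GQ < 20,
  DP < 8, het allele balance outside [0.25, 0.75], half-calls), Mendelian
  masking, exact Hardy–Weinberg test, site filters (missingness > 25%,
  Mendel rate > 10%, HWE p < 1e-6, monomorphic), duplicate-sample
  concordance, and array-vs-WGS sensitivity by MAF.
- **panelbuild** — exact pedigree kinship, greedy unrelated-subset
  selection, transmission-based phasing with windowed haplotype-context
  fill, panel assembly from unrelated individuals, and union-site panel
  merging with reciprocal Li–Stephens fill-in.
- **lsimpute** — a haploid Li–Stephens haplotype-copying HMM
  (forward–backward with per-site scaling) for dosage imputation.
- **evaluate** — the masking harness: hold out test individuals, mask to
  array sites, impute under several panel configurations, and score pooled
  aggregate r² per reference-MAF bin, with panel-sharing accounting.
- **popgen** — BLUE allele frequencies on arbitrary pedigrees,
  rare-variant depletion resampling, drift-enrichment tables, IBD/HBD
  segment detection (truth-label and haplotype-identity modes) and sharing
  summaries, and frequency-binned deleteriousness comparisons
  (Wilcoxon rank-sum).
- **io_cli** — minimal, byte-stable readers/writers (VCF 4.2 with
  GT:GQ:DP:AD, phased panel VCF, PLINK PED, genetic map, manifests,
  BED-like segments, JSON/TSV reports), the pipeline driver, and the CLI.

## CLI

```sh
founderpanel pipeline --seed 1 --out out/          # full demo pipeline
founderpanel simulate --seed 1 --out out/          # simulation artifacts only
founderpanel qc --vcf in.vcf --ped in.ped --out qc/
founderpanel build-panel --vcf qc/qc.vcf --ped in.ped --out panel.vcf
founderpanel merge-panels --panel-a a.vcf --panel-b b.vcf --out merged.vcf
founderpanel impute --target typed.vcf --panel panel.vcf --out dosages.vcf
founderpanel evaluate --seed 1 --out out/
founderpanel popgen --task freq --seed 1 --out out/
```

`pipeline` accepts a YAML config (`--config`) mirroring
`founderpanel.io_cli.PipelineConfig`; all outputs carry a provenance header
(version, seed, config hash) and are byte-identical across reruns with the
same seed.

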