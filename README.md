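# poolsel

Analysis toolkit for evolve-and-resequence (E&R) pool-seq experiments with an
ancestor plus multi-regime, multi-replicate time series of allele counts:

- **counts_io** — allele-count containers; readers for a flat counts TSV and
  VCF with per-sample allelic depths (AD); repeat-mask, coverage-tail
  (nearest-rank 5% quantiles) and sample-presence filters.
- **diversity** — minor allele frequency, depth-corrected per-site
  heterozygosity `pi = C/(C-1) * 2p(1-p)`, Watterson's theta in kb windows,
  arm/center Kolmogorov–Smirnov and per-chromosome Welch comparisons.
- **temporal_ne** — temporal F-statistic Ne estimation with Plan II sampling
  corrections: read-depth only (`waples_planII`) or the two-stage pool-seq
  correction combining read depth and pool size (`jonas_planII`); regime
  ANOVA, autosome-vs-X Welch test, and the breeding-male bound from
  `Ne = 4 Nm Nf / (Nm + Nf)`.
- **afc_scan** — per-SNP binomial-logit GLM scans fit by an IRLS engine
  (vectorized across SNPs): Model 1 (ancestor vs each regime at the final
  generation, planned Wald contrasts) and Model 2 (per-regime regression of
  alt counts on generation), with genome-wide Bonferroni control and
  Haldane–Anscombe handling of fixed cells.
- **peaks** — significance-peak calling (≥3, or conservatively ≥5,
  significant SNPs within any 1 kb span; overlapping qualifying sets merged),
  within-gene merging, genic/pseudogenic/intergenic/mixed classification
  against GFF3, cross-regime overlap tables, width summaries, and arm/center
  enrichment.
- **fertility** — competitive-fertility statistics: Yates-corrected
  one-sample proportion tests with continuity-corrected Wilson intervals
  (matching R `prop.test` exactly), pooled counts, post-insemination
  contribution fraction, fold changes, and quasi-binomial GLM planned
  contrasts.
- **simdata** — Wright–Fisher forward simulator for the full experimental
  design (arm-biased SNP density, low-skewed MAF spectrum, regime-specific
  selection, two-stage pool-seq read counts, beta-binomial fertility assays)
  with ground truth for recovery and calibration tests.
- **pipeline / cli** — end-to-end orchestration with a JSON manifest and a
  `poolsel` command-line interface.

## CLI

```sh
poolsel simulate --outdir sim --seed 1 --n-sites 1000
poolsel filter --counts sim/counts.tsv --meta sim/meta.tsv --mask sim/repeats.bed --out filtered.tsv
poolsel diversity --counts filtered.tsv --meta sim/meta.tsv --domains sim/domains.tsv
poolsel ne --counts filtered.tsv --meta sim/meta.tsv --pool-size 2500 --method jonas --out ne.tsv
poolsel scan --counts filtered.tsv --meta sim/meta.tsv --model 2 --regime BS-PO --out scan.tsv
poolsel peaks --scan-results scan.tsv --gff sim/genes.gff3 --min-snps 3 --out peaks.tsv
poolsel fertility --assays sim/assays.tsv --condition post --contrast ancestor
poolsel run --outdir full_run --seed 1        # whole pipeline + manifest
```

The counts TSV dialect is `chrom pos ref alt <sample>:ref <sample>:alt ...`,
one row per diallelic SNP, 1-based positions. Sample metadata is a TSV with
columns `sample_id regime replicate generation`, where regime is one of
`ANC, WS-P&P, WS-PO, BS-P&P, BS-PO`.

## Design notes

- All randomness is driven by a single seed through `numpy.random.SeedSequence`
  spawning; simulation outputs are byte-reproducible.
- Filters log every drop with a reason and conserve record counts
  (input = retained + dropped), which the pipeline manifest audits.
- The test suite checks the IRLS engine against closed-form saturated
  solutions and an independent statsmodels oracle, the peak caller against a
  brute-force enumeration oracle, the Ne estimators against analytic
  inversion and parameter-recovery simulations, and the proportion test
  against frozen R `prop.test` values.
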