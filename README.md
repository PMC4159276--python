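# exomeimpute

Can the content of an exome genotyping array be recovered by statistical
imputation from ordinary GWAS-array data?  Exome chips were designed from
large sequencing studies of a handful of populations; for any *other*
population, much of their content is monomorphic, and the polymorphic
remainder may already be recoverable by imputing GWAS-array genotypes
against a reference panel — especially when a small population-specific
sequencing panel supplements the cosmopolitan one.

`exomeimpute` is a self-contained pipeline that reproduces this evaluation
on synthetic haplotype data: a seeded founder-mosaic simulator builds
multi-population panels, ascertainment-biased chip content and GWAS arrays;
the pipeline then runs array QC, rebuilds legacy array content via
hierarchical LD surrogates (r² = 1 per panel, then pooled r² ≥ 0.80 within
1 Mb), imputes with a Li–Stephens haplotype-copying HMM
(switch probability ρ = 1 − exp(−4·Ne·d/(100·k)), Ne = 15,000; genotype
calls thresholded at posterior ≥ 0.90), and scores the result with the
field's standard metrics:

* **info** — IMPUTE-style ratio-of-variances certainty,
  `1 − Σ(f_i − e_i²) / (2N·θ̂(1−θ̂))`, clipped to [0, 1];
* **call rate** — samples with a posterior ≥ 0.90 call; a SNP is
  **well-imputed** when info ≥ 0.3 and call rate ≥ 0.95;
* **overall and minor-allele concordance** against the simulated truth,
  binned by MAF (rare ≤ 0.01 < low-frequency < 0.05 ≤ common);
* chip coverage and exonic-recoverability accounting tables.

It is aimed at people studying imputation strategy and array design:
the full evaluation loop is importable as a library, scriptable from a CLI,
and reproducible bit-for-bit from a single seed.

## Worked example

```python
from exomeimpute import ScenarioConfig, SimulationConfig, run_scenario_detailed, compare_panel_configs

result = run_scenario_detailed(ScenarioConfig(simulation=SimulationConfig(seed=1)))
w = result.report.well_imputed_by_panel
print(w[(w.array == "dense") & (w.panel_config == "cosmopolitan")]
        [["maf_bin", "n_snps", "pct_well_imputed"]].to_string(index=False))
```

prints

```
      maf_bin  n_snps  pct_well_imputed
         rare      37         51.351351
low_frequency      10         80.000000
       common      27         92.592593
```

i.e. on this seed, 93% of the common-frequency exome-chip SNPs that are
absent from the GWAS array are confidently imputable from the cosmopolitan
panel alone, but only half of the rare ones — the motivating pattern: the
rarer the variant class the chip exists for, the less of it imputation
recovers, while the easy common class barely needs a chip at all.  The
two-panel comparison on the same run,

```python
print(compare_panel_configs(result.report, "cosmopolitan", "cosmopolitan+specific"))
```

shows what merging the 30-donor population-specific panel buys: the
rare-bin well-imputed percentage rises from 51.4 to 59.0, the
low-frequency bin from 80 to 90, and the pooled minor-allele discordance
falls from 22.5% to 21.3% (per-bin deltas are noisier, with denominators
of a few dozen genotypes on a single seed).

The same run is available from a shell:

```bash
exomeimpute run --seed 1 --out results/
exomeimpute make-fixtures --size tiny --seed 0 --out fixtures/
```

`run` writes the five report tables (`coverage_by_maf.tsv`,
`well_imputed_by_panel.tsv`, `discordance_overall.tsv`,
`discordance_minor_allele.tsv`, `recoverable_content.tsv`) plus the
surrogate-decision log and the panel-configuration deltas.  The individual
stages are also exposed as verbs over standard files — `simulate` (phased
VCF panels), `qc` (cleaned VCFs + removal tables), `rebuild-array`
(surrogate decisions from manifests and phased panels), `impute` (a GP
VCF from phased targets, a reference panel and an IMPUTE-style genetic
map) and `evaluate` (concordance tables from an imputed and an observed
VCF) — so partial pipelines can be scripted.

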