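# Methods

`exomeimpute` asks, on fully synthetic data, the question that motivated the
exome genotyping arrays: if a cohort already has GWAS-array genotypes, how
much of an exome chip's content can statistical imputation recover, and how
much does a small population-specific sequencing panel add?  The package
implements the whole evaluation loop — array QC, LD-surrogate array
reconstruction, Li–Stephens reference-panel imputation, and the standard
quality/coverage metrics — together with a seeded generator that produces
study conditions with the right qualitative structure.

## The synthetic world

### Founder-mosaic model

A full coalescent simulation is unnecessary for this evaluation: what the
analysis needs is (i) long haplotypes shared between target samples and
reference panels, so imputation has something to copy, and (ii) genuinely
population-private rare variation, so array ascertainment bias exists.  The
generator produces both from a founder-mosaic model:

* **Founders.** `n_founders` (default 120) haplotypes over `n_sites`
  (default 2,000) biallelic SNPs on a 2 Mb chromosome (~1 SNP/kb; a uniform
  1 cM/Mb map).  Per-site derived-allele frequencies follow a spectrum
  `∝ f^(-site_freq_alpha)` truncated to `[1/(2·n_founders), 0.5]`
  (default α = 1.3, rare-skewed).
* **Zipf founder usage.** Mosaic segments copy founder *i* with probability
  `∝ (i+1)^(-founder_weight_zipf)` (default 1.2).  Carrier identity is
  weight-biased as well: founder *i* carries a site of frequency *f* with
  probability `min(1, f·n·w_i)`, which preserves the marginal frequency
  spectrum while placing common alleles on heavily-copied (old) lineages and
  rare alleles on the thin tail.  This coupling is what makes rare variants
  *intrinsically* harder to impute: their carrier lineages are sparsely
  represented in any finite reference panel, exactly as in real panels.
* **Population structure.** The top `founder_sharing` fraction (default
  0.7) of founders is shared by all populations.  The remaining tail rows
  are dealt round-robin to the populations as exclusive lineages; each
  exclusive founder is a diverged copy (flip rate `exclusive_divergence`,
  default 0.02) of a random shared tail founder, and drift amplifies the
  exclusive lineages to a fixed `exclusive_weight_share` (default 0.07) of
  their own population's copying.  Population-private variation therefore
  (a) is rare-to-low-frequency, (b) co-segregates with lineages the other
  populations can partly observe — which is why it can appear on an
  ascertained chip — and (c) is recoverable from a population-specific
  panel, because donors carry the same exclusive lineages.
* **Mosaics and mutations.** Each sampled haplotype places crossover
  breakpoints as a Poisson process (`crossover_rate_per_cM`, default 0.75)
  and copies weighted founders between them.  Private point mutations
  (rate `private_mutation_rate` per site per haplotype, default 0.002) fall
  on population-reserved site pools (sites dealt round-robin), plus a small
  hypermutable class (`recurrent_site_fraction`, default 0.05) open to all
  populations — real point mutations essentially never recur across
  populations, and the reservation keeps "population-private" unambiguous
  in the truth.

### Arrays, panels and noise

* **Dense GWAS array** (Omni-like): the 600 sites with pooled MAF ≥ 0.05
  most evenly spaced along the chromosome.
* **Legacy arrays**: a 300-SNP manifest drawn from the common sites is
  rebuilt from the dense array by the hierarchical LD-surrogate search
  (below), mimicking how older array content is emulated from a denser
  product.
* **Exome-style chip**: 250 sites ascertained in *deep design cohorts*
  (250 simulated samples from each non-target population — ascertainment in
  real chips used cohorts far deeper than any imputation panel), with 80%
  drawn from the rare stratum (pooled derived-allele frequency ≤ 0.01,
  rarest first) and the rest from common content.  The target population is
  deliberately ignored: the resulting depletion of target-population
  polymorphism is the ascertainment bias under study.
* **Reference panels**: the two cosmopolitan populations (2 × 100 samples)
  form the cosmopolitan panel; 30 sequenced donors from the target
  population form the population-specific panel (60 haplotypes).  Both are
  perturbed with iid allele noise (`panel_noise_rate = 0.003`) emulating the
  genotype/phasing error of low-coverage sequencing panels; targets and
  truth stay error-free.  Imputation targets are the remaining 70 target
  samples — donors are structurally excluded (the over-fitting guard).
* **Genotyping**: observed calls add genotyping error (0.001, replacement
  with either wrong genotype) and missingness (0.005).

### What the generator does not model

No demographic realism (growth, migration), no indels/CNVs, no sex
chromosomes, no sequencing-read level errors, no strand issues, and no
linkage disequilibrium *within* founders — LD exists only through founder
identity along mosaic segments.  Frequencies are quantized by founder
weights (≳0.1%), so the ultra-rare (<10⁻³) end of a real exome chip is
represented only qualitatively, by the rarest representable classes.
Passing tests therefore show that the pipeline reproduces the *direction*
and rough magnitude of the published patterns under a faithful synthetic
geometry, not that it reproduces any real cohort's percentages.

## Quality control

Three steps, mirroring standard array QC, with removals attributed to the
first triggering rule:

* **A — SNP pseudo-clean (all samples jointly):** duplicate/unknown
  coordinates, disallowed chromosome, unknown strand (metadata checks),
  conflicting allele designation between arrays, cross-array genotype
  concordance < 99.5% (boundary kept), missingness > 5%, Hardy–Weinberg
  exact-test p < 10⁻⁸.
* **B — samples:** missingness > 2%; excessive identity-by-state (IBS
  computed over MAF ≥ 5% SNPs; in each offending pair the lower-call-rate
  member is dropped; default threshold 0.9); PCA outliers (0/1/2 encoding
  with missing = −1, column-centred covariance, top 2 components, flagged
  beyond 6 SD from the sample's own population mean — the outlier rule is
  not quantified in standard descriptions, so both knobs are explicit
  parameters).
* **C — SNPs per population:** missingness > 5% or HWE p < 10⁻³ in any
  population.

The HWE test is the exact conditional test (enumeration of heterozygote
counts on the allele-count margin), chosen for validity at rare-variant
frequencies; it is verified against a full-enumeration oracle for all
margins with total ≤ 200.

## LD-surrogate array reconstruction

For each manifest SNP absent from the dense array, candidates are dense
SNPs within 1 Mb.  Rules are walked strictly in order: (i) r² = 1 in both
LD panels, (ii) r² = 1 in panel 1 only, (iii) r² = 1 in panel 2 only,
(iv) highest pooled-haplotype r², accepted if ≥ 0.80.  "Perfect" tolerates
1e−9 of float slack.  Ties break by distance, then position, so results
are independent of candidate order.  Sites monomorphic in a panel are
ineligible under that panel's rules but may qualify under the other's.  A
dense SNP may serve several targets.

## Imputation engine

A Li–Stephens haplotype-copying HMM stands in for production imputation
software (it is a stand-in, not a re-implementation: no byte-level
equivalence with any external tool is claimed or tested).

* Hidden state: which of the k reference haplotypes is being copied.
  Between adjacent typed sites at genetic distance d cM the chain switches
  with `ρ = 1 − exp(−4·Ne·d/(100·k))`, landing uniformly; emission matches
  the copied allele with probability 1 − θ (θ default 10⁻³, constant per
  site).  Ne defaults to 15,000.
* Posteriors come from scaled forward–backward over the typed sites.  At
  untyped sites the copying posterior is interpolated linearly in genetic
  distance between the flanking typed sites (no transitions charged within
  the gap — the standard read-off shortcut, and a documented divergence
  from an all-sites HMM), and the allele-1 probability is the
  posterior-weighted mean of reference alleles.  With θ = 0 a dead-ended
  chain (no consistent path) falls back to a flat state distribution.
* Genotype posteriors combine a sample's two haplotype runs under
  independence — P(0) = (1−p₁)(1−p₂), P(1) = p₁(1−p₂)+(1−p₁)p₂,
  P(2) = p₁p₂ — and are renormalized against float drift.  Targets enter
  pre-phased (the synthetic truth is phased), so no phasing step exists.
* Work proceeds in 5 Mb core blocks with 5 Mb buffers (clipped); only
  core results are kept.  On the default 2 Mb region this is one chunk;
  chunk-consistency is tested explicitly with sub-megabase cores.
* Discrete calls take the argmax class when its posterior is ≥ 0.90
  (boundary inclusive), else missing.
* Panel merging over the site union cross-imputes each panel's haplotypes
  at the sites it lacks, against the other panel, taking the modal allele
  (ties → allele 0); one deterministic pass each way.

The forward–backward recursion is verified against exhaustive
path-enumeration for k ≤ 4 and ≤ 6 sites.

## Metrics

* **info**: IMPUTE-style ratio-of-variances measure.  With per-sample
  dosage `e_i` and second moment `f_i`, and `θ̂ = Σe_i/2N`:
  `info = 1 − Σ(f_i − e_i²)/(2N·θ̂(1−θ̂))`, clipped to [0, 1], and 1 by
  convention when θ̂ ∈ {0, 1}.  The formula is stated here because the
  metric's name alone does not pin it down.
* **call rate**: fraction of samples with a non-missing thresholded call.
* **well-imputed**: info ≥ 0.3 AND call rate ≥ 0.95, both inclusive.
* **MAF bins**: monomorphic (0), rare (0 < MAF ≤ 0.01),
  low-frequency (0.01 < MAF < 0.05), common (≥ 0.05).  Method descriptions
  and figure captions of the source literature disagree on whether 0.05 is
  common or low-frequency; the package uses common ⇔ MAF ≥ 0.05.  Bins are
  computed from the target samples' genotypes.
* **overall concordance**: matching calls / jointly non-missing calls,
  restricted to well-imputed evaluation SNPs.  Missing calls are excluded
  from the denominator because missingness is already measured by call
  rate.
* **minor-allele concordance**: denominator = observed genotypes carrying
  ≥ 1 minor allele with a non-missing imputed call, across well-imputed
  rare and low-frequency SNPs; this is the metric that exposes the
  miscall-everything-as-major failure mode that overall concordance hides.
  The pooled (rare + low-frequency) figure is the primary statistic; the
  per-bin split is also reported but its denominators are small at this
  simulation scale.
* **Coverage accounting**: chip SNPs per target-MAF bin × whether the site
  is present in at least one reference panel.
* **Recoverable exonic content**: "exonic" is a generator-assigned flag on
  30% of sites.  Per frequency group (rare+low pooled vs common), counts
  of exonic target-polymorphic sites on the study array, on the chip, and
  well-imputed among sites *not* on the study array (array-overlap sites
  are excluded from the imputed counts).

Evaluation sites are chip SNPs absent from the dense array, present in the
reference panel being scored, and surviving chip QC; all study arrays share
this one grid so per-array comparisons have a common denominator.

## Numerical and procedural choices

* Coordinates are 1-based inclusive everywhere; missing genotypes use a
  dedicated −1 sentinel that never enters arithmetic.
* Biallelic SNPs only; other VCF records are skipped and counted.
* Alleles are taken as written; no strand flipping (cross-array allele
  conflicts are a QC removal, not a reconciliation).
* All randomness flows from a single seed through named per-stage
  substreams, so changing one stage's draws does not perturb others and
  end-to-end runs are byte-deterministic.
* Per-run problem size (2,000 sites, 100 + 100 reference samples, 70
  imputation targets, two arrays × two panel configurations) keeps a full
  scenario around 25 s on one CPU; directional claims are checked over
  five seeds.

## Known limitations

* The engine's θ and the interpolation read-off are simplifications of
  production imputation software; accuracy comparisons against such
  software are out of scope.
* Unphased-target imputation is not implemented (targets are simulated
  phased).
* The IBS screen can remove cryptically related target samples under
  strongly skewed founder usage; the default target-population size leaves
  enough survivors that the rare MAF bin (singletons) stays populated.
* Concordance denominators at rare bins are tens of genotypes at this
  scale; per-seed rare-bin percentages are noisy, which is why directional
  claims aggregate over seeds and use the pooled minor-allele statistic.
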