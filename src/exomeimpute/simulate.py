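"""Seeded founder-mosaic simulator for haplotype panels and array designs.

The generator emulates the data constellation the evaluation needs without a
full coalescent model.  A pool of founder haplotypes carries a rare-skewed
allele frequency spectrum; founder *usage* is Zipf-weighted, and carrier
identity is weight-biased, so common alleles ride heavily-copied old
lineages while rare alleles ride the thinly-copied tail — which is what
couples allele frequency to imputability.  A configurable fraction of
founders is shared across populations; the rest are population-exclusive
lineages, each a slightly diverged copy of a shared tail founder whose
within-population copying share is amplified by drift.  Per-haplotype
private mutations fall on population-reserved site pools (plus a small
hypermutable class open to all), so point mutations essentially never recur
across populations.  Together these give the analysis its two key
structures: long shared haplotypes (reference-panel imputation works) and
population-private rare variation (array content ascertained in other
populations is depleted of target-population polymorphism).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    MISSING,
    ArrayDesign,
    FormatError,
    GenotypeMatrix,
    HaplotypePanel,
    VariantRecord,
)

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Knobs of the founder-mosaic generator.

    Defaults define the package's standard study conditions: a 2 Mb region
    with 2,000 SNPs (~1 SNP/kb at 1 cM/Mb, typed-marker spacing comparable
    to a GWAS array), 120 founder haplotypes of which 70% are shared across
    populations, two cosmopolitan populations of 100 samples that play the
    reference/design role, and a 100-sample target population of which 30
    donate a small population-specific panel (60 haplotypes) while the rest
    are imputation targets.
    """

    seed: int = 0
    chrom_length_bp: int = 2_000_000
    n_sites: int = 2000
    n_founders: int = 120
    founder_sharing: float = 0.7
    pop_sizes: dict = field(default_factory=lambda: {"popA": 100, "popB": 100, "popC": 100})
    crossover_rate_per_cM: float = 0.75
    private_mutation_rate: float = 0.002
    recurrent_site_fraction: float = 0.05
    site_freq_alpha: float = 1.3
    founder_weight_zipf: float = 1.2
    exclusive_divergence: float = 0.02
    exclusive_weight_share: float = 0.07
    genotyping_error: float = 0.001
    missing_rate: float = 0.005
    exonic_fraction: float = 0.3
    chrom: str = "1"

    def __post_init__(self) -> None:
        for name in (
            "founder_sharing",
            "crossover_rate_per_cM",
            "private_mutation_rate",
            "recurrent_site_fraction",
            "exclusive_divergence",
            "exclusive_weight_share",
            "genotyping_error",
            "missing_rate",
            "exonic_fraction",
        ):
            v = getattr(self, name)
            if name != "crossover_rate_per_cM" and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.n_sites < 2:
            raise ValueError("n_sites must be >= 2")
        if self.n_founders < 2 or self.n_founders % 2:
            raise ValueError("n_founders must be even and >= 2 (two haplotypes per donor)")
        if any(n <= 0 for n in self.pop_sizes.values()):
            raise ValueError("pop_sizes must be positive")

    def rng(self, stage: str) -> np.random.Generator:
        """Per-stage substream derived from the root seed.

        Changing one stage's draws does not perturb any other stage.
        """
        key = int.from_bytes(stage.encode(), "little") % (2**31)
        return np.random.default_rng(np.random.SeedSequence((self.seed, key)))


@dataclass
class TruthSet:
    """Error-free target genotypes at all panel sites, with provenance flags."""

    true_genotypes: GenotypeMatrix
    population_labels: list[str]
    private_site_flags: dict  # vid -> set of populations carrying the derived allele exclusively
    exonic_flags: dict  # vid -> bool

    def __post_init__(self) -> None:
        if np.any(self.true_genotypes.genotypes == MISSING):
            raise FormatError("truth genotypes must not contain MISSING")


def _sample_site_frequencies(rng, n_sites: int, alpha: float, fmin: float) -> np.ndarray:
    """Inverse-CDF draws from a density proportional to f^(-alpha) on [fmin, 0.5]."""
    u = rng.random(n_sites)
    a, b = fmin, 0.5
    if abs(alpha - 1.0) < 1e-12:
        return a * (b / a) ** u
    e = 1.0 - alpha
    return (a**e + u * (b**e - a**e)) ** (1.0 / e)


def simulate_founders(config: SimulationConfig) -> HaplotypePanel:
    """Draw the founder haplotype pool.

    Per-site derived-allele probabilities follow a spectrum proportional to
    ``f^(-site_freq_alpha)`` truncated to ``[1/(2 n_founders), 0.5]``; site
    positions are uniform over the chromosome, sorted and deduplicated.
    """
    rng = config.rng("founders")
    positions = np.sort(rng.choice(config.chrom_length_bp, size=config.n_sites, replace=False) + 1)
    fmin = 1.0 / (2.0 * config.n_founders)
    freqs = _sample_site_frequencies(rng, len(positions), config.site_freq_alpha, fmin)
    # carrier identity is weight-biased: founder i carries a site with
    # probability proportional to its copying weight, which keeps the
    # marginal founder MAF spectrum at f while placing common alleles on
    # heavily-copied (old) lineages and rare alleles on the tail
    w = founder_weights(config, config.n_founders)
    carry_p = np.clip(freqs[None, :] * (config.n_founders * w)[:, None], 0.0, 1.0)
    haps = (rng.random((config.n_founders, len(positions))) < carry_p).astype(np.int8)
    # population-exclusive founders descend from shared tail lineages: each
    # is a diverged copy of a low-weight shared founder, so population-
    # private variation co-segregates with lineages the other populations
    # can at least partly observe
    n_shared = int(round(config.founder_sharing * config.n_founders))
    if 0 < n_shared < config.n_founders:
        tail_lo = max(n_shared // 2, 1)
        for e in range(n_shared, config.n_founders):
            donor = int(rng.integers(tail_lo, n_shared))
            flip = rng.random(len(positions)) < config.exclusive_divergence
            haps[e] = np.where(flip, 1 - haps[donor], haps[donor])
    ref_idx = rng.integers(0, 4, size=len(positions))
    alt_off = rng.integers(1, 4, size=len(positions))
    variants = [
        VariantRecord(
            chrom=config.chrom,
            pos=int(p),
            vid=f"snp{j}",
            ref=str(_BASES[ref_idx[j]]),
            alt=str(_BASES[(ref_idx[j] + alt_off[j]) % 4]),
        )
        for j, p in enumerate(positions)
    ]
    # founder rows are haplotype donors; sample ids are nominal (2 per id)
    return HaplotypePanel(
        variants=variants,
        haplotypes=haps,
        sample_ids=[f"founder{i}" for i in range(config.n_founders // 2)],
        panel_name="founders",
    )


def accessible_founder_rows(config: SimulationConfig, n_founder_haps: int, pop_label: str) -> np.ndarray:
    """Founder haplotype rows a population's mosaics may copy from.

    The first ``round(founder_sharing * n)`` founders are shared by every
    population; the remaining (exclusive) rows are dealt round-robin to the
    populations in ``pop_sizes`` order.
    """
    if pop_label not in config.pop_sizes:
        raise ValueError(f"unknown population {pop_label!r}")
    n_shared = int(round(config.founder_sharing * n_founder_haps))
    shared = np.arange(n_shared)
    pops = list(config.pop_sizes)
    k = pops.index(pop_label)
    # exclusive founders are dealt round-robin from the low-weight tail, so
    # every population's private variation sits on rarely-copied lineages
    exclusive = np.array(
        [i for i in range(n_shared, n_founder_haps) if (i - n_shared) % len(pops) == k],
        dtype=int,
    )
    return np.concatenate([shared, exclusive])


def founder_weights(config: SimulationConfig, n_founder_haps: int) -> np.ndarray:
    """Copying weight of each founder haplotype (Zipf-like, rank = row order).

    Mosaic segments copy founder ``i`` with probability proportional to
    ``(i + 1) ** -founder_weight_zipf``; exponent 0 recovers uniform usage.
    Skewed usage is what couples allele frequency to imputability: alleles
    on low-weight founders are rare everywhere and thinly represented in any
    reference panel built from the same process.
    """
    w = (np.arange(1, n_founder_haps + 1, dtype=np.float64)) ** (-config.founder_weight_zipf)
    return w / w.sum()


def simulate_population(
    founders: HaplotypePanel, pop_label: str, config: SimulationConfig
) -> HaplotypePanel:
    """Sample a population's haplotypes as founder mosaics.

    Crossover breakpoints follow a Poisson process at
    ``crossover_rate_per_cM`` on a uniform 1 cM/Mb map; segments copy
    accessible founders by their (drift-adjusted) weights.  Private
    mutations flip alleles, per haplotype and site, only on the
    population's reserved site pool (plus the hypermutable class), so
    "population-specific" stays unambiguous in the truth.
    """
    rows = accessible_founder_rows(config, founders.n_haplotypes, pop_label)
    if rows.size == 0:
        raise ValueError(f"population {pop_label!r} has no accessible founders")
    rng = config.rng(f"pop:{pop_label}")
    pool = founders.haplotypes[rows]
    weights = founder_weights(config, founders.n_haplotypes)[rows]
    # genetic drift amplifies a population's private lineages: exclusive
    # founders jointly receive a fixed share of the population's copying
    n_shared_f = int(round(config.founder_sharing * founders.n_haplotypes))
    is_excl = rows >= n_shared_f
    if is_excl.any() and (~is_excl).any():
        share = config.exclusive_weight_share
        weights = weights.astype(np.float64).copy()
        weights[~is_excl] *= (1.0 - share) / weights[~is_excl].sum()
        weights[is_excl] *= share / weights[is_excl].sum()
    weights = weights / weights.sum()
    n_samples = config.pop_sizes[pop_label]
    n_haps = 2 * n_samples
    positions = founders.positions
    total_cm = config.chrom_length_bp / 1e6  # uniform 1 cM/Mb
    mean_xo = config.crossover_rate_per_cM * total_cm

    # mutation targets are population-reserved (round-robin over site index):
    # point mutations essentially never recur across populations, so each
    # population draws its private alleles from its own site pool — except
    # a small hypermutable (CpG-like) class open to every population.
    # Reservation alone keeps "population-private" unambiguous, so owned
    # sites are mutable whether or not founders segregate there.
    pop_list = list(config.pop_sizes)
    sites = np.arange(founders.n_variants)
    mutable = (sites % len(pop_list)) == pop_list.index(pop_label)
    if config.recurrent_site_fraction > 0:
        k = max(1, int(round(1.0 / config.recurrent_site_fraction)))
        mutable |= (sites % k) == 0

    out = np.empty((n_haps, founders.n_variants), dtype=np.int8)
    for h in range(n_haps):
        n_breaks = rng.poisson(mean_xo)
        breaks = np.sort(rng.integers(1, config.chrom_length_bp + 1, size=n_breaks))
        edges = np.concatenate([[0], np.searchsorted(positions, breaks, side="right"),
                                [founders.n_variants]])
        hap = np.empty(founders.n_variants, dtype=np.int8)
        srcs = rng.choice(pool.shape[0], size=len(edges) - 1, p=weights)
        for s in range(len(edges) - 1):
            hap[edges[s]: edges[s + 1]] = pool[srcs[s], edges[s]: edges[s + 1]]
        if config.private_mutation_rate > 0:
            hit = mutable & (rng.random(founders.n_variants) < config.private_mutation_rate)
            hap[hit] = 1 - hap[hit]
        out[h] = hap
    return HaplotypePanel(
        variants=list(founders.variants),
        haplotypes=out,
        sample_ids=[f"{pop_label}_s{i}" for i in range(n_samples)],
        panel_name=pop_label,
    )


def design_dense_array(panel: HaplotypePanel, n_select: int, min_maf: float = 0.05) -> ArrayDesign:
    """Pick ``n_select`` common sites most evenly spaced along the chromosome.

    Eligible sites have MAF >= ``min_maf`` in ``panel``; a greedy grid
    assignment walks ``n_select`` evenly spaced target coordinates and takes
    the nearest unused eligible site (ties: higher MAF, then lower pos).
    """
    maf = panel.maf()
    eligible = np.flatnonzero(maf >= min_maf)
    if eligible.size < n_select:
        raise ValueError(
            f"only {eligible.size} sites with MAF >= {min_maf}; "
            f"short of n_select={n_select} by {n_select - eligible.size}"
        )
    positions = panel.positions
    lo, hi = positions[eligible[0]], positions[eligible[-1]]
    grid = np.linspace(lo, hi, n_select)
    used = np.zeros(len(eligible), dtype=bool)
    chosen: list[int] = []
    for g in grid:
        best = None
        for k, j in enumerate(eligible):
            if used[k]:
                continue
            cand = (abs(positions[j] - g), -maf[j], positions[j])
            if best is None or cand < best[0]:
                best = (cand, k, j)
        used[best[1]] = True
        chosen.append(best[2])
    chosen.sort()
    return ArrayDesign(
        name="dense",
        variant_ids=[panel.variants[j].vid for j in chosen],
        design_rule="dense",
    )


def _evenly_spaced_subset(idx: np.ndarray, k: int) -> np.ndarray:
    """Deterministically take k of idx, evenly spread in list order."""
    if k >= idx.size:
        return idx
    picks = np.unique(np.round(np.linspace(0, idx.size - 1, k)).astype(int))
    # np.unique may merge; top up from unused positions
    if picks.size < k:
        unused = np.setdiff1d(np.arange(idx.size), picks)
        picks = np.sort(np.concatenate([picks, unused[: k - picks.size]]))
    return idx[picks]


def design_exome_chip(
    design_panels: list[HaplotypePanel],
    target_panel: HaplotypePanel,
    n_select: int,
    rare_fraction: float = 0.8,
) -> ArrayDesign:
    """Ascertain chip content in the design panels only.

    Sites polymorphic in the pooled design panels are stratified by pooled
    MAF into rare (<= 0.01) and the rest; ``rare_fraction`` of the chip is
    drawn from the rare stratum.  ``target_panel`` is deliberately ignored:
    the resulting depletion of target-population polymorphism is the
    ascertainment bias under study.
    """
    pooled = np.vstack([p.haplotypes for p in design_panels])
    f = pooled.mean(axis=0)
    maf = np.minimum(f, 1 - f)
    poly = np.flatnonzero(maf > 0)
    if poly.size < n_select:
        raise ValueError(
            f"only {poly.size} polymorphic design-panel sites for n_select={n_select}"
        )
    # the rare stratum ascertains rare *derived* alleles (the chip's target
    # class: functional alleles recently arisen); near-fixed sites whose
    # minor allele is the ancestral one are not chip content at all
    rare = poly[f[poly] <= 0.01]
    other = poly[maf[poly] > 0.01]
    n_rare = min(int(round(rare_fraction * n_select)), rare.size)
    n_other = n_select - n_rare
    if n_other > other.size:  # shift shortfall back to the rare stratum
        n_rare = min(n_select - other.size, rare.size)
        n_other = n_select - n_rare
    if n_rare + n_other < n_select:
        raise ValueError("insufficient polymorphic design-panel sites in the requested strata")
    # rare stratum: rarest derived alleles first (the chip's ascertainment
    # prioritized the rarest functional content); common stratum: spread
    # along the chromosome
    rare_order = rare[np.lexsort((rare, f[rare]))][:n_rare]
    chosen = np.sort(np.concatenate([rare_order, _evenly_spaced_subset(other, n_other)]))
    ref = design_panels[0]
    return ArrayDesign(
        name="exome_chip",
        variant_ids=[ref.variants[j].vid for j in chosen],
        design_rule="exome_style",
    )


def perturb_panel(panel: HaplotypePanel, rate: float, rng: np.random.Generator) -> HaplotypePanel:
    """Flip panel alleles independently at ``rate`` per haplotype per site.

    Emulates the genotype/phasing error of a sequencing-derived reference
    panel (low-coverage panels mis-call a percent-level fraction of rare
    genotypes).  Returns a new panel; the input is untouched.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"noise rate must be in [0,1], got {rate}")
    haps = panel.haplotypes.copy()
    if rate > 0:
        flip = rng.random(haps.shape) < rate
        haps[flip] = 1 - haps[flip]
    return HaplotypePanel(
        variants=list(panel.variants),
        haplotypes=haps,
        sample_ids=list(panel.sample_ids),
        panel_name=panel.panel_name,
    )


def private_site_flags(panels_by_pop: dict) -> dict:
    """Populations carrying each site's derived allele exclusively.

    A site maps to ``{pop}`` when exactly that population's panel is
    polymorphic for the derived allele; sites carried by several (or no)
    populations map to the empty set.
    """
    pops = list(panels_by_pop)
    any_panel = panels_by_pop[pops[0]]
    carriers = {
        pop: panels_by_pop[pop].haplotypes.any(axis=0) for pop in pops
    }
    flags: dict = {}
    for j, v in enumerate(any_panel.variants):
        who = {pop for pop in pops if carriers[pop][j]}
        flags[v.vid] = who if len(who) == 1 else set()
    return flags


def genotype_samples(
    panel: HaplotypePanel,
    design: ArrayDesign,
    config: SimulationConfig,
    panels_by_pop: dict | None = None,
) -> tuple[GenotypeMatrix, TruthSet]:
    """Array-genotype a population and return observed calls plus the truth.

    Observed genotypes at design sites are haplotype-pair sums perturbed by
    ``genotyping_error`` (replacement with either wrong genotype, uniformly)
    and ``missing_rate``; the truth holds error-free genotypes at ALL panel
    sites.
    """
    vid_to_col = panel.vid_index()
    missing_design = [v for v in design.variant_ids if v not in vid_to_col]
    if missing_design:
        raise ValueError(f"design sites not in panel: {missing_design[:5]}")
    cols = [vid_to_col[v] for v in design.variant_ids]
    cols.sort()
    truth_all = panel.haplotypes[0::2, :] + panel.haplotypes[1::2, :]
    rng = config.rng(f"genotyping:{panel.panel_name}:{design.name}")
    obs = truth_all[:, cols].astype(np.int8)
    err = rng.random(obs.shape) < config.genotyping_error
    if err.any():
        # replace with one of the two other genotype classes, uniformly
        shift = rng.integers(1, 3, size=int(err.sum()))
        obs[err] = ((obs[err] + shift) % 3).astype(np.int8)
    miss = rng.random(obs.shape) < config.missing_rate
    obs[miss] = MISSING

    exo_rng = config.rng("exonic")
    exonic = exo_rng.random(panel.n_variants) < config.exonic_fraction
    truth = TruthSet(
        true_genotypes=GenotypeMatrix(
            variants=list(panel.variants),
            genotypes=truth_all.astype(np.int8),
            sample_ids=list(panel.sample_ids),
        ),
        population_labels=[panel.panel_name] * len(panel.sample_ids),
        private_site_flags=private_site_flags(panels_by_pop) if panels_by_pop else {},
        exonic_flags={v.vid: bool(exonic[j]) for j, v in enumerate(panel.variants)},
    )
    observed = GenotypeMatrix(
        variants=[panel.variants[c] for c in cols],
        genotypes=obs,
        sample_ids=list(panel.sample_ids),
    )
    return observed, truth
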