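"""Generator behaviour: spectra, mosaics, ascertainment, genotyping error model."""

import dataclasses

import numpy as np
import pytest

from exomeimpute.core import MISSING
from exomeimpute.simulate import (
    SimulationConfig,
    design_dense_array,
    design_exome_chip,
    genotype_samples,
    perturb_panel,
    private_site_flags,
    simulate_founders,
    simulate_population,
)

from conftest import make_panel


class TestSimulateFounders:
    def test_seed_determinism(self):
        cfg = SimulationConfig(seed=3, n_sites=50, n_founders=8, chrom_length_bp=100_000)
        a = simulate_founders(cfg)
        b = simulate_founders(cfg)
        np.testing.assert_array_equal(a.haplotypes, b.haplotypes)
        assert a.positions.tolist() == b.positions.tolist()

    def test_shape_and_position_ordering(self):
        cfg = SimulationConfig(seed=1, n_sites=10, n_founders=2, chrom_length_bp=50_000,
                               founder_sharing=1.0)
        f = simulate_founders(cfg)
        assert f.haplotypes.shape == (2, 10)
        assert np.all(np.diff(f.positions) > 0)

    def test_alpha_skews_spectrum_toward_rare(self):
        # Monte-Carlo over the stated spectrum: with alpha=1 the median
        # founder derived-allele frequency sits well below 0.25
        medians = []
        for seed in range(10):
            cfg = SimulationConfig(
                seed=seed, n_sites=10_000, n_founders=40, chrom_length_bp=10_000_000,
                site_freq_alpha=1.0, founder_weight_zipf=0.0, founder_sharing=1.0,
            )
            f = simulate_founders(cfg)
            medians.append(np.median(f.allele_frequency()))
        assert np.median(medians) < 0.25

    def test_alpha_zero_is_roughly_uniform(self):
        cfg = SimulationConfig(
            seed=5, n_sites=10_000, n_founders=40, chrom_length_bp=10_000_000,
            site_freq_alpha=0.0, founder_weight_zipf=0.0, founder_sharing=1.0,
        )
        f = simulate_founders(cfg)
        assert 0.2 < np.mean(f.allele_frequency()) < 0.32  # E[f] ~ 0.26 on [1/80, 0.5]


class TestSimulatePopulation:
    def test_no_recombination_no_mutation_copies_a_founder(self):
        cfg = SimulationConfig(
            seed=11, n_sites=60, n_founders=6, chrom_length_bp=100_000,
            crossover_rate_per_cM=0.0, private_mutation_rate=0.0,
            exclusive_divergence=0.0, pop_sizes={"popA": 5, "popB": 5, "popC": 5},
        )
        f = simulate_founders(cfg)
        pop = simulate_population(f, "popA", cfg)
        founder_rows = {tuple(row) for row in f.haplotypes}
        for row in pop.haplotypes:
            assert tuple(row) in founder_rows

    def test_mosaic_closure_without_mutation(self, tiny_sim_config):
        cfg = dataclasses.replace(tiny_sim_config, private_mutation_rate=0.0)
        f = simulate_founders(cfg)
        pop = simulate_population(f, "popB", cfg)
        # every output allele exists among accessible founders at that site
        from exomeimpute.simulate import accessible_founder_rows

        rows = accessible_founder_rows(cfg, f.n_haplotypes, "popB")
        pool = f.haplotypes[rows]
        for j in range(f.n_variants):
            assert set(np.unique(pop.haplotypes[:, j])) <= set(np.unique(pool[:, j]))

    def test_population_specific_sites_exist(self):
        cfg = SimulationConfig(
            seed=2, n_sites=400, n_founders=40, chrom_length_bp=1_000_000,
            founder_sharing=0.5, pop_sizes={"popA": 20, "popB": 20, "popC": 20},
        )
        f = simulate_founders(cfg)
        pops = {p: simulate_population(f, p, cfg) for p in cfg.pop_sizes}
        polyC = pops["popC"].haplotypes.any(axis=0) & ~np.all(pops["popC"].haplotypes, axis=0)
        monoAB = ~(pops["popA"].haplotypes.any(axis=0) | pops["popB"].haplotypes.any(axis=0))
        assert int((polyC & monoAB).sum()) > 0

    def test_seed_determinism(self, tiny_sim_config):
        f = simulate_founders(tiny_sim_config)
        a = simulate_population(f, "popC", tiny_sim_config)
        b = simulate_population(f, "popC", tiny_sim_config)
        np.testing.assert_array_equal(a.haplotypes, b.haplotypes)


class TestDenseArrayDesign:
    def test_all_eligible_selected_when_budget_allows(self, tiny_world):
        cfg, founders, pops = tiny_world
        panel = pops["popA"]
        eligible = {panel.variants[j].vid for j in np.flatnonzero(panel.maf() >= 0.05)}
        design = design_dense_array(panel, n_select=len(eligible), min_maf=0.05)
        assert set(design.variant_ids) == eligible

    def test_boundary_maf_half(self):
        haps = np.array([[0, 0, 1], [1, 0, 1], [0, 0, 0], [1, 1, 0]], dtype=np.int8)
        panel = make_panel(haps)
        design = design_dense_array(panel, n_select=1, min_maf=0.5)
        assert design.variant_ids == ["snp0"]  # only site at exactly MAF 0.5

    def test_shortfall_raises(self, tiny_world):
        _, _, pops = tiny_world
        with pytest.raises(ValueError, match="short"):
            design_dense_array(pops["popA"], n_select=10_000, min_maf=0.05)

    def test_grid_selection_spreads_sites(self):
        # selected positions are more evenly spaced than random draws
        cfg = SimulationConfig(seed=9, n_sites=100, n_founders=20, chrom_length_bp=1_000_000,
                               pop_sizes={"popA": 30, "popB": 2, "popC": 2})
        f = simulate_founders(cfg)
        panel = simulate_population(f, "popA", cfg)
        eligible = np.flatnonzero(panel.maf() >= 0.05)
        design = design_dense_array(panel, n_select=10, min_maf=0.05)
        idx = panel.vid_index()
        pos = np.sort([panel.variants[idx[v]].pos for v in design.variant_ids])
        var_design = np.var(np.diff(pos))
        rng = np.random.default_rng(0)
        worse = 0
        for _ in range(20):
            draw = np.sort(panel.positions[rng.choice(eligible, 10, replace=False)])
            worse += np.var(np.diff(draw)) >= var_design
        assert worse >= 15  # the grid beats random spacing almost always


class TestExomeChipDesign:
    def test_rare_fraction_zero_yields_no_rare_design_sites(self, tiny_world):
        cfg, founders, pops = tiny_world
        chip = design_exome_chip([pops["popA"], pops["popB"]], pops["popC"], 20, rare_fraction=0.0)
        pooled = np.vstack([pops["popA"].haplotypes, pops["popB"].haplotypes])
        f = pooled.mean(axis=0)
        maf = np.minimum(f, 1 - f)
        idx = {v.vid: j for j, v in enumerate(pops["popA"].variants)}
        assert all(maf[idx[v]] > 0.01 for v in chip.variant_ids)

    def test_no_ascertainment_gap_when_design_equals_target(self, tiny_world):
        cfg, founders, pops = tiny_world
        chip = design_exome_chip([pops["popC"]], pops["popC"], 15, rare_fraction=0.5)
        idx = {v.vid: j for j, v in enumerate(pops["popC"].variants)}
        maf = pops["popC"].maf()
        assert all(maf[idx[v]] > 0 for v in chip.variant_ids)

    def test_ascertainment_bias_grows_as_sharing_shrinks(self):
        # monomorphic-in-target fraction is non-decreasing as sharing drops
        fracs = []
        for sharing in (0.9, 0.6, 0.3):
            mono = []
            for seed in (1, 2, 3):
                cfg = SimulationConfig(
                    seed=seed, n_sites=600, n_founders=60, chrom_length_bp=1_000_000,
                    founder_sharing=sharing,
                    pop_sizes={"popA": 40, "popB": 40, "popC": 40},
                )
                f = simulate_founders(cfg)
                pops = {p: simulate_population(f, p, cfg) for p in cfg.pop_sizes}
                chip = design_exome_chip([pops["popA"], pops["popB"]], pops["popC"], 80)
                idx = {v.vid: j for j, v in enumerate(f.variants)}
                tg = pops["popC"].haplotypes
                mono.append(
                    np.mean([
                        tg[:, idx[v]].sum() in (0, tg.shape[0]) for v in chip.variant_ids
                    ])
                )
            fracs.append(np.mean(mono))
        assert fracs[0] <= fracs[1] + 0.05 and fracs[1] <= fracs[2] + 0.05


class TestGenotypeSamples:
    def test_error_free_observation_equals_truth(self, tiny_world):
        cfg, founders, pops = tiny_world
        clean = dataclasses.replace(cfg, genotyping_error=0.0, missing_rate=0.0)
        chip = design_dense_array(pops["popC"], 30)
        obs, truth = genotype_samples(pops["popC"], chip, clean)
        idx = truth.true_genotypes.vid_index()
        cols = [idx[v] for v in obs.vids]
        np.testing.assert_array_equal(obs.genotypes, truth.true_genotypes.genotypes[:, cols])

    def test_all_missing_when_missing_rate_is_one(self, tiny_world):
        cfg, founders, pops = tiny_world
        allmiss = dataclasses.replace(cfg, missing_rate=1.0)
        chip = design_dense_array(pops["popC"], 30)
        obs, truth = genotype_samples(pops["popC"], chip, allmiss)
        assert np.all(obs.genotypes == MISSING)
        assert not np.any(truth.true_genotypes.genotypes == MISSING)

    def test_error_rate_calibration(self):
        # Monte-Carlo: observed mismatch rate vs truth matches the nominal rate
        rates = []
        for seed in range(20):
            cfg = SimulationConfig(
                seed=seed, n_sites=200, n_founders=20, chrom_length_bp=500_000,
                genotyping_error=0.01, missing_rate=0.0,
                pop_sizes={"popA": 2, "popB": 2, "popC": 25},
            )
            f = simulate_founders(cfg)
            pop = simulate_population(f, "popC", cfg)
            design = design_dense_array(pop, 20, min_maf=0.0)
            obs, truth = genotype_samples(pop, design, cfg)
            idx = truth.true_genotypes.vid_index()
            cols = [idx[v] for v in obs.vids]
            rates.append(np.mean(obs.genotypes != truth.true_genotypes.genotypes[:, cols]))
        assert 0.005 <= np.mean(rates) <= 0.015

    def test_truth_conserves_haplotype_sums(self, tiny_world):
        cfg, founders, pops = tiny_world
        chip = design_dense_array(pops["popB"], 20)
        _, truth = genotype_samples(pops["popB"], chip, cfg)
        expected = pops["popB"].haplotypes[0::2] + pops["popB"].haplotypes[1::2]
        np.testing.assert_array_equal(truth.true_genotypes.genotypes, expected)


def test_private_site_flags_match_panel_counts(tiny_world):
    _, _, pops = tiny_world
    flags = private_site_flags(pops)
    idx = {v.vid: j for j, v in enumerate(pops["popA"].variants)}
    for vid, who in flags.items():
        j = idx[vid]
        carriers = {p for p in pops if pops[p].haplotypes[:, j].any()}
        assert who == (carriers if len(carriers) == 1 else set())


def test_perturb_panel_flip_rate_and_purity(tiny_world):
    _, _, pops = tiny_world
    rng = np.random.default_rng(0)
    noisy = perturb_panel(pops["popA"], 0.05, rng)
    frac = np.mean(noisy.haplotypes != pops["popA"].haplotypes)
    assert 0.03 < frac < 0.07
    assert set(np.unique(noisy.haplotypes)) <= {0, 1}
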