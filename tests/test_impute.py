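"""Li–Stephens engine: path-enumeration oracle, chunking, thresholding, panel merge."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exomeimpute.core import MISSING, FormatError, GeneticMap, PosteriorTensor
from exomeimpute.impute import (
    HmmParams,
    impute_genotypes,
    ls_haploid_posteriors,
    make_chunk_plan,
    merge_panels,
    threshold_calls,
)

from conftest import make_panel


def ls_enumeration_oracle(target_hap, typed_cols, ref_haps, positions, n_e, theta):
    """Sum over all k^T copying paths, then read off allele-1 probabilities
    with the same flanking-state interpolation rule, coded independently."""
    k, m = ref_haps.shape
    typed_cols = list(typed_cols)
    T = len(typed_cols)
    cm = (positions - 1) / 1e6  # uniform 1 cM/Mb map
    cm_typed = [cm[c] for c in typed_cols]
    rho = [1.0 - np.exp(-4 * n_e * (cm_typed[t + 1] - cm_typed[t]) / (100 * k)) for t in range(T - 1)]

    def emis(state, t):
        return (1 - theta) if ref_haps[state, typed_cols[t]] == target_hap[t] else theta

    weights = {}
    for path in itertools.product(range(k), repeat=T):
        w = (1.0 / k) * emis(path[0], 0)
        for t in range(1, T):
            trans = (1 - rho[t - 1]) + rho[t - 1] / k if path[t] == path[t - 1] else rho[t - 1] / k
            w *= trans * emis(path[t], t)
        weights[path] = w
    total = sum(weights.values())
    gamma = np.zeros((T, k))
    for path, w in weights.items():
        for t, s in enumerate(path):
            gamma[t, s] += w
    gamma /= total

    p1 = np.zeros(m)
    for j in range(m):
        right = np.searchsorted(typed_cols, j, side="left")
        if right <= 0:
            g = gamma[0]
        elif right >= T:
            g = gamma[T - 1]
        elif typed_cols[right] == j:
            g = gamma[right]
        else:
            span = cm_typed[right] - cm_typed[right - 1]
            lam = 0.5 if span <= 0 else (cm_typed[right] - cm[j]) / span
            g = lam * gamma[right - 1] + (1 - lam) * gamma[right]
        p1[j] = g @ ref_haps[:, j]
    return p1


class TestLsHaploidPosteriors:
    def test_single_reference_haplotype_is_copied_exactly(self, flat_map):
        ref = make_panel([[1, 0, 1, 1], [1, 0, 1, 1]])
        params = HmmParams(error_rate=0.2, map=flat_map)
        p1 = ls_haploid_posteriors(np.array([1, 1]), ["snp0", "snp2"], ref, params)
        np.testing.assert_allclose(p1, [1, 0, 1, 1])

    def test_identical_target_locks_onto_its_twin(self):
        haps = np.array(
            [[1, 0, 1, 0, 1, 1], [0, 1, 0, 1, 0, 0], [1, 1, 0, 0, 1, 0],
             [1, 0, 1, 0, 1, 1]], dtype=np.int8
        )
        ref = make_panel(haps)
        # negligible genetic distance: the copying chain cannot switch away
        params = HmmParams(error_rate=1e-8, map=GeneticMap.uniform(2_000_000, 1e-6))
        typed = ["snp0", "snp1", "snp2", "snp4"]
        p1 = ls_haploid_posteriors(haps[0, [0, 1, 2, 4]], typed, ref, params)
        # untyped sites take the matching haplotype's alleles
        assert abs(p1[3] - haps[0, 3]) < 1e-6
        assert abs(p1[5] - haps[0, 5]) < 1e-6

    def test_matches_path_enumeration_on_reference_case(self, flat_map):
        rng = np.random.default_rng(17)
        haps = rng.integers(0, 2, size=(4, 4)).astype(np.int8)
        ref = make_panel(haps)
        params = HmmParams(error_rate=0.05, map=flat_map)
        typed_cols = [0, 2]
        target = np.array([1, 0], dtype=np.int8)
        got = ls_haploid_posteriors(target, ["snp0", "snp2"], ref, params)
        want = ls_enumeration_oracle(target, typed_cols, haps, ref.positions, 15000.0, 0.05)
        np.testing.assert_allclose(got, want, atol=1e-10)

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 4), st.integers(2, 6))
    def test_forward_backward_equals_enumeration(self, seed, k_ref, n_sites):
        rng = np.random.default_rng(seed)
        haps = rng.integers(0, 2, size=(2 * ((k_ref + 1) // 2) or 2, n_sites)).astype(np.int8)
        haps = haps[: k_ref + (k_ref % 2), :]
        if haps.shape[0] % 2:
            haps = np.vstack([haps, haps[-1:]])
        ref = make_panel(haps)
        n_typed = int(rng.integers(1, n_sites + 1))
        typed_cols = sorted(rng.choice(n_sites, size=n_typed, replace=False).tolist())
        target = rng.integers(0, 2, size=n_typed).astype(np.int8)
        theta = float(rng.uniform(0.01, 0.3))
        params = HmmParams(error_rate=theta, map=GeneticMap.uniform(2_000_000))
        got = ls_haploid_posteriors(target, [ref.variants[c].vid for c in typed_cols], ref, params)
        want = ls_enumeration_oracle(target, typed_cols, ref.haplotypes, ref.positions, 15000.0, theta)
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_high_theta_limit_approaches_allele_frequency(self, flat_map):
        rng = np.random.default_rng(5)
        haps = rng.integers(0, 2, size=(40, 6)).astype(np.int8)
        ref = make_panel(haps)
        params = HmmParams(error_rate=0.499999, map=flat_map)
        p1 = ls_haploid_posteriors(np.array([1, 0]), ["snp0", "snp3"], ref, params)
        np.testing.assert_allclose(p1, ref.allele_frequency(), atol=1e-3)

    def test_zero_typed_sites_rejected(self, flat_map):
        ref = make_panel([[0, 1], [1, 0]])
        with pytest.raises(ValueError):
            ls_haploid_posteriors(np.array([], dtype=np.int8), [], ref, HmmParams(map=flat_map))


class TestChunkPlan:
    def test_short_chromosome_is_single_chunk(self):
        plan = make_chunk_plan(3_000_000, core_bp=5_000_000, buffer_bp=5_000_000)
        assert plan.intervals == [(1, 3_000_000, 1, 3_000_000)]

    def test_twelve_mb_three_cores(self):
        plan = make_chunk_plan(12_000_000, core_bp=5_000_000, buffer_bp=5_000_000)
        cores = [(cs, ce) for cs, ce, _, _ in plan.intervals]
        assert cores == [(1, 5_000_000), (5_000_001, 10_000_000), (10_000_001, 12_000_000)]

    def test_buffers_clipped_to_chromosome(self):
        plan = make_chunk_plan(12_000_000, core_bp=2_000_000, buffer_bp=4_000_000)
        for _, _, bs, be in plan.intervals:
            assert 1 <= bs <= be <= 12_000_000


class TestThresholdCalls:
    @pytest.mark.parametrize(
        "triple,expected",
        [
            ((0.95, 0.04, 0.01), 0),
            ((0.6, 0.3, 0.1), MISSING),
            ((0.90, 0.05, 0.05), 0),  # boundary inclusive
            ((0.02, 0.08, 0.90), 2),
            ((0.05, 0.89, 0.06), MISSING),
        ],
    )
    def test_boundary_semantics(self, triple, expected):
        post = PosteriorTensor(np.array([[list(triple)]]))
        calls = threshold_calls(post, 0.90)
        assert calls[0, 0] == expected

    def test_threshold_domain_enforced(self):
        post = PosteriorTensor(np.full((1, 1, 3), 1 / 3.0))
        with pytest.raises(ValueError):
            threshold_calls(post, 0.2)


class TestImputeGenotypes:
    def _world(self):
        rng = np.random.default_rng(23)
        ref = make_panel(rng.integers(0, 2, size=(30, 40)),
                         positions=np.sort(rng.choice(1_900_000, 40, replace=False) + 1))
        typed_idx = sorted(rng.choice(40, size=12, replace=False).tolist())
        targets = make_panel(
            ref.haplotypes[:4, typed_idx],
            positions=[ref.variants[j].pos for j in typed_idx],
            name="targets",
        )
        targets.variants = [ref.variants[j] for j in typed_idx]
        return ref, targets

    def test_independence_combination(self):
        from exomeimpute.impute import _genotype_posteriors

        np.testing.assert_allclose(
            _genotype_posteriors(np.array([1.0]), np.array([1.0]))[0], [0, 0, 1], atol=1e-12
        )
        np.testing.assert_allclose(
            _genotype_posteriors(np.array([0.5]), np.array([0.5]))[0], [0.25, 0.5, 0.25]
        )

    def test_chunked_equals_unchunked(self, flat_map):
        ref, targets = self._world()
        params = HmmParams(map=flat_map)
        single = impute_genotypes(targets, ref, params, make_chunk_plan(2_000_000, 5_000_000))
        chunked = impute_genotypes(
            targets, ref, params, make_chunk_plan(2_000_000, core_bp=400_000, buffer_bp=5_000_000)
        )
        np.testing.assert_allclose(single.probs, chunked.probs, atol=1e-12)

    def test_posterior_triples_sum_to_one(self, flat_map):
        ref, targets = self._world()
        post = impute_genotypes(targets, ref, HmmParams(map=flat_map), None)
        np.testing.assert_allclose(post.probs.sum(axis=2), 1.0, atol=1e-9)


class TestMergePanels:
    def test_identical_panels_share_site_union(self, flat_map):
        rng = np.random.default_rng(31)
        p = make_panel(rng.integers(0, 2, size=(6, 8)))
        merged = merge_panels(p, p, HmmParams(map=flat_map))
        assert merged.vids == p.vids
        assert merged.n_haplotypes == 2 * p.n_haplotypes
        np.testing.assert_array_equal(merged.haplotypes[: p.n_haplotypes], p.haplotypes)

    def test_subset_panel_recovers_copied_alleles(self):
        # each haplotype gets a unique signature at the shared (typed) sites,
        # so the copying posterior identifies its twin unambiguously
        rng = np.random.default_rng(37)
        full_h = rng.integers(0, 2, size=(8, 10)).astype(np.int8)
        for r in range(8):
            full_h[r, [0, 2, 4]] = [(r >> 2) & 1, (r >> 1) & 1, r & 1]
        full = make_panel(full_h)
        sub = full.subset_variants(range(0, 10, 2)).subset_samples([0, 1])
        params = HmmParams(error_rate=1e-6, map=GeneticMap.uniform(2_000_000, 1e-6))
        merged = merge_panels(full, sub, params)
        # the cross-imputed alleles of the subset panel equal the originals
        idx = merged.vid_index()
        for j, v in enumerate(full.variants):
            np.testing.assert_array_equal(
                merged.haplotypes[8:, idx[v.vid]], full.haplotypes[:4, j]
            )

    def test_disjoint_rare_sites_counted_once(self, flat_map):
        rng = np.random.default_rng(41)
        base = make_panel(rng.integers(0, 2, size=(6, 9)))
        a = base.subset_variants(range(0, 7))
        b = base.subset_variants([0, 2, 4, 7, 8]).subset_samples([0])
        merged = merge_panels(a, b, HmmParams(map=flat_map))
        assert merged.n_variants == 9
        assert np.all(merged.haplotypes >= 0)

    def test_allele_conflict_rejected(self, flat_map):
        a = make_panel([[0, 1], [1, 0]])
        b = make_panel([[0, 1], [1, 0]])
        b.variants = [b.variants[0].__class__("1", b.variants[0].pos, "snp0", "C", "T"),
                      b.variants[1]]
        with pytest.raises(FormatError):
            merge_panels(a, b, HmmParams(map=flat_map))


def test_merged_specific_panel_improves_masked_rare_imputation():
    """Adding a target-population panel lowers minor-allele discordance at
    masked sites (the headline direction of the study), across seeds."""
    import dataclasses

    from exomeimpute.simulate import SimulationConfig, simulate_founders, simulate_population

    wins = 0
    for seed in range(3):
        cfg = SimulationConfig(
            seed=seed, n_sites=400, n_founders=60,
            pop_sizes={"popA": 40, "popB": 40, "popC": 40},
        )
        f = simulate_founders(cfg)
        pops = {p: simulate_population(f, p, cfg) for p in cfg.pop_sizes}
        target = pops["popC"].subset_samples(range(20, 40))
        donors = pops["popC"].subset_samples(range(20))
        cosmo_h = np.vstack([pops["popA"].haplotypes, pops["popB"].haplotypes])
        cosmo = make_panel(cosmo_h, positions=[v.pos for v in f.variants], name="cosmo")
        cosmo.variants = list(f.variants)
        params = HmmParams(map=GeneticMap.uniform(cfg.chrom_length_bp))
        merged = merge_panels(cosmo, donors, params)
        typed_idx = [j for j in range(0, 400, 3) if 0 < cosmo.maf()[j]]
        targets_typed = make_panel(
            target.haplotypes[:, typed_idx],
            positions=[f.variants[j].pos for j in typed_idx], name="t",
        )
        targets_typed.variants = [f.variants[j] for j in typed_idx]

        truth = target.haplotypes[0::2] + target.haplotypes[1::2]
        maf_t = np.minimum(truth.mean(axis=0) / 2, 1 - truth.mean(axis=0) / 2)
        eval_idx = [
            j for j in range(400)
            if j not in set(typed_idx) and 0 < maf_t[j] < 0.05
        ]

        def discordance(ref):
            post = impute_genotypes(targets_typed, ref, params, None)
            calls = threshold_calls(post, 0.9)
            idx = ref.vid_index()
            n = bad = 0
            for j in eval_idx:
                v = f.variants[j].vid
                if v not in idx:
                    continue
                c = calls[:, idx[v]]
                carrier = truth[:, j] > 0
                ok = carrier & (c != MISSING)
                n += int(ok.sum())
                bad += int((c[ok] != truth[ok, j]).sum())
            return bad / n if n else np.nan

        d_cosmo = discordance(cosmo)
        d_merged = discordance(merged)
        if np.isfinite(d_cosmo) and np.isfinite(d_merged) and d_merged <= d_cosmo:
            wins += 1
    assert wins >= 2
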