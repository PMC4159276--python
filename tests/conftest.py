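import numpy as np
import pytest

from exomeimpute.core import GeneticMap, GenotypeMatrix, HaplotypePanel, VariantRecord
from exomeimpute.simulate import SimulationConfig, simulate_founders, simulate_population


def make_variants(positions, chrom="1", prefix="snp"):
    return [
        VariantRecord(chrom=chrom, pos=int(p), vid=f"{prefix}{i}", ref="A", alt="G")
        for i, p in enumerate(positions)
    ]


def make_panel(haps, positions=None, name="panel"):
    haps = np.asarray(haps, dtype=np.int8)
    if positions is None:
        positions = 1000 * (np.arange(haps.shape[1]) + 1)
    return HaplotypePanel(
        variants=make_variants(positions),
        haplotypes=haps,
        sample_ids=[f"s{i}" for i in range(haps.shape[0] // 2)],
        panel_name=name,
    )


def make_matrix(genos, positions=None):
    genos = np.asarray(genos, dtype=np.int8)
    if positions is None:
        positions = 1000 * (np.arange(genos.shape[1]) + 1)
    return GenotypeMatrix(
        variants=make_variants(positions),
        genotypes=genos,
        sample_ids=[f"s{i}" for i in range(genos.shape[0])],
    )


@pytest.fixture(scope="session")
def tiny_sim_config():
    return SimulationConfig(
        seed=7,
        chrom_length_bp=500_000,
        n_sites=200,
        n_founders=20,
        pop_sizes={"popA": 12, "popB": 12, "popC": 12},
    )


@pytest.fixture(scope="session")
def tiny_world(tiny_sim_config):
    founders = simulate_founders(tiny_sim_config)
    pops = {p: simulate_population(founders, p, tiny_sim_config) for p in tiny_sim_config.pop_sizes}
    return tiny_sim_config, founders, pops


@pytest.fixture
def flat_map():
    return GeneticMap.uniform(2_000_000)
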