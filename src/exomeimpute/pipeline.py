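"""End-to-end scenario orchestration: simulate -> QC -> rebuild arrays -> impute -> evaluate.

A scenario emulates the full study design on synthetic data: two
cosmopolitan populations provide the reference/design panels, a third
population — absent from the cosmopolitan panel and carrying
population-private rare variation — is array-genotyped and imputed against
(i) the cosmopolitan panel alone and (ii) the cosmopolitan panel merged
with a small population-specific panel built from sequenced donors of the
target population.  Donor samples are structurally excluded from the
imputation targets (the over-fitting guard).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .arrays import rebuild_array, write_decisions_tsv
from .core import ArrayDesign, GeneticMap, HaplotypePanel
from .impute import HmmParams, impute_genotypes, make_chunk_plan, merge_panels, threshold_calls
from .io import (
    write_genetic_map,
    write_phased_vcf,
    write_report,
    write_vcf,
)
from .metrics import (
    EvaluationReport,
    SnpQuality,
    coverage_accounting,
    maf_bin,
    maf_of,
    minor_allele_concordance,
    overall_concordance,
    recoverable_content,
    snp_quality_table,
)
from .qc import QcThresholds, run_qc
from .simulate import (
    SimulationConfig,
    design_dense_array,
    design_exome_chip,
    genotype_samples,
    perturb_panel,
    simulate_founders,
    simulate_population,
)

logger = logging.getLogger("exomeimpute")


class PipelineStageError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class ScenarioConfig:
    """Full configuration of one end-to-end run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    qc: QcThresholds = field(default_factory=QcThresholds)
    n_e: float = 15000.0
    hmm_error_rate: float = 1e-3
    core_bp: int = 5_000_000
    buffer_bp: int = 5_000_000
    posterior_threshold: float = 0.90
    design_pops: tuple = ("popA", "popB")
    target_pop: str = "popC"
    n_specific_donors: int = 30
    dense_n_select: int = 600
    dense_min_maf: float = 0.05
    legacy_manifest_size: int = 300
    chip_n_select: int = 250
    chip_rare_fraction: float = 0.8
    chip_design_cohort_size: int = 250
    panel_noise_rate: float = 0.003
    study_arrays: tuple = ("dense", "legacy")
    panel_configs: dict = field(
        default_factory=lambda: {
            "cosmopolitan": ("cosmopolitan",),
            "cosmopolitan+specific": ("cosmopolitan", "specific"),
        }
    )
    output_dir: str | None = None

    def __post_init__(self) -> None:
        pops = set(self.simulation.pop_sizes)
        for p in (*self.design_pops, self.target_pop):
            if p not in pops:
                raise ValueError(f"population {p!r} not present in simulation.pop_sizes")
        if not self.panel_configs:
            raise ValueError("at least one panel configuration is required")
        if self.n_specific_donors >= self.simulation.pop_sizes[self.target_pop]:
            raise ValueError("every target-population sample would be a panel donor")


@dataclass
class ScenarioResult:
    """The evaluation report plus the intermediate objects tests inspect."""

    report: EvaluationReport
    truth: object
    designs: dict
    panels: dict
    qc_report: object
    surrogate_decisions: list
    quality: dict  # (array, panel_config) -> {vid: SnpQuality}
    target_sample_ids: list
    donor_sample_ids: list


def _restrict_polymorphic(panel: HaplotypePanel, name: str) -> HaplotypePanel:
    keep = np.flatnonzero(panel.maf() > 0)
    out = panel.subset_variants(keep)
    out.panel_name = name
    return out


def _concat_panels(panels: list[HaplotypePanel], name: str) -> HaplotypePanel:
    haps = np.vstack([p.haplotypes for p in panels])
    sample_ids = [s for p in panels for s in p.sample_ids]
    return HaplotypePanel(
        variants=list(panels[0].variants), haplotypes=haps, sample_ids=sample_ids, panel_name=name
    )


def assert_no_overfitting(target_ids: list, donor_ids: list) -> None:
    """The structural guard: imputation targets never donate panel haplotypes."""
    overlap = set(target_ids) & set(donor_ids)
    if overlap:
        raise PipelineStageError(
            "impute", f"over-fitting: target samples also donate reference haplotypes: {sorted(overlap)[:5]}"
        )


def run_scenario(config: ScenarioConfig) -> EvaluationReport:
    """Run the whole pipeline and return (and optionally write) the report."""
    return run_scenario_detailed(config).report


def run_scenario_detailed(config: ScenarioConfig) -> ScenarioResult:
    sim = config.simulation
    # ---- simulate ---------------------------------------------------------
    founders = simulate_founders(sim)
    pops = {p: simulate_population(founders, p, sim) for p in sim.pop_sizes}
    logger.info("simulated %d populations over %d sites", len(pops), founders.n_variants)

    target_panel = pops[config.target_pop]
    n_donor = config.n_specific_donors
    donors = target_panel.subset_samples(range(n_donor))
    donors.panel_name = "specific_donors"
    target_ids = target_panel.sample_ids[n_donor:]
    donor_ids = list(donors.sample_ids)

    # reference panels carry sequencing/phasing noise, as real
    # low-coverage panels do; targets and truth stay error-free
    noise_rng = sim.rng("panel_noise")
    cosmopolitan = _restrict_polymorphic(
        perturb_panel(
            _concat_panels([pops[p] for p in config.design_pops], "cosmopolitan"),
            config.panel_noise_rate,
            noise_rng,
        ),
        "cosmopolitan",
    )
    specific = _restrict_polymorphic(
        perturb_panel(donors, config.panel_noise_rate, noise_rng), "specific"
    )

    # ---- array designs ----------------------------------------------------
    pooled_all = _concat_panels(list(pops.values()), "pooled")
    # chip content is ascertained in deep design cohorts of the non-target
    # populations (emulating array design from large sequencing studies,
    # far deeper than the imputation reference panel)
    cohort_sizes = {
        p: (config.chip_design_cohort_size if p in config.design_pops else 1)
        for p in sim.pop_sizes
    }
    cohort_sim = dataclasses.replace(
        sim, seed=(sim.seed + 1_000_003) % 2**31, pop_sizes=cohort_sizes
    )
    design_cohorts = [
        simulate_population(founders, p, cohort_sim) for p in config.design_pops
    ]
    try:
        dense = design_dense_array(pooled_all, config.dense_n_select, config.dense_min_maf)
        chip = design_exome_chip(
            design_cohorts,
            target_panel,
            config.chip_n_select,
            config.chip_rare_fraction,
        )
    except ValueError as exc:
        raise PipelineStageError("design", str(exc)) from exc
    rng = sim.rng("legacy_manifest")
    common = np.flatnonzero(pooled_all.maf() >= config.dense_min_maf)
    manifest_idx = np.sort(
        rng.choice(common, size=min(config.legacy_manifest_size, common.size), replace=False)
    )
    manifest = [pooled_all.variants[j].vid for j in manifest_idx]
    legacy, decisions = rebuild_array(
        manifest, dense, pops[config.design_pops[0]], pops[config.design_pops[1]], name="legacy"
    )
    n_recovered = sum(1 for d in decisions if d.rule != "none")
    logger.info(
        "legacy rebuild: %d/%d manifest SNPs recovered (%d direct)",
        n_recovered,
        len(manifest),
        sum(1 for d in decisions if d.rule == "direct"),
    )
    designs = {"dense": dense, "legacy": legacy, "chip": chip}

    # ---- genotype the target cohort and run QC ----------------------------
    panels_by_pop = {p: pops[p] for p in sim.pop_sizes}
    obs_dense, truth = genotype_samples(target_panel, dense, sim, panels_by_pop)
    obs_chip, _ = genotype_samples(target_panel, chip, sim, panels_by_pop)
    try:
        clean, qc_report = run_qc(
            {"dense": obs_dense, "chip": obs_chip},
            config.qc,
            labels=[config.target_pop] * len(target_panel.sample_ids),
        )
    except ValueError as exc:
        raise PipelineStageError("qc", str(exc)) from exc
    logger.info(
        "QC: %d SNP removals, %d sample removals",
        len(qc_report.removed_snps),
        len(qc_report.removed_samples),
    )
    surviving_samples = clean["dense"].sample_ids
    target_ids = [s for s in target_ids if s in surviving_samples]
    assert_no_overfitting(target_ids, donor_ids)

    # ---- reference panel configurations -----------------------------------
    gmap = GeneticMap.uniform(sim.chrom_length_bp)
    params = HmmParams(n_e=config.n_e, error_rate=config.hmm_error_rate, map=gmap)
    base_panels = {"cosmopolitan": cosmopolitan, "specific": specific}
    ref_panels: dict = {}
    for cfg_name, members in config.panel_configs.items():
        missing = [m for m in members if m not in base_panels]
        if missing:
            raise PipelineStageError("panels", f"unknown panel member(s) {missing}")
        ref = base_panels[members[0]]
        for m in members[1:]:
            ref = merge_panels(ref, base_panels[m], params)
        ref_panels[cfg_name] = ref
    panels = dict(base_panels)
    panels.update(ref_panels)

    # ---- impute and evaluate ----------------------------------------------
    plan = make_chunk_plan(sim.chrom_length_bp, config.core_bp, config.buffer_bp)
    target_rows = [target_panel.sample_ids.index(s) for s in target_ids]
    truth_targets = truth.true_genotypes.subset_samples(
        [target_panel.sample_ids.index(s) for s in target_ids]
    )
    clean_dense_vids = set(clean["dense"].vids)
    dense_vid_set = set(designs["dense"].variant_ids)
    clean_chip_vids = set(clean["chip"].vids)
    tgt_vid_idx = target_panel.vid_index()

    well_rows, disc_rows, minor_rows = [], [], []
    quality: dict = {}
    for array_name in config.study_arrays:
        array = designs[array_name]
        # legacy content is a subset of the dense array's sites, so dense QC applies
        typed_all = [v for v in array.variant_ids if v in clean_dense_vids]
        for cfg_name, ref in ref_panels.items():
            ref_vids = set(ref.vids)
            typed = [v for v in typed_all if v in ref_vids]
            if not typed:
                raise PipelineStageError("impute", f"no typed sites usable for {array_name}/{cfg_name}")
            cols = sorted(tgt_vid_idx[v] for v in typed)
            targets_typed = HaplotypePanel(
                variants=[target_panel.variants[c] for c in cols],
                haplotypes=target_panel.haplotypes[
                    [r for s in target_rows for r in (2 * s, 2 * s + 1)], :
                ][:, cols],
                sample_ids=target_ids,
                panel_name="targets",
            )
            try:
                post = impute_genotypes(targets_typed, ref, params, plan)
            except Exception as exc:
                raise PipelineStageError("impute", str(exc)) from exc
            calls = threshold_calls(post, config.posterior_threshold)
            qual = snp_quality_table(post.probs, calls)
            qual_by_vid = {v: q for v, q in zip(ref.vids, qual)}
            quality[(array_name, cfg_name)] = qual_by_vid
            logger.info(
                "imputed %s/%s: %d typed sites, %d reference sites",
                array_name,
                cfg_name,
                len(typed),
                ref.n_variants,
            )

            # evaluation set: chip SNPs in the reference panel, absent from the
            # study array, surviving chip QC
            # one evaluation grid for every study array: chip SNPs absent
            # from the dense array (the union of all study-array content),
            # so per-array results are directly comparable
            eval_vids = [
                v
                for v in chip.variant_ids
                if v in ref_vids and v not in dense_vid_set and v in clean_chip_vids
            ]
            truth_idx = truth_targets.vid_index()
            ref_idx = ref.vid_index()
            bins = []
            keep_vids = []
            for v in eval_vids:
                b = maf_bin(maf_of(truth_targets.genotypes[:, truth_idx[v]]))
                if b != "monomorphic":
                    keep_vids.append(v)
                    bins.append(b)
            # Fig-2-style: share of evaluable chip SNPs that are well-imputed
            bin_counts: dict = {}
            for v, b in zip(keep_vids, bins):
                ok = qual_by_vid[v].well_imputed
                tot, n_ok = bin_counts.get(b, (0, 0))
                bin_counts[b] = (tot + 1, n_ok + ok)
            for b in ("rare", "low_frequency", "common"):
                tot, n_ok = bin_counts.get(b, (0, 0))
                well_rows.append(
                    {
                        "array": array_name,
                        "panel_config": cfg_name,
                        "maf_bin": b,
                        "n_snps": tot,
                        "n_well_imputed": n_ok,
                        "pct_well_imputed": 100.0 * n_ok / tot if tot else np.nan,
                    }
                )
            # concordance restricted to well-imputed evaluation SNPs
            wi_vids = [v for v in keep_vids if qual_by_vid[v].well_imputed]
            wi_bins = [b for v, b in zip(keep_vids, bins) if qual_by_vid[v].well_imputed]
            if wi_vids:
                imp = calls[:, [ref_idx[v] for v in wi_vids]]
                obs = truth_targets.genotypes[:, [truth_idx[v] for v in wi_vids]]
                oc = overall_concordance(imp, obs, wi_bins)
                for r in oc.itertuples():
                    disc_rows.append(
                        {
                            "array": array_name,
                            "panel_config": cfg_name,
                            "maf_bin": r.maf_bin,
                            "n_genotypes": r.n_genotypes,
                            "n_discordant": r.n_discordant,
                            "discordance_pct": 100.0 * (1.0 - r.concordance)
                            if np.isfinite(r.concordance)
                            else np.nan,
                        }
                    )
                mac = minor_allele_concordance(imp, obs, wi_bins)
                for b in ("rare", "low_frequency", "pooled"):
                    e = mac[b]
                    minor_rows.append(
                        {
                            "array": array_name,
                            "panel_config": cfg_name,
                            "maf_bin": b,
                            "n_minor_allele_genotypes": e["n_minor_allele_genotypes"],
                            "n_discordant": e["n_discordant"],
                            "discordance_pct": 100.0 * (1.0 - e["concordance"])
                            if np.isfinite(e["concordance"])
                            else np.nan,
                        }
                    )

    # ---- coverage and recoverability tables --------------------------------
    chip_clean_vids = [v for v in chip.variant_ids if v in clean_chip_vids]
    chip_clean = ArrayDesign(name="chip", variant_ids=chip_clean_vids, design_rule="exome_style")
    obs_chip_targets = clean["chip"].subset_samples(
        [clean["chip"].sample_ids.index(s) for s in target_ids]
    )
    coverage = coverage_accounting(
        chip_clean, [cosmopolitan, specific], obs_chip_targets, population=config.target_pop
    )
    qual_dense = {
        cfg: quality[("dense", cfg)] for cfg in ref_panels if ("dense", cfg) in quality
    }
    recover = recoverable_content(truth, designs["dense"], chip, qual_dense)

    report = EvaluationReport(
        coverage_by_maf=coverage,
        well_imputed_by_panel=pd.DataFrame(well_rows),
        discordance_overall=pd.DataFrame(disc_rows),
        discordance_minor_allele=pd.DataFrame(minor_rows),
        recoverable_content=recover,
    )
    if config.output_dir:
        out = Path(config.output_dir)
        write_report(report, out)
        write_decisions_tsv(decisions, out / "surrogate_decisions.tsv")
    return ScenarioResult(
        report=report,
        truth=truth,
        designs=designs,
        panels=panels,
        qc_report=qc_report,
        surrogate_decisions=decisions,
        quality=quality,
        target_sample_ids=target_ids,
        donor_sample_ids=donor_ids,
    )


def compare_panel_configs(
    report: EvaluationReport, config_a: str, config_b: str, array: str = "dense"
) -> pd.DataFrame:
    """Per-bin deltas between two panel configurations.

    Positive deltas mean ``config_b`` improves on ``config_a``: higher
    well-imputed percentage, lower overall and minor-allele discordance.
    """
    rows = []
    for table, metric, sign in (
        ("well_imputed_by_panel", "pct_well_imputed", +1.0),
        ("discordance_overall", "discordance_pct", -1.0),
        ("discordance_minor_allele", "discordance_pct", -1.0),
    ):
        df = getattr(report, table)
        if len(df) == 0:
            continue
        sub = df[df["array"] == array]
        a = sub[sub["panel_config"] == config_a].set_index("maf_bin")[metric]
        b = sub[sub["panel_config"] == config_b].set_index("maf_bin")[metric]
        if set(a.index) != set(b.index):
            raise ValueError(f"mismatched MAF-bin grids between configs in {table}")
        for bin_label in a.index:
            rows.append(
                {
                    "metric": metric if table != "discordance_minor_allele" else "minor_allele_discordance_pct",
                    "maf_bin": bin_label,
                    config_a: a[bin_label],
                    config_b: b[bin_label],
                    "delta_improvement": sign * (b[bin_label] - a[bin_label]),
                }
            )
    if not rows:
        raise ValueError("report holds no comparable tables")
    return pd.DataFrame(rows)


def make_fixtures(size: str, seed: int, directory) -> dict:
    """Write a miniature self-contained dataset for unit tests.

    ``tiny`` is 20 samples x 200 sites; ``small`` scales the default
    scenario down by ~4x.  Returns the paths written.
    """
    if size not in ("tiny", "small"):
        raise ValueError("size must be 'tiny' or 'small'")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if size == "tiny":
        sim = SimulationConfig(
            seed=seed,
            chrom_length_bp=2_000_000,
            n_sites=200,
            n_founders=12,
            pop_sizes={"popA": 8, "popB": 6, "popC": 6},
            missing_rate=0.01,
        )
    else:
        sim = SimulationConfig(
            seed=seed,
            chrom_length_bp=5_000_000,
            n_sites=500,
            n_founders=20,
            pop_sizes={"popA": 20, "popB": 20, "popC": 20},
        )
    founders = simulate_founders(sim)
    pops = {p: simulate_population(founders, p, sim) for p in sim.pop_sizes}
    dense = design_dense_array(
        _concat_panels(list(pops.values()), "pooled"), n_select=40 if size == "tiny" else 120
    )
    chip = design_exome_chip(
        [pops["popA"], pops["popB"]], pops["popC"], n_select=30 if size == "tiny" else 80
    )
    obs, truth = genotype_samples(pops["popC"], dense, sim, pops)
    gmap = GeneticMap.uniform(sim.chrom_length_bp)
    paths = {}
    for p, panel in pops.items():
        paths[p] = directory / f"{p}.vcf"
        write_phased_vcf(panel, paths[p])
    paths["observed"] = directory / "observed_dense.vcf"
    write_vcf(obs, paths["observed"])
    paths["map"] = directory / "genetic_map.txt"
    write_genetic_map(gmap, paths["map"])
    for name, design in (("dense", dense), ("chip", chip)):
        paths[name] = directory / f"{name}.manifest.txt"
        with open(paths[name], "w") as fh:
            fh.write("\n".join(design.variant_ids) + "\n")
    paths["config"] = directory / "scenario.cfg"
    save_scenario_config(
        ScenarioConfig(
            simulation=sim,
            n_specific_donors=max(1, sim.pop_sizes["popC"] // 3),
            dense_n_select=40 if size == "tiny" else 120,
            chip_n_select=30 if size == "tiny" else 80,
            legacy_manifest_size=20 if size == "tiny" else 60,
            chip_design_cohort_size=20 if size == "tiny" else 60,
        ),
        paths["config"],
    )
    return paths


# ---- flat key/value scenario-config files ---------------------------------

_SIM_FIELDS = {f.name for f in dataclasses.fields(SimulationConfig)}
_QC_FIELDS = {f.name for f in dataclasses.fields(QcThresholds)}


def save_scenario_config(config: ScenarioConfig, path) -> None:
    with open(path, "w") as fh:
        for f in dataclasses.fields(SimulationConfig):
            v = getattr(config.simulation, f.name)
            if f.name == "pop_sizes":
                v = ",".join(f"{k}:{n}" for k, n in v.items())
            fh.write(f"simulation.{f.name} = {v}\n")
        for f in dataclasses.fields(QcThresholds):
            fh.write(f"qc.{f.name} = {getattr(config.qc, f.name)}\n")
        for name in (
            "n_e",
            "hmm_error_rate",
            "core_bp",
            "buffer_bp",
            "posterior_threshold",
            "n_specific_donors",
            "dense_n_select",
            "dense_min_maf",
            "legacy_manifest_size",
            "chip_n_select",
            "chip_rare_fraction",
            "target_pop",
        ):
            fh.write(f"{name} = {getattr(config, name)}\n")
        fh.write(f"design_pops = {','.join(config.design_pops)}\n")
        fh.write(f"study_arrays = {','.join(config.study_arrays)}\n")
        for cfg, members in config.panel_configs.items():
            fh.write(f"panel_config.{cfg} = {','.join(members)}\n")


def load_scenario_config(path) -> ScenarioConfig:
    raw: dict = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            raw[key.strip()] = val.strip()
    sim_kwargs: dict = {}
    qc_kwargs: dict = {}
    top_kwargs: dict = {}
    panel_configs: dict = {}
    for key, val in raw.items():
        if key.startswith("simulation."):
            name = key.split(".", 1)[1]
            if name not in _SIM_FIELDS:
                raise ValueError(f"unknown simulation key {name!r}")
            if name == "pop_sizes":
                sim_kwargs[name] = {
                    k: int(n) for k, n in (item.split(":") for item in val.split(","))
                }
            elif name in ("seed", "chrom_length_bp", "n_sites", "n_founders"):
                sim_kwargs[name] = int(val)
            elif name == "chrom":
                sim_kwargs[name] = val
            else:
                sim_kwargs[name] = float(val)
        elif key.startswith("qc."):
            name = key.split(".", 1)[1]
            if name not in _QC_FIELDS:
                raise ValueError(f"unknown qc key {name!r}")
            qc_kwargs[name] = int(val) if name == "pca_components" else float(val)
        elif key.startswith("panel_config."):
            panel_configs[key.split(".", 1)[1]] = tuple(val.split(","))
        elif key in ("design_pops", "study_arrays"):
            top_kwargs[key] = tuple(val.split(","))
        elif key in ("core_bp", "buffer_bp", "n_specific_donors", "dense_n_select",
                     "legacy_manifest_size", "chip_n_select"):
            top_kwargs[key] = int(val)
        elif key in ("n_e", "hmm_error_rate", "posterior_threshold", "dense_min_maf",
                     "chip_rare_fraction"):
            top_kwargs[key] = float(val)
        elif key in ("target_pop", "output_dir"):
            top_kwargs[key] = val
        else:
            raise ValueError(f"unknown configuration key {key!r}")
    if panel_configs:
        top_kwargs["panel_configs"] = panel_configs
    return ScenarioConfig(
        simulation=SimulationConfig(**sim_kwargs), qc=QcThresholds(**qc_kwargs), **top_kwargs
    )
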