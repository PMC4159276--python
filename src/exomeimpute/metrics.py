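"""Imputation quality and chip-coverage statistics.

Definitions used throughout:

* **info** — IMPUTE-style ratio-of-variances certainty measure.  With
  per-sample dosage ``e_i = p_i(1) + 2 p_i(2)``, ``f_i = p_i(1) + 4 p_i(2)``
  and estimated allele frequency ``theta = sum(e_i) / 2N``::

      info = 1 - sum(f_i - e_i^2) / (2N theta (1 - theta))

  clipped to ``[0, 1]``, and defined as 1 when ``theta`` is 0 or 1.
* **call rate** — fraction of samples with a non-missing thresholded call.
* **well-imputed** — info >= 0.3 AND call rate >= 0.95 (both inclusive).
* **MAF bins** — monomorphic (0), rare (0 < MAF <= 0.01), low-frequency
  (0.01 < MAF < 0.05), common (MAF >= 0.05).
* **overall concordance** — matching calls over jointly non-missing calls.
* **minor-allele concordance** — restricted to observed genotypes carrying
  at least one minor allele, at well-imputed rare and low-frequency SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING, ArrayDesign, GenotypeMatrix, HaplotypePanel

MAF_BIN_LABELS = ("monomorphic", "rare", "low_frequency", "common")

INFO_MIN = 0.3
CALL_RATE_MIN = 0.95


def maf_bin(maf: float) -> str:
    """Frequency category of a site.  Bins partition [0, 0.5] exactly."""
    if not 0.0 <= maf <= 0.5:
        raise ValueError(f"MAF must be in [0, 0.5], got {maf}")
    if maf == 0.0:
        return "monomorphic"
    if maf <= 0.01:
        return "rare"
    if maf < 0.05:
        return "low_frequency"
    return "common"


@dataclass(frozen=True)
class SnpQuality:
    info: float
    call_rate: float

    @property
    def well_imputed(self) -> bool:
        return classify_well_imputed(self.info, self.call_rate)


def info_score(posteriors_at_snp: np.ndarray) -> float:
    """IMPUTE-style info measure for one SNP's posterior triples (N x 3)."""
    p = np.asarray(posteriors_at_snp, dtype=np.float64)
    if p.ndim != 2 or p.shape[1] != 3 or p.shape[0] < 1:
        raise ValueError("expected an N x 3 array of posterior triples")
    e = p[:, 1] + 2.0 * p[:, 2]
    f = p[:, 1] + 4.0 * p[:, 2]
    n = p.shape[0]
    theta = e.sum() / (2.0 * n)
    if theta <= 0.0 or theta >= 1.0:
        return 1.0
    info = 1.0 - (f - e**2).sum() / (2.0 * n * theta * (1.0 - theta))
    return float(min(max(info, 0.0), 1.0))


def snp_call_rate(calls_at_snp: np.ndarray) -> float:
    """Fraction of samples with a non-MISSING thresholded genotype."""
    c = np.asarray(calls_at_snp)
    if c.size < 1:
        raise ValueError("need at least one sample")
    return float((c != MISSING).mean())


def classify_well_imputed(info: float, call_rate: float) -> bool:
    """info >= 0.3 and call rate >= 0.95, both boundaries inclusive."""
    return info >= INFO_MIN and call_rate >= CALL_RATE_MIN


def maf_of(calls_at_site: np.ndarray) -> float:
    """Minor-allele frequency from observed calls (het contributes one of each)."""
    c = np.asarray(calls_at_site)
    called = c != MISSING
    if not called.any():
        raise ValueError("all calls MISSING; MAF undefined")
    f = c[called].sum() / (2.0 * called.sum())
    return float(min(f, 1.0 - f))


def snp_quality_table(probs: np.ndarray, calls: np.ndarray) -> list[SnpQuality]:
    """Per-variant :class:`SnpQuality` from an N x M x 3 tensor and N x M calls."""
    return [
        SnpQuality(info=info_score(probs[:, j, :]), call_rate=snp_call_rate(calls[:, j]))
        for j in range(probs.shape[1])
    ]


def overall_concordance(
    imputed: np.ndarray, observed: np.ndarray, bins: list[str]
) -> pd.DataFrame:
    """Per-MAF-bin concordance of thresholded calls against observed genotypes.

    ``imputed`` and ``observed`` are aligned N x M call matrices over the
    evaluation variant set; ``bins`` labels each variant.  The denominator
    counts jointly non-MISSING calls; a bin with empty denominator is
    flagged with NaN.
    """
    if imputed.shape != observed.shape:
        raise ValueError("imputed and observed call matrices must be aligned")
    rows = []
    bins_arr = np.array(bins)
    for b in MAF_BIN_LABELS:
        cols = np.flatnonzero(bins_arr == b)
        if cols.size == 0:
            continue
        a = imputed[:, cols]
        o = observed[:, cols]
        joint = (a != MISSING) & (o != MISSING)
        n = int(joint.sum())
        n_match = int((a[joint] == o[joint]).sum())
        rows.append(
            {
                "maf_bin": b,
                "n_genotypes": n,
                "n_discordant": n - n_match,
                "concordance": (n_match / n) if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


def minor_allele_concordance(
    imputed: np.ndarray, observed: np.ndarray, bins: list[str]
) -> dict:
    """Concordance over observed minor-allele genotypes at rare/low-frequency SNPs.

    The denominator is observed genotypes (het or minor-allele homozygote)
    with a non-MISSING imputed call, across variants whose bin is ``rare``
    or ``low_frequency``; the numerator is those imputed identically.
    Returns per-bin and pooled counts; empty denominators yield NaN.
    """
    if imputed.shape != observed.shape:
        raise ValueError("imputed and observed call matrices must be aligned")
    bins_arr = np.array(bins)
    out: dict = {}
    pooled_n = pooled_match = 0
    for b in ("rare", "low_frequency"):
        cols = np.flatnonzero(bins_arr == b)
        n = n_match = 0
        for j in cols:
            o = observed[:, j]
            a = imputed[:, j]
            called = o != MISSING
            if not called.any():
                continue
            f = o[called].sum() / (2.0 * called.sum())
            minor_hom = 2 if f <= 0.5 else 0
            carrier = called & ((o == 1) | (o == minor_hom)) & (a != MISSING)
            n += int(carrier.sum())
            n_match += int((a[carrier] == o[carrier]).sum())
        out[b] = {
            "n_minor_allele_genotypes": n,
            "n_discordant": n - n_match,
            "concordance": (n_match / n) if n else np.nan,
        }
        pooled_n += n
        pooled_match += n_match
    out["pooled"] = {
        "n_minor_allele_genotypes": pooled_n,
        "n_discordant": pooled_n - pooled_match,
        "concordance": (pooled_match / pooled_n) if pooled_n else np.nan,
    }
    return out


def chip_monomorphic_fraction(genotypes: GenotypeMatrix, chip: ArrayDesign) -> float:
    """Fraction of chip sites monomorphic in the given cohort's genotypes."""
    idx = genotypes.vid_index()
    n_mono = 0
    for vid in chip.variant_ids:
        j = idx.get(vid)
        if j is None:
            raise ValueError(f"cohort genotypes missing chip site {vid}")
        n_mono += maf_of(genotypes.genotypes[:, j]) == 0.0
    return n_mono / len(chip.variant_ids)


def coverage_accounting(
    chip: ArrayDesign,
    panels: list[HaplotypePanel],
    target_obs: GenotypeMatrix,
    population: str = "target",
) -> pd.DataFrame:
    """Chip-content accounting: target-population MAF bin x reference coverage.

    A chip SNP is *covered* when present in at least one reference panel
    (and could in principle be imputed); bins come from the target
    population's observed genotypes.  Counts conserve: they sum to the chip
    size over the bin x coverage grid.
    """
    panel_vids = set()
    for p in panels:
        panel_vids.update(p.vids)
    obs_idx = target_obs.vid_index()
    rows: dict = {}
    for vid in chip.variant_ids:
        j = obs_idx.get(vid)
        if j is None:
            raise ValueError(f"target observations missing chip site {vid}")
        b = maf_bin(maf_of(target_obs.genotypes[:, j]))
        covered = vid in panel_vids
        key = (b, covered)
        rows[key] = rows.get(key, 0) + 1
    recs = [
        {"population": population, "maf_bin": b, "covered": cov, "n_snps": n}
        for (b, cov), n in sorted(rows.items(), key=lambda kv: (MAF_BIN_LABELS.index(kv[0][0]), kv[0][1]))
    ]
    return pd.DataFrame(recs, columns=["population", "maf_bin", "covered", "n_snps"])


def recoverable_content(
    truth,
    array: ArrayDesign,
    chip: ArrayDesign,
    quality_by_panel: dict,
    eval_vids: dict | None = None,
) -> pd.DataFrame:
    """Exonic-content recoverability, per frequency group and panel config.

    Exonic sites polymorphic in the target truth are grouped into
    rare/low-frequency (pooled) and common; per group the table counts the
    total, the overlap with the study ``array``, presence on the ``chip``,
    and — per panel configuration — sites well-imputed among those *not*
    on the study array (array-overlap sites are excluded from the imputed
    counts).  ``quality_by_panel`` maps config name -> {vid: SnpQuality}.
    """
    g = truth.true_genotypes
    array_set = set(array.variant_ids)
    chip_set = set(chip.variant_ids)
    groups = {"rare_low": [], "common": []}
    for j, v in enumerate(g.variants):
        if not truth.exonic_flags.get(v.vid, False):
            continue
        b = maf_bin(maf_of(g.genotypes[:, j]))
        if b == "monomorphic":
            continue
        groups["rare_low" if b in ("rare", "low_frequency") else "common"].append(v.vid)
    rows = []
    for cfg, qual in quality_by_panel.items():
        for grp, vids in groups.items():
            n_total = len(vids)
            n_array = sum(v in array_set for v in vids)
            n_chip = sum(v in chip_set for v in vids)
            n_imp = sum(
                1
                for v in vids
                if v not in array_set and v in qual and qual[v].well_imputed
            )
            rows.append(
                {
                    "panel_config": cfg,
                    "freq_group": grp,
                    "n_exonic": n_total,
                    "n_on_array": n_array,
                    "n_on_chip": n_chip,
                    "n_imputed": n_imp,
                    "pct_recovered": 100.0 * (n_array + n_imp) / n_total if n_total else np.nan,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "panel_config",
            "freq_group",
            "n_exonic",
            "n_on_array",
            "n_on_chip",
            "n_imputed",
            "pct_recovered",
        ],
    )


@dataclass
class EvaluationReport:
    """The pipeline's report tables (see :data:`exomeimpute.io.REPORT_TABLES`)."""

    coverage_by_maf: pd.DataFrame = field(default_factory=pd.DataFrame)
    well_imputed_by_panel: pd.DataFrame = field(default_factory=pd.DataFrame)
    discordance_overall: pd.DataFrame = field(default_factory=pd.DataFrame)
    discordance_minor_allele: pd.DataFrame = field(default_factory=pd.DataFrame)
    recoverable_content: pd.DataFrame = field(default_factory=pd.DataFrame)
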