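"""Array quality control: SNP pseudo-clean filtering, sample screening, final per-population SNP QC.

The three-step procedure:

* **Step A** (SNPs, all samples jointly, per array): metadata validations —
  (i) unknown/duplicate coordinates, (ii) disallowed chromosome,
  (iii) unknown strand, (iv) conflicting allele designation across arrays —
  then (v) cross-array genotype concordance < ``cross_array_concordance_min``,
  (vi) missingness > ``snp_missing_max``, (vii) Hardy–Weinberg exact-test
  p < ``hwe_p_prelim``.
* **Step B** (samples): (i) missingness > ``sample_missing_max``,
  (ii) excessive pairwise identity-by-state (the lower-call-rate member of
  each offending pair is dropped), (iii) PCA outliers relative to the
  sample's own population.
* **Step C** (SNPs, per population): missingness > ``snp_missing_max`` or
  HWE p < ``hwe_p_final`` in any population.

Removals are attributed to the first rule that triggers them, in the fixed
order A(i)–(vii), B(i)–(iii), C.miss, C.hwe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import MISSING, GenotypeMatrix

_ALLOWED_CHROMS = {str(c) for c in range(1, 23)} | {"X", "Y"} | {
    f"chr{c}" for c in range(1, 23)
} | {"chrX", "chrY"}


@dataclass
class QcThresholds:
    """Cutoffs for the three QC steps (defaults as used throughout)."""

    snp_missing_max: float = 0.05
    hwe_p_prelim: float = 1e-8
    hwe_p_final: float = 1e-3
    sample_missing_max: float = 0.02
    cross_array_concordance_min: float = 0.995
    ibs_maf_min: float = 0.05
    ibs_excess_threshold: float = 0.9
    pca_sd_k: float = 6.0
    pca_components: int = 2

    def __post_init__(self) -> None:
        for name in (
            "snp_missing_max",
            "sample_missing_max",
            "cross_array_concordance_min",
            "ibs_maf_min",
            "ibs_excess_threshold",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("hwe_p_prelim", "hwe_p_final"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0,1), got {v}")


@dataclass
class QcReport:
    """Removal bookkeeping: first-triggering reason per SNP/sample, step survivor counts."""

    removed_snps: dict = field(default_factory=dict)  # (array, vid) -> reason code
    removed_samples: dict = field(default_factory=dict)  # sample_id -> reason code
    surviving_counts: dict = field(default_factory=dict)  # step label -> counts

    def snp_reason(self, array: str, vid: str) -> str | None:
        return self.removed_snps.get((array, vid))


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact two-sided Hardy–Weinberg test p-value.

    Conditions on the allele-count margin: the p-value sums the conditional
    probabilities of every heterozygote count (same margin, same parity)
    whose probability does not exceed that of the observed table.
    Monomorphic sites return 1.0.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("total genotype count must be >= 1")
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    if n_rare == 0:
        return 1.0
    # log P(het = h | margin) up to a constant, via lgamma
    def logp(h: int) -> float:
        hom_r = (n_rare - h) // 2
        hom_c = n - hom_r - h
        return (
            h * math.log(2.0)
            - math.lgamma(h + 1)
            - math.lgamma(hom_r + 1)
            - math.lgamma(hom_c + 1)
        )

    hets = range(n_rare % 2, n_rare + 1, 2)
    logs = np.array([logp(h) for h in hets])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    obs = (n_het - n_rare % 2) // 2
    p = float(probs[probs <= probs[obs] * (1 + 1e-12)].sum())
    return min(p, 1.0)


def snp_missingness(matrix: GenotypeMatrix) -> np.ndarray:
    """Per-variant proportion of MISSING calls."""
    if matrix.n_samples == 0:
        raise ValueError("empty genotype matrix")
    return (matrix.genotypes == MISSING).mean(axis=0)


def sample_missingness(matrix: GenotypeMatrix) -> np.ndarray:
    return (matrix.genotypes == MISSING).mean(axis=1)


def hwe_pvalues(matrix: GenotypeMatrix, rows: np.ndarray | None = None) -> np.ndarray:
    """HWE exact-test p-value per variant over the given sample rows."""
    g = matrix.genotypes if rows is None else matrix.genotypes[rows]
    out = np.ones(matrix.n_variants)
    for j in range(matrix.n_variants):
        col = g[:, j]
        n0 = int((col == 0).sum())
        n1 = int((col == 1).sum())
        n2 = int((col == 2).sum())
        if n0 + n1 + n2 > 0:
            out[j] = hwe_exact_test(n0, n1, n2)
    return out


def cross_array_concordance(m1: GenotypeMatrix, m2: GenotypeMatrix) -> dict:
    """Per-shared-variant genotype concordance between two arrays.

    Shared variants are matched by vid with identical allele pairs (an
    allele conflict is a step A(iv) removal, not a concordance failure).
    The denominator counts samples non-MISSING on both arrays; a variant
    with zero joint calls maps to ``nan``.
    """
    common = [s for s in m1.sample_ids if s in set(m2.sample_ids)]
    if not common:
        raise ValueError("no shared samples between arrays")
    r1 = [m1.sample_ids.index(s) for s in common]
    r2 = [m2.sample_ids.index(s) for s in common]
    idx2 = m2.vid_index()
    out: dict = {}
    for j1, v in enumerate(m1.variants):
        j2 = idx2.get(v.vid)
        if j2 is None:
            continue
        w = m2.variants[j2]
        if (v.ref, v.alt) != (w.ref, w.alt):
            continue  # allele conflict handled by A(iv)
        a = m1.genotypes[r1, j1]
        b = m2.genotypes[r2, j2]
        joint = (a != MISSING) & (b != MISSING)
        out[v.vid] = float((a[joint] == b[joint]).mean()) if joint.any() else float("nan")
    return out


def _maf_from_genotypes(g: np.ndarray) -> np.ndarray:
    called = g != MISSING
    alt = np.where(called, g, 0).sum(axis=0)
    tot = 2 * called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)
    return np.minimum(f, 1 - f)


def ibs_matrix(matrix: GenotypeMatrix, maf_min: float = 0.05) -> np.ndarray:
    """Pairwise identity-by-state over SNPs with MAF >= ``maf_min``.

    Entry (i, j) is the mean of ``(2 - |g_i - g_j|)/2`` over jointly
    non-MISSING filtered SNPs; symmetric with unit diagonal.  Pairs with no
    jointly-called SNP are ``nan`` (flagged to the caller).
    """
    if matrix.n_samples < 2:
        raise ValueError("IBS needs at least 2 samples")
    maf = _maf_from_genotypes(matrix.genotypes)
    keep = np.flatnonzero(np.nan_to_num(maf) >= maf_min)
    g = matrix.genotypes[:, keep].astype(np.float64)
    called = g != MISSING
    n = matrix.n_samples
    out = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            joint = called[i] & called[j]
            if not joint.any():
                out[i, j] = out[j, i] = np.nan
                continue
            s = np.mean((2.0 - np.abs(g[i, joint] - g[j, joint])) / 2.0)
            out[i, j] = out[j, i] = s
    return out


def flag_excess_ibs(
    ibs: np.ndarray, call_rates: np.ndarray, sample_ids: list[str], threshold: float = 0.9
) -> set:
    """Samples to drop for excessive IBS sharing.

    Offending pairs are visited by descending IBS; in each still-offending
    pair the lower-call-rate member is removed (ties: the lexicographically
    later sample id).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0,1)")
    n = len(sample_ids)
    pairs = [
        (ibs[i, j], i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if np.isfinite(ibs[i, j]) and ibs[i, j] > threshold
    ]
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    removed: set = set()
    for _, i, j in pairs:
        if sample_ids[i] in removed or sample_ids[j] in removed:
            continue
        if call_rates[i] > call_rates[j]:
            removed.add(sample_ids[j])
        elif call_rates[j] > call_rates[i]:
            removed.add(sample_ids[i])
        else:
            removed.add(max(sample_ids[i], sample_ids[j]))
    return removed


def pca_flag_outliers(
    matrix: GenotypeMatrix,
    labels: list[str],
    maf_min: float = 0.05,
    n_components: int = 2,
    k_sd: float = 6.0,
) -> set:
    """Samples whose principal-component scores stray from their population.

    Genotypes are encoded 0/1/2 with MISSING as -1, filtered to
    MAF >= ``maf_min``, column-centered; the sample covariance matrix is
    eigendecomposed and samples projected onto the top ``n_components``.
    A sample is flagged when any of its scores lies more than ``k_sd``
    standard deviations from its own population's mean on that component.
    """
    if matrix.n_samples < n_components + 1:
        raise ValueError("not enough samples for the requested number of components")
    maf = _maf_from_genotypes(matrix.genotypes)
    keep = np.flatnonzero(np.nan_to_num(maf) >= maf_min)
    x = matrix.genotypes[:, keep].astype(np.float64)  # MISSING stays -1 by design
    x -= x.mean(axis=0, keepdims=True)
    if not np.any(x.std(axis=0) > 0):
        raise ValueError("degenerate (zero-variance) genotype input for PCA")
    cov = np.cov(x, rowvar=True)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1][:n_components]
    scores = v[:, order] * np.sqrt(np.maximum(w[order], 0.0))
    removed: set = set()
    for pop in sorted(set(labels)):
        rows = np.flatnonzero(np.array(labels) == pop)
        sub = scores[rows]
        mu = sub.mean(axis=0)
        sd = sub.std(axis=0)
        sd = np.where(sd > 0, sd, np.inf)
        bad = np.any(np.abs(sub - mu) > k_sd * sd, axis=1)
        for r in rows[bad]:
            removed.add(matrix.sample_ids[r])
    return removed


def _first_trigger(store: dict, key, reason: str) -> None:
    store.setdefault(key, reason)


def run_qc(
    matrices: dict,
    thresholds: QcThresholds | None = None,
    labels: list[str] | None = None,
) -> tuple[dict, QcReport]:
    """Run the full A -> B -> C procedure over per-array genotype matrices.

    ``matrices`` maps array name to :class:`GenotypeMatrix` over a shared
    sample set; ``labels`` gives each sample's population (defaults to one
    pooled population).  Returns the cleaned matrices and a
    :class:`QcReport`; raises if no sample or no SNP survives.
    """
    th = thresholds or QcThresholds()
    names = list(matrices)
    sample_ids = matrices[names[0]].sample_ids
    for nm in names[1:]:
        if matrices[nm].sample_ids != sample_ids:
            raise ValueError("QC input matrices must share an identical sample set")
    labels = labels or ["all"] * len(sample_ids)
    report = QcReport()
    drop_snps: dict = {nm: {} for nm in names}

    # ---- Step A: SNP pseudo-clean, all samples jointly --------------------
    allele_by_vid: dict = {}
    for nm in names:
        m = matrices[nm]
        seen_pos: set = set()
        for v in m.variants:
            if (v.chrom, v.pos) in seen_pos:
                _first_trigger(drop_snps[nm], v.vid, "A.i")
            seen_pos.add((v.chrom, v.pos))
            if v.chrom not in _ALLOWED_CHROMS:
                _first_trigger(drop_snps[nm], v.vid, "A.ii")
            # A.iii (unknown strand) cannot arise with explicit allele records;
            # the reason code is reserved for real manifests.
            prev = allele_by_vid.get(v.vid)
            if prev is not None and prev != (v.ref, v.alt):
                for nm2 in names:
                    if v.vid in matrices[nm2].vid_index():
                        _first_trigger(drop_snps[nm2], v.vid, "A.iv")
            allele_by_vid.setdefault(v.vid, (v.ref, v.alt))
    if len(names) >= 2:
        for a in range(len(names)):
            for b in range(a + 1, len(names)):
                conc = cross_array_concordance(matrices[names[a]], matrices[names[b]])
                for vid, c in conc.items():
                    if np.isfinite(c) and c < th.cross_array_concordance_min:
                        _first_trigger(drop_snps[names[a]], vid, "A.v")
                        _first_trigger(drop_snps[names[b]], vid, "A.v")
    for nm in names:
        m = matrices[nm]
        miss = snp_missingness(m)
        hwe = hwe_pvalues(m)
        for j, v in enumerate(m.variants):
            if miss[j] > th.snp_missing_max:
                _first_trigger(drop_snps[nm], v.vid, "A.vi")
            if hwe[j] < th.hwe_p_prelim:
                _first_trigger(drop_snps[nm], v.vid, "A.vii")

    stage_a = {
        nm: matrices[nm].subset_variants(
            [j for j, v in enumerate(matrices[nm].variants) if v.vid not in drop_snps[nm]]
        )
        for nm in names
    }
    report.surviving_counts["A"] = {nm: stage_a[nm].n_variants for nm in names}

    # ---- Step B: sample QC ------------------------------------------------
    drop_samples: dict = {}
    n_calls = np.zeros(len(sample_ids))
    n_tot = 0
    for nm in names:
        n_calls += (stage_a[nm].genotypes != MISSING).sum(axis=1)
        n_tot += stage_a[nm].n_variants
    call_rate = n_calls / max(n_tot, 1)
    for i, s in enumerate(sample_ids):
        if 1.0 - call_rate[i] > th.sample_missing_max:
            _first_trigger(drop_samples, s, "B.miss")
    primary = stage_a[names[0]]  # IBS/PCA screened on the densest (first) array
    ibs = ibs_matrix(primary, maf_min=th.ibs_maf_min)
    for s in flag_excess_ibs(ibs, call_rate, sample_ids, th.ibs_excess_threshold):
        _first_trigger(drop_samples, s, "B.ibs")
    for s in pca_flag_outliers(
        primary, labels, maf_min=th.ibs_maf_min, n_components=th.pca_components, k_sd=th.pca_sd_k
    ):
        _first_trigger(drop_samples, s, "B.pca")
    keep_rows = [i for i, s in enumerate(sample_ids) if s not in drop_samples]
    if not keep_rows:
        raise ValueError("QC removed every sample")
    stage_b = {nm: stage_a[nm].subset_samples(keep_rows) for nm in names}
    kept_labels = [labels[i] for i in keep_rows]
    report.surviving_counts["B"] = {"samples": len(keep_rows)}

    # ---- Step C: per-population SNP QC ------------------------------------
    clean: dict = {}
    lab_arr = np.array(kept_labels)
    for nm in names:
        m = stage_b[nm]
        bad: dict = {}
        for pop in sorted(set(kept_labels)):
            rows = np.flatnonzero(lab_arr == pop)
            sub = m.genotypes[rows]
            miss = (sub == MISSING).mean(axis=0)
            hwe = hwe_pvalues(m, rows=rows)
            for j, v in enumerate(m.variants):
                if miss[j] > th.snp_missing_max:
                    _first_trigger(bad, v.vid, "C.miss")
                elif hwe[j] < th.hwe_p_final:
                    _first_trigger(bad, v.vid, "C.hwe")
        for vid, reason in bad.items():
            _first_trigger(drop_snps[nm], vid, reason)
        keep = [j for j, v in enumerate(m.variants) if v.vid not in bad]
        if not keep:
            raise ValueError(f"QC removed every SNP on array {nm!r}")
        clean[nm] = m.subset_variants(keep)
    report.surviving_counts["C"] = {nm: clean[nm].n_variants for nm in names}

    for nm in names:
        for vid, reason in drop_snps[nm].items():
            report.removed_snps[(nm, vid)] = reason
    report.removed_samples = dict(drop_samples)
    return clean, report
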