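"""Li–Stephens haplotype-copying imputation engine.

A phased target haplotype is modelled as an imperfect mosaic of the
reference haplotypes.  The hidden state is the reference haplotype being
copied; between adjacent typed sites separated by ``d`` cM the chain
switches with probability ``rho = 1 - exp(-4 Ne d / (100 k))`` (uniform
over the ``k`` reference haplotypes on a switch), and the copied allele is
observed with per-site mismatch probability ``theta``.  Forward–backward
over the typed sites gives the copying posterior; at untyped sites the
allele-1 probability is the posterior-weighted mean of the reference
alleles, with the copying posterior interpolated linearly in genetic
distance between the flanking typed sites (no transitions are charged
within the untyped gap).

Genotype posteriors combine a sample's two haplotype runs under
independence, imputation is performed per buffered genomic chunk with only
core-interval results retained, and discrete calls threshold the posterior
(argmax class if it reaches the threshold, else missing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    MISSING,
    FormatError,
    GeneticMap,
    GenotypeMatrix,
    HaplotypePanel,
    PosteriorTensor,
    VariantRecord,
)


@dataclass
class HmmParams:
    """Copying-model parameters.

    ``n_e`` is the effective population size scaling the recombination rate
    (default 15000); ``error_rate`` is the per-site copying mismatch
    probability theta.  The reference haplotype count ``k_ref`` is taken
    from the panel at run time.
    """

    n_e: float = 15000.0
    error_rate: float = 1e-3
    map: GeneticMap | None = None

    def __post_init__(self) -> None:
        if self.n_e <= 0:
            raise ValueError("n_e must be positive")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")


@dataclass
class ChunkPlan:
    """Buffered genomic intervals whose cores tile the chromosome."""

    intervals: list  # (core_start, core_end, buffer_start, buffer_end), bp, 1-based inclusive

    def __post_init__(self) -> None:
        prev_end = 0
        for cs, ce, bs, be in self.intervals:
            if cs != prev_end + 1:
                raise ValueError("chunk cores must tile the chromosome without gaps/overlap")
            if not (bs <= cs <= ce <= be):
                raise ValueError("buffer must contain its core")
            prev_end = ce


def make_chunk_plan(chrom_length: int, core_bp: int = 5_000_000, buffer_bp: int = 5_000_000) -> ChunkPlan:
    """Tile ``[1, chrom_length]`` with ``core_bp`` cores plus clipped buffers."""
    if core_bp <= 0:
        raise ValueError("core_bp must be positive")
    intervals = []
    start = 1
    while start <= chrom_length:
        end = min(start + core_bp - 1, chrom_length)
        intervals.append((start, end, max(1, start - buffer_bp), min(chrom_length, end + buffer_bp)))
        start = end + 1
    return ChunkPlan(intervals)


def _switch_probs(cm: np.ndarray, n_e: float, k_ref: int) -> np.ndarray:
    d = np.diff(cm)
    return 1.0 - np.exp(-4.0 * n_e * d / (100.0 * k_ref))


def _normalize(v: np.ndarray) -> tuple[np.ndarray, float]:
    s = v.sum()
    if s <= 0.0:  # all-mismatch dead end (theta == 0); recover with a flat state
        return np.full_like(v, 1.0 / v.size), 1.0
    return v / s, s


def ls_haploid_posteriors(
    target_hap: np.ndarray,
    typed_vids: list[str],
    ref: HaplotypePanel,
    params: HmmParams,
) -> np.ndarray:
    """Posterior allele-1 probability at every reference site for one haplotype.

    ``target_hap`` holds the 0/1 alleles observed at ``typed_vids`` (all of
    which must exist in ``ref``).  Returns a length-``M`` vector over the
    reference panel's sites.
    """
    if len(typed_vids) == 0:
        raise ValueError("at least one typed site is required")
    target_hap = np.asarray(target_hap, dtype=np.int8)
    idx = ref.vid_index()
    missing = [v for v in typed_vids if v not in idx]
    if missing:
        raise ValueError(f"typed sites absent from reference panel: {missing[:5]}")
    typed_cols = np.array([idx[v] for v in typed_vids])
    order = np.argsort(typed_cols)
    typed_cols = typed_cols[order]
    obs = target_hap[order]

    k = ref.n_haplotypes
    h_typed = ref.haplotypes[:, typed_cols]  # k x T
    theta = params.error_rate
    emit = np.where(h_typed == obs[None, :], 1.0 - theta, theta)  # k x T
    gmap = params.map or GeneticMap.uniform(int(ref.positions[-1]))
    cm = np.asarray(gmap.cm_at(ref.positions.astype(np.float64)))
    rho = _switch_probs(cm[typed_cols], params.n_e, k)

    T = typed_cols.size
    fwd = np.empty((T, k))
    f, _ = _normalize(emit[:, 0] / k)
    fwd[0] = f
    for t in range(1, T):
        f = emit[:, t] * ((1.0 - rho[t - 1]) * fwd[t - 1] + rho[t - 1] / k)
        fwd[t], _ = _normalize(f)
    bwd = np.empty((T, k))
    bwd[T - 1] = 1.0 / k
    for t in range(T - 2, -1, -1):
        eb = emit[:, t + 1] * bwd[t + 1]
        b = (1.0 - rho[t]) * eb + rho[t] * eb.mean()
        bwd[t], _ = _normalize(b)
    gamma = fwd * bwd
    gamma /= gamma.sum(axis=1, keepdims=True)

    # read off p(allele=1) at all reference sites, interpolating the copying
    # posterior linearly in cM between flanking typed sites
    m = ref.n_variants
    sites = np.arange(m)
    right = np.searchsorted(typed_cols, sites, side="left")
    left_c = np.clip(right - 1, 0, T - 1)
    right_c = np.clip(right, 0, T - 1)
    cm_typed = cm[typed_cols]
    span = cm_typed[right_c] - cm_typed[left_c]
    with np.errstate(invalid="ignore", divide="ignore"):
        lam = np.where(span > 0, (cm_typed[right_c] - cm) / np.maximum(span, 1e-300), 0.5)
    lam = np.clip(lam, 0.0, 1.0)
    lam[right <= 0] = 1.0  # before first typed site: use first gamma
    lam[right >= T] = 1.0  # after last typed site: left_c == right_c == T-1
    at_typed = (right < T) & (typed_cols[right_c] == sites)
    lam[at_typed] = 0.0  # use that typed site's own gamma (right_c)
    gamma_all = lam[:, None] * gamma[left_c] + (1.0 - lam)[:, None] * gamma[right_c]
    p1 = np.einsum("mk,km->m", gamma_all, ref.haplotypes.astype(np.float64))
    return np.clip(p1, 0.0, 1.0)


def _genotype_posteriors(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Combine two independent haploid allele probabilities into triples."""
    q1, q2 = 1.0 - p1, 1.0 - p2
    probs = np.stack([q1 * q2, p1 * q2 + q1 * p2, p1 * p2], axis=-1)
    probs /= probs.sum(axis=-1, keepdims=True)  # guard float drift
    return probs


def impute_genotypes(
    targets: HaplotypePanel,
    ref: HaplotypePanel,
    params: HmmParams,
    plan: ChunkPlan | None = None,
) -> PosteriorTensor:
    """Impute genotype posteriors at every reference site for phased targets.

    ``targets`` carries the study haplotypes typed at array sites only.
    Each chunk is imputed with its buffer; only core-interval results are
    retained, so a plan whose cores tile the chromosome yields a complete
    tensor.
    """
    if plan is None:
        plan = make_chunk_plan(int(ref.positions[-1]))
    ref_pos = ref.positions
    tgt_pos = targets.positions
    n = len(targets.sample_ids)
    m = ref.n_variants
    probs = np.full((n, m, 3), np.nan)
    covered = np.zeros(m, dtype=bool)
    for cs, ce, bs, be in plan.intervals:
        ref_in = np.flatnonzero((ref_pos >= bs) & (ref_pos <= be))
        core_in = np.flatnonzero((ref_pos >= cs) & (ref_pos <= ce))
        if core_in.size == 0:
            continue
        tgt_in = np.flatnonzero((tgt_pos >= bs) & (tgt_pos <= be))
        if tgt_in.size == 0:
            raise FormatError(
                f"no typed sites fall inside buffered chunk [{bs},{be}]; enlarge the buffer"
            )
        sub_ref = ref.subset_variants(ref_in)
        typed_vids = [targets.variants[j].vid for j in tgt_in]
        core_local = np.searchsorted(ref_in, core_in)
        for s in range(n):
            p1 = ls_haploid_posteriors(
                targets.haplotypes[2 * s, tgt_in], typed_vids, sub_ref, params
            )
            p2 = ls_haploid_posteriors(
                targets.haplotypes[2 * s + 1, tgt_in], typed_vids, sub_ref, params
            )
            probs[s, core_in, :] = _genotype_posteriors(p1[core_local], p2[core_local])
        covered[core_in] = True
    if not covered.all():
        raise FormatError("chunk plan does not cover every reference site")
    return PosteriorTensor(probs=probs)


def threshold_calls(posteriors: PosteriorTensor, threshold: float = 0.90) -> "GenotypeMatrixLike":
    """Discrete calls: argmax class if its posterior reaches ``threshold``, else MISSING."""
    if not (1.0 / 3.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (1/3, 1]")
    p = posteriors.probs
    best = p.argmax(axis=2)
    calls = np.where(p.max(axis=2) >= threshold - 1e-12, best, MISSING).astype(np.int8)
    return calls


def calls_to_matrix(calls: np.ndarray, variants: list[VariantRecord], sample_ids: list[str]) -> GenotypeMatrix:
    return GenotypeMatrix(variants=list(variants), genotypes=calls, sample_ids=list(sample_ids))


def merge_panels(panel_a: HaplotypePanel, panel_b: HaplotypePanel, params: HmmParams) -> HaplotypePanel:
    """Merge two reference panels over the union of their sites.

    At sites absent from one panel, that panel's haplotypes receive the
    modal allele of their own copying posterior computed against the other
    panel (reciprocal cross-imputation, a single deterministic pass each
    way; posterior ties resolve to allele 0).  The merged panel has no
    missing alleles.
    """
    ia, ib = panel_a.vid_index(), panel_b.vid_index()
    shared = [v.vid for v in panel_a.variants if v.vid in ib]
    for vid in shared:
        va, vb = panel_a.variants[ia[vid]], panel_b.variants[ib[vid]]
        if (va.ref, va.alt) != (vb.ref, vb.alt) or va.pos != vb.pos:
            raise FormatError(f"allele/position conflict at shared variant {vid}")
    union: dict[str, VariantRecord] = {}
    for v in list(panel_a.variants) + list(panel_b.variants):
        union.setdefault(v.vid, v)
    variants = sorted(union.values(), key=lambda v: v.pos)
    m = len(variants)
    col = {v.vid: j for j, v in enumerate(variants)}

    def fill(own: HaplotypePanel, other: HaplotypePanel, own_idx: dict) -> np.ndarray:
        out = np.empty((own.n_haplotypes, m), dtype=np.int8)
        exclusive_other = [v.vid for v in other.variants if v.vid not in own_idx]
        for v in own.variants:
            out[:, col[v.vid]] = own.haplotypes[:, own_idx[v.vid]]
        if not exclusive_other:
            return out
        other_idx = other.vid_index()
        typed = [v.vid for v in own.variants if v.vid in other_idx]
        ex_cols = np.array([other_idx[v] for v in exclusive_other])
        if typed:
            own_typed_cols = [own_idx[v] for v in typed]
            for h in range(own.n_haplotypes):
                p1 = ls_haploid_posteriors(
                    own.haplotypes[h, own_typed_cols], typed, other, params
                )
                alleles = (p1[ex_cols] > 0.5).astype(np.int8)
                for vid, a in zip(exclusive_other, alleles):
                    out[h, col[vid]] = a
        else:  # no shared sites: fall back to the other panel's major allele
            major = (other.haplotypes[:, ex_cols].mean(axis=0) > 0.5).astype(np.int8)
            for vid, a in zip(exclusive_other, major):
                out[:, col[vid]] = a
        return out

    merged = np.vstack([fill(panel_a, panel_b, ia), fill(panel_b, panel_a, ib)])
    return HaplotypePanel(
        variants=variants,
        haplotypes=merged,
        sample_ids=list(panel_a.sample_ids) + list(panel_b.sample_ids),
        panel_name=f"{panel_a.panel_name}+{panel_b.panel_name}",
    )
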