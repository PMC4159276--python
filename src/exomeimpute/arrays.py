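"""Rebuilding legacy array content from a dense array via hierarchical LD surrogates.

For each manifest SNP absent from the dense array, a surrogate is sought
among dense-array SNPs within ``window_bp`` by walking four rules in strict
order: perfect correlation (r^2 = 1) in both LD panels, in panel 1 only, in
panel 2 only, then the highest pooled-panel r^2 provided it reaches
``r2_floor``.  Ties within a rule go to the candidate nearest in bp, then
to the lower position, so the outcome is independent of candidate order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ArrayDesign, HaplotypePanel

#: Slack for "perfect correlation" under floating point.
PERFECT_R2 = 1.0 - 1e-9


@dataclass(frozen=True)
class SurrogateDecision:
    target_vid: str
    surrogate_vid: str | None
    rule: str  # i | ii | iii | iv | direct | none
    r2_panel1: float | None = None
    r2_panel2: float | None = None
    distance_bp: int | None = None


def haplotype_r2(panel: HaplotypePanel, vid_a: str, vid_b: str) -> float:
    """Squared LD correlation r^2 = D^2 / (p_a(1-p_a) p_b(1-p_b)) from phased counts."""
    idx = panel.vid_index()
    a = panel.haplotypes[:, idx[vid_a]].astype(np.float64)
    b = panel.haplotypes[:, idx[vid_b]].astype(np.float64)
    return _r2_vectors(a, b)


def _r2_vectors(a: np.ndarray, b: np.ndarray) -> float:
    pa, pb = a.mean(), b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise ValueError("r^2 undefined at a monomorphic site")
    d = (a * b).mean() - pa * pb
    return float(d * d / (pa * (1 - pa) * pb * (1 - pb)))


def _r2_against_candidates(h: np.ndarray, target_col: int, cand_cols: np.ndarray) -> np.ndarray:
    """Vectorized r^2 of one target site against many candidate sites.

    Entries are ``nan`` where the target or a candidate is monomorphic.
    """
    t = h[:, target_col].astype(np.float64)
    c = h[:, cand_cols].astype(np.float64)
    pt = t.mean()
    pc = c.mean(axis=0)
    out = np.full(cand_cols.size, np.nan)
    if pt in (0.0, 1.0):
        return out
    ok = (pc > 0) & (pc < 1)
    d = (t[:, None] * c).mean(axis=0) - pt * pc
    denom = pt * (1 - pt) * pc * (1 - pc)
    out[ok] = (d[ok] ** 2) / denom[ok]
    return out


def find_surrogate(
    target_vid: str,
    dense_design: ArrayDesign,
    panel1: HaplotypePanel,
    panel2: HaplotypePanel,
    window_bp: int = 1_000_000,
    r2_floor: float = 0.80,
) -> SurrogateDecision:
    """Locate a dense-array surrogate for one manifest SNP.

    A target already on the dense array is its own surrogate (rule
    ``direct``).  Rules i–iii require r^2 of at least ``PERFECT_R2`` in the
    respective panel(s); rule iv scores r^2 on the pooled (concatenated)
    haplotypes of both panels and needs at least ``r2_floor``.  A site
    monomorphic in a panel is ineligible under that panel's rule but may
    still qualify under the other panel's rule.  ``rule='none'`` is a valid
    outcome, not an error.
    """
    dense = set(dense_design.variant_ids)
    idx1 = panel1.vid_index()
    if target_vid not in idx1:
        return SurrogateDecision(target_vid, None, "none")
    if target_vid in dense:
        return SurrogateDecision(target_vid, target_vid, "direct", distance_bp=0)
    idx2 = panel2.vid_index()
    tcol1 = idx1[target_vid]
    tpos = panel1.variants[tcol1].pos
    cand_vids = [
        v
        for v in dense_design.variant_ids
        if v in idx1 and v in idx2 and abs(panel1.variants[idx1[v]].pos - tpos) <= window_bp
    ]
    if not cand_vids:
        return SurrogateDecision(target_vid, None, "none")
    cols1 = np.array([idx1[v] for v in cand_vids])
    cols2 = np.array([idx2[v] for v in cand_vids])
    r2_1 = _r2_against_candidates(panel1.haplotypes, tcol1, cols1)
    r2_2 = _r2_against_candidates(panel2.haplotypes, idx2[target_vid], cols2) if target_vid in idx2 else np.full(len(cand_vids), np.nan)
    dist = np.array([abs(panel1.variants[idx1[v]].pos - tpos) for v in cand_vids])
    pos = np.array([panel1.variants[idx1[v]].pos for v in cand_vids])

    def pick(mask: np.ndarray) -> int | None:
        hits = np.flatnonzero(mask)
        if hits.size == 0:
            return None
        order = sorted(hits, key=lambda k: (dist[k], pos[k]))
        return order[0]

    def decision(k: int, rule: str) -> SurrogateDecision:
        return SurrogateDecision(
            target_vid,
            cand_vids[k],
            rule,
            r2_panel1=None if np.isnan(r2_1[k]) else float(r2_1[k]),
            r2_panel2=None if np.isnan(r2_2[k]) else float(r2_2[k]),
            distance_bp=int(dist[k]),
        )

    perfect1 = np.nan_to_num(r2_1, nan=-1.0) >= PERFECT_R2
    perfect2 = np.nan_to_num(r2_2, nan=-1.0) >= PERFECT_R2
    k = pick(perfect1 & perfect2)
    if k is not None:
        return decision(k, "i")
    k = pick(perfect1)
    if k is not None:
        return decision(k, "ii")
    k = pick(perfect2)
    if k is not None:
        return decision(k, "iii")
    # rule iv: pooled haplotypes of both panels
    pooled_t = np.concatenate(
        [panel1.haplotypes[:, tcol1], panel2.haplotypes[:, idx2[target_vid]]]
    ) if target_vid in idx2 else panel1.haplotypes[:, tcol1]
    if target_vid in idx2:
        pooled_c = np.vstack([panel1.haplotypes[:, cols1], panel2.haplotypes[:, cols2]])
    else:
        pooled_c = panel1.haplotypes[:, cols1]
    pt = pooled_t.mean()
    r2_pool = np.full(len(cand_vids), np.nan)
    if 0.0 < pt < 1.0:
        pc = pooled_c.mean(axis=0)
        ok = (pc > 0) & (pc < 1)
        d = (pooled_t[:, None] * pooled_c).mean(axis=0) - pt * pc
        denom = pt * (1 - pt) * pc * (1 - pc)
        r2_pool[ok] = (d[ok] ** 2) / denom[ok]
    best = np.nan_to_num(r2_pool, nan=-1.0)
    if best.max() >= r2_floor:
        top = best >= best.max() - 1e-12
        k = pick(top)
        return decision(k, "iv")
    return SurrogateDecision(target_vid, None, "none")


def rebuild_array(
    target_manifest: list[str],
    dense_design: ArrayDesign,
    panel1: HaplotypePanel,
    panel2: HaplotypePanel,
    window_bp: int = 1_000_000,
    r2_floor: float = 0.80,
    name: str = "legacy_rebuilt",
) -> tuple[ArrayDesign, list[SurrogateDecision]]:
    """Rebuild a legacy manifest as direct dense-array hits plus LD surrogates.

    The output design is the deduplicated union of direct hits and chosen
    surrogates; the decision list covers every manifest entry (rule
    ``none`` where nothing qualified).  A dense site may serve several
    targets.
    """
    decisions = [
        find_surrogate(vid, dense_design, panel1, panel2, window_bp, r2_floor)
        for vid in target_manifest
    ]
    chosen = list(dict.fromkeys(d.surrogate_vid for d in decisions if d.surrogate_vid))
    design = ArrayDesign(name=name, variant_ids=chosen, design_rule="legacy_rebuilt")
    return design, decisions


def write_decisions_tsv(decisions: list[SurrogateDecision], path) -> None:
    with open(path, "w") as fh:
        fh.write("target_vid\tsurrogate_vid\trule\tr2_panel1\tr2_panel2\tdistance_bp\n")
        for d in decisions:
            fh.write(
                f"{d.target_vid}\t{d.surrogate_vid or 'NONE'}\t{d.rule}\t"
                f"{'' if d.r2_panel1 is None else f'{d.r2_panel1:.6f}'}\t"
                f"{'' if d.r2_panel2 is None else f'{d.r2_panel2:.6f}'}\t"
                f"{'' if d.distance_bp is None else d.distance_bp}\n"
            )
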