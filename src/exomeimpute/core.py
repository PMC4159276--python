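"""Core in-memory containers for haplotype panels, genotype matrices and designs.

All genotype arrays use ``int8`` with :data:`MISSING` (``-1``) as the missing
sentinel; haplotype arrays are strictly ``{0, 1}``.  Coordinates are 1-based
inclusive (VCF convention) throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: Sentinel for a missing genotype call.  Never enters arithmetic.
MISSING: int = -1

_VALID_ALLELES = frozenset("ACGT")


class FormatError(ValueError):
    """Raised for malformed input files or inconsistent containers."""


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic SNP.

    Parameters
    ----------
    chrom : str
        Chromosome label.
    pos : int
        1-based base-pair coordinate.
    vid : str
        Variant identifier, unique within a panel.
    ref, alt : str
        Reference and alternate allele, single characters in ``{A,C,G,T}``,
        distinct from each other.
    """

    chrom: str
    pos: int
    vid: str
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"variant {self.vid}: pos must be >= 1, got {self.pos}")
        if self.ref not in _VALID_ALLELES or self.alt not in _VALID_ALLELES:
            raise FormatError(
                f"variant {self.vid}: alleles must be in A/C/G/T, got {self.ref}/{self.alt}"
            )
        if self.ref == self.alt:
            raise FormatError(f"variant {self.vid}: ref and alt alleles are identical")


def _check_variants(variants: Sequence[VariantRecord]) -> None:
    seen: set[str] = set()
    last: tuple[str, int] | None = None
    for v in variants:
        if v.vid in seen:
            raise FormatError(f"duplicate variant id {v.vid!r}")
        seen.add(v.vid)
        key = (v.chrom, v.pos)
        if last is not None and v.chrom == last[0] and v.pos <= last[1]:
            raise FormatError(
                f"positions not strictly increasing at {v.vid} ({v.chrom}:{v.pos})"
            )
        last = key


@dataclass
class HaplotypePanel:
    """Phased reference haplotypes: ``2N`` haplotypes over ``M`` variants.

    ``haplotypes`` is a ``(2N, M)`` int8 array of 0/1 alleles; two consecutive
    rows belong to one sample in ``sample_ids``.
    """

    variants: list[VariantRecord]
    haplotypes: np.ndarray
    sample_ids: list[str]
    panel_name: str = "panel"

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        _check_variants(self.variants)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[1] != len(self.variants):
            raise FormatError(
                f"panel {self.panel_name}: haplotype matrix shape "
                f"{self.haplotypes.shape} does not match {len(self.variants)} variants"
            )
        if self.haplotypes.shape[0] != 2 * len(self.sample_ids):
            raise FormatError(
                f"panel {self.panel_name}: {self.haplotypes.shape[0]} haplotypes for "
                f"{len(self.sample_ids)} samples (expected two per sample)"
            )
        bad = ~np.isin(self.haplotypes, (0, 1))
        if bad.any():
            raise FormatError(f"panel {self.panel_name}: alleles must be 0/1")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants], dtype=np.int64)

    @property
    def vids(self) -> list[str]:
        return [v.vid for v in self.variants]

    def vid_index(self) -> dict[str, int]:
        return {v.vid: i for i, v in enumerate(self.variants)}

    def allele_frequency(self) -> np.ndarray:
        """Derived (allele-1) frequency per variant."""
        return self.haplotypes.mean(axis=0)

    def maf(self) -> np.ndarray:
        f = self.allele_frequency()
        return np.minimum(f, 1.0 - f)

    def subset_variants(self, idx: Iterable[int]) -> "HaplotypePanel":
        idx = list(idx)
        return HaplotypePanel(
            variants=[self.variants[i] for i in idx],
            haplotypes=self.haplotypes[:, idx],
            sample_ids=list(self.sample_ids),
            panel_name=self.panel_name,
        )

    def subset_samples(self, which: Iterable[int]) -> "HaplotypePanel":
        which = list(which)
        rows = [r for s in which for r in (2 * s, 2 * s + 1)]
        return HaplotypePanel(
            variants=list(self.variants),
            haplotypes=self.haplotypes[rows, :],
            sample_ids=[self.sample_ids[s] for s in which],
            panel_name=self.panel_name,
        )

    def to_genotypes(self) -> "GenotypeMatrix":
        g = self.haplotypes[0::2, :] + self.haplotypes[1::2, :]
        return GenotypeMatrix(
            variants=list(self.variants),
            genotypes=g.astype(np.int8),
            sample_ids=list(self.sample_ids),
        )


@dataclass
class GenotypeMatrix:
    """Unphased genotype calls: ``N`` samples x ``M`` variants in {0,1,2,MISSING}."""

    variants: list[VariantRecord]
    genotypes: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        _check_variants(self.variants)
        if self.genotypes.ndim != 2 or self.genotypes.shape != (
            len(self.sample_ids),
            len(self.variants),
        ):
            raise FormatError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise FormatError("genotype values must be in {0,1,2,MISSING}")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants], dtype=np.int64)

    @property
    def vids(self) -> list[str]:
        return [v.vid for v in self.variants]

    def vid_index(self) -> dict[str, int]:
        return {v.vid: i for i, v in enumerate(self.variants)}

    def subset_variants(self, idx: Iterable[int]) -> "GenotypeMatrix":
        idx = list(idx)
        return GenotypeMatrix(
            variants=[self.variants[i] for i in idx],
            genotypes=self.genotypes[:, idx],
            sample_ids=list(self.sample_ids),
        )

    def subset_samples(self, which: Iterable[int]) -> "GenotypeMatrix":
        which = list(which)
        return GenotypeMatrix(
            variants=list(self.variants),
            genotypes=self.genotypes[which, :],
            sample_ids=[self.sample_ids[s] for s in which],
        )


@dataclass
class GeneticMap:
    """Piecewise-linear genetic map (bp -> cumulative cM), IMPUTE dialect.

    Interpolation between entries is linear in bp; positions beyond the last
    entry extrapolate at the last per-bp rate; positions before the first
    entry extrapolate backwards at the first rate (clipped at 0 cM distance
    from the first entry only when queried pairwise).
    """

    positions: np.ndarray  # bp, strictly increasing
    rates: np.ndarray  # cM/Mb
    cumulative: np.ndarray  # cM, non-decreasing

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.rates = np.asarray(self.rates, dtype=np.float64)
        self.cumulative = np.asarray(self.cumulative, dtype=np.float64)
        if self.positions.size < 1:
            raise FormatError("genetic map needs at least one entry")
        if np.any(np.diff(self.positions) <= 0):
            raise FormatError("genetic map positions must be strictly increasing")
        if np.any(np.diff(self.cumulative) < 0):
            raise FormatError("genetic map cumulative cM must be non-decreasing")

    @classmethod
    def uniform(cls, length_bp: int, rate_cm_per_mb: float = 1.0) -> "GeneticMap":
        """Constant-rate map over ``[1, length_bp]``."""
        pos = np.array([1.0, float(length_bp)])
        cm = (pos - 1.0) * rate_cm_per_mb / 1e6
        return cls(pos, np.array([rate_cm_per_mb] * 2), cm)

    def cm_at(self, pos_bp) -> np.ndarray:
        """Cumulative genetic position (cM) at base-pair coordinate(s)."""
        pos = np.atleast_1d(np.asarray(pos_bp, dtype=np.float64))
        cm = np.interp(pos, self.positions, self.cumulative)
        # linear extrapolation at the boundary rates
        last_rate = self.rates[-1] / 1e6
        first_rate = self.rates[0] / 1e6
        above = pos > self.positions[-1]
        below = pos < self.positions[0]
        cm[above] = self.cumulative[-1] + (pos[above] - self.positions[-1]) * last_rate
        cm[below] = self.cumulative[0] - (self.positions[0] - pos[below]) * first_rate
        return cm if np.ndim(pos_bp) else float(cm[0])


@dataclass
class PosteriorTensor:
    """Genotype posteriors: ``N`` samples x ``M`` variants x 3 classes."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 3 or self.probs.shape[2] != 3:
            raise FormatError(f"posterior tensor must be N x M x 3, got {self.probs.shape}")
        if np.any(self.probs < -1e-12):
            raise FormatError("posterior probabilities must be non-negative")
        sums = self.probs.sum(axis=2)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise FormatError("posterior triples must sum to 1 within 1e-6")

    @property
    def n_samples(self) -> int:
        return self.probs.shape[0]

    @property
    def n_variants(self) -> int:
        return self.probs.shape[1]


@dataclass
class ArrayDesign:
    """A named subset of panel variants with its design provenance."""

    name: str
    variant_ids: list[str]
    design_rule: str = "dense"  # dense | legacy_rebuilt | exome_style

    def __post_init__(self) -> None:
        if not self.variant_ids and self.design_rule != "legacy_rebuilt":
            # a legacy rebuild may legitimately recover nothing
            raise FormatError(f"array design {self.name!r} is empty")
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise FormatError(f"array design {self.name!r} has duplicate variant ids")

    def __contains__(self, vid: str) -> bool:
        return vid in set(self.variant_ids)

    def __len__(self) -> int:
        return len(self.variant_ids)
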