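"""Readers and writers for the genetic file formats the pipeline touches.

Supported dialects: VCF 4.x (GT and GP fields; read via :mod:`cyvcf2`),
the IMPUTE hap/legend/sample triplet for phased panels, the IMPUTE
genetic-map text format, and TSV report tables.

Only biallelic SNPs are retained; other records are skipped and counted.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import (
    MISSING,
    FormatError,
    GeneticMap,
    GenotypeMatrix,
    HaplotypePanel,
    PosteriorTensor,
    VariantRecord,
)

logger = logging.getLogger("exomeimpute")

_SNP_ALLELES = frozenset("ACGT")


def _is_biallelic_snp(ref: str, alts: list[str]) -> bool:
    return (
        len(alts) == 1
        and len(ref) == 1
        and len(alts[0]) == 1
        and ref in _SNP_ALLELES
        and alts[0] in _SNP_ALLELES
        and ref != alts[0]
    )


def read_vcf(path, require_phased: bool = False):
    """Read a VCF into a :class:`HaplotypePanel` or :class:`GenotypeMatrix`.

    Non-biallelic / non-SNP records are skipped (a summary count is logged).
    With ``require_phased`` every genotype must use the ``|`` separator and
    the result is a phased panel; otherwise a genotype matrix is returned
    with ``./.`` mapped to :data:`MISSING`.
    """
    path = str(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    n_skipped = 0
    counter = 0
    for rec in vcf:
        counter += 1
        if not _is_biallelic_snp(rec.REF, rec.ALT):
            n_skipped += 1
            continue
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        gts = rec.genotypes  # [allele1, allele2, phased] per sample
        col = np.empty(2 * len(samples) if require_phased else len(samples), dtype=np.int8)
        for i, gt in enumerate(gts):
            if len(gt) == 2:  # haploid call
                raise FormatError(f"{path}: mixed/haploid ploidy at record {vid}")
            a1, a2, phased = gt[0], gt[1], gt[2]
            if require_phased:
                if a1 < 0 or a2 < 0:
                    raise FormatError(
                        f"{path}: missing genotype at phased record {vid}, sample {samples[i]}"
                    )
                if not phased:
                    raise FormatError(
                        f"{path}: unphased genotype ('/') at record {vid}, "
                        f"sample {samples[i]} but phased haplotypes were required"
                    )
                col[2 * i] = a1
                col[2 * i + 1] = a2
            else:
                col[i] = MISSING if (a1 < 0 or a2 < 0) else a1 + a2
        variants.append(
            VariantRecord(chrom=rec.CHROM, pos=rec.POS, vid=vid, ref=rec.REF, alt=rec.ALT[0])
        )
        columns.append(col)
    vcf.close()
    if n_skipped:
        logger.info("read_vcf(%s): skipped %d non-biallelic-SNP records", path, n_skipped)
    mat = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((2 * len(samples) if require_phased else len(samples), 0), dtype=np.int8)
    )
    if require_phased:
        return HaplotypePanel(
            variants=variants, haplotypes=mat, sample_ids=samples, panel_name=Path(path).stem
        )
    return GenotypeMatrix(variants=variants, genotypes=mat, sample_ids=samples)


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
_GT_PHASED = {0: "0|0", 1: "0|1", 2: "1|1"}


def write_vcf(matrix: GenotypeMatrix, path) -> None:
    """Write discrete genotype calls as a minimal VCF (GT only)."""
    _write_vcf_impl(matrix, None, path)


def write_vcf_with_gp(matrix: GenotypeMatrix, posteriors: PosteriorTensor, path) -> None:
    """Write genotypes with a GP FORMAT field carrying posterior triples.

    GP values are rounded to 3 decimals; a write-then-read round trip
    recovers the genotype values exactly.
    """
    if posteriors.probs.shape[:2] != matrix.genotypes.shape:
        raise FormatError(
            f"posterior tensor {posteriors.probs.shape[:2]} does not match genotype "
            f"matrix {matrix.genotypes.shape}"
        )
    _write_vcf_impl(matrix, posteriors, path)


def _write_vcf_impl(matrix: GenotypeMatrix, posteriors: PosteriorTensor | None, path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(v.chrom for v in matrix.variants):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if posteriors is not None:
            fh.write(
                '##FORMAT=<ID=GP,Number=G,Type=Float,Description="Genotype posterior probabilities">\n'
            )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(matrix.sample_ids) + "\n")
        fmt = "GT:GP" if posteriors is not None else "GT"
        for j, v in enumerate(matrix.variants):
            fields = [v.chrom, str(v.pos), v.vid, v.ref, v.alt, ".", "PASS", ".", fmt]
            for i in range(matrix.n_samples):
                cell = _GT_STR[int(matrix.genotypes[i, j])]
                if posteriors is not None:
                    p = posteriors.probs[i, j]
                    cell += f":{p[0]:.3f},{p[1]:.3f},{p[2]:.3f}"
                fields.append(cell)
            fh.write("\t".join(fields) + "\n")


def write_phased_vcf(panel: HaplotypePanel, path) -> None:
    """Write a phased haplotype panel as a VCF with ``|``-separated GT."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(v.chrom for v in panel.variants):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(panel.sample_ids) + "\n")
        for j, v in enumerate(panel.variants):
            fields = [v.chrom, str(v.pos), v.vid, v.ref, v.alt, ".", "PASS", ".", "GT"]
            for i in range(len(panel.sample_ids)):
                a1 = panel.haplotypes[2 * i, j]
                a2 = panel.haplotypes[2 * i + 1, j]
                fields.append(f"{a1}|{a2}")
            fh.write("\t".join(fields) + "\n")


def write_hap_legend_sample(panel: HaplotypePanel, prefix) -> None:
    """Write a panel as an IMPUTE-style .hap / .legend / .sample triplet."""
    prefix = str(prefix)
    with open(prefix + ".legend", "w") as fh:
        fh.write("id position a0 a1\n")
        for v in panel.variants:
            fh.write(f"{v.vid} {v.pos} {v.ref} {v.alt}\n")
    np.savetxt(prefix + ".hap", panel.haplotypes.T, fmt="%d")
    with open(prefix + ".sample", "w") as fh:
        fh.write("sample\n")
        for s in panel.sample_ids:
            fh.write(s + "\n")


def read_hap_legend_sample(prefix, chrom: str = "1", panel_name: str | None = None) -> HaplotypePanel:
    """Read an IMPUTE-style .hap / .legend / .sample panel triplet."""
    prefix = str(prefix)
    legend = pd.read_csv(prefix + ".legend", sep=r"\s+")
    haps = np.loadtxt(prefix + ".hap", dtype=np.int8, ndmin=2).T
    with open(prefix + ".sample") as fh:
        samples = [line.strip() for line in fh][1:]
    variants = [
        VariantRecord(chrom=chrom, pos=int(r.position), vid=str(r.id), ref=str(r.a0), alt=str(r.a1))
        for r in legend.itertuples()
    ]
    return HaplotypePanel(
        variants=variants,
        haplotypes=haps,
        sample_ids=samples,
        panel_name=panel_name or Path(prefix).name,
    )


def read_genetic_map(path) -> GeneticMap:
    """Read an IMPUTE-dialect genetic map (position, rate cM/Mb, cumulative cM)."""
    df = pd.read_csv(path, sep=r"\s+")
    if df.shape[1] < 3:
        raise FormatError(f"{path}: genetic map needs 3 columns (position, rate, cM)")
    pos = df.iloc[:, 0].to_numpy(dtype=np.float64)
    if np.any(np.diff(pos) <= 0):
        raise FormatError(f"{path}: genetic map positions must be strictly increasing")
    return GeneticMap(
        positions=pos,
        rates=df.iloc[:, 1].to_numpy(dtype=np.float64),
        cumulative=df.iloc[:, 2].to_numpy(dtype=np.float64),
    )


def write_genetic_map(gmap: GeneticMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("position COMBINED_rate(cM/Mb) Genetic_Map(cM)\n")
        for p, r, c in zip(gmap.positions, gmap.rates, gmap.cumulative):
            fh.write(f"{int(p)} {r:.6f} {c:.8f}\n")


# Fixed column order for each report table; write_report relies on this.
REPORT_TABLES: dict[str, list[str]] = {
    "coverage_by_maf": ["population", "maf_bin", "covered", "n_snps"],
    "well_imputed_by_panel": [
        "array",
        "panel_config",
        "maf_bin",
        "n_snps",
        "n_well_imputed",
        "pct_well_imputed",
    ],
    "discordance_overall": [
        "array",
        "panel_config",
        "maf_bin",
        "n_genotypes",
        "n_discordant",
        "discordance_pct",
    ],
    "discordance_minor_allele": [
        "array",
        "panel_config",
        "maf_bin",
        "n_minor_allele_genotypes",
        "n_discordant",
        "discordance_pct",
    ],
    "recoverable_content": [
        "panel_config",
        "freq_group",
        "n_exonic",
        "n_on_array",
        "n_on_chip",
        "n_imputed",
        "pct_recovered",
    ],
}


def write_report(report, directory) -> list[Path]:
    """Serialize an :class:`~exomeimpute.metrics.EvaluationReport` to TSV files.

    One file per table with a fixed, documented column order; an empty table
    yields a headers-only file.  Returns the paths written.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name, cols in REPORT_TABLES.items():
        df = getattr(report, name)
        if df is None or len(df) == 0:
            df = pd.DataFrame(columns=cols)
        out = directory / f"{name}.tsv"
        df.to_csv(out, sep="\t", index=False, columns=cols)
        written.append(out)
    return written
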