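"""Readers and writers for the pipeline's on-disk formats.

TSV dialect: tab-separated, UTF-8, header row, ``.`` as the missing token,
and optional ``#``-prefixed metadata lines (seed, config hash) before the
header — bit-stable and diffable. Genotypes travel either as a dosage TSV
(lines x markers) plus a map TSV, or as a plain-text VCF with GT fields
(read back through cyvcf2); alignments as FASTA.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio import AlignIO

from .genotypes import GenotypeMatrix

__all__ = [
    "write_tsv",
    "read_tsv",
    "write_dosage_tsv",
    "read_dosage_tsv",
    "write_map_tsv",
    "read_map_tsv",
    "write_phenotypes_tsv",
    "read_phenotypes_tsv",
    "write_vcf",
    "read_vcf",
    "read_genotypes",
    "read_alignment",
    "write_alignment",
]

MISSING_TOKEN = "."


# ---------------------------------------------------------------------------
# generic TSV with metadata header lines
# ---------------------------------------------------------------------------


def write_tsv(df: pd.DataFrame, path, header_lines=(), index: bool = False) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(
            fh, sep="\t", index=index, na_rep=MISSING_TOKEN, float_format="%.10g",
            lineterminator="\n",
        )


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", comment="#", na_values=[MISSING_TOKEN], **kwargs
    )


# ---------------------------------------------------------------------------
# dosage matrix + map
# ---------------------------------------------------------------------------


def write_dosage_tsv(geno: GenotypeMatrix, path, header_lines=()) -> None:
    """Lines as rows, markers as columns, first column ``line``."""
    df = geno.to_frame().reset_index(names="line")
    write_tsv(df, path, header_lines=header_lines)


def read_dosage_tsv(path, map_path=None) -> GenotypeMatrix:
    df = read_tsv(path)
    if "line" not in df.columns:
        raise ValueError(f"{path}: dosage TSV must have a 'line' first column")
    df = df.set_index("line")
    marker_map = read_map_tsv(map_path) if map_path else None
    dosages = df.to_numpy(dtype=float)
    bad = dosages[~np.isnan(dosages)]
    if bad.size and (bad.min() < 0 or bad.max() > 2):
        raise ValueError(f"{path}: dosages outside [0, 2]")
    return GenotypeMatrix(dosages, list(df.index), list(df.columns), marker_map)


def write_map_tsv(geno: GenotypeMatrix, path, header_lines=()) -> None:
    if geno.marker_map is None:
        raise ValueError("genotype matrix has no marker map")
    write_tsv(geno.marker_map.reset_index(names="marker"), path, header_lines=header_lines)


def read_map_tsv(path) -> pd.DataFrame:
    mm = read_tsv(path)
    required = {"marker", "chrom", "cM"}
    if not required <= set(mm.columns):
        raise ValueError(f"{path}: map TSV needs columns {sorted(required)}")
    return mm.set_index("marker")


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def write_phenotypes_tsv(pheno: pd.DataFrame, path, header_lines=()) -> None:
    cols = ["genotype", "environment", "trait", "value"]
    missing = [c for c in cols if c not in pheno.columns]
    if missing:
        raise ValueError(f"phenotype table lacks columns {missing}")
    write_tsv(pheno[cols], path, header_lines=header_lines)


def read_phenotypes_tsv(path) -> pd.DataFrame:
    df = read_tsv(path, dtype={"genotype": str, "environment": str, "trait": str})
    missing = [c for c in ("genotype", "environment", "trait", "value") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: phenotype TSV lacks columns {missing}")
    return df


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def write_vcf(geno: GenotypeMatrix, path, header_lines=()) -> None:
    """Plain-text VCFv4.2 with GT fields; requires integer dosages 0/1/2.

    Chromosomes become contigs; positions are 1-based bp from the marker
    map (sequential fallback when unmapped). Dosage is the ALT-allele count
    with REF=A, ALT=T placeholders.
    """
    X = geno.dosages
    obs = X[~np.isnan(X)]
    if obs.size and not np.all(np.isin(obs, (0.0, 1.0, 2.0))):
        raise ValueError("VCF output requires raw integer dosages (0/1/2)")
    mm = geno.marker_map
    contigs: list[str] = []
    rows = []
    for j, m in enumerate(geno.marker_ids):
        if mm is not None and m in mm.index:
            chrom = str(mm.loc[m, "chrom"])
            bp = mm.loc[m, "bp"] if "bp" in mm.columns else np.nan
            pos = int(bp) if pd.notna(bp) else j + 1
        else:
            chrom, pos = "un", j + 1
        if chrom not in contigs:
            contigs.append(chrom)
        gts = []
        for v in X[:, j]:
            if np.isnan(v):
                gts.append("./.")
            else:
                gts.append({0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}[v])
        rows.append((chrom, pos, m, gts))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for line in header_lines:
            fh.write(f"##comment={line}\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.line_ids)
            + "\n"
        )
        for chrom, pos, m, gts in rows:
            fh.write(f"{chrom}\t{pos}\t{m}\tA\tT\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")


def read_vcf(path, map_path=None) -> GenotypeMatrix:
    """Read biallelic GT records into a dosage matrix via cyvcf2.

    Multi-allelic records are skipped; the count is stored in
    ``meta["n_multiallelic_skipped"]``. The map is taken from CHROM/POS
    (cM from a map TSV when provided).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    marker_ids, chroms, poss = [], [], []
    columns = []
    n_skipped = 0
    # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
    lookup = np.array([0.0, 1.0, np.nan, 2.0])
    for i, variant in enumerate(vcf):
        if len(variant.ALT) != 1:
            n_skipped += 1
            continue
        marker_ids.append(variant.ID or f"{variant.CHROM}_{variant.POS}")
        chroms.append(variant.CHROM)
        poss.append(variant.POS)
        columns.append(lookup[variant.gt_types])
    vcf.close()
    if not marker_ids:
        raise ValueError(f"{path}: no biallelic records found")
    dosages = np.column_stack(columns)
    if map_path:
        marker_map = read_map_tsv(map_path)
    else:
        marker_map = pd.DataFrame(
            {"marker": marker_ids, "chrom": chroms, "cM": np.nan, "bp": poss}
        ).set_index("marker")
    gm = GenotypeMatrix(dosages, samples, marker_ids, marker_map)
    gm.meta["n_multiallelic_skipped"] = n_skipped
    return gm


def read_genotypes(path, format: str = "tsv", map_path=None) -> GenotypeMatrix:
    """Dispatch to the TSV or VCF reader."""
    if format == "tsv":
        return read_dosage_tsv(path, map_path=map_path)
    if format == "vcf":
        return read_vcf(path, map_path=map_path)
    raise ValueError("format must be 'tsv' or 'vcf'")


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------


def read_alignment(path):
    return AlignIO.read(str(path), "fasta")


def write_alignment(aln, path) -> None:
    AlignIO.write(aln, str(path), "fasta")
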