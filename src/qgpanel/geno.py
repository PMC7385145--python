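"""Marker quality control, imputation, LD analysis, and PCA structure.

QC follows the standard array-genotyping recipe for inbred panels: markers
are dropped when the minor allele frequency falls below 0.05 (boundary
inclusive) or when more than 5% of calls are missing or heterozygous; the
surviving markers' missing/heterozygous calls are imputed with the marker
mean dosage of the observed homozygous calls. Rates are computed on observed
calls before imputation, and heterozygous calls are treated as missing for
the frequency computation.

LD between two loci is the squared allelic correlation
r^2 = (p_ab - p_a p_b)^2 / (p_a (1 - p_a) p_b (1 - p_b)); for fully inbred
0/2 dosages this equals the squared Pearson correlation of the dosage
vectors, which is how it is computed here (an approximation if residual
heterozygotes remain). Population structure is summarized by PCA via SVD of
the column-centred dosage matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "QCReport",
    "LDResult",
    "PCAResult",
    "qc_filter",
    "ld_r2",
    "ld_decay_profile",
    "pca",
]


@dataclass
class QCReport:
    n_input: int
    removed_maf: int
    removed_missing: int
    removed_het: int
    imputed_calls: int
    surviving: int
    removed_markers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        removed = self.removed_maf + self.removed_missing + self.removed_het
        if removed + self.surviving != self.n_input:
            raise ValueError("QC accounting error: removed + surviving != input")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": [
                    "input_markers",
                    "removed_maf",
                    "removed_missing",
                    "removed_het",
                    "imputed_calls",
                    "surviving_markers",
                ],
                "count": [
                    self.n_input,
                    self.removed_maf,
                    self.removed_missing,
                    self.removed_het,
                    self.imputed_calls,
                    self.surviving,
                ],
            }
        )


@dataclass
class LDResult:
    pairs: pd.DataFrame  # chrom, marker_a, marker_b, distance_cM, r2
    bin_summary: pd.DataFrame  # bin_mid_cM, n_pairs, median_r2, mean_r2
    n_unmapped_excluded: int = 0


@dataclass
class PCAResult:
    scores: pd.DataFrame  # line x PC1..PCk
    explained_variance_ratio: np.ndarray  # length k, proportions of total


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def qc_filter(
    geno: GenotypeMatrix,
    maf_min: float = 0.05,
    max_missing: float = 0.05,
    max_het: float = 0.05,
) -> tuple[GenotypeMatrix, QCReport]:
    """Filter markers by MAF / missing rate / heterozygosity rate and impute.

    A marker is retained when MAF >= ``maf_min`` (computed on observed
    homozygous calls), its missing rate is <= ``max_missing`` and its
    heterozygous-call rate is <= ``max_het`` (both strict ">" removal, per
    the "more than 5%" convention). Markers failing several rules are
    counted once, in the order MAF, missing, het. Surviving markers have
    missing and heterozygous calls replaced by the marker mean of observed
    homozygous dosages, so the output contains no missing values. The
    operation is idempotent.
    """
    for name, v in (("maf_min", maf_min), ("max_missing", max_missing), ("max_het", max_het)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    X = geno.dosages
    n = geno.n_lines
    missing = np.isnan(X)
    het = X == 1.0
    hom_mask = ~missing & ~het
    n_hom = hom_mask.sum(axis=0)

    missing_rate = missing.sum(axis=0) / n
    het_rate = het.sum(axis=0) / n
    with np.errstate(invalid="ignore", divide="ignore"):
        p_freq = np.where(n_hom > 0, np.nansum(np.where(hom_mask, X, 0.0), axis=0) / (2.0 * np.maximum(n_hom, 1)), np.nan)
    maf = np.minimum(p_freq, 1.0 - p_freq)

    fail_maf = np.isnan(maf) | (maf < maf_min)
    fail_missing = missing_rate > max_missing
    fail_het = het_rate > max_het

    removed_maf = fail_maf
    removed_missing = fail_missing & ~removed_maf
    removed_het = fail_het & ~removed_maf & ~removed_missing
    keep = ~(fail_maf | fail_missing | fail_het)
    if not keep.any():
        raise ValueError("QC removed every marker: no surviving markers")

    kept_ids = [m for m, k in zip(geno.marker_ids, keep) if k]
    out = geno.subset_markers(kept_ids)
    Xo = out.dosages
    fill_mask = np.isnan(Xo) | (Xo == 1.0)
    n_imputed = int(fill_mask.sum())
    if n_imputed:
        means = 2.0 * p_freq[keep]
        idx = np.where(fill_mask)
        Xo[idx] = means[idx[1]]
    report = QCReport(
        n_input=geno.n_markers,
        removed_maf=int(removed_maf.sum()),
        removed_missing=int(removed_missing.sum()),
        removed_het=int(removed_het.sum()),
        imputed_calls=n_imputed,
        surviving=int(keep.sum()),
        removed_markers=[m for m, k in zip(geno.marker_ids, keep) if not k],
    )
    return out, report


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------


def ld_r2(geno: GenotypeMatrix, marker_a: str, marker_b: str) -> float:
    """Squared correlation LD between two markers (NaN if monomorphic).

    Computed as the squared Pearson correlation of the dosage vectors over
    lines observed for both markers; exact for inbred 0/2 data, where it
    coincides with the haplotype-frequency formulation.
    """
    ia, ib = geno.marker_ids.index(marker_a), geno.marker_ids.index(marker_b)
    x, y = geno.dosages[:, ia], geno.dosages[:, ib]
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_decay_profile(
    geno: GenotypeMatrix, max_distance_cM: float = 50.0, bin_width_cM: float = 1.0
) -> LDResult:
    """All within-chromosome marker-pair r^2 up to a distance cap, binned by cM.

    Unmapped markers are excluded and counted; monomorphic markers yield NaN
    pairs which are dropped from the summary.
    """
    if geno.marker_map is None:
        raise ValueError("no marker map available for LD decay analysis")
    mapped = geno.mapped_marker_ids()
    if not mapped:
        raise ValueError("no mapped markers available for LD decay analysis")
    n_unmapped = geno.n_markers - len(mapped)

    rows = []
    mm = geno.marker_map
    col_of = {m: i for i, m in enumerate(geno.marker_ids)}
    for chrom, sub in mm.loc[mapped].groupby("chrom", sort=True):
        # within-chromosome order: cM, ties broken by marker id
        sub = sub.sort_index().sort_values("cM", kind="stable")
        ids = list(sub.index)
        cms = sub["cM"].to_numpy(dtype=float)
        X = geno.dosages[:, [col_of[m] for m in ids]]
        Xc = X - np.nanmean(X, axis=0, keepdims=True)
        sd = np.nanstd(Xc, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            Z = Xc / sd
        R = np.ma.corrcoef(np.ma.masked_invalid(Z.T)).data if np.isnan(Z).any() else (Z.T @ Z) / Z.shape[0]
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                d = cms[j] - cms[i]
                if d > max_distance_cM:
                    break
                r2 = R[i, j] ** 2 if np.isfinite(R[i, j]) else np.nan
                rows.append((chrom, ids[i], ids[j], float(d), float(r2)))
    pairs = pd.DataFrame(rows, columns=["chrom", "marker_a", "marker_b", "distance_cM", "r2"])

    ok = pairs.dropna(subset=["r2"])
    if len(ok):
        bins = np.arange(0.0, max_distance_cM + bin_width_cM, bin_width_cM)
        cat = pd.cut(ok["distance_cM"], bins=bins, include_lowest=True)
        grouped = ok.groupby(cat, observed=True)["r2"]
        bin_summary = pd.DataFrame(
            {
                "bin_mid_cM": [iv.mid for iv in grouped.median().index],
                "n_pairs": grouped.size().to_numpy(),
                "median_r2": grouped.median().to_numpy(),
                "mean_r2": grouped.mean().to_numpy(),
            }
        )
    else:
        bin_summary = pd.DataFrame(columns=["bin_mid_cM", "n_pairs", "median_r2", "mean_r2"])
    return LDResult(pairs=pairs, bin_summary=bin_summary, n_unmapped_excluded=n_unmapped)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def pca(geno: GenotypeMatrix, k: int = 10) -> PCAResult:
    """PCA of the column-centred dosage matrix via SVD.

    Scores are U * S (line coordinates); explained-variance proportions are
    singular values squared over the total variance, so they sum to 1 over
    all components.
    """
    X = geno.dosages
    if np.isnan(X).any():
        raise ValueError("PCA requires an imputed (QC-passed) matrix")
    n, p = X.shape
    kmax = min(n, p)
    if k > kmax:
        warnings.warn(f"k={k} exceeds min(n, p)={kmax}; clipped")
        k = kmax
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    total = float((s**2).sum())
    scores = U[:, :k] * s[:k]
    ratio = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    return PCAResult(
        scores=pd.DataFrame(
            scores, index=geno.line_ids, columns=[f"PC{i+1}" for i in range(k)]
        ),
        explained_variance_ratio=ratio,
    )
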