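"""Mixed-linear-model GWAS, FDR control, and explained genotypic variance.

The association model is

    y = 1 mu + X beta + P v + Z u + e,    u ~ N(0, G sigma2_a), e ~ N(0, I sigma2_e)

where y are the across-environment BLUEs, X the tested marker, P optional
principal-component covariates and u a polygenic background with the
VanRaden genomic relationship matrix

    G = sum_k (w_ik - 2 p_k)(w_jk - 2 p_k) / (2 sum_k p_k (1 - p_k)).

Four correction variants are supported: ``naive`` (ordinary least squares),
``pc`` (first PCs as fixed covariates), ``g`` (polygenic background), and
``pc_g`` (both). Kinship models use the EMMAX/P3D strategy: the polygenic
variance ratio is estimated once by spectral 1-D REML under the no-marker
model, the data are rotated into the eigenbasis of G, and every marker is
then tested by generalized least squares with a Wald t-test (an exact
per-marker REML option exists behind a flag). Markers collinear with the
covariates are reported as non-estimable rather than as spurious hits.

Marker-trait associations are declared with Benjamini–Hochberg FDR control
at a liberal q = 0.20, and the genotypic variance explained by the declared
set is p_G = (R2_adj / H2) * 100 from a joint multiple regression of the
BLUEs on all MTA, with R2_adj = R2 - (z' / (N - z' - 1)) (1 - R2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .geno import pca as _pca
from .genotypes import GenotypeMatrix

__all__ = [
    "GRM",
    "GwasModelSpec",
    "MTASet",
    "compute_grm",
    "run_gwas",
    "fdr_adjust",
    "genotypic_variance_explained",
    "genomic_inflation",
]

VARIANTS = ("naive", "pc", "g", "pc_g")


@dataclass
class GRM:
    """VanRaden method-1 genomic relationship matrix."""

    matrix: np.ndarray
    line_ids: list[str]
    allele_freqs: np.ndarray
    denominator: float

    def submatrix(self, line_ids) -> np.ndarray:
        idx = [self.line_ids.index(l) for l in line_ids]
        return self.matrix[np.ix_(idx, idx)]

    def cross(self, rows, cols) -> np.ndarray:
        ri = [self.line_ids.index(l) for l in rows]
        ci = [self.line_ids.index(l) for l in cols]
        return self.matrix[np.ix_(ri, ci)]


@dataclass
class GwasModelSpec:
    """Which structure/kinship corrections enter the association model."""

    variant: str = "pc_g"
    n_pcs: int = 3
    per_marker_reml: bool = False

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.n_pcs < 0:
            raise ValueError("n_pcs must be >= 0")

    @property
    def uses_pcs(self) -> bool:
        return self.variant in ("pc", "pc_g")

    @property
    def uses_kinship(self) -> bool:
        return self.variant in ("g", "pc_g")


@dataclass
class MTASet:
    """Explained-genotypic-variance decomposition of a set of MTA."""

    table: pd.DataFrame  # marker, entry_order, beta, p, seq_ss, p_G
    total_p_G: float
    r2: float
    r2_adj: float
    heritability: float
    n_lines: int


# ---------------------------------------------------------------------------
# GRM
# ---------------------------------------------------------------------------


def compute_grm(geno: GenotypeMatrix) -> GRM:
    """VanRaden method-1 GRM with sample allele frequencies.

    Monomorphic markers contribute nothing to numerator or denominator; an
    all-monomorphic matrix raises a zero-denominator error. With sample
    frequencies every row of G sums to zero.
    """
    X = geno.dosages
    if np.isnan(X).any():
        raise ValueError("GRM requires an imputed (QC-passed) matrix")
    p_k = X.mean(axis=0) / 2.0
    W = X - 2.0 * p_k
    denom = 2.0 * float(np.sum(p_k * (1.0 - p_k)))
    if denom <= 0:
        raise ValueError("all markers monomorphic: GRM denominator is zero")
    G = (W @ W.T) / denom
    return GRM(
        matrix=G, line_ids=list(geno.line_ids), allele_freqs=p_k, denominator=denom
    )


# ---------------------------------------------------------------------------
# spectral 1-D REML (EMMA-style) for the kinship null model
# ---------------------------------------------------------------------------


def _kinship_eig(K: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    vals, vecs = np.linalg.eigh((K + K.T) / 2.0)
    if vals.min() < -1e-8 * max(vals.max(), 1.0):
        warnings.warn(
            f"kinship matrix not PSD (min eigenvalue {vals.min():.3g}); "
            "applying automatic ridge"
        )
    vals = np.clip(vals, 0.0, None)
    return vals, vecs


def _reml_delta(y_t: np.ndarray, C_t: np.ndarray, S: np.ndarray) -> float:
    """Estimate delta = sigma2_e / sigma2_a by profiled REML in the eigenbasis."""
    n, c = C_t.shape

    def neg2(t):
        delta = np.exp(t)
        w = 1.0 / (S + delta)
        Cw = C_t * w[:, None]
        A = C_t.T @ Cw
        sign, logdet_A = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(A, Cw.T @ y_t)
        rss = float(y_t @ (w * y_t)) - float(beta @ (Cw.T @ y_t))
        if rss <= 0:
            return np.inf
        return float(np.log(S + delta).sum()) + logdet_A + (n - c) * np.log(rss / (n - c))

    res = optimize.minimize_scalar(neg2, bounds=(-10.0, 10.0), method="bounded")
    return float(np.exp(res.x))


def _batched_gls_scan(y_s, C_s, X_s, raw_scale):
    """Frisch–Waugh scan: per-marker slope, SE and Wald t-test P-value."""
    n, c = C_s.shape
    df = n - c - 1
    Q, _ = np.linalg.qr(C_s)
    ey = y_s - Q @ (Q.T @ y_s)
    E = X_s - Q @ (Q.T @ X_s)
    sxx = np.einsum("ij,ij->j", E, E)
    sxy = E.T @ ey
    syy = float(ey @ ey)
    estimable = sxx > 1e-10 * np.maximum(raw_scale, 1e-30)
    beta = np.where(estimable, sxy / np.where(estimable, sxx, 1.0), np.nan)
    rss = syy - beta * sxy
    with np.errstate(invalid="ignore", divide="ignore"):
        sigma2 = rss / df
        se = np.sqrt(sigma2 / sxx)
        tval = beta / se
    pval = 2.0 * stats.t.sf(np.abs(tval), df)
    pval = np.where(estimable, np.maximum(pval, np.finfo(float).tiny), np.nan)
    return beta, np.where(estimable, se, np.nan), pval, estimable


def run_gwas(
    blues: pd.Series,
    geno: GenotypeMatrix,
    spec: GwasModelSpec | None = None,
    grm: GRM | None = None,
    pc_scores: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-marker association scan under the requested correction variant.

    Returns a frame with columns ``marker, chrom, cM, bp, beta, se, p,
    minus_log10_p, reason`` (``reason`` non-empty for markers that could not
    be tested). The ``naive`` variant is exactly ordinary least squares, so
    its P-values match a two-sided OLS t-test.
    """
    spec = spec or GwasModelSpec()
    lines = [l for l in geno.line_ids if l in set(blues.index)]
    if len(lines) < 3:
        raise ValueError("fewer than 3 lines shared between BLUEs and genotypes")
    sub = geno.subset_lines(lines) if len(lines) != geno.n_lines else geno
    y = blues.loc[lines].to_numpy(dtype=float)
    n = len(lines)
    X = sub.dosages
    if np.isnan(X).any():
        raise ValueError("GWAS requires an imputed (QC-passed) matrix")

    covs = [np.ones((n, 1))]
    if spec.uses_pcs and spec.n_pcs > 0:
        if pc_scores is None:
            pc_scores = _pca(sub, k=spec.n_pcs).scores
        covs.append(pc_scores.loc[lines].to_numpy(dtype=float)[:, : spec.n_pcs])
    C = np.hstack(covs)

    if spec.uses_kinship:
        K = (grm.submatrix(lines) if grm is not None else compute_grm(sub).matrix)
        S, U = _kinship_eig(K)
        y_t, C_t, X_t = U.T @ y, U.T @ C, U.T @ X
        if spec.per_marker_reml:
            return _per_marker_reml_scan(sub, y_t, C_t, X_t, S)
        delta = _reml_delta(y_t, C_t, S)
        w = np.sqrt(1.0 / (S + delta))
        y_s, C_s, X_s = w * y_t, w[:, None] * C_t, w[:, None] * X_t
    else:
        y_s, C_s, X_s = y, C, X

    raw_scale = np.einsum("ij,ij->j", X_s - X_s.mean(0), X_s - X_s.mean(0))
    beta, se, pval, estimable = _batched_gls_scan(y_s, C_s, X_s, raw_scale)
    return _assemble_result(sub, beta, se, pval, estimable)


def _per_marker_reml_scan(sub, y_t, C_t, X_t, S):
    """Exact per-marker REML (slow path, behind GwasModelSpec.per_marker_reml)."""
    out = []
    for j in range(X_t.shape[1]):
        Cj = np.hstack([C_t, X_t[:, j : j + 1]])
        if np.linalg.matrix_rank(Cj) < Cj.shape[1]:
            out.append((np.nan, np.nan, np.nan, False))
            continue
        delta = _reml_delta(y_t, Cj, S)
        w = np.sqrt(1.0 / (S + delta))
        beta, se, p, est = _batched_gls_scan(
            w * y_t, w[:, None] * C_t, (w * X_t[:, j])[:, None], np.array([1.0])
        )
        out.append((beta[0], se[0], p[0], bool(est[0])))
    beta, se, p, est = map(np.asarray, zip(*out))
    return _assemble_result(sub, beta, se, p, est.astype(bool))


def _assemble_result(sub, beta, se, pval, estimable):
    mm = sub.marker_map
    chrom = [
        (mm.loc[m, "chrom"] if mm is not None and m in mm.index else None)
        for m in sub.marker_ids
    ]
    cM = [
        (float(mm.loc[m, "cM"]) if mm is not None and m in mm.index else np.nan)
        for m in sub.marker_ids
    ]
    bp = [
        (mm.loc[m, "bp"] if mm is not None and m in mm.index and "bp" in mm.columns else np.nan)
        for m in sub.marker_ids
    ]
    with np.errstate(invalid="ignore", divide="ignore"):
        mlp = -np.log10(pval)
    return pd.DataFrame(
        {
            "marker": sub.marker_ids,
            "chrom": chrom,
            "cM": cM,
            "bp": bp,
            "beta": beta,
            "se": se,
            "p": pval,
            "minus_log10_p": mlp,
            "reason": ["" if e else "non_estimable" for e in estimable],
        }
    )


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------


def fdr_adjust(pvalues, q: float = 0.20) -> np.ndarray:
    """Benjamini–Hochberg step-up significance flags at FDR level ``q``."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any(np.isnan(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("P-values must lie in (0, 1]")
    flags, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return flags


def genomic_inflation(pvalues) -> float:
    """Genomic inflation factor lambda_GC from the median association chi2."""
    p = np.asarray(list(pvalues), dtype=float)
    p = p[np.isfinite(p)]
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))


# ---------------------------------------------------------------------------
# explained genotypic variance (p_G)
# ---------------------------------------------------------------------------


def genotypic_variance_explained(
    blues: pd.Series,
    geno: GenotypeMatrix,
    mta_markers,
    H2: float,
    assoc: pd.DataFrame | None = None,
    order: str = "ascending_p",
) -> MTASet:
    """p_G of a declared MTA set from a joint multiple regression.

    All MTA enter one multiple linear regression of the BLUEs on their
    dosages; R2 is adjusted as R2_adj = R2 - (z'/(N-z'-1))(1-R2) and the
    total p_G = (R2_adj / H2) * 100. Per-marker p_G is apportioned by
    sequential sums of squares under the entry order: by default markers
    enter most-significant-first (ascending P from ``assoc``; ties broken by
    |beta| descending then marker id), ``order="as_given"`` preserves the
    caller's order, ``order="descending_p"`` reverses the significance
    ranking.
    """
    mta = [str(m) for m in mta_markers]
    if H2 <= 0:
        raise ValueError("H2 must be positive")
    if not mta:
        empty = pd.DataFrame(
            columns=["marker", "entry_order", "seq_ss", "p_G"]
        )
        return MTASet(empty, 0.0, 0.0, 0.0, H2, len(blues))

    lines = [l for l in geno.line_ids if l in set(blues.index)]
    y = blues.loc[lines].to_numpy(dtype=float)
    N, z = len(lines), len(mta)
    if N <= z + 1:
        raise ValueError(f"adjusted R2 undefined: N={N} <= z'+1={z + 1}")

    if order in ("ascending_p", "descending_p"):
        if assoc is None:
            raise ValueError(f"order={order!r} requires the association result")
        a = assoc.set_index("marker").loc[mta]
        key = pd.DataFrame(
            {"p": a["p"].to_numpy(), "negabs": -a["beta"].abs().to_numpy(), "marker": list(a.index)}
        )
        ordered = list(key.sort_values(["p", "negabs", "marker"])["marker"])
        if order == "descending_p":
            ordered = ordered[::-1]
    elif order == "as_given":
        ordered = mta
    else:
        raise ValueError("order must be ascending_p, descending_p or as_given")

    sub = geno.subset_lines(lines) if len(lines) != geno.n_lines else geno
    cols = [sub.marker_ids.index(m) for m in ordered]
    Xm = sub.dosages[:, cols]
    yc = y - y.mean()
    syy = float(yc @ yc)
    if syy <= 0:
        raise ValueError("BLUEs have zero variance")

    # sequential (type-I) sums of squares by growing QR
    Xc = Xm - Xm.mean(axis=0, keepdims=True)
    seq_ss = np.zeros(z)
    prev = 0.0
    for k in range(1, z + 1):
        Q, _ = np.linalg.qr(Xc[:, :k])
        ss = float(np.sum((Q.T @ yc) ** 2))
        seq_ss[k - 1] = ss - prev
        prev = ss
    r2 = prev / syy
    r2_adj = r2 - (z / (N - z - 1)) * (1.0 - r2)
    total_p_G = (r2_adj / H2) * 100.0
    ss_sum = seq_ss.sum()
    per = total_p_G * seq_ss / ss_sum if ss_sum > 0 else np.zeros(z)
    table = pd.DataFrame(
        {
            "marker": ordered,
            "entry_order": np.arange(1, z + 1),
            "seq_ss": seq_ss,
            "p_G": per,
        }
    )
    return MTASet(table, float(total_p_G), float(r2), float(r2_adj), H2, N)
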