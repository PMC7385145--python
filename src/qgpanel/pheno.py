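"""Phenotypic stage: variance components, heritability, BLUEs, correlations.

The workhorse model is the two-way linear mixed model for per-environment
adjusted entry means,

    y_ij = mu + G_i + E_j + e_ij,

fitted by REML twice: once with genotype and environment random (variance
components and broad-sense heritability on an entry-mean basis,
H^2 = sigma2_G / (sigma2_G + sigma2_e / nE)), and once with genotype fixed
and environment random (BLUEs, i.e. generalized-least-squares genotype
means across environments). Both fits exploit the indicator structure of
the random effects through the Woodbury identity, so the capacitance matrix
is only (nG + nE) x (nG + nE) and desk-scale panels fit in milliseconds.

Across-environment consistency of a trait is summarized by the Fisher-z
averaged correlation: each pairwise Pearson r is mapped to
z = artanh(r) = 0.5 * ln((1+r)/(1-r)), the z values are averaged, and the
mean is mapped back with tanh. This is less biased than averaging the raw
correlations directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "VarianceComponents",
    "average_correlation",
    "fit_variance_components",
    "heritability",
    "compute_blues",
    "trait_correlations",
    "validate_phenotype_table",
]

PHENO_COLUMNS = ("genotype", "environment", "trait", "value")


@dataclass
class VarianceComponents:
    """REML variance components of the two-way random model."""

    sigma2_G: float
    sigma2_E: float
    sigma2_e: float
    n_environments: int
    converged: bool
    loglik: float = np.nan

    def __post_init__(self) -> None:
        for name in ("sigma2_G", "sigma2_E", "sigma2_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_environments < 1:
            raise ValueError("n_environments must be >= 1")


def validate_phenotype_table(pheno: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format phenotype contract and drop missing values."""
    missing = [c for c in PHENO_COLUMNS if c not in pheno.columns]
    if missing:
        raise ValueError(f"phenotype table lacks columns {missing}")
    out = pheno.copy()
    n_na = out["value"].isna().sum()
    if n_na:
        warnings.warn(f"dropping {n_na} phenotype records with missing values")
        out = out.dropna(subset=["value"])
    dup = out.duplicated(subset=["genotype", "environment", "trait"])
    if dup.any():
        raise ValueError(
            f"{int(dup.sum())} duplicate (genotype, environment, trait) records"
        )
    return out


# ---------------------------------------------------------------------------
# Fisher-z averaged correlation
# ---------------------------------------------------------------------------


def average_correlation(correlations) -> float:
    """Average correlations on the Fisher-z scale and back-transform.

    Each r must lie strictly inside (-1, 1); the result also does, and it
    always lies between the smallest and largest input.
    """
    r = np.asarray(list(correlations), dtype=float)
    if r.size == 0:
        raise ValueError("cannot average an empty list of correlations")
    if np.any(np.abs(r) >= 1.0) or np.any(np.isnan(r)):
        raise ValueError("correlations must lie strictly inside (-1, 1)")
    return float(np.tanh(np.mean(np.arctanh(r))))


# ---------------------------------------------------------------------------
# REML: two-way random model (genotype + environment random)
# ---------------------------------------------------------------------------


def _design_summaries(y, gi, ej, n_g, n_e):
    """Sufficient statistics for the Woodbury-form REML criterion."""
    c_g = np.bincount(gi, minlength=n_g).astype(float)
    c_e = np.bincount(ej, minlength=n_e).astype(float)
    s_g = np.bincount(gi, weights=y, minlength=n_g)
    s_e = np.bincount(ej, weights=y, minlength=n_e)
    cross = np.zeros((n_g, n_e))
    np.add.at(cross, (gi, ej), 1.0)
    return c_g, c_e, s_g, s_e, cross


def _neg2_reml_two_way(gammas, y, stats_):
    g_g, g_e = gammas
    c_g, c_e, s_g, s_e, cross = stats_
    n = y.size
    n_g, n_e = c_g.size, c_e.size
    m = n_g + n_e
    sg, se = np.sqrt(max(g_g, 0.0)), np.sqrt(max(g_e, 0.0))

    C = np.zeros((m, m))
    C[:n_g, :n_g] = np.diag(1.0 + g_g * c_g)
    C[n_g:, n_g:] = np.diag(1.0 + g_e * c_e)
    C[:n_g, n_g:] = sg * se * cross
    C[n_g:, :n_g] = C[:n_g, n_g:].T

    Mty = np.concatenate([sg * s_g, se * s_e])
    Mt1 = np.concatenate([sg * c_g, se * c_e])
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        return np.inf
    logdet_C = 2.0 * np.log(np.diag(L)).sum()
    a = np.linalg.solve(L, np.column_stack([Mty, Mt1]))
    yty, y1, oto = float(y @ y), float(y.sum()), float(n)
    ySy = yty - float(a[:, 0] @ a[:, 0])
    xSx = oto - float(a[:, 1] @ a[:, 1])
    xSy = y1 - float(a[:, 0] @ a[:, 1])
    if xSx <= 0:
        return np.inf
    yPy = ySy - xSy**2 / xSx
    if yPy <= 0:
        return np.inf
    sigma2 = yPy / (n - 1)
    return logdet_C + np.log(xSx) + (n - 1) * np.log(sigma2)


def _moment_start(y, gi, ej, n_g, n_e):
    """Method-of-moments variance ratios used to initialize the optimizer."""
    resid = y - y.mean()
    g_means = np.bincount(gi, weights=y, minlength=n_g) / np.bincount(gi, minlength=n_g)
    e_means = np.bincount(ej, weights=y, minlength=n_e) / np.bincount(ej, minlength=n_e)
    fitted = g_means[gi] + e_means[ej] - y.mean()
    s2e = max(np.var(y - fitted, ddof=1), 1e-8 * np.var(y)) if y.size > 2 else np.var(y)
    s2g = max(np.var(g_means, ddof=1) - s2e / max(n_e, 1), 1e-3 * s2e)
    s2E = max(np.var(e_means, ddof=1) - s2e / max(n_g, 1), 1e-3 * s2e)
    return s2g / s2e, s2E / s2e


def fit_variance_components(pheno: pd.DataFrame, trait: str) -> VarianceComponents:
    """REML variance components for one trait of a long-format phenotype table.

    Genotype and environment are crossed random effects; components are
    constrained non-negative by bounded optimization of the profiled REML
    criterion, and estimates hitting the boundary are clamped to zero.
    """
    df = validate_phenotype_table(pheno)
    df = df[df["trait"] == trait]
    if df.empty:
        raise ValueError(f"trait {trait!r} not present in phenotype table")
    genos = sorted(df["genotype"].unique())
    envs = sorted(df["environment"].unique())
    if len(genos) < 2:
        raise ValueError("need >= 2 genotypes to estimate sigma2_G")
    if len(envs) < 2:
        raise ValueError("sigma2_E is inestimable from a single environment")
    if len(df) <= len(genos) + len(envs):
        raise ValueError("no replication structure: too few records for REML")

    gi = pd.Categorical(df["genotype"], categories=genos).codes
    ej = pd.Categorical(df["environment"], categories=envs).codes
    y = df["value"].to_numpy(dtype=float)
    stats_ = _design_summaries(y, gi, ej, len(genos), len(envs))

    starts = [(1.0, 1.0), _moment_start(y, gi, ej, len(genos), len(envs))]
    best = None
    for x0 in starts:
        res = optimize.minimize(
            _neg2_reml_two_way,
            x0=np.asarray(x0, dtype=float),
            args=(y, stats_),
            method="L-BFGS-B",
            bounds=[(0.0, 1e7), (0.0, 1e7)],
            options={"ftol": 1e-12, "gtol": 1e-10, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    g_g, g_e = np.maximum(best.x, 0.0)

    # recover the profiled residual variance at the optimum
    c_g, c_e, s_g, s_e, cross = stats_
    crit = _neg2_reml_two_way((g_g, g_e), y, stats_)
    n = y.size
    # re-evaluate pieces to extract sigma2_e
    sigma2_e = _profiled_sigma2(g_g, g_e, y, stats_)
    tiny = 1e-10 * max(sigma2_e, 1.0)
    sigma2_G = 0.0 if g_g * sigma2_e < tiny else g_g * sigma2_e
    sigma2_E = 0.0 if g_e * sigma2_e < tiny else g_e * sigma2_e
    return VarianceComponents(
        sigma2_G=float(sigma2_G),
        sigma2_E=float(sigma2_E),
        sigma2_e=float(sigma2_e),
        n_environments=len(envs),
        converged=bool(best.success and np.isfinite(crit)),
        loglik=-0.5 * float(crit),
    )


def _profiled_sigma2(g_g, g_e, y, stats_):
    c_g, c_e, s_g, s_e, cross = stats_
    n = y.size
    n_g, n_e = c_g.size, c_e.size
    sg, se = np.sqrt(g_g), np.sqrt(g_e)
    m = n_g + n_e
    C = np.zeros((m, m))
    C[:n_g, :n_g] = np.diag(1.0 + g_g * c_g)
    C[n_g:, n_g:] = np.diag(1.0 + g_e * c_e)
    C[:n_g, n_g:] = sg * se * cross
    C[n_g:, :n_g] = C[:n_g, n_g:].T
    Mty = np.concatenate([sg * s_g, se * s_e])
    Mt1 = np.concatenate([sg * c_g, se * c_e])
    L = np.linalg.cholesky(C)
    a = np.linalg.solve(L, np.column_stack([Mty, Mt1]))
    ySy = float(y @ y) - float(a[:, 0] @ a[:, 0])
    xSx = float(n) - float(a[:, 1] @ a[:, 1])
    xSy = float(y.sum()) - float(a[:, 0] @ a[:, 1])
    return (ySy - xSy**2 / xSx) / (n - 1)


# ---------------------------------------------------------------------------
# heritability
# ---------------------------------------------------------------------------


def heritability(vc: VarianceComponents) -> float:
    """Broad-sense heritability on an entry-mean basis.

    H^2 = sigma2_G / (sigma2_G + sigma2_e / nE).
    """
    denom = vc.sigma2_G + vc.sigma2_e / vc.n_environments
    if denom <= 0:
        raise ValueError("heritability undefined: sigma2_G + sigma2_e/nE is zero")
    return vc.sigma2_G / denom


# ---------------------------------------------------------------------------
# BLUEs: genotype fixed, environment random
# ---------------------------------------------------------------------------


def compute_blues(pheno: pd.DataFrame, trait: str) -> pd.Series:
    """Across-environment BLUEs (GLS genotype means) for one trait.

    Genotype is fixed (full incidence, no separate intercept, so each
    coefficient is the predicted genotype mean on the trait scale) and
    environment is random; the environment variance ratio is estimated by
    REML on the same data. On balanced complete data the BLUEs equal the
    plain per-genotype means.
    """
    df = validate_phenotype_table(pheno)
    df = df[df["trait"] == trait]
    if df.empty:
        raise ValueError(f"trait {trait!r} not present in phenotype table")
    genos = sorted(df["genotype"].unique())
    envs = sorted(df["environment"].unique())
    gi = pd.Categorical(df["genotype"], categories=genos).codes
    ej = pd.Categorical(df["environment"], categories=envs).codes
    y = df["value"].to_numpy(dtype=float)
    n, n_g, n_e = y.size, len(genos), len(envs)
    if n_g < 1:
        raise ValueError("no genotypes present")

    c_g = np.bincount(gi, minlength=n_g).astype(float)
    c_e = np.bincount(ej, minlength=n_e).astype(float)
    s_g = np.bincount(gi, weights=y, minlength=n_g)
    s_e = np.bincount(ej, weights=y, minlength=n_e)
    cross = np.zeros((n_g, n_e))
    np.add.at(cross, (gi, ej), 1.0)

    def solve(gamma):
        """GLS pieces under Sigma = I + gamma * Ze Ze'."""
        d = gamma / (1.0 + gamma * c_e)  # Woodbury diagonal
        XtSX = np.diag(c_g) - (cross * d) @ cross.T
        XtSy = s_g - (cross * d) @ s_e
        ytSy = float(y @ y) - float(s_e @ (d * s_e))
        return XtSX, XtSy, ytSy

    def neg2_reml(t):
        gamma = np.exp(t)
        XtSX, XtSy, ytSy = solve(gamma)
        sign, logdet_X = np.linalg.slogdet(XtSX)
        if sign <= 0:
            return np.inf
        try:
            beta = np.linalg.solve(XtSX, XtSy)
        except np.linalg.LinAlgError:
            return np.inf
        rss = ytSy - float(beta @ XtSy)
        if rss <= 0 or n <= n_g:
            return np.inf
        logdet_S = float(np.log1p(gamma * c_e).sum())
        return logdet_S + logdet_X + (n - n_g) * np.log(rss / (n - n_g))

    if n_e >= 2 and n > n_g:
        res = optimize.minimize_scalar(
            neg2_reml, bounds=(-18.0, 16.0), method="bounded",
            options={"xatol": 1e-10},
        )
        gamma = float(np.exp(res.x)) if np.isfinite(res.fun) else 0.0
        # boundary: essentially no environment variance
        if res.x <= -17.5:
            gamma = 0.0
    else:
        gamma = 0.0

    XtSX, XtSy, _ = solve(gamma)
    beta = np.linalg.solve(XtSX, XtSy)
    return pd.Series(beta, index=pd.Index(genos, name="genotype"), name=trait)


# ---------------------------------------------------------------------------
# trait correlations
# ---------------------------------------------------------------------------


def trait_correlations(
    blues: pd.DataFrame, traits: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation matrix (with two-sided p-values) among trait BLUEs.

    ``blues`` is wide (genotype x trait). Pairs are computed on genotypes
    observed for both traits; a constant trait vector yields a missing
    correlation with a warning.
    """
    traits = list(traits) if traits is not None else list(blues.columns)
    k = len(traits)
    r = pd.DataFrame(np.eye(k), index=traits, columns=traits)
    p = pd.DataFrame(np.where(np.eye(k), 0.0, np.nan), index=traits, columns=traits)
    for i in range(k):
        for j in range(i + 1, k):
            pair = blues[[traits[i], traits[j]]].dropna()
            if len(pair) < 3:
                raise ValueError(
                    f"traits {traits[i]!r}/{traits[j]!r} share fewer than 3 genotypes"
                )
            x, yv = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
            if np.ptp(x) == 0 or np.ptp(yv) == 0:
                warnings.warn(
                    f"constant trait vector in pair ({traits[i]}, {traits[j]}); "
                    "correlation undefined"
                )
                rij, pij = np.nan, np.nan
            else:
                rij, pij = stats.pearsonr(x, yv)
            r.iloc[i, j] = r.iloc[j, i] = rij
            p.iloc[i, j] = p.iloc[j, i] = pij
    return r, p
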