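"""Phenotypic stage: Fisher-z averaging, REML components, H2, BLUEs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qgpanel.pheno import (
    VarianceComponents,
    average_correlation,
    compute_blues,
    fit_variance_components,
    heritability,
    trait_correlations,
)


def _long(values: np.ndarray, genos=None, envs=None, trait="t") -> pd.DataFrame:
    n, e = values.shape
    genos = genos or [f"g{i}" for i in range(n)]
    envs = envs or [f"E{j}" for j in range(e)]
    return pd.DataFrame(
        {
            "genotype": np.repeat(genos, e),
            "environment": envs * n,
            "trait": trait,
            "value": values.ravel(),
        }
    )


# ---------------------------------------------------------------------------
# Fisher-z averaged correlation
# ---------------------------------------------------------------------------


class TestAverageCorrelation:
    def test_identical_values_are_fixed_points(self):
        assert average_correlation([0.5, 0.5]) == pytest.approx(0.5)
        assert average_correlation([0.0]) == pytest.approx(0.0)

    def test_matches_independent_tanh_arithmetic(self):
        # tanh((artanh 0.5 + artanh 0.7) / 2), high-precision constant
        assert average_correlation([0.5, 0.7]) == pytest.approx(
            0.6096117967977923, abs=1e-12
        )

    @pytest.mark.parametrize("bad", [[1.0], [-1.0], [0.3, 1.2], []])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            average_correlation(bad)

    @given(
        st.lists(
            st.floats(min_value=-0.99, max_value=0.99, allow_nan=False),
            min_size=1,
            max_size=20,
        )
    )
    @settings(max_examples=100, derandomize=True)
    def test_result_between_min_and_max(self, rs):
        r_bar = average_correlation(rs)
        assert min(rs) - 1e-12 <= r_bar <= max(rs) + 1e-12


# ---------------------------------------------------------------------------
# REML variance components
# ---------------------------------------------------------------------------


def _anova_mom(values: np.ndarray):
    """Balanced two-way method-of-moments estimators (independent oracle)."""
    n, e = values.shape
    grand = values.mean()
    gm = values.mean(axis=1)
    em = values.mean(axis=0)
    ss_g = e * ((gm - grand) ** 2).sum()
    ss_e = n * ((em - grand) ** 2).sum()
    resid = values - gm[:, None] - em[None, :] + grand
    ms_g = ss_g / (n - 1)
    ms_e = ss_e / (e - 1)
    ms_r = (resid**2).sum() / ((n - 1) * (e - 1))
    return (ms_g - ms_r) / e, (ms_e - ms_r) / n, ms_r


class TestVarianceComponents:
    def test_matches_balanced_anova_oracle(self):
        rng = np.random.default_rng(5)
        n, e = 80, 6
        values = (
            rng.normal(0, 1.0, (n, 1))
            + rng.normal(0, np.sqrt(2.0), (1, e))
            + rng.normal(0, np.sqrt(0.5), (n, e))
        )
        vc = fit_variance_components(_long(values), "t")
        s2g, s2E, s2e = _anova_mom(values)
        assert vc.converged
        assert vc.sigma2_G == pytest.approx(s2g, rel=1e-3)
        assert vc.sigma2_E == pytest.approx(s2E, rel=1e-3)
        assert vc.sigma2_e == pytest.approx(s2e, rel=1e-3)

    def test_no_genotypic_signal_gives_near_zero_sigma2_g(self):
        rng = np.random.default_rng(11)
        n, e = 300, 4
        values = rng.normal(0, 1.0, (1, e)) + rng.normal(0, 1.0, (n, e))
        vc = fit_variance_components(_long(values), "t")
        total = vc.sigma2_G + vc.sigma2_E + vc.sigma2_e
        assert vc.sigma2_G < 0.05 * total

    def test_single_environment_rejected(self):
        values = np.random.default_rng(0).normal(size=(10, 1))
        with pytest.raises(ValueError, match="inestimable"):
            fit_variance_components(_long(values), "t")

    def test_duplicate_records_rejected(self):
        df = _long(np.zeros((3, 2)))
        dup = pd.concat([df, df.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            fit_variance_components(dup, "t")


# ---------------------------------------------------------------------------
# heritability
# ---------------------------------------------------------------------------


def _vc(g, e, ne):
    return VarianceComponents(g, 1.0, e, ne, True)


class TestHeritability:
    def test_entry_mean_formula(self):
        # printed-component worked examples, two decimals
        assert round(heritability(_vc(0.29, 0.24, 8)), 2) == 0.91
        assert round(heritability(_vc(0.55, 0.22, 3)), 2) == 0.88

    def test_no_residual_gives_one(self):
        assert heritability(_vc(0.7, 0.0, 5)) == pytest.approx(1.0)

    def test_zero_denominator_raises(self):
        with pytest.raises(ValueError):
            heritability(_vc(0.0, 0.0, 4))

    def test_monotonicity_grid(self):
        gs = np.linspace(0.1, 2.0, 8)
        h_in_g = [heritability(_vc(g, 0.5, 4)) for g in gs]
        assert np.all(np.diff(h_in_g) > 0)
        es = np.linspace(0.1, 2.0, 8)
        h_in_e = [heritability(_vc(1.0, e, 4)) for e in es]
        assert np.all(np.diff(h_in_e) < 0)
        nes = [1, 2, 4, 8, 16]
        h_in_ne = [heritability(_vc(1.0, 0.5, ne)) for ne in nes]
        assert np.all(np.diff(h_in_ne) > 0)


# ---------------------------------------------------------------------------
# BLUEs
# ---------------------------------------------------------------------------


class TestBlues:
    def test_balanced_equals_genotype_means(self):
        rng = np.random.default_rng(3)
        values = rng.normal(10, 2, (40, 5))
        blues = compute_blues(_long(values), "t")
        expected = pd.Series(values.mean(axis=1), index=[f"g{i}" for i in range(40)])
        np.testing.assert_allclose(
            blues.loc[expected.index].to_numpy(), expected.to_numpy(), atol=1e-8
        )

    def test_location_equivariance(self):
        rng = np.random.default_rng(4)
        values = rng.normal(0, 1, (15, 4))
        df = _long(values)
        b0 = compute_blues(df, "t")
        df2 = df.assign(value=df["value"] + 7.5)
        b1 = compute_blues(df2, "t")
        np.testing.assert_allclose(b1.to_numpy() - b0.to_numpy(), 7.5, atol=1e-8)

    def test_unbalanced_matches_direct_gls_solve(self):
        # 3 genotypes x 3 environments with 2 cells missing: assemble the
        # mixed-model GLS solution explicitly with dense matrices.
        rng = np.random.default_rng(8)
        values = rng.normal(5, 1, (3, 3))
        df = _long(values)
        df = df.drop(index=[1, 8]).reset_index(drop=True)  # remove 2 cells
        blues = compute_blues(df, "t")

        genos = sorted(df["genotype"].unique())
        envs = sorted(df["environment"].unique())
        X = pd.get_dummies(df["genotype"]).loc[:, genos].to_numpy(float)
        Z = pd.get_dummies(df["environment"]).loc[:, envs].to_numpy(float)
        y = df["value"].to_numpy()

        # estimate the env variance ratio by scalar REML on a dense grid,
        # then solve the GLS normal equations directly
        def crit(gamma):
            V = np.eye(len(y)) + gamma * Z @ Z.T
            Vi = np.linalg.inv(V)
            XtViX = X.T @ Vi @ X
            beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
            rss = (y - X @ beta) @ Vi @ (y - X @ beta)
            _, ld_v = np.linalg.slogdet(V)
            _, ld_x = np.linalg.slogdet(XtViX)
            return ld_v + ld_x + (len(y) - X.shape[1]) * np.log(rss / (len(y) - X.shape[1]))

        grid = np.exp(np.linspace(-18, 16, 4000))
        gamma = grid[int(np.argmin([crit(g) for g in grid]))]
        V = np.eye(len(y)) + gamma * Z @ Z.T
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        np.testing.assert_allclose(blues.to_numpy(), beta, atol=1e-5)


# ---------------------------------------------------------------------------
# trait correlations
# ---------------------------------------------------------------------------


class TestTraitCorrelations:
    def test_self_and_negated(self):
        x = np.array([1.0, 2.0, 4.0, 3.0, 5.0])
        blues = pd.DataFrame({"a": x, "b": x, "c": -x})
        r, p = trait_correlations(blues)
        assert r.loc["a", "a"] == pytest.approx(1.0)
        assert r.loc["a", "b"] == pytest.approx(1.0)
        assert r.loc["a", "c"] == pytest.approx(-1.0)
        assert np.all(r.to_numpy() == r.to_numpy().T)

    def test_matches_textbook_covariance_ratio(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        r, _ = trait_correlations(pd.DataFrame({"x": x, "y": y}))
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert r.loc["x", "y"] == pytest.approx(num / den, abs=1e-12)

    def test_constant_vector_reported_missing(self):
        blues = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0], "c": [2.0] * 4})
        with pytest.warns(UserWarning, match="constant"):
            r, p = trait_correlations(blues)
        assert np.isnan(r.loc["x", "c"])
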