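"""GRM, association scan, FDR and explained-variance contracts."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from qgpanel import (
    GenotypeMatrix,
    GwasModelSpec,
    compute_blues,
    compute_grm,
    fdr_adjust,
    genomic_inflation,
    genotypic_variance_explained,
    run_gwas,
)
from qgpanel.geno import pca


def _gm(dosages):
    dosages = np.asarray(dosages, dtype=float)
    n, p = dosages.shape
    return GenotypeMatrix(dosages, [f"l{i}" for i in range(n)], [f"m{j}" for j in range(p)])


# ---------------------------------------------------------------------------
# GRM
# ---------------------------------------------------------------------------


class TestComputeGrm:
    def test_matches_hand_evaluated_toy(self):
        # 3 lines x 2 markers: p = (2/3, 2/3), denominator 8/9, worked by hand
        g = _gm([[0, 2], [2, 0], [2, 2]])
        grm = compute_grm(g)
        expected = np.array([[2.5, -2.0, -0.5], [-2.0, 2.5, -0.5], [-0.5, -0.5, 1.0]])
        np.testing.assert_allclose(grm.matrix, expected, atol=1e-12)

    def test_rows_sum_to_zero(self, panel):
        grm = compute_grm(panel)
        np.testing.assert_allclose(grm.matrix.sum(axis=1), 0.0, atol=1e-8)

    def test_duplicated_line_identical_rows(self):
        rng = np.random.default_rng(0)
        X = 2.0 * (rng.random((10, 30)) < 0.5)
        X[1] = X[0]
        grm = compute_grm(_gm(X))
        np.testing.assert_allclose(grm.matrix[0], grm.matrix[1], atol=1e-12)

    def test_invariant_to_marker_order_and_monomorphic_padding(self):
        rng = np.random.default_rng(1)
        X = 2.0 * (rng.random((12, 20)) < 0.4)
        g1 = compute_grm(_gm(X)).matrix
        perm = rng.permutation(20)
        g2 = compute_grm(_gm(X[:, perm])).matrix
        np.testing.assert_allclose(g1, g2, atol=1e-10)
        padded = np.hstack([X, np.zeros((12, 1))])  # monomorphic marker
        g3 = compute_grm(_gm(padded)).matrix
        np.testing.assert_allclose(g1, g3, atol=1e-10)

    def test_all_monomorphic_raises(self):
        with pytest.raises(ValueError, match="monomorphic"):
            compute_grm(_gm(np.zeros((5, 3))))


# ---------------------------------------------------------------------------
# association scan
# ---------------------------------------------------------------------------


class TestRunGwas:
    def test_naive_equals_ols_t_test(self, panel, sparse_trait):
        pheno, _ = sparse_trait
        blues = compute_blues(pheno, "sim_trait")
        assoc = run_gwas(blues, panel, GwasModelSpec("naive"))
        # statsmodels OLS as the independent oracle on a handful of markers
        y = blues.loc[panel.line_ids].to_numpy()
        for j in [0, 13, 101, 400]:
            x = sm.add_constant(panel.dosages[:, j])
            fit = sm.OLS(y, x).fit()
            assert assoc["p"].iloc[j] == pytest.approx(fit.pvalues[1], rel=1e-8)
            assert assoc["beta"].iloc[j] == pytest.approx(fit.params[1], rel=1e-8)

    def test_collinear_marker_reported_non_estimable(self):
        rng = np.random.default_rng(5)
        base = 2.0 * (rng.random(60) < 0.5)
        X = np.column_stack([base, base])
        g = _gm(X)
        blues = pd.Series(rng.normal(size=60), index=g.line_ids)
        # PC1 of a two-identical-marker matrix is collinear with each of them
        scores = pca(g, k=1).scores
        assoc = run_gwas(blues, g, GwasModelSpec("pc", n_pcs=1), pc_scores=scores)
        assert assoc.loc[0, "reason"] == "non_estimable"
        assert np.isnan(assoc.loc[0, "p"])

    def test_kinship_model_detects_planted_qtl(self, panel, sparse_trait):
        pheno, truth = sparse_trait
        blues = compute_blues(pheno, "sim_trait")
        assoc = run_gwas(blues, panel, GwasModelSpec("pc_g"))
        tested = assoc.dropna(subset=["p"])
        flags = fdr_adjust(tested["p"], q=0.20)
        mta = set(tested.loc[flags, "marker"])
        assert sum(m in mta for m in truth.qtl_markers) >= 3

    def test_per_marker_reml_agrees_with_p3d_on_null_scan(self, panel):
        # under a marker-free trait the P3D shortcut and exact per-marker
        # REML are interchangeable
        rng = np.random.default_rng(19)
        blues = pd.Series(rng.normal(size=panel.n_lines), index=panel.line_ids)
        small = panel.subset_markers(panel.marker_ids[:25])
        p3d = run_gwas(blues, small, GwasModelSpec("g"))
        exact = run_gwas(blues, small, GwasModelSpec("g", per_marker_reml=True))
        # the shortcut and the exact scan rank markers the same way and give
        # P-values of the same magnitude (they are different estimators, so
        # exact numerical identity is not expected)
        ok = p3d["p"].notna()
        from scipy import stats as sps

        rho = sps.spearmanr(p3d.loc[ok, "p"], exact.loc[ok, "p"]).statistic
        assert rho > 0.95
        np.testing.assert_allclose(
            -np.log10(p3d.loc[ok, "p"]), -np.log10(exact.loc[ok, "p"]), atol=1.0
        )


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------


def _bh_bruteforce(p, q):
    """Literal step-up definition, independent of statsmodels."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= q * rank / m:
            k_max = rank
    flags = np.zeros(m, dtype=bool)
    flags[order[:k_max]] = True
    return flags


class TestFdrAdjust:
    def test_single_pvalue(self):
        assert fdr_adjust([0.19], q=0.20)[0]
        assert not fdr_adjust([0.21], q=0.20)[0]

    def test_all_ones_none_significant(self):
        assert not fdr_adjust([1.0] * 8, q=0.20).any()

    def test_matches_bruteforce_step_up(self):
        p = [0.01, 0.02, 0.04, 0.9]
        np.testing.assert_array_equal(fdr_adjust(p, 0.20), _bh_bruteforce(p, 0.20))

    @given(
        st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=30),
        st.floats(min_value=0.01, max_value=0.5),
    )
    @settings(max_examples=100, derandomize=True)
    def test_agrees_with_bruteforce_and_is_monotone_in_q(self, p, q):
        np.testing.assert_array_equal(fdr_adjust(p, q), _bh_bruteforce(p, q))
        stricter = fdr_adjust(p, q / 2)
        assert not np.any(stricter & ~fdr_adjust(p, q))

    def test_empty_and_invalid(self):
        assert fdr_adjust([]).size == 0
        with pytest.raises(ValueError):
            fdr_adjust([0.5, np.nan])


# ---------------------------------------------------------------------------
# p_G
# ---------------------------------------------------------------------------


class TestGenotypicVarianceExplained:
    def test_no_mta_zero(self, panel):
        blues = pd.Series(np.arange(panel.n_lines, dtype=float), index=panel.line_ids)
        res = genotypic_variance_explained(blues, panel, [], H2=0.9)
        assert res.total_p_G == 0.0

    def test_printed_adjustment_formula(self):
        # R2=0.5, z'=2, N=100, H2=1 -> 100 * (0.5 - (2/97) * 0.5)
        r2, z, N = 0.5, 2, 100
        expected = 100 * (r2 - (z / (N - z - 1)) * (1 - r2))
        assert expected == pytest.approx(48.96907216494845)
        # engineer data with exactly that R2 via two orthogonal regressors
        rng = np.random.default_rng(2)
        x1 = np.tile([0.0, 2.0], 50)
        x2 = np.repeat([0.0, 2.0], 50)
        noise = rng.normal(size=N)
        # orthogonalize noise against [1, x1, x2]
        Q, _ = np.linalg.qr(np.column_stack([np.ones(N), x1, x2]))
        noise -= Q @ (Q.T @ noise)
        signal = (x1 - x1.mean()) + (x2 - x2.mean())
        # scale noise so R2 is exactly 0.5
        noise *= np.sqrt((signal @ signal) / (noise @ noise))
        y = signal + noise
        g = _gm(np.column_stack([x1, x2]))
        blues = pd.Series(y, index=g.line_ids)
        res = genotypic_variance_explained(blues, g, ["m0", "m1"], H2=1.0, order="as_given")
        assert res.r2 == pytest.approx(0.5, abs=1e-10)
        assert res.total_p_G == pytest.approx(48.96907216494845, abs=1e-8)

    def test_ascending_p_order_and_apportionment(self, panel, sparse_trait):
        pheno, truth = sparse_trait
        blues = compute_blues(pheno, "sim_trait")
        assoc = run_gwas(blues, panel, GwasModelSpec("naive"))
        mta = truth.qtl_markers
        res = genotypic_variance_explained(blues, panel, mta, H2=0.9, assoc=assoc)
        # entry order follows ascending P
        ps = assoc.set_index("marker").loc[res.table["marker"], "p"].to_numpy()
        assert np.all(np.diff(ps) >= 0)
        # per-marker p_G sums to the total
        assert res.table["p_G"].sum() == pytest.approx(res.total_p_G)

    def test_undefined_adjustment_raises(self, panel):
        blues = pd.Series(
            np.arange(4, dtype=float), index=panel.line_ids[:4]
        )
        with pytest.raises(ValueError, match="undefined"):
            genotypic_variance_explained(
                blues, panel.subset_lines(panel.line_ids[:4]),
                panel.marker_ids[:3], H2=0.9, order="as_given",
            )


def test_genomic_inflation_near_one_under_uniform_null():
    rng = np.random.default_rng(0)
    lam = genomic_inflation(rng.uniform(size=20000))
    assert lam == pytest.approx(1.0, abs=0.05)
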