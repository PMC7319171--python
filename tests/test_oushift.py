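import numpy as np
import pytest
from scipy.stats import multivariate_normal

from phyloshift import (OUParameters, bic_weights, bm_covariance,
                        compare_models, detect_shifts_lasso, fit_bm,
                        fit_gls_ou, ou_covariance, read_newick,
                        shift_design_matrix, simulate_bm_traits,
                        simulate_ou_traits)
from phyloshift.oushift import candidate_branches

from conftest import random_tree


class TestBMCovariance:
    def test_three_tip_shared_paths(self, three_tip):
        C = bm_covariance(three_tip)
        labs = list(three_tip.tip_labels)
        i, j, k = labs.index("A"), labs.index("B"), labs.index("C")
        assert C[i, i] == C[j, j] == C[k, k] == 2.0
        assert C[i, j] == 1.0
        assert C[i, k] == C[j, k] == 0.0

    def test_star_tree(self):
        t = read_newick("(A:3,B:3,C:3);")
        assert np.allclose(bm_covariance(t), 3.0 * np.eye(3))

    def test_positive_semidefinite_on_random_trees(self):
        for seed in range(20):
            C = bm_covariance(random_tree(seed, 20))
            assert np.linalg.eigvalsh(C).min() >= -1e-10


class TestOUCovariance:
    def test_closed_form_entry(self, three_tip):
        V = ou_covariance(three_tip, alpha=1.0, sigma2=1.0)
        labs = list(three_tip.tip_labels)
        i, j = labs.index("A"), labs.index("B")
        assert V[i, j] == pytest.approx(0.5 * np.exp(-2) * (1 - np.exp(-2)))

    def test_bm_limit(self, yule50):
        alpha = 1e-6 / yule50.height
        V = ou_covariance(yule50, alpha, sigma2=2.0)
        C = 2.0 * bm_covariance(yule50)
        assert np.allclose(V, C, rtol=1e-4)

    def test_identical_diagonal_on_ultrametric_tree(self, yule50):
        V = ou_covariance(yule50, alpha=3.0, sigma2=1.5)
        T = yule50.height
        expected = 1.5 / 6.0 * (1 - np.exp(-6.0 * T))
        assert np.allclose(np.diag(V), expected)

    def test_non_ultrametric_rejected(self):
        t = read_newick("((A:1,B:1):1,C:5);")
        with pytest.raises(ValueError, match="ultrametric"):
            ou_covariance(t, 1.0, 1.0)


class TestShiftDesign:
    def test_terminal_branch_closed_form(self):
        t = read_newick("(A:1,B:1);")
        b = t.tip_index("A")
        X = shift_design_matrix(t, alpha=np.log(2), branches=[b])
        col = dict(zip(t.tip_labels, X[:, 0]))
        assert col["A"] == pytest.approx(0.5)
        assert col["B"] == 0.0

    def test_saturates_to_one_at_large_alpha(self):
        t = read_newick("(A:1,B:1);")
        X = shift_design_matrix(t, alpha=1e3, branches=[t.tip_index("A")])
        assert X.max() == pytest.approx(1.0)

    def test_internal_branch_covers_whole_clade(self, three_tip):
        b = three_tip.mrca(["A", "B"])
        X = shift_design_matrix(three_tip, alpha=2.0, branches=[b])
        col = dict(zip(three_tip.tip_labels, X[:, 0]))
        # shift starts at the branch start (time 0 of a height-2 tree) and is
        # inherited by A and B for the remaining 2 time units
        expected = 1 - np.exp(-2.0 * 2.0)
        assert col["A"] == pytest.approx(expected)
        assert col["B"] == pytest.approx(expected)
        assert col["C"] == 0.0


class TestGLSFit:
    def test_two_identical_tips(self):
        t = read_newick("(A:1,B:1);")
        fit = fit_gls_ou(t, {"A": 1.0, "B": 1.0})
        assert fit.params.theta0 == pytest.approx(1.0)
        assert fit.params.sigma2 <= 1e-10  # floored

    def test_bm_closed_form_two_tips(self):
        t = read_newick("(A:1,B:1);")
        fit = fit_bm(t, {"A": 0.0, "B": 2.0})
        assert fit.params.theta0 == pytest.approx(1.0)
        assert fit.params.sigma2 == pytest.approx(1.0)
        assert fit.loglik == pytest.approx(-np.log(2 * np.pi) - 1)
        assert fit.n_params == 2
        assert fit.bic == pytest.approx(-2 * fit.loglik + 2 * np.log(2))

    @pytest.mark.parametrize("n_shifts", [0, 1])
    def test_loglik_matches_dense_mvn(self, n_shifts):
        """Whitened-GLS likelihood equals direct multivariate-normal density
        with the full OU covariance."""
        for seed in range(5):
            tree = random_tree(seed, 8)
            shifts = []
            if n_shifts:
                internal = [b for b in candidate_branches(tree)
                            if tree.children[b]]
                shifts = [int(internal[0])]
            x = simulate_bm_traits(tree, 1.0, 0.0, seed=seed)
            fit = fit_gls_ou(tree, x, shifts)
            V = ou_covariance(tree, fit.params.alpha, fit.params.sigma2)
            dense = multivariate_normal(mean=fit.fitted_tip_means, cov=V,
                                        allow_singular=False)
            xv = np.array([x[l] for l in tree.tip_labels])
            assert fit.loglik == pytest.approx(dense.logpdf(xv), rel=1e-8)

    def test_bm_loglik_matches_dense_mvn(self):
        tree = random_tree(3, 10)
        x = simulate_bm_traits(tree, 0.5, 1.0, seed=3)
        fit = fit_bm(tree, x)
        V = fit.params.sigma2 * bm_covariance(tree)
        xv = np.array([x[l] for l in tree.tip_labels])
        dense = multivariate_normal(mean=fit.fitted_tip_means, cov=V)
        assert fit.loglik == pytest.approx(dense.logpdf(xv), rel=1e-8)

    def test_affine_equivariance(self, yule50):
        x = simulate_bm_traits(yule50, 1.0, 0.0, seed=6)
        internal = [b for b in candidate_branches(yule50) if yule50.children[b]]
        s = [int(internal[3])]
        f0 = fit_gls_ou(yule50, x, s)
        f1 = fit_gls_ou(yule50, {l: v + 10.0 for l, v in x.items()}, s)
        assert f1.params.theta0 == pytest.approx(f0.params.theta0 + 10.0)
        assert f1.params.alpha == f0.params.alpha
        assert f1.params.sigma2 == pytest.approx(f0.params.sigma2)
        assert f1.loglik == pytest.approx(f0.loglik)
        assert f1.params.shifts[0][1] == pytest.approx(f0.params.shifts[0][1])

    def test_unidentifiable_shifts_rejected(self, yule50):
        a, b = (int(c) for c in yule50.children[yule50.root])
        x = simulate_bm_traits(yule50, 1.0, 0.0, seed=0)
        with pytest.raises(ValueError, match="singular|unidentifiable"):
            fit_gls_ou(yule50, x, [a, b])

    def test_shift_magnitude_recovery(self, yule50):
        """Fitting at the true shift branch recovers the planted magnitude."""
        sizes = {int(b): yule50.clade_tips(int(b)).size
                 for b in candidate_branches(yule50)}
        b = min((bb for bb, k in sizes.items() if 8 <= k <= 14),
                key=lambda bb: abs(yule50.ages[bb] - 0.5))
        alpha, sd = 2.0, 0.1
        params = OUParameters(alpha=alpha, sigma2=2 * alpha * sd**2,
                              theta0=0.0, shifts=((b, 1.0),))
        errs = []
        for rep in range(30):
            x = simulate_ou_traits(yule50, params, seed=500 + rep)
            fit = fit_gls_ou(yule50, x, [b])
            errs.append(fit.params.shifts[0][1] - 1.0)
        assert abs(np.median(errs)) <= 0.2

    def test_parameter_recovery(self, yule50):
        """Median alpha-hat and sigma2-hat within +-50% of truth for
        alpha * T in the well-identified range."""
        truth = OUParameters(alpha=4.0, sigma2=0.5, theta0=0.0)
        alphas, sigmas = [], []
        for rep in range(30):
            x = simulate_ou_traits(yule50, truth, seed=900 + rep)
            fit = fit_gls_ou(yule50, x, ())
            alphas.append(fit.params.alpha)
            sigmas.append(fit.params.sigma2)
        assert 0.5 * truth.alpha <= np.median(alphas) <= 1.5 * truth.alpha
        assert 0.5 * truth.sigma2 <= np.median(sigmas) <= 1.5 * truth.sigma2


class TestDetect:
    def test_zero_max_shifts_equals_plain_fit(self, yule50):
        x = simulate_bm_traits(yule50, 1.0, 0.0, seed=4)
        d = detect_shifts_lasso(yule50, x, max_shifts=0)
        f = fit_gls_ou(yule50, x, ())
        assert d.shift_branches == ()
        assert d.loglik == pytest.approx(f.loglik)
        assert d.bic == pytest.approx(f.bic)

    def test_detects_planted_large_shift(self, yule50):
        sizes = {int(b): yule50.clade_tips(int(b)).size
                 for b in candidate_branches(yule50)}
        b = min((bb for bb, k in sizes.items() if 8 <= k <= 14),
                key=lambda bb: abs(yule50.ages[bb] - 0.5))
        alpha, sd = 5.0, 0.5
        params = OUParameters(alpha=alpha, sigma2=2 * alpha * sd**2,
                              theta0=0.0, shifts=((b, 4 * sd),))
        x = simulate_ou_traits(yule50, params, seed=77)
        fit = detect_shifts_lasso(yule50, x, max_shifts=3)
        neighbourhood = {b, int(yule50.parent[b])} | set(map(int, yule50.children[b]))
        assert neighbourhood & set(fit.shift_branches)


class TestModelComparison:
    def test_weights_sum_to_one_and_closed_forms(self):
        w = bic_weights({"a": 10.0, "b": 12.0, "c": 12.0})
        assert sum(w.values()) == pytest.approx(1.0)
        assert w["b"] == pytest.approx(w["c"])  # equal BIC, equal weight
        assert w["a"] / w["b"] == pytest.approx(np.e)  # dBIC = 2

    def test_four_models_reported(self, yule50):
        x = simulate_bm_traits(yule50, 1.0, 0.0, seed=12)
        wgd = [yule50.labels[t] for t in
               yule50.clade_tips(int(yule50.children[yule50.root][0]))]
        if len(wgd) < 2 or len(wgd) > 48:
            wgd = list(yule50.tip_labels[:5])
        cmp = compare_models(yule50, x, wgd)
        assert set(cmp.bic) == {"BM", "OU_k0", "OU_variable", "OU_fixed"}
        assert sum(cmp.bicw.values()) == pytest.approx(1.0)
        assert cmp.best in cmp.bic
        assert len(cmp.fits["OU_fixed"].shift_branches) == 1
        for name, fit in cmp.fits.items():
            expected = 2 if name == "BM" else 3 + len(fit.shift_branches)
            assert fit.n_params == expected
            assert fit.bic == pytest.approx(-2 * fit.loglik
                                            + expected * np.log(yule50.n_tips))
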