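"""Score statistic, information matrix, theoretical and permutation nulls."""

import numpy as np
import pytest
from scipy import stats

from isovct import (
    DesignVector,
    build_RC,
    choose_family,
    cumulants,
    family_weights,
    fit_null,
    information,
    permutation_pvalue,
    score_statistic,
    theoretical_pvalue,
)
from isovct import TestConfig as Config            # avoid pytest collection
from isovct import test_gene as run_gene_test
from isovct.vct_test import _permutation_kernel, _residuals

from conftest import make_gene


# --- independent dense-matrix oracle ---------------------------------------

def dense_U(counts, fit, x):
    """U from the explicit Np x Np matrix expression (observation order:
    sample-major, isoforms fastest)."""
    n, p = counts.counts.shape
    y = counts.counts.astype(float).reshape(-1)      # (i, j) -> i*p + j
    gamma = fit.gamma.reshape(-1)
    X = np.zeros((n * p, p))
    for i in range(n):
        X[i * p:(i + 1) * p, :] = x.x[i] * np.eye(p)
    XXt = X @ X.T
    w = family_weights(fit, counts)
    z = y - gamma
    Phi = np.diag(w.phi_diag.reshape(-1))
    W_trace = np.diag(w.w0.reshape(-1))
    quad = z @ Phi @ XXt @ Phi @ z
    trace = np.trace(W_trace @ XXt)
    return 0.5 * (quad - trace)


@pytest.mark.parametrize("family", ["poisson", "nb"])
def test_simplified_U_equals_dense_matrix_form(family):
    """Per-isoform computation of U agrees with the stacked-matrix formula."""
    for k in range(50):
        rng = np.random.default_rng(10_000 + k)
        n = rng.integers(3, 7)
        p = rng.integers(1, 4)
        gene = make_gene(rng.poisson(rng.uniform(1, 10), size=(n, p)) + 1)
        x = DesignVector(rng.normal(size=n) if k % 2 else
                         (np.arange(n) < n // 2).astype(float))
        fit = fit_null(gene, family=family,
                       phi=rng.uniform(0.1, 3.0) if family == "nb" else None)
        got = score_statistic(gene, fit, x)
        expected = dense_U(gene, fit, x)
        assert got.U == pytest.approx(expected, rel=1e-10, abs=1e-10)
        assert got.U == pytest.approx(
            (got.quadratic_term - got.trace_term) / 2, rel=1e-12)


def test_score_worked_example():
    """N=4, p=1, x=(0,0,1,1), y=(1,3,2,6), Poisson fixed fit (gamma=3)."""
    gene = make_gene(np.array([[1], [3], [2], [6]]))
    fit = fit_null(gene, family="poisson")
    score = score_statistic(gene, fit, DesignVector(np.array([0, 0, 1, 1.0])))
    assert score.quadratic_term == pytest.approx(4.0)
    assert score.trace_term == pytest.approx(6.0)
    assert score.U == pytest.approx(-1.0)


def test_zero_design_gives_zero_U():
    gene = make_gene(np.array([[1, 2], [3, 4], [5, 6]]))
    fit = fit_null(gene)
    score = score_statistic(gene, fit, DesignVector(np.zeros(3)))
    assert score.U == 0.0


def test_nb_U_continuous_at_small_phi(rng):
    gene = make_gene(rng.poisson(5, size=(8, 2)))
    x = DesignVector((np.arange(8) < 4).astype(float))
    U_pois = score_statistic(gene, fit_null(gene, family="poisson"), x).U
    U_nb = score_statistic(gene, fit_null(gene, family="nb", phi=1e-10), x).U
    assert U_nb == pytest.approx(U_pois, abs=1e-6)


# --- cumulants and R/C ------------------------------------------------------

class TestCumulants:
    def test_poisson_all_equal_gamma(self):
        k2, k3, k4 = cumulants("poisson", np.array([2.0]))
        assert (k2[0], k3[0], k4[0]) == (2.0, 2.0, 2.0)

    def test_nb_matches_closed_form_nb_cumulants(self):
        """Variance-function relations reproduce the true NB cumulants
        kappa3 = g(1+pg)(1+2pg), kappa4 = g(1+pg)(1+6pg(1+pg))."""
        for gamma, phi in [(1.0, 1.0), (5.0, 0.5), (2.5, 2.0)]:
            k2, k3, k4 = cumulants("nb", np.array([gamma]), phi)
            q = phi * gamma
            assert k2[0] == pytest.approx(gamma * (1 + q))
            assert k3[0] == pytest.approx(gamma * (1 + q) * (1 + 2 * q))
            assert k4[0] == pytest.approx(gamma * (1 + q) * (1 + 6 * q * (1 + q)))

    def test_nb_example_values(self):
        k2, k3, k4 = cumulants("nb", np.array([1.0]), 1.0)
        assert (k2[0], k3[0], k4[0]) == (2.0, 6.0, 26.0)

    def test_monte_carlo_cross_check(self, rng):
        gamma, phi = 1.0, 1.0
        r = 1 / phi
        y = rng.negative_binomial(r, r / (r + gamma), size=1_000_000).astype(float)
        assert np.var(y) == pytest.approx(2.0, rel=0.02)
        assert stats.kstat(y, 3) == pytest.approx(6.0, rel=0.05)

    def test_phi_zero_is_poisson(self):
        g = np.array([3.0, 7.0])
        assert all(np.allclose(a, b) for a, b in
                   zip(cumulants("nb", g, 0.0), cumulants("poisson", g)))


class TestBuildRC:
    def test_poisson_closed_forms(self):
        gene = make_gene(np.array([[2], [2]]))
        fit = fit_null(gene, family="poisson")
        r, c = build_RC(family_weights(fit, gene),
                        cumulants("poisson", fit.gamma))
        assert np.allclose(r, 2 + 2 * 4)       # gamma + 2 gamma^2
        assert np.allclose(c, 2.0)             # gamma

    def test_nb_phi_to_zero_reduction(self):
        gene = make_gene(np.array([[2], [2]]))
        fit = fit_null(gene, family="nb", phi=1e-8)
        r, c = build_RC(family_weights(fit, gene),
                        cumulants("nb", fit.gamma, fit.phi_hat))
        assert np.allclose(r, 10.0, atol=1e-5)

    def test_nb_c_value(self):
        gene = make_gene(np.array([[1], [1]]))
        fit = fit_null(gene, family="nb", phi=1.0)
        _, c = build_RC(family_weights(fit, gene),
                        cumulants("nb", fit.gamma, 1.0))
        assert np.allclose(c, 0.5)


# --- information ------------------------------------------------------------

class TestInformation:
    def test_I_tilde_bounded_by_I_tautau(self, random_gene, balanced_design):
        for k in range(10):
            gene = random_gene(n=8, p=3, seed=500 + k)
            fit = fit_null(gene, family="poisson")
            info = information(gene, fit, balanced_design(8))
            assert 0 < info.I_tilde <= info.I_tautau + 1e-12

    def test_constant_design_rejected(self, random_gene):
        gene = random_gene()
        with pytest.raises(ValueError, match="constant"):
            information(gene, fit_null(gene), DesignVector(np.ones(6)))

    def test_variance_of_U_matches_I_tilde_known_parameters(self):
        """Under a known-parameter Poisson null, Var(U) ~ I_tilde (the primary
        correctness check of the R/C assembly)."""
        rng = np.random.default_rng(42)
        n, p, gamma0, reps = 40, 2, 5.0, 20_000
        x = np.where(np.arange(n) < n // 2, 0.5, -0.5)
        y = rng.poisson(gamma0, size=(reps, n, p))
        q = np.einsum("i,rij->rj", x, y - gamma0)
        trace = np.sum(x**2) * gamma0 * p
        U = 0.5 * ((q**2).sum(axis=1) - trace)
        template = make_gene(np.full((n, p), int(gamma0)))
        fit = fit_null(template, family="poisson")   # column means = gamma0
        info = information(template, fit, DesignVector(x))
        assert abs(U.mean()) < 5 * U.std() / np.sqrt(reps)
        assert U.var() == pytest.approx(info.I_tilde, rel=0.15)

    def test_phi_to_zero_reduction_of_all_quantities(self, rng):
        gene = make_gene(rng.poisson(6, size=(10, 3)))
        x = DesignVector(np.where(np.arange(10) < 5, 0.5, -0.5))
        fit_p = fit_null(gene, family="poisson")
        fit_n = fit_null(gene, family="nb", phi=1e-8)
        U_p = score_statistic(gene, fit_p, x).U
        U_n = score_statistic(gene, fit_n, x).U
        I_p = information(gene, fit_p, x).I_tilde
        I_n = information(gene, fit_n, x).I_tilde
        assert U_n == pytest.approx(U_p, rel=1e-4, abs=1e-8)
        assert I_n == pytest.approx(I_p, rel=1e-4)
        assert theoretical_pvalue(U_n, I_n) == pytest.approx(
            theoretical_pvalue(U_p, I_p), rel=1e-4)


# --- p-values ---------------------------------------------------------------

class TestTheoreticalPvalue:
    def test_zero_score_gives_p_one(self):
        assert theoretical_pvalue(0.0, 5.0) == 1.0

    def test_critical_value(self):
        U = np.sqrt(3.841 * 2.0)
        assert theoretical_pvalue(U, 2.0) == pytest.approx(0.050, abs=5e-4)

    def test_sidedness_for_large_negative_U(self):
        assert theoretical_pvalue(-10.0, 4.0) < 0.01
        assert theoretical_pvalue(-10.0, 4.0, one_sided=True) > 0.5

    def test_nonpositive_information_rejected(self):
        with pytest.raises(ValueError):
            theoretical_pvalue(1.0, 0.0)


class TestPermutation:
    def test_identical_samples_give_p_one(self):
        gene = make_gene(np.tile([3, 7], (6, 1)))
        fit = fit_null(gene)
        x = DesignVector((np.arange(6) < 3).astype(float))
        p, _ = permutation_pvalue(gene, fit, x, B=200)
        assert p == 1.0

    def test_add_one_convention(self, rng):
        """p = 1/(B+1) when the observed U beats every sampled permutation."""
        n = 12
        counts = np.concatenate([rng.poisson(2, (n // 2, 1)),
                                 rng.poisson(40, (n // 2, 1))])
        gene = make_gene(counts)
        fit = fit_null(gene)
        x = DesignVector((np.arange(n) < n // 2).astype(float))
        p, U_perm = permutation_pvalue(gene, fit, x, B=999, seed=1, exact=False)
        if (U_perm < _permutation_kernel(
                _residuals(gene, fit),
                family_weights(fit, gene).w0.sum(axis=1), x.x[None, :])[0]).all():
            assert p == pytest.approx(1 / 1000)
        assert p <= 5 / 1000

    def test_mean_of_permuted_U_matches_closed_form(self, rng):
        """E_perm[U] has an exact closed form under label shuffling (residual
        columns are centered by the fixed-mode fit)."""
        gene = make_gene(rng.poisson(5, size=(20, 3)))
        fit = fit_null(gene, family="poisson")
        x = DesignVector((np.arange(20) < 10).astype(float))
        _, U_perm = permutation_pvalue(gene, fit, x, B=4000, seed=3, exact=False)
        z = _residuals(gene, fit)
        t = family_weights(fit, gene).w0.sum(axis=1)
        n, n1 = 20, 10
        expected = 0.5 * (n1 * (n - n1) / (n * (n - 1)) * np.sum(z**2)
                          - n1 / n * np.sum(t))
        se = U_perm.std() / np.sqrt(len(U_perm))
        assert U_perm.mean() == pytest.approx(expected, abs=3 * se)

    def test_exact_mode_invariant_to_relabeling(self, rng):
        gene = make_gene(rng.poisson(5, size=(8, 2)))
        x = np.array([1, 1, 1, 1, 0, 0, 0, 0.0])
        perm = rng.permutation(8)
        gene2 = make_gene(gene.counts[perm])
        p1, _ = permutation_pvalue(gene, fit_null(gene), DesignVector(x), B=500)
        p2, _ = permutation_pvalue(gene2, fit_null(gene2),
                                   DesignVector(x[perm]), B=500)
        assert p1 == p2


class TestChooseFamily:
    def test_negligible_dispersion_falls_back_to_poisson(self, rng):
        gene = make_gene(rng.poisson(8, size=(40, 2)))
        assert choose_family(gene) == "poisson"

    def test_failed_nb_fit_falls_back_to_poisson(self, monkeypatch, random_gene):
        import isovct.vct_test as vt

        def boom(*args, **kwargs):
            raise RuntimeError("no convergence")

        monkeypatch.setattr(vt, "fit_null", boom)
        assert vt.choose_family(random_gene()) == "poisson"

    def test_overdispersed_genes_keep_nb(self):
        from isovct import Scenario, simulate_gene
        sc = Scenario.from_mean(5.0, N=40, p=4, s=0.0, l=0.0, phi=2.0, family="nb")
        picks = [choose_family(simulate_gene(sc, k).counts) for k in range(200)]
        assert np.mean([f == "nb" for f in picks]) >= 0.95


class TestTestGene:
    def test_constant_design_rejected(self, random_gene):
        with pytest.raises(ValueError, match="constant"):
            run_gene_test(random_gene(), DesignVector(np.zeros(6)))

    def test_B_zero_disables_empirical(self, random_gene, balanced_design):
        res = run_gene_test(random_gene(), balanced_design(6),
                        Config(family="poisson", B=0))
        assert res.p_empirical is None
        assert 0 <= res.p_theoretical <= 1

    def test_deterministic_given_seed(self, random_gene, balanced_design):
        gene, x = random_gene(n=10, p=2), balanced_design(10)
        cfg = Config(family="nb", B=300, seed=7)
        assert run_gene_test(gene, x, cfg) == run_gene_test(gene, x, cfg)

    def test_chi2_consistency(self, random_gene, balanced_design):
        res = run_gene_test(random_gene(n=10), balanced_design(10),
                        Config(family="poisson", B=0))
        assert res.chi2 == pytest.approx(res.U**2 / res.I_tilde)
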