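"""The variance-component score test: statistic, theoretical and empirical nulls.

The score of the log-likelihood with respect to the variance component tau^2
of the per-isoform group effects, evaluated at H0, is

    U = 1/2 * ( z^T Phi X X^T Phi z  -  tr(W0 X X^T) )

with z = Y - gamma_hat the stacked residuals, Phi the NB weighting (identity
for Poisson) and W0 the observed-weight diagonal.  Because X stacks x_i * I_p,
this collapses to a per-isoform form: the quadratic term is
sum_j (sum_i x_i z~_ij)^2 with z~ = Phi z, and the trace term is
sum_i x_i^2 sum_j w0_ij.  The theoretical null standardizes U by the efficient
information I~ = I_tautau - I_at^T I_aa^- I_at and refers U^2/I~ to a 1-df
chi-square; the empirical null permutes the group labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model_core import (
    NB,
    POISSON,
    FIXED,
    DegenerateGeneError,
    DesignVector,
    FamilyWeights,
    IsoformCountMatrix,
    NullFit,
    family_weights,
    fit_null,
)

__all__ = [
    "ScoreValue", "InformationDecomp", "VctResult", "TestConfig",
    "score_statistic", "cumulants", "build_RC", "information",
    "theoretical_pvalue", "permutation_pvalue", "choose_family", "test_gene",
]


@dataclass(frozen=True)
class ScoreValue:
    """U and its two components: U = (quadratic_term - trace_term) / 2."""

    U: float
    quadratic_term: float
    trace_term: float


@dataclass(frozen=True)
class InformationDecomp:
    """Blocks of the information matrix for (tau^2; mu, alpha) at H0."""

    I_tautau: float
    I_at: np.ndarray       # length p+1: (mu, alpha_1..alpha_p) cross terms
    I_aa: np.ndarray       # (p+1) x (p+1), singular by construction
    I_tilde: float
    r_diag: np.ndarray     # N x p diagonal elements of R
    c_diag: np.ndarray     # N x p diagonal elements of C
    kappa2: np.ndarray
    kappa3: np.ndarray
    kappa4: np.ndarray


@dataclass(frozen=True)
class VctResult:
    """Full per-gene test result."""

    gene_id: str
    U: float
    I_tilde: float
    chi2: float
    p_theoretical: float
    p_empirical: float | None
    family_used: str
    B: int
    seed: int | None
    n_isoforms_used: int
    fell_back_poisson: bool = False
    p_one_sided: float | None = None


@dataclass(frozen=True)
class TestConfig:
    """Options for :func:`test_gene`.

    family: "auto" (NB with Poisson fallback), "poisson" or "nb".
    B: permutation count for the empirical null (0 disables it).
    phi_threshold: below this estimated dispersion the Poisson family is used.
    center_design: center x before testing (default).  With per-isoform
    intercepts estimated under H0, the variance-component score built on a raw
    0/1 design is not orthogonal to the intercept scores: U acquires a
    negative mean and a variance well below I_tilde, so the chi-square
    reference loses essentially all power.  Centering restores E[U] = 0 and
    Var(U) ~ I_tilde, and (for balanced binary designs) makes the trace term
    permutation-invariant.
    """

    family: str = "auto"
    mode: str = FIXED
    B: int = 5000
    seed: int | None = 0
    phi_threshold: float = 1e-3
    shrinkage_var: float = 1.0
    one_sided: bool = False
    center_design: bool = True


def _residuals(counts: IsoformCountMatrix, fit: NullFit) -> np.ndarray:
    """Phi-weighted residuals z~_ij feeding the quadratic term."""
    z = counts.counts.astype(float) - fit.gamma
    if fit.family == NB:
        z = z / (1.0 + fit.phi_hat * fit.gamma)
    return z


def score_statistic(counts: IsoformCountMatrix, fit: NullFit,
                    x: DesignVector) -> ScoreValue:
    """The score U for the variance component, family chosen by ``fit``."""
    if len(x) != counts.n_samples:
        raise ValueError("design length does not match the count matrix")
    if fit.gamma.shape != counts.counts.shape:
        raise ValueError("null fit does not match the count matrix")
    z = _residuals(counts, fit)
    weights = family_weights(fit, counts)
    q = x.x @ z                             # per-isoform weighted residual sums
    quadratic = float(q @ q)
    trace = float((x.x**2) @ weights.w0.sum(axis=1))
    return ScoreValue(U=(quadratic - trace) / 2.0,
                      quadratic_term=quadratic, trace_term=trace)


def cumulants(family: str, gamma: np.ndarray,
              phi: float = 0.0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2nd-4th cumulants of the counts from the variance function.

    Exponential-family relations: kappa2 = V, kappa3 = V'V,
    kappa4 = (V''V + V'^2) V.  Poisson (V = gamma): all equal gamma.
    NB (V = gamma + phi*gamma^2): evaluated symbolically.
    """
    gamma = np.asarray(gamma, dtype=float)
    if family == POISSON or phi == 0.0:
        return gamma.copy(), gamma.copy(), gamma.copy()
    V = gamma + phi * gamma**2
    Vp = 1.0 + 2.0 * phi * gamma
    Vpp = 2.0 * phi
    kappa2 = V
    kappa3 = Vp * V
    kappa4 = (Vpp * V + Vp**2) * V
    return kappa2, kappa3, kappa4


def build_RC(weights: FamilyWeights,
             kappas: tuple[np.ndarray, np.ndarray, np.ndarray]
             ) -> tuple[np.ndarray, np.ndarray]:
    """Diagonal elements of the R and C matrices (N x p each).

    R's within-isoform off-diagonal elements are 2 w_i w_i' and are assembled
    implicitly in :func:`information`.  The general forms

        r_ii = w^4 d^-4 k4 + 2 w^2 + e^2 k2 - 2 w^2 d^-2 e k3
        c_ii = w^3 d^-3 k3 - e w d^-1 k2

    reduce to the Poisson closed forms gamma + 2*gamma^2 and gamma.
    """
    k2, k3, k4 = kappas
    w, d, e = weights.w, weights.delta, weights.e
    wd = w / d
    r_diag = wd**4 * k4 + 2.0 * w**2 + e**2 * k2 - 2.0 * wd**2 * e * k3
    c_diag = wd**3 * k3 - e * wd * k2
    return r_diag, c_diag


def information(counts: IsoformCountMatrix, fit: NullFit,
                x: DesignVector) -> InformationDecomp:
    """Efficient information I~ for tau^2 after profiling out (mu, alpha).

    I_tautau = 1/4 J^T (A R A) J with A the diagonal of XX^T (a_i = x_i^2,
    replicated over isoforms) and R block-diagonal with per-isoform N x N
    blocks; I_at = 1/2 K~^T C a~; I_aa = K~^T W K~, inverted by Moore-Penrose
    pseudo-inverse (K~'s columns are linearly dependent by construction).
    """
    x.require_varying()
    weights = family_weights(fit, counts)
    kappas = cumulants(fit.family, fit.gamma, fit.phi_hat)
    r_diag, c_diag = build_RC(weights, kappas)
    a = x.x**2                                       # diagonal of XX^T, per sample

    # I_tautau: per isoform j, a'^T R^j a' with R^j_ii = r_ij and
    # R^j_ii' = 2 w_ij w_i'j (i != i')
    w = weights.w
    diag_part = (a**2) @ r_diag                       # sum_j sum_i a_i^2 r_ij
    aw = a @ w                                        # per-isoform sum_i a_i w_ij
    cross_part = 2.0 * float(np.sum(aw**2) - np.sum((a**2) @ (w**2)))
    I_tautau = 0.25 * (float(diag_part.sum()) + cross_part)

    # I_at: K~ rows are [1 | I_p] per observation
    ca = a @ c_diag                                   # per-isoform sum_i a_i c_ij
    I_at = 0.5 * np.concatenate(([ca.sum()], ca))

    # I_aa = K~^T W K~
    col_w = w.sum(axis=0)
    p = counts.n_isoforms
    I_aa = np.zeros((p + 1, p + 1))
    I_aa[0, 0] = col_w.sum()
    I_aa[0, 1:] = col_w
    I_aa[1:, 0] = col_w
    I_aa[1:, 1:][np.diag_indices(p)] = col_w

    correction = float(I_at @ np.linalg.pinv(I_aa, rcond=1e-10) @ I_at)
    I_tilde = I_tautau - correction
    if not np.isfinite(I_tilde):
        raise FloatingPointError("information overflow: degenerate null fit")
    return InformationDecomp(I_tautau=I_tautau, I_at=I_at, I_aa=I_aa,
                             I_tilde=I_tilde, r_diag=r_diag, c_diag=c_diag,
                             kappa2=kappas[0], kappa3=kappas[1], kappa4=kappas[2])


def theoretical_pvalue(U: float, I_tilde: float, one_sided: bool = False) -> float:
    """Chi-square (default) or one-sided normal p-value for U.

    Default: chi2 = U^2 / I~ against the upper tail of chi^2 with 1 df.  The
    one-sided mode returns P(N(0,1) > U / sqrt(I~)), appropriate because the
    variance-component alternative tau^2 > 0 inflates U upward.
    """
    if not I_tilde > 0:
        raise ValueError("I_tilde must be positive")
    if one_sided:
        return float(stats.norm.sf(U / np.sqrt(I_tilde)))
    return float(stats.chi2.sf(U * U / I_tilde, df=1))


def _permutation_kernel(z: np.ndarray, t: np.ndarray,
                        labels: np.ndarray) -> np.ndarray:
    """U for each row of ``labels`` given residuals z (N x p) and row weight
    sums t (length N)."""
    q = labels @ z
    quad = np.einsum("bj,bj->b", q, q)
    trace = (labels**2) @ t
    return (quad - trace) / 2.0


def _binary_levels(x: np.ndarray) -> tuple[float, float] | None:
    levels = np.unique(x)
    return tuple(levels) if levels.size == 2 else None


def permutation_pvalue(counts: IsoformCountMatrix, fit: NullFit,
                       x: DesignVector, B: int = 5000,
                       seed: int | np.random.Generator | None = 0,
                       exact: bool | None = None,
                       ) -> tuple[float, np.ndarray]:
    """Empirical (permutation) p-value of U; returns (p, permuted U sample).

    The null fit is label-free, so gamma_hat, the residuals and the weight
    row-sums are computed once and only the label vector is redrawn.  One-sided
    with the add-one convention: p = (1 + #{b: U_b >= U_obs}) / (B + 1).

    For a two-level design whose distinct label arrangements number at most B
    (or with ``exact=True``), all C(N, n1) arrangements are enumerated instead
    of sampled; the p-value is then exact and invariant to any relabeling of
    the samples.  ``exact=False`` forces Monte-Carlo sampling.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    z = _residuals(counts, fit)
    t = family_weights(fit, counts).w0.sum(axis=1)
    U_obs = float(_permutation_kernel(z, t, x.x[None, :])[0])

    levels = _binary_levels(x.x)
    if levels is not None and exact is not False:
        from math import comb
        n = x.x.size
        n_hi = int(np.sum(x.x == levels[1]))
        n_arrangements = comb(n, n_hi)
        if exact or n_arrangements <= B:
            from itertools import combinations
            labels = np.full((n_arrangements, n), levels[0])
            for row, pos in enumerate(combinations(range(n), n_hi)):
                labels[row, list(pos)] = levels[1]
            U_perm = _permutation_kernel(z, t, labels)
            # the observed arrangement is one of the enumerated ones
            p = float(np.mean(U_perm >= U_obs))
            return p, U_perm

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = np.tile(np.sort(x.x), (B, 1))
    rng.permuted(labels, axis=1, out=labels)
    U_perm = _permutation_kernel(z, t, labels)
    p = (1.0 + int(np.sum(U_perm >= U_obs))) / (B + 1.0)
    return p, U_perm


def choose_family(counts: IsoformCountMatrix, phi_threshold: float = 1e-3,
                  mode: str = FIXED, shrinkage_var: float = 1.0) -> str:
    """Adaptive family choice: NB unless its fit fails or phi is negligible."""
    try:
        fit = fit_null(counts, family=NB, mode=mode, shrinkage_var=shrinkage_var)
    except DegenerateGeneError:
        raise
    except Exception:
        return POISSON
    if not fit.converged or fit.phi_hat < phi_threshold:
        return POISSON
    return NB


def test_gene(counts: IsoformCountMatrix, x: DesignVector,
              config: TestConfig = TestConfig()) -> VctResult:
    """Run the full test for one gene: family choice, H0 fit, U, both nulls."""
    x = x if isinstance(x, DesignVector) else DesignVector(np.asarray(x, float))
    if len(x) != counts.n_samples:
        raise ValueError("design length does not match the count matrix")
    x.require_varying()
    if config.center_design:
        x = DesignVector(x.x - x.x.mean())
    counts = counts.drop_zero_isoforms()

    fell_back = False
    if config.family == "auto":
        family = choose_family(counts, config.phi_threshold,
                               mode=config.mode, shrinkage_var=config.shrinkage_var)
        fell_back = family == POISSON
    else:
        family = config.family

    fit = fit_null(counts, family=family, mode=config.mode,
                   shrinkage_var=config.shrinkage_var)
    if not fit.converged:
        fit = fit_null(counts, family=family, mode=FIXED)

    score = score_statistic(counts, fit, x)
    info = information(counts, fit, x)
    chi2 = score.U**2 / info.I_tilde
    p_the = theoretical_pvalue(score.U, info.I_tilde, one_sided=config.one_sided)
    p_one = theoretical_pvalue(score.U, info.I_tilde, one_sided=True)

    p_emp = None
    if config.B > 0:
        p_emp, _ = permutation_pvalue(counts, fit, x, B=config.B, seed=config.seed)

    return VctResult(gene_id=counts.gene_id, U=score.U, I_tilde=info.I_tilde,
                     chi2=chi2, p_theoretical=p_the, p_empirical=p_emp,
                     family_used=family, B=config.B, seed=config.seed,
                     n_isoforms_used=counts.n_isoforms,
                     fell_back_poisson=fell_back, p_one_sided=p_one)
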