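"""Core containers and null-model fitting for the isoform-set score test.

One gene is an ``N`` samples x ``p`` isoforms block of counts.  The model is a
log-link GLMM ``g(E(Y_ij)) = mu + alpha_j + beta_j * x_i`` with per-isoform
baseline offsets ``alpha_j`` and per-isoform group effects ``beta_j``; the test
of differential expression is the variance-component test of
``H0: Var(beta_j) = 0``.  Everything the score statistic needs from the null
model is the matrix of fitted means ``gamma_ij = exp(mu + alpha_j)``, the count
family (Poisson or negative binomial) and, for the NB family, the dispersion
``phi`` in ``Var(Y) = gamma + phi * gamma**2``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

logger = logging.getLogger(__name__)

#: Lower bound for the NB dispersion; at this value the NB family is
#: numerically indistinguishable from Poisson.
PHI_FLOOR = 1e-8

#: Upper bound for the NB dispersion search.
PHI_CEIL = 1e4

POISSON = "poisson"
NB = "nb"

FIXED = "fixed"
RANDOM = "random"


class DegenerateGeneError(ValueError):
    """Raised when a gene carries no usable signal (e.g. all-zero counts)."""


@dataclass(frozen=True)
class IsoformCountMatrix:
    """Counts for one gene: ``N`` samples (rows) by ``p`` isoforms (columns).

    Entries must be non-negative integers; fractional expected counts (as in
    TCGA isoform files) are rounded upstream, in the reader.
    """

    counts: np.ndarray
    sample_ids: tuple[str, ...]
    isoform_ids: tuple[str, ...]
    gene_id: str = "gene"

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D samples x isoforms array")
        if not np.all(np.isfinite(counts)):
            raise ValueError(f"gene {self.gene_id}: counts contain undefined entries")
        if np.any(counts < 0):
            raise ValueError(f"gene {self.gene_id}: counts contain negative entries")
        if np.any(counts != np.floor(counts)):
            raise ValueError(f"gene {self.gene_id}: counts must be integral")
        object.__setattr__(self, "counts", counts.astype(np.int64))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "isoform_ids", tuple(self.isoform_ids))
        n, p = self.counts.shape
        if n < 2:
            raise ValueError(f"gene {self.gene_id}: need at least 2 samples")
        if p < 1:
            raise ValueError(f"gene {self.gene_id}: need at least 1 isoform")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match counts")
        if len(self.isoform_ids) != p:
            raise ValueError("isoform_ids length does not match counts")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_isoforms(self) -> int:
        return self.counts.shape[1]

    def drop_zero_isoforms(self) -> "IsoformCountMatrix":
        """Drop isoform columns whose total count is zero (logged).

        Raises :class:`DegenerateGeneError` if no isoform survives.
        """
        keep = self.counts.sum(axis=0) > 0
        if keep.all():
            return self
        dropped = [iso for iso, k in zip(self.isoform_ids, keep) if not k]
        logger.warning(
            "gene %s: dropping %d all-zero isoform(s): %s",
            self.gene_id, len(dropped), ", ".join(dropped),
        )
        if not keep.any():
            raise DegenerateGeneError(f"degenerate gene {self.gene_id}: all counts zero")
        return IsoformCountMatrix(
            counts=self.counts[:, keep],
            sample_ids=self.sample_ids,
            isoform_ids=tuple(iso for iso, k in zip(self.isoform_ids, keep) if k),
            gene_id=self.gene_id,
        )


@dataclass(frozen=True)
class DesignVector:
    """Length-``N`` covariate vector; 0/1 group labels in case-control use."""

    x: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        if x.ndim != 1 or x.size == 0:
            raise ValueError("design must be a non-empty 1-D vector")
        if not np.all(np.isfinite(x)):
            raise ValueError("design contains undefined entries")
        object.__setattr__(self, "x", x)

    def __len__(self) -> int:
        return self.x.size

    def require_varying(self) -> None:
        if np.ptp(self.x) == 0:
            raise ValueError("design vector is constant; the test is undefined")


@dataclass(frozen=True)
class NullFit:
    """H0 estimates for one gene.

    ``gamma`` is the N x p matrix of fitted means ``exp(mu_hat + alpha_hat_j)``
    (constant down each column).  ``phi_hat`` is the NB dispersion, 0.0 for the
    Poisson family.  ``alpha_hat`` is reported under a sum-to-zero constraint;
    only ``gamma`` enters the test statistics.
    """

    family: str
    mu_hat: float
    alpha_hat: np.ndarray
    gamma: np.ndarray
    phi_hat: float
    mode: str = FIXED
    converged: bool = True


@dataclass(frozen=True)
class FamilyWeights:
    """Per-observation GLM weight matrices (all N x p, log link).

    delta_i = 1/g'(gamma_i) = gamma_i; w_i = V(gamma_i)^-1 delta_i^2;
    w0_i = w_i + e_i (y_i - gamma_i);
    e_i = (V' g' + V g'') / (V^2 g'^3) = phi*gamma/(1+phi*gamma)^2 for NB, 0 for
    Poisson; phi_diag holds the diagonal of Phi = Delta^-1 W, i.e.
    1/(1+phi*gamma) (all ones for Poisson).
    """

    delta: np.ndarray
    w: np.ndarray
    w0: np.ndarray
    e: np.ndarray
    phi_diag: np.ndarray


@dataclass(frozen=True)
class Scenario:
    """One simulation setting.

    ``s`` is the variance of the baseline offsets alpha_j, ``l`` the variance
    of the group effects beta_j (``l = 0`` under H0), ``exp(M)`` the baseline
    mean, ``phi`` the NB dispersion and ``family`` the count family.  The
    design is ``n_cases`` ones followed by ``N - n_cases`` zeros (balanced by
    default).
    """

    N: int = 40
    p: int = 2
    s: float = 0.0
    l: float = 0.0
    M: float = 0.0
    phi: float = 0.0
    family: str = POISSON
    n_cases: int | None = None

    def __post_init__(self) -> None:
        if self.s < 0 or self.l < 0 or self.phi < 0:
            raise ValueError("variances and dispersion must be non-negative")
        if self.family not in (POISSON, NB):
            raise ValueError(f"unknown family {self.family!r}")
        if self.n_cases is None:
            object.__setattr__(self, "n_cases", self.N // 2)
        if not 0 < self.n_cases < self.N:
            raise ValueError("n_cases must split N into two non-empty groups")

    @classmethod
    def from_mean(cls, exp_M: float, **kwargs) -> "Scenario":
        """Build a scenario from the baseline mean ``exp(M)`` directly."""
        if exp_M <= 0:
            raise ValueError("exp(M) must be positive")
        return cls(M=float(np.log(exp_M)), **kwargs)

    @property
    def baseline_mean(self) -> float:
        return float(np.exp(self.M))


def _nb_loglik(y: np.ndarray, gamma: np.ndarray, phi: float) -> float:
    """NB log-likelihood at fixed means, Var = gamma + phi*gamma^2 (size 1/phi)."""
    r = 1.0 / phi
    mu = gamma
    return float(
        np.sum(
            special.gammaln(y + r) - special.gammaln(r) - special.gammaln(y + 1.0)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
    )


def _poisson_loglik(y: np.ndarray, gamma: np.ndarray) -> float:
    return float(np.sum(y * np.log(gamma) - gamma - special.gammaln(y + 1.0)))


def estimate_dispersion(counts: IsoformCountMatrix | np.ndarray,
                        gamma: np.ndarray) -> float:
    """Maximum-likelihood NB dispersion ``phi`` at fixed means ``gamma``.

    1-D bounded search on log(phi) in [PHI_FLOOR, PHI_CEIL]; returns the floor
    when the Poisson limit fits as well or better (e.g. under-dispersed data).
    """
    y = counts.counts if isinstance(counts, IsoformCountMatrix) else np.asarray(counts)
    gamma = np.asarray(gamma, dtype=float)
    if np.any(gamma <= 0):
        raise ValueError("gamma must be positive")
    y = y.astype(float)

    def neg_ll(log_phi: float) -> float:
        return -_nb_loglik(y, gamma, float(np.exp(log_phi)))

    res = optimize.minimize_scalar(
        neg_ll,
        bounds=(np.log(PHI_FLOOR), np.log(PHI_CEIL)),
        method="bounded",
        options={"xatol": 1e-7},
    )
    phi = float(np.exp(res.x))
    # near the floor the NB log-likelihood is flat and gammaln(y + 1/phi)
    # noise dominates; snap to the boundary when the Poisson limit (computed
    # exactly) fits as well or better, or when phi is negligible anyway
    if phi <= 1e-6 or _poisson_loglik(y, gamma) >= -res.fun - 1e-8:
        return PHI_FLOOR
    return phi


def _fixed_fit(counts: IsoformCountMatrix) -> tuple[float, np.ndarray, np.ndarray]:
    col_means = counts.counts.mean(axis=0)
    if np.any(col_means <= 0):
        raise DegenerateGeneError(
            f"degenerate gene {counts.gene_id}: isoform with zero total count "
            "(drop_zero_isoforms first)"
        )
    log_means = np.log(col_means)
    mu = float(log_means.mean())
    alpha = log_means - mu
    gamma = np.broadcast_to(col_means, counts.counts.shape).copy()
    return mu, alpha, gamma


def _random_fit(counts: IsoformCountMatrix,
                shrinkage_var: float) -> tuple[float, np.ndarray, np.ndarray, bool]:
    """Ridge-penalized Newton fit of (mu, alpha) under a Poisson likelihood.

    The per-isoform intercepts alpha_j get a N(0, shrinkage_var) penalty; as
    shrinkage_var -> inf the solution approaches the fixed-mode column means.
    """
    y_bar = counts.counts.mean(axis=0)
    if np.any(y_bar <= 0):
        raise DegenerateGeneError(
            f"degenerate gene {counts.gene_id}: isoform with zero total count"
        )
    n, p = counts.counts.shape
    lam = 1.0 / shrinkage_var
    mu = float(np.log(y_bar.mean()))
    alpha = np.zeros(p)
    converged = False
    for _ in range(200):
        gamma_col = np.exp(mu + alpha)
        g_mu = n * np.sum(y_bar - gamma_col)
        g_a = n * (y_bar - gamma_col) - lam * alpha
        grad = np.concatenate(([g_mu], g_a))
        if np.max(np.abs(grad)) < 1e-10 * max(1.0, n * y_bar.max()):
            converged = True
            break
        # Hessian of the penalized negative log-likelihood (arrow structure)
        d = n * gamma_col + lam
        h_mu = n * np.sum(gamma_col)
        # solve [[h_mu, b^T],[b, diag(d)]] step = grad via Schur complement
        b = n * gamma_col
        inv_d_g = g_a / d
        schur = h_mu - np.sum(b * b / d)
        step_mu = (g_mu - np.sum(b * inv_d_g)) / schur
        step_a = inv_d_g - (b / d) * step_mu
        # damped update for stability with extreme starting points
        scale = 1.0
        if max(abs(step_mu), np.max(np.abs(step_a))) > 2.0:
            scale = 2.0 / max(abs(step_mu), np.max(np.abs(step_a)))
        mu += scale * step_mu
        alpha += scale * step_a
    gamma = np.broadcast_to(np.exp(mu + alpha), counts.counts.shape).copy()
    # re-express under the sum-to-zero convention
    shift = float(alpha.mean())
    return mu + shift, alpha - shift, gamma, converged


def fit_null(counts: IsoformCountMatrix,
             family: str = POISSON,
             mode: str = FIXED,
             shrinkage_var: float = 1.0,
             phi: float | None = None) -> NullFit:
    """Fit the no-group-effect model ``log E(Y_ij) = mu + alpha_j``.

    In ``fixed`` mode the per-isoform intercepts are free parameters, so the
    fitted mean of isoform j is exactly its column mean (the intercept-only MLE
    for both families).  ``random`` mode shrinks the intercepts toward a common
    value with prior variance ``shrinkage_var``.  For the NB family the
    dispersion is estimated at the fitted means unless ``phi`` is supplied.
    """
    if family not in (POISSON, NB):
        raise ValueError(f"unknown family {family!r}")
    if mode not in (FIXED, RANDOM):
        raise ValueError(f"unknown mode {mode!r}")
    if not counts.counts.any():
        raise DegenerateGeneError(f"degenerate gene {counts.gene_id}: all counts zero")

    converged = True
    if mode == FIXED:
        mu, alpha, gamma = _fixed_fit(counts)
    else:
        mu, alpha, gamma, converged = _random_fit(counts, shrinkage_var)

    if family == NB:
        if phi is not None:
            if phi <= 0:
                raise ValueError("supplied phi must be positive for the NB family")
            phi_hat = float(phi)
        else:
            phi_hat = estimate_dispersion(counts, gamma)
    else:
        phi_hat = 0.0
    return NullFit(family=family, mu_hat=mu, alpha_hat=alpha, gamma=gamma,
                   phi_hat=phi_hat, mode=mode, converged=converged)


def family_weights(fit: NullFit, counts: IsoformCountMatrix) -> FamilyWeights:
    """Per-observation weights entering U and the information matrix.

    With the log link, delta = gamma for both families.  Poisson: w = gamma,
    e = 0, w0 = w and Phi = I.  NB: w = gamma/(1+phi*gamma),
    e = phi*gamma/(1+phi*gamma)^2, w0 = w + e*(y-gamma), Phi diagonal
    1/(1+phi*gamma).  All NB fields reduce continuously to Poisson as phi -> 0.
    """
    gamma = fit.gamma
    y = counts.counts.astype(float)
    if y.shape != gamma.shape:
        raise ValueError("counts and fitted means have different shapes")
    delta = gamma.copy()
    if fit.family == POISSON:
        w = gamma.copy()
        e = np.zeros_like(gamma)
        w0 = w.copy()
        phi_diag = np.ones_like(gamma)
    else:
        phi = fit.phi_hat
        denom = 1.0 + phi * gamma
        w = gamma / denom
        e = phi * gamma / denom**2
        w0 = w + e * (y - gamma)
        phi_diag = 1.0 / denom
    return FamilyWeights(delta=delta, w=w, w0=w0, e=e, phi_diag=phi_diag)
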