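"""Sampling distributions of the between-group (co)variance estimators and of
the slope estimators.

The between-group variance and covariance estimators of balanced two-level
normal data are quadratic forms in the underlying standard normal draws.
This module provides three increasingly reduced representations:

1. :class:`QuadFormRep` — the exact coefficient matrices of those quadratic
   forms together with their eigendecompositions, so that each estimator is a
   weighted sum of squares of independent standard normals (a signed weighted
   chi-square sum).  This is exact and is validated against direct data
   simulation.
2. :class:`GammaRep` — each block of equal-weight chi-square terms rewritten
   as a scaled gamma variable (if V ~ Gamma(k, theta) then cV ~ Gamma(k,
   c*theta)); the signed blocks represent the estimators as differences of
   gamma sums.
3. :class:`EstimatorDistribution` — an approximate closed-form distribution
   of either slope estimator (ML or regularized Bayes), built from the exact
   first two moments of (s_bxy, s_bx):

   * the numerator is split as ``s_bxy = beta_star * s_bx + C`` with
     ``beta_star = Cov(s_bxy, s_bx) / Var(s_bx)``, so that the remainder C is
     uncorrelated with the denominator;
   * the shrinkage denominator ``D = lam * s_bx + (1 - lam) * prior_loc`` is
     approximated by a gamma variable matched to its exact mean and variance,
     with the shape floored at (J - 1)/2 — the between-group chi-square
     degrees of freedom that drive D's randomness.  The floor is a deliberate
     light-tail regularization: the exact D crosses zero with positive
     probability, so the exact inverse moments do not exist, and the matched
     gamma (support on the positive axis) is what makes the "analytic" MSE a
     finite, usable objective;
   * inverse-gamma moments of 1/D then give mean, variance, MSE and SE.

   Moments are flagged undefined when the matched shape k <= 1 (mean) or
   k <= 2 (variance) — the analogue of an F distribution running out of
   denominator degrees of freedom (df2 = 2k).

The approximation is validated against Monte-Carlo simulation in the test
suite; it is deliberately coarse in the extreme ML corner (tiny J, tiny ICC)
where the true estimator has no finite moments at all.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UndefinedMomentError
from .model import ModelParams, SufficientStats

__all__ = [
    "QuadFormRep",
    "GammaRep",
    "EstimatorDistribution",
    "SecondMoments",
    "build_quadform_reps",
    "gamma_rep_from_quadform",
    "estimator_distribution",
    "analytic_se",
    "model_second_moments",
    "stats_second_moments",
    "plugin_second_moments",
    "sbx_sampling_sd",
    "ratio_moments",
]

# Eigenvalues below this relative threshold are treated as exact zeros
# (rank deficiency at boundary ICCs).
EIG_REL_TOL = 1e-10


# ---------------------------------------------------------------------------
# Second-moment structure of (s_bxy, s_bx)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SecondMoments:
    """Covariance structure of group means ('m') and within deviations ('w').

    ``sig_mxx`` is Var of one group mean of x (= sigma2_bx + sigma2_wx/n in
    the model, or its sample analogue), etc.  These six numbers plus (J, n)
    determine the exact first two moments of the ANOVA estimators:

        Var(s_bx)        = 2 sig_mxx^2/(J-1) + 2 sig_wxx^2/(n^2 J(n-1))
        Var(s_bxy)       = (sig_mxx sig_myy + sig_mxy^2)/(J-1)
                           + (sig_wxx sig_wyy + sig_wxy^2)/(n^2 J(n-1))
        Cov(s_bxy, s_bx) = 2 sig_mxx sig_mxy/(J-1)
                           + 2 sig_wxx sig_wxy/(n^2 J(n-1))

    (Wishart moments of the independent group-mean and within-deviation
    sample covariance matrices.)
    """

    sig_mxx: float
    sig_mxy: float
    sig_myy: float
    sig_wxx: float
    sig_wxy: float
    sig_wyy: float
    J: int
    n: int

    @property
    def var_sbx(self) -> float:
        J, n = self.J, self.n
        return (2 * self.sig_mxx**2 / (J - 1)
                + 2 * self.sig_wxx**2 / (n**2 * J * (n - 1)))

    @property
    def var_sbxy(self) -> float:
        J, n = self.J, self.n
        return ((self.sig_mxx * self.sig_myy + self.sig_mxy**2) / (J - 1)
                + (self.sig_wxx * self.sig_wyy + self.sig_wxy**2)
                / (n**2 * J * (n - 1)))

    @property
    def cov_sbxy_sbx(self) -> float:
        J, n = self.J, self.n
        return (2 * self.sig_mxx * self.sig_mxy / (J - 1)
                + 2 * self.sig_wxx * self.sig_wxy / (n**2 * J * (n - 1)))


def model_second_moments(params: ModelParams) -> SecondMoments:
    """Population second-moment structure implied by model parameters."""
    n = params.n
    sig_wxx = params.sigma2_wx
    sig_wxy = params.beta_w * params.sigma2_wx
    sig_wyy = params.beta_w**2 * params.sigma2_wx + params.sigma2_ew
    return SecondMoments(
        sig_mxx=params.sigma2_bx + sig_wxx / n,
        sig_mxy=params.beta_b * params.sigma2_bx + sig_wxy / n,
        sig_myy=(params.beta_b**2 * params.sigma2_bx + params.sigma2_eb
                 + sig_wyy / n),
        sig_wxx=sig_wxx, sig_wxy=sig_wxy, sig_wyy=sig_wyy,
        J=params.J, n=params.n)


def stats_second_moments(stats: SufficientStats) -> SecondMoments:
    """Raw plug-in second-moment structure from sample statistics (direct
    sample (co)variances of group means and within deviations)."""
    return SecondMoments(
        sig_mxx=stats.var_means_x,
        sig_mxy=stats.cov_means_xy,
        sig_myy=stats.var_means_y,
        sig_wxx=stats.s_wx_hat,
        sig_wxy=stats.s_wxy_hat,
        sig_wyy=stats.s_wy_hat,
        J=stats.J, n=stats.n)


def plugin_second_moments(stats: SufficientStats, beta_center: float
                          ) -> tuple[SecondMoments, float]:
    """Model-structured plug-in second moments for the estimated MSE.

    The analytic MSE is a function of model parameters, so the plug-in
    substitutes parameter *estimates* rather than raw sample moments:
    sigma2_bx -> max(s_bx, 0), beta_w -> s_wxy/s_wx, and residual variances
    clipped at zero.  The slope argument ``beta_center`` (ML plug-in or the
    true value in benchmark mode) enters the moment structure itself, not
    just the bias target.  This matters for robustness: when the plug-in
    slope is extreme (the unstable-ML regime), both the variance and the
    squared-bias surfaces then scale with its square, so the selected prior
    stabilizes instead of chasing the extreme value.

    Returns the structure and the clipped between-variance plug-in (used as
    the distribution's s_bx center).
    """
    s_bx = max(stats.s_bx_hat, 0.0)
    s_wx = stats.s_wx_hat
    n = stats.n
    beta_w = stats.s_wxy_hat / s_wx if s_wx > 0 else 0.0
    sig_eb = max(stats.s_by_hat - beta_center**2 * s_bx, 0.0)
    sig_ew = max(stats.s_wy_hat - beta_w**2 * s_wx, 0.0)
    sig_wyy = beta_w**2 * s_wx + sig_ew
    sm = SecondMoments(
        sig_mxx=s_bx + s_wx / n,
        sig_mxy=beta_center * s_bx + beta_w * s_wx / n,
        sig_myy=beta_center**2 * s_bx + sig_eb + sig_wyy / n,
        sig_wxx=s_wx,
        sig_wxy=beta_w * s_wx,
        sig_wyy=sig_wyy,
        J=stats.J, n=stats.n)
    return sm, s_bx


def sbx_sampling_sd(sm: SecondMoments) -> float:
    """Standard deviation of the between-group variance estimator s_bx."""
    return float(np.sqrt(sm.var_sbx))


# ---------------------------------------------------------------------------
# Exact quadratic-form representation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QuadFormRep:
    """Exact quadratic-form representation of (s_bx, s_bxy).

    Both forms act on the same standard normal working vector z of length
    ``dim = 2J + 2Jn`` (ordering: group-level x components, individual x
    components, group-level y residuals, individual y residuals).  ``A`` is
    the coefficient matrix of s_bx, ``Q`` of s_bxy; ``P_*`` are orthonormal
    eigenvector matrices and ``weights_*`` the eigenvalues, so that e.g.
    ``s_bx = sum_i weights_A[i] * (P_A[:, i] @ z)**2``.
    """

    A: np.ndarray
    Q: np.ndarray
    P_A: np.ndarray
    weights_A: np.ndarray
    P_Q: np.ndarray
    weights_Q: np.ndarray
    J: int
    n: int

    @property
    def dim(self) -> int:
        return self.A.shape[0]

    @property
    def diag_weights(self) -> dict:
        """Nonzero diagonal coefficients of each diagonalized form."""
        return {"s_bx": self.weights_A[self.weights_A != 0],
                "s_bxy": self.weights_Q[self.weights_Q != 0]}

    def sample(self, n_draws: int, rng: np.random.Generator
               ) -> tuple[np.ndarray, np.ndarray]:
        """Draw (s_bx, s_bxy) jointly through the quadratic forms."""
        z = rng.standard_normal((n_draws, self.dim))
        s_bx = (z @ self.P_A) ** 2 @ self.weights_A
        s_bxy = (z @ self.P_Q) ** 2 @ self.weights_Q
        return s_bx, s_bxy


def _anova_form_matrix(J: int, n: int) -> np.ndarray:
    """Matrix M with s_b = v' M v for a stacked vector v of length Jn:
    sample variance of group means minus pooled within variance over n."""
    N = J * n
    G = np.kron(np.eye(J), np.full((1, n), 1.0 / n))       # group averaging
    C = np.eye(J) - np.full((J, J), 1.0 / J)                # centering
    M_means = G.T @ C @ G / (J - 1)
    P_within = np.eye(N) - np.kron(np.eye(J), np.full((n, n), 1.0 / n))
    return M_means - P_within / (n * J * (n - 1))


def build_quadform_reps(params: ModelParams) -> QuadFormRep:
    """Exact quadratic-form representation of the ANOVA estimators.

    The induced distribution of (s_bx, s_bxy) under z ~ N(0, I) matches the
    distribution of the estimators computed from directly simulated data
    (two-path equivalence; validated by Monte Carlo in the tests).
    Intended for moderate J*n; the analytic moment engine does not need these
    matrices.
    """
    for name in ("beta_b", "beta_w", "sigma2_bx", "sigma2_wx", "sigma2_eb",
                 "sigma2_ew"):
        if not np.isfinite(getattr(params, name)):
            raise ValueError(f"non-finite parameter {name}")
    J, n = params.J, params.n
    N = J * n
    dim = 2 * J + 2 * N
    block = np.kron(np.eye(J), np.ones((n, 1)))             # expands J -> Jn

    # x = Sx z,  y = Sy z with z = [zU (J), zR (Jn), zE (J), zeps (Jn)]
    Sx = np.zeros((N, dim))
    Sx[:, :J] = np.sqrt(params.sigma2_bx) * block
    Sx[:, J:J + N] = np.sqrt(params.sigma2_wx) * np.eye(N)
    Sy = np.zeros((N, dim))
    Sy[:, :J] = params.beta_b * np.sqrt(params.sigma2_bx) * block
    Sy[:, J:J + N] = params.beta_w * np.sqrt(params.sigma2_wx) * np.eye(N)
    Sy[:, J + N:2 * J + N] = np.sqrt(params.sigma2_eb) * block
    Sy[:, 2 * J + N:] = np.sqrt(params.sigma2_ew) * np.eye(N)

    M = _anova_form_matrix(J, n)
    A = Sx.T @ M @ Sx
    Q = 0.5 * (Sx.T @ M @ Sy + Sy.T @ M @ Sx)

    def _eig(mat):
        mat = 0.5 * (mat + mat.T)                            # symmetrize
        w, P = np.linalg.eigh(mat)
        cutoff = EIG_REL_TOL * max(np.abs(w).max(), 1e-300)
        w = np.where(np.abs(w) < cutoff, 0.0, w)
        return P, w

    P_A, w_A = _eig(A)
    P_Q, w_Q = _eig(Q)
    return QuadFormRep(A=A, Q=Q, P_A=P_A, weights_A=w_A, P_Q=P_Q,
                       weights_Q=w_Q, J=J, n=n)


# ---------------------------------------------------------------------------
# Gamma representation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GammaRep:
    """Signed gamma-sum representation of one quadratic form.

    Each block of m equal eigenvalues w contributes sign(w) * Gamma(m/2,
    2|w|); ``shapes[i]`` is the half-degree m/2, ``scales[i]`` the signed
    scale 2w.  The analytic mean sum(shapes * scales) equals the trace of the
    coefficient matrix.
    """

    shapes: np.ndarray
    scales: np.ndarray

    def mean(self) -> float:
        return float(self.shapes @ self.scales)

    def variance(self) -> float:
        return float(self.shapes @ self.scales**2)


def _cluster_weights(weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    w = weights[weights != 0]
    if len(w) == 0:
        return np.array([]), np.array([])
    order = np.argsort(w)
    w = w[order]
    tol = 1e-9 * np.abs(w).max()
    counts, values = [], []
    for wi in w:
        if values and abs(wi - values[-1]) <= tol:
            counts[-1] += 1
            # running mean keeps the representative stable
            values[-1] += (wi - values[-1]) / counts[-1]
        else:
            values.append(float(wi))
            counts.append(1)
    return np.array(counts, dtype=float), np.array(values)


def gamma_rep_from_quadform(rep: QuadFormRep) -> dict:
    """Scaled-gamma block representation of both estimator forms.

    Returns ``{"s_bx": GammaRep, "s_bxy": GammaRep}``.  Scaling rule: a
    chi-square block with m degrees of freedom and weight w becomes
    Gamma(m/2, 2w) (for V ~ Gamma(k, theta), cV ~ Gamma(k, c*theta)).
    """
    out = {}
    for key, w in (("s_bx", rep.weights_A), ("s_bxy", rep.weights_Q)):
        counts, values = _cluster_weights(w)
        out[key] = GammaRep(shapes=counts / 2.0, scales=2.0 * values)
    return out


# ---------------------------------------------------------------------------
# Approximate slope-estimator distribution
# ---------------------------------------------------------------------------

def ratio_moments(sm: SecondMoments, sbx_center: float, beta_center: float,
                  lam, prior_loc):
    """Vectorized approximate moments of the shrinkage slope estimator.

    Parameters
    ----------
    sm : SecondMoments
        Second-moment structure (population values or plug-in estimates).
    sbx_center : float
        Central value of s_bx (sigma2_bx in population mode; the observed
        s_bx_hat in plug-in mode — may be negative).
    beta_center : float
        The between-group slope value the MSE is measured against (true
        beta_b, or the plug-in estimate).
    lam, prior_loc : array_like
        Weighting parameter(s) in (0, 1] and prior location(s) >= 0;
        broadcast against each other.

    Returns
    -------
    dict with broadcast arrays ``mean``, ``variance``, ``mse``, ``se``,
    ``k`` (matched denominator gamma shape; df2 = 2k), and boolean masks
    ``mean_defined``, ``var_defined``.  Undefined entries are NaN.
    """
    lam = np.asarray(lam, dtype=float)
    prior_loc = np.asarray(prior_loc, dtype=float)
    lam, prior_loc = np.broadcast_arrays(lam, prior_loc)

    J = sm.J
    var_sbx = sm.var_sbx
    if var_sbx <= 0:
        raise ValueError("degenerate second-moment structure: Var(s_bx) = 0")
    cov = sm.cov_sbxy_sbx
    beta_star = cov / var_sbx
    m_C = (beta_center - beta_star) * sbx_center
    s2_C = max(sm.var_sbxy - cov**2 / var_sbx, 0.0)

    mu_D = lam * sbx_center + (1.0 - lam) * prior_loc
    v_D = lam**2 * var_sbx
    with np.errstate(divide="ignore", invalid="ignore"):
        k_raw = mu_D**2 / v_D
    k = np.maximum(k_raw, (J - 1) / 2.0)
    pos = mu_D > 0
    mean_defined = pos & (k > 1.0)
    var_defined = pos & (k > 2.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        theta = mu_D / k
        r1 = 1.0 / (theta * (k - 1.0))
        a0 = beta_star / lam
        t_m = m_C - beta_star * (1.0 - lam) * prior_loc / lam
        mean = a0 + t_m * r1
        r2 = 1.0 / (theta**2 * (k - 1.0) * (k - 2.0))
        # stable form: Var = s2_C r2 + t_m^2 Var(1/D)
        var_inv_d = 1.0 / (theta**2 * (k - 1.0)**2 * (k - 2.0))
        variance = s2_C * r2 + t_m**2 * var_inv_d
    mean = np.where(mean_defined, mean, np.nan)
    variance = np.where(var_defined, variance, np.nan)
    mse = variance + (mean - beta_center)**2
    se = np.sqrt(variance)
    return {"mean": mean, "variance": variance, "mse": mse, "se": se,
            "k": k, "mean_defined": mean_defined, "var_defined": var_defined,
            "beta_star": beta_star, "m_C": m_C, "s2_C": s2_C}


@dataclass(frozen=True)
class EstimatorDistribution:
    """Approximate distribution summary of a slope estimator.

    ``c_coeffs`` are the six coefficients of the gamma-ratio construction:
    (a0, t_mean, t_var, mu_D, k_D, theta_D) — the offset beta_star/lam, the
    mean and variance of the denominator-orthogonal numerator remainder, and
    the matched denominator gamma's mean/shape/scale.  ``df1`` is the
    between-group degrees of freedom J - 1 driving the numerator; ``df2`` is
    2 * k_D, the denominator degrees of freedom in the F analogy.
    """

    kind: str
    c_coeffs: tuple
    df1: float
    df2: float
    mean: float
    variance: float
    mse: float
    se: float
    beta_b: float
    lam: float
    prior_loc: float


def estimator_distribution(kind: str, params: ModelParams,
                           prior=None) -> EstimatorDistribution:
    """Approximate distribution of the ML or regularized Bayes estimator
    under known model parameters.

    ``kind`` is "ml" (no prior allowed) or "bayes" (prior with ``lam`` and
    ``prior_loc`` attributes required).  Raises
    :class:`UndefinedMomentError` when the variance does not exist for the
    given configuration.
    """
    kind = kind.lower()
    if kind == "ml":
        if prior is not None:
            raise ValueError("ML kind takes no prior")
        lam, loc = 1.0, 0.0
    elif kind == "bayes":
        if prior is None:
            raise ValueError("Bayes kind requires a prior")
        lam, loc = float(prior.lam), float(prior.prior_loc)
    else:
        raise ValueError(f"unknown kind {kind!r}")

    sm = model_second_moments(params)
    res = ratio_moments(sm, sbx_center=params.sigma2_bx,
                        beta_center=params.beta_b, lam=lam, prior_loc=loc)
    k = float(res["k"])
    if not bool(res["var_defined"]):
        raise UndefinedMomentError(
            f"variance undefined: denominator df2 = {2 * k:.3f} <= 4",
            df=2 * k)
    mu_D = lam * params.sigma2_bx + (1 - lam) * loc
    theta = mu_D / k
    t_m = float(res["m_C"]) - float(res["beta_star"]) * (1 - lam) * loc / lam
    return EstimatorDistribution(
        kind=kind,
        c_coeffs=(float(res["beta_star"]) / lam, t_m, float(res["s2_C"]),
                  mu_D, k, theta),
        df1=params.J - 1, df2=2 * k,
        mean=float(res["mean"]), variance=float(res["variance"]),
        mse=float(res["mse"]), se=float(res["se"]),
        beta_b=params.beta_b, lam=lam, prior_loc=loc)


def analytic_se(dist: EstimatorDistribution) -> float:
    """Standard error: square root of the distribution's variance."""
    return float(np.sqrt(dist.variance))
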