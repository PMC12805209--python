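"""Two-level latent covariate model: data containers, sufficient statistics,
the ML slope estimator, and ICC feasibility checks.

The model decomposes an individual-level predictor and outcome into
independent normal between-group and within-group components,

    X_ij = mu_x + U_j + R_ij,          U_j ~ N(0, sigma2_bx),  R_ij ~ N(0, sigma2_wx)
    Y_ij = gamma + beta_b U_j + E_j + beta_w R_ij + eps_ij,

with group-level residual E_j ~ N(0, sigma2_eb) and individual-level residual
eps_ij ~ N(0, sigma2_ew).  The target parameter is the between-group slope
``beta_b`` — the regression of the latent group mean of Y on the latent group
mean of X.  For balanced data (J groups of n members each) the ML estimator is
the ratio of ANOVA-type unbiased estimators of the group-level covariance and
variance::

    beta_hat_ML = s_bxy / s_bx

where ``s_bx = var(group means of x) − s_wx / n`` and analogously for the
covariance.  The ``− s_wx/n`` correction removes the within-group sampling
noise that inflates observed group means, which is exactly what distinguishes
the latent covariate (latent aggregation) approach from regressing on manifest
group means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    DegenerateGroupError,
    DegenerateVarianceError,
    InfeasibleParamsError,
    UnbalancedDataError,
)

__all__ = [
    "GroupedData",
    "ModelParams",
    "SufficientStats",
    "FeasibilityResult",
    "compute_sufficient_stats",
    "ml_estimate",
    "check_icc_feasibility",
    "solve_residual_variances",
    "read_grouped_csv",
]

# Denominator convention for the (co)variance estimators: the group-mean
# (co)variances use J - 1, the pooled within-group (co)variances use
# J * (n - 1).  With these choices E[s_bx] = sigma2_bx exactly, which the
# Monte-Carlo unbiasedness tests pin down.
BETWEEN_DDOF = 1


@dataclass(frozen=True)
class GroupedData:
    """Raw two-level observations, one entry per individual.

    Group labels may be arbitrary hashable values; they are mapped to a
    canonical 0..J-1 index by order of first appearance.
    """

    x: np.ndarray
    y: np.ndarray
    group: np.ndarray

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        group = np.asarray(self.group)
        if not (len(x) == len(y) == len(group)):
            raise ValueError("x, y and group must have equal length")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "group", group)

    @property
    def group_index(self) -> np.ndarray:
        """Canonical 0..J-1 group index by first appearance."""
        codes, _ = pd.factorize(self.group)
        return codes

    @property
    def group_sizes(self) -> np.ndarray:
        return np.bincount(self.group_index)

    @property
    def n_groups(self) -> int:
        return len(self.group_sizes)

    @property
    def balanced(self) -> bool:
        sizes = self.group_sizes
        return bool(np.all(sizes == sizes[0]))

    def to_frame(self, y_col: str = "y", x_col: str = "x",
                 group_col: str = "group") -> pd.DataFrame:
        return pd.DataFrame({y_col: self.y, x_col: self.x,
                             group_col: self.group})

    def to_csv(self, path_or_buf, **kwargs) -> None:
        self.to_frame().to_csv(path_or_buf, index=False, **kwargs)


@dataclass(frozen=True)
class ModelParams:
    """Population parameters of the two-level latent covariate model.

    Variances follow the unit-total-variance convention for X (and, when
    constructed through :meth:`from_design`, for Y): ``icc_x`` then fully
    determines ``sigma2_bx = icc_x`` and ``sigma2_wx = 1 − icc_x``.
    """

    beta_b: float
    beta_w: float
    sigma2_bx: float
    sigma2_wx: float
    sigma2_eb: float
    sigma2_ew: float
    J: int
    n: int
    mu_x: float = 0.0
    intercept_b: float = 0.0

    def __post_init__(self):
        for name in ("sigma2_bx", "sigma2_wx", "sigma2_eb", "sigma2_ew"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if int(self.J) != self.J or int(self.n) != self.n:
            raise ValueError("J and n must be integers")
        if self.J < 2 or self.n < 2:
            raise ValueError("J >= 2 and n >= 2 required")
        object.__setattr__(self, "J", int(self.J))
        object.__setattr__(self, "n", int(self.n))

    @property
    def icc_x(self) -> float:
        tot = self.sigma2_bx + self.sigma2_wx
        return self.sigma2_bx / tot if tot > 0 else 0.0

    @property
    def icc_y(self) -> float:
        b = self.beta_b**2 * self.sigma2_bx + self.sigma2_eb
        w = self.beta_w**2 * self.sigma2_wx + self.sigma2_ew
        tot = b + w
        return b / tot if tot > 0 else 0.0

    @classmethod
    def from_design(cls, icc_x: float, icc_y: float, beta_b: float,
                    beta_w: float, J: int, n: int) -> "ModelParams":
        """Build parameters from an ICC-indexed design cell.

        Solves the residual variances under unit total variance of X and Y;
        raises :class:`InfeasibleParamsError` when no nonnegative solution
        exists.
        """
        s_eb, s_ew = solve_residual_variances(icc_x, icc_y, beta_b, beta_w)
        return cls(beta_b=beta_b, beta_w=beta_w,
                   sigma2_bx=icc_x, sigma2_wx=1.0 - icc_x,
                   sigma2_eb=s_eb, sigma2_ew=s_ew, J=J, n=n)


@dataclass(frozen=True)
class SufficientStats:
    """Group means plus the ANOVA-type within/between (co)variance estimators.

    ``s_bx_hat`` etc. are the unbiased group-level estimators (variance of
    group means minus the within mean square over n); the y-side analogues
    (``s_by_hat``, ``s_wy_hat``) are carried because the analytic MSE engine
    needs the full second-moment structure of both variables.
    """

    xbar_j: np.ndarray
    ybar_j: np.ndarray
    s_bx_hat: float
    s_bxy_hat: float
    s_by_hat: float
    s_wx_hat: float
    s_wxy_hat: float
    s_wy_hat: float
    J: int
    n: int

    @property
    def var_means_x(self) -> float:
        """Sample variance of the observed group means of x."""
        return self.s_bx_hat + self.s_wx_hat / self.n

    @property
    def var_means_y(self) -> float:
        return self.s_by_hat + self.s_wy_hat / self.n

    @property
    def cov_means_xy(self) -> float:
        return self.s_bxy_hat + self.s_wxy_hat / self.n


@dataclass(frozen=True)
class FeasibilityResult:
    """Verdict of the ICC feasibility check."""

    feasible: bool
    sigma2_eb: float
    sigma2_ew: float
    violated: tuple = ()

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.feasible


def compute_sufficient_stats(data: GroupedData) -> SufficientStats:
    """ANOVA decomposition of balanced two-level data.

    Permutation-invariant: reordering individuals within groups or reordering
    groups leaves every statistic unchanged.

    Raises
    ------
    UnbalancedDataError
        If group sizes differ (balance the data first).
    DegenerateGroupError
        If any group has fewer than two members, or J < 2.
    """
    idx = data.group_index
    sizes = np.bincount(idx)
    J = len(sizes)
    if J < 2:
        raise DegenerateGroupError(f"need at least 2 groups, got {J}")
    if np.any(sizes < 2):
        raise DegenerateGroupError("every group must have >= 2 members")
    if not np.all(sizes == sizes[0]):
        raise UnbalancedDataError(
            "balance required: group sizes differ "
            f"(min {sizes.min()}, max {sizes.max()})")
    n = int(sizes[0])

    xbar_j = np.bincount(idx, weights=data.x) / n
    ybar_j = np.bincount(idx, weights=data.y) / n

    xd = data.x - xbar_j[idx]
    yd = data.y - ybar_j[idx]
    wdf = J * (n - 1)
    s_wx = float(xd @ xd) / wdf
    s_wy = float(yd @ yd) / wdf
    s_wxy = float(xd @ yd) / wdf

    bdf = J - BETWEEN_DDOF
    xc = xbar_j - xbar_j.mean()
    yc = ybar_j - ybar_j.mean()
    v_mx = float(xc @ xc) / bdf
    v_my = float(yc @ yc) / bdf
    c_mxy = float(xc @ yc) / bdf

    return SufficientStats(
        xbar_j=xbar_j, ybar_j=ybar_j,
        s_bx_hat=v_mx - s_wx / n,
        s_bxy_hat=c_mxy - s_wxy / n,
        s_by_hat=v_my - s_wy / n,
        s_wx_hat=s_wx, s_wxy_hat=s_wxy, s_wy_hat=s_wy,
        J=J, n=n)


def ml_estimate(stats: SufficientStats) -> float:
    """Maximum likelihood estimator of the between-group slope.

    No truncation of negative between-variance estimates is applied: the
    resulting instability at small J and low ICC is a genuine property of ML
    that the simulation study must be able to reproduce.
    """
    if stats.s_bx_hat == 0.0:
        raise DegenerateVarianceError(
            "estimated between-group variance of x is exactly zero; the ML "
            "slope is undefined")
    return stats.s_bxy_hat / stats.s_bx_hat


def solve_residual_variances(icc_x: float, icc_y: float, beta_b: float,
                             beta_w: float) -> tuple[float, float]:
    """Residual variances under unit total variance of X and Y.

    With sigma2_bx = icc_x and sigma2_wx = 1 − icc_x, requiring the
    between-group share of Var(Y) = 1 to equal icc_y gives::

        sigma2_eb = icc_y − beta_b^2 * icc_x
        sigma2_ew = (1 − icc_y) − beta_w^2 * (1 − icc_x)

    Raises :class:`InfeasibleParamsError` naming the binding constraint when
    either residual variance would be negative.
    """
    res = check_icc_feasibility(icc_x, icc_y, beta_b, beta_w)
    if not res.feasible:
        raise InfeasibleParamsError(
            "no nonnegative residual-variance solution for "
            f"icc_x={icc_x}, icc_y={icc_y}, beta_b={beta_b}, beta_w={beta_w} "
            f"(violated: {', '.join(res.violated)})",
            constraint=res.violated[0])
    return res.sigma2_eb, res.sigma2_ew


def check_icc_feasibility(icc_x: float, icc_y: float, beta_b: float,
                          beta_w: float) -> FeasibilityResult:
    """Does a nonnegative residual-variance solution exist for this design?

    Large slopes are what the constraint excludes: the systematic variance
    contributed at one level may not exceed that level's share of the unit
    total variance of Y.
    """
    if not (0 <= icc_x < 1):
        raise ValueError(f"icc_x must be in [0, 1), got {icc_x}")
    if not (0 < icc_y < 1):
        raise ValueError(f"icc_y must be in (0, 1), got {icc_y}")
    s_eb = icc_y - beta_b**2 * icc_x
    s_ew = (1.0 - icc_y) - beta_w**2 * (1.0 - icc_x)
    violated = []
    if s_eb < 0:
        violated.append("between_residual_nonnegative")
    if s_ew < 0:
        violated.append("within_residual_nonnegative")
    return FeasibilityResult(feasible=not violated, sigma2_eb=s_eb,
                             sigma2_ew=s_ew, violated=tuple(violated))


def read_grouped_csv(path_or_buf, y: str, x: str, group: str,
                     drop_missing: bool = True) -> tuple[GroupedData, int]:
    """Read long-format two-level data from CSV (header required).

    Returns the data plus the number of rows dropped for missing values.
    Numeric columns are parsed strictly (locale-independent decimal point).
    """
    df = pd.read_csv(path_or_buf)
    for col in (y, x, group):
        if col not in df.columns:
            raise KeyError(f"column {col!r} not found in CSV "
                           f"(available: {list(df.columns)})")
    sub = df[[y, x, group]].copy()
    for col in (y, x):
        sub[col] = pd.to_numeric(sub[col], errors="raise")
    n_before = len(sub)
    if drop_missing:
        sub = sub.dropna()
    dropped = n_before - len(sub)
    data = GroupedData(x=sub[x].to_numpy(dtype=float),
                       y=sub[y].to_numpy(dtype=float),
                       group=sub[group].to_numpy())
    return data, dropped
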