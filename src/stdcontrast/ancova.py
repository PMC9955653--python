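"""Fixed-effects ANCOVA fitting and standardized-contrast estimation.

The model has ``G`` treatment groups, ``P`` shared-slope covariates, and
independent normal errors::

    Y_ij = mu_i + sum_k X_kij * beta_k + eps_ij,   eps_ij ~ N(0, sigma^2)

Everything downstream (interval estimation, precision analysis, sample-size
planning) consumes the quantities computed here: the contrast estimate
``psi_hat`` of the adjusted group means, its standardized version
``psi_hat / sigma_hat``, the covariate-disparity statistic ``Q`` and the
variance factor ``V = a + Q/(N_T - G)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = [
    "ANCOVAData",
    "ContrastSpec",
    "ANCOVAFit",
    "ContrastEstimate",
    "fit_ancova",
    "contrast_estimate",
    "variance_factor",
    "unbias_factor",
]

#: condition-number threshold above which the pooled covariate
#: cross-product matrix is treated as singular
COND_LIMIT = 1e12

_ZERO_SUM_TOL = 1e-12


@dataclass(frozen=True)
class ANCOVAData:
    """Long-format ANCOVA data: one row per subject.

    Group labels are mapped to indices in first-appearance order; contrast
    coefficients are matched by that order.
    """

    group: np.ndarray  # (N_T,) labels, any hashable dtype
    y: np.ndarray  # (N_T,) response
    x: np.ndarray  # (N_T, P) covariates

    # derived, filled in __post_init__
    group_labels: tuple = field(init=False)
    group_index: np.ndarray = field(init=False)

    def __post_init__(self):
        group = np.asarray(self.group)
        y = np.asarray(self.y, dtype=float)
        x = np.atleast_2d(np.asarray(self.x, dtype=float))
        if x.shape[0] != y.shape[0] and x.shape[1] == y.shape[0]:
            x = x.T
        if y.ndim != 1:
            raise ValueError("response must be one-dimensional")
        if group.shape[0] != y.shape[0] or x.shape[0] != y.shape[0]:
            raise ValueError("group, y and x must have one row per subject")
        if not (np.isfinite(y).all() and np.isfinite(x).all()):
            raise ValueError("non-finite values in response or covariates")
        labels, index = np.unique(group, return_inverse=True)
        # np.unique sorts; remap to first-appearance order
        order = np.argsort([np.flatnonzero(group == lab)[0] for lab in labels])
        rank = np.empty_like(order)
        rank[order] = np.arange(len(labels))
        index = rank[index]
        labels = tuple(labels[order])
        if len(labels) < 2:
            raise ValueError("need at least two treatment groups")
        if x.shape[1] < 1:
            raise ValueError("need at least one covariate")
        object.__setattr__(self, "group", group)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "group_labels", labels)
        object.__setattr__(self, "group_index", index)

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)

    @property
    def n_covariates(self) -> int:
        return self.x.shape[1]

    @property
    def n_total(self) -> int:
        return self.y.shape[0]

    @property
    def group_sizes(self) -> np.ndarray:
        return np.bincount(self.group_index, minlength=self.n_groups)


@dataclass(frozen=True)
class ContrastSpec:
    """Linear contrast coefficients ``c_i`` over groups with sum(c) = 0."""

    coefficients: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.coefficients, dtype=float)
        if c.ndim != 1 or c.size < 2:
            raise ValueError("contrast must be a vector over >= 2 groups")
        if abs(c.sum()) > _ZERO_SUM_TOL:
            raise ValueError(f"contrast coefficients must sum to zero, got {c.sum():g}")
        if not np.any(c != 0.0):
            raise ValueError("contrast must have at least one nonzero coefficient")
        object.__setattr__(self, "coefficients", c)

    def __len__(self) -> int:
        return self.coefficients.size


@dataclass(frozen=True)
class ANCOVAFit:
    """Least-squares ANCOVA fit summary."""

    mu: np.ndarray  # (G,) intercept estimates
    mu_adjusted: np.ndarray  # (G,) adjusted means at the grand covariate means
    beta: np.ndarray  # (P,) common slopes
    xbar_groups: np.ndarray  # (G, P) group covariate means
    xbar_grand: np.ndarray  # (P,) grand covariate means
    s_xx: np.ndarray  # pooled within-group covariate cross-products
    s_xy: np.ndarray
    v_xx: np.ndarray  # S_XX / (N_T - G)
    sse: float
    sigma_sq: float  # SSE / nu
    nu: int  # N_T - G - P
    group_sizes: np.ndarray
    group_labels: tuple
    n_total: int


@dataclass(frozen=True)
class ContrastEstimate:
    """Contrast estimate with the sufficient statistics for every interval."""

    psi_hat: float  # contrast of intercepts, response units
    psi_star_hat: float  # psi_hat / sigma_hat
    psi_star_ub: float  # bias-corrected u(nu) * psi_star_hat (nan if nu <= 1)
    u: float  # small-sample bias-correction factor
    a: float  # sum c_i^2 / N_i
    Q: float  # covariate-disparity statistic
    V: float  # a + Q / (N_T - G)
    tau_sq: float  # sigma_sq * V
    t_obs: float  # psi_star_hat / sqrt(V)
    nu: int
    sigma_sq: float


def fit_ancova(data: ANCOVAData) -> ANCOVAFit:
    """Fit the ANCOVA model by pooled within-group least squares.

    Solves the normal equations ``S_XX beta = S_XY`` on the within-group
    centered covariates, then recovers intercepts and adjusted means.

    Raises
    ------
    ValueError
        If the pooled covariate cross-product matrix is (numerically)
        singular ("collinear covariates") or the residual degrees of
        freedom ``nu = N_T - G - P`` fall below 1.
    """
    g, p, n_tot = data.n_groups, data.n_covariates, data.n_total
    nu = n_tot - g - p
    if nu < 1:
        raise ValueError(
            f"insufficient residual degrees of freedom: nu = {n_tot} - {g} - {p} = {nu} < 1"
        )
    sizes = data.group_sizes
    idx = data.group_index

    ybar = np.bincount(idx, weights=data.y, minlength=g) / sizes
    xbar = np.vstack(
        [np.bincount(idx, weights=data.x[:, k], minlength=g) / sizes for k in range(p)]
    ).T  # (G, P)

    xc = data.x - xbar[idx]  # within-group centered
    yc = data.y - ybar[idx]
    s_xx = xc.T @ xc
    s_xy = xc.T @ yc

    if not np.isfinite(s_xx).all() or np.linalg.cond(s_xx) > COND_LIMIT:
        raise ValueError("collinear covariates: pooled cross-product matrix is singular")
    beta = np.linalg.solve(s_xx, s_xy)

    sse = float(yc @ yc - s_xy @ beta)
    sse = max(sse, 0.0)  # guard tiny negative round-off
    sigma_sq = sse / nu

    xbar_grand = data.x.mean(axis=0)
    mu = ybar - xbar @ beta
    mu_adj = mu + xbar_grand @ beta

    return ANCOVAFit(
        mu=mu,
        mu_adjusted=mu_adj,
        beta=beta,
        xbar_groups=xbar,
        xbar_grand=xbar_grand,
        s_xx=s_xx,
        s_xy=s_xy,
        v_xx=s_xx / (n_tot - g),
        sse=sse,
        sigma_sq=sigma_sq,
        nu=nu,
        group_sizes=sizes,
        group_labels=data.group_labels,
        n_total=n_tot,
    )


def variance_factor(group_sizes, contrast_coeffs, Q: float) -> float:
    """Variance factor ``V = a + Q/(N_T - G)`` with ``a = sum c_i^2 / N_i``.

    ``sigma^2 V`` is the variance of the contrast estimate; ``Q`` is the
    covariate-disparity statistic.
    """
    sizes = np.asarray(group_sizes, dtype=float)
    c = np.asarray(contrast_coeffs, dtype=float)
    if Q < 0:
        raise ValueError("Q must be >= 0")
    a = float(np.sum(c**2 / sizes))
    return a + Q / (sizes.sum() - sizes.size)


def contrast_estimate(fit: ANCOVAFit, contrast: ContrastSpec) -> ContrastEstimate:
    """Standardized-contrast estimate and its variance factor.

    ``Q = (sum_i c_i xbar_i)' V_XX^{-1} (sum_i c_i xbar_i)`` measures the
    sample disparity of the contrasted covariate means; ``V = a + Q/(N_T-G)``
    multiplies ``sigma^2`` in the variance of ``psi_hat``.
    """
    c = contrast.coefficients
    if len(contrast) != len(fit.group_labels):
        raise ValueError(
            f"contrast length {len(contrast)} does not match {len(fit.group_labels)} groups"
        )
    a = float(np.sum(c**2 / fit.group_sizes))
    h = c @ fit.xbar_groups  # (P,)
    Q = float(h @ np.linalg.solve(fit.v_xx, h))
    Q = max(Q, 0.0)
    V = variance_factor(fit.group_sizes, c, Q)
    psi_hat = float(c @ fit.mu)

    sigma_hat = np.sqrt(fit.sigma_sq)
    psi_star = psi_hat / sigma_hat if sigma_hat > 0 else np.inf * np.sign(psi_hat)
    if fit.nu > 1:
        u = unbias_factor(fit.nu)
        psi_star_ub = u * psi_star
    else:
        u, psi_star_ub = np.nan, np.nan
    return ContrastEstimate(
        psi_hat=psi_hat,
        psi_star_hat=float(psi_star),
        psi_star_ub=float(psi_star_ub),
        u=float(u),
        a=a,
        Q=Q,
        V=float(V),
        tau_sq=float(fit.sigma_sq * V),
        t_obs=float(psi_star / np.sqrt(V)),
        nu=fit.nu,
        sigma_sq=fit.sigma_sq,
    )


def unbias_factor(nu: float) -> float:
    """Small-sample bias-correction factor ``u(nu)``.

    ``u = Gamma(nu/2) / { (nu/2)^{1/2} Gamma((nu-1)/2) }``, the factor that
    makes ``u * psi_hat / sigma_hat`` unbiased for the standardized contrast
    (same correction as Hedges' g versus Cohen's d). Computed on the
    log-gamma scale for stability; ``0 < u < 1`` for finite ``nu > 1``.
    """
    if nu <= 1:
        raise ValueError("unbiased correction undefined: requires nu > 1")
    return float(np.exp(gammaln(nu / 2.0) - gammaln((nu - 1.0) / 2.0) - 0.5 * np.log(nu / 2.0)))
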