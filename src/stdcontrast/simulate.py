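"""Monte Carlo engines for coverage and precision validation.

Two designs are implemented, plus the synthetic-data generator every other
module's tests draw on:

* ``simulate_coverage`` — conditional (fixed-covariate) simulation: the
  contrast estimate and error variance are drawn directly from their
  sampling laws ``psi_hat ~ N(psi, sigma^2 V)`` and
  ``sigma_hat^2 = sigma^2 chi^2(nu)/nu`` with the covariate statistic ``Q``
  held fixed, and all three standardized-contrast intervals are assessed
  for coverage.
* ``simulate_precision`` — full-model simulation: covariates are drawn from
  their (multi)normal or standardized non-normal law, responses from the
  ANCOVA model, each replicate is refit, and the exact interval's width is
  recorded.

Coverage of the exact interval is scored through the probability-integral
pivot: the true standardized contrast lies inside the interval exactly when
the noncentral-t CDF at the observed statistic, evaluated at the true
noncentrality, falls strictly between the two tail levels. This is
algebraically identical to computing both limits and comparing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import special, stats

from .ancova import ANCOVAData, ContrastSpec, contrast_estimate, fit_ancova
from .intervals import noncentral_t_ncp_bulk
from .precision import DesignSpec

__all__ = ["SimConfig", "SimResult", "simulate_coverage", "simulate_precision", "generate_dataset"]

COVARIATE_LAWS = ("normal", "exponential", "gamma", "laplace", "lognormal", "uniform")


@dataclass(frozen=True)
class SimConfig:
    """Monte Carlo settings.

    Non-normal laws are affinely standardized to zero mean and unit
    variance before the group means and covariance structure are applied,
    so the disparity ``theta`` is preserved across laws. The named laws and
    their raw parameters: Exponential(1), Gamma(shape 5, scale 5^{-1/2}),
    Laplace(0, 1), Lognormal(0, 1/4), Uniform(0, 1); the gamma scale-vs-rate
    reading is immaterial after standardization (it only rescales).
    """

    reps: int = 10_000
    seed: int | None = None
    error_law: str = "normal"  # normal | t10
    covariate_law: str = "normal"
    beta: float = 0.5  # common slope for every covariate
    intercepts: np.ndarray | None = None  # default: psi * c / sum(c^2)

    def __post_init__(self):
        if self.reps < 1:
            raise ValueError("replicate count must be >= 1")
        if self.error_law not in ("normal", "t10"):
            raise ValueError("error_law must be 'normal' or 't10'")
        if self.covariate_law not in COVARIATE_LAWS:
            raise ValueError(f"covariate_law must be one of {COVARIATE_LAWS}")


@dataclass(frozen=True)
class SimResult:
    """Simulation summary; coverage fields for the conditional design,
    width/assurance fields for the full-model design."""

    reps: int
    coverage: dict | None = None  # {method: {upper, lower, two_sided}}
    deviation: dict | None = None  # coverage minus nominal
    se: dict | None = None  # binomial standard errors
    mean_width: float | None = None
    mean_width_se: float | None = None
    assurance: float | None = None
    assurance_se: float | None = None
    n_redrawn: int = 0
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimResult":
        return cls(**d)


def _binom_se(p: float, n: int) -> float:
    return math.sqrt(p * (1.0 - p) / n)


def simulate_coverage(
    n_total: int,
    psi_star: float,
    alpha: float,
    *,
    reps: int = 10_000,
    seed: int | None = None,
    sigma_sq: float = 3.2728,
    Q: float = 0.2131,
    contrast=(-1.0, 0.5, 0.5),
    p: int = 1,
) -> SimResult:
    """Conditional coverage simulation for all three standardized intervals.

    Defaults reproduce the learning-disabilities study conditions: error
    variance 3.2728, fixed covariate disparity statistic ``Q = 0.2131``,
    balanced three-group design, contrast ``{-1, 1/2, 1/2}``. One-sided
    intervals are assessed at level ``1 - alpha/2`` and combined into the
    two-sided ``1 - alpha`` interval.
    """
    c = ContrastSpec(np.asarray(contrast, dtype=float)).coefficients
    g = c.size
    if n_total % g:
        raise ValueError("balanced design requires N_T divisible by the group count")
    n_i = n_total // g
    a = float(np.sum(c**2)) / n_i
    V = a + Q / (n_total - g)
    nu = n_total - g - p
    if nu < 1:
        raise ValueError("nu < 1")
    sigma = math.sqrt(sigma_sq)
    psi = psi_star * sigma

    rng = np.random.default_rng(seed)
    psi_hat = rng.normal(psi, sigma * math.sqrt(V), size=reps)
    sigma_sq_hat = sigma_sq * rng.chisquare(nu, size=reps) / nu
    psi_star_hat = psi_hat / np.sqrt(sigma_sq_hat)
    t_obs = psi_star_hat / math.sqrt(V)

    lam_true = psi_star / math.sqrt(V)
    u = special.nctdtr(nu, lam_true, t_obs)  # pivot for the exact interval
    a1 = a2 = alpha / 2.0

    z = stats.norm.isf(a1)
    h_asym = z * np.sqrt(V + psi_star_hat**2 / (2.0 * nu))
    h_dir = stats.t.isf(a1, nu) * math.sqrt(V)

    cov_exact_up = u < 1.0 - a1  # psi_star above the lower limit
    cov_exact_lo = u > a2
    cov = {
        "exact": (cov_exact_up, cov_exact_lo),
        "asymptotic": (psi_star > psi_star_hat - h_asym, psi_star < psi_star_hat + h_asym),
        "direct": (psi_star > psi_star_hat - h_dir, psi_star < psi_star_hat + h_dir),
    }
    coverage, deviation, se = {}, {}, {}
    for method, (up, lo) in cov.items():
        p_up, p_lo, p_two = float(up.mean()), float(lo.mean()), float((up & lo).mean())
        coverage[method] = {"upper": p_up, "lower": p_lo, "two_sided": p_two}
        deviation[method] = {
            "upper": p_up - (1.0 - a1),
            "lower": p_lo - (1.0 - a2),
            "two_sided": p_two - (1.0 - alpha),
        }
        se[method] = {k: _binom_se(v, reps) for k, v in coverage[method].items()}
    return SimResult(
        reps=reps,
        coverage=coverage,
        deviation=deviation,
        se=se,
        meta={"n_total": n_total, "psi_star": psi_star, "alpha": alpha, "V": V, "nu": nu},
    )


def _standardized_draws(rng: np.random.Generator, law: str, size) -> np.ndarray:
    """Draws from the named law, affinely standardized to mean 0, variance 1."""
    if law == "normal":
        return rng.standard_normal(size)
    if law == "exponential":
        return rng.exponential(1.0, size) - 1.0
    if law == "gamma":
        shape, scale = 5.0, 5.0**-0.5
        x = rng.gamma(shape, scale, size)
        return (x - shape * scale) / (math.sqrt(shape) * scale)
    if law == "laplace":
        return rng.laplace(0.0, 1.0, size) / math.sqrt(2.0)
    if law == "lognormal":
        s2 = 0.25
        x = rng.lognormal(0.0, math.sqrt(s2), size)
        mean = math.exp(s2 / 2.0)
        sd = math.sqrt((math.exp(s2) - 1.0) * math.exp(s2))
        return (x - mean) / sd
    if law == "uniform":
        return (rng.uniform(0.0, 1.0, size) - 0.5) * math.sqrt(12.0)
    raise ValueError(f"unknown law {law!r}")


def _error_draws(rng: np.random.Generator, law: str, size) -> np.ndarray:
    if law == "normal":
        return rng.standard_normal(size)
    # t(10) scaled to unit variance
    return rng.standard_t(10, size) / math.sqrt(10.0 / 8.0)


def _resolve_intercepts(design: DesignSpec, config: SimConfig) -> np.ndarray:
    if config.intercepts is not None:
        mu = np.asarray(config.intercepts, dtype=float)
        if mu.size != design.n_groups:
            raise ValueError("intercepts must have one entry per group")
        return mu
    c = design.contrast.coefficients
    psi = design.psi_star * math.sqrt(design.sigma_sq)
    return psi * c / float(np.sum(c**2))


def generate_dataset(
    design: DesignSpec,
    n_total: int,
    config: SimConfig | None = None,
    seed: int | None = None,
    *,
    rng_cov: np.random.Generator | None = None,
    rng_err: np.random.Generator | None = None,
) -> ANCOVAData:
    """One synthetic dataset from the design's generating model.

    Covariates are drawn per group around the model's mean vectors with the
    common covariance; responses follow the ANCOVA model with slopes
    ``config.beta`` on every covariate. Deterministic under ``seed``
    (covariates and errors use independent substreams).
    """
    config = config or SimConfig()
    if rng_cov is None or rng_err is None:
        ss = np.random.SeedSequence(seed)
        rng_cov, rng_err = (np.random.default_rng(s) for s in ss.spawn(2))
    sizes = design.group_sizes(n_total)
    g, p = design.n_groups, design.p
    mu_x, sigma_x = design.covariates.mean_vectors(g)
    chol = np.linalg.cholesky(sigma_x)
    intercepts = _resolve_intercepts(design, config)
    beta = np.full(p, config.beta)

    group = np.repeat(np.arange(g), sizes)
    z = _standardized_draws(rng_cov, config.covariate_law, (n_total, p))
    x = z @ chol.T + mu_x[group]
    eps = _error_draws(rng_err, config.error_law, n_total) * math.sqrt(design.sigma_sq)
    y = intercepts[group] + x @ beta + eps
    return ANCOVAData(group=group, y=y, x=x)


def simulate_precision(
    design: DesignSpec,
    n_total: int,
    omega: float | None = None,
    config: SimConfig | None = None,
) -> SimResult:
    """Full-model simulation of the exact interval's width distribution.

    Each replicate draws covariates and responses, refits the ANCOVA model,
    and records the two-sided exact interval width
    ``W = V_hat^{1/2} d(T_O)``. Returns the mean width (simulated expected
    width) and, when ``omega`` is given, the fraction of replicates with
    ``W <= omega`` (simulated assurance), both with standard errors.
    Replicates with singular fits are redrawn; more than 0.1% of them is an
    error.
    """
    config = config or SimConfig()
    ss = np.random.SeedSequence(config.seed)
    rng_cov, rng_err = (np.random.default_rng(s) for s in ss.spawn(2))
    reps = config.reps

    t_obs = np.empty(reps)
    V = np.empty(reps)
    redrawn = 0
    contrast = design.contrast
    for r in range(reps):
        while True:
            data = generate_dataset(design, n_total, config, rng_cov=rng_cov, rng_err=rng_err)
            try:
                est = contrast_estimate(fit_ancova(data), contrast)
            except ValueError:
                redrawn += 1
                if redrawn > max(1, reps // 1000):
                    raise RuntimeError("more than 0.1% of replicates had singular fits")
                continue
            break
        t_obs[r] = est.t_obs
        V[r] = est.V

    alpha = design.alpha
    nu = design.nu(n_total)
    d = noncentral_t_ncp_bulk(t_obs, nu, alpha / 2.0) - noncentral_t_ncp_bulk(
        t_obs, nu, 1.0 - alpha / 2.0
    )
    w = np.sqrt(V) * d
    mean_w = float(w.mean())
    out = dict(
        reps=reps,
        mean_width=mean_w,
        mean_width_se=float(w.std(ddof=1) / math.sqrt(reps)),
        n_redrawn=redrawn,
        meta={"n_total": n_total, "alpha": alpha, "nu": nu, "omega": omega},
    )
    if omega is not None:
        p_hat = float((w <= omega).mean())
        out.update(assurance=p_hat, assurance_se=_binom_se(p_hat, reps))
    return SimResult(**out)
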