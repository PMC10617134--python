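"""Causal-effect estimators and power calculations.

Two estimation arms are supported.  With individual-level data the Wald
ratio divides the GRS-outcome association by the GRS-LDL-C association
(first-order delta-method standard error).  With summary statistics the
correlated-variant IVW estimator fits a generalized least-squares
regression of outcome betas on exposure betas through the origin, with
weight matrix Ω_ij = se_i · se_j · ρ_ij built from the LD correlation
matrix; heterogeneity is assessed by the generalized Cochran's Q.  Power
functions implement the standard non-centrality formulation for the
smallest detectable effect at given alpha and power.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats

from .ld import LDMatrix

Z_95 = float(stats.norm.ppf(0.975))

MAX_CONDITION_NUMBER = 1e8


class EstimationError(ValueError):
    pass


class WeakDenominatorWarning(UserWarning):
    """Denominator association too weak for a stable ratio estimate."""


@dataclass(frozen=True)
class CausalEstimate:
    """Effect per SD change in LDL-C, with 95% CI and heterogeneity.

    ``beta`` is on the SD-outcome (or log-odds) scale; the CI is
    beta ± 1.96·se under the normal reference.  Q fields are populated for
    the IVW method only (df = k − 1).
    """

    beta: float
    se: float
    pvalue: float
    method: str
    k_variants: int
    q: float | None = None
    q_df: int | None = None
    q_pvalue: float | None = None

    @property
    def ci_low(self) -> float:
        return self.beta - Z_95 * self.se

    @property
    def ci_high(self) -> float:
        return self.beta + Z_95 * self.se

    @property
    def odds_ratio(self) -> float:
        """exp(beta), meaningful when the outcome arm is log-odds."""
        return float(np.exp(self.beta))


@dataclass(frozen=True)
class PowerSpec:
    """Inputs for a post hoc detectable-effect calculation."""

    r2_xz: float
    outcome_type: str = "continuous"  # or "binary"
    alpha: float = 0.05
    power: float = 0.8
    n: int | None = None
    n_cases: int | None = None
    n_controls: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1 and 0 < self.power < 1):
            raise ValueError("alpha and power must lie in (0,1)")
        if not (0 < self.r2_xz < 1):
            raise ValueError("r2_xz must lie in (0,1)")


# ---------------------------------------------------------------------------
# Wald ratio

def wald_ratio(num, den, ldl_decrease: bool = False) -> CausalEstimate:
    """Ratio estimator: (GRS-on-outcome) / (GRS-on-LDL-C).

    ``num`` and ``den`` are association results from the same cohort and
    covariate set.  The standard error is the first-order delta method,
    num.se / |den.beta|, which ignores denominator variance — adequate
    when the instrument is strong (F > 10), which the pipeline flags.
    With ``ldl_decrease=True`` the sign is flipped so the estimate reads
    per SD *decrease* in LDL-C, the presentation convention for genetic
    inhibition of a lipid target.
    """
    if den.beta == 0:
        raise EstimationError("wald_ratio: zero denominator association")
    if abs(den.beta) / den.se < 2:
        warnings.warn(
            f"denominator |beta|/se = {abs(den.beta) / den.se:.2f} < 2; "
            "ratio estimate may be unstable", WeakDenominatorWarning,
            stacklevel=2,
        )
    beta = num.beta / den.beta
    if ldl_decrease:
        beta = -beta
    se = num.se / abs(den.beta)
    p = 2 * stats.norm.sf(abs(beta) / se) if se > 0 else 0.0
    return CausalEstimate(beta=float(beta), se=float(se), pvalue=float(p),
                          method="wald", k_variants=1)


# ---------------------------------------------------------------------------
# correlated-variant IVW

def _omega_factor(sy: np.ndarray, ld: LDMatrix | np.ndarray):
    rho = ld.r if isinstance(ld, LDMatrix) else np.asarray(ld, dtype=float)
    omega = np.outer(sy, sy) * rho
    cond = np.linalg.cond(omega)
    if not np.isfinite(cond) or cond > MAX_CONDITION_NUMBER:
        raise EstimationError(
            f"weight matrix ill-conditioned (cond={cond:.3g}); "
            "clump instruments at a stricter r² threshold"
        )
    return linalg.cho_factor(omega, lower=True)


def ivw_correlated(bx, by, sy, ld: LDMatrix | np.ndarray) -> CausalEstimate:
    """Inverse-variance-weighted estimate accounting for variant correlation.

    Generalized least squares of outcome betas ``by`` on exposure betas
    ``bx`` through the origin with covariance Ω_ij = sy_i·sy_j·ρ_ij:

        beta = (bxᵀ Ω⁻¹ by) / (bxᵀ Ω⁻¹ bx),   se = (bxᵀ Ω⁻¹ bx)^(−1/2)

    solved via a Cholesky factorization of Ω rather than explicit
    inversion.  With ρ = I this reduces to textbook fixed-effect IVW, and
    with k = 1 to the Wald ratio.  Heterogeneity (k ≥ 2) is returned as
    the generalized Cochran's Q against a chi-squared(k−1) reference.
    """
    bx = np.atleast_1d(np.asarray(bx, dtype=float))
    by = np.atleast_1d(np.asarray(by, dtype=float))
    sy = np.atleast_1d(np.asarray(sy, dtype=float))
    k = len(bx)
    if not (len(by) == len(sy) == k) or k < 1:
        raise EstimationError("bx, by, sy must share a positive length")
    if isinstance(ld, LDMatrix) and len(ld) != k:
        raise EstimationError("LD matrix dimension does not match instruments")
    if np.any(sy <= 0):
        raise EstimationError("outcome standard errors must be positive")
    cf = _omega_factor(sy, ld)
    oinv_bx = linalg.cho_solve(cf, bx)
    denom = float(bx @ oinv_bx)
    if denom <= 0:
        raise EstimationError("degenerate exposure betas (bx' O^-1 bx <= 0)")
    beta = float(oinv_bx @ by) / denom
    se = denom ** -0.5
    p = float(2 * stats.norm.sf(abs(beta) / se))
    q = q_df = q_p = None
    if k >= 2:
        q, q_df, q_p = cochran_q(bx, by, sy, ld, beta)
    return CausalEstimate(beta=beta, se=se, pvalue=p, method="ivw_correlated",
                          k_variants=k, q=q, q_df=q_df, q_pvalue=q_p)


def cochran_q(bx, by, sy, ld, beta_hat: float):
    """Generalized heterogeneity statistic for k >= 2 instruments.

    Q = (by − beta_hat·bx)ᵀ Ω⁻¹ (by − beta_hat·bx), df = k − 1, with an
    upper-tail chi-squared p-value.
    """
    bx = np.atleast_1d(np.asarray(bx, dtype=float))
    by = np.atleast_1d(np.asarray(by, dtype=float))
    sy = np.atleast_1d(np.asarray(sy, dtype=float))
    k = len(bx)
    if k < 2:
        raise EstimationError("Cochran's Q requires at least 2 instruments")
    resid = by - beta_hat * bx
    cf = _omega_factor(sy, ld)
    q = float(resid @ linalg.cho_solve(cf, resid))
    df = k - 1
    p = float(stats.chi2.sf(q, df))
    return q, df, p


# ---------------------------------------------------------------------------
# power

def _z_sum(alpha: float, power: float) -> float:
    return float(stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(power))


def power_continuous(spec: PowerSpec) -> float:
    """Smallest detectable |beta| for a continuous outcome.

    Non-centrality NCP = n·R²_xz·beta² gives
    |beta| = (z_{1−alpha/2} + z_{power}) / sqrt(n·R²_xz), in SD outcome
    per SD exposure.
    """
    if spec.outcome_type != "continuous":
        raise EstimationError("power_continuous requires a continuous outcome spec")
    if not spec.n:
        raise EstimationError("power_continuous requires n")
    return _z_sum(spec.alpha, spec.power) / np.sqrt(spec.n * spec.r2_xz)


def power_binary(spec: PowerSpec) -> float:
    """Smallest detectable odds ratio (protective side) for a binary outcome.

    With case fraction K = cases/(cases+controls),
    |ln OR| = (z_{1−alpha/2} + z_{power}) / sqrt(N·R²_xz·K(1−K)); the
    protective OR exp(−|ln OR|) is returned, matching the convention of
    reporting detectable risk reduction per SD-lower exposure.
    """
    if spec.outcome_type != "binary":
        raise EstimationError("power_binary requires a binary outcome spec")
    if not (spec.n_cases and spec.n_controls):
        raise EstimationError("power_binary requires n_cases and n_controls")
    n_total = spec.n_cases + spec.n_controls
    k_frac = spec.n_cases / n_total
    ln_or = _z_sum(spec.alpha, spec.power) / np.sqrt(
        n_total * spec.r2_xz * k_frac * (1 - k_frac)
    )
    return float(np.exp(-ln_or))


def achieved_power(beta: float, ncp_scale: float, alpha: float = 0.05) -> float:
    """Power to detect |beta| given NCP scale (n·R² or N·R²·K(1−K)).

    The numeric inverse of the detectable-effect formulas, used for
    consistency checks.
    """
    z_a = stats.norm.ppf(1 - alpha / 2)
    mu = abs(beta) * np.sqrt(ncp_scale)
    return float(stats.norm.sf(z_a - mu) + stats.norm.cdf(-z_a - mu))
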