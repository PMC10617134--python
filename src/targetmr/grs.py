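"""Genetic risk scores and covariate-adjusted association fits.

The GRS for a target is the sum over instruments of (external |beta|) ×
(dosage of the LDL-C-lowering allele), so a higher score means more
LDL-lowering alleles.  Associations of the score with standardized
phenotypes are estimated by (weighted) least squares adjusted for age,
sex and ancestry principal components; instrument strength in the cohort
is summarized by the partial R² of the score after covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .instruments import InstrumentSet

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ["age", "sex", "pc1", "pc2", "pc3", "pc4", "pc5", "pc6"]


class AssociationError(ValueError):
    pass


@dataclass(frozen=True)
class AssocResult:
    """A covariate-adjusted slope of outcome on GRS (or on a dosage)."""

    beta: float
    se: float
    pvalue: float
    n_used: int
    partial_r2: float


def build_grs(cohort, iset: InstrumentSet, dosage_prefix: str = "g_") -> pd.Series:
    """Per-individual weighted count of LDL-C-lowering alleles.

    Cohort dosage columns (``g_<variant_id>``) count copies of the allele
    named in the cohort's variant manifest; where that stored allele is
    not the instrument's counted (LDL-lowering) allele the dosage is
    re-oriented as 2 − d.  Individuals missing any instrument dosage get a
    missing score (logged), rather than a silently mean-imputed one.
    """
    data = cohort.data if hasattr(cohort, "data") else cohort
    manifest = cohort.variants.set_index("variant_id") if hasattr(cohort, "variants") else None
    score = np.zeros(len(data), dtype=float)
    any_missing = np.zeros(len(data), dtype=bool)
    for _, row in iset.variants.iterrows():
        col = dosage_prefix + row["variant_id"]
        if col not in data.columns:
            raise AssociationError(f"cohort lacks dosage column {col!r}")
        d = data[col].to_numpy(dtype=float)
        if manifest is not None:
            stored = manifest.loc[row["variant_id"], "counted_allele"]
            if stored != row["counted_allele"]:
                d = 2.0 - d
        score += row["weight"] * d
        any_missing |= ~np.isfinite(d)
    if any_missing.any():
        logger.info("build_grs: %d individual(s) with missing dosages excluded",
                    int(any_missing.sum()))
    score[any_missing] = np.nan
    return pd.Series(score, index=data.index, name=f"grs_{iset.gene.name}")


def standardize_outcome(values: pd.Series) -> pd.Series:
    """Center and scale to mean 0, SD 1 over non-missing entries.

    Uses the sample (n−1) SD.  Missing entries are preserved.  A constant
    (zero-SD) outcome raises, naming the series.
    """
    x = pd.Series(values, dtype=float)
    obs = x.dropna()
    if len(obs) < 2:
        raise AssociationError(f"outcome {x.name!r}: fewer than 2 observed values")
    sd = obs.std(ddof=1)
    if not sd > 0:
        raise AssociationError(f"outcome {x.name!r}: zero standard deviation")
    return (x - obs.mean()) / sd


def _design(x: np.ndarray, covars: np.ndarray | None) -> np.ndarray:
    cols = [np.ones_like(x), x]
    if covars is not None and covars.size:
        cols.extend(covars.T)
    return np.column_stack(cols)


def fit_covariate_adjusted(
    y,
    x,
    covars: pd.DataFrame | None = None,
    weights=None,
) -> AssocResult:
    """Weighted least-squares slope of ``y`` on ``x`` given covariates.

    Listwise-complete rows only; model-based (non-robust) standard errors
    with a normal reference for the p-value.  ``partial_r2`` is the share
    of covariate-residual variance explained by ``x`` (see
    :func:`partial_r2`).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    C = None if covars is None else np.asarray(covars, dtype=float)
    w = None if weights is None else np.asarray(weights, dtype=float)
    mask = np.isfinite(y) & np.isfinite(x)
    if C is not None:
        mask &= np.all(np.isfinite(C), axis=1)
    if w is not None:
        if np.any(w[mask] < 0):
            raise AssociationError("weights must be non-negative")
        mask &= np.isfinite(w) & (w > 0)
    n_used = int(mask.sum())
    k_covar = 0 if C is None else C.shape[1]
    if n_used < k_covar + 2:
        raise AssociationError(
            f"only {n_used} usable rows for {k_covar + 2}-parameter model"
        )
    X = _design(x[mask], None if C is None else C[mask])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise AssociationError("collinear covariates (design matrix rank-deficient)")
    wm = np.ones(n_used) if w is None else w[mask]
    fit = sm.WLS(y[mask], X, weights=wm).fit()
    fit0 = sm.WLS(y[mask], np.delete(X, 1, axis=1), weights=wm).fit()
    pr2 = partial_r2(fit, fit0)
    beta, se = float(fit.params[1]), float(fit.bse[1])
    p = float(2 * stats.norm.sf(abs(beta / se))) if se > 0 else 0.0
    return AssocResult(beta=beta, se=se, pvalue=p, n_used=n_used, partial_r2=pr2)


def partial_r2(fit_with, fit_without) -> float:
    """Proportion of residual variance explained by the added regressor.

    (RSS_without − RSS_with) / RSS_without, where the "without" model
    drops the GRS term but keeps all covariates.  Both fits must use the
    same rows (and weights).
    """
    if fit_with.nobs != fit_without.nobs:
        raise AssociationError("partial_r2: fits use different rows")
    rss1 = float(fit_with.ssr)
    rss0 = float(fit_without.ssr)
    if rss0 <= 0:
        raise AssociationError("partial_r2: covariate-only model has zero RSS")
    val = (rss0 - rss1) / rss0
    return float(min(max(val, 0.0), 1.0))


def fit_many_outcomes(
    Y: pd.DataFrame,
    x,
    covars: pd.DataFrame | None = None,
    weights=None,
) -> pd.DataFrame:
    """Vectorized covariate-adjusted slopes for a panel of outcomes.

    Equivalent to calling :func:`fit_covariate_adjusted` per column of
    ``Y`` (listwise within each outcome), via the Frisch-Waugh
    residualization done once.  Returns a frame indexed by outcome with
    beta, se, pvalue, n_used.  Rows missing ``x``, a covariate or a
    weight are excluded globally; rows missing only an outcome are
    excluded for that outcome.
    """
    x = np.asarray(x, dtype=float)
    C = None if covars is None else np.asarray(covars, dtype=float)
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    base = np.isfinite(x) & np.isfinite(w) & (w > 0)
    if C is not None:
        base &= np.all(np.isfinite(C), axis=1)
    X0 = np.ones((int(base.sum()), 1)) if C is None else np.column_stack(
        [np.ones(int(base.sum())), C[base]]
    )
    xb, wb = x[base], w[base]
    Xw = X0 * wb[:, None]
    P0 = np.linalg.solve(X0.T @ Xw, Xw.T)
    x_res = xb - X0 @ (P0 @ xb)
    p_params = X0.shape[1] + 1
    rows = {}
    for col in Y.columns:
        y = Y[col].to_numpy(dtype=float)[base]
        ok = np.isfinite(y)
        if ok.all():
            yr = y - X0 @ (P0 @ y)
            xr, wr, n = x_res, wb, len(y)
        else:
            Xs, ws, xs = X0[ok], wb[ok], xb[ok]
            Xw_s = Xs * ws[:, None]
            Ps = np.linalg.solve(Xs.T @ Xw_s, Xw_s.T)
            xr = xs - Xs @ (Ps @ xs)
            yr = y[ok] - Xs @ (Ps @ y[ok])
            wr, n = ws, int(ok.sum())
        sxx = float(np.sum(wr * xr * xr))
        beta = float(np.sum(wr * xr * yr) / sxx)
        e = yr - beta * xr
        sigma2 = float(np.sum(wr * e * e) / (n - p_params))
        se = float(np.sqrt(sigma2 / sxx))
        rows[col] = dict(beta=beta, se=se,
                         pvalue=float(2 * stats.norm.sf(abs(beta) / se)),
                         n_used=n)
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "outcome"
    return out


def per_variant_associations(
    cohort,
    variant_ids: list[str],
    phenotype: str = "ldl_std",
    covariates: list[str] | None = None,
    dosage_prefix: str = "g_",
) -> pd.DataFrame:
    """Covariate-adjusted per-variant dosage associations in the cohort.

    Produces the internal arm used for two-cohort instrument validation,
    in canonical summary-stat form (beta per counted-allele copy).
    """
    data = cohort.data if hasattr(cohort, "data") else cohort
    covariates = DEFAULT_COVARIATES if covariates is None else covariates
    C = data[covariates]
    manifest = cohort.variants.set_index("variant_id")
    rows = []
    for vid in variant_ids:
        d = data[dosage_prefix + vid]
        res = fit_covariate_adjusted(data[phenotype], d, C)
        m = manifest.loc[vid]
        rows.append(dict(
            variant_id=vid, chrom=str(m["chrom"]), pos=int(m["pos"]),
            effect_allele=m["counted_allele"], other_allele=m["other_allele"],
            eaf=float(d.mean() / 2.0), beta=res.beta, se=res.se,
            pvalue=res.pvalue, n=res.n_used,
        ))
    return pd.DataFrame(rows)
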