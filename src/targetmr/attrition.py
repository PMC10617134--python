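"""Attrition correction: multiple imputation, participation weights, pooling.

Cohort follow-ups lose participants non-randomly; analyses restricted to
responders can be biased when participation depends on variables related
to the outcomes.  Two complementary corrections are combined here, as in
standard missing-data practice for birth-cohort studies:

* chained-equations multiple imputation with predictive mean matching
  (PMM): each missing value is replaced by an observed donor value whose
  model-predicted mean is among the ``k`` closest, preserving the support
  and distribution shape of the variable;
* inverse probability of participation weights (IPW) from a logistic
  response model, so responders who resemble non-responders count more.

The analysis model is fitted, weighted, within each of ``m`` completed
datasets and the results combined by Rubin's rules with Barnard-Rubin
degrees of freedom.

The PMM engine is implemented here with an explicit
:class:`numpy.random.Generator` so that one master seed reproduces the
ensemble exactly (Bayesian parameter draws included); statsmodels is used
for the ordinary logistic/least-squares fits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

MIN_DONORS = 20
DEFAULT_M = 50
PMM_K_DONORS = 5
PMM_N_ITER = 10


class AttritionError(ValueError):
    pass


@dataclass
class ImputationEnsemble:
    """``m`` completed copies of a cohort table.

    Observed cells are identical across copies; only originally missing
    cells vary between them.
    """

    m: int
    completed_tables: list[pd.DataFrame]
    seed: int
    predictor_manifest: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.m != len(self.completed_tables):
            raise AttritionError("m does not match number of completed tables")

    def write(self, out_dir) -> None:
        """Persist as one CSV per imputation plus a JSON manifest."""
        import json
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for j, table in enumerate(self.completed_tables, start=1):
            table.to_csv(out / f"imputation_{j:03d}.csv", index=False,
                         float_format="%.8g")
        (out / "manifest.json").write_text(json.dumps({
            "m": self.m, "seed": self.seed,
            "predictor_manifest": self.predictor_manifest,
        }, indent=2))


@dataclass(frozen=True)
class PooledResult:
    """Rubin's-rules combination of per-imputation estimates."""

    estimate: float
    within_var: float
    between_var: float
    total_var: float
    se: float
    df: float
    pvalue: float
    m: int


# ---------------------------------------------------------------------------
# predictive mean matching

def _pmm_impute_variable(
    y: np.ndarray,
    X: np.ndarray,
    miss: np.ndarray,
    rng: np.random.Generator,
    k_donors: int,
) -> np.ndarray:
    """One PMM draw for one variable.

    Type-1 matching: donors are ranked by |X_obs b_hat − X_mis b_draw|
    where b_draw is a posterior draw of the regression coefficients, and
    the imputed value is the observed y of a randomly chosen donor among
    the ``k_donors`` nearest.
    """
    obs = ~miss
    Xo, yo = X[obs], y[obs]
    n_obs, p = Xo.shape
    XtX = Xo.T @ Xo
    ridge = 1e-8 * np.trace(XtX) / p  # guards exactly collinear predictors
    XtX_inv = np.linalg.inv(XtX + ridge * np.eye(p))
    b_hat = XtX_inv @ (Xo.T @ yo)
    resid = yo - Xo @ b_hat
    dof = max(n_obs - p, 1)
    sigma2 = float(resid @ resid) / dof
    # posterior draws: sigma² from scaled inv-chi², beta | sigma² normal
    sigma2_draw = float(resid @ resid) / rng.chisquare(dof)
    chol = np.linalg.cholesky(XtX_inv * sigma2_draw + 1e-32 * np.eye(p))
    b_draw = b_hat + chol @ rng.standard_normal(p)
    yhat_obs = Xo @ b_hat
    yhat_mis = X[miss] @ b_draw
    k = min(k_donors, n_obs)
    # nearest-donor matching on predicted means
    dist = np.abs(yhat_obs[None, :] - yhat_mis[:, None])
    nearest = np.argpartition(dist, k - 1, axis=1)[:, :k]
    choice = rng.integers(0, k, size=len(yhat_mis))
    donors = nearest[np.arange(len(yhat_mis)), choice]
    out = y.copy()
    out[miss] = yo[donors]
    return out


def impute_pmm(
    cohort,
    m: int = DEFAULT_M,
    seed: int = 0,
    predictors: list[str] | None = None,
    targets: list[str] | None = None,
    k_donors: int = PMM_K_DONORS,
    n_iter: int = PMM_N_ITER,
) -> ImputationEnsemble:
    """Chained-equations PMM over all variables with missing values.

    Parameters
    ----------
    cohort
        A data frame (or an object with a ``.data`` frame).
    predictors
        The imputation-model manifest: fully observed variables entering
        every conditional model.  Required in pipeline use; defaults to
        all complete numeric columns.
    targets
        Variables to impute; defaults to every column with missingness.

    Every target needs at least ``MIN_DONORS`` observed donors.  When no
    predictor itself contains missing values the chained system is solved
    in a single sweep (the conditionals do not interact); otherwise
    ``n_iter`` sweeps are run from a random-donor initialization.
    """
    data = (cohort.data if hasattr(cohort, "data") else cohort).copy()
    if m < 1:
        raise AttritionError("m must be >= 1")
    if targets is None:
        targets = [c for c in data.columns if data[c].isna().any()]
    if predictors is None:
        predictors = [
            c for c in data.columns
            if c not in targets
            and pd.api.types.is_numeric_dtype(data[c])
            and not data[c].isna().any()
        ]
    for v in targets:
        n_obs = int(data[v].notna().sum())
        if n_obs < MIN_DONORS:
            raise AttritionError(
                f"variable {v!r} has only {n_obs} observed donors (< {MIN_DONORS})"
            )
    miss_masks = {v: data[v].isna().to_numpy() for v in targets}
    if not targets or all(not mask.any() for mask in miss_masks.values()):
        return ImputationEnsemble(
            m=m, completed_tables=[data.copy() for _ in range(m)],
            seed=seed, predictor_manifest=list(predictors),
        )
    chained = any(data[p].isna().any() for p in predictors)
    sweeps = n_iter if chained else 1
    ss = np.random.SeedSequence([int(seed), 0x1A7])
    child_seeds = ss.spawn(m)
    tables: list[pd.DataFrame] = []
    for j in range(m):
        rng = np.random.default_rng(child_seeds[j])
        work = data.copy()
        # initialize missing cells with random observed donors
        for v in targets:
            mask = miss_masks[v]
            if mask.any():
                donors = work.loc[~mask, v].to_numpy()
                work.loc[mask, v] = rng.choice(donors, size=int(mask.sum()))
        for _ in range(sweeps):
            for v in targets:
                mask = miss_masks[v]
                if not mask.any():
                    continue
                preds = [p for p in predictors if p != v]
                X = np.column_stack(
                    [np.ones(len(work))] + [work[p].to_numpy(dtype=float) for p in preds]
                )
                y = data[v].to_numpy(dtype=float).copy()
                y[mask] = work.loc[mask, v].to_numpy(dtype=float)
                work[v] = _pmm_impute_variable(y, X, mask, rng, k_donors)
        tables.append(work)
    return ImputationEnsemble(
        m=m, completed_tables=tables, seed=seed,
        predictor_manifest=list(predictors),
    )


# ---------------------------------------------------------------------------
# inverse probability of participation weights

def fit_response_model(
    cohort,
    predictors: list[str],
    response_col: str = "responded",
) -> pd.Series:
    """Logistic model of participation; returns fitted probabilities.

    Zero-variance predictors are dropped (an all-constant manifest
    reduces to the intercept-only model, whose fitted probability is the
    observed response rate).  A degenerate response (all 0 or all 1) or
    quasi-separation (fitted probabilities within 1e-6 of the bounds)
    raises with advice to review the predictor manifest.
    """
    data = cohort.data if hasattr(cohort, "data") else cohort
    y = data[response_col].to_numpy(dtype=float)
    if y.min() == y.max():
        raise AttritionError("response indicator has no variation")
    used = [p for p in predictors if data[p].std(ddof=0) > 0]
    X = sm.add_constant(data[used].to_numpy(dtype=float)) if used else np.ones((len(y), 1))
    fit = sm.Logit(y, X).fit(disp=0)
    p = np.asarray(fit.predict(X), dtype=float)
    if np.any(p < 1e-6) or np.any(p > 1 - 1e-6):
        raise AttritionError(
            "response model is (quasi-)separated; review the predictor manifest"
        )
    return pd.Series(p, index=data.index, name="p_respond")


def compute_ipw(
    probabilities,
    responded=None,
    truncation: tuple[float, float] | None = (1.0, 99.0),
) -> pd.Series:
    """Inverse-probability-of-participation weights.

    Responders get 1/p, truncated at the given (lower, upper) weight
    percentiles for stability, then normalized to mean 1 among
    responders.  Non-responders get weight 0 (they contribute no rows to
    the weighted analysis).
    """
    p = pd.Series(probabilities, dtype=float)
    if not ((p > 0) & (p < 1)).all():
        raise AttritionError("participation probabilities must lie in (0,1)")
    resp = (
        pd.Series(responded, index=p.index).astype(bool)
        if responded is not None
        else pd.Series(True, index=p.index)
    )
    w = pd.Series(0.0, index=p.index, name="ipw")
    w[resp] = 1.0 / p[resp]
    if truncation is not None and resp.any():
        lo, hi = np.percentile(w[resp], truncation)
        w[resp] = w[resp].clip(lo, hi)
    if resp.any():
        w[resp] = w[resp] / w[resp].mean()
    return w


# ---------------------------------------------------------------------------
# Rubin's rules

def pool_rubin(estimates, variances, df_com: float | None = None) -> PooledResult:
    """Combine per-imputation estimates by Rubin's rules.

    estimate = mean(q_i); W = mean(v_i); B = var(q_i, ddof=1);
    T = W + (1 + 1/m)·B.  Degrees of freedom follow Barnard-Rubin when a
    complete-data ``df_com`` is supplied, otherwise the classical
    (m−1)·(1 + W/((1+1/m)B))² form; with B = 0 the reference is normal.
    """
    q = np.asarray(estimates, dtype=float)
    v = np.asarray(variances, dtype=float)
    m = len(q)
    if m < 2:
        raise AttritionError("Rubin pooling requires m >= 2 imputations")
    if len(v) != m:
        raise AttritionError("estimates and variances differ in length")
    qbar = float(q.mean())
    w = float(v.mean())
    b = float(q.var(ddof=1))
    t = w + (1 + 1 / m) * b
    se = float(np.sqrt(t))
    if b > 0 and t > 0:
        lam = (1 + 1 / m) * b / t
        df_old = (m - 1) / lam**2
        if df_com is not None:
            df_obs = (df_com + 1) / (df_com + 3) * df_com * (1 - lam)
            df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
        else:
            df = df_old
        p = float(2 * stats.t.sf(abs(qbar) / se, df)) if se > 0 else 0.0
    else:
        df = float("inf")
        p = float(2 * stats.norm.sf(abs(qbar) / se)) if se > 0 else 0.0
    return PooledResult(
        estimate=qbar, within_var=w, between_var=b, total_var=t,
        se=se, df=float(df), pvalue=p, m=m,
    )
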