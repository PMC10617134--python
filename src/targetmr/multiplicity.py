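"""Multiple-testing correction via the effective number of tests.

Correlated outcome panels (e.g. NMR metabolomics) make a plain Bonferroni
denominator too severe.  The effective number of tests is taken as the
smallest number of principal components of the outcome correlation matrix
whose cumulative eigenvalue share reaches a variance target (99%); the
corrected significance threshold is alpha divided by that count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VARIANCE_TARGET = 0.99
ALPHA = 0.05


class MultiplicityError(ValueError):
    pass


@dataclass(frozen=True)
class MultiplicityResult:
    """Effective-test count and the implied significance threshold."""

    n_outcomes: int
    n_eff: int
    alpha: float
    threshold: float
    eigenvalues: np.ndarray

    def __post_init__(self) -> None:
        assert 1 <= self.n_eff <= self.n_outcomes


def _nearest_psd_clip(c: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix to PSD by clipping eigenvalues at 0."""
    w, v = np.linalg.eigh(c)
    if w.min() >= 0:
        return c
    w = np.clip(w, 0.0, None)
    out = (v * w) @ v.T
    d = np.sqrt(np.clip(np.diag(out), 1e-12, None))
    out = out / np.outer(d, d)  # restore unit diagonal
    np.fill_diagonal(out, 1.0)
    return out


def effective_tests(
    outcomes: pd.DataFrame,
    variance_target: float = VARIANCE_TARGET,
    alpha: float = ALPHA,
) -> MultiplicityResult:
    """PCA of the outcome correlation matrix.

    Correlations are estimated pairwise-complete (missingness is allowed,
    so this runs before imputation); estimation noise occasionally breaks
    positive semi-definiteness, in which case the matrix is projected to
    the nearest PSD matrix by eigenvalue clipping.  ``n_eff`` is the
    smallest k whose top-k eigenvalue share reaches ``variance_target``.
    """
    if outcomes.shape[1] < 2:
        raise MultiplicityError("need at least 2 outcomes")
    corr = outcomes.corr(method="pearson").to_numpy()
    if not np.all(np.isfinite(corr)):
        raise MultiplicityError("non-finite pairwise correlations (outcome with <2 shared observations?)")
    corr = _nearest_psd_clip(corr)
    eig = np.linalg.eigvalsh(corr)[::-1]
    eig = np.clip(eig, 0.0, None)
    share = np.cumsum(eig) / eig.sum()
    n_eff = int(np.searchsorted(share, variance_target - 1e-12) + 1)
    n_eff = min(n_eff, outcomes.shape[1])
    res = MultiplicityResult(
        n_outcomes=outcomes.shape[1], n_eff=n_eff, alpha=alpha,
        threshold=alpha / n_eff, eigenvalues=eig,
    )
    logger.info(
        "effective_tests: %d outcomes -> %d effective tests, threshold %.6g",
        res.n_outcomes, res.n_eff, res.threshold,
    )
    return res


def classify_results(
    estimates: pd.DataFrame,
    threshold: float,
    alpha: float = ALPHA,
    panel_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Annotate estimate rows by significance class.

    ``corrected`` if p < threshold, else ``nominal`` if p < alpha, else
    ``null``.  A panel map (outcome -> efficacy|safety) tags each row if
    not already tagged.
    """
    out = estimates.copy()
    p = out["pvalue"].to_numpy(dtype=float)
    cls = np.where(p < threshold, "corrected", np.where(p < alpha, "nominal", "null"))
    out["class"] = cls
    if panel_map is not None:
        out["panel"] = out["outcome"].map(panel_map)
    return out


FOREST_COLUMNS = [
    "target", "outcome", "panel", "beta", "ci_low", "ci_high", "pvalue", "class",
]


def export_forest_table(annotated: pd.DataFrame, path) -> pd.DataFrame:
    """Write a forest-plot-ready tab-separated table.

    Sorted by panel, then outcome, then target, so row order is
    deterministic across runs; values round-trip at 6 significant
    decimals.  Returns the written frame.
    """
    if annotated.empty:
        out = pd.DataFrame(columns=FOREST_COLUMNS)
    else:
        out = annotated[FOREST_COLUMNS].sort_values(
            ["panel", "outcome", "target"], kind="mergesort"
        ).reset_index(drop=True)
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return out
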