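"""Linkage-disequilibrium correlation matrices.

An :class:`LDMatrix` stores pairwise genotype correlations (signed r, not
r²) for an ordered panel of variants, as estimated from a reference panel
such as 1000 Genomes.  It is consumed by LD clumping and by the
correlated-variant IVW estimator, where the weight matrix is built from
these correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: eigenvalue tolerance below which a matrix is rejected as non-PSD
PSD_TOL = 1e-8


class LDMatrixError(ValueError):
    """Raised for malformed or inconsistent LD matrices."""


@dataclass
class LDMatrix:
    """Square matrix of pairwise variant correlations (signed r).

    Parameters
    ----------
    variant_ids
        Ordered variant identifiers labelling rows/columns.
    r
        Square correlation matrix: symmetric, unit diagonal, entries in
        [-1, 1], positive semi-definite within ``PSD_TOL``.
    """

    variant_ids: list[str]
    r: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.variant_ids = list(self.variant_ids)
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.variant_ids)
        if self.r.shape != (k, k):
            raise LDMatrixError(
                f"matrix shape {self.r.shape} does not match {k} variant ids"
            )
        if k == 0:
            return
        if not np.allclose(self.r, self.r.T, atol=1e-10):
            raise LDMatrixError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise LDMatrixError("LD matrix diagonal must be 1")
        if np.any(np.abs(self.r) > 1 + 1e-10):
            raise LDMatrixError("LD correlations must lie in [-1, 1]")
        w = np.linalg.eigvalsh(self.r)
        if w.min() < -PSD_TOL:
            raise LDMatrixError(
                f"LD matrix is not positive semi-definite (min eigenvalue {w.min():.3g})"
            )

    def __len__(self) -> int:
        return len(self.variant_ids)

    def _index(self, variant_id: str) -> int:
        try:
            return self.variant_ids.index(variant_id)
        except ValueError:
            raise LDMatrixError(f"variant {variant_id!r} absent from LD matrix") from None

    def corr(self, a: str, b: str) -> float:
        """Signed correlation between two variants."""
        return float(self.r[self._index(a), self._index(b)])

    def r2(self, a: str, b: str) -> float:
        """Squared correlation (the clumping metric)."""
        return self.corr(a, b) ** 2

    def subset(self, ids: list[str]) -> "LDMatrix":
        """Restrict to ``ids`` in the given order."""
        idx = [self._index(v) for v in ids]
        return LDMatrix(list(ids), self.r[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.variant_ids, columns=self.variant_ids)


def write_ld_matrix(ld: LDMatrix, path) -> None:
    """Write as tab-separated square text with a variant-id header row."""
    ld.to_frame().to_csv(path, sep="\t", index_label="variant_id", float_format="%.10g")


def read_ld_matrix(path) -> LDMatrix:
    """Read a matrix written by :func:`write_ld_matrix`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise LDMatrixError("LD matrix row and column labels disagree")
    return LDMatrix([str(v) for v in df.columns], df.to_numpy(dtype=float))


def block_diagonal(blocks: list[LDMatrix]) -> LDMatrix:
    """Combine disjoint LD panels (zero cross-block correlation)."""
    ids: list[str] = []
    for b in blocks:
        ids.extend(b.variant_ids)
    if len(set(ids)) != len(ids):
        raise LDMatrixError("duplicate variant ids across LD blocks")
    r = np.zeros((len(ids), len(ids)))
    off = 0
    for b in blocks:
        k = len(b)
        r[off:off + k, off:off + k] = b.r
        off += k
    return LDMatrix(ids, r)
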