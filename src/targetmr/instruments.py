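"""Cis-instrument selection for a drug-target gene.

Variants are retained if they fall within a flanking window (default
±100 kb) of the target gene, pass genome-wide significance (p < 5e-8) in
the external GWAS, replicate in the individual-level validation cohort
(p < 0.05, direction-consistent), and survive greedy LD clumping at
r² < 0.3 within a 10,000 kb window.  The surviving set is weighted by the
absolute external effect and oriented so that the counted allele is the
LDL-C-lowering allele, ready for genetic-risk-score construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ld import LDMatrix

logger = logging.getLogger(__name__)

GWAS_P_THRESHOLD = 5e-8
COHORT_P_THRESHOLD = 0.05
CLUMP_R2 = 0.3
CLUMP_WINDOW_KB = 10_000
DEFAULT_FLANK_BP = 100_000
WEAK_F_THRESHOLD = 10.0


class InstrumentSelectionError(ValueError):
    pass


@dataclass(frozen=True)
class GeneRegion:
    """A drug-target gene with its cis flank (1-based bp, inclusive bounds)."""

    name: str
    chrom: str
    start: int
    end: int
    flank: int = DEFAULT_FLANK_BP

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.name}: start > end")
        if self.flank < 0:
            raise ValueError(f"{self.name}: flank must be >= 0")

    @property
    def window(self) -> tuple[int, int]:
        """Inclusive cis window [start - flank, end + flank]."""
        return (self.start - self.flank, self.end + self.flank)

    def contains(self, pos: int) -> bool:
        lo, hi = self.window
        return lo <= pos <= hi


@dataclass
class InstrumentSet:
    """Validated, clumped, LDL-lowering-oriented instruments for one gene.

    ``variants`` is a harmonized table (external + internal association
    columns) carrying, after :func:`orient_weights`, a positive ``weight``
    and the ``counted_allele`` per variant.  ``selection_log`` records a
    pass/fail flag per input variant per filter, partitioning the input.
    """

    gene: GeneRegion
    variants: pd.DataFrame
    ld: LDMatrix
    selection_log: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.variants["variant_id"])

    @property
    def weights(self) -> np.ndarray:
        return self.variants["weight"].to_numpy(dtype=float)

    def to_frame(self) -> pd.DataFrame:
        out = self.variants.copy()
        out.insert(0, "gene", self.gene.name)
        return out


# ---------------------------------------------------------------------------
# filters

def select_region_variants(
    records: pd.DataFrame,
    region: GeneRegion,
    p_threshold: float = GWAS_P_THRESHOLD,
) -> pd.DataFrame:
    """Variants inside the cis window at genome-wide significance.

    The window boundary is inclusive; the p-value cut is strict
    (p == threshold is excluded).  An empty result is legitimate (some
    targets yield no instruments) and is logged, not raised.
    """
    lo, hi = region.window
    mask = (
        (records["chrom"].astype(str) == str(region.chrom))
        & (records["pos"] >= lo)
        & (records["pos"] <= hi)
        & (records["pvalue"] < p_threshold)
    )
    out = records.loc[mask].reset_index(drop=True)
    if out.empty:
        logger.info(
            "select_region_variants: no variant passed for %s "
            "(window %s:%d-%d, p<%g)", region.name, region.chrom, lo, hi, p_threshold,
        )
    return out


def clump(
    records: pd.DataFrame,
    ld: LDMatrix,
    r2_max: float = CLUMP_R2,
    window_kb: float = CLUMP_WINDOW_KB,
) -> pd.DataFrame:
    """Greedy LD clumping.

    Repeatedly promote the remaining variant with the smallest p-value to
    index status, then remove every other remaining variant within
    ``window_kb`` of it whose r² with the index is >= ``r2_max``.  Returns
    the index variants ordered by p-value.  Ties in p are broken by
    position, then variant id, so the result is deterministic.
    """
    if records.empty:
        return records.reset_index(drop=True)
    for vid in records["variant_id"]:
        if vid not in ld.variant_ids:
            raise InstrumentSelectionError(f"variant {vid!r} absent from LD matrix")
    window_bp = window_kb * 1000.0
    pool = records.sort_values(
        ["pvalue", "pos", "variant_id"], kind="mergesort"
    ).reset_index(drop=True)
    remaining = list(pool.index)
    kept: list[int] = []
    while remaining:
        idx = remaining.pop(0)
        kept.append(idx)
        index_row = pool.loc[idx]
        pruned = []
        for j in remaining:
            row = pool.loc[j]
            if (
                abs(row["pos"] - index_row["pos"]) <= window_bp
                and ld.r2(index_row["variant_id"], row["variant_id"]) >= r2_max
            ):
                continue
            pruned.append(j)
        remaining = pruned
    return pool.loc[kept].reset_index(drop=True)


def validate_in_cohort(
    pairs: pd.DataFrame,
    alpha: float = COHORT_P_THRESHOLD,
    require_direction: bool = True,
) -> pd.DataFrame:
    """Two-cohort replication filter.

    Keeps harmonized variants whose internal (validation-cohort)
    association has p < ``alpha`` and, by default, the same sign as the
    external effect — a sign-discordant "replication" would corrupt GRS
    weighting and is dropped.
    """
    ok = pairs["internal_pvalue"] < alpha
    if require_direction:
        ok &= np.sign(pairs["internal_beta"]) == np.sign(pairs["beta"])
    return pairs.loc[ok].reset_index(drop=True)


def f_statistic(beta, se):
    """Approximate instrument F statistic, beta²/se².

    Accepts scalars or arrays; raises on non-positive se.  F < 10 is the
    conventional weak-instrument flag (checked by callers).
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise InstrumentSelectionError("standard errors must be positive")
    f = (beta / se) ** 2
    return float(f) if f.ndim == 0 else f


def is_weak(beta, se, threshold: float = WEAK_F_THRESHOLD):
    f = f_statistic(beta, se)
    return f < threshold


# ---------------------------------------------------------------------------
# instrument-set assembly

def build_instrument_set(
    harmonized: pd.DataFrame,
    region: GeneRegion,
    ld: LDMatrix,
    p_threshold: float = GWAS_P_THRESHOLD,
    cohort_alpha: float = COHORT_P_THRESHOLD,
    r2_max: float = CLUMP_R2,
    window_kb: float = CLUMP_WINDOW_KB,
    require_direction: bool = True,
) -> InstrumentSet:
    """Run the full selection chain and assemble an oriented InstrumentSet.

    Order: cis-window + genome-wide significance -> cohort replication ->
    LD clumping -> LDL-lowering weight orientation.  ``selection_log``
    assigns each input variant to exactly one outcome category.
    """
    log = pd.DataFrame({"variant_id": harmonized["variant_id"]})
    stage1 = select_region_variants(harmonized, region, p_threshold)
    log["pass_region_gwas"] = log["variant_id"].isin(stage1["variant_id"])
    stage2 = validate_in_cohort(stage1, cohort_alpha, require_direction)
    log["pass_cohort"] = log["variant_id"].isin(stage2["variant_id"])
    stage3 = clump(stage2, ld, r2_max, window_kb)
    log["pass_clump"] = log["variant_id"].isin(stage3["variant_id"])
    log["selected"] = log["pass_region_gwas"] & log["pass_cohort"] & log["pass_clump"]
    sub_ld = ld.subset(list(stage3["variant_id"])) if len(stage3) else LDMatrix([], np.empty((0, 0)))
    iset = InstrumentSet(gene=region, variants=stage3, ld=sub_ld, selection_log=log)
    if len(iset):
        iset = orient_weights(iset)
    logger.info(
        "%s: %d/%d variants selected", region.name, len(iset), len(harmonized)
    )
    return iset


def orient_weights(iset: InstrumentSet) -> InstrumentSet:
    """Orient each instrument to its LDL-C-lowering allele.

    If the external beta is negative the effect allele already lowers
    LDL-C and is counted as-is; if positive, the other allele is the
    lowering one.  The GRS weight is |external beta|.  Downstream dosages
    must be re-oriented to count the same allele (see
    :func:`targetmr.grs.build_grs`).
    """
    v = iset.variants.copy()
    if (v["beta"] == 0).any():
        bad = v.loc[v["beta"] == 0, "variant_id"].tolist()
        raise InstrumentSelectionError(f"zero external beta (uninformative): {bad}")
    lowering_is_effect = v["beta"] < 0
    v["counted_allele"] = np.where(lowering_is_effect, v["effect_allele"], v["other_allele"])
    v["weight"] = v["beta"].abs()
    return replace(iset, variants=v)


def select_index_variant(iset: InstrumentSet) -> InstrumentSet:
    """Single-instrument sensitivity set: the smallest external p-value.

    Ties are broken by position, then variant id.
    """
    if not len(iset):
        raise InstrumentSelectionError(f"{iset.gene.name}: empty instrument set")
    v = iset.variants.sort_values(
        ["pvalue", "pos", "variant_id"], kind="mergesort"
    ).head(1).reset_index(drop=True)
    return replace(iset, variants=v, ld=iset.ld.subset(list(v["variant_id"])))


def write_instrument_set(iset: InstrumentSet, path) -> None:
    """Serialize variants + weights + counted alleles as tab-separated text."""
    iset.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_gene_regions(path, flank: int = DEFAULT_FLANK_BP) -> list[GeneRegion]:
    """Read targets from a BED-like 4-column file: name, chrom, start, end.

    Tab- or whitespace-separated, ``#`` comments allowed; coordinates are
    1-based inclusive.  ``flank`` applies to every region.
    """
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise InstrumentSelectionError(
                    f"gene-region line needs 4 columns (name chrom start end): {line!r}"
                )
            name, chrom, start, end = parts[:4]
            regions.append(GeneRegion(name, chrom, int(start), int(end), flank))
    return regions
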