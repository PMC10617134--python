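"""GWAS summary-statistics I/O and allele harmonization.

The canonical on-disk form is a tab-separated table with columns
``variant_id, chrom, pos, effect_allele, other_allele, eaf, beta, se,
pvalue, n``.  Other dialects (e.g. GLGC or GWAS-SSF column names) are
mapped in via a column-name dictionary on read.

Harmonization aligns an *internal* (validation-cohort) association record
onto the allele frame of the *external* (weight-source) record: swapped
alleles flip the sign of beta and complement the allele frequency; records
on the opposite strand are complemented first.  Palindromic (A/T, C/G)
variants cannot be strand-resolved from alleles alone and are flagged;
those with near-0.5 external frequency are dropped by
:func:`drop_ambiguous_palindromes` because frequency cannot disambiguate
the strand either.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: relative tolerance for the |beta/se| vs p-value consistency check
_Z_CONSISTENCY_RTOL = 0.10


class SummaryStatsFormatError(ValueError):
    """Raised when a summary-statistics file cannot be interpreted."""


class HarmonizationError(ValueError):
    """Raised when two records' allele sets cannot be reconciled."""


@dataclass(frozen=True)
class VariantRecord:
    """One variant's marginal association from a GWAS.

    ``beta`` is the per-effect-allele effect (for LDL-C, on the SD scale of
    the standardized phenotype), ``eaf`` the effect-allele frequency.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    n: int

    def is_valid(self) -> bool:
        return not self.validation_errors()

    def validation_errors(self) -> list[str]:
        errs = []
        if not (self.se > 0):
            errs.append("se must be > 0")
        if not (0 < self.eaf < 1):
            errs.append("eaf must be in (0,1)")
        if not self.effect_allele or not self.other_allele:
            errs.append("alleles must be non-empty")
        elif self.effect_allele == self.other_allele:
            errs.append("alleles must be distinct")
        if not (0 < self.pvalue <= 1):
            errs.append("pvalue must be in (0,1]")
        elif self.se > 0 and not _p_consistent(self.beta, self.se, self.pvalue):
            errs.append("pvalue inconsistent with |beta/se|")
        return errs

    @property
    def palindromic(self) -> bool:
        pair = {self.effect_allele, self.other_allele}
        return pair == {"A", "T"} or pair == {"C", "G"}


def _p_consistent(beta: float, se: float, pvalue: float) -> bool:
    """Check the two-sided normal p against |beta/se| within 10% on the z scale."""
    z = abs(beta / se)
    if pvalue <= 5e-300:  # beyond float resolution of the normal tail
        return z > 35
    z_from_p = stats.norm.isf(pvalue / 2.0)
    return abs(z_from_p - z) <= _Z_CONSISTENCY_RTOL * max(z, 1.0)


@dataclass(frozen=True)
class HarmonizedPair:
    """External and internal records aligned to one allele frame."""

    variant_id: str
    external: VariantRecord
    internal: VariantRecord
    flipped: bool
    strand_flipped: bool
    palindromic: bool


# ---------------------------------------------------------------------------
# I/O

def read_summary_stats(path, dialect: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a summary-statistics table, validating every row.

    Parameters
    ----------
    path
        Tab-separated file.
    dialect
        Optional map from file column names to canonical names, e.g.
        ``{"rsid": "variant_id", "p": "pvalue"}``.

    Rows failing record invariants (non-positive se, out-of-range eaf,
    identical alleles, p inconsistent with beta/se) are dropped with a
    logged count.  A missing required column raises
    :class:`SummaryStatsFormatError` naming the column.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if dialect:
        df = df.rename(columns=dialect)
    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            raise SummaryStatsFormatError(f"required column {col!r} missing from {path}")
    df = df[CANONICAL_COLUMNS].copy()
    df["chrom"] = df["chrom"].astype(str)
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()
    keep = np.ones(len(df), dtype=bool)
    for i, row in enumerate(df.itertuples(index=False)):
        rec = VariantRecord(*row)
        if not rec.is_valid():
            keep[i] = False
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("read_summary_stats: dropped %d invalid row(s) from %s", n_dropped, path)
    out = df.loc[keep].reset_index(drop=True)
    out["pos"] = out["pos"].astype(int)
    out["n"] = out["n"].astype(int)
    return out


def write_summary_stats(df: pd.DataFrame, path) -> None:
    """Write in the canonical tab-separated dialect."""
    df[CANONICAL_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.10g")


def records_from_frame(df: pd.DataFrame) -> list[VariantRecord]:
    return [VariantRecord(**row) for row in df[CANONICAL_COLUMNS].to_dict("records")]


def frame_from_records(records: list[VariantRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records], columns=CANONICAL_COLUMNS)


# ---------------------------------------------------------------------------
# harmonization

def _complement_alleles(a: str, b: str) -> tuple[str, str]:
    try:
        return ("".join(_COMPLEMENT[c] for c in a), "".join(_COMPLEMENT[c] for c in b))
    except KeyError:
        raise HarmonizationError(f"cannot strand-complement alleles {a}/{b}") from None


def harmonize(external: VariantRecord, internal: VariantRecord) -> HarmonizedPair:
    """Align ``internal`` onto the allele frame of ``external``.

    Four cases are resolved in order: exact allele match; swapped alleles
    (beta negated, eaf complemented); strand-complemented match; strand-
    complemented swap.  Anything else raises :class:`HarmonizationError`.
    """
    if external.variant_id != internal.variant_id:
        raise HarmonizationError(
            f"variant ids differ: {external.variant_id} vs {internal.variant_id}"
        )
    ea, oa = external.effect_allele, external.other_allele
    iea, ioa = internal.effect_allele, internal.other_allele
    flipped = strand = False
    if (iea, ioa) == (ea, oa):
        aligned = internal
    elif (iea, ioa) == (oa, ea):
        aligned = _swap(internal)
        flipped = True
    else:
        cea, coa = _complement_alleles(iea, ioa)
        if (cea, coa) == (ea, oa):
            aligned = replace(internal, effect_allele=cea, other_allele=coa)
            strand = True
        elif (cea, coa) == (oa, ea):
            aligned = _swap(replace(internal, effect_allele=cea, other_allele=coa))
            flipped = strand = True
        else:
            raise HarmonizationError(
                f"{external.variant_id}: alleles {iea}/{ioa} incompatible with {ea}/{oa}"
            )
    return HarmonizedPair(
        variant_id=external.variant_id,
        external=external,
        internal=aligned,
        flipped=flipped,
        strand_flipped=strand,
        palindromic=external.palindromic,
    )


def _swap(rec: VariantRecord) -> VariantRecord:
    return replace(
        rec,
        effect_allele=rec.other_allele,
        other_allele=rec.effect_allele,
        beta=-rec.beta,
        eaf=1.0 - rec.eaf,
    )


def harmonize_tables(external: pd.DataFrame, internal: pd.DataFrame) -> pd.DataFrame:
    """Harmonize two canonical tables on ``variant_id``.

    Returns one row per shared variant with the external columns plus
    ``internal_beta, internal_se, internal_pvalue, internal_eaf, internal_n,
    flipped, strand_flipped, palindromic``.  Chrom/pos disagreement at a
    shared rsID is logged as a warning (build drift), not an error;
    incompatible allele sets raise.
    """
    ext = {r.variant_id: r for r in records_from_frame(external)}
    intl = {r.variant_id: r for r in records_from_frame(internal)}
    rows = []
    for vid, e in ext.items():
        if vid not in intl:
            continue
        i = intl[vid]
        if (e.chrom, e.pos) != (i.chrom, i.pos):
            logger.warning(
                "harmonize: %s position differs between sources (%s:%d vs %s:%d)",
                vid, e.chrom, e.pos, i.chrom, i.pos,
            )
        pair = harmonize(e, i)
        row = dict(e.__dict__)
        row.update(
            internal_beta=pair.internal.beta,
            internal_se=pair.internal.se,
            internal_pvalue=pair.internal.pvalue,
            internal_eaf=pair.internal.eaf,
            internal_n=pair.internal.n,
            flipped=pair.flipped,
            strand_flipped=pair.strand_flipped,
            palindromic=pair.palindromic,
        )
        rows.append(row)
    cols = CANONICAL_COLUMNS + [
        "internal_beta", "internal_se", "internal_pvalue", "internal_eaf",
        "internal_n", "flipped", "strand_flipped", "palindromic",
    ]
    return pd.DataFrame(rows, columns=cols)


def drop_ambiguous_palindromes(
    pairs: pd.DataFrame, eaf_window: tuple[float, float] = (0.42, 0.58)
) -> pd.DataFrame:
    """Remove palindromic pairs whose external EAF lies inside ``eaf_window``.

    Inside the window the allele frequency cannot distinguish the two
    strand interpretations, so the variant is unusable; outside it the
    frequency pins the strand and the variant is kept.
    """
    lo, hi = eaf_window
    ambiguous = pairs["palindromic"] & (pairs["eaf"] > lo) & (pairs["eaf"] < hi)
    n_removed = int(ambiguous.sum())
    if n_removed:
        logger.info("drop_ambiguous_palindromes: removed %d variant(s)", n_removed)
    return pairs.loc[~ambiguous].reset_index(drop=True)
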