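"""Seeded synthetic study generator.

Emulates the three inputs a drug-target MR safety screen consumes, with
the statistical structure the analysis assumes:

* GWAS summary statistics for LDL-C (large middle-aged EAS population)
  and for CAD (case-control counts), over cis panels around the target
  genes plus decoy variants, with sampling noise correlated according to
  the LD matrix;
* block-structured LD reference panels per gene region;
* an individual-level adolescent cohort: genotype dosages from a latent
  Gaussian-copula model calibrated so dosage correlations match the LD
  matrix, covariates (age, sex, 6 ancestry PCs), LDL-C in mmol/L with a
  medication-masking mechanism, a panel of continuous outcomes correlated
  through LDL-C and through shared residual factors, and an MAR
  participation mechanism driving outcome missingness.

One master seed drives independent sub-streams per component (panel
layout, GWAS noise, genotypes, phenotype noise, missingness), so toggling
one component does not shift the draws of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .ld import LDMatrix, block_diagonal
from .instruments import GeneRegion

# z threshold corresponding to p = 5e-8, for placing decoys around it
_Z_GWS = float(stats.norm.isf(5e-8 / 2))

_STREAM = {
    "panel": 0x01, "gwas_ldl": 0x02, "gwas_cad": 0x03, "genotypes": 0x04,
    "covariates": 0x05, "ldl": 0x06, "outcomes": 0x07, "missing": 0x08,
    "medication": 0x09,
}

FRIEDEWALD_TG_LIMIT = 4.5  # mmol/L; formula invalid at higher triglycerides
MEDICATION_FACTOR = 0.7


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# configuration

@dataclass
class RegionSpec:
    """One target-gene cis panel.

    ``true_betas`` are joint per-allele effects on SD-standardized LDL-C
    in the GWAS population; ``cohort_beta_scale`` multiplies them in the
    adolescent cohort (per-allele lipid effects are larger at age ~17
    than the middle-aged GWAS betas imply; see methods note).  Decoys:
    ``n_null_inside`` sub-threshold variants inside the cis window and
    ``n_null_outside`` variants beyond the flank, half of them genuinely
    genome-wide significant so the window filter is load-bearing.
    """

    gene: GeneRegion
    mafs: tuple[float, ...] = ()
    true_betas: tuple[float, ...] = ()
    ld_blocks: tuple[tuple[int, float], ...] = ()
    n_null_inside: int = 0
    n_null_outside: int = 0
    cohort_beta_scale: float = 1.0

    def __post_init__(self) -> None:
        if len(self.mafs) != len(self.true_betas):
            raise SimulationError(f"{self.gene.name}: mafs/true_betas length mismatch")
        if any(not (0 < m <= 0.5) for m in self.mafs):
            raise SimulationError(f"{self.gene.name}: MAFs must lie in (0, 0.5]")
        if sum(s for s, _ in self.ld_blocks) != len(self.mafs):
            raise SimulationError(f"{self.gene.name}: LD block sizes must cover causal variants")
        if any(abs(r) >= 1 for _, r in self.ld_blocks):
            raise SimulationError(f"{self.gene.name}: |within-block r| must be < 1")


@dataclass(frozen=True)
class OutcomeSpec:
    """One continuous outcome: causal LDL effect and residual structure.

    ``theta`` is the causal effect of SD-LDL-C on the SD-standardized
    outcome; ``pair`` groups near-duplicate outcomes sharing a residual
    factor (correlation ``pair_r``); ``u_loading`` is the loading on the
    cohort-wide latent factor that also drives participation.
    """

    name: str
    panel: str  # "efficacy" | "safety"
    theta: float = 0.0
    pair: int | None = None
    pair_r: float = 0.985
    u_loading: float = 0.3


@dataclass
class SimConfig:
    """Full study configuration (all components seeded from ``seed``)."""

    seed: int = 0
    n_cohort: int = 3443
    n_gwas: int = 146_492
    cad_n_cases: int = 29_319
    cad_n_controls: int = 183_134
    theta_cad: float = 0.4155  # log-odds of CAD per SD-higher LDL-C
    regions: list[RegionSpec] = field(default_factory=list)
    outcomes: list[OutcomeSpec] = field(default_factory=list)
    med_fraction: float = 0.01
    item_missing_rate: float = 0.02
    missing_model_coefs: dict[str, float] = field(default_factory=dict)
    ldl_mean_mmol: float = 1.61
    ldl_sd_mmol: float = 0.355
    mean_age: float = 17.6
    sd_age: float = 0.8
    male_fraction: float = 0.5112  # 1760 of 3443

    def __post_init__(self) -> None:
        for name, v in (("n_cohort", self.n_cohort), ("n_gwas", self.n_gwas),
                        ("cad_n_cases", self.cad_n_cases),
                        ("cad_n_controls", self.cad_n_controls)):
            if v <= 0:
                raise SimulationError(f"{name} must be > 0")
        if not (0 <= self.med_fraction < 1):
            raise SimulationError("med_fraction must lie in [0, 1)")
        for o in self.outcomes:
            if abs(o.theta) >= 1:
                raise SimulationError(f"outcome {o.name}: |theta| must be < 1")

    # flat views of the primary region, convenient for single-region use
    @property
    def k_variants_region(self) -> int:
        return len(self.regions[0].mafs)

    @property
    def mafs(self) -> tuple[float, ...]:
        return self.regions[0].mafs

    @property
    def true_variant_betas(self) -> tuple[float, ...]:
        return self.regions[0].true_betas

    @property
    def ld_blocks(self) -> tuple[tuple[int, float], ...]:
        return self.regions[0].ld_blocks

    @property
    def theta_causal(self) -> dict[str, float]:
        return {o.name: o.theta for o in self.outcomes}

    @property
    def n_outcomes(self) -> int:
        return len(self.outcomes)

    def _rng(self, component: str, extra: int = 0) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), _STREAM[component], extra])
        )


def _betas_from_z(z_targets, mafs, n_gwas, ld_blocks=None) -> tuple[float, ...]:
    """Per-allele joint betas whose GWAS *marginal* z-scores hit the targets.

    The marginal (single-variant) effect of variant j is the LD projection
    of the joint effects, b_marg√v = R (b√v); inverting R makes the
    emulated per-variant F statistics match the requested z² values.
    """
    mafs = np.asarray(mafs, dtype=float)
    z = np.asarray(z_targets, dtype=float)
    v = 2 * mafs * (1 - mafs)
    if ld_blocks:
        R = simulate_ld_matrix(list(ld_blocks)).r
        scaled = np.linalg.solve(R, z / np.sqrt(n_gwas))
    else:
        scaled = z / np.sqrt(n_gwas)
    return tuple(float(b) for b in scaled / np.sqrt(v))


# GRCh37 coordinates of the three lipid-target genes
HMGCR_REGION = GeneRegion("HMGCR", "5", 74_632_154, 74_657_929)
PCSK9_REGION = GeneRegion("PCSK9", "1", 55_505_221, 55_530_525)
NPC1L1_REGION = GeneRegion("NPC1L1", "7", 44_552_134, 44_580_914)

_EFFICACY_NAMES = [
    "apob", "apob_apoa1", "total_c", "ldl_c", "clinical_ldl_c", "non_hdl_c",
    "remnant_c", "vldl_c", "idl_c", "hdl_c", "total_tg", "vldl_tg",
    "l_ldl_c", "m_ldl_c", "s_ldl_c", "m_vldl_c", "s_vldl_c", "xs_vldl_c",
    "idl_p", "l_ldl_p", "m_ldl_p", "s_ldl_p", "total_pl", "ldl_pl", "ldl_ce",
]
_SAFETY_NAMES = [
    "linoleic_acid", "omega6", "omega3", "pufa", "mufa", "sfa", "total_fa",
    "ala", "gln", "gly", "his", "ile", "leu", "val", "phe", "tyr",
    "glucose", "lactate", "pyruvate", "citrate", "glycerol", "acetate",
    "acetoacetate", "bohbutyrate", "creatinine", "albumin", "glyca",
    "height", "weight", "bmi", "waist", "hip", "head_circ", "sitting_height",
    "fat_mass", "lean_mass", "trunk_fat", "body_fat_pct",
    "fev1", "fvc", "fev1_fvc", "pef", "fef2575",
    "hb", "hct", "rbc", "mcv", "mch", "mchc", "rdw", "wbc", "neut", "lymph",
    "mono", "eos", "baso", "plt", "mpv", "urea", "alp", "alt", "bilirubin",
    "total_protein",
]


def default_outcome_panel(
    n_outcomes: int = 100,
    efficacy_fraction: float = 0.25,
    theta_range: tuple[float, float] = (0.35, 0.85),
    safety_thetas: dict[str, float] | None = None,
) -> list[OutcomeSpec]:
    """Outcome panel emulating an adolescent biobank follow-up.

    ``n_outcomes`` continuous outcomes, a quarter of them cholesterol-
    related efficacy outcomes with causal LDL effects spread over
    ``theta_range``, the rest null safety outcomes.  About half the
    outcomes come in near-duplicate pairs (residual correlation 0.985),
    mirroring the redundancy of NMR panels; this is what makes the
    effective number of tests fall below the panel size.
    """
    n_eff = max(2, int(round(n_outcomes * efficacy_fraction)))
    n_saf = n_outcomes - n_eff
    safety_thetas = safety_thetas or {}

    def _names(base: list[str], n: int, prefix: str) -> list[str]:
        out = list(base[:n])
        out += [f"{prefix}_{i:02d}" for i in range(len(out), n)]
        return out

    specs: list[OutcomeSpec] = []
    pair_id = 0
    eff_names = _names(_EFFICACY_NAMES, n_eff, "eff")
    n_eff_pairs = n_eff // 2 - (n_eff // 2) // 2  # pair roughly half
    thetas = np.linspace(theta_range[1], theta_range[0], n_eff - n_eff_pairs)
    ti = 0
    i = 0
    while i < n_eff:
        if pair_id < n_eff_pairs and i + 1 < n_eff:
            th = float(thetas[ti]); ti += 1
            specs.append(OutcomeSpec(eff_names[i], "efficacy", th, pair=pair_id))
            specs.append(OutcomeSpec(eff_names[i + 1], "efficacy", th, pair=pair_id))
            pair_id += 1
            i += 2
        else:
            specs.append(OutcomeSpec(eff_names[i], "efficacy", float(thetas[ti])))
            ti += 1
            i += 1
    saf_names = _names(_SAFETY_NAMES, n_saf, "saf")
    n_saf_pairs = n_saf // 4
    i = 0
    while i < n_saf:
        th = float(safety_thetas.get(saf_names[i], 0.0))
        if i // 2 < n_saf_pairs and i + 1 < n_saf:
            specs.append(OutcomeSpec(saf_names[i], "safety", th, pair=pair_id))
            specs.append(OutcomeSpec(saf_names[i + 1], "safety",
                                     float(safety_thetas.get(saf_names[i + 1], th)),
                                     pair=pair_id))
            pair_id += 1
            i += 2
        else:
            specs.append(OutcomeSpec(saf_names[i], "safety", th))
            i += 1
    return specs[:n_outcomes]


def default_config(seed: int = 0, n_outcomes: int = 100) -> SimConfig:
    """Study conditions emulating the published HMGCR/PCSK9 screen.

    GWAS arm: n = 146,492 for LDL-C; CAD 29,319 cases / 183,134 controls;
    HMGCR instruments with F statistics spanning ~38-266 and PCSK9 ~34-42;
    protective CAD effect OR ~0.66 per SD-lower LDL-C.  Cohort arm:
    n = 3443 adolescents aged ~17.6, 100 outcomes, ~25% attrition.
    """
    n_gwas = 146_492
    hmgcr = RegionSpec(
        gene=HMGCR_REGION,
        mafs=(0.12, 0.34, 0.05, 0.21, 0.28),
        true_betas=_betas_from_z((6.3, 9.0, 12.0, 14.5, 16.2),
                                 (0.12, 0.34, 0.05, 0.21, 0.28), n_gwas,
                                 ((2, 0.45), (3, 0.25))),
        ld_blocks=((2, 0.45), (3, 0.25)),
        n_null_inside=25, n_null_outside=25,
        cohort_beta_scale=3.5,
    )
    pcsk9 = RegionSpec(
        gene=PCSK9_REGION,
        mafs=(0.15, 0.30, 0.08),
        true_betas=_betas_from_z((5.9, 6.2, 6.4), (0.15, 0.30, 0.08), n_gwas,
                                 ((3, 0.30),)),
        ld_blocks=((3, 0.30),),
        n_null_inside=10, n_null_outside=10,
        cohort_beta_scale=4.0,
    )
    npc1l1 = RegionSpec(
        gene=NPC1L1_REGION, n_null_inside=6, n_null_outside=4,
    )
    return SimConfig(
        seed=seed,
        regions=[hmgcr, pcsk9, npc1l1],
        outcomes=default_outcome_panel(n_outcomes),
        missing_model_coefs={
            "intercept": 1.3, "age_c": -0.25, "sex": -0.2, "baseline": -0.5,
        },
    )


def selection_fixture_config(seed: int = 0, n_outcomes: int = 8) -> SimConfig:
    """Stress fixture for the selection filters: 5 strong planted
    instruments plus 50 decoys in one HMGCR-like region."""
    n_gwas = 146_492
    region = RegionSpec(
        gene=HMGCR_REGION,
        mafs=(0.12, 0.34, 0.05, 0.21, 0.28),
        true_betas=_betas_from_z((12.0, 15.0, 18.0, 21.0, 25.0),
                                 (0.12, 0.34, 0.05, 0.21, 0.28), n_gwas,
                                 ((2, 0.45), (3, 0.25))),
        ld_blocks=((2, 0.45), (3, 0.25)),
        n_null_inside=25, n_null_outside=25,
        cohort_beta_scale=2.5,
    )
    return SimConfig(
        seed=seed,
        regions=[region],
        outcomes=default_outcome_panel(n_outcomes),
        missing_model_coefs={"intercept": 1.3, "age_c": -0.25, "sex": -0.2,
                             "baseline": -0.5},
    )


# ---------------------------------------------------------------------------
# small deterministic formulas

def apply_medication_correction(ldl_observed, on_med):
    """Undo lipid-lowering medication: divide observed LDL-C by 0.7.

    Individuals on medication have their untreated LDL-C estimated as
    observed / 0.7; others are returned unchanged.  LDL-C must be
    positive (mmol/L).
    """
    ldl = np.asarray(ldl_observed, dtype=float)
    if np.any(ldl <= 0):
        raise SimulationError("LDL-C must be positive")
    med = np.asarray(on_med, dtype=bool)
    out = np.where(med, ldl / MEDICATION_FACTOR, ldl)
    return float(out) if out.ndim == 0 else out


def friedewald_ldl(tc, hdl, tg):
    """Friedewald LDL-C (mmol/L): TC − HDL − TG/2.2.

    Invalid at triglycerides >= 4.5 mmol/L, where the fixed TG/2.2 VLDL
    approximation breaks down; such inputs are refused.
    """
    tc = np.asarray(tc, dtype=float)
    hdl = np.asarray(hdl, dtype=float)
    tg = np.asarray(tg, dtype=float)
    if np.any(tg >= FRIEDEWALD_TG_LIMIT):
        raise SimulationError(
            f"Friedewald equation invalid at TG >= {FRIEDEWALD_TG_LIMIT} mmol/L"
        )
    out = tc - hdl - tg / 2.2
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# LD and genotypes

def simulate_ld_matrix(
    blocks: list[tuple[int, float]],
    variant_ids: list[str] | None = None,
) -> LDMatrix:
    """Block-diagonal compound-symmetric LD: constant r within blocks,
    zero across.  Requires |r| < 1 so each block is positive definite."""
    sizes = [int(s) for s, _ in blocks]
    if any(s < 1 for s in sizes):
        raise SimulationError("block sizes must be >= 1")
    if any(abs(r) >= 1 for _, r in blocks):
        raise SimulationError("|within-block r| must be < 1 for a valid correlation")
    k = sum(sizes)
    ids = variant_ids if variant_ids is not None else [f"v{i+1}" for i in range(k)]
    if len(ids) != k:
        raise SimulationError("variant_ids length must equal total block size")
    mats = []
    off = 0
    for size, r in blocks:
        m = np.full((size, size), float(r))
        np.fill_diagonal(m, 1.0)
        mats.append(LDMatrix(ids[off:off + size], m))
        off += size
    return block_diagonal(mats)


_TETRACHORIC_CACHE: dict[tuple[float, float, float], float] = {}


def _binary_corr(latent_r: float, p1: float, p2: float) -> float:
    """Correlation of threshold indicators under a bivariate normal."""
    h1, h2 = stats.norm.ppf(p1), stats.norm.ppf(p2)
    p11 = stats.multivariate_normal(
        mean=[0.0, 0.0], cov=[[1.0, latent_r], [latent_r, 1.0]]
    ).cdf([h1, h2])
    return (p11 - p1 * p2) / np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))


def _latent_corr(target_r: float, p1: float, p2: float) -> float:
    """Tetrachoric-style calibration: latent Gaussian correlation whose
    thresholded indicators correlate at ``target_r``."""
    if target_r == 0.0:
        return 0.0
    key = (round(target_r, 6), round(p1, 6), round(p2, 6))
    if key not in _TETRACHORIC_CACHE:
        from scipy.optimize import brentq
        lo, hi = (-0.9999, 0.0) if target_r < 0 else (0.0, 0.9999)
        f = lambda r: _binary_corr(r, p1, p2) - target_r
        try:
            _TETRACHORIC_CACHE[key] = brentq(f, lo, hi, xtol=1e-6)
        except ValueError:
            # target unattainable for these frequencies; use the boundary
            _TETRACHORIC_CACHE[key] = hi if target_r > 0 else lo
    return _TETRACHORIC_CACHE[key]


def simulate_genotypes(
    n: int,
    mafs,
    ld: LDMatrix,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Dosages in {0,1,2} from a latent Gaussian-copula threshold model.

    Two independent haplotypes are drawn per individual from a latent
    multivariate normal whose pairwise correlations are calibrated
    (tetrachoric inversion) so that the correlation of the resulting
    allele indicators — and hence of the dosages — matches the target LD
    matrix.
    """
    mafs = np.asarray(mafs, dtype=float)
    k = len(mafs)
    if len(ld) != k:
        raise SimulationError(f"LD dimension {len(ld)} does not match {k} MAFs")
    if np.any((mafs <= 0) | (mafs > 0.5)):
        raise SimulationError("MAFs must lie in (0, 0.5]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    latent = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            if ld.r[i, j] != 0:
                latent[i, j] = latent[j, i] = _latent_corr(ld.r[i, j], mafs[i], mafs[j])
    w, v = np.linalg.eigh(latent)
    w = np.clip(w, 1e-10, None)
    L = v * np.sqrt(w)
    thresh = stats.norm.ppf(mafs)
    h1 = (rng.standard_normal((n, k)) @ L.T) < thresh
    h2 = (rng.standard_normal((n, k)) @ L.T) < thresh
    return (h1.astype(np.int8) + h2.astype(np.int8)).astype(float)


# ---------------------------------------------------------------------------
# variant panels and GWAS arms

_BASES = np.array(list("ACGT"))
_NONPALINDROMIC = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                   ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


def build_variant_panel(cfg: SimConfig) -> pd.DataFrame:
    """Deterministic variant layout for all regions.

    Columns: variant_id, region, chrom, pos, effect_allele, other_allele,
    maf, joint_beta (GWAS-population per-allele effect), in_window,
    is_planted.  Decoy composition per region: inside-window decoys are
    sub-threshold (|z| target uniform on [1, 4.5]); half the outside
    decoys are genuinely significant so the cis-window filter is
    exercised, and a couple of decoys are palindromic with near-0.5
    frequency to exercise strand-ambiguity handling.
    """
    rng = cfg._rng("panel")
    rows = []
    for reg in cfg.regions:
        g = reg.gene
        k = len(reg.mafs)
        pos_causal = np.linspace(g.start + 500, g.end - 500, max(k, 1)).astype(int)[:k]
        for i in range(k):
            ea, oa = _NONPALINDROMIC[int(rng.integers(len(_NONPALINDROMIC)))]
            rows.append(dict(
                variant_id=f"rs{g.name[0]}{1000 + i}", region=g.name, chrom=g.chrom,
                pos=int(pos_causal[i]), effect_allele=ea, other_allele=oa,
                maf=float(reg.mafs[i]), joint_beta=float(reg.true_betas[i]),
                in_window=True, is_planted=True,
            ))
        lo, hi = g.window
        v_region = 2 * np.asarray(reg.mafs) * (1 - np.asarray(reg.mafs)) if k else None
        for i in range(reg.n_null_inside):
            maf = float(rng.uniform(0.05, 0.5))
            z = float(rng.uniform(0.5, 3.0))  # well below genome-wide significance
            beta = z / np.sqrt(cfg.n_gwas * 2 * maf * (1 - maf))
            side = rng.integers(2)
            pos = int(rng.integers(lo, g.start)) if side == 0 else int(rng.integers(g.end + 1, hi + 1))
            palindromic = i < 2
            if palindromic:
                ea, oa = ("A", "T") if rng.integers(2) else ("C", "G")
                maf = float(rng.uniform(0.44, 0.5))
            else:
                ea, oa = _NONPALINDROMIC[int(rng.integers(len(_NONPALINDROMIC)))]
            rows.append(dict(
                variant_id=f"rs{g.name[0]}{2000 + i}", region=g.name, chrom=g.chrom,
                pos=pos, effect_allele=ea, other_allele=oa, maf=maf,
                joint_beta=float(beta * rng.choice([-1, 1])),
                in_window=True, is_planted=False,
            ))
        for i in range(reg.n_null_outside):
            maf = float(rng.uniform(0.05, 0.5))
            strong = i % 2 == 0  # half are significant but outside the window
            z = float(rng.uniform(8.0, 14.0)) if strong else 0.0
            beta = z / np.sqrt(cfg.n_gwas * 2 * maf * (1 - maf))
            offset = int(rng.integers(g.flank + 1_000, g.flank + 500_000))
            pos = g.start - offset if i % 2 else g.end + offset
            ea, oa = _NONPALINDROMIC[int(rng.integers(len(_NONPALINDROMIC)))]
            rows.append(dict(
                variant_id=f"rs{g.name[0]}{3000 + i}", region=g.name, chrom=g.chrom,
                pos=pos, effect_allele=ea, other_allele=oa, maf=maf,
                joint_beta=float(beta), in_window=False, is_planted=False,
            ))
    return pd.DataFrame(rows)


def region_ld_matrix(cfg: SimConfig, panel: pd.DataFrame, region_name: str) -> LDMatrix:
    """LD over one region's panel: configured blocks over planted
    variants, decoys uncorrelated."""
    sub = panel[panel["region"] == region_name]
    reg = next(r for r in cfg.regions if r.gene.name == region_name)
    planted_ids = list(sub.loc[sub["is_planted"], "variant_id"])
    decoy_ids = list(sub.loc[~sub["is_planted"], "variant_id"])
    mats = []
    if planted_ids:
        mats.append(simulate_ld_matrix(list(reg.ld_blocks), planted_ids))
    if decoy_ids:
        mats.append(LDMatrix(decoy_ids, np.eye(len(decoy_ids))))
    return block_diagonal(mats)


def study_ld(cfg: SimConfig, panel: pd.DataFrame) -> dict[str, LDMatrix]:
    return {r.gene.name: region_ld_matrix(cfg, panel, r.gene.name) for r in cfg.regions}


def _marginal_betas(panel_region: pd.DataFrame, ld: LDMatrix) -> np.ndarray:
    """Joint -> marginal per-allele effects through the LD projection:
    b_marg_j = sum_k r_jk b_k sqrt(v_k / v_j)."""
    order = list(panel_region["variant_id"])
    R = ld.subset(order).r
    v = 2 * panel_region["maf"].to_numpy() * (1 - panel_region["maf"].to_numpy())
    b = panel_region["joint_beta"].to_numpy()
    return (R @ (b * np.sqrt(v))) / np.sqrt(v)


def simulate_summary_gwas(
    cfg: SimConfig,
    phenotype: str = "ldl",
    panel: pd.DataFrame | None = None,
    ld: dict[str, LDMatrix] | None = None,
) -> pd.DataFrame:
    """Per-variant marginal GWAS table in canonical summary-stat form.

    For the exposure ("ldl"): marginal betas from the LD projection of
    the joint effects, se = 1/sqrt(n·2f(1−f)) on the SD scale.  For the
    binary outcome ("cad"): per-allele log-odds theta_CAD × marginal LDL
    beta, with se implied by case/control counts and allele frequency.
    Sampling noise is drawn jointly across variants with correlation
    equal to the LD matrix, as for estimates from one sample.
    """
    if phenotype not in ("ldl", "cad"):
        raise SimulationError("phenotype must be 'ldl' or 'cad'")
    panel = build_variant_panel(cfg) if panel is None else panel
    ld = study_ld(cfg, panel) if ld is None else ld
    rng = cfg._rng("gwas_ldl" if phenotype == "ldl" else "gwas_cad")
    frames = []
    for reg in cfg.regions:
        sub = panel[panel["region"] == reg.gene.name].reset_index(drop=True)
        if sub.empty:
            continue
        rld = ld[reg.gene.name].subset(list(sub["variant_id"]))
        v = 2 * sub["maf"].to_numpy() * (1 - sub["maf"].to_numpy())
        b_marg = _marginal_betas(sub, rld)
        if phenotype == "ldl":
            se = 1.0 / np.sqrt(cfg.n_gwas * v)
            n_col = cfg.n_gwas
        else:
            n_total = cfg.cad_n_cases + cfg.cad_n_controls
            k_frac = cfg.cad_n_cases / n_total
            b_marg = cfg.theta_cad * b_marg
            se = 1.0 / np.sqrt(n_total * k_frac * (1 - k_frac) * v)
            n_col = n_total
        w, vec = np.linalg.eigh(rld.r)
        L = vec * np.sqrt(np.clip(w, 1e-12, None))
        noise = se * (L @ rng.standard_normal(len(sub)))
        beta_hat = b_marg + noise
        z = np.abs(beta_hat) / se
        pval = np.clip(2 * stats.norm.sf(z), 1e-320, 1.0)
        frames.append(pd.DataFrame(dict(
            variant_id=sub["variant_id"], chrom=sub["chrom"], pos=sub["pos"],
            effect_allele=sub["effect_allele"], other_allele=sub["other_allele"],
            eaf=sub["maf"], beta=beta_hat, se=se, pvalue=pval, n=n_col,
        )))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# cohort

@dataclass
class CohortTable:
    """Individual-level follow-up table plus its variant manifest.

    ``data`` columns: id, age, sex, pc1..pc6, on_med, ldl (observed
    mmol/L), ldl_std (medication-corrected, standardized), baseline
    (always-observed auxiliary), responded, g_<variant_id> dosages, and
    one column per outcome (NaN where unobserved).  ``variants`` records,
    per dosage column, which allele the stored dosage counts.
    """

    data: pd.DataFrame
    variants: pd.DataFrame
    outcome_names: list[str]
    panel_map: dict[str, str]

    def __len__(self) -> int:
        return len(self.data)

    @property
    def dosage_columns(self) -> list[str]:
        return ["g_" + v for v in self.variants["variant_id"]]

    def write(self, data_path, manifest_path, outcome_manifest_path=None) -> None:
        self.data.to_csv(data_path, index=False, float_format="%.8g")
        self.variants.to_csv(manifest_path, index=False)
        if outcome_manifest_path is not None:
            pd.DataFrame({
                "outcome": self.outcome_names,
                "panel": [self.panel_map[o] for o in self.outcome_names],
            }).to_csv(outcome_manifest_path, sep="\t", index=False)


def write_vcf_dosages(cohort: "CohortTable", path) -> None:
    """Export cohort dosages as an uncompressed VCF with a DS FORMAT field.

    The ALT allele is the manifest's counted allele (the one the stored
    dosage counts), so DS round-trips exactly.
    """
    data = cohort.data
    samples = [f"S{int(i)}" for i in data["id"]]
    man = cohort.variants.sort_values(["chrom", "pos"], kind="mergesort")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of the ALT allele">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for _, row in man.iterrows():
            ds = data["g_" + row["variant_id"]].to_numpy(dtype=float)
            fields = [str(row["chrom"]), str(int(row["pos"])), row["variant_id"],
                      row["other_allele"], row["counted_allele"], ".", "PASS", ".", "DS"]
            fh.write("\t".join(fields) + "\t" + "\t".join(f"{d:g}" for d in ds) + "\n")


def read_vcf_dosages(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read DS dosages from a VCF written by :func:`write_vcf_dosages`.

    Returns (dosage frame with ``g_<id>`` columns, variant manifest with
    the counted/other alleles).  Uses pysam's VCF reader.
    """
    import pysam

    vcf = pysam.VariantFile(path)
    cols: dict[str, np.ndarray] = {}
    rows = []
    for rec in vcf:
        ds = np.array([s["DS"] for s in rec.samples.values()], dtype=float)
        cols["g_" + rec.id] = ds
        rows.append(dict(variant_id=rec.id, chrom=rec.chrom, pos=rec.pos,
                         counted_allele=rec.alts[0], other_allele=rec.ref))
    return pd.DataFrame(cols), pd.DataFrame(rows)


def simulate_cohort(
    cfg: SimConfig,
    panel: pd.DataFrame | None = None,
    ld: dict[str, LDMatrix] | None = None,
) -> CohortTable:
    """Generate the adolescent cohort.

    LDL-C is built as the genetic load (region-scaled joint betas) plus
    small age/sex effects and noise on the SD scale, mapped to mmol/L;
    the observed value is multiplied by 0.7 for medicated individuals and
    ``ldl_std`` is re-standardized after the /0.7 correction.  Each
    outcome is theta × latent SD-LDL plus a structured residual (shared
    latent factor + pair factors).  Participation follows a logistic
    model on the configured predictors; non-responders have all outcomes
    missing, and responders additionally lose a small MCAR fraction of
    items.
    """
    panel = build_variant_panel(cfg) if panel is None else panel
    ld = study_ld(cfg, panel) if ld is None else ld
    n = cfg.n_cohort
    g_rng = cfg._rng("genotypes")
    cov_rng = cfg._rng("covariates")
    ldl_rng = cfg._rng("ldl")
    out_rng = cfg._rng("outcomes")
    mis_rng = cfg._rng("missing")
    med_rng = cfg._rng("medication")

    dosage_blocks, manifest_rows = [], []
    scale = {}
    for reg in cfg.regions:
        sub = panel[panel["region"] == reg.gene.name].reset_index(drop=True)
        if sub.empty:
            continue
        rld = ld[reg.gene.name].subset(list(sub["variant_id"]))
        dos = simulate_genotypes(n, sub["maf"].to_numpy(), rld, g_rng)
        # randomly choose which allele the cohort's dosage file counts,
        # so harmonization against the external frame is exercised
        flip = g_rng.random(len(sub)) < 0.5
        stored = np.where(flip, 2.0 - dos, dos)
        for j, row in sub.iterrows():
            counted = row["other_allele"] if flip[j] else row["effect_allele"]
            other = row["effect_allele"] if flip[j] else row["other_allele"]
            manifest_rows.append(dict(
                variant_id=row["variant_id"], chrom=row["chrom"], pos=row["pos"],
                counted_allele=counted, other_allele=other,
                maf=row["maf"], region=row["region"],
            ))
        dosage_blocks.append((sub, dos, stored))
        scale[reg.gene.name] = reg.cohort_beta_scale

    age = cov_rng.normal(cfg.mean_age, cfg.sd_age, n)
    sex = (cov_rng.random(n) < cfg.male_fraction).astype(int)
    pcs = cov_rng.standard_normal((n, 6))

    genetic = np.zeros(n)
    for sub, dos, _ in dosage_blocks:
        b = sub["joint_beta"].to_numpy() * scale[sub["region"].iloc[0]]
        centered = dos - 2 * sub["maf"].to_numpy()
        genetic += centered @ b
    age_c = age - cfg.mean_age
    lin = genetic + 0.02 * age_c + 0.05 * sex
    resid_var = max(1.0 - np.var(lin), 0.1)
    ldl_latent = lin + np.sqrt(resid_var) * ldl_rng.standard_normal(n)
    ldl_true_mmol = cfg.ldl_mean_mmol + cfg.ldl_sd_mmol * ldl_latent
    ldl_true_mmol = np.clip(ldl_true_mmol, 0.3, None)
    on_med = med_rng.random(n) < cfg.med_fraction
    ldl_obs = np.where(on_med, ldl_true_mmol * MEDICATION_FACTOR, ldl_true_mmol)
    ldl_corr = apply_medication_correction(ldl_obs, on_med)
    ldl_std = (ldl_corr - ldl_corr.mean()) / ldl_corr.std(ddof=1)

    u = out_rng.standard_normal(n)
    baseline = u + 0.5 * out_rng.standard_normal(n)
    pair_ids = sorted({o.pair for o in cfg.outcomes if o.pair is not None})
    pair_factors = {p: out_rng.standard_normal(n) for p in pair_ids}
    outcomes = {}
    for o in cfg.outcomes:
        lam = o.u_loading
        if o.pair is not None:
            c2 = max(o.pair_r - lam**2, 0.0)
            c = np.sqrt(c2)
            d = np.sqrt(max(1.0 - lam**2 - c2, 1e-4))
            f = pair_factors[o.pair]
        else:
            c, f, d = 0.0, 0.0, np.sqrt(1.0 - lam**2)
        resid = lam * u + c * f + d * out_rng.standard_normal(n)
        sd_resid = np.sqrt(max(1.0 - o.theta**2, 1e-6))
        outcomes[o.name] = o.theta * ldl_latent + sd_resid * resid

    predictors = {
        "intercept": np.ones(n), "age_c": age_c, "sex": sex.astype(float),
        "baseline": baseline, "ldl_std": ldl_std,
        "pc1": pcs[:, 0],
    }
    eta = np.zeros(n)
    for name, coef in cfg.missing_model_coefs.items():
        if name not in predictors:
            raise SimulationError(f"unknown response-model predictor {name!r}")
        eta += coef * predictors[name]
    p_respond = 1.0 / (1.0 + np.exp(-eta))
    responded = (mis_rng.random(n) < p_respond).astype(int)

    columns = {
        "id": np.arange(1, n + 1),
        "age": age, "sex": sex,
        **{f"pc{i+1}": pcs[:, i] for i in range(6)},
        "on_med": on_med.astype(int),
        "ldl": ldl_obs, "ldl_std": ldl_std, "baseline": baseline,
        "responded": responded,
    }
    for sub, _, stored in dosage_blocks:
        for j, vid in enumerate(sub["variant_id"]):
            columns["g_" + vid] = stored[:, j]
    miss_resp = responded == 0
    for o in cfg.outcomes:
        vals = outcomes[o.name].copy()
        vals[miss_resp] = np.nan
        item = (~miss_resp) & (mis_rng.random(n) < cfg.item_missing_rate)
        vals[item] = np.nan
        columns[o.name] = vals
    data = pd.DataFrame(columns)
    return CohortTable(
        data=data,
        variants=pd.DataFrame(manifest_rows),
        outcome_names=[o.name for o in cfg.outcomes],
        panel_map={o.name: o.panel for o in cfg.outcomes},
    )


@dataclass
class SyntheticStudy:
    """Bundle of all generated inputs plus the generating truth."""

    config: SimConfig
    panel: pd.DataFrame
    ld: dict[str, LDMatrix]
    gwas_ldl: pd.DataFrame
    gwas_cad: pd.DataFrame
    cohort: CohortTable


def simulate_study(cfg: SimConfig) -> SyntheticStudy:
    """Generate every pipeline input from one configuration."""
    panel = build_variant_panel(cfg)
    ld = study_ld(cfg, panel)
    return SyntheticStudy(
        config=cfg,
        panel=panel,
        ld=ld,
        gwas_ldl=simulate_summary_gwas(cfg, "ldl", panel, ld),
        gwas_cad=simulate_summary_gwas(cfg, "cad", panel, ld),
        cohort=simulate_cohort(cfg, panel, ld),
    )


def config_to_yaml(cfg: SimConfig) -> str:
    """Serialize a configuration as a structured key-value document."""
    import yaml

    d = asdict(cfg)
    for i, reg in enumerate(cfg.regions):
        d["regions"][i]["gene"] = asdict(reg.gene)
    return yaml.safe_dump(d, sort_keys=False)


def config_from_yaml(text: str) -> SimConfig:
    import yaml

    d = yaml.safe_load(text)
    regions = []
    for r in d.pop("regions", []):
        g = r.pop("gene")
        r["mafs"] = tuple(r.get("mafs", ()))
        r["true_betas"] = tuple(r.get("true_betas", ()))
        r["ld_blocks"] = tuple((int(s), float(x)) for s, x in r.get("ld_blocks", ()))
        regions.append(RegionSpec(gene=GeneRegion(**g), **r))
    outcomes = [OutcomeSpec(**o) for o in d.pop("outcomes", [])]
    return SimConfig(regions=regions, outcomes=outcomes, **d)
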