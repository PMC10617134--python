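"""Cis-instrument selection: window/significance filter, clumping against
an independent oracle, cohort validation, strength, and orientation."""

import numpy as np
import pandas as pd
import pytest

import targetmr as tmr
from targetmr.instruments import (
    GeneRegion, InstrumentSelectionError, InstrumentSet, clump,
    f_statistic, orient_weights, select_index_variant,
    select_region_variants, validate_in_cohort, build_instrument_set,
)
from targetmr.ld import LDMatrix
from targetmr.pipeline import PipelineConfig, select_for_target
from .conftest import make_records

REGION = GeneRegion("HMGCR", "5", 74_632_154, 74_657_929)


class TestRegionFilter:
    def test_window_boundary_is_inclusive(self):
        recs = make_records([{"pos": REGION.start - 100_000, "pvalue": 1e-10, "beta": 0.064}])
        assert len(select_region_variants(recs, REGION)) == 1

    def test_one_bp_outside_is_excluded(self):
        recs = make_records([{"pos": REGION.start - 100_001, "pvalue": 1e-10, "beta": 0.064}])
        assert len(select_region_variants(recs, REGION)) == 0

    def test_threshold_is_strict(self):
        recs = make_records([{"pvalue": 5e-8, "beta": 0.0545},
                             {"pvalue": 4.9e-8, "beta": 0.0546}])
        out = select_region_variants(recs, REGION)
        assert list(out["variant_id"]) == ["rs2"]

    def test_empty_result_is_not_an_error(self):
        recs = make_records([{"pvalue": 0.5, "beta": 0.005}])
        assert select_region_variants(recs, REGION).empty


def _clump_oracle(records, ld, r2_max, window_bp):
    """Reference greedy clumping written independently: repeatedly pick
    the smallest-p remaining variant, discard conflicting neighbours."""
    df = records.copy().reset_index(drop=True)
    alive = set(df.index)
    kept = []
    order = df.sort_values(["pvalue", "pos", "variant_id"]).index
    for i in order:
        if i not in alive:
            continue
        kept.append(i)
        alive.discard(i)
        for j in list(alive):
            close = abs(df.loc[j, "pos"] - df.loc[i, "pos"]) <= window_bp
            if close and ld.r2(df.loc[i, "variant_id"], df.loc[j, "variant_id"]) >= r2_max:
                alive.discard(j)
    return sorted(df.loc[kept, "variant_id"])


class TestClumping:
    def _ld(self, ids, r):
        return LDMatrix(ids, r)

    def test_greedy_example(self):
        recs = make_records([
            {"pvalue": 1e-20, "beta": 0.17, "se": 0.0184, "pos": 74_640_000},
            {"pvalue": 1e-10, "beta": 0.12, "se": 0.0184, "pos": 74_641_000},
            {"pvalue": 1e-9, "beta": 0.11, "se": 0.0182, "pos": 74_642_000},
        ])
        r = np.array([[1, np.sqrt(0.5), np.sqrt(0.1)],
                      [np.sqrt(0.5), 1, np.sqrt(0.1)],
                      [np.sqrt(0.1), np.sqrt(0.1), 1.0]])
        out = clump(recs, self._ld(["rs1", "rs2", "rs3"], r))
        assert sorted(out["variant_id"]) == ["rs1", "rs3"]

    def test_uncorrelated_all_retained(self):
        recs = make_records([{"pos": 74_640_000 + i * 1000, "beta": 0.1 + 0.01 * i}
                             for i in range(4)])
        out = clump(recs, self._ld(list(recs["variant_id"]), np.eye(4)))
        assert len(out) == 4

    def test_absent_variant_raises_naming_it(self):
        recs = make_records([{}])
        with pytest.raises(InstrumentSelectionError, match="rs1"):
            clump(recs, self._ld(["other"], np.eye(1)))

    @pytest.mark.parametrize("trial", range(12))
    def test_matches_exhaustive_oracle_on_small_instances(self, trial):
        rng = np.random.default_rng(100 + trial)
        k = int(rng.integers(2, 9))
        pos = np.sort(rng.integers(74_540_000, 74_750_000, size=k))
        recs = make_records([
            {"pos": int(pos[i]), "beta": float(rng.uniform(0.06, 0.2)),
             "se": 0.01} for i in range(k)
        ])
        a = rng.standard_normal((k, k + 3))
        c = a @ a.T
        d = np.sqrt(np.diag(c))
        r = c / np.outer(d, d)
        ld = self._ld(list(recs["variant_id"]), r)
        got = sorted(clump(recs, ld, 0.3, 10)["variant_id"])  # 10 kb window
        want = _clump_oracle(recs, ld, 0.3, 10_000)
        assert got == want
        # retained set is pairwise r² < 0.3 whenever within the window
        kept = clump(recs, ld, 0.3, 10)
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                if abs(kept.loc[i, "pos"] - kept.loc[j, "pos"]) <= 10_000:
                    assert ld.r2(kept.loc[i, "variant_id"], kept.loc[j, "variant_id"]) < 0.3


class TestCohortValidation:
    def _pairs(self, rows):
        df = make_records([{k: v for k, v in r.items() if not k.startswith("internal")}
                           for r in rows])
        for col in ("internal_beta", "internal_pvalue"):
            df[col] = [r[col] for r in rows]
        return df

    def test_replicating_variant_retained(self):
        pairs = self._pairs([{"beta": 0.1, "internal_beta": 0.2, "internal_pvalue": 0.049}])
        assert len(validate_in_cohort(pairs)) == 1

    def test_non_replicating_dropped(self):
        pairs = self._pairs([{"beta": 0.1, "internal_beta": 0.2, "internal_pvalue": 0.2}])
        assert len(validate_in_cohort(pairs)) == 0

    def test_sign_discordant_dropped_unless_disabled(self):
        pairs = self._pairs([{"beta": 0.1, "internal_beta": -0.2, "internal_pvalue": 0.01}])
        assert len(validate_in_cohort(pairs)) == 0
        assert len(validate_in_cohort(pairs, require_direction=False)) == 1


class TestFStatistic:
    def test_arithmetic(self):
        assert f_statistic(0.1, 0.02) == pytest.approx(25.0)
        assert f_statistic(0.0, 0.5) == 0.0

    def test_rejects_bad_se(self):
        with pytest.raises(InstrumentSelectionError):
            f_statistic(0.1, 0.0)

    def test_emulated_glgc_range(self):
        # five variants with |z| spanning 6.2-16.3 give F between 38 and 266
        z = np.array([6.2, 9.0, 12.0, 14.5, 16.3])
        se = np.full(5, 0.004)
        f = f_statistic(z * se, se)
        assert f.min() >= 38 and f.max() <= 266


class TestIndexVariantAndOrientation:
    def _iset(self, rows, counted=None):
        v = make_records(rows)
        ld = LDMatrix(list(v["variant_id"]), np.eye(len(v)))
        return InstrumentSet(REGION, v, ld)

    def test_smallest_p_selected(self):
        iset = orient_weights(self._iset([{"pvalue": 1e-20, "beta": 0.17, "se": 0.0184},
                                          {"pvalue": 1e-9, "beta": 0.11, "se": 0.0182}]))
        assert select_index_variant(iset).variant_ids == ["rs1"]

    def test_singleton_is_identity(self):
        iset = orient_weights(self._iset([{"beta": 0.15, "se": 0.01}]))
        assert select_index_variant(iset).variant_ids == iset.variant_ids

    def test_p_tie_broken_by_position(self):
        iset = orient_weights(self._iset([
            {"pvalue": 1e-12, "beta": 0.14, "se": 0.02, "pos": 74_650_000},
            {"pvalue": 1e-12, "beta": 0.14, "se": 0.02, "pos": 74_640_000},
        ]))
        assert select_index_variant(iset).variants.iloc[0]["pos"] == 74_640_000

    def test_empty_set_raises(self):
        empty = InstrumentSet(REGION, make_records([]), LDMatrix([], np.empty((0, 0))))
        with pytest.raises(InstrumentSelectionError):
            select_index_variant(empty)

    def test_positive_beta_counts_other_allele(self):
        iset = orient_weights(self._iset([{"beta": 0.05, "effect_allele": "A",
                                           "other_allele": "G", "se": 0.009}]))
        row = iset.variants.iloc[0]
        assert row["counted_allele"] == "G" and row["weight"] == pytest.approx(0.05)

    def test_negative_beta_counts_effect_allele(self):
        iset = orient_weights(self._iset([{"beta": -0.05, "effect_allele": "A",
                                           "other_allele": "G", "se": 0.009}]))
        row = iset.variants.iloc[0]
        assert row["counted_allele"] == "A" and row["weight"] == pytest.approx(0.05)

    def test_zero_beta_rejected(self):
        with pytest.raises(InstrumentSelectionError):
            orient_weights(self._iset([{"beta": 0.0, "se": 0.01, "pvalue": 1.0}]))


class TestEndToEndSelection:
    def test_selection_log_partitions_input(self, fixture_study):
        region = fixture_study.config.regions[0].gene
        iset, _ = select_for_target(fixture_study, region, PipelineConfig())
        log = iset.selection_log
        # every harmonized variant appears exactly once with a verdict
        assert log["variant_id"].is_unique
        assert log["selected"].sum() == len(iset)

    def test_planted_set_recovered_exactly(self, fixture_study):
        region = fixture_study.config.regions[0].gene
        iset, _ = select_for_target(fixture_study, region, PipelineConfig())
        planted = sorted(
            fixture_study.panel.loc[fixture_study.panel["is_planted"], "variant_id"]
        )
        assert sorted(iset.variant_ids) == planted

    def test_recovery_rate_across_seeds(self):
        from targetmr.synthetic import simulate_study
        hits = 0
        n_seeds = 25
        for seed in range(n_seeds):
            study = simulate_study(tmr.selection_fixture_config(seed=300 + seed, n_outcomes=2))
            region = study.config.regions[0].gene
            iset, _ = select_for_target(study, region, PipelineConfig())
            planted = sorted(study.panel.loc[study.panel["is_planted"], "variant_id"])
            hits += sorted(iset.variant_ids) == planted
        assert hits >= int(0.95 * n_seeds)

    def test_clumped_output_pairwise_r2_below_threshold(self, fixture_study):
        region = fixture_study.config.regions[0].gene
        iset, _ = select_for_target(fixture_study, region, PipelineConfig())
        ids = iset.variant_ids
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                assert iset.ld.r2(ids[i], ids[j]) < 0.3

    def test_grs_orientation_gives_negative_ldl_slope(self, fixture_study):
        from targetmr import build_grs, fit_covariate_adjusted
        region = fixture_study.config.regions[0].gene
        iset, _ = select_for_target(fixture_study, region, PipelineConfig())
        co = fixture_study.cohort
        score = build_grs(co, iset)
        fit = fit_covariate_adjusted(co.data["ldl_std"], score,
                                     co.data[["age", "sex", "pc1"]])
        assert fit.beta < 0 and fit.pvalue < 1e-10
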