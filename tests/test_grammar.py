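"""Grammar statistics against hand computations and enumeration oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epimpra.design import LibraryDesign, build_class1, build_class2, build_snv_library
from epimpra.grammar import (
    bh_adjust,
    fit_pairwise_synergy,
    fit_variant_effects,
    homotypic_trend,
    order_anova,
    positional_enrichment,
    spearman_test,
)
from epimpra.simulate import EffectConfig, simulate_activities, simulate_design_truth


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.037])[0] == pytest.approx(0.037)

    def test_hand_step_up_example(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_one(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_nan_propagates_without_affecting_ranks(self):
        adj = bh_adjust([0.01, np.nan, 0.02])
        assert np.isnan(adj[1])
        assert np.allclose(adj[[0, 2]], bh_adjust([0.01, 0.02]))

    def test_monotone_and_at_least_p(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=30)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestSpearmanTest:
    def test_exact_p_matches_enumeration_oracle_on_six_points(self):
        x = np.array([1.0, 1.0, 2.0, 2.0, 4.0, 4.0])
        y = np.array([0.3, 0.1, 0.5, 0.2, 0.9, 0.4])
        rho, p = spearman_test(x, y)
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        rho_obs = np.corrcoef(rx, ry)[0, 1]
        null = [
            np.corrcoef(rx, perm)[0, 1] for perm in itertools.permutations(ry)
        ]
        p_oracle = np.mean([abs(r) >= abs(rho_obs) - 1e-12 for r in null])
        assert rho == pytest.approx(rho_obs)
        assert p == pytest.approx(p_oracle)

    def test_constant_input_gives_nan(self):
        rho, p = spearman_test([1, 2, 3], [5, 5, 5])
        assert math.isnan(rho) and math.isnan(p)

    def test_large_n_uses_asymptotic_and_matches_scipy(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        rho, p = spearman_test(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


class TestHomotypicTrend:
    def test_strictly_increasing_gives_rho_one(self, pair_design):
        truth = simulate_design_truth(
            pair_design, EffectConfig(motif_effects={"CEBPA": 0.5}), assays=("mpra",)
        )
        act = simulate_activities(truth, noise_sd=0.0, n_replicates=2, seed=0)
        # y is tied exactly where x is tied, so the rank vectors coincide
        out = homotypic_trend(act, pair_design)
        row = out[(out.motif == "CEBPA") & (out.assay == "mpra")].iloc[0]
        assert row.spearman_rho == pytest.approx(1.0)

    def test_constant_activity_flagged_na(self, pair_design):
        truth = simulate_design_truth(pair_design, EffectConfig(), assays=("mpra",))
        act = simulate_activities(truth, noise_sd=0.0, n_replicates=2, seed=0)
        out = homotypic_trend(act, pair_design)
        assert (out.flag == "constant_activity").all()
        assert out.spearman_rho.isna().all()

    def test_adjustment_within_assay_family(self, pair_design):
        rng = np.random.default_rng(5)
        truth = simulate_design_truth(pair_design, EffectConfig(), assays=("mpra", "atac"))
        act = simulate_activities(truth, noise_sd=0.3, n_replicates=3, seed=5)
        out = homotypic_trend(act, pair_design)
        for _assay, grp in out.groupby("assay"):
            assert np.allclose(
                grp.adj_p.to_numpy(), bh_adjust(grp.p_value.to_numpy()), equal_nan=True
            )


class TestPairwiseSynergy:
    def test_noise_free_additive_model_recovers_coefficients(self, pair_design):
        cfg = EffectConfig(motif_effects={"CEBPA": 0.5, "PPARA": 0.3})
        truth = simulate_design_truth(pair_design, cfg, assays=("mpra",))
        act = simulate_activities(truth, noise_sd=0.0, n_replicates=1, seed=0)
        out = fit_pairwise_synergy(act, pair_design)
        row = out[(out.tf1 == "CEBPA") & (out.tf2 == "PPARA")].iloc[0]
        assert row.coef_count_tf1 == pytest.approx(0.5, abs=1e-9)
        assert row.coef_count_tf2 == pytest.approx(0.3, abs=1e-9)
        assert row.coef_k == pytest.approx(0.0, abs=1e-9)
        assert row.p_k == pytest.approx(1.0)
        assert row.direction == "none"

    def test_noise_free_planted_synergy_recovered_exactly(self, pair_design):
        cfg = EffectConfig(
            motif_effects={"CEBPA": 0.5, "PPARA": 0.3}, synergy={("CEBPA", "PPARA"): 0.4}
        )
        truth = simulate_design_truth(pair_design, cfg, assays=("mpra",))
        act = simulate_activities(truth, noise_sd=0.0, n_replicates=1, seed=0)
        out = fit_pairwise_synergy(act, pair_design)
        row = out[(out.tf1 == "CEBPA") & (out.tf2 == "PPARA")].iloc[0]
        assert row.coef_k == pytest.approx(0.4, abs=1e-9)
        assert row.direction == "synergy"

    def test_missing_class2_rows_flagged_rank_deficient(self, motifs8, templates):
        design = LibraryDesign(
            elements=build_class1(motifs8[:2], templates),
            motif_set=motifs8[:2],
            templates=templates,
        )
        truth = simulate_design_truth(design, EffectConfig(), assays=("mpra",))
        act = simulate_activities(truth, noise_sd=0.1, n_replicates=2, seed=0)
        out = fit_pairwise_synergy(act, design)
        assert (out.flag == "rank_deficient").all()
        assert out.coef_k.isna().all()


class TestOrderAnova:
    def test_planted_permutation_shift_detected(self, quad_design):
        truth = simulate_design_truth(quad_design, EffectConfig(), assays=("mpra",))
        target = ("CEBPA", "CTCF", "FOXA1", "HNF1A")
        shifted = [
            e.id
            for e in quad_design.by_class("class3")
            if tuple(n for n, _c, _s in sorted(e.motif_layout, key=lambda t: t[2])) == target
        ]
        truth.truth.loc[shifted, "mpra"] += 2.0
        act = simulate_activities(truth, noise_sd=0.2, n_replicates=3, seed=1)
        out = order_anova(act, quad_design)
        row = out[out.combination == "CEBPA+CTCF+FOXA1+HNF1A"].iloc[0]
        assert row.adj_p < 0.01
        assert row.delta_max_min == pytest.approx(2.0, abs=0.5)

    def test_degenerate_constant_flagged(self, quad_design):
        truth = simulate_design_truth(quad_design, EffectConfig(), assays=("mpra",))
        act = simulate_activities(truth, noise_sd=0.0, n_replicates=2, seed=0)
        out = order_anova(act, quad_design)
        assert (out.flag == "degenerate_constant").all()

    def test_too_few_groups_flagged(self, quad_design):
        truth = simulate_design_truth(quad_design, EffectConfig(), assays=("mpra",))
        act = simulate_activities(truth, noise_sd=0.1, n_replicates=2, seed=0)
        keep_orders = [
            e.id
            for e in quad_design.by_class("class3")
            if e.motif_layout[0][0] == "CEBPA"  # CEBPA in slot 1 only: 6 of 24 orders
        ][:2]
        act = act[act.element_id.isin(keep_orders)]
        out = order_anova(act, quad_design)
        assert (out.flag == "too_few_groups").all()


class TestPositionalEnrichment:
    def _toy_design(self, motif_set, templates):
        from epimpra.design import build_class3

        return LibraryDesign(
            elements=build_class3(motif_set[:4], templates[:1]),
            motif_set=motif_set[:4],
            templates=templates[:1],
        )

    def test_p_matches_exhaustive_enumeration(self, motif_set, templates):
        # population of 12 elements, draw 4; oracle enumerates all C(12,4) draws
        design = self._toy_design(motif_set, templates)
        ids = [e.id for e in design.by_class("class3")][:12]
        design = LibraryDesign(
            elements=[e for e in design.elements if e.id in ids],
            motif_set=design.motif_set,
            templates=design.templates,
        )
        activity = pd.Series(np.linspace(1, 0, 12), index=ids)
        out = positional_enrichment(activity, design, n_extreme=4)
        slot_sets = {
            e.id: {(n, s) for n, _c, s in e.motif_layout} for e in design.elements
        }
        for row in out.itertuples():
            K = sum((row.motif, row.slot) in slot_sets[i] for i in ids)
            members = set(activity.sort_values(ascending=False).index[:4] if row.group == "top"
                          else activity.sort_values(ascending=False).index[-4:])
            k = sum((row.motif, row.slot) in slot_sets[i] for i in members)
            total = hits = 0
            flags = [(row.motif, row.slot) in slot_sets[i] for i in ids]
            for combo in itertools.combinations(range(12), 4):
                total += 1
                drawn = sum(flags[i] for i in combo)
                if row.direction == "enriched":
                    hits += drawn >= k
                else:
                    hits += drawn <= k
            assert row.p_value == pytest.approx(hits / total, abs=1e-12)

    def test_equal_frequency_gives_unit_odds_ratio(self, motif_set, templates):
        design = self._toy_design(motif_set, templates)
        ids = [e.id for e in design.by_class("class3")]
        activity = pd.Series(np.arange(len(ids), dtype=float), index=ids)
        out = positional_enrichment(activity, design, n_extreme=len(ids) // 3)
        # every motif occupies each slot in exactly 1/4 of all permutations,
        # but the extremes are arbitrary here; just verify the OR identity rows
        ones = out[(out.k / out.n - out.K / out.N).abs() < 1e-12]
        assert (ones.odds_ratio - 1.0).abs().max() < 1e-9 if len(ones) else True

    def test_boundary_odds_ratio_capped_with_flag(self, motif_set, templates):
        design = self._toy_design(motif_set, templates)
        # rank so that CEBPA-at-slot-1 elements occupy the entire top set
        ids = [e.id for e in design.by_class("class3")]
        slot1 = [e.id for e in design.elements if e.motif_layout[0][0] == "CEBPA"]
        scores = pd.Series(0.0, index=ids)
        scores[slot1] = 1.0
        n_top = len(slot1)
        out = positional_enrichment(scores, design, n_extreme=n_top)
        row = out[(out.motif == "CEBPA") & (out.slot == 1) & (out.group == "top")].iloc[0]
        assert np.isinf(row.odds_ratio) and row.flag == "boundary"

    def test_n_extreme_larger_than_population_raises(self, motif_set, templates):
        design = self._toy_design(motif_set, templates)
        ids = [e.id for e in design.by_class("class3")]
        activity = pd.Series(np.arange(len(ids), dtype=float), index=ids)
        with pytest.raises(ValueError, match="exceeds"):
            positional_enrichment(activity, design, n_extreme=len(ids) + 1)


class TestVariantEffects:
    def _counts(self, elements, values, assays=("atac", "inserted"), samples=("r1", "r2")):
        rows = []
        for sample in samples:
            for assay in assays:
                for e in elements:
                    rows.append(
                        {
                            "element_id": e.id,
                            "sample": sample,
                            "assay": assay,
                            "count": values(e, sample, assay),
                        }
                    )
        return pd.DataFrame(rows)

    def test_variants_identical_to_wild_type_give_zero_coefficients(self):
        elements = build_snv_library("c", "ACGTACGTAC")
        counts = self._counts(elements, lambda e, s, a: 100)
        out = fit_variant_effects(counts, elements, enriched_assay="atac")
        assert np.allclose(out.coef, 0.0, atol=1e-9)
        assert not out.significant.any()

    def test_enriched_equal_inserted_gives_unit_slope(self):
        elements = build_snv_library("c", "ACGTACGTAC")
        rng = np.random.default_rng(1)
        per_element = {
            (e.id, s): int(rng.integers(20, 400)) for e in elements for s in ("r1", "r2")
        }
        counts = self._counts(elements, lambda e, s, a: per_element[(e.id, s)])
        out = fit_variant_effects(counts, elements, enriched_assay="atac")
        assert out.attrs["inserted_slope"] == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(out.coef, 0.0, atol=1e-9)

    def test_absent_variant_omitted_and_logged(self):
        elements = build_snv_library("c", "ACGTACGTAC")
        dropped = elements[5].id
        counts = self._counts(elements, lambda e, s, a: 100)
        counts = counts[counts.element_id != dropped]
        out = fit_variant_effects(counts, elements, enriched_assay="atac")
        assert dropped in out.attrs["omitted"]
        assert dropped not in set(out.variant_id)
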