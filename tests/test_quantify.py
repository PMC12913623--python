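"""UMI counting, CPM/TMM normalization, and activity computation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epimpra.quantify import (
    NormalizationError,
    combine_replicates,
    cpm_normalize,
    dedup_umis,
    epigenetic_activity,
    filter_mpra_elements,
    mpra_activity,
    quantify_epigenetic,
    tmm_factor,
    tmm_trimmed_mean,
)


def _tags(records):
    return pd.DataFrame(records, columns=["element_id", "umi", "sample", "assay"])


class TestDedupUmis:
    def test_duplicate_umis_collapse_to_one(self):
        tags = _tags([("e1", "AAAA", "r1", "rna")] * 3)
        counts = dedup_umis(tags)
        assert counts["count"].tolist() == [1]

    def test_empty_table_gives_empty_counts(self):
        assert dedup_umis(_tags([])).empty

    @settings(max_examples=20, deadline=None)
    @given(st.lists(
        st.tuples(
            st.sampled_from(["e1", "e2", "e3"]),
            st.text(alphabet="ACGT", min_size=2, max_size=2),
            st.sampled_from(["r1", "r2"]),
            st.sampled_from(["rna", "inserted"]),
        ),
        min_size=1,
        max_size=200,
    ))
    def test_matches_set_cardinality_oracle(self, records):
        counts = dedup_umis(_tags(records))
        oracle = {}
        for element, umi, sample, assay in records:
            oracle.setdefault((element, sample, assay), set()).add(umi)
        got = {
            (r.element_id, r.sample, r.assay): r.count for r in counts.itertuples()
        }
        assert got == {k: len(v) for k, v in oracle.items()}


class TestCpmNormalize:
    def _counts(self, values):
        return pd.DataFrame(
            {
                "element_id": [f"e{i}" for i in range(len(values))],
                "sample": "r1",
                "assay": "atac",
                "count": values,
            }
        )

    def test_sums_to_one_million_per_library(self):
        cpm = cpm_normalize(self._counts([10, 20, 70]))
        assert cpm["cpm"].sum() == pytest.approx(1e6)

    def test_scale_invariance(self):
        a = cpm_normalize(self._counts([3, 5, 9]))["cpm"]
        b = cpm_normalize(self._counts([6, 10, 18]))["cpm"]
        assert np.allclose(a, b)

    def test_matches_sum_oracle_on_random_table(self):
        rng = np.random.default_rng(0)
        values = rng.integers(0, 1000, size=50)
        cpm = cpm_normalize(self._counts(values))["cpm"].to_numpy()
        assert np.allclose(cpm, values / values.sum() * 1e6)

    def test_zero_library_size_raises(self):
        with pytest.raises(NormalizationError, match="zero library"):
            cpm_normalize(self._counts([0, 0]))


class TestTmmFactor:
    def _series(self, values, prefix="neg"):
        return pd.Series(values, index=[f"{prefix}{i}" for i in range(len(values))])

    def test_equal_counts_give_unit_factor(self):
        e = self._series([10.0] * 20)
        assert tmm_factor(e, e, e.index) == pytest.approx(1.0)

    def test_uniform_doubling_gives_factor_two(self):
        i = self._series(np.linspace(10, 100, 20))
        assert tmm_factor(2 * i, i, i.index) == pytest.approx(2.0)

    def test_planted_outliers_are_trimmed(self):
        rng = np.random.default_rng(1)
        inserted = self._series(rng.uniform(50, 150, size=40))
        enriched = inserted * 2.0
        enriched.iloc[:4] *= 50.0  # 10% wild outliers
        f = tmm_factor(enriched, inserted, inserted.index)
        assert abs(np.log2(f) - 1.0) < np.log2(1.05)

    def test_too_few_negatives_raises(self):
        e = self._series([10.0] * 5)
        with pytest.raises(NormalizationError, match="negative controls"):
            tmm_factor(e, e, e.index)

    def test_anchoring_zeroes_trimmed_mean_exactly(self):
        rng = np.random.default_rng(2)
        inserted = self._series(rng.uniform(20, 300, size=60))
        enriched = inserted * rng.lognormal(0.7, 0.4, size=60)
        f = tmm_factor(enriched, inserted, inserted.index)
        residual = tmm_trimmed_mean(enriched / f, inserted, inserted.index)
        assert abs(residual) < 1e-9


class TestEpigeneticActivity:
    def test_equal_counts_give_zero_log2(self):
        e = pd.Series({"a": 10.0, "b": 20.0})
        out = epigenetic_activity(e, e, f=1.0)
        assert np.allclose(out["log2_activity"], 0.0)

    def test_fourfold_enriched_with_factor_two_gives_one(self):
        i = pd.Series({"a": 5.0})
        out = epigenetic_activity(4 * i, i, f=2.0)
        assert out["log2_activity"].iloc[0] == pytest.approx(1.0)

    def test_low_inserted_flagged_and_nan(self):
        e = pd.Series({"a": 10.0, "b": 10.0})
        raw = pd.Series({"a": 100, "b": 2})
        out = epigenetic_activity(e, e, raw_inserted=raw, min_inserted=5)
        assert out.loc["b", "qc_flag"] == "low_inserted"
        assert np.isnan(out.loc["b", "log2_activity"])
        assert out.loc["a", "qc_flag"] == ""


class TestCombineReplicates:
    def test_identical_replicates_equal_single(self):
        rows = pd.DataFrame(
            {
                "element_id": ["a", "a"],
                "sample": ["r1", "r2"],
                "enriched": [40.0, 40.0],
                "inserted": [10.0, 10.0],
            }
        )
        out = combine_replicates(rows)
        assert out.loc["a", "log2_activity"] == pytest.approx(2.0)

    def test_ratio_of_totals_not_mean_of_ratios(self):
        rows = pd.DataFrame(
            {
                "element_id": ["a"] * 2,
                "sample": ["r1", "r2"],
                "enriched": [10.0, 400.0],
                "inserted": [10.0, 100.0],
            }
        )
        out = combine_replicates(rows)
        # totals: 410/110; mean of ratios would be (1+4)/2
        assert out.loc["a", "log2_activity"] == pytest.approx(np.log2(410 / 110))

    def test_missing_replicate_flagged(self):
        rows = pd.DataFrame(
            {
                "element_id": ["a", "a", "b"],
                "sample": ["r1", "r2", "r1"],
                "enriched": [10.0, 10.0, 8.0],
                "inserted": [10.0, 10.0, 8.0],
            }
        )
        out = combine_replicates(rows)
        assert out.loc["b", "qc_flag"] == "missing_in_replicate"
        assert out.loc["a", "qc_flag"] == ""


class TestMpraFilters:
    def _barcodes(self, rows):
        return pd.DataFrame(
            rows, columns=["element_id", "barcode", "sample", "dna_count", "rna_count"]
        )

    def test_element_below_threshold_excluded(self):
        rows = [("e1", f"b{i}", "r1", 10, 10) for i in range(4)]
        filtered, exclusions = filter_mpra_elements(self._barcodes(rows), min_barcodes=5)
        assert filtered.empty
        assert exclusions[0]["reason"] == "low_barcodes"

    def test_rna_only_barcode_dropped_then_element_excluded(self):
        rows = [("e1", f"b{i}", "r1", 10, 10) for i in range(4)]
        rows.append(("e1", "b4", "r1", 0, 10))  # RNA-only barcode
        filtered, exclusions = filter_mpra_elements(self._barcodes(rows), min_barcodes=5)
        assert filtered.empty and len(exclusions) == 1

    def test_zero_threshold_is_identity_after_presence_filter(self):
        rows = [("e1", "b0", "r1", 3, 7), ("e2", "b1", "r1", 5, 5)]
        filtered, exclusions = filter_mpra_elements(self._barcodes(rows), min_barcodes=0)
        assert len(filtered) == 2 and not exclusions


class TestMpraActivity:
    def test_mean_of_barcode_ratios(self):
        # balancing element keeps DNA and RNA library sizes equal so the
        # CPM scaling cancels and the plain ratio arithmetic is visible
        rows = pd.DataFrame(
            {
                "element_id": ["e1"] * 3 + ["e2"],
                "barcode": ["b1", "b2", "b3", "b4"],
                "sample": "r1",
                "dna_count": [10, 10, 10, 70],
                "rna_count": [10, 20, 40, 30],
            }
        )
        out = mpra_activity(rows)
        e1 = out[out["element_id"] == "e1"].iloc[0]
        assert e1["ratio"] == pytest.approx(7 / 3)
        e2 = out[out["element_id"] == "e2"].iloc[0]
        assert e2["ratio"] == pytest.approx(30 / 70)

    def test_single_barcode_equals_its_ratio(self):
        rows = pd.DataFrame(
            {
                "element_id": ["e1", "e2"],
                "barcode": ["b1", "b2"],
                "sample": "r1",
                "dna_count": [10, 10],
                "rna_count": [30, 10],
            }
        )
        out = mpra_activity(rows).set_index("element_id")
        assert out.loc["e1", "ratio"] / out.loc["e2", "ratio"] == pytest.approx(3.0)

    def test_all_equal_gives_log2_zero_after_anchoring(self):
        negatives = [f"n{i}" for i in range(10)]
        rows = pd.DataFrame(
            {
                "element_id": np.repeat(negatives, 3),
                "barcode": [f"b{i}" for i in range(30)],
                "sample": "r1",
                "dna_count": 10,
                "rna_count": 10,
            }
        )
        out = mpra_activity(rows, negative_ids=negatives)
        assert np.allclose(out["log2_activity"], 0.0, atol=1e-12)


@pytest.fixture(scope="module")
def simulated():
    from epimpra.simulate import GroundTruth, simulate_counts

    ids = [f"el{i}" for i in range(300)] + [f"neg{i}" for i in range(200)]
    rng = np.random.default_rng(11)
    truth = pd.DataFrame(
        {"atac": np.where([i.startswith("neg") for i in ids], 0.0, rng.normal(0.5, 1.5, 500))},
        index=ids,
    )
    gt = GroundTruth(truth=truth, negative_ids=[i for i in ids if i.startswith("neg")])
    counts, _ = simulate_counts(
        gt,
        n_replicates=3,
        seed=12,
        barcode_assay="none",
        enriched_assays=("atac",),
        enriched_depth=200.0,
        dispersion=0.1,
    )
    return gt, counts


class TestPipelineInvariants:
    """End-to-end anchoring and recovery on simulated negative-binomial counts."""

    def test_activity_invariant_to_library_scaling(self, simulated):
        # +1 keeps every count positive so the zero-count pseudocount
        # boundary (documented separately) stays out of the comparison
        gt, counts = simulated
        counts = counts.assign(count=counts["count"] + 1)
        scaled = counts.copy()
        mask = (scaled["sample"] == "rep1") & (scaled["assay"] == "atac")
        scaled.loc[mask, "count"] *= 7
        a = quantify_epigenetic(counts, gt.negative_ids, enriched_assays=("atac",))
        b = quantify_epigenetic(scaled, gt.negative_ids, enriched_assays=("atac",))
        pd.testing.assert_frame_equal(a.combined, b.combined)

    def test_planted_activity_recovery(self, simulated):
        from scipy.stats import spearmanr

        gt, counts = simulated
        res = quantify_epigenetic(counts, gt.negative_ids, enriched_assays=("atac",))
        est = res.activity("atac").dropna()
        planted = [i for i in est.index if not i.startswith("neg")]
        rho = spearmanr(gt.truth["atac"][planted], est[planted]).statistic
        assert rho >= 0.9
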