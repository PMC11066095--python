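"""Wild-type normalization, filtering, batch adjustment, and summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_fm
from mavelayers.containers import FrequencyMatrix
from mavelayers.preprocess import (
    batch_adjust,
    detection_mask,
    filter_variants,
    normalize_to_wildtype,
    summarize_replicates,
    to_cpm,
)


class TestNormalizeToWildtype:
    @pytest.mark.parametrize(
        "count, wt, expected",
        [(0, 0, 1.0), (4, 9, 4.5 / 9.5), (99, 199, 99.5 / 199.5)],
    )
    def test_pseudocount_formula(self, count, wt, expected):
        counts = pd.DataFrame({"s1": [count]}, index=["c1.AAA>AAC"])
        wt_counts = pd.DataFrame({"s1": [wt]}, index=pd.Index([1], name="position"))
        positions = pd.Series({"c1.AAA>AAC": 1})
        fm = normalize_to_wildtype(counts, wt_counts, positions)
        assert fm.data.iloc[0, 0] == pytest.approx(expected, abs=1e-12)
        assert fm.transform == "raw_freq"

    def test_missing_wildtype_position_rejected(self):
        counts = pd.DataFrame({"s1": [3]}, index=["c2.AAA>AAC"])
        wt_counts = pd.DataFrame({"s1": [7]}, index=pd.Index([1], name="position"))
        with pytest.raises(KeyError, match="position"):
            normalize_to_wildtype(counts, wt_counts, pd.Series({"c2.AAA>AAC": 2}))

    @given(count=st.integers(100, 10_000), wt=st.integers(100, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_scale_covariance(self, count, wt):
        """Doubling both counts changes the frequency only at O(1/count)."""
        f1 = (count + 0.5) / (wt + 0.5)
        f2 = (2 * count + 0.5) / (2 * wt + 0.5)
        assert abs(f2 - f1) / f1 < 2.0 / min(count, wt)


class TestFilterVariants:
    def _sheet(self):
        return pd.DataFrame(
            {
                "sample_id": ["gDNA_1", "gDNA_2", "totalRNA_1"],
                "readout": ["gDNA", "gDNA", "totalRNA"],
                "bio_rep": [1, 2, 1],
                "tech_rep": [1, 1, 1],
                "batch": ["B1", "B1", "B1"],
            }
        )

    def test_absolute_floor_and_negctrl_rules(self):
        fm = make_fm(
            [
                [1e-6, 1e-6, 1e-6],  # fails the 10**-5.8 floor
                [2e-4, 2e-4, 2e-4],  # below its negative-control frequency
                [3e-4, 3e-4, 3e-4],  # equal to negctrl: retained (strict <)
                [1e-3, 1e-3, 1e-3],  # clean
            ],
            columns=["gDNA_1", "gDNA_2", "totalRNA_1"],
        )
        negctrl = pd.Series([1e-7, 3e-4, 3e-4, 1e-5], index=fm.data.index)
        kept, log = filter_variants(fm, negctrl, self._sheet())
        assert list(kept.data.index) == ["v2", "v3"]
        rules = log.set_index("variant_id")["rule"]
        assert rules["v0"] == "min_frequency"
        assert rules["v1"] == "below_negctrl"

    def test_each_removal_has_exactly_one_rule(self):
        fm = make_fm([[1e-6, 1e-6, 1e-6]], columns=["gDNA_1", "gDNA_2", "totalRNA_1"])
        negctrl = pd.Series([1e-3], index=fm.data.index)  # would also fire
        _, log = filter_variants(fm, negctrl, self._sheet())
        assert len(log) == 1
        assert log.iloc[0]["rule"] == "min_frequency"

    def test_flagged_exclusion_column(self):
        """A boolean exclusion column removes variants ahead of other rules."""
        fm = make_fm(
            [[1e-3, 1e-3, 1e-3], [1e-3, 1e-3, 1e-3]],
            columns=["gDNA_1", "gDNA_2", "totalRNA_1"],
        )
        negctrl = pd.Series([1e-5, 1e-5], index=fm.data.index)
        excluded = pd.Series([True, False], index=fm.data.index)
        kept, log = filter_variants(fm, negctrl, self._sheet(), excluded=excluded)
        assert list(kept.data.index) == ["v1"]
        assert log.iloc[0]["rule"] == "flagged_exclusion"

    def test_empty_result_allowed_with_warning(self, caplog):
        fm = make_fm([[1e-9, 1e-9, 1e-9]], columns=["gDNA_1", "gDNA_2", "totalRNA_1"])
        negctrl = pd.Series([1e-12], index=fm.data.index)
        with caplog.at_level("WARNING"):
            kept, _ = filter_variants(fm, negctrl, self._sheet())
        assert len(kept.data) == 0
        assert any("removed every variant" in m for m in caplog.messages)


class TestBatchAdjust:
    def _fm(self, values, columns):
        return make_fm(values, columns=columns, transform="ln_freq")

    def test_single_batch_identity(self):
        fm = self._fm([[1.0, 2.0, 3.0]], ["a", "b", "c"])
        batches = pd.Series({"a": "B1", "b": "B1", "c": "B1"})
        out = batch_adjust(fm, batches)
        pd.testing.assert_frame_equal(out.data, fm.data)

    def test_constant_offset_removed_exactly(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(20, 4))
        delta = rng.normal(size=(20, 1)) * 2.0
        values = np.hstack([base, base + delta])
        cols = [f"s{i}" for i in range(8)]
        batches = pd.Series(["B1"] * 4 + ["B2"] * 4, index=cols)
        out = batch_adjust(self._fm(values, cols), batches)
        b1 = out.data[cols[:4]].mean(axis=1)
        b2 = out.data[cols[4:]].mean(axis=1)
        assert np.allclose(b1, b2, atol=1e-12)

    def test_constant_variant_unchanged(self):
        values = np.full((1, 4), 3.7)
        cols = list("abcd")
        batches = pd.Series(["B1", "B1", "B2", "B2"], index=cols)
        out = batch_adjust(self._fm(values, cols), batches)
        assert np.allclose(out.data.values, 3.7)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=(10, 6))
        cols = [f"s{i}" for i in range(6)]
        batches = pd.Series(["B1", "B1", "B2", "B2", "B2", "B2"], index=cols)
        once = batch_adjust(self._fm(values, cols), batches)
        twice = batch_adjust(once, batches)
        pd.testing.assert_frame_equal(once.data, twice.data)

    def test_group_preserving_design_keeps_group_difference(self):
        """Group means survive adjustment when the model matrix is used."""
        cols = [f"s{i}" for i in range(8)]
        groups = pd.Series(["gDNA"] * 4 + ["totalRNA"] * 4, index=cols)
        batches = pd.Series(["B1", "B2"] * 4, index=cols)
        rng = np.random.default_rng(2)
        base = rng.normal(size=(10, 8))
        base[:, 4:] += 1.5  # real group effect
        base[:, batches.to_numpy() == "B2"] += 0.7  # batch effect
        out = batch_adjust(self._fm(base, cols), batches, preserve_groups=groups)
        gap = out.data[cols[4:]].mean(axis=1) - out.data[cols[:4]].mean(axis=1)
        assert np.allclose(gap - gap.mean(), gap - gap.mean())  # finite
        assert gap.mean() == pytest.approx(1.5, abs=0.5)
        resid = out.data.to_numpy() - np.column_stack(
            [out.data[cols[:4]].mean(axis=1)] * 4 + [out.data[cols[4:]].mean(axis=1)] * 4
        )
        b1 = resid[:, batches.to_numpy() == "B1"].mean(axis=1)
        b2 = resid[:, batches.to_numpy() == "B2"].mean(axis=1)
        assert np.allclose(b1, b2, atol=1e-12)

    def test_confounded_groups_rejected(self):
        cols = list("abcd")
        groups = pd.Series(["g1", "g1", "g2", "g2"], index=cols)
        batches = pd.Series(["B1", "B1", "B2", "B2"], index=cols)
        with pytest.raises(ValueError, match="confounded"):
            batch_adjust(self._fm(np.zeros((2, 4)), cols), batches, preserve_groups=groups)


class TestSummarizeReplicates:
    def _sheet(self, n_tech):
        rows = []
        for tech in range(1, n_tech + 1):
            rows.append(
                {
                    "sample_id": f"gDNA_b1_t{tech}",
                    "readout": "gDNA",
                    "bio_rep": 1,
                    "tech_rep": tech,
                    "batch": "B1",
                }
            )
        return pd.DataFrame(rows)

    def test_odd_median(self):
        fm = make_fm([[1.0, 2.0, 9.0]], columns=[f"gDNA_b1_t{t}" for t in (1, 2, 3)])
        out, out_sheet = summarize_replicates(fm, self._sheet(3), "technical")
        assert out.data.iloc[0, 0] == 2.0
        assert list(out.data.columns) == ["gDNA_b1"]
        assert list(out_sheet["readout"]) == ["gDNA"]

    def test_even_median_is_mean_of_central_pair(self):
        fm = make_fm([[1.0, 4.0]], columns=["gDNA_b1_t1", "gDNA_b1_t2"])
        out, _ = summarize_replicates(fm, self._sheet(2), "technical")
        assert out.data.iloc[0, 0] == 2.5

    def test_single_replicate_passthrough(self):
        fm = make_fm([[7.0]], columns=["gDNA_b1_t1"])
        out, _ = summarize_replicates(fm, self._sheet(1), "technical")
        assert out.data.iloc[0, 0] == 7.0

    def test_biological_level_keys_by_readout(self, small_sheet):
        fm = make_fm(np.arange(8.0)[None, :], columns=small_sheet["sample_id"])
        bio, bio_sheet = summarize_replicates(fm, small_sheet, "technical")
        layer, _ = summarize_replicates(bio, bio_sheet, "biological")
        assert sorted(layer.data.columns) == ["gDNA", "totalRNA"]


class TestToCpm:
    def test_closure_example(self):
        fm = make_fm(np.array([[1.0], [1.0], [2.0]]), columns=["s"])
        out = to_cpm(fm)
        assert list(out.data["s"]) == [250_000, 250_000, 500_000]

    def test_idempotent(self):
        fm = make_fm(np.array([[1.0], [3.0]]), columns=["s"])
        once = to_cpm(fm)
        twice = to_cpm(once)
        pd.testing.assert_frame_equal(once.data, twice.data)
        assert twice.data["s"].sum() == pytest.approx(1e6, abs=1e-6)

    def test_zero_column_rejected(self):
        fm = make_fm(np.array([[0.0], [0.0]]), columns=["s"])
        with pytest.raises(ValueError, match="all-zero"):
            to_cpm(fm)


class TestDetectionMask:
    def _fm_and_sheet(self, values):
        sheet = pd.DataFrame(
            {
                "sample_id": ["gDNA_b1", "gDNA_b2", "totalRNA_b1", "totalRNA_b2"],
                "readout": ["gDNA", "gDNA", "totalRNA", "totalRNA"],
                "bio_rep": [1, 2, 1, 2],
                "tech_rep": [1, 1, 1, 1],
                "batch": ["B1"] * 4,
            }
        )
        return make_fm(values, columns=sheet["sample_id"], transform="ln_freq"), sheet

    def test_kept_dropped_boundaries(self):
        fm, sheet = self._fm_and_sheet(
            [
                [-9.0, -9.0, -9.0, -9.0],  # kept
                [-10.0, -9.0, -9.0, -9.0],  # exactly -10: dropped (strict >)
                [-9.0, -9.0, -9.0, -20.0],  # undetected in one replicate: dropped
            ]
        )
        kept = detection_mask(fm, sheet, readouts=["gDNA", "totalRNA"])
        assert list(kept) == ["v0"]

    def test_readout_without_samples_rejected(self):
        fm, sheet = self._fm_and_sheet([[-9.0] * 4])
        with pytest.raises(ValueError, match="polysome_F4"):
            detection_mask(fm, sheet, readouts=["polysome_F4"])
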