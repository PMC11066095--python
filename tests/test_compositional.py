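"""Compositional effect-size engine: Monte-Carlo instances, CLR/IQLR,
effects, Welch/BH, and the comparison driver."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_fm
from helpers import brute_force_effect
from mavelayers.compositional import (
    benjamini_hochberg,
    clr_transform,
    dirichlet_instances,
    effect_size,
    fold_change_point_estimate,
    iqlr_features,
    run_comparison,
    welch_bh,
)
from mavelayers.containers import FrequencyMatrix


def _variances_to_clr(variances):
    """CLR array (V, 3, 1) whose per-variant sample variance equals ``variances``."""
    clr = np.zeros((len(variances), 3, 1))
    for i, v in enumerate(variances):
        x = np.sqrt(v)
        clr[i, :, 0] = [0.0, x, -x]
    return clr


class TestDirichletInstances:
    def test_point_mode_is_map_composition(self):
        counts = pd.DataFrame({"s": [3, 1]})
        point = dirichlet_instances(counts, 0, seed=0)
        assert point.shape == (2, 1, 1)
        np.testing.assert_allclose(point[:, 0, 0], [3.5 / 5.0, 1.5 / 5.0])

    def test_zero_counts_expectation_uniform(self):
        counts = pd.DataFrame({"s": [0, 0, 0, 0]})
        draws = dirichlet_instances(counts, 4000, seed=1)
        np.testing.assert_allclose(draws.mean(axis=2)[:, 0], 0.25, atol=0.02)

    def test_concentration_with_count_magnitude(self):
        """Single draws converge to the closed count vector as counts grow."""
        target = np.array([0.5, 0.3, 0.2])
        tv = []
        for scale in (1e2, 1e4, 1e6):
            counts = pd.DataFrame({"s": (target * scale).astype(int)})
            draw = dirichlet_instances(counts, 1, seed=2)[:, 0, 0]
            tv.append(0.5 * np.abs(draw - target).sum())
        assert tv[2] < tv[1] < tv[0]

    def test_seed_reproducibility_and_validation(self):
        counts = pd.DataFrame({"s": [5, 2]})
        a = dirichlet_instances(counts, 8, seed=3)
        b = dirichlet_instances(counts, 8, seed=3)
        np.testing.assert_array_equal(a, b)
        with pytest.raises(ValueError):
            dirichlet_instances(counts, -1, seed=0)


class TestClrTransform:
    def test_uniform_composition_is_zero(self):
        p = np.full((4, 1, 1), 0.25)
        np.testing.assert_allclose(clr_transform(p), 0.0, atol=1e-15)

    def test_geometric_mean_denominator(self):
        p = np.array([2.0, 4.0, 8.0])[:, None, None] / 14.0
        np.testing.assert_allclose(
            clr_transform(p)[:, 0, 0], [-np.log(2), 0.0, np.log(2)], atol=1e-12
        )

    def test_single_feature_denominator(self):
        p = np.array([2.0, 4.0, 8.0])[:, None, None] / 14.0
        np.testing.assert_allclose(
            clr_transform(p, [1])[:, 0, 0], [np.log(0.5), 0.0, np.log(2.0)], atol=1e-12
        )

    def test_rows_sum_to_zero_with_full_denominator(self):
        rng = np.random.default_rng(0)
        p = rng.dirichlet(np.ones(30), size=(5, 7)).transpose(2, 0, 1)
        clr = clr_transform(p)
        np.testing.assert_allclose(clr.sum(axis=0), 0.0, atol=1e-10)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            clr_transform(np.array([[[0.0]], [[1.0]]]))


class TestIqlrFeatures:
    def test_interpolated_quartiles_ten_features(self):
        clr = _variances_to_clr(range(10))  # variances 0..9, Q1=2.25, Q3=6.75
        np.testing.assert_array_equal(iqlr_features(clr), [3, 4, 5, 6])

    def test_interpolated_quartiles_four_features(self):
        clr = _variances_to_clr(range(4))  # Q1=0.75, Q3=2.25
        np.testing.assert_array_equal(iqlr_features(clr), [1, 2])

    def test_tied_variances_return_all(self):
        clr = _variances_to_clr([2.0] * 6)
        np.testing.assert_array_equal(iqlr_features(clr), np.arange(6))

    def test_too_few_features_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            iqlr_features(_variances_to_clr([1.0, 2.0]))


class TestEffectSize:
    def test_identical_groups_zero(self):
        g = np.arange(8.0).reshape(1, 8, 1)
        out = effect_size(g, g.copy())
        assert out["diff_btw"][0] == 0.0
        assert out["effect"][0] == 0.0

    def test_hand_enumerated_example(self):
        a = np.array([0.0, 1.0]).reshape(1, 2, 1)
        b = np.array([2.0, 4.0]).reshape(1, 2, 1)
        out = effect_size(a, b)
        assert out["diff_btw"][0] == 2.5
        assert out["diff_win"][0] == 2.0
        assert out["effect"][0] == 1.25

    def test_antisymmetry_under_group_swap(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(6, 4, 5))
        b = rng.normal(size=(6, 4, 5))
        fwd = effect_size(a, b)
        rev = effect_size(b, a)
        np.testing.assert_allclose(fwd["effect"], -rev["effect"], atol=1e-12)
        np.testing.assert_allclose(fwd["diff_btw"], -rev["diff_btw"], atol=1e-12)

    def test_matches_brute_force_enumeration(self):
        """Point-mode effects equal the independent all-pairs oracle to 1e-12."""
        rng = np.random.default_rng(7)
        for _ in range(25):
            n_var = rng.integers(1, 7)
            a = rng.normal(size=(n_var, 4, 1))
            b = rng.normal(size=(n_var, 4, 1))
            out = effect_size(a, b)
            for v in range(n_var):
                diff_btw, diff_win, effect = brute_force_effect(a[v, :, 0], b[v, :, 0])
                assert out["diff_btw"][v] == pytest.approx(diff_btw, abs=1e-12)
                assert out["diff_win"][v] == pytest.approx(diff_win, abs=1e-12)
                assert out["effect"][v] == pytest.approx(effect, abs=1e-12)

    def test_ci_brackets_effect(self):
        rng = np.random.default_rng(11)
        a = rng.normal(size=(10, 4, 64))
        b = rng.normal(0.5, 1.0, size=(10, 4, 64))
        out = effect_size(a, b)
        assert (out["ci_low"] <= out["effect"] + 1e-12).all()
        assert (out["effect"] <= out["ci_high"] + 1e-12).all()

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            effect_size(np.zeros((1, 1, 1)), np.zeros((1, 2, 1)))


class TestWelchBh:
    def test_identical_zero_variance_groups_give_p_one(self):
        g = np.ones((3, 4, 1))
        p, fdr = welch_bh(g, g.copy())
        np.testing.assert_allclose(p, 1.0)
        np.testing.assert_allclose(fdr, 1.0)

    def test_bh_step_up_example(self):
        np.testing.assert_allclose(
            benjamini_hochberg(np.array([0.01, 0.02, 0.03, 0.04])), [0.04] * 4
        )

    def test_bh_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        p = rng.uniform(size=200)
        expected = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(benjamini_hochberg(p), expected, atol=1e-12)

    def test_adding_null_variant_never_lowers_other_fdrs(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=20)
        base = benjamini_hochberg(p)
        extended = benjamini_hochberg(np.append(p, 0.999))[:-1]
        assert (extended >= base - 1e-12).all()

    def test_fdr_at_least_p(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=(50, 4, 16))
        b = rng.normal(size=(50, 4, 16))
        p, fdr = welch_bh(a, b)
        assert (fdr >= p - 1e-12).all()


class TestScaleInvariance:
    def test_point_mode_invariant_to_sample_rescaling(self):
        """Rescaling one raw-frequency column and reclosing to CPM leaves
        point-mode CLR, effects, and p-values unchanged."""
        from mavelayers.preprocess import to_cpm

        rng = np.random.default_rng(9)
        values = rng.lognormal(size=(30, 8))
        cols = [f"s{i}" for i in range(8)]
        base = to_cpm(make_fm(values, columns=cols))
        scaled_values = values.copy()
        scaled_values[:, 3] *= 37.5
        scaled = to_cpm(make_fm(scaled_values, columns=cols))

        def chain(cpm):
            inst = dirichlet_instances(cpm.data, 0, seed=0)
            clr = clr_transform(inst, iqlr_features(clr_transform(inst)))
            eff = effect_size(clr[:, :4, :], clr[:, 4:, :])
            p, fdr = welch_bh(clr[:, :4, :], clr[:, 4:, :])
            return clr, eff["effect"], p

        clr_a, eff_a, p_a = chain(base)
        clr_b, eff_b, p_b = chain(scaled)
        np.testing.assert_allclose(clr_a, clr_b, atol=1e-10)
        np.testing.assert_allclose(eff_a, eff_b, atol=1e-10)
        np.testing.assert_allclose(p_a, p_b, atol=1e-10)


def _ln_fm_and_sheet(rng, n_var=200, effect_ids=(), fold=1.0):
    """Technical-replicate-level ln frequencies for a 2-readout design."""
    rows, cols = [], []
    for readout in ("gDNA", "totalRNA"):
        for bio in range(1, 5):
            for tech in (1, 2):
                cols.append(f"{readout}_b{bio}_t{tech}")
                rows.append((readout, bio, tech))
    sheet = pd.DataFrame(
        {
            "sample_id": cols,
            "readout": [r for r, _, _ in rows],
            "bio_rep": [b for _, b, _ in rows],
            "tech_rep": [t for _, _, t in rows],
            "batch": "B1",
        }
    )
    base = rng.normal(-7.0, 0.3, size=(n_var, 1))
    values = base + rng.normal(0, 0.15, size=(n_var, len(cols)))
    is_rna = np.array([r == "totalRNA" for r, _, _ in rows])
    for vid in effect_ids:
        values[vid, is_rna] += np.log(fold)
    fm = make_fm(values, columns=cols, transform="ln_freq")
    return fm, sheet


class TestRunComparison:
    def test_global_null_fdr_controlled(self):
        fm, sheet = _ln_fm_and_sheet(np.random.default_rng(12))
        table = run_comparison(fm, sheet, ("totalRNA", "gDNA"), n_instances=16, seed=1).table
        frac = (table["fdr"] < 0.05).mean()
        # under the null the discovery fraction stays within binomial error of 5%
        margin = 3 * np.sqrt(0.05 * 0.95 / len(table))
        assert frac <= 0.05 + margin

    def test_programmed_effects_detected_with_negative_sign(self):
        rng = np.random.default_rng(13)
        fm, sheet = _ln_fm_and_sheet(rng, effect_ids=range(20), fold=0.25)
        table = run_comparison(fm, sheet, ("totalRNA", "gDNA"), n_instances=16, seed=2).table
        hits = table.iloc[:20]
        assert (hits["effect"] < 0).all()
        assert (hits["fdr"] < 0.1).mean() >= 0.9

    def test_low_protein_flip_negates_effects(self):
        rng = np.random.default_rng(14)
        fm, sheet = _ln_fm_and_sheet(rng)
        sheet = sheet.assign(readout=sheet["readout"].map({"gDNA": "gDNA", "totalRNA": "flow_P3"}))
        fm.data.columns = sheet["sample_id"] = [
            c.replace("totalRNA", "flow_P3") for c in fm.data.columns
        ]
        flipped = run_comparison(fm, sheet, ("flow_P3", "gDNA"), n_instances=0, seed=3).table
        plain = run_comparison(
            fm, sheet, ("flow_P3", "gDNA"), n_instances=0, seed=3, flip_low_protein=False
        ).table
        np.testing.assert_allclose(flipped["effect"], -plain["effect"], atol=1e-12)
        np.testing.assert_allclose(flipped["ci_low"], -plain["ci_high"], atol=1e-12)

    def test_undetected_variant_absent_from_output(self):
        rng = np.random.default_rng(15)
        fm, sheet = _ln_fm_and_sheet(rng)
        fm.data.iloc[0, :] = -30.0  # below the detection mask everywhere
        table = run_comparison(fm, sheet, ("totalRNA", "gDNA"), n_instances=0, seed=4).table
        assert "v0" not in set(table["variant_id"])
        assert len(table) == len(fm.data) - 1


class TestFoldChange:
    def test_identical_groups_give_fold_one(self):
        fm = make_fm(np.full((3, 4), -7.0), columns=list("abcd"), transform="ln_freq")
        folds = fold_change_point_estimate(fm, ["a", "b"], ["c", "d"])
        np.testing.assert_allclose(folds, 1.0)

    def test_ln2_difference_gives_fold_two(self):
        values = np.array([[np.log(2), np.log(2), 0.0, 0.0]])
        fm = make_fm(values, columns=list("abcd"), transform="ln_freq")
        folds = fold_change_point_estimate(fm, ["a", "b"], ["c", "d"])
        assert folds.iloc[0] == pytest.approx(2.0, abs=1e-12)

    def test_empty_group_rejected(self):
        fm = make_fm(np.zeros((1, 2)), columns=list("ab"), transform="ln_freq")
        with pytest.raises(ValueError):
            fold_change_point_estimate(fm, [], ["a"])


class TestCiConstruction:
    def test_interval_holds_central_three_quarters_of_instance_effects(self):
        """The reported interval is the central 75% of per-instance effects."""
        rng = np.random.default_rng(16)
        counts = pd.DataFrame(
            rng.integers(50, 500, size=(12, 8)).astype(float),
            columns=[f"s{i}" for i in range(8)],
        )
        inst = dirichlet_instances(counts, 256, seed=1)
        clr = clr_transform(inst)
        out = effect_size(clr[:, :4, :], clr[:, 4:, :])
        inside = (out["effects_per_instance"] >= out["ci_low"][:, None]) & (
            out["effects_per_instance"] <= out["ci_high"][:, None]
        )
        np.testing.assert_allclose(inside.mean(axis=1), 0.75, atol=0.02)

    def test_interval_covers_the_map_point_effect(self):
        """The MC interval contains the MAP (point-mode) effect across seeds."""
        rng = np.random.default_rng(17)
        counts = pd.DataFrame(
            rng.integers(100, 400, size=(10, 8)).astype(float),
            columns=[f"s{i}" for i in range(8)],
        )
        point = clr_transform(dirichlet_instances(counts, 0, seed=0))
        ref = effect_size(point[:, :4, :], point[:, 4:, :])["effect"]
        covered = []
        for seed in range(30):
            clr = clr_transform(dirichlet_instances(counts, 64, seed=seed))
            out = effect_size(clr[:, :4, :], clr[:, 4:, :])
            covered.append((out["ci_low"] <= ref) & (ref <= out["ci_high"]))
        assert np.mean(covered) >= 0.9
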