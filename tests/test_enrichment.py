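"""Group comparison: fold change, tests, z-scores, modes, classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fluxscape.enrichment import (
    compare_groups,
    fold_change,
    group_fluxes,
    test_reaction,
    z_score,
)

from oracles import exact_ks_pvalue

finite = st.floats(-1e6, 1e6, allow_nan=False)


class TestFoldChange:
    def test_equal_means_give_zero(self):
        assert fold_change(1.0, 1.0) == 0.0

    def test_direct_substitution(self):
        assert fold_change(3.0, 1.0) == pytest.approx(0.5)

    def test_sign_discordant_pair_saturates(self):
        assert fold_change(1.0, -1.0) == pytest.approx(1.0)

    def test_both_zero_is_zero(self):
        assert fold_change(0.0, 0.0) == 0.0

    @given(finite, finite)
    @settings(derandomize=True, max_examples=300)
    def test_antisymmetric_and_bounded(self, a, b):
        fc = fold_change(a, b)
        assert -1.0 <= fc <= 1.0
        assert fc == pytest.approx(-fold_change(b, a), abs=1e-12)


class TestTwoSampleTests:
    def test_identical_lists_give_p_one(self):
        v = [1.0, 2.0, 3.0]
        assert test_reaction(v, v, test="ks") == pytest.approx(1.0)

    def test_disjoint_supports_give_tiny_p(self):
        rng = np.random.default_rng(0)
        v1 = rng.uniform(0, 1, 20)
        v2 = rng.uniform(5, 6, 20)
        assert test_reaction(v1, v2, test="ks") < 1e-8

    def test_constant_equal_lists_convention(self):
        assert test_reaction([2.0, 2.0], [2.0, 2.0], test="mannwhitney") == 1.0

    def test_ks_matches_exact_lattice_count(self):
        """Seeded 15-point lists: p equals the exact small-sample KS value."""
        rng = np.random.default_rng(321)
        for _ in range(5):
            v1 = rng.normal(0.0, 1.0, 15)
            v2 = rng.normal(0.4, 1.2, 15)
            assert test_reaction(v1, v2, test="ks") == pytest.approx(
                exact_ks_pvalue(v1, v2), rel=1e-9)

    def test_unknown_test_rejected(self):
        with pytest.raises(ValueError, match="unknown test"):
            test_reaction([1, 2], [3, 4], test="anova")


class TestZScore:
    def test_identical_lists_give_zero(self):
        assert z_score([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_closed_form_unit_case(self):
        # mean gap s, var1 = var2 = s^2, n = 2 each -> z = 1
        s = 3.0
        v1 = [s / 2 - s * np.sqrt(2) / 2 + s, s / 2 + s * np.sqrt(2) / 2 + s]
        v2 = [s / 2 - s * np.sqrt(2) / 2, s / 2 + s * np.sqrt(2) / 2]
        assert z_score(v1, v2) == pytest.approx(1.0)

    def test_matches_textbook_formula_on_random_lists(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            v1 = rng.normal(2, 1.5, rng.integers(3, 30))
            v2 = rng.normal(0, 0.5, rng.integers(3, 30))
            m1, m2 = np.mean(v1), np.mean(v2)
            s1 = np.sum((v1 - m1) ** 2) / (len(v1) - 1)
            s2 = np.sum((v2 - m2) ** 2) / (len(v2) - 1)
            expected = (m1 - m2) / np.sqrt(s1 / len(v1) + s2 / len(v2))
            assert z_score(v1, v2) == pytest.approx(expected, rel=1e-12)

    def test_both_variances_zero_with_gap_is_undefined(self):
        assert np.isnan(z_score([1.0, 1.0], [2.0, 2.0]))


def _toy_groups(seed=0, shift=0.0, n=12, reactions=("R1", "R2")):
    rng = np.random.default_rng(seed)
    mk = lambda mu: pd.DataFrame(
        {r: rng.normal(mu, 1.0, n) for r in reactions},
        index=[f"s{mu}_{i}" for i in range(n)],
    )
    return {"A": mk(0.0 + shift), "B": mk(0.0)}


class TestCompareGroups:
    def test_pair_mode_emits_all_pairs(self):
        groups = {**_toy_groups(), "C": _toy_groups(seed=5)["B"].rename(
            index=lambda s: "c" + s)}
        labels = [lab for lab, _ in compare_groups(groups, mode="one_vs_one")]
        assert labels == ["A_vs_B", "A_vs_C", "B_vs_C"]

    def test_one_vs_all_pools_other_samples(self):
        groups = _toy_groups()
        results = dict(compare_groups(groups, mode="one_vs_all"))
        assert set(results) == {"A_vs_rest", "B_vs_rest"}
        rec = results["A_vs_rest"].set_index("reaction_id")
        assert rec.loc["R1", "avg2"] == pytest.approx(
            groups["B"]["R1"].mean())

    def test_control_mode_excludes_control_vs_itself(self):
        groups = {**_toy_groups(), "ctrl": _toy_groups(seed=2)["B"].rename(
            index=lambda s: "k" + s)}
        labels = [lab for lab, _ in
                  compare_groups(groups, mode="one_vs_control", control="ctrl")]
        assert labels == ["A_vs_ctrl", "B_vs_ctrl"]

    def test_unknown_control_lists_available_groups(self):
        with pytest.raises(ValueError, match="available.*A"):
            compare_groups(_toy_groups(), mode="one_vs_control", control="zz")

    def test_identical_groups_yield_no_significance(self):
        frame = _toy_groups()["B"]
        groups = {"A": frame, "B": frame.copy()}
        _, table = compare_groups(groups, mode="one_vs_one")[0]
        assert (table["style_class"] == "not_significant").all()
        assert (table["p_value"] == 1.0).all()

    def test_swapping_groups_flips_direction_and_keeps_p(self):
        groups = _toy_groups(shift=3.0)
        _, ab = compare_groups({"A": groups["A"], "B": groups["B"]})[0]
        _, ba = compare_groups({"B": groups["B"], "A": groups["A"]})[0]
        assert np.allclose(ab["p_value"], ba["p_value"])
        assert np.allclose(ab["fold_change"], -ba["fold_change"])
        flip = {"up": "down", "down": "up"}
        for mine, theirs in zip(ab["style_class"], ba["style_class"]):
            if mine in flip:
                assert theirs == flip[mine]

    def test_threshold_monotonicity(self):
        groups = _toy_groups(shift=1.0, seed=3)

        def n_sig(p_thr, fc_thr):
            _, t = compare_groups(groups, p_threshold=p_thr,
                                  fc_threshold=fc_thr)[0]
            return (t["style_class"] != "not_significant").sum()

        assert n_sig(0.2, 1.2) >= n_sig(0.05, 1.2)
        assert n_sig(0.05, 1.05) >= n_sig(0.05, 1.5)

    def test_sign_discordant_pairs_classified_as_flips(self):
        rng = np.random.default_rng(1)
        groups = {
            "A": pd.DataFrame({"R": rng.normal(5, 0.3, 10)}),
            "B": pd.DataFrame({"R": rng.normal(-5, 0.3, 10)}),
        }
        _, table = compare_groups(groups)[0]
        assert table.loc[0, "style_class"] == "sign_flip_up"

    def test_fc_gate_blocks_small_same_sign_differences(self):
        rng = np.random.default_rng(2)
        # tight distributions 10 vs 10.5: significant by KS, < 20% apart
        groups = {
            "A": pd.DataFrame({"R": rng.normal(10.5, 0.01, 30)}),
            "B": pd.DataFrame({"R": rng.normal(10.0, 0.01, 30)}),
        }
        _, table = compare_groups(groups)[0]
        assert table.loc[0, "p_value"] < 0.05
        assert table.loc[0, "style_class"] == "not_significant"
        _, table = compare_groups(groups, fc_threshold=1.01)[0]
        assert table.loc[0, "style_class"] == "up"

    def test_eq1_threshold_variant(self):
        rng = np.random.default_rng(4)
        groups = {
            "A": pd.DataFrame({"R": rng.normal(12.1, 0.01, 30)}),
            "B": pd.DataFrame({"R": rng.normal(10.0, 0.01, 30)}),
        }
        # ratio 1.21 passes the default gate; |eq1 fc| ~ 0.095 > (t-1)/(t+1) ~ 0.091
        _, table = compare_groups(groups, fc_on_eq1=True)[0]
        assert table.loc[0, "style_class"] == "up"

    def test_group_assignment_splits_frame(self):
        frame = pd.DataFrame(
            {"R1": [1.0, 2.0, 3.0, 4.0]}, index=["a1", "a2", "b1", "b2"])
        groups = group_fluxes(frame, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        assert list(groups["A"].index) == ["a1", "a2"]
        with pytest.raises(ValueError, match="without group"):
            group_fluxes(frame, {"a1": "A"})

    def test_bh_correction_never_decreases_p(self):
        groups = _toy_groups(shift=1.0, seed=6)
        _, raw = compare_groups(groups)[0]
        _, adj = compare_groups(groups, correction="bh")[0]
        assert (adj["p_value"] >= raw["p_value"] - 1e-12).all()
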