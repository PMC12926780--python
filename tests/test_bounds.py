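"""RAS normalization, bound scaling, and medium constraints."""

import numpy as np
import pandas as pd
import pytest

from fluxscape.bounds import (
    Medium,
    apply_medium,
    apply_ras_to_bounds,
    build_sample_models,
    normalize_ras,
)


class TestNormalize:
    def test_row_divided_by_its_max(self):
        ras = pd.DataFrame({"s1": [2.0], "s2": [4.0], "s3": [8.0]}, index=["R1"])
        out = normalize_ras(ras)
        assert out.loc["R1"].tolist() == [0.25, 0.5, 1.0]

    def test_zero_max_row_becomes_missing_by_default(self):
        ras = pd.DataFrame({"s1": [0.0], "s2": [0.0]}, index=["R1"])
        assert normalize_ras(ras).loc["R1"].isna().all()

    def test_zero_max_row_closes_under_flag(self):
        ras = pd.DataFrame({"s1": [0.0], "s2": [0.0]}, index=["R1"])
        assert normalize_ras(ras, zero_ras_closes=True).loc["R1"].tolist() == [0.0, 0.0]

    def test_single_sample_row_is_one(self):
        ras = pd.DataFrame({"s1": [7.0]}, index=["R1"])
        assert normalize_ras(ras).loc["R1", "s1"] == 1.0

    def test_normalization_is_per_reaction_not_global(self):
        ras = pd.DataFrame({"s1": [2.0, 100.0], "s2": [4.0, 50.0]},
                           index=["R1", "R2"])
        out = normalize_ras(ras)
        assert out.loc["R1"].tolist() == [0.5, 1.0]
        assert out.loc["R2"].tolist() == [1.0, 0.5]

    def test_missing_propagates_and_outputs_in_unit_interval(self):
        ras = pd.DataFrame({"s1": [np.nan, 3.0], "s2": [2.0, 1.0]},
                           index=["R1", "R2"])
        out = normalize_ras(ras)
        assert np.isnan(out.loc["R1", "s1"])
        values = out.to_numpy().ravel()
        values = values[~np.isnan(values)]
        assert ((0 <= values) & (values <= 1)).all()


class TestRasScaling:
    def test_irreversible_bounds_scaled(self, chain_model):
        bset = apply_ras_to_bounds(chain_model, {"P1R1": 0.4})
        assert bset.bounds["P1R1"] == (0.0, 400.0)

    def test_reversible_bounds_scaled_symmetrically(self, chain_model):
        rec = chain_model.reaction("P1R1")
        rec.lower_bound = -1000.0
        bset = apply_ras_to_bounds(chain_model, {"P1R1": 0.25})
        assert bset.bounds["P1R1"] == (-250.0, 250.0)

    def test_missing_ras_keeps_bounds(self, chain_model):
        bset = apply_ras_to_bounds(chain_model, {"P1R1": float("nan")})
        assert bset.bounds["P1R1"] == (0.0, 1000.0)

    def test_no_gpr_reaction_untouched(self, chain_model):
        bset = apply_ras_to_bounds(chain_model, {"EX_B": 0.1, "P1R1": 0.5})
        assert bset.bounds["EX_B"] == (0.0, 1000.0)

    def test_exchanges_exempt_unless_requested(self, parallel_model):
        parallel_model.reaction("EX_A").gpr_text = "g1"
        parallel_model.reaction("EX_A").gpr = None
        model = parallel_model
        model.reactions[0].__post_init__()
        bset = apply_ras_to_bounds(model, {"EX_A": 0.5})
        assert bset.bounds["EX_A"] == (-10.0, 1000.0)
        bset = apply_ras_to_bounds(model, {"EX_A": 0.5}, scale_exchanges=True)
        assert bset.bounds["EX_A"] == (-5.0, 500.0)

    def test_scaling_never_widens(self, parallel_model):
        rng = np.random.default_rng(0)
        column = {r.id: rng.uniform(0, 1) for r in parallel_model.reactions}
        bset = apply_ras_to_bounds(parallel_model, column)
        for rec in parallel_model.reactions:
            lo, hi = bset.bounds[rec.id]
            assert abs(lo) <= abs(rec.lower_bound) + 1e-12
            assert abs(hi) <= abs(rec.upper_bound) + 1e-12

    def test_out_of_range_score_rejected(self, chain_model):
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            apply_ras_to_bounds(chain_model, {"P1R1": 1.5})


class TestMedium:
    def test_listed_metabolite_opens_unlisted_closes(self, chain_model):
        bset = apply_medium(chain_model, Medium({"A[e]": 10.0}))
        assert bset.bounds["EX_A"] == (-10.0, 1000.0)
        assert bset.bounds["EX_B"] == (0.0, 1000.0)

    def test_empty_medium_closes_all_uptakes(self, chain_model):
        bset = apply_medium(chain_model, Medium({}))
        assert all(bset.bounds[r.id][0] == 0.0
                   for r in chain_model.reactions if r.is_exchange)

    def test_orphan_metabolite_warns_but_does_not_fail(self, chain_model, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="fluxscape.bounds"):
            bset = apply_medium(chain_model, Medium({"Z[e]": 5.0}))
        assert "Z[e]" in caplog.text
        assert bset.bounds["EX_A"] == (0.0, 1000.0)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            Medium({"A[e]": -1.0})


class TestComposition:
    def test_one_bounds_set_per_sample(self, chain_model):
        norm = pd.DataFrame({"s1": [1.0], "s2": [0.5], "s3": [0.25]},
                            index=["P1R1"])
        sets = build_sample_models(chain_model, norm)
        assert [b.sample for b in sets] == ["s1", "s2", "s3"]

    def test_all_ones_no_medium_is_identity(self, chain_model):
        norm = pd.DataFrame({"s1": [1.0]}, index=["P1R1"])
        bset = build_sample_models(chain_model, norm)[0]
        for rec in chain_model.reactions:
            assert bset.bounds[rec.id] == (rec.lower_bound, rec.upper_bound)

    def test_medium_and_ras_compose(self, chain_model):
        norm = pd.DataFrame({"s1": [0.4]}, index=["P1R1"])
        bset = build_sample_models(chain_model, norm,
                                   medium=Medium({"A[e]": 10.0}))[0]
        assert bset.bounds["EX_A"] == (-10.0, 1000.0)
        assert bset.bounds["P1R1"] == (0.0, 400.0)
        assert bset.bounds["EX_B"] == (0.0, 1000.0)

    def test_order_independence_when_targets_disjoint(self, chain_model):
        """Medium touches exchanges, RAS touches GPR reactions: order is moot."""
        medium = Medium({"A[e]": 7.0})
        column = {"P1R1": 0.3}
        med_first = apply_ras_to_bounds(
            chain_model, column, base=apply_medium(chain_model, medium))
        ras_first = apply_medium(
            chain_model, medium, base=apply_ras_to_bounds(chain_model, column))
        assert med_first.bounds == ras_first.bounds

    def test_zero_flux_feasible_iff_no_positive_lower_bound(self, twogroup):
        from fluxscape.bounds import normalize_ras
        from fluxscape.gpr import expression_to_ras
        model = twogroup["model"]
        ras = expression_to_ras(model, twogroup["expression"])
        sets = build_sample_models(model, normalize_ras(ras),
                                   medium=twogroup["medium"])
        for bset in sets:
            zero_ok = all(lo <= 0 <= hi for lo, hi in bset.bounds.values())
            any_positive_lb = any(lo > 0 for lo, _ in bset.bounds.values())
            assert zero_ok == (not any_positive_lb)
            assert zero_ok
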