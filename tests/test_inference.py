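"""Pruning likelihood, ML fitting, AICc weights and ancestral marginals."""

import itertools
import math

import numpy as np
import pytest

import biogeofit as bg
from biogeofit.chronogram import parse_newick
from biogeofit.decmodels import BiogeoParams, ModelSpec
from biogeofit.inference import (
    RangeEvolutionModel,
    aicc,
    fit_ml,
    model_weights,
    run_model_grid,
)
from biogeofit.rangespace import Geography, GeoRange, build_state_space
from biogeofit.scenarios import TimeStratum, build_scenario

from conftest import brute_force_reference


class TestLikelihoodBasics:
    def test_single_area_survival_closed_form(self):
        """With one area the only process is extirpation; each surviving
        branch of length t contributes exp(-e t) to the likelihood."""
        sp = build_state_space(["A"], 1)
        tree = parse_newick("(t1:2,t2:2):0;")
        geo = Geography(sp, {"t1": GeoRange(1), "t2": GeoRange(1)})
        e = 0.1
        lnL = RangeEvolutionModel(tree, geo, "DEC").loglike(BiogeoParams(0.0, e))
        assert lnL == pytest.approx(-e * 4, abs=1e-10)

    def test_impossible_data_gives_neg_inf(self, space2, tree4, geo4_2areas):
        # d = 0 but tips occupy different areas: zero likelihood
        model = RangeEvolutionModel(tree4, geo4_2areas, "DIVALIKE")
        assert model.loglike(BiogeoParams(0.0, 0.0)) == float("-inf")

    def test_j_zero_matches_base_model(self, tree4, geo4_2areas):
        for base in ("DEC", "DIVALIKE", "BAYAREALIKE"):
            params = BiogeoParams(0.2, 0.1, 0.0)
            base_ll = RangeEvolutionModel(tree4, geo4_2areas, base).loglike(
                BiogeoParams(0.2, 0.1)
            )
            plus_ll = RangeEvolutionModel(tree4, geo4_2areas, base + "+J").loglike(params)
            assert plus_ll == pytest.approx(base_ll, abs=1e-10)

    def test_likelihood_invariant_under_child_swap_and_reorder(self, space2):
        geo = Geography(
            space2,
            {"t1": GeoRange(1), "t2": GeoRange(2), "t3": GeoRange(3), "t4": GeoRange(1)},
        )
        params = BiogeoParams(0.25, 0.1)
        trees = [
            "((t1:1,t2:1):1.5,(t3:2.5,t4:2.5):0.0):0;",
            "((t2:1,t1:1):1.5,(t4:2.5,t3:2.5):0.0):0;",
            "((t3:2.5,t4:2.5):0.0,(t1:1,t2:1):1.5):0;",
        ]
        lls = [
            RangeEvolutionModel(parse_newick(t), geo, "DEC").loglike(params)
            for t in trees
        ]
        assert lls[0] == pytest.approx(lls[1], abs=1e-12)
        assert lls[0] == pytest.approx(lls[2], abs=1e-12)


class TestOracleEquivalence:
    """Pruning lnL and node marginals vs. exhaustive enumeration."""

    @pytest.mark.parametrize("model_name", ["DEC", "DIVALIKE", "BAYAREALIKE", "DEC+J",
                                            "DIVALIKE+J", "BAYAREALIKE+J"])
    def test_four_tip_two_area(self, model_name, space2, tree4, geo4_2areas):
        spec = ModelSpec.from_name(model_name)
        params = BiogeoParams(0.3, 0.15, 0.7 if spec.with_j else 0.0)
        ref_ll, ref_marg = brute_force_reference(tree4, geo4_2areas, spec, params, space2)
        model = RangeEvolutionModel(tree4, geo4_2areas, spec)
        assert model.loglike(params) == pytest.approx(ref_ll, abs=1e-8)
        probs = model.ancestral_state_probabilities(params)
        for n in tree4.internal_nodes():
            got = probs.loc[model.node_id_of(n)].to_numpy()
            assert np.allclose(got, ref_marg[id(n)], atol=1e-8)
            assert got.sum() == pytest.approx(1.0, abs=1e-9)

    def test_three_tip_three_area(self, space3):
        tree = parse_newick("((t1:1,t2:1):1,t3:2):0;")
        geo = Geography(
            space3,
            {"t1": GeoRange(0b001), "t2": GeoRange(0b010), "t3": GeoRange(0b110)},
        )
        spec = ModelSpec("DEC", with_j=True)
        params = BiogeoParams(0.2, 0.1, 1.2)
        ref_ll, ref_marg = brute_force_reference(tree, geo, spec, params, space3)
        model = RangeEvolutionModel(tree, geo, spec)
        assert model.loglike(params) == pytest.approx(ref_ll, abs=1e-8)
        probs = model.ancestral_state_probabilities(params)
        for n in tree.internal_nodes():
            assert np.allclose(
                probs.loc[model.node_id_of(n)].to_numpy(), ref_marg[id(n)], atol=1e-8
            )


class TestStratificationConsistency:
    def test_identical_multipliers_equal_unstratified(self, space2, tree4, geo4_2areas):
        """Slicing branches at stratum boundaries must not change the
        likelihood when every stratum carries the same multipliers."""
        strata = tuple(
            TimeStratum(i, lo, hi)
            for i, (lo, hi) in enumerate([(0, 1.2), (1.2, 2.1), (2.1, 50)])
        )
        stratified = build_scenario("null", ["A", "B"], strata=strata)
        params = BiogeoParams(0.3, 0.2)
        ll_strat = RangeEvolutionModel(tree4, geo4_2areas, "DEC", stratified).loglike(params)
        ll_flat = RangeEvolutionModel(tree4, geo4_2areas, "DEC").loglike(params)
        assert ll_strat == pytest.approx(ll_flat, abs=1e-10)


class TestFitting:
    def test_aicc_formula(self):
        assert aicc(-100, 2, 39) == pytest.approx(204 + 12 / 36)
        assert aicc(-100, 3, 39) == pytest.approx(206 + 24 / 35)

    def test_nesting_plus_j_never_worse(self, tree4, geo4_2areas):
        base = fit_ml(tree4, geo4_2areas, "DEC")
        plus = fit_ml(tree4, geo4_2areas, "DEC+J")
        assert plus.llf >= base.llf - 1e-6

    def test_fit_recovers_reasonable_rates(self, space2, tree4, geo4_2areas):
        res = fit_ml(tree4, geo4_2areas, "DEC")
        assert res.converged
        assert np.isfinite(res.llf)
        assert res.k == 2
        assert res.aicc == pytest.approx(aicc(res.llf, 2, 4))
        assert "DEC" in res.summary()


class _StubResult:
    """Duck-typed stand-in carrying only what model_weights consumes."""

    def __init__(self, aicc_val, k=2, name="DEC", scenario="null"):
        self.aicc = aicc_val
        self.k = k
        self.model_name = name
        self.scenario_name = scenario
        self.delta_aicc = None
        self.aicc_wt = None


class TestModelWeights:
    def test_weights_for_delta_two(self):
        a, b = _StubResult(100.0, name="DEC"), _StubResult(102.0, name="DIVALIKE")
        ranked = model_weights([b, a])
        assert [r.aicc for r in ranked] == [100.0, 102.0]
        assert ranked[0].aicc_wt == pytest.approx(0.73106, abs=1e-5)
        assert ranked[1].aicc_wt == pytest.approx(0.26894, abs=1e-5)

    def test_single_model_weight_one(self):
        (only,) = model_weights([_StubResult(50.0)])
        assert only.aicc_wt == pytest.approx(1.0)
        assert only.delta_aicc == 0.0

    def test_equal_aicc_equal_weights_with_name_tiebreak(self):
        ranked = model_weights([_StubResult(10.0, name="DIVALIKE"),
                                _StubResult(10.0, name="DEC")])
        assert ranked[0].aicc_wt == pytest.approx(0.5)
        assert ranked[1].aicc_wt == pytest.approx(0.5)
        assert ranked[0].model_name == "DEC"


class TestAncestralRanges:
    def test_no_change_limit_concentrates_on_shared_range(self, space2):
        tree = parse_newick("((t1:1,t2:1):1,(t3:2,t4:2):0.0):0;")
        geo = Geography(space2, {t: GeoRange(1) for t in ("t1", "t2", "t3", "t4")})
        model = RangeEvolutionModel(tree, geo, "DEC")
        probs = model.ancestral_state_probabilities(BiogeoParams(1e-9, 1e-9))
        root_row = probs.loc[model.node_id_of(tree.root)]
        assert root_row["A"] > 0.999

    def test_rows_sum_to_one(self, tree4, geo4_2areas):
        model = RangeEvolutionModel(tree4, geo4_2areas, "DIVALIKE")
        probs = model.ancestral_state_probabilities(BiogeoParams(0.3, 0.1))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)


@pytest.fixture(scope="module")
def small_dataset():
    from biogeofit import fixtures as fx
    from biogeofit.simulate import simulate_ranges, simulate_yule_tree

    space = fx.build_paper_state_space()
    tree = simulate_yule_tree(8, 0.05, 21)
    scen = fx.paper_scenarios()["closing_americas"]
    data = simulate_ranges(
        tree, "DEC", scen, BiogeoParams(0.03, 0.01),
        space.states[1], 22, space=space,
    )
    return tree, data.geography


class TestModelGrid:
    def test_grid_has_24_ranked_rows(self, small_dataset):
        from biogeofit import fixtures as fx

        tree, geo = small_dataset
        table = run_model_grid(tree, geo, fx.paper_scenarios())
        assert len(table) == 24
        assert set(table["scenario"]) == {"null", "panama", "closing_americas",
                                          "gaarlandia"}
        assert set(table["model"]) == {"DEC", "DEC+J", "DIVALIKE", "DIVALIKE+J",
                                       "BAYAREALIKE", "BAYAREALIKE+J"}
        ok = table[table["error"] == ""]
        assert ok["AICc_wt"].sum() == pytest.approx(1.0, abs=1e-9)
        assert ok["AICc"].is_monotonic_increasing
        assert ok["delta_AICc"].iloc[0] == pytest.approx(0.0)
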