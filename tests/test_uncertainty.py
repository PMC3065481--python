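"""Range construction, distribution fitting, tornado and PSA."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from refill_cea.cea_core import incremental
from refill_cea.model_params import (
    CostCategory,
    Perspective,
    SensitivitySettings,
)
from refill_cea.uncertainty import (
    build_ranges,
    ceac,
    ceac_crossover,
    fit_beta,
    fit_gamma,
    one_way,
    plane_summary,
    run_psa,
    se_from_range,
)

SOCIETAL = Perspective.LIMITED_SOCIETAL


class TestSEFromRange:
    @pytest.mark.parametrize(
        "low, high, expected",
        [(0.1568, 0.2352, 0.0200), (121.5, 486.0, 92.99)],
    )
    def test_examples(self, low, high, expected):
        assert se_from_range(low, high) == pytest.approx(expected, abs=5e-3)

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            se_from_range(2.0, 2.0)

    @given(
        low=st.floats(-100, 100),
        width=st.floats(0.1, 100),
        shift=st.floats(-1000, 1000),
    )
    def test_translation_invariance(self, low, width, shift):
        assert se_from_range(low + shift, low + width + shift) == pytest.approx(
            se_from_range(low, low + width), rel=1e-9
        )


class TestMomentMatching:
    def test_beta_example(self):
        alpha, beta = fit_beta(0.196, 0.02)
        assert alpha == pytest.approx(77.02, abs=0.01)
        assert beta == pytest.approx(315.94, abs=0.01)

    def test_gamma_example(self):
        shape, scale = fit_gamma(243.0, 92.99)
        assert shape == pytest.approx(6.83, abs=0.01)
        assert scale == pytest.approx(35.58, abs=0.01)

    def test_beta_symmetry_at_half(self):
        alpha, beta = fit_beta(0.5, 0.1)
        assert alpha == pytest.approx(beta)

    def test_gamma_exponential_when_cv_is_one(self):
        shape, scale = fit_gamma(243.0, 243.0)
        assert shape == pytest.approx(1.0)
        assert scale == pytest.approx(243.0)

    def test_beta_variance_constraint_named(self):
        with pytest.raises(ValueError, match="se\\^2 < mean"):
            fit_beta(0.5, 0.6)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fit_beta(1.5, 0.1)
        with pytest.raises(ValueError):
            fit_gamma(-1.0, 1.0)

    @given(
        mean=st.floats(0.01, 0.99),
        cv=st.floats(0.05, 0.5),
    )
    def test_fitted_moments_are_exact_algebraically(self, mean, cv):
        se = cv * min(mean, 1 - mean)
        alpha, beta = fit_beta(mean, se)
        assert alpha / (alpha + beta) == pytest.approx(mean, abs=1e-9)
        var = alpha * beta / ((alpha + beta) ** 2 * (alpha + beta + 1))
        assert var == pytest.approx(se * se, rel=1e-9)
        shape, scale = fit_gamma(max(mean, 1e-3) * 100, se * 100)
        assert shape * scale == pytest.approx(max(mean, 1e-3) * 100, rel=1e-12)

    @pytest.mark.parametrize(
        "kind, mean, se",
        [("beta", 0.196, 0.0200), ("beta", 0.186, 0.01898), ("gamma", 243.0, 92.99)],
    )
    def test_sampled_moments_match_targets(self, kind, mean, se):
        """10^6 draws reproduce the target mean and SD within 0.5%."""
        rng = np.random.default_rng(12345)
        if kind == "beta":
            a, b = fit_beta(mean, se)
            x = rng.beta(a, b, size=1_000_000)
        else:
            shape, scale = fit_gamma(mean, se)
            x = rng.gamma(shape, scale, size=1_000_000)
        assert x.mean() == pytest.approx(mean, rel=5e-3)
        assert x.std() == pytest.approx(se, rel=5e-3)


class TestBuildRanges:
    def test_published_ranges(self, model):
        params = {p.name: p for p in build_ranges(model)}
        art = params["cost:art"]
        assert (art.low, art.high) == (121.5, 486.0)
        p_soc = params["p_fir:soc"]
        assert p_soc.low == pytest.approx(0.1568)
        assert p_soc.high == pytest.approx(0.2352)
        assert p_soc.se == pytest.approx(0.0200, abs=1e-4)

    def test_fitted_means_equal_point_estimates(self, model):
        for p in build_ranges(model):
            kind, p1, p2 = p.dist
            fitted_mean = p1 / (p1 + p2) if kind == "beta" else p1 * p2
            assert fitted_mean == pytest.approx(p.mean, abs=1e-9), p.name

    def test_roles_match_distributions(self, model):
        for p in build_ranges(model):
            assert p.dist[0] == ("beta" if p.role == "probability" else "gamma")
            assert p.low <= p.mean <= p.high

    def test_zero_cost_excluded_with_warning(self, model):
        prp_costs = dict(model.intervention.costs.category_costs)
        prp_costs[CostCategory.RADIOLOGY] = 0.0
        prp = dataclasses.replace(
            model.intervention,
            costs=dataclasses.replace(
                model.intervention.costs, category_costs=prp_costs
            ),
        )
        degen = dataclasses.replace(model, intervention=prp)
        with pytest.warns(UserWarning, match="degenerate range"):
            params = build_ranges(degen)
        names = {p.name for p in params}
        assert not any("radiology" in n and "prp" in n for n in names)

    def test_independent_mode_splits_every_category(self, model):
        names = {p.name for p in build_ranges(model, shared_costs=False)}
        assert "cost:art:prp" in names and "cost:art:soc" in names
        assert "cost:art" not in names


class TestOneWay:
    def test_shared_components_cancel_in_delta_cost(self, model):
        rows = {r.name: r for r in one_way(model, SOCIETAL, "delta_cost")}
        assert rows["cost:art"].swing == 0.0
        assert rows["cost:transport"].swing == 0.0
        # arm-specific categories do move the difference
        assert rows["cost:personnel:soc"].swing > 0.0
        assert rows["cost:residual:soc"].swing > 0.0

    def test_probabilities_never_swing_costs(self, model):
        rows = {r.name: r for r in one_way(model, SOCIETAL, "delta_cost")}
        assert rows["p_fir:prp"].swing == 0.0
        eff = {r.name: r for r in one_way(model, SOCIETAL, "delta_effect")}
        assert eff["p_fir:prp"].swing > 0.0
        assert eff["cost:art"].swing == 0.0

    def test_independent_mode_art_dominates(self, model):
        rows = one_way(model, SOCIETAL, "delta_cost", shared_costs=False)
        assert rows[0].name in ("cost:art:prp", "cost:art:soc")
        assert rows[0].swing == pytest.approx(364.5)

    def test_rows_sorted_by_swing(self, model):
        swings = [r.swing for r in one_way(model, SOCIETAL, "delta_cost")]
        assert swings == sorted(swings, reverse=True)

    def test_unknown_target_rejected(self, model):
        with pytest.raises(ValueError):
            one_way(model, SOCIETAL, "icer")


class TestPSA:
    def test_reproducible_for_fixed_seed(self, model):
        a = run_psa(model, SOCIETAL, n_iter=500, seed=7).draws
        b = run_psa(model, SOCIETAL, n_iter=500, seed=7).draws
        pd.testing.assert_frame_equal(a, b)
        c = run_psa(model, SOCIETAL, n_iter=500, seed=8).draws
        assert not a["delta_cost"].equals(c["delta_cost"])

    def test_increments_equal_per_strategy_differences(self, model):
        draws = run_psa(model, SOCIETAL, n_iter=1000, seed=2).draws
        np.testing.assert_array_equal(
            draws["delta_cost"], draws["cost_prp"] - draws["cost_soc"]
        )
        np.testing.assert_array_equal(
            draws["delta_effect"], draws["effect_prp"] - draws["effect_soc"]
        )

    def test_means_match_deterministic_base_case(self, model):
        """Law of large numbers: PSA means sit within 3 Monte-Carlo SEs of
        the deterministic component-sum increments."""
        draws = run_psa(model, SOCIETAL, n_iter=10_000, seed=4).draws
        dc, de = incremental(model, SOCIETAL, use_override=False)
        for col, target in (("delta_cost", dc), ("delta_effect", de)):
            x = draws[col]
            assert x.mean() == pytest.approx(
                target, abs=3 * x.std() / math.sqrt(len(x))
            )

    def test_deterministic_limit(self, model):
        """With vanishing ranges every draw collapses to the base case."""
        tight = dataclasses.replace(
            model,
            sensitivity=SensitivitySettings(
                cost_low_factor=1 - 1e-9, cost_high_factor=1 + 1e-9, prob_delta=1e-9
            ),
        )
        draws = run_psa(tight, SOCIETAL, n_iter=200, seed=6, sample_residual=True).draws
        dc, de = incremental(model, SOCIETAL, use_override=False)
        np.testing.assert_allclose(draws["delta_cost"], dc, atol=1e-3)
        np.testing.assert_allclose(draws["delta_effect"], de, atol=1e-6)

    def test_moh_perspective_excludes_patient_costs(self, model):
        soc_draws = run_psa(model, SOCIETAL, n_iter=2000, seed=9).draws
        moh_draws = run_psa(model, Perspective.MOH, n_iter=2000, seed=9).draws
        # same seed, fewer categories summed: MoH costs strictly smaller
        assert (moh_draws["cost_prp"] < soc_draws["cost_prp"]).all()

    def test_n_iter_validated(self, model):
        with pytest.raises(ValueError):
            run_psa(model, SOCIETAL, n_iter=0, seed=1)


@pytest.fixture(scope="module")
def draws(model):
    return run_psa(model, SOCIETAL, n_iter=10_000, seed=11).draws


class TestPlaneAndCEAC:
    def test_all_replicates_cost_saving(self, draws):
        assert (draws["delta_cost"] < 0).mean() == 1.0
        summary = plane_summary(draws)
        assert summary["SW"] + summary["SE"] == pytest.approx(1.0)

    def test_fractions_sum_to_one(self, draws):
        assert sum(plane_summary(draws).values()) == pytest.approx(1.0)

    def test_manual_draws_one_per_quadrant(self):
        frame = pd.DataFrame(
            {
                "delta_cost": [1.0, -1.0, -1.0, 1.0],
                "delta_effect": [1.0, 1.0, -1.0, -1.0],
                "quadrant": ["NE", "SE", "SW", "NW"],
            }
        )
        assert plane_summary(frame) == {
            "NE": 0.25, "SE": 0.25, "SW": 0.25, "NW": 0.25, "axis": 0.0,
        }

    def test_ceac_at_zero_wtp_counts_cost_saving_draws(self, draws):
        curve = ceac(draws, np.array([0.0, 100.0]))
        assert curve["p_prp_ce"].iloc[0] == (draws["delta_cost"] < 0).mean()

    def test_ceac_probabilities_complementary(self, draws):
        curve = ceac(draws)
        assert ((curve["p_prp_ce"] + curve["p_soc_ce"]) == 1.0).all()
        assert curve["p_prp_ce"].between(0, 1).all()

    def test_ceac_monotone_when_all_draws_southwest(self, draws):
        sw = draws[draws["quadrant"] == "SW"]
        p = ceac(sw)["p_prp_ce"].to_numpy()
        assert (np.diff(p) <= 0).all()

    def test_crossover_near_deterministic_icer(self, draws):
        crossover = ceac_crossover(ceac(draws))
        assert 12_000 < crossover < 15_000

    def test_degenerate_draws_step_at_icer(self):
        """A single base-case draw yields a step CEAC falling at 13,500."""
        frame = pd.DataFrame({"delta_cost": [-135.0], "delta_effect": [-0.010]})
        curve = ceac(frame)
        below = curve[curve["wtp"] < 13_500]["p_prp_ce"]
        at_or_above = curve[curve["wtp"] >= 13_500]["p_prp_ce"]
        assert (below == 1.0).all()
        assert (at_or_above == 0.0).all()

    def test_empty_draws_rejected(self):
        with pytest.raises(ValueError):
            ceac(pd.DataFrame({"delta_cost": [], "delta_effect": []}))
        with pytest.raises(ValueError):
            plane_summary(pd.DataFrame({"quadrant": []}))
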