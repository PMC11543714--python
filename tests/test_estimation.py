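"""Maximum-likelihood fitting, G^2, intervals, identifiability."""

import numpy as np
import pandas as pd
import pytest

from truthmpt import (
    ConstraintSet,
    FrequencyTable,
    build_three_sources_model,
    check_identifiability,
    confidence_intervals,
    fit,
    g_squared,
)
from truthmpt.estimation import _em, compile_model
from truthmpt.power import expected_table
from truthmpt.synthetic_data import default_design, simulate


class TestGSquared:
    def test_fair_split_toy_case(self, coin_model):
        """Observed [30,10] against a fixed fair coin: G^2 = 10.465, df 1."""
        res = fit(
            coin_model,
            np.array([30.0, 10.0]),
            constraints=ConstraintSet(fixed={"p": 0.5}),
            starts=1,
            seed=0,
        )
        hand = 2 * (30 * np.log(30 / 20) + 10 * np.log(10 / 20))
        assert res.g_squared == pytest.approx(hand, abs=1e-9)
        assert res.g_squared == pytest.approx(10.465, abs=1e-3)
        assert res.df == 1

    def test_zero_observed_cells_contribute_nothing(self):
        assert g_squared([0.0, 10.0], [5.0, 5.0]) == pytest.approx(
            2 * 10 * np.log(2.0)
        )

    def test_zero_expected_with_positive_observed_is_infinite(self):
        assert g_squared([1.0, 9.0], [0.0, 10.0]) == np.inf


class TestFit:
    def test_recovers_generating_values_from_expected_data(
        self, two_group_model, design, cartesian_params
    ):
        """Noise-free expected frequencies are fitted exactly."""
        table = expected_table(two_group_model, cartesian_params, design)
        res = fit(two_group_model, table, starts=2, seed=3)
        assert res.g_squared < 1e-6
        truth = two_group_model.expand_parameters(cartesian_params)
        for name in two_group_model.free_parameters():
            assert res.estimates[name] == pytest.approx(truth[name], abs=1e-4)

    def test_matches_grid_search_oracle(self, two_param_model):
        """ML fit agrees with a 0.01-resolution grid search.

        Counts are exact expected values at (p, q) = (.5, .3), so the
        global optimum lies on the grid.
        """
        counts = np.array([50.0, 50.0, 15.0, 35.0, 50.0])
        res = fit(two_param_model, counts, starts=5, seed=1)
        grid = np.arange(0.01, 1.0, 0.01)
        best = -np.inf
        for p in grid:
            ll_t1 = 50 * np.log(p) + 50 * np.log(1 - p)
            for q in grid:
                ll = (
                    ll_t1
                    + 15 * np.log(p * q)
                    + 35 * np.log(p * (1 - q))
                    + 50 * np.log(1 - p)
                )
                best = max(best, ll)
        assert res.log_likelihood >= best - 1e-9
        assert res.log_likelihood == pytest.approx(best, abs=1e-6)

    def test_em_and_quasi_newton_agree(self, two_param_model):
        """The EM fixed point matches the polished optimum in logL."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            p, q = rng.uniform(0.1, 0.9, 2)
            c1 = rng.multinomial(100, [p, 1 - p])
            c2 = rng.multinomial(100, [p * q, p * (1 - q), 1 - p])
            counts = np.concatenate([c1, c2]).astype(float)
            em_only = fit(
                two_param_model, counts, starts=3, seed=7, polish=False, tol=1e-13
            )
            polished = fit(two_param_model, counts, starts=3, seed=7, polish=True)
            assert polished.log_likelihood - em_only.log_likelihood < 1e-5
            assert polished.log_likelihood >= em_only.log_likelihood - 1e-9

    def test_em_loglikelihood_is_monotone(self, two_group_model, design,
                                          cartesian_params):
        table = simulate(design, cartesian_params, seed=5)
        compiled = compile_model(two_group_model)
        counts = table.counts_for(two_group_model)
        track = []
        _em(compiled, counts, np.full(compiled.n_free, 0.5), track=track)
        diffs = np.diff(track)
        assert np.all(diffs >= -1e-9)

    def test_empty_tree_raises(self, two_group_model, design, cartesian_params):
        table = simulate(design, cartesian_params, seed=5)
        frame = table.frame[table.frame["item_condition"] != "new"]
        with pytest.raises(ValueError, match="zero total"):
            fit(two_group_model, FrequencyTable(frame), starts=1, seed=0)

    def test_unknown_response_label_raises(self, two_group_model):
        frame = pd.DataFrame(
            [{"group": "HTB", "item_condition": "old_true",
              "response": "maybe", "count": 3}]
        )
        with pytest.raises(ValueError, match="maybe"):
            FrequencyTable(frame).counts_for(two_group_model)

    def test_negative_counts_raise(self):
        frame = pd.DataFrame(
            [{"group": "", "item_condition": "t", "response": "a", "count": -1}]
        )
        with pytest.raises(ValueError, match="negative"):
            FrequencyTable(frame)


class TestConfidenceIntervals:
    def test_width_shrinks_with_root_n(self, two_group_model, cartesian_params):
        """Wald CI width scales as 1/sqrt(N) for interior parameters."""
        widths = {}
        for factor in (1, 16):
            design = default_design(103 * factor, 105 * factor)
            table = simulate(design, cartesian_params, seed=9)
            res = fit(two_group_model, table, starts=2, seed=9)
            ci = confidence_intervals(res)
            widths[factor] = np.array([hi - lo for lo, hi in ci.values()])
        ratio = widths[1] / widths[16]
        assert np.median(ratio) == pytest.approx(4.0, rel=0.15)

    def test_intervals_truncated_to_unit_range(self, coin_model):
        res = fit(coin_model, np.array([99.0, 1.0]), starts=2, seed=0)
        lo, hi = res.ci95["p"]
        assert 0.0 <= lo <= hi <= 1.0
        assert hi > 0.97


class TestIdentifiability:
    def test_base_model_with_constraint_is_full_rank(self, one_group_model):
        """With D_new = D_unchecked the model is locally identifiable."""
        res = check_identifiability(one_group_model, n_points=10, seed=0)
        assert res.rank == res.n_free == 11
        assert not res.deficient

    def test_unconstrained_model_is_saturated_and_ill_conditioned(self):
        """Without the constraint the model has as many parameters as free
        data proportions (df 0).  Its Jacobian is generically full rank —
        the identification problem reported in applied work is practical
        (near-flat likelihood directions), visible here as a much smaller
        minimum singular value than for the constrained model.
        """
        unconstrained = build_three_sources_model(False, identifiable=False)
        assert unconstrained.df == 0
        res = check_identifiability(unconstrained, n_points=10, seed=0)
        assert res.rank == res.n_free == 12
        constrained = check_identifiability(
            build_three_sources_model(False), n_points=10, seed=0
        )
        assert res.min_singular_value < constrained.min_singular_value

    def test_coin_model_rank_one(self, coin_model):
        res = check_identifiability(coin_model, n_points=3, seed=0)
        assert res.rank == 1
        assert not res.deficient
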