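"""Equilibrium iteration, analytic conditions, stability classification."""

import numpy as np
import pytest

from matechoice import (
    ModelParams,
    Stability,
    basin_sweep,
    classify_stability,
    condition_both_costly,
    condition_care,
    condition_costly_trait,
    condition_guarding,
    condition_internal_costly,
    edge_equilibrium_p2,
    iterate_to_equilibrium,
    region_map,
    state_from_freqs,
    step,
    summarize,
    trajectory_to_dataframe,
)


class TestIterate:
    def test_neutral_parameters_converge_in_place(self):
        p = ModelParams(a=0.0, delta_e=0.0, delta_theta=0.0)
        traj = iterate_to_equilibrium(state_from_freqs(0.3, 0.6, 0.05), p)
        assert traj.converged
        s = traj.final_summary
        assert s.p2 == pytest.approx(0.3, abs=1e-9)
        assert s.t2 == pytest.approx(0.6, abs=1e-9)
        assert s.D == pytest.approx(0.0, abs=1e-9)

    def test_care_condition_met_fixes_trait(self, fig2b_params):
        traj = iterate_to_equilibrium(state_from_freqs(0.5, 0.5), fig2b_params)
        assert traj.converged
        assert traj.final_summary.t2 == pytest.approx(1.0, abs=1e-6)

    def test_care_condition_violated_low_start_loses_preference(self, fig2a_params):
        traj = iterate_to_equilibrium(state_from_freqs(0.1, 0.1), fig2a_params)
        assert traj.converged
        assert traj.final_summary.p2 == pytest.approx(0.0, abs=1e-6)

    def test_records_first_and_last_states(self, fig2b_params):
        traj = iterate_to_equilibrium(state_from_freqs(0.5, 0.5), fig2b_params)
        assert traj.recorded_at[0] == 0
        assert traj.recorded_at[-1] == traj.generations
        df = trajectory_to_dataframe(traj)
        assert list(df.columns) == ["generation", "x1", "x2", "x3", "x4", "p2", "t2", "D"]

    def test_non_convergence_flagged_not_raised(self, fig2b_params):
        traj = iterate_to_equilibrium(state_from_freqs(0.5, 0.5), fig2b_params,
                                      max_gen=5)
        assert not traj.converged
        assert traj.generations == 5

    def test_validates_arguments(self, fig2b_params):
        with pytest.raises(ValueError):
            iterate_to_equilibrium(state_from_freqs(0.5, 0.5), fig2b_params, tol=0.0)
        with pytest.raises(ValueError):
            iterate_to_equilibrium(state_from_freqs(0.5, 0.5), fig2b_params, max_gen=0)


class TestConditions:
    @pytest.mark.parametrize("kw,expected", [
        ({"e": 0.8, "delta_e": 0.7, "theta": 0.8, "delta_theta": 0.1}, True),
        ({"e": 0.8, "delta_e": 0.0, "theta": 0.8, "delta_theta": 0.1}, False),
        ({"e": 0.8, "delta_e": 0.4, "theta": 0.8, "delta_theta": 0.1}, False),  # boundary: strict
    ])
    def test_guarding_polymorphism_condition(self, kw, expected):
        assert condition_guarding(ModelParams(tradeoff="guarding", **kw)) is expected

    @pytest.mark.parametrize("delta_e,expected", [(0.1, False), (0.8, True)])
    def test_care_persistence_condition(self, delta_e, expected):
        p = ModelParams(e=0.8, delta_e=delta_e, b=0.8, delta=0.1, theta=0.8,
                        tradeoff="care")
        assert condition_care(p) is expected

    def test_care_condition_trivial_when_care_costless(self):
        p = ModelParams(e=0.8, delta_e=0.1, b=0.8, delta=0.0, theta=0.8, tradeoff="care")
        assert condition_care(p) is True

    @pytest.mark.parametrize("kw,expected", [
        ({"s_f": 0.05, "b": 0.8, "delta": 0.1}, False),   # threshold 0.1125
        ({"s_f": 0.0, "b": 0.8, "delta": 0.1}, True),
        ({"s_f": 0.05, "b": 0.8, "delta": 0.2}, True),
    ])
    def test_costly_trait_condition(self, kw, expected):
        assert condition_costly_trait(ModelParams(tradeoff="care", **kw)) is expected

    @pytest.mark.parametrize("kw,expected", [
        ({"s_f": 0.05, "theta": 0.7, "delta": 0.1, "b": 0.8, "e": 0.8, "delta_e": 0.8}, True),
        ({"s_f": 0.2, "theta": 0.85, "delta": 0.1, "b": 0.8, "e": 0.8, "delta_e": 0.8}, False),
    ])
    def test_internal_costly_condition(self, kw, expected):
        assert condition_internal_costly(ModelParams(tradeoff="care", **kw)) is expected

    @pytest.mark.parametrize("s_f,s_m,theta,expected", [
        (0.05, 0.05, 0.7, True),    # 0.9025 > 0.7
        (0.0, 0.0, 0.99, True),
        (0.15, 0.15, 0.9, False),   # 0.7225 < 0.9
    ])
    def test_both_costly_condition(self, s_f, s_m, theta, expected):
        p = ModelParams(s_f=s_f, s_m=s_m, theta=theta, tradeoff="care")
        assert condition_both_costly(p) is expected


class TestEdgeEquilibrium:
    def base(self, **kw):
        return ModelParams(e=0.8, b=0.8, theta=0.8, delta=0.1, tradeoff="care", **kw)

    def test_formula_value_is_edge_fixed_point(self):
        # closed form gives 0.5 here; independently confirmed as the root of
        # the trait-lost edge dynamics (bisection of the fixed-point equation)
        p = self.base(delta_e=0.16)
        p_star = edge_equilibrium_p2(p)
        assert p_star == pytest.approx(0.5, abs=1e-12)
        x_star = state_from_freqs(p_star, 0.0)
        assert np.max(np.abs(step(x_star, p) - x_star)) < 1e-12

    def test_formula_outside_unit_interval_returns_none(self):
        assert edge_equilibrium_p2(self.base(delta_e=0.8)) is None   # value > 1
        assert edge_equilibrium_p2(self.base(delta_e=0.1)) is None   # value < 0

    def test_edge_dynamics_converge_to_formula_value(self):
        p = self.base(delta_e=0.16)
        for p0 in (0.45, 0.55):
            traj = iterate_to_equilibrium(state_from_freqs(p0, 0.0), p)
            assert traj.final_summary.p2 == pytest.approx(0.5, abs=1e-6)

    def test_costly_preference_variant_is_edge_fixed_point(self):
        p = self.base(delta_e=0.25, s_m=0.02)
        p_star = edge_equilibrium_p2(p)
        assert p_star is not None and 0 < p_star < 1
        x_star = state_from_freqs(p_star, 0.0)
        assert np.max(np.abs(step(x_star, p) - x_star)) < 1e-12

    def test_guarding_variant_unsupported(self):
        with pytest.raises(ValueError):
            edge_equilibrium_p2(ModelParams(tradeoff="guarding"))


class TestClassifyStability:
    def test_guarding_interior_is_neutral_line(self, fig1_params):
        traj = iterate_to_equilibrium(state_from_freqs(0.5, 0.5), fig1_params)
        rep = classify_stability(traj.final_state, fig1_params)
        assert rep.stability is Stability.NEUTRAL_LINE
        assert np.sum(np.abs(rep.eigenvalues - 1.0) < 1e-4) == 1
        assert rep.summary.D > 0  # P2-T2 association along the line

    def test_corner_stable_when_trait_too_costly(self):
        # tiny delta and delta_e with a costly trait: loss of both alleles is
        # locally stable (blue region of the published parameter planes)
        p = ModelParams(a=2.0, e=0.8, delta_e=0.001, b=0.8, delta=0.02,
                        theta=0.7, s_f=0.05, tradeoff="care")
        rep = classify_stability(state_from_freqs(0.0, 0.0), p)
        assert rep.stability is Stability.STABLE

    def test_costless_trait_corner_lies_on_neutral_line(self, fig2a_params):
        # with s_f = 0 the trait is neutral once P2 is lost, so the corner is
        # one point of a neutral line rather than an isolated attractor
        rep = classify_stability(state_from_freqs(0.0, 0.0), fig2a_params)
        assert rep.stability is Stability.NEUTRAL_LINE

    def test_interior_stable_in_costly_care_model(self):
        p = ModelParams(a=2.0, e=0.8, delta_e=0.8, b=0.8, delta=0.3, theta=0.7,
                        s_f=0.05, tradeoff="care")
        traj = iterate_to_equilibrium(state_from_freqs(0.9, 0.9), p)
        rep = classify_stability(traj.final_state, p)
        assert rep.stability is Stability.STABLE
        assert 0 < rep.summary.t2 < 1 and 0 < rep.summary.p2 < 1
        assert rep.summary.D > 0

    def test_trait_fixed_line_is_neutral(self):
        p = ModelParams(a=2.0, e=0.8, delta_e=0.8, b=0.8, delta=0.3, theta=0.7,
                        s_f=0.05, tradeoff="care")
        traj = iterate_to_equilibrium(state_from_freqs(0.9, 0.95), p)
        assert traj.final_summary.t2 == pytest.approx(1.0, abs=1e-6)
        rep = classify_stability(traj.final_state, p)
        assert rep.stability is Stability.NEUTRAL_LINE

    def test_rejects_non_fixed_point(self, fig2b_params):
        with pytest.raises(ValueError):
            classify_stability(state_from_freqs(0.5, 0.5), fig2b_params)


class TestBasinSweep:
    GRID = [(p, t) for p in (0.1, 0.5, 0.9) for t in (0.1, 0.5, 0.9)]

    def test_condition_met_all_starts_fix_trait(self, fig2b_params):
        df = basin_sweep(fig2b_params, self.GRID)
        assert (df["outcome"] == "t2_fixed").all()
        assert df["converged"].all()

    def test_condition_violated_outcome_depends_on_start(self, fig2a_params):
        df = basin_sweep(fig2a_params, self.GRID)
        outcomes = set(df["outcome"])
        assert "t2_fixed" in outcomes and "p2_lost" in outcomes

    def test_neutral_parameters_map_to_themselves(self):
        p = ModelParams(a=0.0, delta_e=0.0, delta_theta=0.0)
        df = basin_sweep(p, [(0.3, 0.7)])
        assert df.loc[0, "p2"] == pytest.approx(0.3, abs=1e-9)
        assert df.loc[0, "t2"] == pytest.approx(0.7, abs=1e-9)


class TestRegionMap:
    BASE = ModelParams(a=2.0, e=0.8, b=0.8, theta=0.7, s_f=0.05,
                       delta=0.1, delta_e=0.1, tradeoff="care")

    def test_costly_trait_threshold_splits_grid(self):
        df = region_map(self.BASE, ("delta", (0.0, 0.3), 13),
                        ("delta_e", (0.1, 0.9), 3))
        thr = 0.05 * (1 + 1 / 0.8)  # s_f * (1 + 1/b) = 0.1125
        assert (df.loc[df["delta"] > thr, "costly_trait"]).all()
        assert (~df.loc[df["delta"] < thr, "costly_trait"]).all()

    def test_trait_cannot_evolve_class(self):
        # condition (3) and the internal condition both fail: no trait outcome
        df = region_map(self.BASE, ("delta", (0.02, 0.02), 1),
                        ("delta_e", (0.001, 0.001), 1))
        row = df.iloc[0]
        assert not row["costly_trait"]
        assert row["analytic_class"] in ("trait_cannot_evolve",) or "interior" in row["analytic_class"]

    def test_degenerate_grid_matches_direct_flags(self):
        from matechoice import condition_flags
        df = region_map(self.BASE, ("delta", (0.3, 0.3), 1), ("delta_e", (0.8, 0.8), 1),
                        numeric=True)
        assert len(df) == 1
        from dataclasses import replace
        p = replace(self.BASE, delta=0.3, delta_e=0.8)
        for k, v in condition_flags(p).items():
            assert df.iloc[0][k] == v
        assert df.iloc[0]["origin_stable"] in (True, False)


class TestPaperInvariants:
    def test_guarding_bifurcation_at_condition_boundary(self, fig1_params):
        """Interior polymorphism exists iff the EPC gain beats the paternity loss."""
        from dataclasses import replace
        for delta_e, interior in ((0.3, False), (0.5, True), (0.7, True)):
            p = replace(fig1_params, delta_e=delta_e)
            traj = iterate_to_equilibrium(state_from_freqs(0.5, 0.5), p)
            s = traj.final_summary
            assert condition_guarding(p) is interior
            assert (1e-3 < s.p2 < 1 - 1e-3) is interior

    def test_care_bifurcation_small_initial_preference(self):
        """P2 invades from low frequency iff the care-model condition holds."""
        from dataclasses import replace
        base = ModelParams(a=1.5, e=0.8, theta=0.8, delta=0.1, b=0.8, tradeoff="care")
        for delta_e, grows in ((0.1, False), (0.8, True)):
            p = replace(base, delta_e=delta_e)
            x = state_from_freqs(0.05, 0.5, 0.0)
            s50 = x
            for _ in range(50):
                s50 = step(s50, p)
            assert condition_care(p) is grows
            assert (summarize(s50).p2 > 0.05) is grows

    def test_costly_guarding_always_loses_trait(self, fig1_params):
        from dataclasses import replace
        p = replace(fig1_params, s_f=0.05)
        rng = np.random.default_rng(11)
        for _ in range(5):
            start = state_from_freqs(rng.uniform(0.1, 0.9), rng.uniform(0.1, 0.9))
            traj = iterate_to_equilibrium(start, p)
            assert traj.final_summary.t2 < 1e-6
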