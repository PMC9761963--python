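"""Phase-1 FBA, phase-2 construction, objective reuse and the full FVA loop."""

import numpy as np
import pytest
import scipy.sparse as sp

from fvaprune import (
    FVAConfig,
    InfeasibleModelError,
    MetabolicModel,
    TaskState,
    UnboundedObjectiveError,
    apply_objective_reuse,
    build_phase2,
    conventional_lp_count,
    run_fba,
    run_fva,
    run_fva_nominal,
)
from fvaprune.fva import REMOVED_REUSE, SOLVED, task_order
from .conftest import random_model

V_MAX_EXPECTED = np.array([1e5, 5e4, 1e5, 0.0, 0.0, 1e5, 0.0])


def chain_model(lb, ub, c):
    """v1 = v2 (one metabolite, two reactions) with the given boxes."""
    return MetabolicModel(
        ["M"], ["R1", "R2"], sp.csc_matrix(np.array([[1.0, -1.0]])),
        np.asarray(lb, float), np.asarray(ub, float), np.asarray(c, float),
    )


class TestRunFba:
    def test_example_optimum_is_zero_at_origin(self, example_model):
        sol = run_fba(example_model)
        assert sol.optimal and sol.is_vertex
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(sol.v, np.zeros(7), atol=1e-9)

    def test_zero_objective_gives_zero_optimum(self):
        with pytest.warns(UserWarning, match="all-zero"):
            m = chain_model([0, 0], [10, 10], [0, 0])
        assert run_fba(m).objective_value == pytest.approx(0.0)

    def test_unbounded_objective_aborts_fva(self):
        m = chain_model([0, 0], [np.inf, np.inf], [1, 0])
        with pytest.raises(UnboundedObjectiveError):
            run_fva(m)

    def test_infeasible_model_aborts_fva(self):
        m = chain_model([0, 5], [1, 6], [1, 0])
        with pytest.raises(InfeasibleModelError):
            run_fva(m)


class TestBuildPhase2:
    def test_mu_one_enforces_exact_optimality(self, example_model):
        # with c^T v >= Z0 the objective flux is pinned to its optimum
        with build_phase2(example_model, Z0=0.0, mu=1.0) as s:
            sol = s.solve("max", example_model.objective)
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_example_row_is_redundant_at_mu_09(self, example_model):
        # v4 >= 0.9 * 0 duplicates v4's lower bound: extents are unchanged
        with_row = run_fva_nominal(example_model, mu=0.9)
        np.testing.assert_allclose(with_row.v_max, V_MAX_EXPECTED, atol=1e-6)
        np.testing.assert_allclose(with_row.v_min, np.zeros(7), atol=1e-6)

    def test_negative_z0_row_is_tighter_than_optimum(self):
        # Z0 = -1 (both fluxes forced negative); mu=0.9 demands c'v >= -0.9 > Z0,
        # so the phase-2 polytope is empty and the run must abort explicitly.
        m = chain_model([-5, -5], [-1, -1], [1, 0])
        assert run_fba(m).objective_value == pytest.approx(-1.0)
        with pytest.raises(InfeasibleModelError, match="mu"):
            run_fva(m, FVAConfig(mu=0.9))

    def test_phase1_witness_rejected_when_phase2_infeasible(self):
        # the gating flag alone decides whether inspection may use the witness
        from fvaprune import inspect_solution

        tasks = TaskState(2)
        cfg = FVAConfig(mu=0.9)
        v_star = np.array([-1.0, -1.0])  # attains upper bounds
        inspect_solution(v_star, np.array([-5.0, -5.0]), np.array([-1.0, -1.0]),
                         tasks, cfg, witness_is_phase2_feasible=False)
        assert tasks.n_removed == 0 and tasks.inspect_ops == 0


class TestObjectiveReuse:
    def test_indicator_objective_reuses_phase1(self, example_model):
        tasks = TaskState(7)
        apply_objective_reuse(example_model, Z0=0.0, tasks=tasks, config=FVAConfig())
        assert tasks.status(3, "max") == REMOVED_REUSE
        assert tasks[(3, "max")].witness_value == 0.0
        assert tasks.n_removed == 1

    def test_multi_reaction_objective_is_not_reused(self, example_model):
        m = example_model.copy()
        m.objective = np.array([1.0, 0, 0, 1.0, 0, 0, 0])
        tasks = TaskState(7)
        apply_objective_reuse(m, Z0=0.0, tasks=tasks, config=FVAConfig())
        assert tasks.n_removed == 0

    def test_negative_indicator_reuses_minimum(self):
        # c = -e2 over v1 = v2 with boxes [5,10]: Z0 = max(-v2) = -5,
        # so min v2 = Z0 / (-1) = 5; cross-check by solving that LP
        m = chain_model([5, 5], [10, 10], [0, -1])
        z0 = run_fba(m).objective_value
        assert z0 == pytest.approx(-5.0)
        tasks = TaskState(2)
        apply_objective_reuse(m, Z0=z0, tasks=tasks, config=FVAConfig())
        assert tasks.status(1, "min") == REMOVED_REUSE
        assert tasks[(1, "min")].witness_value == pytest.approx(5.0)
        direct = run_fva_nominal(m, mu=1.0)
        assert direct.v_min[1] == pytest.approx(5.0)


class TestRunFva:
    def test_worked_example_counts_and_extents(self, example_model):
        res = run_fva(example_model, FVAConfig(mu=0.9))
        assert res.Z0 == pytest.approx(0.0, abs=1e-9)
        assert res.lps_solved == 7
        assert res.lps_removed == 8
        np.testing.assert_allclose(res.v_min, np.zeros(7), atol=1e-6)
        np.testing.assert_allclose(res.v_max, V_MAX_EXPECTED, atol=1e-6)
        assert sum(m == "solved" for m in res.method_max) == 4  # upper LPs run
        assert sum(m == "solved" for m in res.method_min) == 2  # lower LPs run
        assert res.method_max[3] == "reused"

    def test_conventional_mode_solves_2n_plus_1(self, example_model):
        cfg = FVAConfig(mu=0.9, enable_inspection=False, enable_objective_reuse=False)
        res = run_fva(example_model, cfg)
        assert res.lps_solved == conventional_lp_count(7) == 15
        assert res.lps_removed == 0

    def test_nominal_equals_pruned_extents(self, example_model):
        pruned = run_fva(example_model, FVAConfig(mu=0.9))
        nominal = run_fva_nominal(example_model, mu=0.9)
        np.testing.assert_allclose(pruned.v_min, nominal.v_min, atol=1e-6)
        np.testing.assert_allclose(pruned.v_max, nominal.v_max, atol=1e-6)

    def test_empty_model_takes_one_lp(self):
        empty = MetabolicModel([], [], sp.csc_matrix((0, 0)),
                               np.zeros(0), np.zeros(0), np.zeros(0))
        res = run_fva_nominal(empty)
        assert res.lps_solved == 1 and res.n == 0

    @pytest.mark.parametrize("order", ["ub-then-lb", "lb-then-ub", "interleaved"])
    def test_task_order_changes_counts_not_extents(self, example_model, order):
        res = run_fva(example_model, FVAConfig(mu=0.9, order=order))
        np.testing.assert_allclose(res.v_min, np.zeros(7), atol=1e-6)
        np.testing.assert_allclose(res.v_max, V_MAX_EXPECTED, atol=1e-6)
        assert res.lps_solved <= conventional_lp_count(7)

    def test_fixed_reactions_removed_without_lps(self):
        m = chain_model([3, 0], [3, 10], [0, 1])  # R1 fixed at 3 (so v2 = 3 too)
        res = run_fva(m)
        assert res.method_min[0] == res.method_max[0] == "fixed"
        assert res.v_min[0] == res.v_max[0] == 3.0
        nominal = run_fva_nominal(m)
        assert nominal.lps_solved == 5
        np.testing.assert_allclose(res.v_min, nominal.v_min, atol=1e-6)
        np.testing.assert_allclose(res.v_max, nominal.v_max, atol=1e-6)

    def test_unbounded_phase2_extent_recorded_as_inf(self):
        # decoupled reaction with an open upper bound: its max extent is +inf
        m = MetabolicModel(
            ["M"], ["R1", "R2", "R3"],
            sp.csc_matrix(np.array([[1.0, -1.0, 0.0]])),
            np.array([0.0, 0.0, 0.0]), np.array([10.0, 10.0, np.inf]),
            np.array([1.0, 0.0, 0.0]),
        )
        res = run_fva(m)
        assert res.v_max[2] == np.inf
        assert res.method_max[2] == "solved"  # an infinite bound is never "attained"
        assert res.lps_solved + res.lps_removed == conventional_lp_count(3)

    @pytest.mark.parametrize("seed", [2, 9, 23, 57])
    def test_accounting_identity_on_random_models(self, seed):
        model = random_model(seed)
        res = run_fva(model, FVAConfig(mu=0.9))
        assert res.lps_solved + res.lps_removed == conventional_lp_count(model.n)
        assert res.lps_solved <= conventional_lp_count(model.n)
        # extents respect the box and min <= max
        assert np.all(res.v_min <= res.v_max + 1e-6)
        assert np.all(res.v_min >= model.lower_bounds - 1e-6)
        assert np.all(res.v_max <= model.upper_bounds + 1e-6)

    def test_strict_reduction_when_n_exceeds_m(self, example_model):
        res = run_fva(example_model, FVAConfig(mu=0.9))
        assert res.lps_solved < conventional_lp_count(example_model.n)

    def test_interval_nesting_in_mu(self):
        # pick a model with Z0 > 0 so tightening mu genuinely shrinks phase 2
        model = next(m for m in map(random_model, range(1, 50))
                     if run_fba(m).objective_value > 1.0)
        loose = run_fva(model, FVAConfig(mu=0.5))
        tight = run_fva(model, FVAConfig(mu=0.9))
        assert np.all(tight.v_min >= loose.v_min - 1e-6)
        assert np.all(tight.v_max <= loose.v_max + 1e-6)

    def test_witness_soundness_spot_check(self, example_model):
        """Re-solving a removed task's LP reproduces the witnessed extent."""
        res = run_fva(example_model, FVAConfig(mu=0.9))
        nominal = run_fva_nominal(example_model, mu=0.9)
        for i in range(7):
            if res.method_max[i] in ("inspected", "reused"):
                assert res.v_max[i] == pytest.approx(nominal.v_max[i], abs=1e-6)
            if res.method_min[i] in ("inspected", "reused"):
                assert res.v_min[i] == pytest.approx(nominal.v_min[i], abs=1e-6)


class TestConfig:
    def test_mu_out_of_range_rejected(self):
        for mu in (0.0, -0.5, 1.5):
            with pytest.raises(ValueError, match="mu"):
                FVAConfig(mu=mu)

    def test_unknown_order_rejected(self):
        with pytest.raises(ValueError, match="order"):
            FVAConfig(order="random")

    def test_task_order_covers_all_tasks_once(self):
        for order in ("ub-then-lb", "lb-then-ub", "interleaved"):
            tasks = task_order(4, order)
            assert len(tasks) == 8 and len(set(tasks)) == 8


def test_task_state_terminal_transitions_are_single():
    tasks = TaskState(2)
    tasks.mark_solved(0, "max")
    assert tasks.status(0, "max") == SOLVED
    with pytest.raises(RuntimeError, match="terminal"):
        tasks.mark_solved(0, "max")
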