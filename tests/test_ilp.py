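from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barcosel import (
    DistanceSpec,
    InfeasibleFixedSetError,
    SelectionProblem,
    SelectionResult,
    SolverOptions,
    build,
    cost,
    solve_problem,
    to_lp,
    verify,
)

from conftest import enumerate_optimum, make_pool, random_pool


class TestBuildStructure:
    def test_counts_for_length_eight(self, set_a):
        st_ = build(SelectionProblem(pool=set_a, n=8))
        assert st_.n_aux_positional == 48
        assert st_.n_positional_balance_constraints == 96
        assert st_.n_aux_global == 4
        assert st_.n_global_balance_constraints == 8
        assert st_.n_balance_constraints == 104

    @pytest.mark.parametrize("L", [1, 2, 6, 8, 12])
    def test_closed_forms_depend_only_on_length(self, L):
        pool = make_pool("A" * L, "C" * L, "G" * L, "T" * L)
        st_ = build(SelectionProblem(pool=pool, n=2, spec=DistanceSpec(min_distance=0)))
        assert st_.n_aux_positional + st_.n_aux_global == 6 * L + 4
        assert st_.n_balance_constraints == 12 * L + 8
        assert st_.n_binary == 4
        assert st_.A_eq.shape[0] == 1  # cardinality only

    def test_pair_and_fixing_constraints_counted(self):
        pool = make_pool("AAAA", "AAAT", "TTTT", "CCGG")
        st_ = build(
            SelectionProblem(
                pool=pool, n=2, spec=DistanceSpec(min_distance=3),
                fixed_indices=frozenset({2}),
            )
        )
        assert st_.pair_constraints == ((0, 1),)
        assert st_.n_fixing_constraints == 1
        assert st_.A_eq.shape[0] == 2

    def test_not_enough_candidates(self, set_a):
        with pytest.raises(ValueError, match="not enough candidates"):
            SelectionProblem(pool=set_a, n=9)

    def test_unknown_fixed_barcode(self, set_a):
        with pytest.raises(ValueError, match="unknown fixed barcode"):
            SelectionProblem(pool=set_a, n=8, fixed_indices=frozenset({99}))

    def test_fixed_conflict_fails_fast_with_named_pair(self):
        pool = make_pool("AAAA", "AAAT", "TTTT")
        problem = SelectionProblem(
            pool=pool, n=2, fixed_indices=frozenset({0, 1}),
            spec=DistanceSpec(min_distance=3),
        )
        with pytest.raises(InfeasibleFixedSetError, match="'b1' and 'b2'"):
            build(problem)

    def test_fixed_conflict_override_drops_pair(self):
        pool = make_pool("AAAA", "AAAT", "TTTT")
        st_ = build(
            SelectionProblem(
                pool=pool, n=2, fixed_indices=frozenset({0, 1}),
                spec=DistanceSpec(min_distance=3), allow_fixed_conflicts=True,
            )
        )
        assert st_.skipped_fixed_pairs == ((0, 1),)
        assert st_.pair_constraints == ()

    def test_lp_export_mentions_all_variable_groups(self, set_a):
        text = to_lp(build(SelectionProblem(pool=set_a, n=4)))
        assert "Minimize" in text and "Binaries" in text
        assert "t_pos1_groupAC" in text and "t_global_T" in text
        assert "x0" in text and "x7" in text


class TestSolve:
    def test_reference_set_full_selection_cost_zero(self, set_a):
        res = solve_problem(SelectionProblem(pool=set_a, n=8))
        assert res.status == "optimal"
        assert res.objective_value == 0
        assert len(res.selected) == 8

    def test_two_close_barcodes_infeasible(self):
        pool = make_pool("AAAA", "AAAT")
        res = solve_problem(SelectionProblem(pool=pool, n=2))
        assert res.status == "infeasible"
        assert res.selected == ()
        assert res.objective_value is None

    def test_objective_matches_exact_recomputation(self, set_a):
        res = solve_problem(SelectionProblem(pool=set_a, n=5))
        assert res.objective_value == cost(res.selected).total
        assert res.solver_objective == pytest.approx(float(res.objective_value), abs=1e-6)

    def test_branch_depth_limit_warns(self, set_a):
        problem = SelectionProblem(
            pool=set_a, n=4,
            solver_options=SolverOptions(branch_depth_limit=5),
        )
        with pytest.warns(UserWarning, match="branch_depth_limit"):
            res = solve_problem(problem)
        assert res.status == "optimal"

    def test_time_limit_must_be_positive(self):
        with pytest.raises(ValueError, match="time_limit"):
            SolverOptions(time_limit=0)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    st.integers(3, 8), st.integers(2, 5), st.integers(1, 4),
    st.integers(0, 3), st.integers(0, 2**31 - 1),
)
def test_oracle_equivalence(M, L, n, d, seed):
    """Solver optimum equals exhaustive enumeration over all C(M, n) subsets."""
    rng = np.random.default_rng(seed)
    pool = random_pool(rng, M, L)
    n = min(n, M)
    spec = DistanceSpec(min_distance=d)
    expected = enumerate_optimum(pool, n, spec)
    res = solve_problem(SelectionProblem(pool=pool, n=n, spec=spec))
    if expected is None:
        assert res.status == "infeasible"
    else:
        assert res.status == "optimal"
        assert res.objective_value == expected


@settings(derandomize=True, max_examples=20, deadline=None)
@given(st.integers(4, 8), st.integers(2, 5), st.integers(2, 4), st.integers(0, 2**31 - 1))
def test_monotone_in_min_distance(M, L, n, seed):
    """Relaxing the distance threshold never worsens the optimum."""
    rng = np.random.default_rng(seed)
    pool = random_pool(rng, M, L)
    n = min(n, M)
    objectives = []
    for d in (3, 2, 1, 0):
        res = solve_problem(SelectionProblem(pool=pool, n=n, spec=DistanceSpec(min_distance=d)))
        objectives.append(None if res.status == "infeasible" else res.objective_value)
    seen = [o for o in objectives if o is not None]
    assert seen == sorted(seen, reverse=True)
    # once feasible, staying feasible as d decreases
    first_feasible = next((i for i, o in enumerate(objectives) if o is not None), None)
    if first_feasible is not None:
        assert all(o is not None for o in objectives[first_feasible:])


class TestAugmentConstraints:
    def test_fixed_set_always_included_and_objective_no_better(self):
        rng = np.random.default_rng(7)
        pool = random_pool(rng, 8, 4)
        spec = DistanceSpec(min_distance=1)
        free = solve_problem(SelectionProblem(pool=pool, n=4, spec=spec))
        fixed = frozenset({0, 3})
        res = solve_problem(
            SelectionProblem(pool=pool, n=4, spec=spec, fixed_indices=fixed)
        )
        assert fixed <= set(res.selected_indices)
        assert res.objective_value >= free.objective_value
        expected = enumerate_optimum(pool, 4, spec, fixed=fixed)
        assert res.objective_value == expected


class TestVerify:
    def test_optimal_result_verifies_ok(self, set_a):
        problem = SelectionProblem(pool=set_a, n=6)
        res = solve_problem(problem)
        verdict = verify(res, problem)
        assert verdict.ok
        assert verdict.violations == ()

    def test_missing_fixed_barcode_flagged(self, set_a):
        problem = SelectionProblem(pool=set_a, n=2, fixed_indices=frozenset({0}))
        fake = SelectionResult(
            status="optimal",
            selected=(set_a[1], set_a[2]),
            selected_indices=(1, 2),
            objective_value=cost([set_a[1], set_a[2]]).total,
            breakdown=None,
        )
        verdict = verify(fake, problem)
        assert not verdict.ok
        assert any("fixing constraint" in v for v in verdict.violations)

    def test_close_pair_flagged(self):
        pool = make_pool("AAAA", "AAAT", "TTTT")
        problem = SelectionProblem(pool=pool, n=2, spec=DistanceSpec(min_distance=3))
        fake = SelectionResult(
            status="optimal",
            selected=(pool[0], pool[1]),  # distance 1 < 3
            selected_indices=(0, 1),
            objective_value=cost([pool[0], pool[1]]).total,
            breakdown=None,
        )
        verdict = verify(fake, problem)
        assert any("distance constraint" in v for v in verdict.violations)

    def test_wrong_cardinality_flagged(self, set_a):
        problem = SelectionProblem(pool=set_a, n=3)
        fake = SelectionResult(
            status="optimal",
            selected=(set_a[0],),
            selected_indices=(0,),
            objective_value=cost([set_a[0]]).total,
            breakdown=None,
        )
        verdict = verify(fake, problem)
        assert any("cardinality constraint" in v for v in verdict.violations)

    def test_objective_mismatch_flagged(self, set_a):
        problem = SelectionProblem(pool=set_a, n=2)
        fake = SelectionResult(
            status="optimal",
            selected=(set_a[0], set_a[2]),
            selected_indices=(0, 2),
            objective_value=Fraction(-1),
            breakdown=None,
        )
        verdict = verify(fake, problem)
        assert any("objective mismatch" in v for v in verdict.violations)
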