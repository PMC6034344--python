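"""Mixed-integer linear program for balance-optimal barcode subset selection.

The selection task — pick n of M candidate barcodes minimizing the
nucleotide-balance cost while keeping every selected pair at least d apart —
is encoded as a MILP:

* one binary indicator x_i per candidate barcode;
* the absolute-value terms of the cost are linearized with continuous
  auxiliary variables, min |e| becoming min t subject to t >= e and
  t >= -e.  Six auxiliaries per barcode position (two laser-group terms,
  four single-nucleotide terms) plus four for global balance: 6L + 4
  auxiliaries and 12L + 8 balance inequalities in total, independent of M;
* one inequality x_j + x_k <= 1 for every pair of candidates closer than
  the minimum distance;
* the cardinality equation sum_i x_i = n, and x_i = 1 for barcodes fixed
  into the solution (augment mode).

Any MILP solver can process this structure; the bundled backend is HiGHS
via :func:`scipy.optimize.milp`.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from . import balance
from .distances import DistanceSpec, forbidden_pairs
from .io import Barcode, CandidatePool

#: Auxiliary-variable labels per barcode position, in variable order.
POSITIONAL_TERMS = ("groupAC", "groupGT", "A", "C", "G", "T")


class InfeasibleFixedSetError(ValueError):
    """The fixed (initial) barcodes already violate the distance threshold."""


class SolverError(RuntimeError):
    """The backend failed or stopped without producing a usable answer."""


@dataclass(frozen=True)
class SolverOptions:
    """Backend controls.

    time_limit : float
        Wall-clock budget in seconds (default 10).  If it is hit, the best
        incumbent found so far is returned.
    branch_depth_limit : int
        Maximum branch-and-bound depth; 0 means unrestricted.  Honored only
        if the backend supports it (HiGHS does not; a warning is issued).
    seed : int | None
        Repeatability hint passed to the backend when supported.
    backend_options : dict
        Opaque pass-through of extra backend parameters.
    """

    time_limit: float = 10.0
    branch_depth_limit: int = 0
    seed: int | None = None
    backend_options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time_limit <= 0:
            raise ValueError("time_limit must be > 0 seconds")


@dataclass(frozen=True)
class SelectionProblem:
    """Everything needed to pose one selection task.

    fixed_indices force candidates into the solution (augment mode).  If two
    fixed barcodes violate the distance threshold the model would be
    trivially infeasible; by default this is rejected up front with the
    offending pair named, unless ``allow_fixed_conflicts`` is set, in which
    case the fixed-fixed pair constraints are dropped and the user proceeds
    knowingly.
    """

    pool: CandidatePool
    n: int
    spec: DistanceSpec = DistanceSpec()
    fixed_indices: frozenset[int] = frozenset()
    solver_options: SolverOptions = SolverOptions()
    allow_fixed_conflicts: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "fixed_indices", frozenset(self.fixed_indices))
        if self.n < 1:
            raise ValueError("subset size n must be >= 1")
        if self.n > self.pool.M:
            raise ValueError(
                f"not enough candidates: requested n={self.n} from a pool of "
                f"M={self.pool.M}"
            )
        for i in self.fixed_indices:
            if not 0 <= i < self.pool.M:
                raise ValueError(f"unknown fixed barcode: index {i} not in pool")
        if len(self.fixed_indices) > self.n:
            raise ValueError(
                f"not enough room: {len(self.fixed_indices)} fixed barcodes "
                f"exceed subset size n={self.n}"
            )


@dataclass(frozen=True)
class IlpStructure:
    """The assembled MILP: variables, constraint matrices, bookkeeping.

    Variable order is the M binaries first, then the 6L positional
    auxiliaries (position-major, :data:`POSITIONAL_TERMS` within each
    position), then the 4 global auxiliaries.
    """

    problem: SelectionProblem
    A_ub: sparse.csr_matrix
    b_ub: np.ndarray
    A_eq: sparse.csr_matrix
    b_eq: np.ndarray
    pair_constraints: tuple[tuple[int, int], ...]
    skipped_fixed_pairs: tuple[tuple[int, int], ...]

    @property
    def n_binary(self) -> int:
        return self.problem.pool.M

    @property
    def n_aux_positional(self) -> int:
        return 6 * self.problem.pool.L

    @property
    def n_aux_global(self) -> int:
        return 4

    @property
    def n_variables(self) -> int:
        return self.n_binary + self.n_aux_positional + self.n_aux_global

    @property
    def n_positional_balance_constraints(self) -> int:
        return 2 * self.n_aux_positional

    @property
    def n_global_balance_constraints(self) -> int:
        return 2 * self.n_aux_global

    @property
    def n_balance_constraints(self) -> int:
        return self.n_positional_balance_constraints + self.n_global_balance_constraints

    @property
    def n_pair_constraints(self) -> int:
        return len(self.pair_constraints)

    @property
    def n_fixing_constraints(self) -> int:
        return len(self.problem.fixed_indices)

    def aux_name(self, k: int) -> str:
        """Human-readable name of auxiliary variable k (0-based)."""
        L = self.problem.pool.L
        if k < 6 * L:
            l, term = divmod(k, 6)
            return f"t_pos{l + 1}_{POSITIONAL_TERMS[term]}"
        return f"t_global_{'ACGT'[k - 6 * L]}"


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of a solve: the chosen barcodes plus diagnostics.

    ``objective_value`` and ``breakdown`` are recomputed independently from
    the selected sequences with exact rational arithmetic; they are None
    when the problem is infeasible.
    """

    status: str  # optimal | feasible_time_limited | infeasible
    selected: tuple[Barcode, ...]
    selected_indices: tuple[int, ...]
    objective_value: Fraction | None
    breakdown: balance.CostBreakdown | None
    message: str = ""
    solver_objective: float | None = None
    wall_time: float = 0.0


@dataclass(frozen=True)
class Verdict:
    ok: bool
    violations: tuple[str, ...]


def build(problem: SelectionProblem) -> IlpStructure:
    """Assemble the MILP structure for a selection problem.

    Balance-constraint counts depend only on barcode length L (6L + 4
    auxiliaries, two inequalities each); pair-exclusion constraints come
    from the all-pairs distance screen.
    """
    pool, n = problem.pool, problem.n
    M, L = pool.M, pool.L
    n_aux = 6 * L + 4
    nvar = M + n_aux

    pairs = sorted(forbidden_pairs(pool, problem.spec))
    fixed = problem.fixed_indices
    conflicts = [(j, k) for j, k in pairs if j in fixed and k in fixed]
    if conflicts:
        if not problem.allow_fixed_conflicts:
            j, k = conflicts[0]
            raise InfeasibleFixedSetError(
                f"fixed barcodes '{pool[j].id}' and '{pool[k].id}' are closer "
                f"than the minimum distance {problem.spec.min_distance}; "
                "drop one or set allow_fixed_conflicts to proceed anyway"
            )
        pairs = [p for p in pairs if p not in set(conflicts)]

    # indicator coefficient rows: which barcodes contribute to each count
    seqs = pool.sequences
    # has[nuc][i] = 1 if barcode i carries nuc at the position in question
    def position_indicator(l: int, nucs: tuple[str, ...]) -> np.ndarray:
        return np.fromiter((1.0 if s[l] in nucs else 0.0 for s in seqs), float, M)

    def global_counts(nuc: str) -> np.ndarray:
        return np.fromiter((float(s.count(nuc)) for s in seqs), float, M)

    rows: list[np.ndarray] = []
    b_ub: list[float] = []

    def add_abs(coeffs: np.ndarray, aux_index: int, target: float) -> None:
        # t >= e  and  t >= -e  for  e = coeffs . x - target
        row = np.zeros(nvar)
        row[:M] = coeffs
        row[M + aux_index] = -1.0
        rows.append(row)
        b_ub.append(target)
        row2 = np.zeros(nvar)
        row2[:M] = -coeffs
        row2[M + aux_index] = -1.0
        rows.append(row2)
        b_ub.append(-target)

    # targets n/2, n/4, n*L/4 are dyadic rationals: exact as binary floats
    for l in range(L):
        base = 6 * l
        add_abs(position_indicator(l, ("A", "C")), base + 0, n / 2)
        add_abs(position_indicator(l, ("G", "T")), base + 1, n / 2)
        for t, nuc in enumerate("ACGT"):
            add_abs(position_indicator(l, (nuc,)), base + 2 + t, n / 4)
    for g, nuc in enumerate("ACGT"):
        add_abs(global_counts(nuc), 6 * L + g, n * L / 4)

    for j, k in pairs:
        row = np.zeros(nvar)
        row[j] = row[k] = 1.0
        rows.append(row)
        b_ub.append(1.0)

    A_ub = sparse.csr_matrix(np.vstack(rows))

    eq_rows = [np.concatenate([np.ones(M), np.zeros(n_aux)])]
    b_eq = [float(n)]
    for i in sorted(fixed):
        row = np.zeros(nvar)
        row[i] = 1.0
        eq_rows.append(row)
        b_eq.append(1.0)
    A_eq = sparse.csr_matrix(np.vstack(eq_rows))

    return IlpStructure(
        problem=problem,
        A_ub=A_ub,
        b_ub=np.asarray(b_ub),
        A_eq=A_eq,
        b_eq=np.asarray(b_eq),
        pair_constraints=tuple(pairs),
        skipped_fixed_pairs=tuple(conflicts) if problem.allow_fixed_conflicts else (),
    )


def solve(structure: IlpStructure, options: SolverOptions | None = None) -> SelectionResult:
    """Run the MILP through the HiGHS backend and re-verify the answer.

    Returns status "optimal" when the solver proves optimality,
    "feasible_time_limited" when the time limit stops the search with an
    incumbent, and "infeasible" when no subset of size n satisfies the
    distance constraints.  The objective and cost breakdown of a feasible
    answer are recomputed from the selected sequences, never trusted from
    the solver's floating-point objective.
    """
    if options is None:
        options = structure.problem.solver_options
    if options.branch_depth_limit:
        warnings.warn(
            "branch_depth_limit is not supported by the HiGHS backend; ignored",
            stacklevel=2,
        )

    M = structure.n_binary
    nvar = structure.n_variables
    c = np.concatenate([np.zeros(M), np.ones(nvar - M)])
    integrality = np.concatenate([np.ones(M), np.zeros(nvar - M)])
    bounds = Bounds(
        lb=np.zeros(nvar),
        ub=np.concatenate([np.ones(M), np.full(nvar - M, np.inf)]),
    )
    constraints = [
        LinearConstraint(structure.A_ub, -np.inf, structure.b_ub),
        LinearConstraint(structure.A_eq, structure.b_eq, structure.b_eq),
    ]
    milp_options = {"time_limit": options.time_limit, **options.backend_options}

    t0 = time.perf_counter()
    res = milp(
        c,
        constraints=constraints,
        integrality=integrality,
        bounds=bounds,
        options=milp_options,
    )
    elapsed = time.perf_counter() - t0

    if res.status == 2:
        return SelectionResult(
            status="infeasible",
            selected=(),
            selected_indices=(),
            objective_value=None,
            breakdown=None,
            message=(
                "no feasible subset: the distance constraints and the "
                f"cardinality n={structure.problem.n} cannot be satisfied "
                "together"
            ),
            wall_time=elapsed,
        )
    if res.x is None:
        raise SolverError(f"solver error: {res.message} (status {res.status})")

    idx = tuple(i for i in range(M) if res.x[i] > 0.5)
    selected = tuple(structure.problem.pool[i] for i in idx)
    breakdown = balance.cost(selected)
    status = "optimal" if res.status == 0 else "feasible_time_limited"
    return SelectionResult(
        status=status,
        selected=selected,
        selected_indices=idx,
        objective_value=breakdown.total,
        breakdown=breakdown,
        message=res.message,
        solver_objective=float(res.fun),
        wall_time=elapsed,
    )


def solve_problem(problem: SelectionProblem) -> SelectionResult:
    """Convenience wrapper: build then solve with the problem's options."""
    return solve(build(problem), problem.solver_options)


def verify(result: SelectionResult, problem: SelectionProblem) -> Verdict:
    """Defensive re-check of a solver answer against the problem contract.

    Recomputes subset size, all pairwise distances, fixed-barcode inclusion
    and the cost, and reports every violation with its constraint family.
    """
    if result.status == "infeasible":
        raise ValueError("cannot verify an infeasible result")
    violations: list[str] = []
    if len(result.selected) != problem.n:
        violations.append(
            f"cardinality constraint: got {len(result.selected)} barcodes, "
            f"expected n={problem.n}"
        )
    spec = problem.spec
    for a in range(len(result.selected)):
        for b in range(a + 1, len(result.selected)):
            d = spec.distance(result.selected[a].seq, result.selected[b].seq)
            if d < spec.min_distance:
                pj, pk = result.selected[a].id, result.selected[b].id
                if (
                    problem.allow_fixed_conflicts
                    and result.selected_indices
                    and result.selected_indices[a] in problem.fixed_indices
                    and result.selected_indices[b] in problem.fixed_indices
                ):
                    continue  # user waived fixed-fixed conflicts
                violations.append(
                    f"distance constraint: pair ('{pj}', '{pk}') at distance "
                    f"{d} < {spec.min_distance}"
                )
    chosen = set(result.selected_indices)
    for i in sorted(problem.fixed_indices):
        if i not in chosen:
            violations.append(
                f"fixing constraint: fixed barcode '{problem.pool[i].id}' missing"
            )
    if result.selected:
        recomputed = balance.cost(result.selected).total
        if result.objective_value != recomputed:
            violations.append(
                f"objective mismatch: reported {result.objective_value}, "
                f"recomputed {recomputed}"
            )
    return Verdict(ok=not violations, violations=tuple(violations))


def to_lp(structure: IlpStructure) -> str:
    """Export the model in CPLEX LP text format for debugging."""
    M = structure.n_binary
    pool = structure.problem.pool

    def vname(j: int) -> str:
        return f"x{j}" if j < M else structure.aux_name(j - M)

    def expr(row: np.ndarray) -> str:
        terms = []
        for j in np.nonzero(row)[0]:
            coef = row[j]
            sign = "+" if coef >= 0 else "-"
            mag = abs(coef)
            coef_s = "" if mag == 1 else f"{mag:g} "
            terms.append(f"{sign} {coef_s}{vname(j)}")
        s = " ".join(terms)
        return s[2:] if s.startswith("+ ") else s

    lines = ["Minimize", " obj: " + " + ".join(
        structure.aux_name(k) for k in range(structure.n_variables - M)
    ), "Subject To"]
    A_ub = structure.A_ub.toarray()
    for r in range(A_ub.shape[0]):
        lines.append(f" c{r + 1}: {expr(A_ub[r])} <= {structure.b_ub[r]:g}")
    A_eq = structure.A_eq.toarray()
    for r in range(A_eq.shape[0]):
        lines.append(
            f" e{r + 1}: {expr(A_eq[r])} = {structure.b_eq[r]:g}"
        )
    lines.append("Binaries")
    lines.append(" " + " ".join(f"x{j}" for j in range(M)))
    lines.append("End")
    _ = pool  # ids available via comments if ever needed
    return "\n".join(lines) + "\n"
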