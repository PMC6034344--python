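"""The three application modes: select, check and augment.

* select — pick the balance-optimal subset of n barcodes from a candidate
  FASTA, subject to the minimum pairwise distance.
* check — diagnose an existing barcode set as-is: minimum pairwise
  distance, every violating pair, cost breakdown and balance table.  No
  optimization runs and the set is never altered; the verdict answers
  questions like whether two libraries' index sets can share a lane.
* augment — extend a committed barcode set: the initial barcodes are fixed
  into the solution and the solver picks the requested number of new ones
  that are distance-compatible and balance-optimal together with them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import pandas as pd

from . import balance
from .distances import DistanceSpec, pair_distances
from .ilp import (
    SelectionProblem,
    SelectionResult,
    SolverOptions,
    solve_problem,
)
from .io import Barcode, CandidatePool, read_fasta, write_fasta

logger = logging.getLogger("barcosel")


@dataclass(frozen=True)
class RunConfig:
    """One run of the tool: mode, inputs, knobs, output paths."""

    mode: str
    candidates_path: str | Path
    n: int | None = None
    initial_path: str | Path | None = None
    metric: str = "hamming"
    min_distance: int = 3
    time_limit: float = 10.0
    branch_depth_limit: int = 0
    allow_fixed_conflicts: bool = False
    backend_options: dict = field(default_factory=dict)
    out_fasta: str | Path | None = None
    report_tsv: str | Path | None = None
    plot_path: str | Path | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("select", "check", "augment"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "select" and self.n is None:
            raise ValueError("select mode requires the subset size n")
        if self.mode == "augment" and self.initial_path is None:
            raise ValueError("augment mode requires an initial barcode set")

    @property
    def spec(self) -> DistanceSpec:
        return DistanceSpec(metric=self.metric, min_distance=self.min_distance)

    @property
    def solver_options(self) -> SolverOptions:
        return SolverOptions(
            time_limit=self.time_limit,
            branch_depth_limit=self.branch_depth_limit,
            backend_options=dict(self.backend_options),
        )


@dataclass(frozen=True)
class CheckReport:
    """Diagnostics of an existing barcode set (check mode)."""

    pool: CandidatePool
    spec: DistanceSpec
    min_distance_observed: int | None  # None when the pool has one barcode
    violating_pairs: tuple[tuple[str, str, int], ...]
    breakdown: balance.CostBreakdown
    table: pd.DataFrame

    @property
    def compatible(self) -> bool:
        return not self.violating_pairs

    def violations_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.violating_pairs, columns=["id_j", "id_k", "distance"]
        )


@dataclass(frozen=True)
class AugmentResult:
    """Augment-mode outcome: the full solution plus what is new in it."""

    result: SelectionResult
    pool: CandidatePool
    initial_ids: tuple[str, ...]
    new_barcodes: tuple[Barcode, ...]


# ---------------------------------------------------------------- library API


def select_pool(
    pool: CandidatePool,
    n: int,
    spec: DistanceSpec = DistanceSpec(),
    options: SolverOptions = SolverOptions(),
) -> SelectionResult:
    """Select the balance-optimal subset of n barcodes from a pool."""
    problem = SelectionProblem(pool=pool, n=n, spec=spec, solver_options=options)
    result = solve_problem(problem)
    _log_run("select", pool, n, spec, result)
    return result


def check_pool(pool: CandidatePool, spec: DistanceSpec = DistanceSpec()) -> CheckReport:
    """Diagnose a barcode set without optimizing or altering it."""
    violating = []
    observed = None
    if pool.M >= 2:
        observed_min = None
        for j, k, d in pair_distances(pool, spec.metric):
            observed_min = d if observed_min is None else min(observed_min, d)
            if d < spec.min_distance:
                violating.append((pool[j].id, pool[k].id, d))
        observed = observed_min
    report = CheckReport(
        pool=pool,
        spec=spec,
        min_distance_observed=observed,
        violating_pairs=tuple(violating),
        breakdown=balance.cost(pool.barcodes),
        table=balance.balance_table(pool.barcodes),
    )
    logger.info(
        "check: M=%d L=%d metric=%s threshold=%d min_observed=%s "
        "violations=%d cost=%s verdict=%s",
        pool.M, pool.L, spec.metric, spec.min_distance, observed,
        len(violating), float(report.breakdown.total),
        "compatible" if report.compatible else "incompatible",
    )
    return report


def augment_pool(
    candidates: CandidatePool,
    initial: CandidatePool,
    n_new: int,
    spec: DistanceSpec = DistanceSpec(),
    options: SolverOptions = SolverOptions(),
    allow_fixed_conflicts: bool = False,
) -> AugmentResult:
    """Extend an existing barcode set with n_new optimally chosen barcodes.

    Initial barcodes are matched to candidates by sequence; those absent
    from the candidate pool are appended to it (the initial set need not be
    a subset of the candidates).  The solve then fixes them in and selects
    |initial| + n_new barcodes in total.  With n_new = 0 this degenerates
    to re-reporting the initial set.
    """
    if n_new < 0:
        raise ValueError("number of new barcodes must be >= 0")
    working = list(candidates.barcodes)
    seq_to_idx: dict[str, int] = {}
    for i, bc in enumerate(working):
        seq_to_idx.setdefault(bc.seq, i)
    ids_in_use = {bc.id for bc in working}

    fixed: set[int] = set()
    for bc in initial:
        if bc.seq in seq_to_idx:
            fixed.add(seq_to_idx[bc.seq])
        else:
            new_id = bc.id
            while new_id in ids_in_use:
                new_id += "_initial"
            appended = Barcode(new_id, bc.seq)
            working.append(appended)
            ids_in_use.add(new_id)
            idx = len(working) - 1
            seq_to_idx[bc.seq] = idx
            fixed.add(idx)

    pool = CandidatePool(tuple(working))
    n_total = len(fixed) + n_new
    problem = SelectionProblem(
        pool=pool,
        n=n_total,
        spec=spec,
        fixed_indices=frozenset(fixed),
        solver_options=options,
        allow_fixed_conflicts=allow_fixed_conflicts,
    )
    result = solve_problem(problem)
    _log_run("augment", pool, n_total, spec, result)
    initial_ids = tuple(pool[i].id for i in sorted(fixed))
    new_barcodes = tuple(
        pool[i] for i in result.selected_indices if i not in fixed
    )
    return AugmentResult(
        result=result, pool=pool, initial_ids=initial_ids, new_barcodes=new_barcodes
    )


# --------------------------------------------------------------- config runs


def select(config: RunConfig) -> SelectionResult:
    """Run select mode from a config; write FASTA / report / plot outputs."""
    pool = read_fasta(config.candidates_path)
    result = select_pool(pool, config.n, config.spec, config.solver_options)
    _write_outputs(result.selected, config, result)
    return result


def check(config: RunConfig) -> CheckReport:
    """Run check mode from a config; write the balance report if asked."""
    pool = read_fasta(config.candidates_path)
    report = check_pool(pool, config.spec)
    if config.report_tsv is not None:
        report.table.to_csv(config.report_tsv, sep="\t", index=False)
    if config.plot_path is not None:
        fig = balance.balance_plot(pool.barcodes)
        fig.savefig(config.plot_path)
    return report


def augment(config: RunConfig) -> AugmentResult:
    """Run augment mode from a config; n is the number of NEW barcodes."""
    candidates = read_fasta(config.candidates_path)
    initial = read_fasta(config.initial_path)
    n_new = config.n if config.n is not None else 0
    outcome = augment_pool(
        candidates,
        initial,
        n_new,
        config.spec,
        config.solver_options,
        config.allow_fixed_conflicts,
    )
    _write_outputs(outcome.result.selected, config, outcome.result)
    return outcome


def run(config: RunConfig):
    """Dispatch on config.mode."""
    return {"select": select, "check": check, "augment": augment}[config.mode](config)


def _write_outputs(selected, config: RunConfig, result: SelectionResult) -> None:
    if result.status == "infeasible" or not selected:
        return
    if config.out_fasta is not None:
        write_fasta(selected, config.out_fasta)
    if config.report_tsv is not None:
        balance.balance_report(selected, destination=config.report_tsv)
    if config.plot_path is not None:
        fig = balance.balance_plot(selected)
        fig.savefig(config.plot_path)


def _log_run(
    mode: str,
    pool: CandidatePool,
    n: int,
    spec: DistanceSpec,
    result: SelectionResult,
) -> None:
    obj = None if result.objective_value is None else float(result.objective_value)
    logger.info(
        "%s: M=%d L=%d n=%d metric=%s threshold=%d status=%s objective=%s "
        "wall_time=%.3fs",
        mode, pool.M, pool.L, n, spec.metric, spec.min_distance,
        result.status, obj, result.wall_time,
    )


def cost_summary(breakdown: balance.CostBreakdown) -> str:
    def fmt(x: Fraction) -> str:
        return str(int(x)) if x.denominator == 1 else f"{float(x):g}"

    return (
        f"cost total={fmt(breakdown.total)} "
        f"(laser-group={fmt(breakdown.positional_group_cost)}, "
        f"per-nucleotide={fmt(breakdown.positional_single_cost)}, "
        f"global={fmt(breakdown.global_cost)})"
    )
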