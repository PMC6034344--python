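from __future__ import annotations

from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest

from barcosel import CandidatePool, Barcode, DistanceSpec, cost
from barcosel import fixtures as fx


def make_pool(*seqs: str, prefix: str = "b") -> CandidatePool:
    return CandidatePool(tuple(Barcode(f"{prefix}{i + 1}", s) for i, s in enumerate(seqs)))


def enumerate_optimum(
    pool: CandidatePool,
    n: int,
    spec: DistanceSpec,
    fixed: frozenset[int] = frozenset(),
) -> Fraction | None:
    """Exhaustive oracle: minimum cost over all feasible C(M, n) subsets.

    Recomputes distances with a naive double loop, independent of the
    package's forbidden-pair screen.  Returns None when no subset of size n
    (containing `fixed`) satisfies the pairwise distance threshold.
    """
    seqs = pool.sequences
    best: Fraction | None = None
    for combo in combinations(range(pool.M), n):
        if not fixed <= set(combo):
            continue
        ok = all(
            spec.distance(seqs[j], seqs[k]) >= spec.min_distance
            for j, k in combinations(combo, 2)
        )
        if not ok:
            continue
        c = cost([seqs[i] for i in combo]).total
        if best is None or c < best:
            best = c
    return best


def random_pool(rng: np.random.Generator, M: int, L: int) -> CandidatePool:
    seqs = set()
    while len(seqs) < M:
        seqs.add("".join(rng.choice(list("ACGT"), size=L)))
    return make_pool(*sorted(seqs))


@pytest.fixture(scope="session")
def reference_sets() -> dict[str, CandidatePool]:
    return fx.reference_sets()


@pytest.fixture(scope="session")
def set_a(reference_sets) -> CandidatePool:
    return reference_sets["A"]


@pytest.fixture(scope="session")
def set_d(reference_sets) -> CandidatePool:
    return reference_sets["D"]
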