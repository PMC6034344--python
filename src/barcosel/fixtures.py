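"""Reference barcode sets and synthetic candidate-pool generation.

Two sources of test data, neither requiring any download:

* :func:`reference_sets` — four published 8-nt barcode sets (8, 12, 16 and
  24 barcodes) that are perfectly balanced at every position and pairwise
  at least three mismatches apart, i.e. cost 0 under the balance model and
  compatible at the default distance threshold;
* :func:`generate` — synthetic pools with a planted cost-zero subset among
  biased decoys, so that selection has a known optimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import balance
from .distances import hamming, min_pairwise_distance
from .io import Barcode, CandidatePool

# Published optimal 8-bp barcode sets: perfectly position-balanced,
# pairwise Hamming distance >= 3 within each set.
SET_A = (
    "AACACATC", "AGAGTGCG", "CCGTATAT", "CTTGGTTG",
    "GAGATAAC", "GTACAGGA", "TCTCGCCT", "TGCTCCGA",
)
SET_B = (
    "AGTTGCTG", "ATAGAGTC", "ATCATTGC", "CAGTTCCA",
    "CATGGAAT", "CGCAAGCT", "GAGATAAC", "GCAGATAA",
    "GGCTCTTG", "TCGCCAGA", "TCTCGCCT", "TTACCGGG",
)
SET_C = (
    "ACACAGGC", "ACTGTTAG", "ATAGAGTC", "ATTAGCTG",
    "CAGTTCCA", "CCGTATAT", "CGCAAGCT", "CTGGCACA",
    "GACACTAA", "GGAGTAGA", "GGCTCTTG", "GGGAGATC",
    "TACTGCAG", "TATCCAGT", "TCTCGCCT", "TTACTGGC",
)
SET_D = (
    "ACACAGGC", "AGCCTACT", "AGTTCCGC", "ATACGGAT",
    "ATGACGAA", "ATGGTCTC", "CAGTTCCA", "CATGTTGA",
    "CCTGAACC", "CGAACTTC", "CTCCGGTT", "CTGAATCA",
    "GAAAGAAG", "GAGATTGT", "GCATCACG", "GCCGAATG",
    "GCTGAAGA", "GGCTCTTG", "TACTGCAG", "TATCTGTG",
    "TCTCGCCT", "TGAGAGAT", "TGCTCCGA", "TTGAGTAC",
)


def _pool(prefix: str, seqs: tuple[str, ...]) -> CandidatePool:
    width = len(str(len(seqs)))
    return CandidatePool(
        tuple(
            Barcode(f"{prefix}{i + 1:0{width}d}", s) for i, s in enumerate(seqs)
        )
    )


def reference_sets() -> dict[str, CandidatePool]:
    """The four published reference sets as pools keyed "A".."D"."""
    return {
        "A": _pool("A", SET_A),
        "B": _pool("B", SET_B),
        "C": _pool("C", SET_C),
        "D": _pool("D", SET_D),
    }


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic candidate pool.

    M, L : pool size and barcode length.
    planted_n : size of the planted cost-zero subset (must be a multiple of
        4) or None for a pool with no planted structure.
    min_distance : Hamming distance the planted subset must satisfy
        pairwise (the decoys are unconstrained, as in real candidate lists).
    decoy_bias : in [0, 1); skews decoy composition toward A so that adding
        a decoy to the planted subset worsens balance.  0 means uniform.
    seed : RNG seed; the same spec and seed always produce the same pool.
    """

    M: int = 32
    L: int = 8
    planted_n: int | None = 8
    min_distance: int = 3
    decoy_bias: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_n is not None:
            if self.planted_n % 4 != 0 or self.planted_n < 4:
                raise ValueError("planted_n must be a positive multiple of 4")
            if self.planted_n > self.M:
                raise ValueError("planted_n cannot exceed pool size M")
        if not 0 <= self.decoy_bias < 1:
            raise ValueError("decoy_bias must be in [0, 1)")


def _plant_balanced(
    rng: np.random.Generator, n: int, L: int, min_distance: int, max_tries: int
) -> list[str] | None:
    """Column-wise balanced construction with pairwise-distance rejection.

    Each position gets a random permutation of the multiset
    {A, C, G, T} * (n/4), so every column is perfectly balanced by
    construction; candidates are rejected until all pairwise Hamming
    distances reach min_distance.
    """
    column_pool = np.array(list("ACGT" * (n // 4)))
    for _ in range(max_tries):
        cols = [rng.permutation(column_pool) for _ in range(L)]
        seqs = ["".join(cols[l][i] for l in range(L)) for i in range(n)]
        if all(
            hamming(seqs[a], seqs[b]) >= min_distance
            for a in range(n)
            for b in range(a + 1, n)
        ):
            return seqs
    return None


def generate(spec: FixtureSpec) -> tuple[CandidatePool, tuple[str, ...]]:
    """Generate a candidate pool; returns (pool, ids of the planted subset).

    The planted subset is verified post hoc — cost exactly zero and minimum
    pairwise Hamming distance >= spec.min_distance — before being returned;
    construction alone is never trusted.  Decoys are sampled with an
    A-skewed composition and de-duplicated so pool validation stays quiet.

    Raises ValueError ("cannot plant subset") when the requested structure
    is combinatorially too tight, e.g. more balanced far-apart sequences
    than the sequence space supports.
    """
    rng = np.random.default_rng(spec.seed)
    planted: list[str] = []
    if spec.planted_n is not None:
        got = _plant_balanced(rng, spec.planted_n, spec.L, spec.min_distance, 500)
        if got is None:
            raise ValueError(
                f"cannot plant subset: no {spec.planted_n} sequences of length "
                f"{spec.L} at pairwise distance >= {spec.min_distance} found in "
                "500 attempts; lower planted_n or min_distance, or raise L"
            )
        planted = got
        # self-check: never trust construction alone
        assert balance.cost(planted).total == 0
        mpd = min_pairwise_distance(_pool("p", tuple(planted)), "hamming")
        assert mpd >= spec.min_distance

    b = spec.decoy_bias
    probs = np.array([1 + 3 * b, 1 - b, 1 - b, 1 - b]) / 4.0
    nucs = np.array(list("ACGT"))
    seen = set(planted)
    decoys: list[str] = []
    while len(decoys) < spec.M - len(planted):
        s = "".join(rng.choice(nucs, size=spec.L, p=probs))
        if s not in seen:
            seen.add(s)
            decoys.append(s)

    seqs = planted + decoys
    order = rng.permutation(len(seqs))
    width = len(str(spec.M))
    barcodes = tuple(
        Barcode(f"bc{i + 1:0{width}d}", seqs[order[i]]) for i in range(len(seqs))
    )
    pool = CandidatePool(barcodes)
    planted_set = set(planted)
    planted_ids = tuple(bc.id for bc in barcodes if bc.seq in planted_set)
    return pool, planted_ids
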