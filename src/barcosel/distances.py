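"""Pairwise barcode distances and minimum-distance constraint screening.

Demultiplexing tolerates up to m substitution errors per read index when
every barcode pair is at least 2m+1 apart; the default minimum distance of
3 therefore tolerates one sequencing error.  Two metrics are supported:
Hamming (gapless mismatch count) and Levenshtein (edit distance counting
substitutions, insertions and deletions).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .io import CandidatePool

METRICS = ("hamming", "levenshtein")


@dataclass(frozen=True)
class DistanceSpec:
    """Distance metric plus the minimum pairwise distance required.

    Parameters
    ----------
    metric : {"hamming", "levenshtein"}
    min_distance : int
        Threshold d; a pair at distance < d is forbidden from co-occurring
        in a selected set.  Default 3.
    """

    metric: str = "hamming"
    min_distance: int = 3

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}; choose from {METRICS}")
        if self.min_distance < 0:
            raise ValueError("min_distance must be >= 0")

    @property
    def tolerated_mismatches(self) -> int:
        """Number m of correctable substitution errors: floor((d-1)/2).

        The 2m+1 guarantee is stated for Hamming distance; for Levenshtein
        mode this is a heuristic figure only.
        """
        return max(0, (self.min_distance - 1) // 2)

    def distance(self, a: str, b: str) -> int:
        return hamming(a, b) if self.metric == "hamming" else levenshtein(a, b)


def hamming(a: str, b: str) -> int:
    """Number of mismatching positions between equal-length sequences."""
    if len(a) != len(b):
        raise ValueError(
            f"length mismatch: hamming distance needs equal lengths "
            f"({len(a)} vs {len(b)})"
        )
    return sum(x != y for x, y in zip(a, b))


def levenshtein(a: str, b: str) -> int:
    """Edit distance: minimum substitutions + insertions + deletions.

    Plain global edit distance over the full sequences; no free end gaps.
    With fixed-length index reads this can be optimistic about real
    demultiplexing behaviour (an indel shifts all downstream cycles).
    """
    if len(a) < len(b):
        a, b = b, a
    # single-row DP; O(len(a)*len(b)) time, O(len(b)) space
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def forbidden_pairs(pool: CandidatePool, spec: DistanceSpec) -> set[tuple[int, int]]:
    """Index pairs (j, k), j < k, whose distance is below the threshold.

    These are exactly the pairs that must not co-occur in a selected set.
    All M(M-1)/2 pairs are examined.
    """
    seqs = pool.sequences
    out: set[tuple[int, int]] = set()
    for j in range(len(seqs)):
        for k in range(j + 1, len(seqs)):
            if spec.distance(seqs[j], seqs[k]) < spec.min_distance:
                out.add((j, k))
    return out


def min_pairwise_distance(pool: CandidatePool, metric: str = "hamming") -> int:
    """Minimum distance over all unordered barcode pairs in the pool."""
    if pool.M < 2:
        raise ValueError("need at least two barcodes to compute pairwise distances")
    spec = DistanceSpec(metric=metric, min_distance=0)
    seqs = pool.sequences
    return min(
        spec.distance(seqs[j], seqs[k])
        for j in range(len(seqs))
        for k in range(j + 1, len(seqs))
    )


def pair_distances(pool: CandidatePool, metric: str = "hamming") -> Iterable[tuple[int, int, int]]:
    """Yield (j, k, distance) for every unordered pair, j < k."""
    spec = DistanceSpec(metric=metric, min_distance=0)
    seqs = pool.sequences
    for j in range(len(seqs)):
        for k in range(j + 1, len(seqs)):
            yield j, k, spec.distance(seqs[j], seqs[k])
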