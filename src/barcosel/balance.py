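"""Nucleotide-balance cost of a barcode set, with per-position diagnostics.

On two-laser Illumina chemistry the red laser reads A/C and the green laser
reads G/T, so at every sequencing cycle each laser group should light up in
about half of the clusters, and ideally each of the four nucleotides appears
in a quarter of the barcodes.  The cost of a subset of n barcodes of length
L sums, over positions l = 1..L, the absolute deviations

    |n_l^{A} + n_l^{C} - n/2| + |n_l^{G} + n_l^{T} - n/2|
    + |n_l^{A} - n/4| + |n_l^{C} - n/4| + |n_l^{G} - n/4| + |n_l^{T} - n/4|

plus four global terms |N^{X} - nL/4| (X in {A, C, G, T}) where N^{X} counts
nucleotide X over all positions.  The group terms matter when perfect
four-way balance is unattainable (n not a multiple of 4): they pull the
solution toward A/C vs G/T balance, which the basecaller needs most.

All targets (n/2, n/4, nL/4) are handled as exact rationals so that
"cost == 0" is an exact statement, never an epsilon comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd

from .io import Barcode

if TYPE_CHECKING:  # pragma: no cover
    import matplotlib.figure

NUCLEOTIDES = "ACGT"
#: Laser detection groups on two-channel Illumina chemistry.
LASER_GROUPS = (("A", "C"), ("G", "T"))


@dataclass(frozen=True)
class BalanceProfile:
    """Exact nucleotide counts for a subset of n barcodes of length L.

    Attributes
    ----------
    position_counts : (L, 4) int array
        Row l gives (n_l^A, n_l^C, n_l^G, n_l^T): how many of the n
        barcodes carry each nucleotide at position l.  Rows sum to n.
    global_counts : (4,) int array
        Totals over all positions; sums to n * L.
    """

    position_counts: np.ndarray
    global_counts: np.ndarray
    n: int
    L: int

    def __post_init__(self) -> None:
        assert self.position_counts.shape == (self.L, 4)
        assert (self.position_counts.sum(axis=1) == self.n).all()
        assert (self.global_counts == self.position_counts.sum(axis=0)).all()


@dataclass(frozen=True)
class CostBreakdown:
    """The three parts of the balance cost, as exact rationals.

    ``positional_group_cost`` covers the two laser-group terms per position,
    ``positional_single_cost`` the four per-nucleotide terms per position,
    ``global_cost`` the four whole-barcode terms.  ``total`` is their sum.
    Parts can be fractional when n is not divisible by 2 or 4.
    """

    positional_group_cost: Fraction
    positional_single_cost: Fraction
    global_cost: Fraction

    @property
    def total(self) -> Fraction:
        return self.positional_group_cost + self.positional_single_cost + self.global_cost


def _as_sequences(subset: Iterable[Barcode | str]) -> list[str]:
    seqs = [bc.seq if isinstance(bc, Barcode) else str(bc) for bc in subset]
    if not seqs:
        raise ValueError("empty set: balance is undefined for zero barcodes")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("length mismatch: balance needs equal-length barcodes")
    return seqs


def profile(subset: Iterable[Barcode | str]) -> BalanceProfile:
    """Count nucleotides per position and globally for a barcode subset."""
    seqs = _as_sequences(subset)
    n, L = len(seqs), len(seqs[0])
    counts = np.zeros((L, 4), dtype=int)
    idx = {nuc: i for i, nuc in enumerate(NUCLEOTIDES)}
    for s in seqs:
        for l, ch in enumerate(s):
            counts[l, idx[ch]] += 1
    return BalanceProfile(
        position_counts=counts, global_counts=counts.sum(axis=0), n=n, L=L
    )


def cost(subset: Iterable[Barcode | str]) -> CostBreakdown:
    """Evaluate the balance cost of a subset, exactly.

    Zero if and only if every position carries exactly n/4 of each
    nucleotide, which requires n to be a multiple of four.
    """
    prof = profile(subset)
    return cost_of_profile(prof)


def cost_of_profile(prof: BalanceProfile) -> CostBreakdown:
    n, L = prof.n, prof.L
    half = Fraction(n, 2)
    quarter = Fraction(n, 4)
    gtarget = Fraction(n * L, 4)

    group = Fraction(0)
    single = Fraction(0)
    for l in range(L):
        nA, nC, nG, nT = (int(c) for c in prof.position_counts[l])
        group += abs(nA + nC - half) + abs(nG + nT - half)
        for c in (nA, nC, nG, nT):
            single += abs(c - quarter)
    glob = sum((abs(int(c) - gtarget) for c in prof.global_counts), Fraction(0))
    return CostBreakdown(
        positional_group_cost=group,
        positional_single_cost=single,
        global_cost=glob,
    )


def balance_table(subset: Iterable[Barcode | str]) -> pd.DataFrame:
    """Per-position counts and fractions, plus a "total" row.

    Columns: position, count_A..count_T, frac_A..frac_T.  The "total" row
    aggregates over the whole barcode length; fraction rows sum to 1.
    """
    prof = profile(subset)
    rows = []
    for l in range(prof.L):
        counts = prof.position_counts[l]
        rows.append([l + 1, *counts, *(counts / prof.n)])
    g = prof.global_counts
    rows.append(["total", *g, *(g / (prof.n * prof.L))])
    cols = (
        ["position"]
        + [f"count_{x}" for x in NUCLEOTIDES]
        + [f"frac_{x}" for x in NUCLEOTIDES]
    )
    return pd.DataFrame(rows, columns=cols)


def balance_report(
    subset: Sequence[Barcode | str],
    destination=None,
    plot_path: str | None = None,
) -> pd.DataFrame:
    """Write the balance table as TSV and, optionally, a stacked-bar plot.

    The plot shows per-position nucleotide composition with a separate
    "total" column, mirroring the standard balance diagnostic for index
    sets.  The TSV is the canonical output; the image is a convenience.
    """
    table = balance_table(subset)
    if destination is not None:
        table.to_csv(destination, sep="\t", index=False)
    if plot_path is not None:
        fig = balance_plot(subset)
        fig.savefig(plot_path)
        import matplotlib.pyplot as plt

        plt.close(fig)
    return table


def balance_plot(subset: Sequence[Barcode | str]) -> "matplotlib.figure.Figure":
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    prof = profile(subset)
    fracs = prof.position_counts / prof.n
    total = prof.global_counts / (prof.n * prof.L)
    data = np.vstack([fracs, total])
    labels = [str(l + 1) for l in range(prof.L)] + ["total"]
    colors = {"A": "#2ca02c", "C": "#1f77b4", "G": "#7f7f7f", "T": "#d62728"}

    fig, ax = plt.subplots(figsize=(max(4.0, 0.5 * len(labels)), 3.2))
    bottom = np.zeros(len(labels))
    for i, nuc in enumerate(NUCLEOTIDES):
        ax.bar(labels, data[:, i], bottom=bottom, label=nuc, color=colors[nuc])
        bottom += data[:, i]
    ax.axhline(0.5, color="k", lw=0.8, ls="--")
    ax.set_xlabel("barcode position")
    ax.set_ylabel("nucleotide fraction")
    ax.set_ylim(0, 1)
    ax.legend(ncols=4, loc="upper center", bbox_to_anchor=(0.5, 1.18), frameon=False)
    fig.tight_layout()
    return fig
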