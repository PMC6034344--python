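"""Reading, writing and validation of barcode sets in FASTA format.

A barcode is a short fixed-length DNA tag over {A, C, G, T} used to label
samples in a multiplexed sequencing run.  A candidate pool is an ordered
collection of equal-length barcodes from which subsets are selected.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Union

from Bio import SeqIO

ALPHABET = frozenset("ACGT")

PathOrHandle = Union[str, Path, IO[str]]


class FastaFormatError(ValueError):
    """Raised when a FASTA input cannot be validated into a candidate pool."""


@dataclass(frozen=True)
class Barcode:
    """A single barcode: a non-empty identifier and a DNA sequence.

    The sequence is normalized to upper case; only A/C/G/T are permitted.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaFormatError("invalid identifier: empty id")
        object.__setattr__(self, "seq", self.seq.upper())
        for pos, ch in enumerate(self.seq, start=1):
            if ch not in ALPHABET:
                raise FastaFormatError(
                    f"invalid alphabet: record '{self.id}' has character "
                    f"{ch!r} at position {pos} (only A, C, G, T allowed)"
                )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class CandidatePool:
    """An ordered pool of equal-length barcodes.

    Attributes
    ----------
    barcodes : tuple of Barcode
        Members in input order.
    """

    barcodes: tuple[Barcode, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.barcodes:
            raise FastaFormatError("no records: a pool needs at least one barcode")
        object.__setattr__(self, "barcodes", tuple(self.barcodes))
        first = self.barcodes[0]
        seen_ids: set[str] = set()
        seen_seqs: dict[str, str] = {}
        for bc in self.barcodes:
            if len(bc) != len(first):
                raise FastaFormatError(
                    f"length mismatch: record '{bc.id}' has length {len(bc)}, "
                    f"expected {len(first)} (as in '{first.id}')"
                )
            if bc.id in seen_ids:
                raise FastaFormatError(f"duplicate identifier: '{bc.id}'")
            seen_ids.add(bc.id)
            if bc.seq in seen_seqs:
                warnings.warn(
                    f"duplicate sequence {bc.seq} shared by records "
                    f"'{seen_seqs[bc.seq]}' and '{bc.id}'; any distance "
                    "threshold >= 1 will exclude one of them from a selection",
                    stacklevel=3,
                )
            else:
                seen_seqs[bc.seq] = bc.id

    @property
    def M(self) -> int:
        """Pool size (number of candidate barcodes)."""
        return len(self.barcodes)

    @property
    def L(self) -> int:
        """Common barcode length in nucleotides."""
        return len(self.barcodes[0])

    @property
    def sequences(self) -> tuple[str, ...]:
        return tuple(bc.seq for bc in self.barcodes)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(bc.id for bc in self.barcodes)

    def __len__(self) -> int:
        return self.M

    def __iter__(self):
        return iter(self.barcodes)

    def __getitem__(self, i: int) -> Barcode:
        return self.barcodes[i]


def read_fasta(source: PathOrHandle) -> CandidatePool:
    """Parse a FASTA file (or open text handle) into a validated pool.

    Sequences are upper-cased; records are kept in file order; multi-line
    (wrapped) sequences are supported.  Raises :class:`FastaFormatError` for
    empty input, unequal lengths, non-ACGT characters or duplicate ids.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            records = list(SeqIO.parse(fh, "fasta"))
    else:
        records = list(SeqIO.parse(source, "fasta"))
    if not records:
        raise FastaFormatError("no records: input FASTA is empty")
    return CandidatePool(tuple(Barcode(rec.id, str(rec.seq)) for rec in records))


def read_fasta_str(text: str) -> CandidatePool:
    """Parse FASTA given directly as a string."""
    return read_fasta(_io.StringIO(text))


def write_fasta(barcodes: Iterable[Barcode], destination: PathOrHandle | None = None) -> str:
    """Write barcodes as FASTA text; optionally also to a path or handle.

    Returns the FASTA text.  Round-trips through :func:`read_fasta` to an
    equal pool.  Raises :class:`FastaFormatError` on an empty collection.
    """
    barcodes = list(barcodes)
    if not barcodes:
        raise FastaFormatError("nothing to write: empty barcode collection")
    text = "".join(f">{bc.id}\n{bc.seq}\n" for bc in barcodes)
    if destination is not None:
        if isinstance(destination, (str, Path)):
            with open(destination, "w") as fh:
                fh.write(text)
        else:
            destination.write(text)
    return text
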