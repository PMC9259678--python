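"""Assembly FASTA I/O and per-stage quality statistics.

The pipeline's unit of data is the *transfrag*: a nucleotide sequence
reconstructed by a de novo assembler, which may represent a full transcript,
a partial one, or an artifact.  This module reads and writes assembly FASTA
files with strict alphabet validation and computes the quality statistics
reported at every pipeline stage (transcript count, GC%, median contig
length, N50, total bases).
"""

from __future__ import annotations

import json
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

from .errors import InputError, ValidationError

_VALID_BASES = frozenset("ACGTN")


@dataclass
class SequenceRecord:
    """A single nucleotide transfrag.

    ``bases`` is uppercase over {A,C,G,T,N}; ``source_assembly`` labels the
    assembler run the record came from (empty when unknown).
    """

    id: str
    bases: str
    description: str = ""
    source_assembly: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sequence record has an empty id")
        self.bases = self.bases.upper()
        if not self.bases:
            raise ValidationError(f"sequence {self.id!r} has an empty body")
        bad = set(self.bases) - _VALID_BASES
        if bad:
            raise ValidationError(
                f"sequence {self.id!r} contains characters outside ACGTN: "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class AssemblySet:
    """An ordered, id-unique collection of :class:`SequenceRecord`.

    Iteration order is the ingest order; no operation in the toolkit
    depends on hashing or storage internals for ordering.
    """

    label: str = ""
    records: list[SequenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index: dict[str, SequenceRecord] = {}
        for rec in self.records:
            if rec.id in self._index:
                raise ValidationError(f"duplicate sequence id {rec.id!r}")
            self._index[rec.id] = rec

    def add(self, rec: SequenceRecord) -> None:
        if rec.id in self._index:
            raise ValidationError(f"duplicate sequence id {rec.id!r}")
        self.records.append(rec)
        self._index[rec.id] = rec

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, rec_id: str) -> bool:
        return rec_id in self._index

    def get(self, rec_id: str) -> SequenceRecord:
        try:
            return self._index[rec_id]
        except KeyError:
            raise ValidationError(f"unknown sequence id {rec_id!r}") from None

    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]

    def subset(self, keep_ids: Iterable[str], label: str | None = None) -> "AssemblySet":
        """Sub-assembly of ``keep_ids``, in this set's ingest order."""
        keep = set(keep_ids)
        missing = keep - set(self._index)
        if missing:
            raise ValidationError(f"unknown sequence ids: {sorted(missing)[:5]}")
        return AssemblySet(
            label=self.label if label is None else label,
            records=[rec for rec in self.records if rec.id in keep],
        )


@dataclass(frozen=True)
class AssemblyStats:
    """Whole-assembly quality summary (the per-stage QC row)."""

    n_transcripts: int
    gc_percent: float
    median_length: float
    n50: int
    total_bases: int

    def to_dict(self) -> dict:
        return {
            "n_transcripts": self.n_transcripts,
            "gc_percent": self.gc_percent,
            "median_length": self.median_length,
            "n50": self.n50,
            "total_bases": self.total_bases,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


def read_fasta(path: str | Path, label: str = "", source_assembly: str = "") -> AssemblySet:
    """Read a (wrapped or single-line) FASTA file into an :class:`AssemblySet`.

    The header token before the first whitespace becomes the record id, the
    remainder the description.  Lowercase bases are uppercased; characters
    outside {A,C,G,T,N} raise :class:`ValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"FASTA file not found: {path}")
    assembly = AssemblySet(label=label or path.stem)
    src = source_assembly or assembly.label
    for entry in SeqIO.parse(str(path), "fasta"):
        assembly.add(
            SequenceRecord(
                id=entry.id,
                bases=str(entry.seq),
                description=entry.description[len(entry.id):].strip(),
                source_assembly=src,
            )
        )
    return assembly


def write_fasta(assembly: AssemblySet | Iterable[SequenceRecord], path: str | Path,
                line_width: int = 60) -> Path:
    """Write records as FASTA, wrapping sequence lines at ``line_width``.

    Round-trips losslessly through :func:`read_fasta` (ids, descriptions
    and bases).  An empty assembly produces an empty file.
    """
    if line_width < 1:
        raise ValidationError("line_width must be >= 1")
    path = Path(path)
    with open(path, "w") as fh:
        for rec in assembly:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.bases), line_width):
                fh.write(rec.bases[i:i + line_width] + "\n")
    return path


def compute_n50(lengths: Sequence[int]) -> int:
    """N50: the length L such that sequences of length >= L hold at least
    half of the total bases (descending cumulative sums, threshold >=)."""
    if not lengths:
        raise ValidationError("N50 of an empty length set is undefined")
    if any(x <= 0 for x in lengths):
        raise ValidationError("lengths must be positive")
    total = sum(lengths)
    half = total / 2
    acc = 0
    for length in sorted(lengths, reverse=True):
        acc += length
        if acc >= half:
            return length
    raise AssertionError("unreachable")  # pragma: no cover


def compute_stats(assembly: AssemblySet | Iterable[SequenceRecord]) -> AssemblyStats:
    """Compute the five stage-QC statistics for an assembly.

    GC% counts G+C over A+C+G+T only: N bases are excluded from both
    numerator and denominator, the usual assembly-QC convention.
    """
    records = list(assembly)
    if not records:
        raise ValidationError("cannot compute statistics of an empty assembly")
    lengths = [len(rec) for rec in records]
    gc = at = 0
    for rec in records:
        b = rec.bases
        gc += b.count("G") + b.count("C")
        at += b.count("A") + b.count("T")
    if gc + at == 0:
        raise ValidationError("assembly contains only N bases; GC% undefined")
    return AssemblyStats(
        n_transcripts=len(records),
        gc_percent=100.0 * gc / (gc + at),
        median_length=float(statistics.median(lengths)),
        n50=compute_n50(lengths),
        total_bases=sum(lengths),
    )
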