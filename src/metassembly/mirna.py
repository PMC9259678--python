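"""miRNA-precursor candidate screening.

Combines two signals: an externally computed hairpin score per transcript
(HHMMiR convention — lower is more hairpin-like) and an internally computed
match to a known mature miRNA.  A transcript is a precursor candidate iff
its hairpin score is at or below ``score_max`` (default 0.71) *and* it
carries at least one full-length, ungapped placement of a mature sequence
with at most ``max_mismatch`` substitutions (default 2), on either strand.

At mature-miRNA lengths (~22 nt) a gapped alignment with at most two
mismatches is effectively a full-length ungapped match, so matching is
implemented as an exhaustive Hamming scan — exact and easily audited.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from ._align import revcomp
from .errors import InputError, ValidationError
from .seqio import AssemblySet

_RNA_OK = frozenset("ACGUTN")


@dataclass
class HairpinScoreTable:
    """transcript id -> hairpin score (lower = more hairpin-like)."""

    scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tid, score in self.scores.items():
            if not np.isfinite(score):
                raise ValidationError(f"non-finite hairpin score for {tid!r}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HairpinScoreTable":
        """Two-column TSV ``transcript_id<TAB>score``; an optional header
        row (non-numeric second field) and ``#`` comments are skipped."""
        path = Path(path)
        if not path.exists():
            raise InputError(f"score table not found: {path}")
        scores: dict[str, float] = {}
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ValidationError(f"{path}: line {lineno}: expected 2 columns")
            try:
                score = float(parts[1])
            except ValueError:
                if lineno == 1:
                    continue  # header row
                raise ValidationError(
                    f"{path}: line {lineno}: non-numeric score {parts[1]!r}"
                ) from None
            scores[parts[0]] = score
        return cls(scores=scores)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("transcript_id\tscore\n")
            for tid, score in self.scores.items():
                fh.write(f"{tid}\t{score}\n")
        return path


@dataclass(frozen=True)
class MatureMatch:
    """A full-length ungapped placement of a mature sequence on a transcript.

    ``start`` is the leftmost coordinate of the matched window on the
    transcript's forward strand, for both strands.
    """

    transcript_id: str
    mature_id: str
    start: int
    strand: str  # "forward" | "reverse"
    mismatches: int


@dataclass
class PrecursorCandidate:
    transcript_id: str
    score: float
    matches: list[MatureMatch] = field(default_factory=list)


def load_mature_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a mature-miRNA FASTA (RNA alphabet permitted): U is normalised
    to T and sequences uppercased; characters outside AUCGT/N are rejected."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"mature FASTA not found: {path}")
    matures: list[tuple[str, str]] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        bad = set(seq) - _RNA_OK
        if bad:
            raise ValidationError(
                f"mature sequence {entry.id!r} contains invalid characters: "
                f"{sorted(bad)}"
            )
        matures.append((entry.id, seq.replace("U", "T")))
    return matures


def _scan_one(bases: np.ndarray, mature: np.ndarray, max_mismatch: int) -> list[tuple[int, int]]:
    """(offset, mismatches) of every window of ``bases`` within Hamming
    distance ``max_mismatch`` of ``mature`` (both as uint8 arrays)."""
    m = mature.size
    if m > bases.size:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(bases, m)
    mism = (windows != mature).sum(axis=1)
    return [(int(i), int(mism[i])) for i in np.nonzero(mism <= max_mismatch)[0]]


def match_mature(assembly: AssemblySet, matures: Sequence[tuple[str, str]],
                 max_mismatch: int = 2) -> list[MatureMatch]:
    """All full-length ungapped placements of each mature on each transcript
    (both strands) with at most ``max_mismatch`` substitutions.

    A mature longer than a transcript is silently skipped for that pair.
    Output ordered by (transcript, mature, start, strand).
    """
    if max_mismatch < 0:
        raise ValidationError("max_mismatch must be >= 0")
    mature_arrays = [
        (mid, np.frombuffer(seq.encode(), dtype=np.uint8)) for mid, seq in matures
    ]
    out: list[MatureMatch] = []
    for rec in assembly:
        fwd = np.frombuffer(rec.bases.encode(), dtype=np.uint8)
        rev = np.frombuffer(revcomp(rec.bases).encode(), dtype=np.uint8)
        n = len(rec.bases)
        for mid, arr in mature_arrays:
            for offset, mism in _scan_one(fwd, arr, max_mismatch):
                out.append(MatureMatch(rec.id, mid, offset, "forward", mism))
            for offset, mism in _scan_one(rev, arr, max_mismatch):
                # leftmost forward-strand coordinate of the matched window
                out.append(
                    MatureMatch(rec.id, mid, n - offset - arr.size, "reverse", mism)
                )
    out.sort(key=lambda m: (m.transcript_id, m.mature_id, m.start, m.strand))
    return out


def call_candidates(scores: HairpinScoreTable,
                    matches: Iterable[MatureMatch],
                    score_max: float = 0.71) -> list[PrecursorCandidate]:
    """Precursor candidates: hairpin score <= ``score_max`` (inclusive)
    AND at least one mature match.  Transcripts absent from the score table
    are never candidates.  Each candidate carries all its matches."""
    if not np.isfinite(score_max):
        raise ValidationError("score_max must be finite")
    by_transcript: dict[str, list[MatureMatch]] = {}
    for match in matches:
        by_transcript.setdefault(match.transcript_id, []).append(match)
    out: list[PrecursorCandidate] = []
    for tid in sorted(by_transcript):
        score = scores.scores.get(tid)
        if score is None or score > score_max:
            continue
        out.append(PrecursorCandidate(tid, score, by_transcript[tid]))
    return out


def write_candidates(candidates: Sequence[PrecursorCandidate],
                     tsv_path: str | Path,
                     json_path: str | Path | None = None) -> Path:
    """Candidates TSV (+ optional JSON summary)."""
    tsv_path = Path(tsv_path)
    with open(tsv_path, "w") as fh:
        fh.write("transcript_id\tscore\tn_matches\tbest_mature_id\tbest_mismatches\n")
        for cand in candidates:
            best = min(cand.matches, key=lambda m: (m.mismatches, m.mature_id, m.start))
            fh.write(
                f"{cand.transcript_id}\t{cand.score}\t{len(cand.matches)}\t"
                f"{best.mature_id}\t{best.mismatches}\n"
            )
    if json_path is not None:
        summary = {
            "n_candidates": len(candidates),
            "n_matches_total": sum(len(c.matches) for c in candidates),
            "matured_ids": sorted({m.mature_id for c in candidates for m in c.matches}),
        }
        Path(json_path).write_text(json.dumps(summary, indent=2) + "\n")
    return tsv_path
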