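"""All-vs-all containment scan and redundancy pruning.

A transcript whose sequence is almost entirely included in a longer
transcript is redundant (a mis-assembled fragment or a chimeric copy).
For every (shorter, longer) candidate pair sharing a seed k-mer, matched
blocks are found by seeding on shared k-mers, merging runs along each
alignment diagonal, bridging mismatch gaps and extending block ends while
the per-block identity stays at or above ``block_identity_min``.  Blocks
are ungapped (substitutions only, no indels within a block); their
projections onto the shorter sequence are merged into an interval union,
and ``covered_fraction`` = union length / shorter length.

Pruning removes every record covered strictly more than ``coverage_min``
(default 90%) of its own length by a strictly longer record, in a single
pass against the original set.  Equal-length mutual containments are
resolved by keeping the lexicographically smaller id.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from . import _align
from .errors import ValidationError
from .seqio import AssemblySet


@dataclass(frozen=True)
class ContainmentParams:
    coverage_min: float = 0.90       # strict-greater removal trigger
    block_identity_min: float = 0.95
    kmer_size: int = 15
    both_strands: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.coverage_min < 1.0):
            raise ValidationError("coverage_min must be in (0, 1)")
        if not (0.0 < self.block_identity_min <= 1.0):
            raise ValidationError("block_identity_min must be in (0, 1]")
        if self.kmer_size < 4:
            raise ValidationError("kmer_size must be >= 4")


@dataclass(frozen=True)
class ContainmentHit:
    contained_id: str
    container_id: str
    covered_fraction: float
    n_blocks: int
    strand: str  # "forward" | "reverse"


def _exact_runs(s: str, t: str, k: int) -> dict[int, list[tuple[int, int]]]:
    """Per-diagonal exactly-matching intervals of s against t.

    Returns {diagonal: [(start, end) on s]}; overlapping or abutting k-mer
    hits on the same diagonal are merged into maximal exact intervals.
    """
    pos_t: dict[str, list[int]] = defaultdict(list)
    for j in range(len(t) - k + 1):
        pos_t[t[j:j + k]].append(j)
    hits: dict[int, list[int]] = defaultdict(list)
    for i in range(len(s) - k + 1):
        for j in pos_t.get(s[i:i + k], ()):
            hits[j - i].append(i)
    runs: dict[int, list[tuple[int, int]]] = {}
    for diag, starts in hits.items():
        merged: list[tuple[int, int]] = []
        cur_start = prev = starts[0]
        for i in starts[1:]:
            if i <= prev + k:  # windows overlap or abut: union stays exact
                prev = i
            else:
                merged.append((cur_start, prev + k))
                cur_start = prev = i
        merged.append((cur_start, prev + k))
        runs[diag] = merged
    return runs


def _bridge_and_extend(s: str, t: str, diag: int,
                       runs: list[tuple[int, int]],
                       identity_min: float) -> list[tuple[int, int, int]]:
    """Chain exact runs on one diagonal into blocks.

    Adjacent runs are merged when the bridged block's identity (matches /
    span, the gap counted as mismatches) stays >= identity_min; block ends
    are then extended outward to the best-scoring endpoint (match +1,
    mismatch -2), so extension cannot drift into unrelated sequence.  An
    extension that would pull the block's identity below ``identity_min``
    is discarded.  Returns (start, end, matches) triples on s.
    """
    blocks: list[tuple[int, int, int]] = []
    cur_start, cur_end = runs[0]
    matches = cur_end - cur_start
    for start, end in runs[1:]:
        new_matches = matches + (end - start)
        if new_matches / (end - cur_start) >= identity_min:
            matches, cur_end = new_matches, end
        else:
            blocks.append((cur_start, cur_end, matches))
            cur_start, cur_end = start, end
            matches = end - start
    blocks.append((cur_start, cur_end, matches))

    out: list[tuple[int, int, int]] = []
    for start, end, matches in blocks:
        # rightward score-maximal extension
        best_end, best_end_matches = end, matches
        score = best = 0
        m = matches
        e = end
        limit = min(len(s), len(t) - diag)
        while e < limit and best - score < 20:  # X-drop cutoff
            if s[e] == t[e + diag]:
                score += 1
                m += 1
            else:
                score -= 2
            e += 1
            if score > best:
                best = score
                best_end, best_end_matches = e, m
        ext_end, ext_matches = best_end, best_end_matches
        # leftward
        best_start, best_start_matches = start, ext_matches
        score = best = 0
        m = ext_matches
        b = start
        low = max(0, -diag)
        while b > low and best - score < 20:
            b -= 1
            if s[b] == t[b + diag]:
                score += 1
                m += 1
            else:
                score -= 2
            if score > best:
                best = score
                best_start, best_start_matches = b, m
        if best_start_matches / (ext_end - best_start) >= identity_min:
            out.append((best_start, ext_end, best_start_matches))
        else:
            out.append((start, end, matches))
    return out


def _union_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for start, end in intervals[1:]:
        if start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(a, b) for a, b in merged]


def _coverage_one_strand(s: str, t: str, params: ContainmentParams
                         ) -> tuple[float, int]:
    runs = _exact_runs(s, t, params.kmer_size)
    intervals: list[tuple[int, int]] = []
    for diag, diag_runs in runs.items():
        for start, end, _ in _bridge_and_extend(
            s, t, diag, diag_runs, params.block_identity_min
        ):
            intervals.append((start, end))
    union = _union_intervals(intervals)
    covered = sum(end - start for start, end in union)
    return covered / len(s), len(union)


def pair_coverage(s: str, t: str, params: ContainmentParams = ContainmentParams()
                  ) -> tuple[float, int, str]:
    """Covered fraction of ``s`` by matched blocks of ``t`` (best strand).

    Returns (covered_fraction, n_blocks, strand).
    """
    cov_f, blocks_f = _coverage_one_strand(s, t, params)
    if not params.both_strands:
        return cov_f, blocks_f, "forward"
    cov_r, blocks_r = _coverage_one_strand(s, _align.revcomp(t), params)
    if cov_r > cov_f:
        return cov_r, blocks_r, "reverse"
    return cov_f, blocks_f, "forward"


def containment_scan(assembly: AssemblySet,
                     params: ContainmentParams = ContainmentParams()
                     ) -> list[ContainmentHit]:
    """Scan every (shorter, longer) pair sharing a seed k-mer.

    Emits a hit for every pair with covered_fraction > 0; equal-length
    pairs are scanned in both orientations.  Ordered deterministically by
    (contained_id, container_id).
    """
    records = list(assembly)
    k = params.kmer_size
    by_kmer: dict[str, list[int]] = defaultdict(list)
    for idx, rec in enumerate(records):
        for kmer in set(_align.kmer_positions(rec.bases, k)):
            by_kmer[kmer].append(idx)

    hits: list[ContainmentHit] = []
    for idx, rec in enumerate(records):
        candidates: set[int] = set()
        for kmer in set(_align.kmer_positions(rec.bases, k)):
            candidates.update(by_kmer.get(kmer, ()))
        if params.both_strands:
            for kmer in set(_align.kmer_positions(_align.revcomp(rec.bases), k)):
                candidates.update(by_kmer.get(kmer, ()))
        for jdx in candidates:
            if jdx == idx:
                continue
            other = records[jdx]
            # rec must be the contained (shorter) side; equal-length pairs
            # are scanned from both sides across the outer loop
            if len(other) < len(rec):
                continue
            cov, n_blocks, strand = pair_coverage(rec.bases, other.bases, params)
            if cov > 0.0:
                hits.append(
                    ContainmentHit(
                        contained_id=rec.id,
                        container_id=other.id,
                        covered_fraction=cov,
                        n_blocks=n_blocks,
                        strand=strand,
                    )
                )
    hits.sort(key=lambda h: (h.contained_id, h.container_id))
    return hits


def containment_prune(assembly: AssemblySet,
                      params: ContainmentParams = ContainmentParams(),
                      hits: Sequence[ContainmentHit] | None = None
                      ) -> tuple[AssemblySet, list[ContainmentHit]]:
    """Remove contained records in a single pass against the original set.

    A record is removed when some hit covers it strictly more than
    ``coverage_min`` by a strictly longer record — or by an equal-length
    record with a lexicographically smaller id (mutual containment).
    Removal is decided on the original set: a fragment contained only in
    another removed fragment is still removed.  Output preserves ingest
    order.  Returns (pruned assembly, hits used).
    """
    if hits is None:
        hits = containment_scan(assembly, params)
    lengths = {rec.id: len(rec) for rec in assembly}
    removed: set[str] = set()
    for hit in hits:
        if hit.covered_fraction <= params.coverage_min:
            continue
        lc, ln = lengths[hit.contained_id], lengths[hit.container_id]
        if ln > lc or (ln == lc and hit.container_id < hit.contained_id):
            removed.add(hit.contained_id)
    keep = [rec.id for rec in assembly if rec.id not in removed]
    return assembly.subset(keep), list(hits)


def write_hits_tsv(hits: Iterable[ContainmentHit], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("contained_id\tcontainer_id\tcovered_fraction\tn_blocks\tstrand\n")
        for hit in hits:
            strand = "+" if hit.strand == "forward" else "-"
            fh.write(
                f"{hit.contained_id}\t{hit.container_id}\t"
                f"{hit.covered_fraction:.4f}\t{hit.n_blocks}\t{strand}\n"
            )
    return path
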