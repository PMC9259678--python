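"""Greedy incremental identity clustering of transfrags.

Near-identical sequences produced by different assemblers are collapsed
into clusters represented by their longest member, in the style of
nucleotide CD-HIT at 95% identity: records are processed in descending
length order (ties by ascending id), each record joins the first existing
cluster whose representative reaches ``identity_min`` on either strand, or
founds a new cluster.

Identity is the semi-global, shorter-denominator convention of
:mod:`metassembly._align`; an exact substring of a representative therefore
scores 1.0.  A provably lossless k-mer prefilter skips representative
comparisons only when the shared k-mer count cannot reach ``identity_min``.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from . import _align
from .errors import ValidationError
from .seqio import AssemblySet, SequenceRecord


@dataclass(frozen=True)
class ClusterParams:
    identity_min: float = 0.95
    kmer_size: int = 11
    both_strands: bool = True
    assign_mode: str = "first_hit"  # or "best_hit"
    use_prefilter: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.identity_min <= 1.0):
            raise ValidationError("identity_min must be in (0, 1]")
        if self.kmer_size < 4:
            raise ValidationError("kmer_size must be >= 4")
        if self.assign_mode not in ("first_hit", "best_hit"):
            raise ValidationError("assign_mode must be first_hit or best_hit")


@dataclass
class ClusterAssignment:
    """One cluster: its representative plus all members (the representative
    itself is listed as a member with identity 1.0, forward strand)."""

    representative_id: str
    member_ids: list[str] = field(default_factory=list)
    member_identities: dict[str, float] = field(default_factory=dict)
    member_strand: dict[str, str] = field(default_factory=dict)


def pairwise_identity(a: SequenceRecord | str, b: SequenceRecord | str,
                      strand: str = "forward") -> float:
    """Identity between two sequences on the given strand of ``b``.

    Semi-global on the shorter sequence; ``strand="reverse"`` reverse-
    complements ``b`` first.
    """
    sa = a.bases if isinstance(a, SequenceRecord) else a
    sb = b.bases if isinstance(b, SequenceRecord) else b
    if strand == "reverse":
        sb = _align.revcomp(sb)
    elif strand != "forward":
        raise ValidationError(f"unknown strand {strand!r}")
    return _align.identity(sa, sb)


class _RepIndex:
    """Inverted k-mer index over cluster representatives, supporting the
    lossless prefilter bound of :func:`metassembly._align.min_shared_kmers`."""

    def __init__(self, k: int) -> None:
        self.k = k
        self._by_kmer: dict[str, list[int]] = defaultdict(list)
        self.n_reps = 0

    def add(self, bases: str) -> None:
        idx = self.n_reps
        self.n_reps += 1
        for kmer in set(_align.kmer_positions(bases, self.k)):
            self._by_kmer[kmer].append(idx)

    def shared_counts(self, bases: str) -> dict[int, int]:
        """For each representative, the number of k-mer positions of
        ``bases`` whose k-mer occurs in that representative."""
        counts: dict[int, int] = defaultdict(int)
        by_kmer = self._by_kmer
        for kmer in _align.kmer_positions(bases, self.k):
            for rep in by_kmer.get(kmer, ()):
                counts[rep] += 1
        return counts


def greedy_cluster(assembly: AssemblySet,
                   params: ClusterParams = ClusterParams()) -> list[ClusterAssignment]:
    """Cluster an assembly greedily at ``params.identity_min``.

    Deterministic and invariant under input permutation: the processing
    order is (descending length, ascending id).
    """
    if len(assembly) == 0:
        raise ValidationError("cannot cluster an empty assembly")
    order = sorted(assembly, key=lambda r: (-len(r), r.id))
    clusters: list[ClusterAssignment] = []
    rep_bases: list[str] = []
    index = _RepIndex(params.kmer_size)

    for rec in order:
        fwd_counts = index.shared_counts(rec.bases) if params.use_prefilter else None
        rev_counts = None
        if params.use_prefilter and params.both_strands:
            rev_counts = index.shared_counts(_align.revcomp(rec.bases))
        need = _align.min_shared_kmers(len(rec), params.kmer_size, params.identity_min)

        best: tuple[float, int, str] | None = None  # (identity, cluster idx, strand)
        for ci in range(len(clusters)):
            if params.use_prefilter and need > 0:
                ok_fwd = fwd_counts.get(ci, 0) >= need
                ok_rev = params.both_strands and rev_counts.get(ci, 0) >= need
                if not (ok_fwd or ok_rev):
                    continue
            ident = _align.identity(rec.bases, rep_bases[ci])
            strand = "forward"
            if params.both_strands:
                ident_rev = _align.identity(_align.revcomp(rec.bases), rep_bases[ci])
                if ident_rev > ident:
                    ident, strand = ident_rev, "reverse"
            if ident >= params.identity_min:
                if params.assign_mode == "first_hit":
                    best = (ident, ci, strand)
                    break
                if best is None or ident > best[0]:
                    best = (ident, ci, strand)

        if best is None:
            cluster = ClusterAssignment(representative_id=rec.id)
            cluster.member_ids.append(rec.id)
            cluster.member_identities[rec.id] = 1.0
            cluster.member_strand[rec.id] = "forward"
            clusters.append(cluster)
            rep_bases.append(rec.bases)
            index.add(rec.bases)
        else:
            ident, ci, strand = best
            cluster = clusters[ci]
            cluster.member_ids.append(rec.id)
            cluster.member_identities[rec.id] = ident
            cluster.member_strand[rec.id] = strand
    return clusters


def representatives(clusters: Sequence[ClusterAssignment],
                    assembly: AssemblySet) -> AssemblySet:
    """Sub-assembly of one record per cluster, in ingest order."""
    rep_ids = [c.representative_id for c in clusters]
    return assembly.subset(rep_ids)


def write_clusters_tsv(clusters: Iterable[ClusterAssignment], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("representative_id\tmember_id\tidentity\tstrand\n")
        for cluster in clusters:
            for member in cluster.member_ids:
                strand = "+" if cluster.member_strand[member] == "forward" else "-"
                fh.write(
                    f"{cluster.representative_id}\t{member}\t"
                    f"{cluster.member_identities[member]:.4f}\t{strand}\n"
                )
    return path
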