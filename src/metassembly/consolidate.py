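"""Coding-sequence consolidation: group transcripts into genes and classify
alternates.

A deliberately compact take on coding-sequence-driven meta-assembly
consolidation: each transcript's most likely coding sequence is the longest
ATG-initiated open reading frame over all six frames; transcripts are
grouped into genes by single-linkage over CDS-level identity, the longest
CDS becomes the gene's primary, and the remaining members are classified as
high-identity alternates (``althi``), medium-identity alternates
(``altmid``) or partial fragments (``part``).  Transcripts without an
acceptable ORF become singleton non-coding groups.  Classification uses CDS
identity only — no amino-acid clustering, UTR evidence or codon-usage
model.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Seq import Seq

from . import _align
from .errors import ValidationError
from .seqio import AssemblySet, SequenceRecord

STOP_CODONS = {"TAA", "TAG", "TGA"}

CATEGORIES = ("main", "noclass", "althi", "altmid", "part", "noncoding")


@dataclass(frozen=True)
class ConsolidateParams:
    min_cds: int = 90
    althi_min: float = 0.98
    altmid_min: float = 0.90
    part_max_frac: float = 0.70
    # prefilter word size for CDS pairing; at altmid_min 0.90 the lossless
    # shared-k-mer bound is positive for every CDS >= min_cds only for k <= 8
    kmer_size: int = 8

    def __post_init__(self) -> None:
        if self.min_cds < 3 or self.min_cds % 3:
            raise ValidationError("min_cds must be a positive multiple of 3")
        if not (0.0 < self.altmid_min < self.althi_min <= 1.0):
            raise ValidationError("require 0 < altmid_min < althi_min <= 1")
        if not (0.0 < self.part_max_frac < 1.0):
            raise ValidationError("part_max_frac must be in (0, 1)")


@dataclass(frozen=True)
class OrfCall:
    """The selected open reading frame of one transcript.

    ``cds_start``/``cds_end`` are 0-based, end-exclusive offsets on the
    *forward* strand of the transcript; ``frame`` is +1..+3 for forward
    frames and -1..-3 for frames on the reverse complement.  ``cds``
    holds the coding-orientation nucleotide sequence.
    """

    transcript_id: str
    frame: int
    cds_start: int
    cds_end: int
    cds_length: int
    cds: str
    protein: str
    complete: bool


@dataclass
class GeneGroup:
    """One consolidated gene: a primary transcript plus classified members."""

    gene_id: str
    primary_id: str
    members: dict[str, str] = field(default_factory=dict)   # transcript -> category
    coding: dict[str, bool] = field(default_factory=dict)
    orfs: dict[str, OrfCall] = field(default_factory=dict)


def _scan_strand(seq: str, min_cds: int):
    """Yield (offset, end, has_stop) for the longest-per-start ORFs of the
    three frames of ``seq``; coordinates are on ``seq`` itself."""
    n = len(seq)
    for off in range(3):
        start = None
        for pos in range(off, n - 2, 3):
            codon = seq[pos:pos + 3]
            if codon in STOP_CODONS:
                if start is not None:
                    length = pos + 3 - start
                    if length >= min_cds:
                        yield off, start, pos + 3, True
                    start = None
            elif codon == "ATG" and start is None:
                start = pos
        if start is not None:
            # open-ended ORF running off the contig edge
            end = start + ((n - start) // 3) * 3
            if end - start >= min_cds:
                yield off, start, end, False


def find_longest_orf(record: SequenceRecord, min_cds: int = 90) -> OrfCall | None:
    """Longest ATG-initiated ORF over all six frames, or None below ``min_cds``.

    The stop codon is included in the CDS when present; an ORF running off
    the contig edge is allowed but flagged ``complete=False``.  Ties are
    broken by strand (forward first), then frame index, then scan position.
    """
    if min_cds < 3 or min_cds % 3:
        raise ValidationError("min_cds must be a positive multiple of 3")
    n = len(record.bases)
    best: tuple[int, OrfCall] | None = None
    for strand_idx, seq in enumerate((record.bases, _align.revcomp(record.bases))):
        for off, start, end, has_stop in _scan_strand(seq, min_cds):
            length = end - start
            if best is not None and length <= best[0]:
                continue
            cds = seq[start:end]
            protein = str(Seq(cds[:-3] if has_stop else cds).translate())
            if strand_idx == 0:
                frame, fwd_start, fwd_end = off + 1, start, end
            else:
                frame, fwd_start, fwd_end = -(off + 1), n - end, n - start
            best = (
                length,
                OrfCall(
                    transcript_id=record.id,
                    frame=frame,
                    cds_start=fwd_start,
                    cds_end=fwd_end,
                    cds_length=length,
                    cds=cds,
                    protein=protein,
                    complete=has_stop,
                ),
            )
    return best[1] if best else None


def _candidate_pairs(orfs: list[OrfCall], k: int, altmid_min: float):
    """Ordered CDS index pairs that could reach altmid_min identity, via the
    lossless shared-k-mer bound (all pairs when the bound is vacuous)."""
    by_kmer: dict[str, list[int]] = defaultdict(list)
    for i, orf in enumerate(orfs):
        for kmer in set(_align.kmer_positions(orf.cds, k)):
            by_kmer[kmer].append(i)
    # CDSs for which the shared-k-mer bound is vacuous can never be skipped,
    # shared k-mers or not
    vacuous = [
        j for j, orf in enumerate(orfs)
        if _align.min_shared_kmers(orf.cds_length, k, altmid_min) <= 0
    ]
    for i, orf in enumerate(orfs):
        counts: dict[int, int] = defaultdict(int)
        for kmer in _align.kmer_positions(orf.cds, k):
            for j in by_kmer.get(kmer, ()):
                if j > i:
                    counts[j] += 1
        for j, c in counts.items():
            # the bound applies to the shorter CDS of the pair; the working
            # order sorts CDS length descending, so that is orfs[j]
            need = _align.min_shared_kmers(orfs[j].cds_length, k, altmid_min)
            if need <= 0 or c >= need:
                yield i, j
        for j in vacuous:
            if j > i and j not in counts:
                yield i, j


class _DSU:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def consolidate(assembly: AssemblySet,
                params: ConsolidateParams = ConsolidateParams()) -> list[GeneGroup]:
    """Group transcripts into :class:`GeneGroup` objects.

    Coding transcripts are linked (single-linkage) whenever their CDS
    identity reaches ``altmid_min``; within a group the primary is the
    longest CDS (ties: longest transcript, then ascending id) and is
    categorised ``main`` when alternates exist, else ``noclass``.  Members
    are ``part`` when their CDS is shorter than ``part_max_frac`` of the
    primary's (overriding alternate labels), otherwise ``althi`` or
    ``altmid`` by identity to the primary.  Gene ids are ``ESG`` plus a
    zero-padded ordinal assigned in ingest order of the primary.
    """
    orf_by_id: dict[str, OrfCall] = {}
    coding_records: list[SequenceRecord] = []
    for rec in assembly:
        orf = find_longest_orf(rec, params.min_cds)
        if orf is not None:
            orf_by_id[rec.id] = orf
            coding_records.append(rec)

    # deterministic working order regardless of input permutation
    coding_records.sort(key=lambda r: (-orf_by_id[r.id].cds_length, -len(r), r.id))
    orfs = [orf_by_id[r.id] for r in coding_records]

    dsu = _DSU(len(orfs))
    for i, j in _candidate_pairs(orfs, params.kmer_size, params.altmid_min):
        if dsu.find(i) != dsu.find(j):
            if _align.identity(orfs[i].cds, orfs[j].cds) >= params.altmid_min:
                dsu.union(i, j)

    groups_by_root: dict[int, list[int]] = defaultdict(list)
    for i in range(len(orfs)):
        groups_by_root[dsu.find(i)].append(i)

    ingest_pos = {rec.id: pos for pos, rec in enumerate(assembly)}
    raw_groups: list[tuple[int, GeneGroup]] = []
    for indices in groups_by_root.values():
        # working order already sorts by CDS length desc, transcript length
        # desc, id asc — the primary is the first index
        indices.sort()
        primary = orfs[indices[0]]
        group = GeneGroup(gene_id="", primary_id=primary.transcript_id)
        group.members[primary.transcript_id] = (
            "main" if len(indices) > 1 else "noclass"
        )
        group.coding[primary.transcript_id] = True
        group.orfs[primary.transcript_id] = primary
        for idx in indices[1:]:
            orf = orfs[idx]
            if orf.cds_length < params.part_max_frac * primary.cds_length:
                category = "part"
            else:
                ident = _align.identity(orf.cds, primary.cds)
                category = "althi" if ident >= params.althi_min else "altmid"
            group.members[orf.transcript_id] = category
            group.coding[orf.transcript_id] = True
            group.orfs[orf.transcript_id] = orf
        raw_groups.append((ingest_pos[primary.transcript_id], group))

    for rec in assembly:
        if rec.id not in orf_by_id:
            group = GeneGroup(gene_id="", primary_id=rec.id)
            group.members[rec.id] = "noncoding"
            group.coding[rec.id] = False
            raw_groups.append((ingest_pos[rec.id], group))

    raw_groups.sort(key=lambda t: t[0])
    groups = []
    for ordinal, (_, group) in enumerate(raw_groups, start=1):
        group.gene_id = f"ESG{ordinal:06d}"
        groups.append(group)
    return groups


def select_okay_set(groups: Sequence[GeneGroup], assembly: AssemblySet,
                    drop_part: bool = False,
                    drop_noncoding: bool = False) -> AssemblySet:
    """Survivor set after consolidation.

    The default profile retains everything (redundancy removal is delegated
    to the containment and abundance stages); stricter profiles drop
    ``part`` and/or ``noncoding`` members.
    """
    keep: list[str] = []
    for group in groups:
        for tid, category in group.members.items():
            if drop_part and category == "part":
                continue
            if drop_noncoding and category == "noncoding":
                continue
            keep.append(tid)
    return assembly.subset(keep)


def write_gene_map(groups: Iterable[GeneGroup], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("gene_id\ttranscript_id\tcategory\tcoding\tcds_start\tcds_end\tframe\n")
        for group in groups:
            for tid, category in group.members.items():
                orf = group.orfs.get(tid)
                if orf is None:
                    fh.write(f"{group.gene_id}\t{tid}\t{category}\tFalse\t.\t.\t.\n")
                else:
                    fh.write(
                        f"{group.gene_id}\t{tid}\t{category}\tTrue\t"
                        f"{orf.cds_start}\t{orf.cds_end}\t{orf.frame}\n"
                    )
    return path


def write_primary_proteins(groups: Iterable[GeneGroup], path: str | Path) -> Path:
    """Protein FASTA of each gene's primary CDS translation."""
    path = Path(path)
    with open(path, "w") as fh:
        for group in groups:
            orf = group.orfs.get(group.primary_id)
            if orf is None:
                continue
            fh.write(f">{group.gene_id} {group.primary_id}\n")
            for i in range(0, len(orf.protein), 60):
                fh.write(orf.protein[i:i + 60] + "\n")
    return path
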