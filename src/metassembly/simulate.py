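"""Seeded synthetic multi-assembler transcriptomes with ground truth.

The generator emulates the redundancy structure the consolidation pipeline
targets, so every stage is testable without external data:

* gene families: a shared coding core (ATG ... stop, preceded by an
  in-frame upstream stop so the planted ORF is exactly recoverable) flanked
  by isoform-specific UTRs.  Alternate isoforms share the CDS verbatim but
  carry their own unique UTR sequence (alternative first/last exons), so
  they are genuinely distinct transcripts the pipeline must retain;
* exact duplicates: the same transcript reported by a second assembler
  under a different id;
* mutated near-duplicates: per-base substitutions at ``dup_mutation_rate``
  plus a 3-base truncation;
* contained fragments: a contiguous substring of a parent plus a short
  unique flap; the manifest records ``cov``, the fraction of the
  fragment's own length covered by its parent — exactly what the
  containment stage measures;
* contaminants: free-standing random sequences, designated unexpressed.

Quantification tables are zero-inflated log-normal TPM with a season
effect, renormalised to one million per sample.  The miRNA fixture builds
hairpin precursors (arm + loop + reverse-complemented arm) with matures
planted at controlled mismatch counts, plus score/match decoys.

All randomness flows from a single integer seed through named
``numpy.random.SeedSequence`` substreams; identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._align import revcomp
from .errors import ValidationError
from .quant import QuantTable, SampleDesign
from .seqio import AssemblySet, SequenceRecord, write_fasta

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class SimParams:
    """Study conditions for the synthetic transcriptome.

    Defaults produce roughly 2,000 records across two assembler labels,
    with artifact rates and a GC target in the range typical of crustacean
    de novo assemblies.
    """

    seed: int = 0
    n_genes: int = 450
    isoforms_per_gene: tuple[int, int] = (1, 4)
    length_meanlog: float = 7.2
    length_sdlog: float = 0.7
    length_min: int = 200
    length_max: int = 20000
    gc_target: float = 0.36
    share_rate: float = 0.40          # cross-assembler exact copies
    dup_rate: float = 0.15            # mutated near-duplicate copies
    dup_mutation_rate: float = 0.01
    frag_rate: float = 0.25           # contained-fragment artifacts
    frag_cov_range: tuple[float, float] = (0.93, 0.99)
    frag_subfrac_range: tuple[float, float] = (0.45, 0.85)
    contaminant_n: int = 80
    # expression model
    n_samples: int = 12
    expr_meanlog: float = 3.0
    expr_sdlog: float = 1.0
    season_effect_sdlog: float = 0.7
    noise_sdlog: float = 0.4
    dropout: float = 0.10
    # miRNA fixture
    n_matures: int = 20
    mature_len_range: tuple[int, int] = (21, 22)
    arm_len: int = 70
    loop_len: int = 12
    n_planted: int = 30
    planted_mismatch_counts: tuple[int, ...] = (0, 1, 2)
    n_decoy_match: int = 10
    n_decoy_score: int = 10
    n_decoy_plain: int = 20

    def __post_init__(self) -> None:
        for p in (self.share_rate, self.dup_rate, self.dup_mutation_rate,
                  self.frag_rate, self.dropout):
            if not (0.0 <= p <= 1.0):
                raise ValidationError("probabilities must be in [0, 1]")
        for lo, hi in (self.frag_cov_range, self.frag_subfrac_range):
            if not (0.0 < lo < hi < 1.0):
                raise ValidationError("range bounds must satisfy 0 < lo < hi < 1")
        if not (0.0 < self.gc_target < 1.0):
            raise ValidationError("gc_target must be in (0, 1)")
        if self.isoforms_per_gene[0] < 1 or (
            self.isoforms_per_gene[0] > self.isoforms_per_gene[1]
        ):
            raise ValidationError("isoforms_per_gene must be (min>=1, max>=min)")
        if self.arm_len < self.mature_len_range[1]:
            raise ValidationError("hairpin arm must fit a mature sequence")


@dataclass
class ManifestEntry:
    record_id: str
    role: str              # primary_isoform | alt_isoform | duplicate_of |
                           # fragment_of | contaminant
    source_assembly: str
    length: int
    gene_index: int | None = None
    parent_id: str | None = None
    cov: float | None = None          # fragment_of only, 3 decimals
    intended_survivor: bool = True
    expressed: bool = True


@dataclass
class TruthManifest:
    """Ground truth for one simulated transcriptome."""

    entries: dict[str, ManifestEntry] = field(default_factory=dict)
    # generating per-season-level mean TPM (pre-normalisation, relative)
    level_means: dict[str, dict[str, float]] = field(default_factory=dict)
    true_tpm: pd.DataFrame | None = None

    def add(self, entry: ManifestEntry) -> None:
        if entry.record_id in self.entries:
            raise ValidationError(f"duplicate manifest id {entry.record_id!r}")
        self.entries[entry.record_id] = entry

    def intended_survivors(self) -> set[str]:
        return {e.record_id for e in self.entries.values() if e.intended_survivor}

    def gene_partition(self, ids=None) -> dict[str, int]:
        """record id -> planted gene index (contaminants get singletons)."""
        ids = set(ids) if ids is not None else set(self.entries)
        out: dict[str, int] = {}
        next_singleton = -1
        for rid in self.entries:
            if rid not in ids:
                continue
            gene = self.entries[rid].gene_index
            if gene is None:
                out[rid] = next_singleton
                next_singleton -= 1
            else:
                out[rid] = gene
        return out

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            rid: {
                "role": e.role,
                "source_assembly": e.source_assembly,
                "length": e.length,
                "gene_index": e.gene_index,
                "parent_id": e.parent_id,
                "cov": e.cov,
                "intended_survivor": e.intended_survivor,
                "expressed": e.expressed,
            }
            for rid, e in self.entries.items()
        }
        path.write_text(json.dumps(payload, indent=1) + "\n")
        return path


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    draws = rng.choice(4, size=n, p=p)
    return _BASES[draws].tobytes().decode()


def _make_cds(rng: np.random.Generator, cds_len: int, gc: float) -> str:
    """ATG + stop-free body + TAA, total length ``cds_len`` (multiple of 3)."""
    body = list(_random_bases(rng, cds_len - 6, gc))
    for pos in range(0, len(body) - 2, 3):
        if "".join(body[pos:pos + 3]) in _STOPS:
            body[pos + 1] = "C"  # TAA->TCA, TAG->TCG, TGA->TCA: no stop
    return "ATG" + "".join(body) + "TAA"


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(len(choices))]
    return arr.tobytes().decode()


def _draw_length(rng: np.random.Generator, params: SimParams) -> int:
    while True:
        n = int(np.exp(rng.normal(params.length_meanlog, params.length_sdlog)))
        if params.length_min <= n <= params.length_max:
            return n


def simulate_transcriptome(params: SimParams = SimParams()
                           ) -> tuple[AssemblySet, TruthManifest]:
    """Generate the synthetic multi-assembler transcriptome.

    Returns a single :class:`AssemblySet` whose records carry
    ``source_assembly`` labels (``asmA``/``asmB``); split per label with
    :func:`split_by_assembly` to obtain per-assembler FASTA inputs.
    """
    root = np.random.SeedSequence(params.seed)
    gene_rng, artifact_rng = (np.random.default_rng(s) for s in root.spawn(2))

    assembly = AssemblySet(label="synthetic")
    manifest = TruthManifest()

    def add(record: SequenceRecord, entry: ManifestEntry) -> None:
        assembly.add(record)
        manifest.add(entry)

    for g in range(params.n_genes):
        total = _draw_length(gene_rng, params)
        cds_frac = gene_rng.uniform(0.55, 0.75)
        cds_len = max(90, (int(total * cds_frac) // 3) * 3)
        cds = _make_cds(gene_rng, cds_len, params.gc_target)
        n_iso = int(gene_rng.integers(params.isoforms_per_gene[0],
                                      params.isoforms_per_gene[1] + 1))
        for iso in range(n_iso):
            utr5 = _random_bases(
                gene_rng, max(3, int(total * gene_rng.uniform(0.10, 0.25))),
                params.gc_target,
            )
            utr3 = _random_bases(
                gene_rng, max(3, int(total * gene_rng.uniform(0.15, 0.30))),
                params.gc_target,
            )
            # in-frame upstream stop pins the recovered ORF to the planted CDS
            bases = utr5[:-3] + "TAA" + cds + utr3
            rid = f"T{g:05d}.{iso}"
            role = "primary_isoform" if iso == 0 else "alt_isoform"
            add(
                SequenceRecord(rid, bases, source_assembly="asmA"),
                ManifestEntry(rid, role, "asmA", len(bases), gene_index=g),
            )
            # cross-assembler exact copy
            if artifact_rng.random() < params.share_rate:
                cid = rid + ".b"
                add(
                    SequenceRecord(cid, bases, source_assembly="asmB"),
                    ManifestEntry(cid, "duplicate_of", "asmB", len(bases),
                                  gene_index=g, parent_id=rid,
                                  intended_survivor=False),
                )
            # mutated, slightly truncated near-duplicate
            if artifact_rng.random() < params.dup_rate:
                mseq = _mutate(artifact_rng, bases[:-3], params.dup_mutation_rate)
                mid = rid + ".m"
                add(
                    SequenceRecord(mid, mseq, source_assembly="asmB"),
                    ManifestEntry(mid, "duplicate_of", "asmB", len(mseq),
                                  gene_index=g, parent_id=rid,
                                  intended_survivor=False),
                )
            # contained fragment with a unique flap
            if artifact_rng.random() < params.frag_rate:
                sub_frac = artifact_rng.uniform(*params.frag_subfrac_range)
                # flap (< 8% of sub_len at cov >= 0.93) must keep the
                # fragment strictly shorter than its parent
                sub_len = min(int(len(bases) * sub_frac), int(0.90 * len(bases)))
                start = int(artifact_rng.integers(0, len(bases) - sub_len + 1))
                sub = bases[start:start + sub_len]
                cov = artifact_rng.uniform(*params.frag_cov_range)
                flap_len = max(1, round(sub_len * (1 - cov) / cov))
                flap = _random_bases(artifact_rng, flap_len, params.gc_target)
                fseq = sub + flap if artifact_rng.random() < 0.5 else flap + sub
                fid = rid + ".f"
                src = "asmA" if artifact_rng.random() < 0.5 else "asmB"
                add(
                    SequenceRecord(fid, fseq, source_assembly=src),
                    ManifestEntry(fid, "fragment_of", src, len(fseq),
                                  gene_index=g, parent_id=rid,
                                  cov=round(sub_len / len(fseq), 3),
                                  intended_survivor=False),
                )

    for c in range(params.contaminant_n):
        seq = _random_bases(artifact_rng, _draw_length(artifact_rng, params), 0.50)
        cid = f"X{c:04d}"
        src = "asmA" if c % 2 == 0 else "asmB"
        add(
            SequenceRecord(cid, seq, source_assembly=src),
            ManifestEntry(cid, "contaminant", src, len(seq),
                          intended_survivor=False, expressed=False),
        )
    return assembly, manifest


def split_by_assembly(assembly: AssemblySet) -> dict[str, AssemblySet]:
    """Partition records by their ``source_assembly`` label."""
    out: dict[str, AssemblySet] = {}
    for rec in assembly:
        out.setdefault(rec.source_assembly,
                       AssemblySet(label=rec.source_assembly)).add(rec)
    return out


def default_design(n_samples: int) -> SampleDesign:
    """Balanced three-factor design: season, area, sex."""
    samples = [f"S{i + 1:02d}" for i in range(n_samples)]
    season = {s: ("summer" if i % 2 == 0 else "winter") for i, s in enumerate(samples)}
    area = {s: ("areaA" if (i // 2) % 2 == 0 else "areaB") for i, s in enumerate(samples)}
    sex = {s: ("F" if (i + i // 2) % 2 == 0 else "M") for i, s in enumerate(samples)}
    return SampleDesign(sample_ids=samples,
                        factors={"season": season, "area": area, "sex": sex})


def simulate_quant(manifest: TruthManifest, params: SimParams = SimParams()
                   ) -> tuple[QuantTable, SampleDesign]:
    """Zero-inflated log-normal TPM per condition level.

    Expressed records get a base abundance and a multiplicative season
    effect; per-sample values add log-normal noise and dropout; columns are
    renormalised so TPM sums to one million per sample.  Designated
    unexpressed records (contaminants) are 0 everywhere.  Generating
    season-level means are recorded in ``manifest.level_means``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(params.seed).spawn(3)[2])
    design = default_design(params.n_samples)
    season = design.factors["season"]
    ids = list(manifest.entries)
    tpm = np.zeros((len(ids), params.n_samples))
    for row, rid in enumerate(ids):
        entry = manifest.entries[rid]
        if not entry.expressed:
            manifest.level_means[rid] = {"summer": 0.0, "winter": 0.0}
            continue
        base = float(np.exp(rng.normal(params.expr_meanlog, params.expr_sdlog)))
        effect = float(np.exp(rng.normal(0.0, params.season_effect_sdlog)))
        means = {"summer": base, "winter": base * effect}
        manifest.level_means[rid] = means
        for col, sample in enumerate(design.sample_ids):
            if rng.random() < params.dropout:
                continue
            tpm[row, col] = means[season[sample]] * float(
                np.exp(rng.normal(0.0, params.noise_sdlog))
            )
    sums = tpm.sum(axis=0)
    sums[sums == 0] = 1.0
    tpm = tpm / sums * 1e6

    lengths = np.array([manifest.entries[r].length for r in ids], dtype=float)
    eff_len = np.maximum(lengths - 150, 10.0)
    reads = np.round(tpm * eff_len[:, None] / 500.0)
    quant = QuantTable(
        tpm=pd.DataFrame(tpm, index=ids, columns=design.sample_ids),
        num_reads=pd.DataFrame(reads, index=ids, columns=design.sample_ids),
    )
    manifest.true_tpm = quant.tpm
    return quant, design


def write_quant_files(quant: QuantTable, design: SampleDesign,
                      outdir: str | Path,
                      lengths: dict[str, int] | None = None
                      ) -> tuple[list[Path], Path]:
    """Write per-sample ``quant.sf``-dialect TSVs and the design CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ids = quant.transcript_ids
    if lengths is None:
        lengths = {t: 0 for t in ids}
    lens = np.array([lengths[t] for t in ids], dtype=int)
    eff = np.maximum(lens - 150, 10)
    paths: list[Path] = []
    for sample in quant.sample_ids:
        df = pd.DataFrame(
            {
                "Name": ids,
                "Length": lens,
                "EffectiveLength": eff,
                "TPM": quant.tpm[sample].to_numpy(),
                "NumReads": quant.num_reads[sample].to_numpy(),
            }
        )
        path = outdir / f"{sample}.quant.sf"
        df.to_csv(path, sep="\t", index=False)
        paths.append(path)
    design_path = outdir / "design.csv"
    design.to_csv(design_path)
    return paths, design_path


@dataclass
class MirnaManifest:
    expected_candidates: list[str] = field(default_factory=list)
    planted: dict[str, tuple[str, int]] = field(default_factory=dict)  # id -> (mature, mism)


def _embed_with_mismatches(rng: np.random.Generator, host: str, insert: str,
                           offset: int, n_mismatch: int) -> str:
    arr = list(insert)
    pos = rng.choice(len(arr), size=n_mismatch, replace=False)
    for i in pos:
        alternatives = [b for b in "ACGT" if b != arr[i]]
        arr[i] = alternatives[int(rng.integers(3))]
    return host[:offset] + "".join(arr) + host[offset + len(insert):]


def simulate_mirna_fixture(params: SimParams = SimParams()
                           ) -> tuple[AssemblySet, list[tuple[str, str]],
                                      "HairpinScoreTable", MirnaManifest]:
    """Hairpin precursors with planted mature matches, plus decoys.

    Planted precursors carry a mature at a controlled mismatch count and a
    synthetic hairpin score <= 0.71; decoys are (a) mature match but score
    > 0.71, (b) score <= 0.71 but the mature planted at 3 mismatches,
    (c) plain unrelated sequences.  The synthetic scores stand in for an
    external hairpin classifier: the combination rule, not the scorer, is
    under test here.
    """
    from .mirna import HairpinScoreTable  # local import avoids a cycle

    rng = np.random.default_rng(np.random.SeedSequence(params.seed).spawn(4)[3])
    matures = [
        (
            f"mir-{i:03d}",
            _random_bases(rng, int(rng.integers(params.mature_len_range[0],
                                                params.mature_len_range[1] + 1)), 0.5),
        )
        for i in range(params.n_matures)
    ]
    assembly = AssemblySet(label="mirna-fixture")
    scores: dict[str, float] = {}
    manifest = MirnaManifest()

    def hairpin(arm: str) -> str:
        return arm + _random_bases(rng, params.loop_len, 0.5) + revcomp(arm)

    counts = params.planted_mismatch_counts
    for i in range(params.n_planted):
        mid, mseq = matures[int(rng.integers(params.n_matures))]
        n_mism = counts[i % len(counts)]
        arm = _random_bases(rng, params.arm_len, 0.5)
        offset = int(rng.integers(0, params.arm_len - len(mseq) + 1))
        arm = _embed_with_mismatches(rng, arm, mseq, offset, n_mism)
        rid = f"H{i:03d}"
        assembly.add(SequenceRecord(rid, hairpin(arm), source_assembly="mirna"))
        scores[rid] = float(rng.uniform(0.30, 0.71))
        manifest.planted[rid] = (mid, n_mism)
        manifest.expected_candidates.append(rid)

    for i in range(params.n_decoy_match):  # match, but hairpin score too high
        mid, mseq = matures[int(rng.integers(params.n_matures))]
        seq = _random_bases(rng, 2 * params.arm_len + params.loop_len, 0.5)
        offset = int(rng.integers(0, len(seq) - len(mseq) + 1))
        rid = f"DM{i:03d}"
        assembly.add(SequenceRecord(
            rid, seq[:offset] + mseq + seq[offset + len(mseq):],
            source_assembly="mirna"))
        scores[rid] = float(rng.uniform(0.72, 0.95))

    for i in range(params.n_decoy_score):  # score ok, mature at 3 mismatches
        mid, mseq = matures[int(rng.integers(params.n_matures))]
        arm = _random_bases(rng, params.arm_len, 0.5)
        offset = int(rng.integers(0, params.arm_len - len(mseq) + 1))
        arm = _embed_with_mismatches(rng, arm, mseq, offset, 3)
        rid = f"DS{i:03d}"
        assembly.add(SequenceRecord(rid, hairpin(arm), source_assembly="mirna"))
        scores[rid] = float(rng.uniform(0.30, 0.71))

    for i in range(params.n_decoy_plain):
        rid = f"DP{i:03d}"
        assembly.add(SequenceRecord(
            rid, _random_bases(rng, 2 * params.arm_len + params.loop_len, 0.5),
            source_assembly="mirna"))
        scores[rid] = 0.90

    return assembly, matures, HairpinScoreTable(scores=scores), manifest


def write_simulation(outdir: str | Path, params: SimParams = SimParams()) -> dict:
    """Generate everything and write it under ``outdir``.

    Writes one FASTA per assembler label, per-sample quant.sf files, the
    design CSV, the mature FASTA, hairpin score TSV and manifest JSON.
    Returns a dict of written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    assembly, manifest = simulate_transcriptome(params)
    quant, design = simulate_quant(manifest, params)
    lengths = {rid: e.length for rid, e in manifest.entries.items()}

    paths: dict[str, object] = {}
    fasta_paths = {}
    for label, sub in split_by_assembly(assembly).items():
        fasta_paths[label] = str(write_fasta(sub, outdir / f"{label}.fasta"))
    paths["assemblies"] = fasta_paths
    quant_paths, design_path = write_quant_files(quant, design, outdir, lengths)
    paths["quant"] = [str(p) for p in quant_paths]
    paths["design"] = str(design_path)
    paths["manifest"] = str(manifest.to_json(outdir / "manifest.json"))

    mirna_assembly, matures, score_table, mirna_manifest = simulate_mirna_fixture(params)
    paths["mirna_fasta"] = str(write_fasta(mirna_assembly, outdir / "mirna_transcripts.fasta"))
    with open(outdir / "matures.fasta", "w") as fh:
        for mid, seq in matures:
            fh.write(f">{mid}\n{seq.replace('T', 'U')}\n")
    paths["matures"] = str(outdir / "matures.fasta")
    paths["scores"] = str(score_table.to_tsv(outdir / "hairpin_scores.tsv"))
    (outdir / "mirna_expected.json").write_text(
        json.dumps({"expected_candidates": mirna_manifest.expected_candidates},
                   indent=1) + "\n")
    paths["mirna_expected"] = str(outdir / "mirna_expected.json")
    return paths
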