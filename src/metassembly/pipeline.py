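"""Pipeline orchestration: the full consolidation workflow in stage order.

Stages: (1) per-assembly expression filter (>= 1 TPM in at least one
condition level); (2) pool all survivors; (3) greedy identity clustering at
95% and representative selection; (4) coding-sequence consolidation into
genes; (5) containment pruning (> 90% own-length coverage by a longer
transcript); (6) mean-abundance filter (>= 0.1 TPM).  Each stage appends a
:class:`~metassembly.report.StageReport`; outputs (final FASTA, gene map,
cluster and containment TSVs, ledger JSON and stage table) are written
under the configured output directory.

The pipeline contains no unseeded randomness: re-running the same
configuration is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cluster import (ClusterAssignment, ClusterParams, greedy_cluster,
                      representatives, write_clusters_tsv)
from .consolidate import (ConsolidateParams, GeneGroup, consolidate,
                          select_okay_set, write_gene_map,
                          write_primary_proteins)
from .containment import (ContainmentHit, ContainmentParams,
                          containment_prune, write_hits_tsv)
from .errors import InputError, ValidationError
from .quant import (FilterThresholds, QuantTable, SampleDesign,
                    expression_filter, load_quant, mean_abundance_filter)
from .report import StageReport, render_report
from .seqio import AssemblySet, compute_stats, read_fasta, write_fasta


@dataclass
class PipelineConfig:
    """All inputs and thresholds of one pipeline run.

    ``assemblies`` is a list of (fasta path, label, library_group) triples;
    the library group (e.g. stranded/unstranded) is bookkeeping only.  The
    seed is recorded in every report for provenance; the pipeline itself is
    deterministic.
    """

    assemblies: list[tuple[str, str, str]]
    quant_paths: list[str]
    sample_ids: list[str]
    design_path: str
    outdir: str
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    cluster_params: ClusterParams = field(default_factory=ClusterParams)
    consolidate_params: ConsolidateParams = field(
        default_factory=ConsolidateParams)
    containment_params: ContainmentParams = field(
        default_factory=ContainmentParams)
    mature_path: str | None = None
    hairpin_score_path: str | None = None
    mirna_score_max: float = 0.71
    mirna_max_mismatch: int = 2
    seed: int = 0

    def validate_paths(self) -> None:
        for path, _, _ in self.assemblies:
            if not Path(path).exists():
                raise InputError(f"assembly not found: {path}")
        for path in self.quant_paths:
            if not Path(path).exists():
                raise InputError(f"quant file not found: {path}")
        if not Path(self.design_path).exists():
            raise InputError(f"design file not found: {self.design_path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        kwargs = dict(
            assemblies=[tuple(entry) for entry in raw["assemblies"]],
            quant_paths=list(raw["quant_paths"]),
            sample_ids=list(raw["sample_ids"]),
            design_path=raw["design_path"],
            outdir=raw["outdir"],
            seed=int(raw.get("seed", 0)),
        )
        if "thresholds" in raw:
            kwargs["thresholds"] = FilterThresholds(**raw["thresholds"])
        if "cluster" in raw:
            kwargs["cluster_params"] = ClusterParams(**raw["cluster"])
        if "consolidate" in raw:
            kwargs["consolidate_params"] = ConsolidateParams(**raw["consolidate"])
        if "containment" in raw:
            kwargs["containment_params"] = ContainmentParams(**raw["containment"])
        for key in ("mature_path", "hairpin_score_path"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


@dataclass
class PipelineResult:
    final: AssemblySet
    reports: list[StageReport]
    groups: list[GeneGroup]
    clusters: list[ClusterAssignment]
    hits: list[ContainmentHit]


def _stats_or_none(assembly: AssemblySet):
    return compute_stats(assembly) if len(assembly) else None


def run_pipeline(config: PipelineConfig,
                 assemblies: dict[str, AssemblySet] | None = None,
                 quant: QuantTable | None = None,
                 design: SampleDesign | None = None,
                 write_outputs: bool = True) -> PipelineResult:
    """Run all six stages and (optionally) write outputs.

    ``assemblies``/``quant``/``design`` may be supplied in memory to skip
    re-reading the configured paths (the CLI always reads from disk).
    """
    if assemblies is None:
        config.validate_paths()
        assemblies = {
            label: read_fasta(path, label=label, source_assembly=label)
            for path, label, _ in config.assemblies
        }
    if quant is None:
        quant = load_quant(config.quant_paths, config.sample_ids)
    if design is None:
        design = SampleDesign.from_csv(config.design_path)

    reports: list[StageReport] = []
    seed_echo = {"seed": config.seed}

    # (1) per-assembly expression filter
    filtered: list[AssemblySet] = []
    for label, assembly in assemblies.items():
        sub_quant = quant.subset(assembly.ids())
        kept = set(expression_filter(sub_quant, design, config.thresholds))
        # ids missing from the quant table have unknown (zero) abundance
        survivors = assembly.subset([i for i in assembly.ids() if i in kept])
        reports.append(StageReport(
            stage=f"expression_filter[{label}]",
            input_n=len(assembly),
            kept_n=len(survivors),
            removed_n=len(assembly) - len(survivors),
            stats_before=_stats_or_none(assembly),
            stats_after=_stats_or_none(survivors),
            parameters={"condition_tpm_min": config.thresholds.condition_tpm_min,
                        **seed_echo},
        ))
        filtered.append(survivors)

    # (2) pool survivors across assemblers
    pooled = AssemblySet(label="pooled")
    for sub in filtered:
        for rec in sub:
            pooled.add(rec)
    if len(pooled) == 0:
        raise ValidationError("no transcripts survive the expression filter")
    reports.append(StageReport(
        stage="pool", input_n=len(pooled), kept_n=len(pooled), removed_n=0,
        stats_before=_stats_or_none(pooled), stats_after=_stats_or_none(pooled),
        parameters=dict(seed_echo),
    ))

    # (3) identity clustering -> representatives
    clusters = greedy_cluster(pooled, config.cluster_params)
    reps = representatives(clusters, pooled)
    reports.append(StageReport(
        stage="cluster", input_n=len(pooled), kept_n=len(reps),
        removed_n=len(pooled) - len(reps),
        stats_before=_stats_or_none(pooled), stats_after=_stats_or_none(reps),
        parameters={"identity_min": config.cluster_params.identity_min,
                    "kmer_size": config.cluster_params.kmer_size,
                    "both_strands": config.cluster_params.both_strands,
                    "assign_mode": config.cluster_params.assign_mode,
                    **seed_echo},
    ))

    # (4) coding-sequence consolidation (grouping only; nothing dropped)
    groups = consolidate(reps, config.consolidate_params)
    okay = select_okay_set(groups, reps)
    reports.append(StageReport(
        stage="consolidate", input_n=len(reps), kept_n=len(okay),
        removed_n=len(reps) - len(okay),
        stats_before=_stats_or_none(reps), stats_after=_stats_or_none(okay),
        parameters={"min_cds": config.consolidate_params.min_cds,
                    "althi_min": config.consolidate_params.althi_min,
                    "altmid_min": config.consolidate_params.altmid_min,
                    "part_max_frac": config.consolidate_params.part_max_frac,
                    "n_genes": len(groups), **seed_echo},
    ))

    # (5) containment pruning
    pruned, hits = containment_prune(okay, config.containment_params)
    reports.append(StageReport(
        stage="containment", input_n=len(okay), kept_n=len(pruned),
        removed_n=len(okay) - len(pruned),
        stats_before=_stats_or_none(okay), stats_after=_stats_or_none(pruned),
        parameters={"coverage_min": config.containment_params.coverage_min,
                    "block_identity_min": config.containment_params.block_identity_min,
                    "kmer_size": config.containment_params.kmer_size,
                    **seed_echo},
    ))

    # (6) mean-abundance filter
    final_quant = quant.subset(pruned.ids())
    kept_ids = set(mean_abundance_filter(final_quant, config.thresholds))
    final = pruned.subset([i for i in pruned.ids() if i in kept_ids])
    reports.append(StageReport(
        stage="abundance_filter", input_n=len(pruned), kept_n=len(final),
        removed_n=len(pruned) - len(final),
        stats_before=_stats_or_none(pruned), stats_after=_stats_or_none(final),
        parameters={"mean_tpm_min": config.thresholds.mean_tpm_min, **seed_echo},
    ))

    result = PipelineResult(final=final, reports=reports, groups=groups,
                            clusters=clusters, hits=hits)
    if write_outputs:
        _write_outputs(config, result)
    return result


def _write_outputs(config: PipelineConfig, result: PipelineResult) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(result.final, outdir / "final.fasta")
    write_clusters_tsv(result.clusters, outdir / "clusters.tsv")
    write_hits_tsv(result.hits, outdir / "containment_hits.tsv")
    write_gene_map(result.groups, outdir / "gene_map.tsv")
    write_primary_proteins(result.groups, outdir / "primary_proteins.fasta")
    final_ids = set(result.final.ids())
    surviving = [
        g for g in result.groups if any(t in final_ids for t in g.members)
    ]
    with open(outdir / "final_gene_map.tsv", "w") as fh:
        fh.write("gene_id\ttranscript_id\tcategory\n")
        for group in surviving:
            for tid, category in group.members.items():
                if tid in final_ids:
                    fh.write(f"{group.gene_id}\t{tid}\t{category}\n")
    render_report(result.reports, outdir / "ledger.json", outdir / "stage_table.txt")
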