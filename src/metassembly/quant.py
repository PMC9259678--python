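"""Expression-based transcript filters over Salmon-style quantification.

Two filters are applied at different pipeline stages:

* the *per-condition* filter on raw assemblies: keep a transcript iff the
  mean TPM within at least one level of at least one experimental factor
  (e.g. season, area, sex) reaches ``condition_tpm_min`` (default 1 TPM,
  boundary inclusive);
* the *mean-abundance* filter on the consolidated set: keep a transcript
  iff its mean TPM across all samples is not strictly below
  ``mean_tpm_min`` (default 0.1 TPM).

Quantifications are read from the ``quant.sf`` TSV dialect (columns Name,
Length, EffectiveLength, TPM, NumReads), one file per sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import FormatError, InputError, ValidationError

logger = logging.getLogger(__name__)

QUANT_COLUMNS = ["Name", "Length", "EffectiveLength", "TPM", "NumReads"]


@dataclass(frozen=True)
class FilterThresholds:
    """The two expression thresholds, in TPM units."""

    condition_tpm_min: float = 1.0
    mean_tpm_min: float = 0.1

    def __post_init__(self) -> None:
        if self.condition_tpm_min < 0 or self.mean_tpm_min < 0:
            raise ValidationError("TPM thresholds must be non-negative")


@dataclass
class QuantTable:
    """TPM and read-count matrices indexed (transcript, sample).

    Backed by two aligned pandas DataFrames; row order is the transcript
    ingest order and is preserved by every operation.
    """

    tpm: pd.DataFrame
    num_reads: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.tpm.index) != list(self.num_reads.index) or list(
            self.tpm.columns
        ) != list(self.num_reads.columns):
            raise ValidationError("tpm and num_reads matrices are not aligned")
        if self.tpm.index.has_duplicates:
            raise ValidationError("duplicate transcript ids in quant table")
        if self.tpm.columns.has_duplicates:
            raise ValidationError("duplicate sample ids in quant table")
        if (self.tpm.values < 0).any() or (self.num_reads.values < 0).any():
            raise ValidationError("negative entries in quant table")

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.tpm.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.tpm.columns)

    def subset(self, transcript_ids: Sequence[str]) -> "QuantTable":
        keep = [t for t in self.transcript_ids if t in set(transcript_ids)]
        return QuantTable(tpm=self.tpm.loc[keep], num_reads=self.num_reads.loc[keep])


@dataclass
class SampleDesign:
    """Mapping of samples to experimental factor levels."""

    sample_ids: list[str]
    factors: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids in design")
        for name, levels in self.factors.items():
            for sample in self.sample_ids:
                if sample not in levels:
                    raise ValidationError(
                        f"sample {sample!r} has no level for factor {name!r}"
                    )
                if not levels[sample]:
                    raise ValidationError(
                        f"empty level label for sample {sample!r}, factor {name!r}"
                    )

    @classmethod
    def from_csv(cls, path: str | Path) -> "SampleDesign":
        """Read a design sheet: CSV with header ``sample,<factor1>,<factor2>,...``"""
        path = Path(path)
        if not path.exists():
            raise InputError(f"design file not found: {path}")
        df = pd.read_csv(path, dtype=str)
        if df.columns[0] != "sample":
            raise FormatError(
                f"design sheet must start with a 'sample' column, got {df.columns[0]!r}"
            )
        samples = list(df["sample"])
        factors = {
            col: dict(zip(samples, df[col])) for col in df.columns[1:]
        }
        return cls(sample_ids=samples, factors=factors)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        rows = {"sample": self.sample_ids}
        for name, levels in self.factors.items():
            rows[name] = [levels[s] for s in self.sample_ids]
        pd.DataFrame(rows).to_csv(path, index=False)
        return path


def _read_quant_file(path: Path) -> pd.DataFrame:
    if not path.exists():
        raise InputError(f"quant file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in QUANT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing} in quant header")
    for col in ("TPM", "NumReads"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            # +2: one for the header line, one for 0-based indexing
            line = int(bad.idxmax()) + 2
            raise FormatError(f"{path}: non-numeric {col} value on line {line}")
        df[col] = numeric
    if df["Name"].duplicated().any():
        dup = df["Name"][df["Name"].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate transcript name {dup!r}")
    return df


def load_quant(paths: Sequence[str | Path], sample_ids: Sequence[str]) -> QuantTable:
    """Assemble per-sample ``quant.sf`` files into a :class:`QuantTable`.

    Transcript rows are the union of Names across files, ordered by first
    appearance; a transcript absent from some file gets TPM 0 there (with a
    logged warning), since assemblies and quantifications may be regenerated
    independently.
    """
    if len(paths) != len(sample_ids):
        raise ValidationError("one quant file per sample id is required")
    if not paths:
        raise ValidationError("no quant files given")
    frames = {sid: _read_quant_file(Path(p)) for p, sid in zip(paths, sample_ids)}
    order: list[str] = []
    seen: set[str] = set()
    for df in frames.values():
        for name in df["Name"]:
            if name not in seen:
                seen.add(name)
                order.append(name)
    tpm = pd.DataFrame(0.0, index=order, columns=list(sample_ids))
    reads = pd.DataFrame(0.0, index=order, columns=list(sample_ids))
    for sid, df in frames.items():
        absent = len(order) - len(df)
        if absent:
            logger.warning(
                "sample %s: %d transcript(s) absent from its quant file; TPM set to 0",
                sid, absent,
            )
        tpm.loc[list(df["Name"]), sid] = df["TPM"].to_numpy(dtype=float)
        reads.loc[list(df["Name"]), sid] = df["NumReads"].to_numpy(dtype=float)
    return QuantTable(tpm=tpm, num_reads=reads)


def condition_level_means(
    quant: QuantTable, design: SampleDesign, factor: str
) -> dict[str, pd.Series]:
    """Arithmetic mean TPM per transcript within each level of ``factor``."""
    if factor not in design.factors:
        raise ValidationError(f"unknown factor {factor!r}")
    levels = design.factors[factor]
    unknown = [s for s in quant.sample_ids if s not in levels]
    if unknown:
        raise ValidationError(f"samples not in design: {unknown}")
    out: dict[str, pd.Series] = {}
    for level in sorted(set(levels[s] for s in quant.sample_ids)):
        cols = [s for s in quant.sample_ids if levels[s] == level]
        out[level] = quant.tpm[cols].mean(axis=1)
    return out


def expression_filter(
    quant: QuantTable,
    design: SampleDesign,
    thresholds: FilterThresholds = FilterThresholds(),
) -> list[str]:
    """Per-condition expression filter on a raw assembly.

    A transcript is kept iff the mean TPM of at least one level of at least
    one declared factor reaches ``condition_tpm_min`` (inclusive).  Returns
    the kept ids in quant-table (ingest) order.
    """
    if not design.factors:
        raise ValidationError("design declares no factors")
    kept = pd.Series(False, index=quant.tpm.index)
    for factor in design.factors:
        for level_means in condition_level_means(quant, design, factor).values():
            kept |= level_means >= thresholds.condition_tpm_min
    return [t for t, ok in kept.items() if ok]


def mean_abundance_filter(
    quant: QuantTable, thresholds: FilterThresholds = FilterThresholds()
) -> list[str]:
    """Keep transcripts whose mean TPM over all samples is not strictly
    below ``mean_tpm_min`` (a mean of exactly the threshold is kept)."""
    if not quant.transcript_ids:
        raise ValidationError("empty quant table")
    means = quant.tpm.mean(axis=1)
    return [t for t, m in means.items() if m >= thresholds.mean_tpm_min]


def write_id_list(ids: Sequence[str], path: str | Path) -> Path:
    path = Path(path)
    path.write_text("".join(f"{t}\n" for t in ids))
    return path


def filter_report(input_n: int, kept_n: int, thresholds: FilterThresholds) -> dict:
    return {
        "input_n": input_n,
        "kept_n": kept_n,
        "removed_n": input_n - kept_n,
        "thresholds": {
            "condition_tpm_min": thresholds.condition_tpm_min,
            "mean_tpm_min": thresholds.mean_tpm_min,
        },
    }
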