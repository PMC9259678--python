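"""Shared fixtures: seeded RNGs, small random assemblies, and one
session-scoped full pipeline run on the default synthetic dataset."""

from __future__ import annotations

import numpy as np
import pytest

from metassembly.pipeline import PipelineConfig, run_pipeline
from metassembly.seqio import AssemblySet, SequenceRecord
from metassembly.simulate import (SimParams, simulate_quant,
                                  simulate_transcriptome, split_by_assembly)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return BASES[rng.choice(4, size=n, p=p)].tobytes().decode()


def mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    arr = list(seq)
    pos = rng.choice(len(arr), size=n_subs, replace=False)
    for i in pos:
        arr[i] = "ACGT"[("ACGT".index(arr[i]) + 1 + int(rng.integers(3))) % 4]
    return "".join(arr)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def small_assembly(rng) -> AssemblySet:
    asm = AssemblySet(label="random")
    for i in range(50):
        asm.add(SequenceRecord(f"r{i:03d}", random_seq(rng, int(rng.integers(100, 800)))))
    return asm


@pytest.fixture(scope="session")
def default_sim():
    """Default-condition synthetic dataset (seed fixed for the suite)."""
    params = SimParams(seed=7)
    assembly, manifest = simulate_transcriptome(params)
    quant, design = simulate_quant(manifest, params)
    return params, assembly, manifest, quant, design


@pytest.fixture(scope="session")
def default_pipeline_run(default_sim, tmp_path_factory):
    """Full pipeline on the default synthetic dataset, run once per session."""
    params, assembly, manifest, quant, design = default_sim
    outdir = tmp_path_factory.mktemp("pipeline")
    config = PipelineConfig(assemblies=[], quant_paths=[], sample_ids=[],
                            design_path="", outdir=str(outdir), seed=params.seed)
    result = run_pipeline(config, assemblies=split_by_assembly(assembly),
                          quant=quant, design=design, write_outputs=True)
    return config, result
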