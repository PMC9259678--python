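"""Expression filters: quant.sf loading, level means, both TPM filters."""

import numpy as np
import pandas as pd
import pytest

from metassembly.errors import FormatError, ValidationError
from metassembly.quant import (FilterThresholds, QuantTable, SampleDesign,
                               condition_level_means, expression_filter,
                               load_quant, mean_abundance_filter)


def make_quant(tpm: dict[str, list[float]], samples: list[str]) -> QuantTable:
    df = pd.DataFrame(tpm, index=samples).T
    df.columns = samples
    return QuantTable(tpm=df, num_reads=df * 10)


def write_quant_sf(path, names, tpms):
    lines = ["Name\tLength\tEffectiveLength\tTPM\tNumReads"]
    for name, tpm in zip(names, tpms):
        lines.append(f"{name}\t1000\t850\t{tpm}\t{tpm * 10}")
    path.write_text("\n".join(lines) + "\n")


class TestLoadQuant:
    def test_two_files_identical_names(self, tmp_path):
        write_quant_sf(tmp_path / "s1.sf", ["t1", "t2"], [5.0, 0.0])
        write_quant_sf(tmp_path / "s2.sf", ["t1", "t2"], [1.5, 2.0])
        quant = load_quant([tmp_path / "s1.sf", tmp_path / "s2.sf"], ["s1", "s2"])
        assert quant.transcript_ids == ["t1", "t2"]
        assert quant.tpm.loc["t2", "s2"] == 2.0

    def test_missing_column_reported(self, tmp_path):
        (tmp_path / "bad.sf").write_text("Name\tLength\tNumReads\na\t1\t2\n")
        with pytest.raises(FormatError, match="TPM"):
            load_quant([tmp_path / "bad.sf"], ["s1"])

    def test_non_numeric_tpm_line_number(self, tmp_path):
        (tmp_path / "bad.sf").write_text(
            "Name\tLength\tEffectiveLength\tTPM\tNumReads\n"
            "a\t10\t5\t1.0\t3\nb\t10\t5\toops\t3\n")
        with pytest.raises(FormatError, match="line 3"):
            load_quant([tmp_path / "bad.sf"], ["s1"])

    def test_union_of_names_fills_zero(self, tmp_path):
        write_quant_sf(tmp_path / "s1.sf", ["t1", "t2"], [5.0, 1.0])
        write_quant_sf(tmp_path / "s2.sf", ["t1"], [3.0])
        quant = load_quant([tmp_path / "s1.sf", tmp_path / "s2.sf"], ["s1", "s2"])
        assert quant.tpm.loc["t2", "s2"] == 0.0


def two_level_design(samples):
    half = len(samples) // 2
    season = {s: ("summer" if i < half else "winter") for i, s in enumerate(samples)}
    return SampleDesign(sample_ids=samples, factors={"season": season})


class TestConditionLevelMeans:
    def test_single_level_is_overall_mean(self):
        quant = make_quant({"t1": [1.0, 3.0], "t2": [0.0, 8.0]}, ["s1", "s2"])
        design = SampleDesign(sample_ids=["s1", "s2"],
                              factors={"f": {"s1": "x", "s2": "x"}})
        means = condition_level_means(quant, design, "f")
        assert means["x"]["t1"] == 2.0 and means["x"]["t2"] == 4.0

    def test_singleton_levels_equal_sample_values(self):
        quant = make_quant({"t1": [1.0, 3.0]}, ["s1", "s2"])
        design = SampleDesign(sample_ids=["s1", "s2"],
                              factors={"f": {"s1": "a", "s2": "b"}})
        means = condition_level_means(quant, design, "f")
        assert means["a"]["t1"] == 1.0 and means["b"]["t1"] == 3.0

    def test_matches_naive_loop_oracle(self, rng):
        samples = [f"s{i}" for i in range(6)]
        tpm = {f"t{i}": list(rng.uniform(0, 50, 6)) for i in range(20)}
        quant = make_quant(tpm, samples)
        design = two_level_design(samples)
        means = condition_level_means(quant, design, "season")
        for level in ("summer", "winter"):
            cols = [s for s in samples if design.factors["season"][s] == level]
            for tid in tpm:
                expected = sum(
                    tpm[tid][samples.index(c)] for c in cols) / len(cols)
                assert means[level][tid] == pytest.approx(expected)

    def test_unknown_factor_and_sample_errors(self):
        quant = make_quant({"t1": [1.0]}, ["s1"])
        design = SampleDesign(sample_ids=["s1"], factors={"f": {"s1": "x"}})
        with pytest.raises(ValidationError):
            condition_level_means(quant, design, "nope")
        design2 = SampleDesign(sample_ids=["sX"], factors={"f": {"sX": "x"}})
        with pytest.raises(ValidationError):
            condition_level_means(quant, design2, "f")


class TestExpressionFilter:
    def test_all_zero_removed(self):
        quant = make_quant({"t1": [0.0, 0.0], "t2": [9.0, 9.0]}, ["s1", "s2"])
        kept = expression_filter(quant, two_level_design(["s1", "s2"]))
        assert kept == ["t2"]

    def test_level_mean_exactly_one_kept(self):
        # threshold is inclusive: a single level mean of exactly 1.0 keeps
        quant = make_quant({"t1": [1.0, 1.0, 0.0, 0.0]}, ["s1", "s2", "s3", "s4"])
        kept = expression_filter(quant, two_level_design(["s1", "s2", "s3", "s4"]))
        assert kept == ["t1"]
        quant2 = make_quant({"t1": [0.99, 0.99, 0.0, 0.0]}, ["s1", "s2", "s3", "s4"])
        assert expression_filter(quant2, two_level_design(["s1", "s2", "s3", "s4"])) == []

    def test_matches_exhaustive_enumeration_oracle(self, rng):
        samples = [f"s{i}" for i in range(8)]
        factors = {
            "season": {s: ("su" if i % 2 else "wi") for i, s in enumerate(samples)},
            "area": {s: "abc"[i % 3] for i, s in enumerate(samples)},
            "sex": {s: ("F" if i < 4 else "M") for i, s in enumerate(samples)},
        }
        design = SampleDesign(sample_ids=samples, factors=factors)
        tpm = {f"t{i}": list(rng.uniform(0, 2.2, 8).round(2)) for i in range(50)}
        quant = make_quant(tpm, samples)
        kept = expression_filter(quant, design)
        expected = []
        for tid, values in tpm.items():
            ok = False
            for fac, levels in factors.items():
                for level in set(levels.values()):
                    cols = [i for i, s in enumerate(samples) if levels[s] == level]
                    if sum(values[i] for i in cols) / len(cols) >= 1.0:
                        ok = True
            if ok:
                expected.append(tid)
        assert kept == expected

    def test_idempotent_and_monotone(self, rng):
        samples = [f"s{i}" for i in range(6)]
        quant = make_quant({f"t{i}": list(rng.uniform(0, 3, 6)) for i in range(40)},
                           samples)
        design = two_level_design(samples)
        kept = expression_filter(quant, design)
        again = expression_filter(quant.subset(kept), design)
        assert again == kept
        stricter = expression_filter(
            quant, design, FilterThresholds(condition_tpm_min=2.0))
        assert set(stricter) <= set(kept)

    def test_invariant_under_consistent_permutation(self, rng):
        samples = [f"s{i}" for i in range(6)]
        tpm = {f"t{i}": list(rng.uniform(0, 3, 6)) for i in range(30)}
        quant = make_quant(tpm, samples)
        design = two_level_design(samples)
        perm = list(reversed(samples))
        quant_p = QuantTable(tpm=quant.tpm[perm], num_reads=quant.num_reads[perm])
        assert expression_filter(quant, design) == expression_filter(quant_p, design)


class TestMeanAbundanceFilter:
    def test_boundary_exactly_point_one_kept(self):
        # "below 0.1" is strict: a mean of exactly 0.1 survives
        quant = make_quant({"t1": [0.1, 0.1], "t2": [0.0999, 0.0999]}, ["s1", "s2"])
        assert mean_abundance_filter(quant) == ["t1"]

    def test_matches_naive_oracle(self, rng):
        samples = [f"s{i}" for i in range(4)]
        tpm = {f"t{i}": list(rng.uniform(0, 0.3, 4)) for i in range(100)}
        quant = make_quant(tpm, samples)
        kept = mean_abundance_filter(quant)
        expected = [t for t, v in tpm.items() if np.mean(v) >= 0.1]
        assert kept == expected

    def test_idempotent(self, rng):
        samples = ["s1", "s2"]
        quant = make_quant({f"t{i}": list(rng.uniform(0, 0.3, 2)) for i in range(30)},
                           samples)
        kept = mean_abundance_filter(quant)
        assert mean_abundance_filter(quant.subset(kept)) == kept


def test_negative_tpm_rejected():
    with pytest.raises(ValidationError):
        make_quant({"t1": [-1.0]}, ["s1"])
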