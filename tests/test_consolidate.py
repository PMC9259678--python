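"""ORF calling and coding-sequence gene consolidation."""

import pytest

from metassembly.consolidate import (ConsolidateParams, consolidate,
                                     find_longest_orf, select_okay_set)
from metassembly.errors import ValidationError
from metassembly.seqio import AssemblySet, SequenceRecord
from oracles import orf_oracle, rc

from conftest import random_seq


def make_cds(rng, n_codons: int) -> str:
    """ATG + stop-free random codons + TAA."""
    stops = {"TAA", "TAG", "TGA"}
    codons = []
    while len(codons) < n_codons:
        c = random_seq(rng, 3)
        if c not in stops:
            codons.append(c)
    return "ATG" + "".join(codons) + "TAA"


class TestFindLongestOrf:
    def test_minimal_complete_orf(self):
        rec = SequenceRecord("a", "ATGAAATAG")
        orf = find_longest_orf(rec, min_cds=9)
        assert orf.cds_length == 9
        assert orf.protein == "MK"
        assert orf.complete
        assert orf.frame == 1 and orf.cds_start == 0 and orf.cds_end == 9

    def test_reverse_complement_same_protein(self):
        rec = SequenceRecord("a", rc("ATGAAATAG"))
        orf = find_longest_orf(rec, min_cds=9)
        assert orf.protein == "MK"
        assert orf.frame == -1

    def test_none_when_below_min(self):
        assert find_longest_orf(SequenceRecord("a", "CCCCCC"), min_cds=9) is None

    def test_open_ended_orf_flagged_incomplete(self):
        rec = SequenceRecord("a", "ATGAAAAAAAAA")
        orf = find_longest_orf(rec, min_cds=9)
        assert not orf.complete
        assert orf.cds_length == 12

    def test_matches_six_frame_enumeration_oracle(self, rng):
        for _ in range(150):
            seq = random_seq(rng, int(rng.integers(60, 400)))
            rec = SequenceRecord("a", seq)
            got = find_longest_orf(rec, min_cds=30)
            expected = orf_oracle(seq, 30)
            if expected is None:
                assert got is None
                continue
            length, strand_idx, off, start, has_stop = expected
            assert got.cds_length == length
            assert (got.frame > 0) == (strand_idx == 0)
            assert abs(got.frame) == off + 1
            scanned = seq if strand_idx == 0 else rc(seq)
            assert got.cds == scanned[start:start + length]
            assert got.complete == has_stop

    def test_invalid_min_cds(self):
        with pytest.raises(ValidationError):
            find_longest_orf(SequenceRecord("a", "ATGAAATAG"), min_cds=10)


def isoform_family(rng, n_genes=5, isoforms=3, cds_codons=120):
    """Gene families sharing an identical CDS core with unique UTRs."""
    asm = AssemblySet(label="families")
    truth = {}
    for g in range(n_genes):
        cds = make_cds(rng, cds_codons)
        for i in range(isoforms):
            utr5 = random_seq(rng, int(rng.integers(80, 200)))
            utr3 = random_seq(rng, int(rng.integers(80, 200)))
            rid = f"g{g}i{i}"
            asm.add(SequenceRecord(rid, utr5[:-3] + "TAA" + cds + utr3))
            truth[rid] = g
    return asm, truth


class TestConsolidate:
    def test_unrelated_coding_transcripts_are_noclass_singletons(self, rng):
        asm = AssemblySet(records=[
            SequenceRecord(f"u{i}", random_seq(rng, 60) + make_cds(rng, 80)
                           + random_seq(rng, 60))
            for i in range(6)
        ])
        groups = consolidate(asm)
        assert len(groups) == 6
        assert all(list(g.members.values()) == ["noclass"] for g in groups)

    def test_embedded_cds_copy_is_althi(self, rng):
        cds = make_cds(rng, 150)
        primary = random_seq(rng, 100) + "TAA" + cds + random_seq(rng, 100)
        copy = random_seq(rng, 300) + "TAA" + cds + random_seq(rng, 350)
        asm = AssemblySet(records=[SequenceRecord("p", primary),
                                   SequenceRecord("c", copy)])
        groups = consolidate(asm)
        assert len(groups) == 1
        group = groups[0]
        assert group.primary_id == "c"  # same CDS, longer transcript wins
        assert group.members["p"] == "althi"
        assert group.members["c"] == "main"

    def test_planted_families_recovered(self, rng):
        asm, truth = isoform_family(rng)
        groups = consolidate(asm)
        assert len(groups) == 5
        for group in groups:
            genes = {truth[t] for t in group.members}
            assert len(genes) == 1
            categories = sorted(group.members.values())
            assert categories == ["althi", "althi", "main"]

    def test_noncoding_singletons(self, rng):
        # random 200-mers rarely contain a 300-base ORF
        asm = AssemblySet(records=[
            SequenceRecord(f"n{i}", random_seq(rng, 200)) for i in range(5)])
        groups = consolidate(asm, ConsolidateParams(min_cds=300))
        assert len(groups) == 5
        for group in groups:
            assert list(group.members.values()) == ["noncoding"]
            assert not group.coding[group.primary_id]

    def test_partition_property_and_gene_ids(self, rng):
        asm, _ = isoform_family(rng, n_genes=4, isoforms=2)
        groups = consolidate(asm)
        seen = [t for g in groups for t in g.members]
        assert sorted(seen) == sorted(asm.ids())
        assert [g.gene_id for g in groups] == [
            f"ESG{i + 1:06d}" for i in range(len(groups))]

    def test_part_category_for_truncated_cds(self, rng):
        cds = make_cds(rng, 200)
        full = random_seq(rng, 100) + "TAA" + cds + random_seq(rng, 100)
        # fragment carries only 40% of the CDS (below part_max_frac 0.70)
        frag_cds = cds[: (int(len(cds) * 0.4) // 3) * 3]
        frag = random_seq(rng, 50) + "TAA" + frag_cds + "TAA" + random_seq(rng, 50)
        asm = AssemblySet(records=[SequenceRecord("full", full),
                                   SequenceRecord("frag", frag)])
        groups = consolidate(asm)
        assert len(groups) == 1
        assert groups[0].members["frag"] == "part"

    def test_deterministic_under_permutation(self, rng):
        asm, _ = isoform_family(rng, n_genes=4, isoforms=3)
        perm = list(asm)
        rng.shuffle(perm)
        g1 = consolidate(asm)
        g2 = consolidate(AssemblySet(records=perm))
        partition1 = {frozenset(g.members) for g in g1}
        partition2 = {frozenset(g.members) for g in g2}
        assert partition1 == partition2
        assert {g.primary_id for g in g1} == {g.primary_id for g in g2}

    def test_parameter_validation(self):
        with pytest.raises(ValidationError):
            ConsolidateParams(althi_min=0.5, altmid_min=0.9)
        with pytest.raises(ValidationError):
            ConsolidateParams(part_max_frac=1.5)


class TestSelectOkaySet:
    def test_default_profile_is_identity(self, rng):
        asm, _ = isoform_family(rng, n_genes=3, isoforms=2)
        groups = consolidate(asm)
        assert select_okay_set(groups, asm).ids() == asm.ids()

    def test_drop_part_excludes_exactly_parts(self, rng):
        cds = make_cds(rng, 200)
        full = random_seq(rng, 100) + "TAA" + cds + random_seq(rng, 100)
        frag_cds = cds[: (int(len(cds) * 0.4) // 3) * 3]
        frag = random_seq(rng, 50) + "TAA" + frag_cds + "TAA" + random_seq(rng, 50)
        asm = AssemblySet(records=[SequenceRecord("full", full),
                                   SequenceRecord("frag", frag)])
        groups = consolidate(asm)
        kept = select_okay_set(groups, asm, drop_part=True)
        assert kept.ids() == ["full"]

    def test_drop_noncoding_matches_manifest(self, rng):
        coding = [SequenceRecord(f"c{i}", random_seq(rng, 60) + make_cds(rng, 100)
                                 + random_seq(rng, 60)) for i in range(4)]
        noncoding = [SequenceRecord(f"n{i}", random_seq(rng, 150)) for i in range(3)]
        asm = AssemblySet(records=coding + noncoding)
        groups = consolidate(asm, ConsolidateParams(min_cds=240))
        kept = select_okay_set(groups, asm, drop_noncoding=True)
        assert kept.ids() == [r.id for r in coding]
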