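"""Greedy identity clustering against full-DP oracles."""

import numpy as np
import pytest

from metassembly.cluster import (ClusterParams, greedy_cluster,
                                 pairwise_identity, representatives)
from metassembly.errors import ValidationError
from metassembly.seqio import AssemblySet, SequenceRecord
from oracles import identity_oracle, rc

from conftest import mutate, random_seq


class TestPairwiseIdentity:
    def test_identical_sequences(self, rng):
        s = random_seq(rng, 300)
        assert pairwise_identity(s, s) == 1.0

    def test_exact_substring_scores_one(self, rng):
        s = random_seq(rng, 500)
        assert pairwise_identity(s[100:300], s) == 1.0

    def test_reverse_strand(self, rng):
        s = random_seq(rng, 200)
        assert pairwise_identity(s, rc(s), strand="reverse") == 1.0

    def test_matches_dp_oracle_on_mutated_pairs(self, rng):
        for _ in range(200):
            n = int(rng.integers(60, 320))
            a = random_seq(rng, n)
            n_subs = int(rng.integers(0, max(1, n // 10)))
            b = mutate(rng, a, n_subs)
            if rng.random() < 0.3:  # sometimes embed in a longer context
                b = random_seq(rng, 40) + b + random_seq(rng, 40)
            assert pairwise_identity(a, b) == pytest.approx(
                identity_oracle(a, b), abs=1e-9)

    def test_unrelated_sequences_below_threshold(self, rng):
        a, b = random_seq(rng, 400), random_seq(rng, 400)
        assert pairwise_identity(a, b) < 0.95


def family_fixture(rng, n_families=20, members=5, length=400):
    """Planted partition: intra-family identity >= 0.97, inter < 0.8."""
    asm = AssemblySet(label="families")
    truth = {}
    for f in range(n_families):
        base = random_seq(rng, length)
        for m in range(members):
            seq = base if m == 0 else mutate(rng, base, int(0.03 * length * rng.random()))
            rid = f"f{f:02d}m{m}"
            asm.add(SequenceRecord(rid, seq))
            truth[rid] = f
    return asm, truth


class TestGreedyCluster:
    def test_two_identical_sequences_merge(self, rng):
        s = random_seq(rng, 200)
        asm = AssemblySet(records=[SequenceRecord("a", s), SequenceRecord("b", s)])
        clusters = greedy_cluster(asm)
        assert len(clusters) == 1 and len(clusters[0].member_ids) == 2
        assert clusters[0].representative_id == "a"  # equal length: id order

    def test_threshold_boundary_96_vs_94(self, rng):
        # 95% is the collapse threshold: 4% mutations merge, 6% split
        base = random_seq(rng, 1000)
        near = mutate(rng, base, 40)   # 96% identity
        far = mutate(rng, base, 60)    # 94% identity
        asm_near = AssemblySet(records=[SequenceRecord("a", base),
                                        SequenceRecord("b", near)])
        asm_far = AssemblySet(records=[SequenceRecord("a", base),
                                       SequenceRecord("b", far)])
        assert len(greedy_cluster(asm_near)) == 1
        assert len(greedy_cluster(asm_far)) == 2

    def test_planted_partition_recovery(self, rng):
        asm, truth = family_fixture(rng)
        clusters = greedy_cluster(asm)
        assert len(clusters) == 20
        for cluster in clusters:
            families = {truth[m] for m in cluster.member_ids}
            assert len(families) == 1

    def test_members_reach_threshold_and_rep_is_longest(self, rng):
        asm, _ = family_fixture(rng, n_families=8, members=4)
        clusters = greedy_cluster(asm)
        lengths = {r.id: len(r) for r in asm}
        for cluster in clusters:
            rep_len = lengths[cluster.representative_id]
            for member in cluster.member_ids:
                assert cluster.member_identities[member] >= 0.95
                assert lengths[member] <= rep_len
                # oracle check of the stored identity
                assert cluster.member_identities[member] == pytest.approx(
                    identity_oracle(asm.get(member).bases,
                                    asm.get(cluster.representative_id).bases,
                                    both_strands=True), abs=1e-9)

    def test_new_reps_mutually_below_threshold(self, rng):
        asm, _ = family_fixture(rng, n_families=10, members=3)
        clusters = greedy_cluster(asm)
        reps = [asm.get(c.representative_id).bases for c in clusters]
        for i in range(len(reps)):
            for j in range(i + 1, len(reps)):
                assert identity_oracle(reps[i], reps[j], both_strands=True) < 0.95

    def test_reverse_strand_members_detected(self, rng):
        s = random_seq(rng, 300)
        asm = AssemblySet(records=[SequenceRecord("a", s + "ACGT"),
                                   SequenceRecord("b", rc(s))])
        clusters = greedy_cluster(asm)
        assert len(clusters) == 1
        assert clusters[0].member_strand["b"] == "reverse"

    def test_permutation_invariance(self, rng):
        asm, _ = family_fixture(rng, n_families=6, members=4, length=250)
        perm_records = list(asm)
        rng.shuffle(perm_records)
        c1 = greedy_cluster(asm)
        c2 = greedy_cluster(AssemblySet(records=perm_records))
        as_sets = lambda cs: {
            (c.representative_id, frozenset(c.member_ids)) for c in cs
        }
        assert as_sets(c1) == as_sets(c2)

    def test_prefilter_soundness(self, rng):
        asm, _ = family_fixture(rng, n_families=6, members=4, length=250)
        with_pf = greedy_cluster(asm, ClusterParams(use_prefilter=True))
        without_pf = greedy_cluster(asm, ClusterParams(use_prefilter=False))
        assert [
            (c.representative_id, c.member_ids) for c in with_pf
        ] == [(c.representative_id, c.member_ids) for c in without_pf]

    def test_empty_assembly_rejected(self):
        with pytest.raises(ValidationError):
            greedy_cluster(AssemblySet())


class TestRepresentatives:
    def test_duplicate_free_set_is_identity(self, rng):
        asm = AssemblySet(records=[
            SequenceRecord(f"u{i}", random_seq(rng, 200)) for i in range(10)])
        clusters = greedy_cluster(asm)
        reps = representatives(clusters, asm)
        assert reps.ids() == asm.ids()

    def test_size_equals_cluster_count(self, rng):
        asm, _ = family_fixture(rng, n_families=5, members=3, length=200)
        clusters = greedy_cluster(asm)
        reps = representatives(clusters, asm)
        assert len(reps) == len(clusters) == 5

    def test_dangling_id_rejected(self, rng):
        asm = AssemblySet(records=[SequenceRecord("a", random_seq(rng, 50))])
        clusters = greedy_cluster(asm)
        clusters[0].representative_id = "ghost"
        with pytest.raises(ValidationError):
            representatives(clusters, asm)


def test_invalid_params_rejected():
    with pytest.raises(ValidationError):
        ClusterParams(identity_min=0.0)
    with pytest.raises(ValidationError):
        ClusterParams(kmer_size=3)
    with pytest.raises(ValidationError):
        ClusterParams(assign_mode="middle")
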