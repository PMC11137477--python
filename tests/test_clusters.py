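from __future__ import annotations

import numpy as np
import pytest

from liftcompare.annotation_io import LiftCompareError, match_features
from liftcompare.clusters import (ClusterInput, build_cluster_inputs, cluster_reference,
                                  derive_target_clusters, pair_identity, pair_similar,
                                  summarize_copy_number, write_clusters_tsv,
                                  write_cluster_summary, ClusterComparison)
from liftcompare.fixtures import MutationSpec, apply_mutations, make_reference

from conftest import AA20, make_protein_family


def _prot(gene_id, seq):
    return ClusterInput(gene_id, seq, "protein")


def _mutate(seq: str, positions, rng) -> str:
    out = list(seq)
    for p in positions:
        choices = [c for c in AA20 if c != out[p]]
        out[p] = choices[rng.integers(0, len(choices))]
    return "".join(out)


class TestPairSimilar:
    def test_identical_sequences_always_pass(self):
        a = _prot("a", "MKVLQ" * 20)
        assert pair_similar(a, _prot("b", a.sequence), 1.0, 1.0)

    def test_length_ratio_bound(self):
        rng = np.random.default_rng(0)
        seq = "".join(AA20[i] for i in rng.integers(0, 20, size=100))
        a, b = _prot("a", seq), _prot("b", seq[:80])
        assert not pair_similar(a, b, min_id=0.0, min_cov=0.9)

    def test_identity_threshold_boundary(self):
        rng = np.random.default_rng(1)
        seq = "".join(AA20[i] for i in rng.integers(0, 20, size=100))
        other = _mutate(seq, rng.choice(100, size=8, replace=False), rng)
        a, b = _prot("a", seq), _prot("b", other)
        assert pair_identity(a, b) == pytest.approx(0.92)
        assert pair_similar(a, b, min_id=0.9)
        assert not pair_similar(a, b, min_id=0.95)

    def test_mixed_alphabets_rejected(self):
        with pytest.raises(LiftCompareError):
            pair_similar(_prot("a", "MKV"), ClusterInput("b", "ATG", "nucleotide"))


class TestClusterReference:
    def test_identical_triplet_forms_one_cluster(self):
        seq = "MKVLQWERTY" * 10
        clusters = cluster_reference([_prot(g, seq) for g in ("g1", "g2", "g3")])
        assert len(clusters) == 1
        assert sorted(clusters[0].members) == ["g1", "g2", "g3"]

    def test_unrelated_sequences_stay_apart(self):
        rng = np.random.default_rng(2)
        seqs = ["".join(AA20[i] for i in rng.integers(0, 20, size=120)) for _ in range(2)]
        clusters = cluster_reference([_prot(f"g{i}", s) for i, s in enumerate(seqs)])
        assert len(clusters) == 2
        assert all(len(c.members) == 1 for c in clusters)

    def test_family_with_divergent_outlier(self):
        """Founder + four 2%-divergent copies cluster; a 20%-divergent copy does not."""
        rng = np.random.default_rng(3)
        founder = "".join(AA20[i] for i in rng.integers(0, 20, size=300))
        inputs = [_prot("f0", founder)]
        for i in range(4):
            inputs.append(_prot(f"f{i+1}",
                                _mutate(founder, rng.choice(300, 6, replace=False), rng)))
        inputs.append(_prot("far", _mutate(founder, rng.choice(300, 60, replace=False), rng)))
        clusters = cluster_reference(inputs)
        sizes = sorted(len(c.members) for c in clusters)
        assert sizes == [1, 5]
        singleton = next(c for c in clusters if len(c.members) == 1)
        assert singleton.members == ["far"]

    def test_partition_property_on_fixture(self, standard_fixture):
        ref, _ = standard_fixture
        inputs = build_cluster_inputs(ref.assembly, ref.annotation)
        clusters = cluster_reference(inputs)
        members = [m for c in clusters for m in c.members]
        assert sorted(members) == sorted(i.gene_id for i in inputs)
        assert all(c.representative in c.members for c in clusters)

    def test_raising_min_id_never_merges_clusters(self):
        rng = np.random.default_rng(4)
        inputs = []
        for fam, div in enumerate([0.02, 0.05, 0.12]):
            for i, seq in enumerate(make_protein_family(rng, 200, 4, div)):
                inputs.append(_prot(f"fam{fam}_m{i}", seq))
        counts = [len(cluster_reference(inputs, min_id=t))
                  for t in (0.80, 0.90, 0.95)]
        assert counts == sorted(counts)

    def test_duplicate_gene_ids_rejected(self):
        with pytest.raises(LiftCompareError):
            cluster_reference([_prot("g", "MKV" * 30), _prot("g", "MKV" * 30)])


class TestTargetClusters:
    def test_copy_loss_without_extra_copies(self, standard_fixture):
        ref, tgt = standard_fixture
        match = match_features(ref.annotation, tgt.annotation)
        inputs = build_cluster_inputs(ref.assembly, ref.annotation)
        clusters = cluster_reference(inputs)
        comps = derive_target_clusters(clusters, match, inputs)  # no extra copies passed
        deleted = next(iter(match.unmapped_ids))
        comp = next(c for c in comps if deleted in c.ref_members)
        assert comp.delta == -1

    def test_suffix_attachment_gains_a_copy(self):
        ref = make_reference(n_genes=4, n_chroms=1, coding_fraction=1.0, seed=6)
        g1 = ref.annotation.gene_ids()[0]
        tgt = apply_mutations(ref, [MutationSpec(g1, "gene_duplication",
                                                 sub_rate=0.02, seed=7)])
        match = match_features(ref.annotation, tgt.annotation)
        inputs = build_cluster_inputs(ref.assembly, ref.annotation)
        extra = build_cluster_inputs(tgt.assembly, tgt.annotation,
                                     sorted(match.extra_copy_ids))
        comps = derive_target_clusters(cluster_reference(inputs), match, inputs, extra)
        comp = next(c for c in comps if g1 in c.ref_members)
        assert comp.delta == 1 and f"{g1}_1" in comp.tgt_members

    def test_extra_copy_attaches_to_closest_paralog(self):
        rng = np.random.default_rng(8)
        founder = "".join(AA20[i] for i in rng.integers(0, 20, size=200))
        near = _mutate(founder, rng.choice(200, 4, replace=False), rng)   # ~98%
        inputs = [_prot("gA", founder), _prot("gB", near)]
        clusters = cluster_reference(inputs)
        assert len(clusters) == 1
        # copy: 95%-ish identical to gA, further from gB
        copy_seq = _mutate(founder, rng.choice(200, 10, replace=False), rng)
        from liftcompare.annotation_io import FeatureMatch
        fm = FeatureMatch(shared_gene_ids={"gA", "gB"}, shared_transcript_ids=set(),
                          unmapped_ids=set(), extra_copy_ids={"gA_1": "gA"},
                          unrecognized_ids=set())
        comps = derive_target_clusters(clusters, fm, inputs,
                                       [_prot("gA_1", copy_seq)])
        best = max(("gA", "gB"),
                   key=lambda g: pair_identity(_prot("x", copy_seq),
                                               next(i for i in inputs if i.gene_id == g)))
        assert comps[0].attachments["gA_1"] == best

    def test_exact_tie_attaches_to_smaller_id(self):
        seq = "MKVLQWERTY" * 15
        inputs = [_prot("gB", seq), _prot("gA", seq)]
        clusters = cluster_reference(inputs)
        from liftcompare.annotation_io import FeatureMatch
        fm = FeatureMatch(shared_gene_ids={"gA", "gB"}, shared_transcript_ids=set(),
                          unmapped_ids=set(), extra_copy_ids={"gA_1": "gA"},
                          unrecognized_ids=set())
        comps = derive_target_clusters(clusters, fm, inputs, [_prot("gA_1", seq)])
        assert comps[0].attachments["gA_1"] == "gA"

    def test_conservation_of_target_counts(self, standard_fixture):
        ref, tgt = standard_fixture
        match = match_features(ref.annotation, tgt.annotation)
        inputs = build_cluster_inputs(ref.assembly, ref.annotation)
        extra = build_cluster_inputs(tgt.assembly, tgt.annotation,
                                     sorted(match.extra_copy_ids))
        comps = derive_target_clusters(cluster_reference(inputs), match, inputs, extra)
        total = sum(c.tgt_count for c in comps)
        attached = sum(len(c.attachments) for c in comps)
        assert total == len(match.shared_gene_ids) + attached


class TestSummary:
    def test_all_zero_deltas(self):
        comps = [ClusterComparison(f"c{i}", ["a"], ["a"]) for i in range(3)]
        s = summarize_copy_number(comps)
        assert (s.copies_lost, s.copies_gained) == (0, 0)
        assert s.clusters_unchanged == 3

    def test_mixed_deltas_arithmetic(self):
        comps = [ClusterComparison("c1", ["a"], []),                       # -1
                 ClusterComparison("c2", ["a", "b"], []),                  # -2
                 ClusterComparison("c3", ["a"], ["a", "a_1", "a_2", "a_3"])]  # +3
        s = summarize_copy_number(comps)
        assert (s.clusters_lost, s.clusters_gained) == (2, 1)
        assert (s.copies_lost, s.copies_gained) == (3, 3)

    def test_injected_duplications_and_deletion_recovered(self):
        ref = make_reference(n_genes=12, n_chroms=2, coding_fraction=0.8, seed=21)
        gids = ref.annotation.gene_ids()
        tgt = apply_mutations(ref, [
            MutationSpec(gids[0], "gene_duplication", sub_rate=0.02, seed=1),
            MutationSpec(gids[4], "gene_duplication", sub_rate=0.02, seed=2),
            MutationSpec(gids[7], "gene_deletion", seed=3)])
        match = match_features(ref.annotation, tgt.annotation)
        inputs = build_cluster_inputs(ref.assembly, ref.annotation)
        extra = build_cluster_inputs(tgt.assembly, tgt.annotation,
                                     sorted(match.extra_copy_ids))
        comps = derive_target_clusters(cluster_reference(inputs), match, inputs, extra)
        s = summarize_copy_number(comps)
        assert (s.clusters_gained, s.clusters_lost) == (2, 1)
        assert (s.copies_gained, s.copies_lost) == (2, 1)

    def test_output_files(self, tmp_path):
        comps = [ClusterComparison("c1", ["a", "b"], ["a"])]
        write_clusters_tsv(comps, tmp_path / "c.tsv")
        write_cluster_summary(summarize_copy_number(comps), tmp_path / "s.txt")
        assert "c1\t2\t1\ta,b\ta" in (tmp_path / "c.tsv").read_text()
        assert "total_copies_lost\t1" in (tmp_path / "s.txt").read_text()
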