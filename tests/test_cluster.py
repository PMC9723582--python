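import numpy as np
import pytest

import edlib
from rocits import simulate as sim
from rocits.cluster import (
    assign_taxonomy,
    extract_16s,
    filter_small_clusters,
    find_motif,
    global_identity_prefilter,
    greedy_cluster,
    similarity_rescue_16s,
)
from rocits.config import ClusterConfig
from rocits.consensus import RocItsSequence
from rocits.seqio import SeqRecord


def _rocits(i, seq):
    return RocItsSequence(f"s{i}", seq, 5, 5, f"r{i}")


class TestExtract16S:
    def test_constructed_span(self, template):
        base, its_start = template
        s16 = extract_16s(base)
        assert s16 == base[:its_start]

    def test_missing_rev_site_gives_none(self, template):
        base, its_start = template
        truncated = base[: its_start - 30]
        assert extract_16s(truncated) is None

    def test_mismatch_budget(self, template):
        base, its_start = template
        mutated = "T" + base[1:]  # 27F site starts with A
        assert extract_16s(mutated, max_mismatch=0) is None
        assert extract_16s(mutated, max_mismatch=1) == mutated[:its_start]


class TestSimilarityRescue:
    def test_mutated_primer_rescued(self, template):
        base, its_start = template
        seed = base[:its_start]
        mutated = "TTT" + base[3:]
        rs = _rocits(0, mutated)
        assert extract_16s(mutated) is None
        rescued = similarity_rescue_16s([rs], [seed])
        assert "s0" in rescued
        assert abs(len(rescued["s0"]) - its_start) <= 3

    def test_random_query_not_extracted(self, template):
        rng = np.random.default_rng(0)
        junk = "".join(rng.choice(list("ACGT"), size=2000))
        assert similarity_rescue_16s([_rocits(1, junk)], [template[0][:1400]]) == {}

    def test_empty_seed_set_rejected(self):
        with pytest.raises(ValueError):
            similarity_rescue_16s([], [])


class TestGreedyCluster:
    def test_identical_sequences_one_cluster(self):
        seqs = [(f"s{i}", "ACGT" * 500) for i in range(10)]
        clusters = greedy_cluster(seqs, 0.95)
        assert len(clusters) == 1
        assert clusters[0].size == 10

    def test_two_groups_at_90pct_separate(self, template):
        base, its = template
        other = sim.make_rrn_set(base, 2, [[("snp", 190)]], 1)[1]  # ~90% identity
        seqs = [(f"a{i}", base) for i in range(4)] + [
            (f"b{i}", other) for i in range(4)
        ]
        # oracle: full pairwise identity matrix confirms group structure
        ident = 1 - edlib.align(base, other)["editDistance"] / len(base)
        assert ident < 0.95
        clusters = greedy_cluster(seqs, 0.95)
        assert len(clusters) == 2
        groups = [set(c.member_ids) for c in clusters]
        assert {f"a{i}" for i in range(4)} in groups
        assert {f"b{i}" for i in range(4)} in groups

    def test_threshold_sweep_monotone(self, template):
        base, its = template
        variants = sim.make_rrn_set(
            base, 5, [[("snp", 30)], [("snp", 80)], [("snp", 150)], [("snp", 220)]], 2
        )
        seqs = [(f"v{i}", s) for i, s in enumerate(variants)]
        counts = [
            len(greedy_cluster(seqs, t)) for t in (0.90, 0.93, 0.96, 0.99)
        ]
        assert counts == sorted(counts)

    def test_identity_one_gives_singletons(self):
        seqs = [("a", "ACGT" * 400), ("b", "ACGT" * 399 + "ACGA")]
        clusters = greedy_cluster(seqs, 1.0)
        assert len(clusters) == 2

    def test_partition_property(self, template):
        base, its = template
        variants = sim.make_rrn_set(base, 4, [4, 100, 200], 3)
        seqs = [(f"v{i}", s) for i, s in enumerate(variants)]
        clusters = greedy_cluster(seqs, 0.95)
        all_ids = sorted(m for c in clusters for m in c.member_ids)
        assert all_ids == sorted(s for s, _ in seqs)


class TestFilterSmallClusters:
    def _mk(self, sizes):
        return [
            greedy_cluster([(f"c{i}_{j}", "ACGT" * 100) for j in range(n)], 0.9)[0]
            for i, n in enumerate(sizes)
        ]

    def test_genus_min_members(self):
        kept, excluded = filter_small_clusters(self._mk([10, 4]), min_members=5)
        assert len(kept) == 1 and kept[0].size == 10
        assert len(excluded) == 4

    def test_rrn_input_fraction(self):
        kept, excluded = filter_small_clusters(
            self._mk([150, 40, 8]), input_fraction=0.05
        )
        assert [c.size for c in kept] == [150, 40]
        assert len(excluded) == 8  # floor = ceil(0.05 * 198) = 10

    def test_rescue_overrides_fraction(self):
        kept, _ = filter_small_clusters(
            self._mk([150, 40, 8]), input_fraction=0.05, rescue_min_members=6
        )
        assert len(kept) == 3


class TestAssignTaxonomy:
    def _community(self, template):
        base, its = template
        seqs = {f"s{i}": base for i in range(9)}
        return seqs

    @staticmethod
    def _v4(seq):
        from rocits.cluster import PRIMER_515F, PRIMER_806R_SITE

        fwd = find_motif(seq, PRIMER_515F, 2)
        rev = find_motif(seq[fwd[1]:], PRIMER_806R_SITE, 2)
        return seq[fwd[0] : fwd[1] + rev[1]]

    def test_unanimous(self, template):
        seqs = self._community(template)
        cluster = greedy_cluster(sorted(seqs.items()), 0.95)[0]
        refs = [SeqRecord("ref1", self._v4(template[0]), description="Bacillus")]
        out = assign_taxonomy(cluster, seqs, refs)
        assert out.taxonomy == "Bacillus"
        assert out.taxonomy_fraction == 1.0

    def test_modal_fraction(self, template):
        base, its = template
        # diverge the 16S interior but keep the primer sites intact
        core = base[25 : its - 30]
        mutated = sim.make_rrn_set(core, 2, [[("snp", 200)]], 5)[1]
        other = base[:25] + mutated + base[its - 30 :]
        seqs = {f"s{i}": base for i in range(9)}
        seqs["s9"] = other
        cluster = greedy_cluster(sorted(seqs.items()), 0.5)[0]
        assert cluster.size == 10
        refs = [
            SeqRecord("ref1", self._v4(base), description="Bacillus"),
            SeqRecord("ref2", self._v4(other), description="Pseudomonas"),
        ]
        out = assign_taxonomy(cluster, seqs, refs)
        assert out.taxonomy == "Bacillus"
        assert out.taxonomy_fraction == pytest.approx(0.9)

    def test_empty_refs_rejected(self, template):
        seqs = self._community(template)
        cluster = greedy_cluster(sorted(seqs.items()), 0.95)[0]
        with pytest.raises(ValueError):
            assign_taxonomy(cluster, seqs, [])


class TestGlobalIdentityPrefilter:
    def test_low_error_consensus_kept(self, template):
        base, _ = template
        noisy = sim.apply_errors(
            base, sim.ErrorModel(0.0005, 0.0003, 0.0002, 1, 0),
            np.random.default_rng(1),
        )
        kept, _ = global_identity_prefilter([("x", noisy)], [base])
        assert [k for k, _ in kept] == ["x"]

    def test_unrelated_sequence_discarded(self, template):
        junk = "".join(np.random.default_rng(2).choice(list("ACGT"), size=2500))
        kept, discarded = global_identity_prefilter([("j", junk)], [template[0]])
        assert discarded == ["j"]

    def test_chimera_of_two_refs_passes(self, template):
        """Documents that the pre-filter does NOT remove chimeras: a 50/50
        crossover of two 95%-identical references stays ~97% identical to
        either parent."""
        base, its = template
        other = sim.make_rrn_set(base, 2, [[("snp", 90)]], 3)[1]
        bp = len(base) // 2
        chim = base[:bp] + other[bp:]
        kept, _ = global_identity_prefilter([("c", chim)], [base, other], 0.95)
        assert [k for k, _ in kept] == ["c"]


def test_find_motif_iupac():
    assert find_motif("TTAGAGTTTGATCCTGGCTCAGAA", "AGAGTTTGATCMTGGCTCAG") == (2, 22)
    assert find_motif("AAAA", "AGAGTTTGATCMTGGCTCAG") is None
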