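import pytest

from oracles import brute_single_linkage
from uvigkit.fixtures import mutate_to_identity, random_sequence, substream
from uvigkit.records import ViralContig, reverse_complement
from uvigkit.votu import ClusteringParams, build_aligner, build_votus, pairwise_ani


@pytest.fixture(scope="module")
def aligner():
    return build_aligner()


class TestPairwiseAni:
    def test_identical_sequences(self, aligner):
        seq = random_sequence(800, substream(0, "ani"))
        result = pairwise_ani(seq, seq, aligner=aligner)
        assert result.ani_pct == 100.0
        assert result.af_shorter_pct == 100.0

    def test_reverse_complement_full_identity(self, aligner):
        seq = random_sequence(800, substream(1, "ani"))
        result = pairwise_ani(seq, reverse_complement(seq), aligner=aligner)
        assert result.ani_pct == 100.0
        assert result.af_shorter_pct == 100.0

    def test_contained_half_fully_covered(self, aligner):
        seq = random_sequence(1000, substream(2, "ani"))
        result = pairwise_ani(seq, seq[:500], aligner=aligner)
        assert result.ani_pct == 100.0
        assert result.af_shorter_pct == 100.0

    def test_ten_percent_substitutions_recovered(self, aligner):
        seq = random_sequence(1000, substream(3, "ani"))
        mutated = mutate_to_identity(seq, 90, seed=3)
        result = pairwise_ani(seq, mutated, aligner=aligner)
        assert result.ani_pct == pytest.approx(90, abs=1)
        assert result.af_shorter_pct >= 99

    def test_symmetric_on_random_pairs(self, aligner):
        rng = substream(4, "ani")
        for i in range(4):
            a = random_sequence(int(rng.integers(300, 900)), rng)
            b = (
                mutate_to_identity(a, 92, seed=i)
                if i % 2
                else random_sequence(int(rng.integers(300, 900)), rng)
            )
            assert pairwise_ani(a, b, aligner=aligner) == pairwise_ani(b, a, aligner=aligner)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_ani("", "ACGT")

    def test_unrelated_pair_low_aligned_fraction(self, aligner):
        rng = substream(5, "ani")
        a, b = random_sequence(1000, rng), random_sequence(1000, rng)
        assert pairwise_ani(a, b, aligner=aligner).af_shorter_pct < 85


class TestBuildVotus:
    def test_identical_triplet_forms_one_vc(self):
        seq = random_sequence(600, substream(6, "votu"))
        contigs = [ViralContig(id=f"c{i}", sequence=seq) for i in range(3)]
        votus = build_votus(contigs)
        assert len(votus) == 1
        assert votus[0].name == "vc_1"
        assert set(votus[0].member_ids) == {"c0", "c1", "c2"}

    def test_single_linkage_chains_through_middle_member(self, aligner):
        """A-B and B-C pass the thresholds while A-C does not; single
        linkage still produces one cluster."""
        b = random_sequence(1500, substream(7, "votu"))
        a = mutate_to_identity(b, 97, seed=71)
        c = mutate_to_identity(b, 96, seed=72)
        assert pairwise_ani(a, b, aligner=aligner).ani_pct >= 95
        assert pairwise_ani(b, c, aligner=aligner).ani_pct >= 95
        assert pairwise_ani(a, c, aligner=aligner).ani_pct < 95
        votus = build_votus(
            [ViralContig(id="A", sequence=a), ViralContig(id="B", sequence=b),
             ViralContig(id="C", sequence=c)]
        )
        assert len(votus) == 1
        assert set(votus[0].member_ids) == {"A", "B", "C"}

    def test_unrelated_sequences_are_singletons(self):
        rng = substream(8, "votu")
        contigs = [ViralContig(id=f"u{i}", sequence=random_sequence(700, rng)) for i in range(4)]
        votus = build_votus(contigs)
        assert len(votus) == 4
        assert all(v.name.startswith("sg_") for v in votus)

    def test_members_partition_input(self):
        rng = substream(9, "votu")
        base = random_sequence(800, rng)
        contigs = [ViralContig(id=f"m{i}", sequence=mutate_to_identity(base, 98, seed=i)) for i in range(3)]
        contigs += [ViralContig(id=f"u{i}", sequence=random_sequence(800, rng)) for i in range(3)]
        votus = build_votus(contigs)
        members = [m for v in votus for m in v.member_ids]
        assert sorted(members) == sorted(c.id for c in contigs)

    def test_adding_a_sequence_never_splits_a_cluster(self):
        rng = substream(10, "votu")
        base = random_sequence(800, rng)
        contigs = [ViralContig(id=f"m{i}", sequence=mutate_to_identity(base, 97, seed=20 + i)) for i in range(3)]
        before = {frozenset(v.member_ids) for v in build_votus(contigs)}
        extra = contigs + [ViralContig(id="new", sequence=mutate_to_identity(base, 96, seed=30))]
        after = build_votus(extra)
        for cluster in before:
            assert any(cluster <= set(v.member_ids) for v in after)

    def test_raising_ani_threshold_never_merges(self):
        rng = substream(11, "votu")
        base = random_sequence(1000, rng)
        contigs = [
            ViralContig(id="r", sequence=base),
            ViralContig(id="near", sequence=mutate_to_identity(base, 97, seed=41)),
            ViralContig(id="far", sequence=mutate_to_identity(base, 91, seed=42)),
        ]
        counts = [
            len(build_votus(contigs, ClusteringParams(min_ani_pct=t)))
            for t in (90.0, 95.0, 99.5)
        ]
        assert counts == sorted(counts)

    def test_kmer_prefilter_does_not_change_clusters(self):
        rng = substream(12, "votu")
        base = random_sequence(700, rng)
        contigs = [ViralContig(id=f"m{i}", sequence=mutate_to_identity(base, 96, seed=50 + i)) for i in range(2)]
        contigs += [ViralContig(id=f"u{i}", sequence=random_sequence(700, rng)) for i in range(2)]
        with_filter = {frozenset(v.member_ids) for v in build_votus(contigs)}
        without = {frozenset(v.member_ids) for v in build_votus(contigs, prefilter_min_shared=0)}
        assert with_filter == without

    def test_duplicate_ids_rejected(self):
        seq = random_sequence(300, substream(13, "votu"))
        contigs = [ViralContig(id="dup", sequence=seq), ViralContig(id="dup", sequence=seq)]
        with pytest.raises(ValueError, match="unique"):
            build_votus(contigs)


def test_clusters_match_union_find_over_pairwise_edges():
    """Clustering route (graph components) agrees with a hand-rolled
    union-find over independently computed threshold edges."""
    rng = substream(14, "uf")
    contigs = []
    for fam in range(3):
        base = random_sequence(600, rng)
        for j in range(2):
            contigs.append(
                ViralContig(id=f"f{fam}_{j}", sequence=mutate_to_identity(base, 97, seed=fam * 10 + j))
            )
    contigs += [ViralContig(id=f"solo{i}", sequence=random_sequence(600, rng)) for i in range(2)]
    aligner = build_aligner()
    ids = [c.id for c in contigs]
    edges = []
    for i in range(len(contigs)):
        for j in range(i + 1, len(contigs)):
            r = pairwise_ani(contigs[i].sequence, contigs[j].sequence, aligner=aligner)
            if r.ani_pct >= 95 and r.af_shorter_pct >= 85:
                edges.append((ids[i], ids[j]))
    expected = brute_single_linkage(ids, edges)
    observed = {frozenset(v.member_ids) for v in build_votus(contigs)}
    assert observed == expected
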