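import math

import pytest

from densfam.mergefilter import (
    deduplicate_seeds,
    filter_metaclusters,
    mc_statistics,
    merge_metaclusters,
    metacluster_distance,
)
from densfam.meta import Metacluster
from densfam.model import Region

from conftest import make_mc, make_pc


def pc_with_shared(qid, own_prefix, n_own, shared_proteins):
    """Primary cluster with n_own private members plus the given shared ones."""
    subs = [(f"{own_prefix}{i}", 1, 100) for i in range(n_own)]
    subs += [(p, 1, 100) for p in shared_proteins]
    return make_pc(qid, (1, 100), subs)


class TestMetaclusterDistance:
    def test_identical_singletons_zero(self):
        pc = make_pc("Q", (1, 100), [("P1", 1, 100), ("P2", 1, 100)])
        a = make_mc("MC000001", pc)
        b = make_mc("MC000002", pc)
        assert metacluster_distance(a, b) == 0.0

    def test_nothing_shared_one(self):
        a = make_mc("MC000001", make_pc("Q1", (1, 100), [("P1", 1, 100)]))
        b = make_mc("MC000002", make_pc("Q2", (1, 100), [("P2", 1, 100)]))
        assert metacluster_distance(a, b) == 1.0

    def test_mean_over_all_cross_pairs(self):
        # 2x2 member pairs with distances 0.8, 0.9, 0.8, 0.9 -> mean 0.85
        # each pc has 10 members; sharing 2 -> 0.8, sharing 1 -> 0.9
        a1 = pc_with_shared("QA1", "A1_", 8, ["X1", "X2"])
        a2 = pc_with_shared("QA2", "A2_", 8, ["Y1", "Y2"])
        b1 = pc_with_shared("QB1", "B1_", 8, ["X1", "X2"])  # shares 2 with a1
        b2 = pc_with_shared("QB2", "B2_", 9, ["Y1"])  # shares 1 with a2
        # cross terms: d(a1,b1)=0.8, d(a1,b2)=1.0 ... adjust to spec pattern:
        # instead assert on the constructed values directly
        from densfam.meta import primary_cluster_distance

        assert primary_cluster_distance(a1, b1) == pytest.approx(0.8)
        assert primary_cluster_distance(a2, b2) == pytest.approx(0.9)
        A = make_mc("MC000001", a1, a2)
        B = make_mc("MC000002", b1, b2)
        expected = (0.8 + 1.0 + 1.0 + 0.9) / 4
        assert metacluster_distance(A, B) == pytest.approx(expected)


class TestMergeRule:
    @staticmethod
    def mc_pair_at(shared: int, size: int = 10):
        """Two single-pc metaclusters at distance 1 - shared/size."""
        shared_proteins = [f"X{i}" for i in range(shared)]
        a = pc_with_shared("QA", "A", size - shared, shared_proteins)
        b = pc_with_shared("QB", "B", size - shared, shared_proteins)
        return make_mc("MC000001", a), make_mc("MC000002", b)

    def test_merge_below_threshold(self):
        a, b = self.mc_pair_at(shared=2)  # distance 0.8 < 0.9
        merged, decisions = merge_metaclusters([a, b])
        assert len(merged) == 1
        assert decisions[0].merged
        assert decisions[0].avg_distance == pytest.approx(0.8)

    def test_no_merge_above_threshold(self):
        a, b = self.mc_pair_at(shared=0)  # distance 1.0
        merged, decisions = merge_metaclusters([a, b])
        assert len(merged) == 2
        assert not decisions[0].merged

    def test_chain_merges_transitively(self):
        # A-B close, B-C close, A-C far -> one component of 3
        a = pc_with_shared("QA", "A", 2, ["S1"] * 0 + ["AB1", "AB2"])
        b = pc_with_shared("QB", "B", 0, ["AB1", "AB2", "BC1", "BC2"])
        c = pc_with_shared("QC", "C", 2, ["BC1", "BC2"])
        A, B, C = make_mc("MC000001", a), make_mc("MC000002", b), make_mc("MC000003", c)
        assert metacluster_distance(A, C) == 1.0
        merged, _ = merge_metaclusters([A, B, C])
        assert len(merged) == 1

    def test_idempotent(self):
        a, b = self.mc_pair_at(shared=2)
        merged, _ = merge_metaclusters([a, b])
        again, decisions = merge_metaclusters(merged)
        assert len(again) == len(merged)
        assert [m.seeds for m in again] == [m.seeds for m in merged]

    def test_order_invariance(self, rng):
        mcs = []
        for k in range(3):
            a, b = self.mc_pair_at(shared=2)
            # relabel to unique ids and disjoint proteins per pair
            a2 = make_mc(f"MC00000{2*k+1}", *[
                make_pc(pc.query_id + f"_{k}", (1, 100),
                        [(r.protein_id + f"_{k}", r.start, r.end) for r in pc.subject_regions])
                for pc in a.primary_members
            ])
            b2 = make_mc(f"MC00000{2*k+2}", *[
                make_pc(pc.query_id + f"_{k}", (1, 100),
                        [(r.protein_id + f"_{k}", r.start, r.end) for r in pc.subject_regions])
                for pc in b.primary_members
            ])
            mcs.extend([a2, b2])
        base, _ = merge_metaclusters(mcs)
        base_seeds = sorted(tuple(m.seeds) for m in base)
        for _ in range(10):
            shuffled = [mcs[i] for i in rng.permutation(len(mcs))]
            merged, _ = merge_metaclusters(shuffled)
            assert sorted(tuple(m.seeds) for m in merged) == base_seeds

    def test_keep_shared_only_mode(self):
        a, b = self.mc_pair_at(shared=2)
        merged, _ = merge_metaclusters([a, b], keep_shared_only=True)
        assert len(merged) == 1
        # only the 2 shared proteins' regions survive
        assert {r.protein_id for r in merged[0].seeds} == {"X0", "X1"}


class TestDeduplicateSeeds:
    @staticmethod
    def mc_with_seeds(seeds):
        pc = make_pc("Q", (1, 100), [(s.protein_id, s.start, s.end) for s in seeds])
        return Metacluster("MC000001", (pc,), tuple(seeds))

    def test_near_duplicates_keep_longest(self):
        mc = self.mc_with_seeds([Region("P1", 1, 100), Region("P1", 2, 100)])
        out = deduplicate_seeds(mc)
        assert out.seeds == (Region("P1", 1, 100),)

    def test_disjoint_seeds_kept(self):
        mc = self.mc_with_seeds([Region("P1", 1, 100), Region("P1", 200, 300)])
        assert len(deduplicate_seeds(mc).seeds) == 2

    def test_identical_duplicates_collapse(self):
        # identical regions are already unique in a Metacluster; verify stability
        mc = self.mc_with_seeds([Region("P1", 1, 100)])
        assert deduplicate_seeds(mc).seeds == (Region("P1", 1, 100),)

    def test_same_interval_different_proteins_kept(self):
        mc = self.mc_with_seeds([Region("P1", 1, 100), Region("P2", 1, 100)])
        assert len(deduplicate_seeds(mc).seeds) == 2

    def test_never_increases_seed_count(self, rng):
        for _ in range(10):
            seeds = []
            for _ in range(int(rng.integers(1, 20))):
                s = int(rng.integers(1, 50))
                seeds.append(Region(f"P{int(rng.integers(1, 4))}", s, s + int(rng.integers(30, 120))))
            mc = self.mc_with_seeds(list(dict.fromkeys(seeds)))
            assert len(deduplicate_seeds(mc).seeds) <= len(mc.seeds)


class TestStatisticsAndFilter:
    @staticmethod
    def mc_with_lengths(lengths, protein="P1"):
        seeds = []
        pos = 1
        for L in lengths:
            seeds.append(Region(protein, pos, pos + L - 1))
            pos += L + 10
        pc = make_pc("Q", (1, 100), [(s.protein_id, s.start, s.end) for s in seeds])
        return Metacluster("MC000001", (pc,), tuple(seeds))

    def test_stats_single(self):
        assert mc_statistics(self.mc_with_lengths([100])) == (1, 100.0, 0.0)

    def test_stats_population_sd(self):
        n, mean, sd = mc_statistics(self.mc_with_lengths([40, 60]))
        assert (n, mean, sd) == (2, 50.0, 10.0)

    def test_stats_constant(self):
        assert mc_statistics(self.mc_with_lengths([50, 50, 50])) == (3, 50.0, 0.0)

    def test_filter_strict_boundaries(self):
        kept = self.mc_with_lengths([60] * 51)
        at_seed_boundary = self.mc_with_lengths([60] * 50)
        at_length_boundary = self.mc_with_lengths([50] * 51)
        result = filter_metaclusters([kept, at_seed_boundary, at_length_boundary])
        assert result == [kept]

    def test_filter_never_increases(self):
        mcs = [self.mc_with_lengths([60] * 51), self.mc_with_lengths([60] * 10)]
        assert len(filter_metaclusters(mcs)) <= len(mcs)

    def test_length_just_above_boundary(self):
        lengths = [50] * 50 + [55]  # mean 50.098 > 50
        assert filter_metaclusters([self.mc_with_lengths(lengths)]) != []
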