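import numpy as np
import pytest
from scipy import stats

from densfam.compare import (
    UNK,
    build_clan_map,
    classify_overlap,
    compare_metacluster,
    composition_labels,
    coverage_stats,
    dominant_architecture,
    fit_pareto_tail,
    index_annotations,
    overlap_fractions,
    percent_variants,
    seed_architecture,
    size_ccdf,
)
from densfam.meta import Metacluster
from densfam.model import DomainAnnotation, ProteinSet, Region, ResidueTracks

from conftest import make_pc


def ann(pid, fam, start, end, clan=None):
    return DomainAnnotation(pid, fam, clan, Region(pid, start, end))


def mc_of(seeds):
    pc = make_pc("Q", (1, 100), [(s.protein_id, s.start, s.end) for s in seeds])
    return Metacluster("MC000001", (pc,), tuple(seeds))


class TestSeedArchitecture:
    def test_ordered_families(self):
        idx = index_annotations([ann("P", "A", 10, 60), ann("P", "B", 100, 180)])
        assert seed_architecture(Region("P", 50, 200), idx) == ("A", "B")

    def test_no_overlap_none(self):
        idx = index_annotations([ann("P", "A", 201, 250)])
        assert seed_architecture(Region("P", 50, 200), idx) is None

    def test_single_residue_overlap_counts(self):
        idx = index_annotations([ann("P", "A", 200, 250)])
        assert seed_architecture(Region("P", 50, 200), idx) == ("A",)


class TestDominantArchitecture:
    def test_modal_architecture(self):
        seeds, anns = [], []
        for i in range(6):
            seeds.append(Region(f"P{i}", 1, 200))
            anns += [ann(f"P{i}", "A", 1, 90), ann(f"P{i}", "B", 100, 190)]
        for i in range(6, 10):
            seeds.append(Region(f"P{i}", 1, 200))
            anns.append(ann(f"P{i}", "A", 1, 90))
        da, pct = dominant_architecture(mc_of(seeds), index_annotations(anns))
        assert da == ("A", "B")
        assert pct == 60.0

    def test_unannotated_unk(self):
        da, pct = dominant_architecture(mc_of([Region("P1", 1, 100)]), {})
        assert (da, pct) == (UNK, 0.0)

    def test_tie_lexicographic(self):
        seeds, anns = [], []
        for i in range(5):
            seeds.append(Region(f"P{i}", 1, 100))
            anns.append(ann(f"P{i}", "A", 1, 90))
        for i in range(5, 10):
            seeds.append(Region(f"P{i}", 1, 100))
            anns.append(ann(f"P{i}", "B", 1, 90))
        da, pct = dominant_architecture(mc_of(seeds), index_annotations(anns))
        assert da == ("A",)
        assert pct == 50.0


class TestPercentVariants:
    def test_all_exact(self):
        seeds = [Region(f"P{i}", 1, 100) for i in range(4)]
        anns = [ann(f"P{i}", "A", 1, 90) for i in range(4)]
        result = percent_variants(mc_of(seeds), ("A",), index_annotations(anns))
        assert result == (100.0, 100.0, 100.0, 100.0)

    def test_sub_architecture_counts_in_dacf(self):
        seeds, anns = [], []
        for i in range(2):  # exact (A,B)
            seeds.append(Region(f"P{i}", 1, 200))
            anns += [ann(f"P{i}", "A", 1, 90), ann(f"P{i}", "B", 100, 190)]
        for i in range(2, 4):  # sub-architecture (A,)
            seeds.append(Region(f"P{i}", 1, 200))
            anns.append(ann(f"P{i}", "A", 1, 90))
        p_da, p_dac, p_dacf, p_dacfa = percent_variants(
            mc_of(seeds), ("A", "B"), index_annotations(anns)
        )
        assert p_da == 50.0
        assert p_dacf == 100.0

    def test_super_architecture_only_in_dacfa(self):
        seeds, anns = [], []
        seeds.append(Region("P0", 1, 200))
        anns += [ann("P0", "A", 1, 90), ann("P0", "B", 100, 190)]
        seeds.append(Region("P1", 1, 300))
        anns += [ann("P1", "A", 1, 90), ann("P1", "B", 100, 190), ann("P1", "C", 200, 290)]
        p_da, p_dac, p_dacf, p_dacfa = percent_variants(
            mc_of(seeds), ("A", "B"), index_annotations(anns)
        )
        assert p_da == 50.0
        assert p_dacf == 50.0
        assert p_dacfa == 100.0

    def test_unannotated_counts_as_empty_subset(self):
        seeds = [Region("P0", 1, 200), Region("P1", 1, 200)]
        anns = [ann("P0", "A", 1, 90), ann("P0", "B", 100, 190)]
        p_da, p_dac, p_dacf, p_dacfa = percent_variants(
            mc_of(seeds), ("A", "B"), index_annotations(anns)
        )
        assert p_da == 50.0
        assert p_dacf == 100.0  # unannotated seed = empty sub-architecture

    def test_monotone_chain_random(self, rng):
        fams = ["A", "B", "C", "D"]
        for _ in range(20):
            seeds, anns = [], []
            for i in range(int(rng.integers(2, 12))):
                pid = f"P{i}"
                seeds.append(Region(pid, 1, 400))
                pos = 1
                for f in rng.choice(fams, size=int(rng.integers(0, 4)), replace=False):
                    anns.append(ann(pid, str(f), pos, pos + 50, clan=f"CL{f}"))
                    pos += 80
            idx = index_annotations(anns)
            cm = build_clan_map(anns)
            da, _ = dominant_architecture(mc_of(seeds), idx)
            if da == UNK:
                continue
            chain = percent_variants(mc_of(seeds), da, idx, cm)
            assert chain[0] <= chain[1] <= chain[2] <= chain[3]


class TestOverlapFractions:
    def test_perfect_agreement(self):
        anns = index_annotations([ann("P", "A", 1, 100)])
        assert overlap_fractions(mc_of([Region("P", 1, 100)]), ("A",), anns) == (0.0, 0.0)

    def test_reference_undercovered(self):
        anns = index_annotations([ann("P", "A", 1, 100)])
        fred, fext = overlap_fractions(mc_of([Region("P", 1, 80)]), ("A",), anns)
        assert (fred, fext) == (pytest.approx(0.2), 0.0)

    def test_both_directions(self):
        anns = index_annotations([ann("P", "A", 1, 100)])
        fred, fext = overlap_fractions(mc_of([Region("P", 21, 120)]), ("A",), anns)
        assert fred == pytest.approx(20 / 100)
        assert fext == pytest.approx(20 / 100)  # 20 of the seed's 100 residues

    def test_no_matching_seed_error(self):
        anns = index_annotations([ann("P", "B", 1, 100)])
        with pytest.raises(ValueError, match="matches"):
            overlap_fractions(mc_of([Region("P", 1, 100)]), ("A",), anns)


class TestClassifyOverlap:
    @pytest.mark.parametrize(
        "fred,fext,label",
        [
            (0.1, 0.1, "equivalent"),
            (0.5, 0.5, "shifted"),
            (0.3, 0.05, "reduced"),
            (0.05, 0.3, "extended"),
            (0.2, 0.2, "equivalent"),  # boundary inclusive
            (0.2, 0.21, "extended"),
            (0.21, 0.2, "reduced"),
        ],
    )
    def test_rule_table(self, fred, fext, label):
        assert classify_overlap(fred, fext) == label

    def test_out_of_range_error(self):
        with pytest.raises(ValueError):
            classify_overlap(1.2, 0.1)


class TestCompareRecord:
    def test_unannotated_mc_all_unk(self):
        rec = compare_metacluster(mc_of([Region("P1", 1, 100)]), [])
        assert rec.DA == UNK and rec.Label == UNK and rec.Pfam_sequences == 0

    def test_label_requires_majority(self):
        # DA held by < 50% of seeds: percents reported but label UNK
        seeds = [Region(f"P{i}", 1, 100) for i in range(5)]
        anns = [ann("P0", "A", 1, 90), ann("P1", "B", 1, 90)]
        rec = compare_metacluster(mc_of(seeds), anns)
        assert rec.DA == ("A",)
        assert rec.Label == UNK


class TestCompositionLabels:
    @staticmethod
    def tracks_with_lc(frac, length=100):
        tracks = ResidueTracks()
        n_lc = int(round(frac * length))
        mask = np.zeros(length, dtype=bool)
        mask[:n_lc] = True
        tracks.low_complexity["P1"] = mask
        tracks.coiled_coil["P1"] = np.zeros(length, dtype=bool)
        tracks.disordered["P1"] = np.zeros(length, dtype=bool)
        tracks.tm_count["P1"] = 0
        return tracks

    def test_above_threshold_labeled(self):
        mc = mc_of([Region("P1", 1, 100)])
        labels = composition_labels(mc, self.tracks_with_lc(0.11))
        assert "LowComplexity" in labels.labels

    def test_exactly_threshold_not_labeled(self):
        mc = mc_of([Region("P1", 1, 100)])
        labels = composition_labels(mc, self.tracks_with_lc(0.10))
        assert "LowComplexity" not in labels.labels

    def test_tm_inclusive(self):
        mc = mc_of([Region("P1", 1, 100)])
        tracks = self.tracks_with_lc(0.0)
        tracks.tm_count["P1"] = 2
        labels = composition_labels(mc, tracks)
        assert labels.mean_tm == 2.0
        assert "Transmembrane" in labels.labels

    def test_disordered_strict(self):
        mc = mc_of([Region("P1", 1, 100)])
        tracks = self.tracks_with_lc(0.0)
        tracks.disordered["P1"][:50] = True
        assert "Disordered" not in composition_labels(mc, tracks).labels
        tracks.disordered["P1"][:51] = True
        assert "Disordered" in composition_labels(mc, tracks).labels

    def test_missing_track_all_false(self):
        mc = mc_of([Region("P1", 1, 100)])
        labels = composition_labels(mc, ResidueTracks())
        assert labels.labels == frozenset()


class TestCoverage:
    def test_union_of_overlapping_regions(self):
        ps = ProteinSet({"P1": "A" * 100})
        res, seq = coverage_stats([Region("P1", 1, 50), Region("P1", 41, 60)], ps)
        assert res == pytest.approx(0.6)
        assert seq == 1.0

    def test_no_members(self):
        ps = ProteinSet({"P1": "A" * 100})
        assert coverage_stats([], ps) == (0.0, 0.0)

    def test_full_coverage(self):
        ps = ProteinSet({"P1": "A" * 50, "P2": "A" * 70})
        res, seq = coverage_stats([Region("P1", 1, 50), Region("P2", 1, 70)], ps)
        assert (res, seq) == (1.0, 1.0)

    def test_split_invariance(self):
        ps = ProteinSet({"P1": "A" * 100})
        whole = coverage_stats([Region("P1", 11, 50)], ps)
        halves = coverage_stats([Region("P1", 11, 30), Region("P1", 31, 50)], ps)
        assert whole == halves

    def test_unknown_protein_error(self):
        ps = ProteinSet({"P1": "A" * 100})
        with pytest.raises(ValueError):
            coverage_stats([Region("P2", 1, 10)], ps)


class TestTailFit:
    def test_recovers_pareto_exponent(self):
        rng = np.random.default_rng(7)
        sizes = stats.pareto(b=1.25).rvs(size=10_000, random_state=rng)
        fit = fit_pareto_tail(sizes)
        assert fit.exponent == pytest.approx(1.25, abs=0.05)

    def test_constant_sizes_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_pareto_tail([5.0] * 100)

    def test_duplication_invariance(self):
        rng = np.random.default_rng(3)
        sizes = stats.pareto(b=1.5).rvs(size=500, random_state=rng)
        a = fit_pareto_tail(sizes).exponent
        b = fit_pareto_tail(np.concatenate([sizes, sizes])).exponent
        assert a == pytest.approx(b)

    def test_too_few_sizes_error(self):
        with pytest.raises(ValueError, match="need"):
            fit_pareto_tail([1.0, 2.0, 3.0])

    def test_ccdf_starts_at_one(self):
        table = size_ccdf([1, 2, 2, 5])
        assert table[0] == (1.0, 1.0)
        assert table[-1][1] == pytest.approx(0.25)
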