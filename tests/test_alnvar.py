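import numpy as np
import pytest

from structflex import alnvar
from structflex.grouping import StructuralGroup
from structflex.io import ChainStructure
from structflex.superpose import Correspondence, SuperpositionResult


def make_group(rows, gid="g", prefix="m"):
    members = [ChainStructure(f"{prefix}{i}", [], 1.5) for i in range(len(rows))]
    return StructuralGroup(gid, members, list(rows))


def comp(id_a, id_b, row_a, row_b):
    pairs = []
    ia = ib = 0
    for ca, cb in zip(row_a, row_b):
        if ca != "-" and cb != "-":
            pairs.append((ia, ib))
        if ca != "-":
            ia += 1
        if cb != "-":
            ib += 1
    corr = Correspondence(tuple(pairs), row_a, row_b)
    return SuperpositionResult(corr, np.eye(3), np.zeros(3), 1.0, 0.8,
                               len(pairs), 2.0, id_a, id_b)


@pytest.fixture()
def toy_pair():
    """Two groups of 5-residue proteins with two hand-written alignments."""
    ga = make_group(["ACDEF", "ACDEF"], gid="A", prefix="a")
    gb = make_group(["ACDEF", "ACDEF"], gid="B", prefix="b")
    comparisons = [
        comp("a0", "b0", "ACDEF", "ACDEF"),      # identity pairing
        comp("a0", "b1", "ACDEF", "ACDEF"),
        comp("a1", "b0", "ACDEF-", "-ACDEF"),    # shifted by one
        comp("a1", "b1", "ACDEF", "ACDEF"),
    ]
    return alnvar.GroupPair(ga, gb, comparisons)


class TestClassifySites:
    def test_consistent_partner_is_common(self):
        ga = make_group(["ACD"], gid="A", prefix="a")
        gb = make_group(["ACD"], gid="B", prefix="b")
        gp = alnvar.GroupPair(ga, gb, [comp("a0", "b0", "ACD", "ACD"),
                                       comp("a0", "b0", "ACD", "ACD")])
        sc = alnvar.classify_sites(gp)
        assert sc.classes_a == ["common"] * 3
        assert (sc.rc, sc.rm, sc.rg) == (100.0, 0.0, 0.0)

    def test_conflicting_partner_is_multi(self, toy_pair):
        sc = alnvar.classify_sites(toy_pair)
        # a1 aligns shifted, so every a-side residue has two distinct partners
        assert "multi" in sc.classes_a

    def test_ratios_partition_to_100(self, toy_pair):
        sc = alnvar.classify_sites(toy_pair)
        assert sc.rc + sc.rm + sc.rg == pytest.approx(100.0)

    def test_eq2_arithmetic(self):
        """10-residue proteins with 7 common sites each: Nc = 7, Rc = 70%."""
        seq = "ACDEFGHIKL"
        ga = make_group([seq], gid="A", prefix="a")
        gb = make_group([seq], gid="B", prefix="b")
        rows_1 = (seq + "-", "-" + seq)  # shifts last 3 into disagreement
        c1 = comp("a0", "b0", seq, seq)
        c2 = comp("a0", "b0", seq[:7] + "---" + seq[7:], seq[:7] + seq[7:] + "---")
        gp = alnvar.GroupPair(ga, gb, [c1, c2])
        sc = alnvar.classify_sites(gp)
        assert sc.nc == pytest.approx(7.0)
        assert sc.rc == pytest.approx(70.0)

    def test_matches_brute_force_tally(self, toy_pair):
        """Ratios equal an exhaustive per-site tally over the toy alignments."""
        sc = alnvar.classify_sites(toy_pair)
        # brute force: per a-side residue, set of partners over comparisons
        partner_sets = {i: set() for i in range(5)}
        for c in toy_pair.comparisons:
            if not c.id_a.startswith("a"):
                continue
            matched = dict(c.correspondence.pairs)
            for i in range(5):
                partner_sets[i].add(matched.get(i, "-"))
        expect_a = []
        for i in range(5):
            s = partner_sets[i]
            if s == {"-"}:
                expect_a.append("gap")
            elif len(s) == 1:
                expect_a.append("common")
            else:
                expect_a.append("multi")
        assert sc.classes_a == expect_a

    def test_single_comparison_flagged_degenerate(self):
        ga = make_group(["ACDEF"], gid="A", prefix="a")
        gb = make_group(["ACDEF"], gid="B", prefix="b")
        gp = alnvar.GroupPair(ga, gb, [comp("a0", "b0", "ACDEF", "ACDEF")])
        sc = alnvar.classify_sites(gp)
        assert sc.degenerate
        assert set(sc.classes_a) <= {"common", "gap"}

    def test_identical_comparisons_give_rm_zero(self):
        ga = make_group(["ACDEF", "ACDEF"], gid="A", prefix="a")
        gb = make_group(["ACDEF"], gid="B", prefix="b")
        comparisons = [comp("a0", "b0", "ACDEF", "ACDEF"),
                       comp("a1", "b0", "ACDEF", "ACDEF")]
        sc = alnvar.classify_sites(alnvar.GroupPair(ga, gb, comparisons))
        assert sc.rm == 0.0


class TestPipelinePartition:
    def test_all_group_pairs_partition(self, pipeline_report):
        for sc in pipeline_report.site_classes.values():
            assert sc.rc + sc.rm + sc.rg == pytest.approx(100.0, abs=1e-9)
            assert sc.nc + sc.nm + sc.ng == pytest.approx(sc.na)


class TestStateDistribution:
    def test_weight_splitting(self):
        ga = make_group(["AC"], gid="A", prefix="a")
        gb = make_group(["AC"], gid="B", prefix="b")
        gp = alnvar.GroupPair(ga, gb, [comp("a0", "b0", "AC", "AC"),
                                       comp("a0", "b0", "AC", "AC")])
        sc = alnvar.classify_sites(gp)
        # site 1: pure helix; site 2: two-state wobble C/E
        states_a = [{"a0": "H"}, {"a0": "C", "x": "E"}]
        states_b = [{"b0": "H"}, {"b0": "C"}]
        d = alnvar.ss_distribution_by_class(gp, sc, states_a, states_b)
        common = d.fractions["common"]
        # 4 site-observations in class common: H, (0.5C+0.5E), H, C
        assert common["H"] == pytest.approx(2.0 / 4.0)
        assert common["C"] == pytest.approx(1.5 / 4.0)
        assert common["E"] == pytest.approx(0.5 / 4.0)

    def test_three_state_site_splits_in_thirds(self):
        ga = make_group(["A"], gid="A", prefix="a")
        gb = make_group(["A"], gid="B", prefix="b")
        gp = alnvar.GroupPair(ga, gb, [comp("a0", "b0", "A", "A"),
                                       comp("a0", "b0", "A", "A")])
        sc = alnvar.classify_sites(gp)
        d = alnvar.ss_distribution_by_class(
            gp, sc, [{"a0": "C", "x": "H", "y": "E"}], [{"b0": "C"}])
        assert d.fractions["common"]["H"] == pytest.approx((1 / 3) / 2)

    def test_fractions_sum_to_one_per_populated_class(self, pipeline_report):
        for gp in pipeline_report.group_pairs:
            sc = pipeline_report.site_classes[gp.pair_id]
            d = alnvar.ss_distribution_by_class(
                gp, sc,
                pipeline_report.wobble_tables[gp.group_a.group_id].site_states,
                pipeline_report.wobble_tables[gp.group_b.group_id].site_states,
            )
            for cls, tot in d.totals.items():
                if tot > 0:
                    assert sum(d.fractions[cls].values()) == pytest.approx(1.0, abs=1e-9)
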