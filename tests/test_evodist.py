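import numpy as np
import pytest
from scipy import stats as sps

from structflex import evodist
from structflex.synthetic import mutate_sequence

AA = list("ACDEFGHIKLMNPQRSTVWY")


class TestEvolutionaryDistance:
    def test_identical_gapfree_is_zero(self):
        assert evodist.evolutionary_distance("AR", "AR").ed == pytest.approx(0.0)

    def test_single_mismatch_arithmetic(self):
        # M(A,R) = -1, M(A,A) = 4, M(R,R) = 5
        r = evodist.evolutionary_distance("A", "R")
        assert r.ed == pytest.approx((1 - 2 * (-1) / 9) * 100)
        assert round(r.ed, 2) == 122.22

    def test_two_column_arithmetic(self):
        r = evodist.evolutionary_distance("AA", "AR")
        assert round(r.ed, 2) == 64.71

    def test_gap_columns_excluded(self):
        full = evodist.evolutionary_distance("AR", "AR")
        gapped = evodist.evolutionary_distance("AR-W", "AR--")
        assert gapped.ed == pytest.approx(full.ed)
        assert gapped.n == 2

    def test_all_gap_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            evodist.evolutionary_distance("A-", "-A")

    def test_symmetry(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 30))
            sx = "".join(rng.choice(AA + ["-"], n))
            sy = "".join(rng.choice(AA + ["-"], n))
            if not any(a != "-" and b != "-" for a, b in zip(sx, sy)):
                continue
            assert evodist.evolutionary_distance(sx, sy).ed == pytest.approx(
                evodist.evolutionary_distance(sy, sx).ed, abs=1e-12)

    def test_increases_with_substitution_load(self, rng):
        """ED rank-correlates with the number of substitutions applied."""
        base = "".join(rng.choice(AA, 120))
        counts, eds = [], []
        for _ in range(100):
            k = int(rng.integers(1, 40))
            mutant, sites = mutate_sequence(base, k, rng)
            counts.append(len(sites))
            eds.append(evodist.evolutionary_distance(base, mutant).ed)
        rho = sps.spearmanr(counts, eds).statistic
        assert rho > 0.9


class TestExtremeSelection:
    def _mkcomp(self, rmsd, tm, ids=("x", "y")):
        class C:
            pass

        c = C()
        c.rmsd, c.tm_score, (c.id_a, c.id_b) = rmsd, tm, ids
        return c

    def test_rmsd_extremes(self):
        comps = [self._mkcomp(1.0, 0.8, ("a", "b")),
                 self._mkcomp(2.0, 0.6, ("a", "c")),
                 self._mkcomp(0.5, 0.9, ("a", "d"))]
        best, worst = evodist.select_extreme_alignments(comps, "rmsd")
        assert best.rmsd == 0.5 and worst.rmsd == 2.0

    def test_tm_extremes(self):
        comps = [self._mkcomp(1.0, 0.4, ("a", "b")), self._mkcomp(2.0, 0.9, ("a", "c"))]
        best, worst = evodist.select_extreme_alignments(comps, "tm")
        assert best.tm_score == 0.9 and worst.tm_score == 0.4

    def test_ties_break_lexicographically(self):
        comps = [self._mkcomp(1.0, 0.5, ("b", "x")), self._mkcomp(1.0, 0.5, ("a", "x"))]
        best, worst = evodist.select_extreme_alignments(comps, "rmsd")
        assert best.id_a == "a" and worst.id_a == "a"

    def test_single_comparison_rejected(self):
        with pytest.raises(ValueError):
            evodist.select_extreme_alignments([self._mkcomp(1.0, 0.5)], "rmsd")


class TestGapCounting:
    def test_terminal_columns_trimmed(self):
        g = evodist.count_gaps("-AC", "MAC")
        assert g.openings == 0 and g.extensions == 0

    def test_two_internal_openings(self):
        g = evodist.count_gaps("ACD-E", "AC-GE")
        assert g.openings == 2 and g.extensions == 0

    def test_run_of_three(self):
        g = evodist.count_gaps("A---E", "ACDFE")
        assert g.openings == 1 and g.extensions == 2

    def test_row_swap_invariance(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 20))
            sx = "".join(rng.choice(AA + ["-"], n))
            sy = "".join(rng.choice(AA + ["-"], n))
            g0 = evodist.count_gaps(sx, sy)
            g1 = evodist.count_gaps(sy, sx)
            assert (g0.openings, g0.extensions) == (g1.openings, g1.extensions)

    def test_run_length_identity(self, rng):
        """openings + extensions equals total internal gap columns per row."""
        for _ in range(50):
            n = int(rng.integers(4, 25))
            sx = "".join(rng.choice(AA + ["-"], n))
            sy = "".join(rng.choice(AA, n))
            cx, cy = evodist.trim_terminal_gaps(sx, sy)
            g = evodist.count_gaps(sx, sy)
            assert g.openings_a + g.extensions_a == cx.count("-")

    def test_fully_consumed_alignment_degenerate(self):
        g = evodist.count_gaps("A-", "-A")
        assert g.degenerate
        assert g.openings == 0


class TestQuadrants:
    @pytest.mark.parametrize("dx,dy,expect", [
        (1, 2, "I"), (-1, 2, "II"), (-3, -1, "III"), (1, -2, "IV"),
        (0, 5, "axis"), (2, 0, "axis"), (0, 0, "origin"),
    ])
    def test_labels(self, dx, dy, expect):
        assert evodist.quadrant(dx, dy) == expect


class TestExceptionAnalysis:
    def _pair(self, pid, rows_best, rows_worst):
        import numpy as np

        from structflex.superpose import Correspondence, SuperpositionResult

        def mk(rmsd, rows, ids):
            pairs = []
            ia = ib = 0
            for a, b in zip(*rows):
                if a != "-" and b != "-":
                    pairs.append((ia, ib))
                if a != "-":
                    ia += 1
                if b != "-":
                    ib += 1
            corr = Correspondence(tuple(pairs), rows[0], rows[1])
            return SuperpositionResult(corr, np.eye(3), np.zeros(3), rmsd, 1 / (1 + rmsd),
                                       len(pairs), 2.0, *ids)

        class GP:
            pass

        gp = GP()
        gp.pair_id = pid
        gp.comparisons = [mk(0.5, rows_best, ("a", "b")), mk(2.0, rows_worst, ("a", "c"))]
        return gp

    def test_conforming_and_exception(self):
        conforming = self._pair("p1", ("AAAA", "AAAA"), ("AAAA", "ARRA"))
        exception = self._pair("p2", ("AAAA", "ARRA"), ("AAAA", "AAAA"))
        records, census = evodist.exception_analysis([conforming, exception], "rmsd")
        assert [r.is_exception for r in records] == [False, True]
        assert sum(census.values()) == 1

    def test_zero_difference_not_exception(self):
        same = self._pair("p", ("AAAA", "AAAA"), ("AAAA", "AAAA"))
        records, census = evodist.exception_analysis([same], "rmsd")
        assert records[0].zero_difference and not records[0].is_exception
        assert sum(census.values()) == 0

    def test_census_totals_equal_exception_count(self, pipeline_report):
        for crit, (records, census) in (("rmsd", pipeline_report.exceptions_rmsd),
                                        ("tm", pipeline_report.exceptions_tm)):
            n_exc = sum(1 for r in records if r.is_exception)
            assert sum(census.values()) == n_exc
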