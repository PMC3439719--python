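"""Evolutionary distance of structure-derived alignments and gap diagnostics.

The evolutionary distance (ED) of an aligned pair Sx, Sy is a BLOSUM62-
normalized dissimilarity over the n both-residue columns:

    ED = [1 - 2 * sum M(x_i, y_i) / (sum M(x_i, x_i) + sum M(y_i, y_i))] * 100

so that ED = 0 for identical gap-free sequences and grows with substitution
load.  Per group pair the best/worst structural comparisons (min/max RMSD, or
max/min TM-score) are selected and the expectation ED(best) <= ED(worst) is
audited; exceptions are profiled by their gap-opening/extension differences
after terminal trimming.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .align import GAP, blosum62_score


@dataclass(frozen=True)
class EDResult:
    ed: float
    cross_sum: float  # sum of M(x_i, y_i)
    self_sum: float   # sum of M(x_i, x_i) + M(y_i, y_i)
    n: int


@dataclass(frozen=True)
class GapCounts:
    openings_a: int
    extensions_a: int
    openings_b: int
    extensions_b: int
    degenerate: bool = False

    @property
    def openings(self) -> int:
        return self.openings_a + self.openings_b

    @property
    def extensions(self) -> int:
        return self.extensions_a + self.extensions_b


@dataclass(frozen=True)
class ExceptionRecord:
    pair_id: str
    criterion: str  # "rmsd" or "tm"
    ed_best: float
    ed_worst: float
    ed_difference: float  # ed_best - ed_worst
    delta_openings: int   # gaps(best) - gaps(worst)
    delta_extensions: int
    quadrant: str         # I, II, III, IV, axis, origin
    is_exception: bool
    zero_difference: bool


def evolutionary_distance(sx: str, sy: str) -> EDResult:
    """ED over the both-residue columns of an aligned pair (gap columns
    contribute to none of the three sums)."""
    if len(sx) != len(sy):
        raise ValueError("aligned strings must have equal length")
    cross = sxx = syy = 0.0
    n = 0
    for a, b in zip(sx, sy):
        if a == GAP or b == GAP:
            continue
        n += 1
        cross += blosum62_score(a, b)
        sxx += blosum62_score(a, a)
        syy += blosum62_score(b, b)
    if n == 0:
        raise ValueError("no aligned residues")
    ed = (1.0 - 2.0 * cross / (sxx + syy)) * 100.0
    return EDResult(ed, cross, sxx + syy, n)


def select_extreme_alignments(comparisons, criterion: str):
    """Best/worst comparisons by the structural criterion.

    For 'rmsd': best = minimum, worst = maximum.  For 'tm': best = maximum,
    worst = minimum.  Ties break lexicographically on the structure-id pair.
    """
    comparisons = sorted(comparisons, key=lambda c: (c.id_a, c.id_b))
    if len(comparisons) < 2:
        raise ValueError("need at least 2 comparisons")
    # min/max return the first optimum, i.e. the lexicographically smallest id pair
    if criterion == "rmsd":
        best = min(comparisons, key=lambda c: c.rmsd)
        worst = max(comparisons, key=lambda c: c.rmsd)
    elif criterion == "tm":
        best = max(comparisons, key=lambda c: c.tm_score)
        worst = min(comparisons, key=lambda c: c.tm_score)
    else:
        raise ValueError(f"unknown criterion: {criterion!r}")
    return best, worst


def trim_terminal_gaps(sx: str, sy: str) -> tuple[str, str]:
    """Drop leading/trailing columns belonging to a terminal gap run in
    either row, leaving the aligned core."""
    start, end = 0, len(sx)
    while start < end and (sx[start] == GAP or sy[start] == GAP):
        start += 1
    while end > start and (sx[end - 1] == GAP or sy[end - 1] == GAP):
        end -= 1
    return sx[start:end], sy[start:end]


def _row_gap_runs(row: str) -> tuple[int, int]:
    openings = extensions = 0
    run = 0
    for ch in row:
        if ch == GAP:
            run += 1
        else:
            if run:
                openings += 1
                extensions += run - 1
            run = 0
    if run:
        openings += 1
        extensions += run - 1
    return openings, extensions


def count_gaps(sx: str, sy: str) -> GapCounts:
    """Gap openings/extensions per row of the terminally-trimmed core.

    A run of k >= 1 gaps counts 1 opening and k-1 extensions.
    """
    cx, cy = trim_terminal_gaps(sx, sy)
    if not cx:
        return GapCounts(0, 0, 0, 0, degenerate=True)
    oa, ea = _row_gap_runs(cx)
    ob, eb = _row_gap_runs(cy)
    return GapCounts(oa, ea, ob, eb)


def quadrant(dx: int, dy: int) -> str:
    if dx == 0 and dy == 0:
        return "origin"
    if dx == 0 or dy == 0:
        return "axis"
    if dx > 0 and dy > 0:
        return "I"
    if dx < 0 < dy:
        return "II"
    if dx < 0 and dy < 0:
        return "III"
    return "IV"


def exception_analysis(group_pairs, criterion: str = "rmsd"
                       ) -> tuple[list[ExceptionRecord], Counter]:
    """Audit ED(best) <= ED(worst) across group pairs.

    ``group_pairs`` yields objects with ``pair_id`` and ``comparisons``
    (SuperpositionResults).  An exception is ED(best) > ED(worst); zero
    difference is its own class.  For exceptions, gap differences are
    gaps(best) - gaps(worst) and the (delta openings, delta extensions)
    plane gives the quadrant census.
    """
    records = []
    census: Counter = Counter()
    for gp in group_pairs:
        best, worst = select_extreme_alignments(gp.comparisons, criterion)
        ed_b = evolutionary_distance(best.correspondence.aligned_a,
                                     best.correspondence.aligned_b).ed
        ed_w = evolutionary_distance(worst.correspondence.aligned_a,
                                     worst.correspondence.aligned_b).ed
        diff = ed_b - ed_w
        is_exc = diff > 0
        zero = diff == 0
        gb = count_gaps(best.correspondence.aligned_a, best.correspondence.aligned_b)
        gw = count_gaps(worst.correspondence.aligned_a, worst.correspondence.aligned_b)
        dx = gb.openings - gw.openings
        dy = gb.extensions - gw.extensions
        q = quadrant(dx, dy)
        records.append(ExceptionRecord(gp.pair_id, criterion, ed_b, ed_w, diff,
                                       dx, dy, q, is_exc, zero))
        if is_exc:
            census[q] += 1
    return records, census
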