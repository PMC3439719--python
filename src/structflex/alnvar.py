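"""Sequence-alignment variation across the structural comparisons of a group pair.

All cross-comparisons between two structural groups yield one structure-based
sequence alignment each.  A residue site whose partner is identical in every
comparison is a *common site*; a site aligned to a gap in every comparison is
a *gap site*; everything else (different partners, or a mix of partners and
gaps) is a *multi site*.  Ratios follow

    Rx = Nx / Na * 100%

with Nx the per-class count averaged over the two proteins and Na the average
of the two protein lengths, so Rc + Rm + Rg = 100% by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import GAP
from .grouping import StructuralGroup
from .superpose import SuperpositionResult

CLASSES = ("common", "multi", "gap")


@dataclass
class GroupPair:
    """All cross-group structural comparisons between two groups of a family."""

    group_a: StructuralGroup
    group_b: StructuralGroup
    comparisons: list[SuperpositionResult]

    @property
    def pair_id(self) -> str:
        return f"{self.group_a.group_id}|{self.group_b.group_id}"

    @property
    def rmsd_max(self) -> float:
        return max(c.rmsd for c in self.comparisons)

    @property
    def rmsd_min(self) -> float:
        return min(c.rmsd for c in self.comparisons)

    @property
    def tm_max(self) -> float:
        return max(c.tm_score for c in self.comparisons)

    @property
    def tm_min(self) -> float:
        return min(c.tm_score for c in self.comparisons)


@dataclass
class SiteClassification:
    classes_a: list[str]  # per A-side MSA column in CLASSES, or "" if unobserved
    classes_b: list[str]
    nc: float
    nm: float
    ng: float
    na: float
    rc: float
    rm: float
    rg: float
    degenerate: bool = False  # single comparison: common/gap only


def _residue_to_column(msa_row: str) -> list[int]:
    """Map 0-based ungapped residue index -> MSA column for one row."""
    return [col for col, ch in enumerate(msa_row) if ch != GAP]


def _votes(pair: GroupPair, side: str) -> list[dict]:
    """Per MSA column of the given side's group, the partner column (or GAP)
    voted by each comparison covering that column."""
    group = pair.group_a if side == "a" else pair.group_b
    other = pair.group_b if side == "a" else pair.group_a
    ncol = len(group.msa[0])
    row_of = dict(zip(group.member_ids, group.msa))
    row_of_other = dict(zip(other.member_ids, other.msa))
    votes: list[dict] = [dict() for _ in range(ncol)]
    for k, comp in enumerate(pair.comparisons):
        mid = comp.id_a if side == "a" else comp.id_b
        oid = comp.id_b if side == "a" else comp.id_a
        r2c = _residue_to_column(row_of[mid])
        r2c_other = _residue_to_column(row_of_other[oid])
        partner = {}
        for i, j in comp.correspondence.pairs:
            if side == "a":
                partner[i] = j
            else:
                partner[j] = i
        n_res = len(r2c)
        for ridx in range(n_res):
            col = r2c[ridx]
            p = partner.get(ridx)
            votes[col][k] = GAP if p is None else r2c_other[p]
    return votes


def _classify(votes: list[dict]) -> list[str]:
    out = []
    for v in votes:
        if not v:
            out.append("")
        elif all(p == GAP for p in v.values()):
            out.append("gap")
        elif len(set(v.values())) == 1:
            out.append("common")
        else:
            out.append("multi")
    return out


def classify_sites(pair: GroupPair) -> SiteClassification:
    """Classify every residue site of both proteins as common/multi/gap.

    A site's class aggregates its partner across all comparisons of the group
    pair; counts are averaged over the two proteins and normalized by the
    average protein length (Na), so the three ratios sum to 100%.
    """
    if not pair.comparisons:
        raise ValueError("group pair has no comparisons")
    ca = _classify(_votes(pair, "a"))
    cb = _classify(_votes(pair, "b"))
    counts = {}
    for cls in CLASSES:
        counts[cls] = (sum(1 for c in ca if c == cls) + sum(1 for c in cb if c == cls)) / 2.0
    na = (sum(1 for c in ca if c) + sum(1 for c in cb if c)) / 2.0
    if na == 0:
        raise ValueError("no observed sites")
    rc, rm, rg = (counts[c] / na * 100.0 for c in CLASSES)
    return SiteClassification(ca, cb, counts["common"], counts["multi"], counts["gap"],
                              na, rc, rm, rg, degenerate=len(pair.comparisons) < 2)


def variation_ratios(sc: SiteClassification) -> tuple[float, float, float]:
    """(Rc, Rm, Rg) percentages."""
    if sc.na == 0:
        raise ValueError("Na is zero")
    return sc.rc, sc.rm, sc.rg


@dataclass
class StateDistribution:
    """Per site class, the C/H/E state fractions (each class sums to 1)."""

    fractions: dict[str, dict[str, float]] = field(default_factory=dict)
    totals: dict[str, float] = field(default_factory=dict)


def ss_distribution_by_class(
    pair: GroupPair,
    sc: SiteClassification,
    site_states_a: list[dict[str, str]],
    site_states_b: list[dict[str, str]],
) -> StateDistribution:
    """Secondary-structure state composition of each site class.

    Each site contributes weight 1, split equally among its observed distinct
    3-states (0.5 each at a two-state wobble site, 1/3 each at a three-state
    site), accumulated into the site's class for both proteins.
    """
    acc = {cls: {"C": 0.0, "H": 0.0, "E": 0.0} for cls in CLASSES}
    tot = {cls: 0.0 for cls in CLASSES}
    for classes, site_states in ((sc.classes_a, site_states_a), (sc.classes_b, site_states_b)):
        for cls, states in zip(classes, site_states):
            if cls not in CLASSES or not states:
                continue
            distinct = sorted(set(states.values()))
            w = 1.0 / len(distinct)
            for s in distinct:
                acc[cls][s] += w
            tot[cls] += 1.0
    fractions = {
        cls: {s: (acc[cls][s] / tot[cls] if tot[cls] else 0.0) for s in "CHE"}
        for cls in CLASSES
    }
    return StateDistribution(fractions, tot)
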