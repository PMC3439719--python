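"""Secondary-structure wobble across a structural group.

An equivalent site (MSA column) whose member structures disagree on the
3-state secondary structure is a *wobble site*.  The wobble ratio is

    Rw = Nw / Na * 100%

with Nw the wobble-site count and Na the total observed sites.  'Wobble
Total' is the group-wide ratio; 'Wobble Single' the ratio over one structure
pair.  This module also tallies the wobble types (C<=>E, C<=>H, H<=>E),
regresses Wobble Total on the maximum Wobble Single, tests mutation-site
enrichment, and relates coil content at wobble sites to X-ray resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import statkit
from .align import GAP
from .grouping import StructuralGroup

WOBBLE_TYPES = ("C<=>E", "C<=>H", "H<=>E")
_PAIR_TO_TYPE = {
    frozenset("CE"): "C<=>E",
    frozenset("CH"): "C<=>H",
    frozenset("HE"): "H<=>E",
}


@dataclass
class WobbleTable:
    group_id: str
    site_states: list[dict[str, str]]  # per MSA column: member id -> 3-state
    wobble_flags: list[bool]
    nw: int
    na: int
    rw: float  # percent
    type_counts: dict[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class WobblePairSummary:
    id_a: str
    id_b: str
    wobble_single: float  # percent
    resolution_a: float | None
    resolution_b: float | None


@dataclass
class ResolutionCoilCurve:
    bin_edges: np.ndarray      # lower edges, 0.1 A apart
    coil_ratio: np.ndarray     # per populated bin
    counts: np.ndarray         # states attributed per bin
    pcc: float
    pcc_p: float
    fit: statkit.FitResult
    min_states: int            # bin-population filter applied to pcc/fit


def wobble_ratio(nw: int, na: int) -> float:
    """Rw = Nw / Na * 100 (percent)."""
    if na <= 0:
        raise ValueError("Na must be positive")
    return nw / na * 100.0


def _column_states(group: StructuralGroup, states3: dict[str, str]) -> list[dict[str, str]]:
    """Per MSA column, each member's 3-state; gap positions contribute nothing."""
    out: list[dict[str, str]] = []
    ncol = len(group.msa[0]) if group.msa else 0
    pointers = {m: 0 for m in group.member_ids}
    for mid in group.member_ids:
        row = group.msa[group.member_ids.index(mid)]
        expected = sum(1 for c in row if c != GAP)
        if len(states3[mid]) != expected:
            raise ValueError(
                f"{mid}: states3 length {len(states3[mid])} != ungapped row length {expected}"
            )
    for col in range(ncol):
        states: dict[str, str] = {}
        for mid, row in zip(group.member_ids, group.msa):
            if row[col] != GAP:
                states[mid] = states3[mid][pointers[mid]]
                pointers[mid] += 1
        out.append(states)
    return out


def find_wobble_sites(group: StructuralGroup, states3: dict[str, str]) -> WobbleTable:
    """Wobble table for a group given each member's 3-state string.

    ``states3[member_id]`` maps 1:1 onto that member's non-gap MSA positions.
    Na counts columns with at least one observed state.
    """
    site_states = _column_states(group, states3)
    flags = [len(set(s.values())) >= 2 for s in site_states]
    na = sum(1 for s in site_states if s)
    nw = sum(flags)
    table = WobbleTable(group.group_id, site_states, flags, nw, na,
                        wobble_ratio(nw, na) if na else 0.0)
    table.type_counts = classify_wobble_types(table)
    return table


def classify_wobble_types(table: WobbleTable) -> dict[str, int]:
    """Tally wobble types per column; every unordered state pair present is
    incremented, so a three-state column increments all three tallies."""
    counts = {t: 0 for t in WOBBLE_TYPES}
    for states, flag in zip(table.site_states, table.wobble_flags):
        if not flag:
            continue
        present = set(states.values())
        for pair, name in _PAIR_TO_TYPE.items():
            if pair <= present:
                counts[name] += 1
    return counts


def wobble_single(group: StructuralGroup, states3: dict[str, str],
                  id_a: str, id_b: str) -> WobblePairSummary:
    """Wobble ratio over one structure pair: wobble sites where the two
    disagree, over the columns where at least one of the two is present."""
    site_states = _column_states(group, states3)
    nw = na = 0
    for states in site_states:
        sa, sb = states.get(id_a), states.get(id_b)
        if sa is None and sb is None:
            continue
        na += 1
        if sa is not None and sb is not None and sa != sb:
            nw += 1
    res = {m.structure_id: m.resolution for m in group.members}
    return WobblePairSummary(id_a, id_b, wobble_ratio(nw, na) if na else 0.0,
                             res[id_a], res[id_b])


def group_pair_summaries(group: StructuralGroup, states3: dict[str, str]
                         ) -> list[WobblePairSummary]:
    """Wobble Single for every member pair (all C(m,2) combinations)."""
    ids = group.member_ids
    return [wobble_single(group, states3, ids[i], ids[j])
            for i in range(len(ids)) for j in range(i + 1, len(ids))]


def wobble_total_vs_single(totals, max_singles) -> dict:
    """Regress Wobble Total on the maximum Wobble Single across groups.

    Returns the through-origin slope, the unconstrained fit, and the implied
    fraction (slope-1)/slope of wobble sites visible only in intermediate
    conformations (those beyond the two most different structures).
    """
    totals = np.asarray(totals, dtype=float)
    max_singles = np.asarray(max_singles, dtype=float)
    if totals.size < 3:
        raise ValueError("need at least 3 groups")
    origin = statkit.linear_fit(max_singles, totals, through_origin=True)
    free = statkit.linear_fit(max_singles, totals, through_origin=False)
    s = origin.slope
    return {
        "slope_through_origin": s,
        "fit_through_origin": origin,
        "fit": free,
        "intermediate_fraction": (s - 1.0) / s if s != 0 else float("nan"),
    }


def mutation_wobble_stats(table: WobbleTable, mutation_sites: set[int]):
    """2x2 mutation-site wobble enrichment: (mutation wobble / non-wobble) vs
    (all sites wobble / non-wobble), Yates-corrected chi-square.

    Returns None when the group carries no mutation sites.
    """
    if not mutation_sites:
        return None
    mut_w = sum(1 for c in mutation_sites
                if 1 <= c <= len(table.wobble_flags) and table.wobble_flags[c - 1])
    mut_n = len(mutation_sites) - mut_w
    contingency = [[mut_w, mut_n], [table.nw, table.na - table.nw]]
    result = statkit.chi_square_2x2(contingency, yates=True)
    return {"table": contingency, "chi2": result,
            "mutation_rw": wobble_ratio(mut_w, len(mutation_sites))}


def resolution_coil_curve(
    pair_states: list[tuple[float, str]],
    bin_width: float = 0.1,
    min_states: int = 0,
) -> ResolutionCoilCurve:
    """Coil fraction at wobble sites versus X-ray resolution.

    ``pair_states`` holds one (resolution, state) record per structure per
    wobble site per structure pair: whenever two structures wobble at a
    site, each structure's 3-state is attributed to that structure's
    resolution bin (lower-edge labels, width 0.1 A by default).  The PCC and
    linear fit of coil ratio on bin midpoint may be restricted to bins with
    more than ``min_states`` attributed states.
    """
    if not pair_states:
        raise ValueError("no wobble states to bin")
    res = np.array([r for r, _ in pair_states], dtype=float)
    is_coil = np.array([s == "C" for _, s in pair_states], dtype=float)
    lo = np.floor(res.min() / bin_width) * bin_width
    idx = np.floor((res - lo) / bin_width + 1e-9).astype(int)
    nbins = idx.max() + 1
    counts = np.bincount(idx, minlength=nbins)
    coil = np.bincount(idx, weights=is_coil, minlength=nbins)
    populated = counts > 0
    edges = lo + bin_width * np.arange(nbins)
    ratio = np.zeros(nbins)
    ratio[populated] = coil[populated] / counts[populated]

    sel = counts > min_states
    if sel.sum() < 3:
        sel = populated
    mid = edges + bin_width / 2.0
    try:
        pcc, p = statkit.pearson_cc(mid[sel], ratio[sel])
    except ValueError:  # constant coil ratio: correlation undefined
        pcc, p = float("nan"), float("nan")
    fit = statkit.linear_fit(mid[sel], ratio[sel])
    return ResolutionCoilCurve(edges[populated], ratio[populated], counts[populated],
                               pcc, p, fit, min_states)
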