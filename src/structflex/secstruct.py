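"""Secondary-structure assignment and 3-state reduction.

When no DSSP file accompanies a structure, a simplified Kabsch–Sander
assignment is computed from backbone geometry: amide hydrogens are imputed,
H-bonds scored with the classic electrostatic energy model, and helix/strand
patterns derived from n-turns and bridge ladders.  Supplied DSSP files always
take precedence (see the pipeline module).

The downstream wobble analysis consumes only three states: H (helix: H/G/I),
E (sheet), C (everything else).
"""

from __future__ import annotations

import logging

import numpy as np

from .io import ChainStructure, SecondaryStructureString

log = logging.getLogger(__name__)

HBOND_ENERGY_CUTOFF = -0.5  # kcal/mol
_Q1Q2_F = 0.084 * 332.0  # partial charges times electrostatic constant

THREE_STATE_MAP = {
    "H": "H", "G": "H", "I": "H",
    "E": "E",
    "B": "C", "T": "C", "S": "C", "-": "C", "C": "C",
}


def hbond_energy(r_on: float, r_ch: float, r_oh: float, r_cn: float) -> float:
    """Kabsch–Sander electrostatic H-bond energy in kcal/mol.

    E = 0.084 * 332 * (1/rON + 1/rCH - 1/rOH - 1/rCN).  Distances below the
    0.5 A clash guard are clamped (with a warning) rather than rejected.
    """
    dists = []
    for r in (r_on, r_ch, r_oh, r_cn):
        if r <= 0.5:
            log.warning("hbond distance %.3f A clamped to 0.5 A", r)
            r = 0.5
        dists.append(r)
    r_on, r_ch, r_oh, r_cn = dists
    return _Q1Q2_F * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def _impute_hydrogens(cs: ChainStructure) -> list[np.ndarray | None]:
    """Amide H at 1.01 A from N, along the previous residue's O->C direction.

    The first residue (and any residue after a missing-atom gap) gets no H,
    matching the convention of the original assignment method.
    """
    hpos: list[np.ndarray | None] = [None] * len(cs)
    for i in range(1, len(cs)):
        prev, cur = cs.residues[i - 1], cs.residues[i]
        if "C" not in prev.atoms or "O" not in prev.atoms or "N" not in cur.atoms:
            continue
        d = prev.atoms["C"] - prev.atoms["O"]
        norm = np.linalg.norm(d)
        if norm == 0:
            continue
        hpos[i] = cur.atoms["N"] + 1.01 * d / norm
    return hpos


def compute_hbonds(cs: ChainStructure) -> set[tuple[int, int]]:
    """Backbone H-bonds as (donor_index, acceptor_index) residue pairs (0-based).

    donor i contributes N-H, acceptor j contributes C=O; accepted when the
    electrostatic energy is below -0.5 kcal/mol and |i-j| >= 2.  Prolines
    (no amide H) are handled implicitly: the H is still imputed from backbone
    geometry, a simplification documented in the methods note.
    """
    n = len(cs)
    hpos = _impute_hydrogens(cs)
    npos = [r.atoms.get("N") for r in cs.residues]
    cpos = [r.atoms.get("C") for r in cs.residues]
    opos = [r.atoms.get("O") for r in cs.residues]
    ca = cs.ca_coords()
    bonds: set[tuple[int, int]] = set()
    for i in range(n):  # donor
        if npos[i] is None or hpos[i] is None:
            continue
        for j in range(n):  # acceptor
            if abs(i - j) < 2 or cpos[j] is None or opos[j] is None:
                continue
            # cheap CA-CA prefilter (9 A, as in the classic implementation)
            if np.linalg.norm(ca[i] - ca[j]) > 9.0:
                continue
            e = hbond_energy(
                float(np.linalg.norm(opos[j] - npos[i])),
                float(np.linalg.norm(cpos[j] - hpos[i])),
                float(np.linalg.norm(opos[j] - hpos[i])),
                float(np.linalg.norm(cpos[j] - npos[i])),
            )
            if e < HBOND_ENERGY_CUTOFF:
                bonds.add((i, j))
    return bonds


def assign_secondary_structure(cs: ChainStructure) -> SecondaryStructureString:
    """Simplified 8-state assignment from backbone coordinates.

    Priority: H (two consecutive i->i+4 turns) > E (bridge ladders of
    length >= 2) > B (isolated bridge) > G (3-10) > I (pi) > T (turn) > '-'.
    Bends ('S') are never emitted.  Chains shorter than 5 residues are all '-'.
    """
    n = len(cs)
    if n < 5:
        return _finish("-" * n)
    hb = compute_hbonds(cs)

    def turn(i: int, k: int) -> bool:
        # k-turn at i: CO(i) accepts the NH of residue i+k
        return (i + k, i) in hb

    states = ["-"] * n

    # bridges
    def par(i, j):
        return (turn_pair(j, i - 1) and turn_pair(i + 1, j)) or (
            turn_pair(i, j - 1) and turn_pair(j + 1, i)
        )

    def anti(i, j):
        return ((i, j) in hb and (j, i) in hb) or (
            turn_pair(j + 1, i - 1) and turn_pair(i + 1, j - 1)
        )

    def turn_pair(d, a):
        return 0 <= d < n and 0 <= a < n and (d, a) in hb

    bridges: set[tuple[int, int]] = set()
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            if par(i, j) or anti(i, j):
                bridges.add((i, j))

    # ladders: consecutive bridges (i, j) & (i+1, j+1) (parallel) or (i+1, j-1)
    ladder_members: set[int] = set()
    bridge_members: set[int] = set()
    for (i, j) in bridges:
        bridge_members.update((i, j))
        if (i + 1, j + 1) in bridges or (i + 1, j - 1) in bridges or (i - 1, j + 1) in bridges \
           or (i - 1, j - 1) in bridges:
            ladder_members.update((i, j))

    # two consecutive k-turns at i and i+1 put residues i+1..i+k in the helix
    def mark_runs(k: int, letter: str):
        for i in range(n - 1):
            if turn(i, k) and turn(i + 1, k):
                for m in range(i + 1, min(i + 1 + k, n)):
                    if states[m] == "-":
                        states[m] = letter

    mark_runs(4, "H")
    for m in ladder_members:
        if states[m] in ("-", "T"):
            states[m] = "E"
    for m in bridge_members - ladder_members:
        if states[m] == "-":
            states[m] = "B"
    mark_runs(3, "G")
    mark_runs(5, "I")
    # remaining turns
    for k in (3, 4, 5):
        for i in range(n):
            if turn(i, k):
                for m in range(i + 1, min(i + k, n)):
                    if states[m] == "-":
                        states[m] = "T"
    return _finish("".join(states))


def reduce_to_three_states(states8: str) -> str:
    """Map the 8-state alphabet onto H/E/C: H,G,I -> H; E -> E; rest -> C."""
    out = []
    for ch in states8:
        mapped = THREE_STATE_MAP.get(ch)
        if mapped is None:
            raise ValueError(f"unknown secondary-structure letter: {ch!r}")
        out.append(mapped)
    return "".join(out)


def _finish(states8: str) -> SecondaryStructureString:
    return SecondaryStructureString(states8=states8, states3=reduce_to_three_states(states8))
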