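"""Synthetic ensembles of near-identical-sequence protein structures.

Every analysis stage in this package is exercised against generated families
with known ground truth.  A family owns a segment layout (helix/strand/coil
stretches) realized as an ideal backbone from canonical bond geometry and
per-state phi/psi angles.  Groups within a family differ by a few point
substitutions; structures within a group differ by

* hinge motion: designated coil linkers whose dihedrals are perturbed per
  structure (Normal(0, spread) degrees), rotating the downstream domain as a
  rigid body;
* secondary-structure wobble: designated helix segments rebuilt as coil in a
  random subset of structures (whole-segment state flips);
* thermal jitter: smooth, chain-correlated Gaussian displacement of each
  residue, with per-state amplitude.

Each structure's X-ray resolution is drawn from a linear-in-coil-fraction
model, so the downstream resolution/coil analysis has a recoverable slope
sign.  A single seeded generator drives every draw; the same seed yields
byte-identical PDB output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import ChainStructure, ResidueRecord, write_pdb_chain

# canonical backbone geometry (Angstrom, degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA = 180.0

PHI_PSI = {"H": (-57.0, -47.0), "E": (-120.0, 120.0)}
COIL_PHI_RANGE = (-160.0, -70.0)
COIL_PSI_RANGE = (90.0, 175.0)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: residues this close to a segment boundary are excluded from both the
#: ground-truth wobble core and the rigid core (terminal assignment drift)
BOUNDARY_MARGIN = 2


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic ensembles.

    Defaults give 3 families x 3 groups x 6 structures: large enough for
    every selection rule and statistic to engage, small enough to run in
    seconds.  One hinge linker and one flip-capable helix per chain emulate
    the flexibility the analysis is meant to detect.
    """

    n_families: int = 3
    groups_per_family: int = 3
    structures_per_group: int = 6
    segment_layout: tuple[tuple[str, int], ...] = (
        ("C", 4), ("H", 16), ("C", 5), ("H", 14), ("C", 4), ("H", 12),
        ("C", 5), ("H", 18), ("C", 4), ("H", 16), ("C", 4),
    )
    hinge_segments: tuple[int, ...] = (2,)       # indices into segment_layout (coil)
    flip_segments: tuple[int, ...] = (1, 9)      # helix segments that may flip to coil
    flip_probability: float = 0.3
    hinge_spread: float = 8.0                    # degrees, total angular scale of a hinge
    jitter: dict = field(default_factory=lambda: {"H": 0.08, "E": 0.08, "C": 0.2})
    mutation_probability: float = 0.45           # per group: carries a mutated member
    mutation_wobble_bias: float = 0.5            # chance a mutation sits in a flip core
    substitutions_between_groups: int = 4
    terminal_truncation_max: int = 2             # residues removable per chain end, per group
    resolution_intercept: float = 1.3            # Angstrom
    resolution_slope: float = 1.5                # Angstrom per unit coil fraction
    resolution_noise: float = 0.15
    seed: int = 0

    def total_length(self) -> int:
        return sum(n for _, n in self.segment_layout)


@dataclass
class GroundTruth:
    """Realized ground truth for one generated family."""

    family_id: str
    group_ids: list[str]
    sequences: dict[str, str]                  # group id -> sequence of first member
    wobble_sites: dict[str, set[int]]          # group id -> 1-based core flip sites
    rigid_sites: dict[str, set[int]]           # group id -> 1-based rigid-core sites
    mutation_sites: dict[str, set[int]]        # group id -> 1-based substituted sites
    substitution_counts: dict[str, int]        # group id -> subs vs family base
    coil_fraction: dict[str, float]            # structure id -> realized coil fraction
    resolution: dict[str, float]               # structure id -> assigned resolution
    state_labels: dict[str, str]               # structure id -> realized 3-state string


def _place_atom(a, b, c, bond: float, angle: float, dihedral: float) -> np.ndarray:
    """Position a fourth atom from three predecessors (natural extension
    reference frame): |cd| = bond, angle(b,c,d) = angle, dihedral(a,b,c,d)."""
    ang = math.radians(angle)
    tor = math.radians(dihedral)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array(
        [-bond * math.cos(ang), bond * math.sin(ang) * math.cos(tor),
         bond * math.sin(ang) * math.sin(tor)]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def build_backbone(phi_psi: np.ndarray) -> list[dict[str, np.ndarray]]:
    """Ideal backbone (N, CA, C, O per residue) from an (L, 2) phi/psi array.

    phi of the first residue is unused; omega is fixed trans.
    """
    L = len(phi_psi)
    atoms: list[dict[str, np.ndarray]] = []
    n0 = np.zeros(3)
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = math.radians(ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    atoms.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, L):
        prev = atoms[i - 1]
        n = _place_atom(prev["N"], prev["CA"], prev["C"], BOND_C_N, ANGLE_CA_C_N,
                        phi_psi[i - 1, 1])
        ca = _place_atom(prev["CA"], prev["C"], n, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        c = _place_atom(prev["C"], n, ca, BOND_CA_C, ANGLE_N_CA_C, phi_psi[i, 0])
        atoms.append({"N": n, "CA": ca, "C": c})
    # carbonyl oxygens: trans to the next amide nitrogen (psi + 180)
    for i in range(L):
        psi = phi_psi[i, 1]
        atoms[i]["O"] = _place_atom(atoms[i]["N"], atoms[i]["CA"], atoms[i]["C"],
                                    BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
    return atoms


def _segment_table(layout):
    """(state, start, end) 0-based half-open spans for each segment."""
    spans = []
    pos = 0
    for state, n in layout:
        spans.append((state, pos, pos + n))
        pos += n
    return spans


def _coil_dihedrals(n: int, rng) -> np.ndarray:
    """Extended (PPII/beta-like) coil for template linkers: no H-bond runs."""
    phi = rng.uniform(*COIL_PHI_RANGE, size=n)
    psi = rng.uniform(*COIL_PSI_RANGE, size=n)
    return np.column_stack([phi, psi])


# loop basins for flipped (helix -> coil) segments: compact turns included so
# a rebuilt loop can stay within the footprint of the helix it replaces
_LOOP_BASINS = np.array([(-75.0, 150.0), (-120.0, 130.0), (-90.0, 0.0), (70.0, 40.0)])
_LOOP_WEIGHTS = np.array([0.3, 0.2, 0.3, 0.2])


def _loop_dihedrals(n: int, rng) -> np.ndarray:
    basins = _LOOP_BASINS[rng.choice(len(_LOOP_BASINS), size=n, p=_LOOP_WEIGHTS)]
    return basins + rng.normal(0.0, 12.0, size=(n, 2))


def _smooth_noise(L: int, rng, window: int = 5) -> np.ndarray:
    """Chain-correlated unit-variance displacement field, (L, 3)."""
    raw = rng.normal(size=(L + 2 * window, 3))
    kernel = np.exp(-0.5 * (np.arange(-window, window + 1) / (window / 2.0)) ** 2)
    kernel /= kernel.sum()
    sm = np.apply_along_axis(lambda v: np.convolve(v, kernel, mode="same"), 0, raw)
    sm = sm[window:-window]
    std = sm.std()
    return sm / std if std > 0 else sm


def _local_flip(dih: np.ndarray, s: int, e: int, rng, n_candidates: int = 12) -> np.ndarray:
    """Coil dihedrals for a flipped helix segment, chosen among random draws
    to keep the change local: the candidate minimizing the whole-chain
    superposed C-alpha RMSD to the unflipped conformation wins (standing in
    for the tertiary packing that restrains loops in a real protein)."""
    from .superpose import kabsch_superpose

    base_ca = np.array([a["CA"] for a in build_backbone(dih)])
    best = None
    best_cost = np.inf
    for _ in range(n_candidates):
        cand = _loop_dihedrals(e - s, rng)
        trial = dih.copy()
        trial[s:e] = cand
        ca = np.array([a["CA"] for a in build_backbone(trial)])
        _, _, cost = kabsch_superpose(base_ca, ca)
        if cost < best_cost:
            best_cost = cost
            best = cand
    return best


def chain_from_dihedrals(phi_psi, sequence: str | None = None,
                         structure_id: str = "SYNT:A",
                         resolution: float | None = None) -> ChainStructure:
    """Build a ChainStructure directly from an (L, 2) phi/psi array."""
    phi_psi = np.asarray(phi_psi, dtype=float)
    atoms = build_backbone(phi_psi)
    L = len(atoms)
    seq = sequence or "A" * L
    residues = [ResidueRecord("A", i + 1, str(i + 1), seq[i], atoms[i]) for i in range(L)]
    return ChainStructure(structure_id, residues, resolution)


# pleated antiparallel strand: alternating dihedrals keep the two halves of a
# hairpin in H-bond registry along their whole length
_HAIRPIN_STRAND = ((-120.0, 135.0), (-100.0, 125.0))
_HAIRPIN_TURN = ((55.0, 40.0), (90.0, 0.0))


def build_hairpin_chain(n_strand: int = 7, structure_id: str = "HPIN:A") -> ChainStructure:
    """Ideal two-strand antiparallel beta-hairpin (type I'-like turn).

    Odd strand lengths keep cross-strand H-bond registry over the full
    strand; even lengths register only near the turn (the 2-residue turn
    shifts the pleat parity).
    """
    # both strands start on the same pleat phase: that is what keeps the
    # cross-strand H-bond registry along the whole hairpin
    strand = [_HAIRPIN_STRAND[i % 2] for i in range(n_strand)]
    dih = strand + list(_HAIRPIN_TURN) + strand
    return chain_from_dihedrals(np.array(dih), structure_id=structure_id)


def build_helix_chain(n: int = 18, structure_id: str = "HLIX:A") -> ChainStructure:
    """Ideal poly-ALA alpha-helix (phi -57, psi -47)."""
    return chain_from_dihedrals(np.tile(PHI_PSI["H"], (n, 1)), structure_id=structure_id)


def assign_resolution(coil_fraction: float, model: tuple[float, float, float], rng) -> float:
    """Resolution = a + b * coil_fraction + Normal(0, sigma), clipped to
    [0.8, 3.49] Angstrom."""
    if not 0.0 <= coil_fraction <= 1.0:
        raise ValueError("coil_fraction must be in [0, 1]")
    a, b, sigma = model
    r = a + b * coil_fraction + (rng.normal(0.0, sigma) if sigma > 0 else 0.0)
    return float(np.clip(r, 0.8, 3.49))


def mutate_sequence(seq: str, n_subs: int, rng) -> tuple[str, list[int]]:
    """Apply n point substitutions at distinct random sites; returns the new
    sequence and the 1-based substituted positions."""
    sites = rng.choice(len(seq), size=min(n_subs, len(seq)), replace=False)
    out = list(seq)
    for s in sites:
        choices = [a for a in AMINO_ACIDS if a != out[s]]
        out[s] = choices[rng.integers(len(choices))]
    return "".join(out), sorted(int(s) + 1 for s in sites)


def generate_family(config: GeneratorConfig, family_index: int, rng) -> tuple[dict, GroundTruth]:
    """One family: {group_id: [ChainStructure, ...]} plus its ground truth."""
    L = config.total_length()
    if L < 10:
        raise ValueError("segment layout must cover at least 10 residues")
    spans = _segment_table(config.segment_layout)
    fam_letter = chr(ord("A") + family_index)
    family_id = f"FAM{fam_letter}"

    base_seq = "".join(AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), size=L))

    # family template dihedrals: ideal helix/strand plus one fixed coil draw
    template = np.zeros((L, 2))
    for state, s, e in spans:
        if state in PHI_PSI:
            template[s:e] = PHI_PSI[state]
        else:
            template[s:e] = _coil_dihedrals(e - s, rng)

    flip_spans = [spans[i] for i in config.flip_segments]
    hinge_spans = [spans[i] for i in config.hinge_segments]
    for st, _, _ in flip_spans:
        if st != "H":
            raise ValueError("flip segments must be helix segments")
    for st, _, _ in hinge_spans:
        if st != "C":
            raise ValueError("hinge segments must be coil segments")

    groups: dict[str, list[ChainStructure]] = {}
    truth = GroundTruth(family_id, [], {}, {}, {}, {}, {}, {}, {}, {})
    res_model = (config.resolution_intercept, config.resolution_slope,
                 config.resolution_noise)

    flip_cores: list[int] = []  # 0-based residues in flip-segment cores
    for _, s, e in flip_spans:
        flip_cores.extend(range(s + BOUNDARY_MARGIN, e - BOUNDARY_MARGIN))

    for g in range(config.groups_per_family):
        group_id = f"{family_id}-G{g + 1}"
        truth.group_ids.append(group_id)
        if g == 0:
            seq, subs = base_seq, []
        else:
            seq, subs = mutate_sequence(base_seq, config.substitutions_between_groups, rng)
        truth.substitution_counts[group_id] = len(subs)

        # crystals of the same protein often resolve slightly different spans:
        # each group loses 0..max residues from each terminus
        tmax = config.terminal_truncation_max
        lo = int(rng.integers(0, tmax + 1)) if tmax > 0 else 0
        hi = L - (int(rng.integers(0, tmax + 1)) if tmax > 0 else 0)

        # occasional engineered point mutation, biased toward flexible cores
        # (researchers alter functionally important, hence mobile, sites)
        mut_sites_global: set[int] = set()  # 0-based
        mutated_members: dict[int, str] = {}
        if config.mutation_probability > 0 and rng.random() < config.mutation_probability:
            in_window = [p for p in flip_cores if lo <= p < hi]
            if in_window and rng.random() < config.mutation_wobble_bias:
                site = int(in_window[rng.integers(len(in_window))])
            else:
                site = int(rng.integers(lo, hi))
            mseq = list(seq)
            mseq[site] = [a for a in AMINO_ACIDS if a != seq[site]][rng.integers(19)]
            member = int(rng.integers(1, config.structures_per_group))
            mutated_members[member] = "".join(mseq)
            mut_sites_global = {site}
        truth.mutation_sites[group_id] = {p - lo + 1 for p in mut_sites_global}

        members: list[ChainStructure] = []
        flipped_any: dict[tuple[int, int], list[bool]] = {
            (s, e): [] for _, s, e in flip_spans
        }
        for m in range(config.structures_per_group):
            entry = f"{fam_letter}{g + 1}{m:02d}"
            sid = f"{entry}:A"
            dih = template.copy()
            labels = []
            for state, s, e in spans:
                labels.extend(state * (e - s))
            # hinge motion: perturb linker dihedrals; the stated spread is the
            # total angular scale of the hinge, distributed over its dihedrals
            for _, s, e in hinge_spans:
                if config.hinge_spread > 0:
                    per = config.hinge_spread / math.sqrt(2 * (e - s))
                    dih[s:e] += rng.normal(0.0, per, size=(e - s, 2))
            # wobble: whole-segment helix -> coil flips; among candidate coil
            # draws keep the one least displacing the downstream domain, so a
            # local secondary-structure change stays local (tertiary packing
            # is what restrains it in a real protein)
            for _, s, e in flip_spans:
                flip = bool(rng.random() < config.flip_probability)
                flipped_any[(s, e)].append(flip)
                if flip:
                    dih[s:e] = _local_flip(dih, s, e, rng)
                    labels[s:e] = "C" * (e - s)
            atoms = build_backbone(dih)
            # smooth per-state jitter
            sigmas = np.array([config.jitter.get(st, 0.0) for st in labels])
            if np.any(sigmas > 0):
                disp = _smooth_noise(L, rng) * sigmas[:, None]
                for i, d in enumerate(disp):
                    for name in atoms[i]:
                        atoms[i][name] = atoms[i][name] + d
            member_seq = mutated_members.get(m, seq)[lo:hi]
            labels_str = "".join(labels[lo:hi])
            coil_frac = labels_str.count("C") / len(labels_str)
            resolution = assign_resolution(coil_frac, res_model, rng)
            residues = [
                ResidueRecord("A", k + 1, str(k + 1), member_seq[k],
                              {name: v.copy() for name, v in atoms[lo + k].items()})
                for k in range(hi - lo)
            ]
            members.append(ChainStructure(sid, residues, resolution))
            truth.coil_fraction[sid] = coil_frac
            truth.resolution[sid] = resolution
            truth.state_labels[sid] = labels_str

        def to_local(global_positions_0based):
            return {p - lo + 1 for p in global_positions_0based if lo <= p < hi}

        # realized wobble core: flip segments whose members disagree
        wobble: set[int] = set()
        for (s, e), flips in flipped_any.items():
            if 0 < sum(flips) < len(flips):
                wobble |= to_local(range(s + BOUNDARY_MARGIN, e - BOUNDARY_MARGIN))
        rigid: set[int] = set()
        for state, s, e in spans:
            if (state, s, e) in flip_spans or (state, s, e) in hinge_spans:
                continue
            rigid |= to_local(range(s + BOUNDARY_MARGIN, e - BOUNDARY_MARGIN))
        truth.wobble_sites[group_id] = wobble
        truth.rigid_sites[group_id] = rigid
        truth.sequences[group_id] = seq[lo:hi]
        groups[group_id] = members
    return groups, truth


def generate_dataset(config: GeneratorConfig) -> tuple[dict, list[GroundTruth]]:
    """All families under one seeded stream: {family_id: {group_id: members}}."""
    rng = np.random.default_rng(config.seed)
    families: dict[str, dict[str, list[ChainStructure]]] = {}
    truths: list[GroundTruth] = []
    for f in range(config.n_families):
        groups, truth = generate_family(config, f, rng)
        families[truth.family_id] = groups
        truths.append(truth)
    return families, truths


def write_dataset(families: dict, truths: list[GroundTruth], outdir) -> None:
    """Write PDB files, the grouping metadata table and the ground-truth table."""
    from pathlib import Path

    out = Path(outdir)
    pdb_dir = out / "pdb"
    pdb_dir.mkdir(parents=True, exist_ok=True)
    meta_lines = ["structure_id\tgroup_id\tfamily_id\tchain\tfile"]
    for fam_id, groups in families.items():
        for group_id, members in groups.items():
            for cs in members:
                entry = cs.structure_id.split(":")[0]
                fname = f"{entry}.pdb"
                write_pdb_chain(cs, pdb_dir / fname)
                meta_lines.append(
                    f"{cs.structure_id}\t{group_id}\t{fam_id}\tA\tpdb/{fname}"
                )
    (out / "metadata.tsv").write_text("\n".join(meta_lines) + "\n")

    truth_lines = ["family_id\tgroup_id\tkind\tvalue"]
    for t in truths:
        for gid in t.group_ids:
            truth_lines.append(
                f"{t.family_id}\t{gid}\twobble_sites\t"
                + ",".join(map(str, sorted(t.wobble_sites[gid])))
            )
            truth_lines.append(
                f"{t.family_id}\t{gid}\tmutation_sites\t"
                + ",".join(map(str, sorted(t.mutation_sites[gid])))
            )
            truth_lines.append(
                f"{t.family_id}\t{gid}\tsubstitutions\t{t.substitution_counts[gid]}"
            )
    (out / "ground_truth.tsv").write_text("\n".join(truth_lines) + "\n")
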