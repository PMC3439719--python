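"""Structural-group construction.

Chains sharing a (near-)identical sequence form a *structural group*: the
unit of the within-group flexibility and wobble analyses.  This module
clusters sequences at a configurable identity threshold (default 0.99),
applies the dataset selection rules (resolution cutoff, minimum group size,
minimum unique proteins per family), builds the within-group multiple
alignment, and locates mutation sites.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

from . import align
from .io import ChainStructure

DEFAULT_IDENTITY = 0.99
DEFAULT_RESOLUTION_CUTOFF = 3.5  # Angstrom, structures must be strictly below
DEFAULT_MIN_MEMBERS = 4          # groups must have MORE than this many members
DEFAULT_MIN_FAMILY_GROUPS = 3    # families must keep at least this many groups


@dataclass
class StructuralGroup:
    group_id: str
    members: list[ChainStructure]
    msa: list[str] = field(default_factory=list)
    mutation_sites: set[int] = field(default_factory=set)  # 1-based MSA columns
    family_id: str = ""

    def __post_init__(self):
        if self.msa:
            lengths = {len(r) for r in self.msa}
            if len(lengths) > 1:
                raise ValueError("MSA rows have unequal lengths")

    @property
    def member_ids(self) -> list[str]:
        return [m.structure_id for m in self.members]


@dataclass
class SelectionReport:
    kept: list[str]
    dropped: list[tuple[str, str]]  # (group_id, rule violated)
    resolution_cutoff: float = DEFAULT_RESOLUTION_CUTOFF
    min_members: int = DEFAULT_MIN_MEMBERS
    min_family_groups: int = DEFAULT_MIN_FAMILY_GROUPS


def cluster_identity(sequences: list[tuple[str, str]], threshold: float = DEFAULT_IDENTITY
                     ) -> list[list[str]]:
    """Greedy longest-first single-representative clustering by global identity.

    Sequences are sorted longest first (lexicographic id tie-break); each
    joins the first existing cluster whose representative aligns with
    identity >= threshold, else founds a new cluster.  Identity is matches
    over alignment length, gaps included.
    """
    if not sequences:
        raise ValueError("no sequences to cluster")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    for sid, seq in sequences:
        if not seq:
            raise ValueError(f"empty sequence: {sid!r}")
    order = sorted(sequences, key=lambda kv: (-len(kv[1]), kv[0]))
    reps: list[str] = []
    clusters: list[list[str]] = []
    for sid, seq in order:
        for k, rep in enumerate(reps):
            if seq == rep or align.identity(rep, seq) >= threshold:
                clusters[k].append(sid)
                break
        else:
            reps.append(seq)
            clusters.append([sid])
    return clusters


def apply_selection_rules(
    groups: list[StructuralGroup],
    resolution_cutoff: float = DEFAULT_RESOLUTION_CUTOFF,
    min_members: int = DEFAULT_MIN_MEMBERS,
    min_family_groups: int = DEFAULT_MIN_FAMILY_GROUPS,
) -> tuple[list[StructuralGroup], SelectionReport]:
    """Apply the dataset selection rules, in order:

    1. drop structures with unknown resolution or resolution >= cutoff;
    2. drop groups left with <= ``min_members`` structures (strictly more
       than 4 required by default);
    3. drop families left with fewer than ``min_family_groups`` groups.

    Returns the surviving groups (members filtered in place order) and a
    report listing every dropped group with the rule it violated.
    """
    kept: list[StructuralGroup] = []
    dropped: list[tuple[str, str]] = []
    for g in groups:
        members = [m for m in g.members
                   if m.resolution is not None and m.resolution < resolution_cutoff]
        if len(members) <= min_members:
            dropped.append((g.group_id, f"<= {min_members} structures after resolution filter"))
            continue
        kept.append(StructuralGroup(g.group_id, members, family_id=g.family_id))
    fam_counts = Counter(g.family_id for g in kept)
    final = []
    for g in kept:
        if fam_counts[g.family_id] < min_family_groups:
            dropped.append((g.group_id, f"family has < {min_family_groups} groups"))
        else:
            final.append(g)
    report = SelectionReport([g.group_id for g in final], dropped,
                             resolution_cutoff, min_members, min_family_groups)
    return final, report


def build_group_msa(sequences: list[str]) -> list[str]:
    """Progressive reference-anchored multiple alignment.

    The longest sequence (first occurrence on ties) anchors; every other
    member is aligned to it pairwise and the pairwise alignments are merged
    on anchor positions.  Adequate for the near-identical sequences of a
    structural group, where insertions are rare and short.
    """
    if not sequences:
        raise ValueError("no sequences")
    if len(sequences) == 1:
        return [sequences[0]]
    anchor_idx = max(range(len(sequences)), key=lambda i: (len(sequences[i]), -i))
    anchor = sequences[anchor_idx]

    # per member: residue (or gap) at each anchor position, plus insertions
    # keyed by (anchor_pos, offset) where anchor_pos is the preceding column
    per_member: list[dict] = []
    insert_len: dict[int, int] = defaultdict(int)
    for seq in sequences:
        if seq == anchor:
            per_member.append({"at": list(anchor), "ins": {}})
            continue
        row_anchor, row_mem = align.pairwise_align(anchor, seq)
        at = []
        ins: dict[int, list[str]] = defaultdict(list)
        apos = 0  # anchor residues consumed
        for ca, cm in zip(row_anchor, row_mem):
            if ca != align.GAP:
                at.append(cm)
                apos += 1
            else:
                ins[apos].append(cm)  # insertion after anchor residue apos
        per_member.append({"at": at, "ins": dict(ins)})
        for pos, chars in ins.items():
            insert_len[pos] = max(insert_len[pos], len(chars))

    msa = []
    for rec in per_member:
        row = []
        for pos in range(len(anchor) + 1):
            chars = rec["ins"].get(pos, [])
            row.extend(chars)
            row.extend(align.GAP * (insert_len.get(pos, 0) - len(chars)))
            if pos < len(anchor):
                row.append(rec["at"][pos])
        msa.append("".join(row))
    assert len({len(r) for r in msa}) == 1
    return msa


def detect_mutation_sites(msa: list[str]) -> set[int]:
    """1-based MSA columns holding >= 2 distinct non-gap residues.

    Gap-versus-residue columns are not mutations: mutations here are point
    substitutions between otherwise identical sequences.
    """
    if not msa:
        return set()
    sites = set()
    for col in range(len(msa[0])):
        residues = {row[col] for row in msa if row[col] != align.GAP}
        if len(residues) >= 2:
            sites.add(col + 1)
    return sites


def make_group(group_id: str, members: list[ChainStructure], family_id: str = "") -> StructuralGroup:
    """Assemble a StructuralGroup: members, MSA and mutation sites."""
    msa = build_group_msa([m.sequence for m in members])
    return StructuralGroup(group_id, members, msa, detect_mutation_sites(msa), family_id)
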