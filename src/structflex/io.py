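"""Coordinate and secondary-structure file I/O.

Reads single chains out of PDB-format files (via gemmi), classic DSSP output
files, and writes minimal single-chain PDB files.  The in-memory containers
(`ResidueRecord`, `ChainStructure`) carry exactly what the downstream analysis
consumes: one-letter sequence, backbone N/CA/C/O coordinates, X-ray
resolution and ligand/complex flags.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import gemmi
import numpy as np

log = logging.getLogger(__name__)

BACKBONE_ATOMS = ("N", "CA", "C", "O")

# ions and other single-atom heteroatoms commonly deposited with protein entries
_WATER_NAMES = {"HOH", "DOD", "WAT"}


@dataclass
class ResidueRecord:
    """One residue: ordinal position, author numbering, and backbone atoms."""

    chain_id: str
    seq_index: int  # 1-based ordinal over parsed residues
    pdb_number: str  # author residue number + insertion code, as metadata only
    aa: str
    atoms: dict[str, np.ndarray] = field(default_factory=dict)

    def ca(self) -> np.ndarray:
        return self.atoms["CA"]


@dataclass
class ChainStructure:
    """A single protein chain with backbone coordinates and entry metadata."""

    structure_id: str
    residues: list[ResidueRecord]
    resolution: float | None = None
    ligand_flags: dict[str, bool] = field(
        default_factory=lambda: {"has_ligand": False, "has_ion": False, "in_protein_complex": False}
    )

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def ca_coords(self) -> np.ndarray:
        """(L, 3) array of C-alpha coordinates in residue order."""
        return np.array([r.ca() for r in self.residues], dtype=float)


@dataclass(frozen=True)
class SecondaryStructureString:
    """8-state DSSP string and its 3-state (H/E/C) reduction, residue-aligned."""

    states8: str
    states3: str

    def __post_init__(self):
        if len(self.states8) != len(self.states3):
            raise ValueError("states8 and states3 must have equal length")


def _one_letter(resname: str) -> str:
    info = gemmi.find_tabulated_residue(resname)
    if info is not None and info.is_amino_acid():
        code = info.one_letter_code.upper()
        if code.isalpha() and code in "ACDEFGHIKLMNPQRSTVWY":
            return code
    return "X"


def read_pdb_chain(path, chain: str, model: int = 1) -> ChainStructure:
    """Read one chain of a PDB file into a ChainStructure.

    Only the requested model is read (first by default); residues lacking a CA
    atom are skipped with a warning; for alternate locations only the blank or
    'A' altloc is kept; nonstandard amino acids map to 'X'.
    """
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    mdl = st[min(model - 1, len(st) - 1)]
    gchain = mdl.find_chain(chain)
    if gchain is None:
        raise ValueError(f"chain not found: {chain!r} in {path}")

    residues: list[ResidueRecord] = []
    n_protein_chains = 0
    has_ligand = has_ion = False
    for ch in mdl:
        polymer = ch.get_polymer()
        if polymer.check_polymer_type() in (
            gemmi.PolymerType.PeptideL,
            gemmi.PolymerType.PeptideD,
        ):
            n_protein_chains += 1
        for res in ch:
            info = gemmi.find_tabulated_residue(res.name)
            is_aa = info is not None and info.is_amino_acid()
            if not is_aa and res.name not in _WATER_NAMES:
                if len(res) == 1:
                    has_ion = True
                else:
                    has_ligand = True

    idx = 0
    for res in gchain:
        info = gemmi.find_tabulated_residue(res.name)
        if info is None or not info.is_amino_acid():
            continue
        atoms: dict[str, np.ndarray] = {}
        for atom in res:
            if atom.name in BACKBONE_ATOMS and atom.altloc in ("", "\x00", "A"):
                if atom.name not in atoms:
                    atoms[atom.name] = np.array(
                        [atom.pos.x, atom.pos.y, atom.pos.z], dtype=float
                    )
        if "CA" not in atoms:
            log.warning("%s:%s residue %s%s has no CA atom; skipped",
                        path, chain, res.name, res.seqid)
            continue
        idx += 1
        residues.append(
            ResidueRecord(
                chain_id=chain,
                seq_index=idx,
                pdb_number=f"{res.seqid.num}{res.seqid.icode}".strip(),
                aa=_one_letter(res.name),
                atoms=atoms,
            )
        )
    if not residues:
        raise ValueError(f"chain not found (no amino-acid residues with CA): {chain!r}")

    resolution = float(st.resolution) if st.resolution and st.resolution > 0 else None
    entry = st.name.strip() or "XXXX"
    return ChainStructure(
        structure_id=f"{entry}:{chain}",
        residues=residues,
        resolution=resolution,
        ligand_flags={
            "has_ligand": has_ligand,
            "has_ion": has_ion,
            "in_protein_complex": n_protein_chains > 1,
        },
    )


_THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR", "X": "UNK",
}

_ELEMENT = {"N": "N", "CA": "C", "C": "C", "O": "O"}


def write_pdb_chain(cs: ChainStructure, path) -> None:
    """Write a ChainStructure as a minimal single-chain PDB file.

    Emits a REMARK 2 resolution record when resolution is known; coordinates
    are written at the format's 3-decimal precision.
    """
    if len(cs) == 0:
        raise ValueError("cannot write an empty chain")
    lines = []
    entry = cs.structure_id.split(":")[0][:4].upper() or "XXXX"
    lines.append(f"HEADER    PROTEIN                                 01-JAN-00   {entry:<4}")
    if cs.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION.    {cs.resolution:.2f} ANGSTROMS.")
    serial = 1
    chain_id = cs.residues[0].chain_id[:1] or "A"
    for res in cs.residues:
        resname = _THREE_LETTER.get(res.aa, "UNK")
        for name in BACKBONE_ATOMS:
            if name not in res.atoms:
                continue
            x, y, z = res.atoms[name]
            if not all(-999.999 <= v <= 9999.999 for v in (x, y, z)):
                raise ValueError(f"coordinate out of PDB fixed-width range: {(x, y, z)}")
            if not all(math.isfinite(v) for v in (x, y, z)):
                raise ValueError("non-finite coordinate")
            lines.append(
                f"ATOM  {serial:>5} {name:^4} {resname:<3} {chain_id}{res.seq_index:>4}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {_ELEMENT[name]:>2}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_dssp_chain(path, chain: str, expected_length: int | None = None) -> str:
    """Read the 8-state secondary-structure string for one chain from a
    classic-format DSSP file.

    Blank structure columns map to '-'; chain-break rows ('!') are skipped.
    ``expected_length`` (e.g. the residue count of the matching
    ChainStructure) is validated when given.
    """
    states = []
    in_table = False
    found_chain = False
    with open(path) as fh:
        for line in fh:
            if line.startswith("  #  RESIDUE"):
                in_table = True
                continue
            if not in_table or len(line) < 17:
                continue
            aa = line[13]
            if aa == "!":  # chain break
                continue
            if line[11] != chain:
                continue
            found_chain = True
            ss = line[16]
            states.append("-" if ss == " " else ss)
    if not found_chain:
        raise ValueError(f"chain {chain!r} not present in DSSP file {path}")
    s8 = "".join(states)
    if expected_length is not None and len(s8) != expected_length:
        raise ValueError(
            f"DSSP residue count {len(s8)} does not match chain residue count {expected_length}"
        )
    return s8


def write_fasta(records: list[tuple[str, str]], path) -> None:
    """Write (id, sequence) records in FASTA format."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
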