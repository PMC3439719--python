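"""Sequence-alignment primitives shared across modules.

Global Needleman–Wunsch alignment with BLOSUM62 and affine gaps (open -10,
extend -1, free end gaps) via Bio.Align.PairwiseAligner, plus identity and
BLOSUM62 score lookups.  'X' (unknown residue) scores 0 against everything.
"""

from __future__ import annotations

from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

GAP = "-"


@lru_cache(maxsize=1)
def blosum62():
    return substitution_matrices.load("BLOSUM62")


def blosum62_score(a: str, b: str) -> float:
    """BLOSUM62 score for a residue pair; unknown residues score 0."""
    m = blosum62()
    if a not in m.alphabet or b not in m.alphabet or "X" in (a, b):
        return 0.0
    return float(m[a, b])


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.substitution_matrix = blosum62()
    al.open_gap_score = -10.0
    al.extend_gap_score = -1.0
    try:
        al.end_insertion_score = 0.0
        al.end_deletion_score = 0.0
    except AttributeError:  # older biopython naming
        al.target_end_gap_score = 0.0
        al.query_end_gap_score = 0.0
    al.mode = "global"
    return al


def _sanitize(seq: str) -> str:
    alphabet = set(blosum62().alphabet)
    return "".join(c if c in alphabet else "X" for c in seq.upper())


def pairwise_align(seq_a: str, seq_b: str) -> tuple[str, str]:
    """Globally align two sequences; returns the two gapped strings.

    Deterministic: the first optimal alignment under biopython's canonical
    traceback order is taken.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    aln = _aligner().align(_sanitize(seq_a), _sanitize(seq_b))[0]
    a_row, b_row = str(aln[0]), str(aln[1])
    # restore original letters (sanitizing may have rewritten rare codes)
    a_out, b_out = [], []
    ia = ib = 0
    for ca, cb in zip(a_row, b_row):
        if ca != GAP:
            ca = seq_a[ia]
            ia += 1
        if cb != GAP:
            cb = seq_b[ib]
            ib += 1
        a_out.append(ca)
        b_out.append(cb)
    return "".join(a_out), "".join(b_out)


def identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment identity: matches / alignment length (gaps included)."""
    row_a, row_b = pairwise_align(seq_a, seq_b)
    matches = sum(1 for x, y in zip(row_a, row_b) if x == y and x != GAP)
    return matches / len(row_a)


def alignment_pairs(row_a: str, row_b: str) -> list[tuple[int, int]]:
    """(i, j) residue-index pairs (0-based) for the both-residue columns."""
    pairs = []
    ia = ib = 0
    for ca, cb in zip(row_a, row_b):
        if ca != GAP and cb != GAP:
            pairs.append((ia, ib))
        if ca != GAP:
            ia += 1
        if cb != GAP:
            ib += 1
    return pairs
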