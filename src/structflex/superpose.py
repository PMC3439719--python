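"""Rigid-body superposition and structure-based pairwise alignment.

Implements the Kabsch least-squares superposition, the length-normalized
TM-score, and an iterative structure-based aligner (superpose / re-align by
dynamic programming on inter-residue distances) for chains whose sequences
are too diverged for a sequence-level correspondence.  Within a structural
group — the dominant case here, where sequences are (near-)identical — the
correspondence is taken from the sequence alignment and the RMSD is the pure
Kabsch value over the matched C-alpha pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import align
from .io import ChainStructure

D0_MIN = 0.5  # Angstrom floor for the TM-score scale parameter
DEFAULT_GAP_PENALTY = 0.6
MAX_ITERATIONS = 30
MIN_ALIGNED = 10


@dataclass(frozen=True)
class Correspondence:
    """Colinear residue-residue pairing between two chains."""

    pairs: tuple[tuple[int, int], ...]  # 0-based indices, strictly increasing
    aligned_a: str
    aligned_b: str

    def __post_init__(self):
        last = (-1, -1)
        for i, j in self.pairs:
            if i <= last[0] or j <= last[1]:
                raise ValueError("correspondence is not colinear")
            last = (i, j)


@dataclass(frozen=True)
class SuperpositionResult:
    correspondence: Correspondence
    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray  # 3-vector
    rmsd: float
    tm_score: float
    n_aligned: int
    d0: float
    id_a: str = ""
    id_b: str = ""


def kabsch_superpose(A, B) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid transform mapping point set B onto A.

    Returns (rotation R, translation t, rmsd) with det(R) = +1 (reflections
    excluded by sign correction); the transform acts as x -> R @ x + t.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError(f"point sets must both be (n, 3); got {A.shape} and {B.shape}")
    if len(A) < 3:
        raise ValueError("need at least 3 points for a unique rotation")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    H = (B - cb).T @ (A - ca)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca - R @ cb
    diff = A - (B @ R.T + t)
    rmsd = float(np.sqrt((diff**2).sum(axis=1).mean()))
    return R, t, rmsd


def tm_d0(l_norm: int) -> float:
    """TM-score distance scale d0(L) = 1.24 (L-15)^(1/3) - 1.8, floored at 0.5 A."""
    if l_norm <= 15:
        return D0_MIN
    return max(D0_MIN, 1.24 * (l_norm - 15) ** (1.0 / 3.0) - 1.8)


def compute_tm_score(distances, l_norm: int) -> float:
    """TM = (1/L_norm) * sum 1 / (1 + (d_i/d0)^2) over the aligned pairs."""
    if l_norm < 1:
        raise ValueError("l_norm must be >= 1")
    d = np.asarray(distances, dtype=float)
    if np.any(d < 0):
        raise ValueError("negative distance")
    d0 = tm_d0(l_norm)
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / l_norm)


def _norm_length(la: int, lb: int, policy: str) -> int:
    if policy == "shorter":
        return min(la, lb)
    if policy == "average":
        return round((la + lb) / 2)
    raise ValueError(f"unknown TM normalization policy: {policy!r}")


def _corr_from_rows(row_a: str, row_b: str) -> Correspondence:
    return Correspondence(
        pairs=tuple(align.alignment_pairs(row_a, row_b)), aligned_a=row_a, aligned_b=row_b
    )


def _corr_from_pairs(pairs, seq_a: str, seq_b: str) -> Correspondence:
    """Build gapped strings realizing an increasing pair list."""
    ra, rb = [], []
    pa = pb = 0
    for i, j in pairs:
        while pa < i:
            ra.append(seq_a[pa]); rb.append(align.GAP); pa += 1
        while pb < j:
            ra.append(align.GAP); rb.append(seq_b[pb]); pb += 1
        ra.append(seq_a[pa]); rb.append(seq_b[pb]); pa += 1; pb += 1
    while pa < len(seq_a):
        ra.append(seq_a[pa]); rb.append(align.GAP); pa += 1
    while pb < len(seq_b):
        ra.append(align.GAP); rb.append(seq_b[pb]); pb += 1
    return Correspondence(pairs=tuple(pairs), aligned_a="".join(ra), aligned_b="".join(rb))


def _superpose_on_pairs(xa, xb, pairs):
    ia = [p[0] for p in pairs]
    ib = [p[1] for p in pairs]
    return kabsch_superpose(xa[ia], xb[ib])


def distance_dp(dist: np.ndarray, d0: float, gap_penalty: float = DEFAULT_GAP_PENALTY):
    """Global DP alignment maximizing sum of 1/(1+(d_ij/d0)^2) minus linear
    gap penalties (end gaps free); returns the pair list."""
    la, lb = dist.shape
    score = 1.0 / (1.0 + (dist / d0) ** 2)
    F = np.zeros((la + 1, lb + 1))
    ptr = np.zeros((la + 1, lb + 1), dtype=np.int8)  # 0 diag, 1 up(gap in b), 2 left
    # free end gaps: first row/col stay 0, pointers along the border
    ptr[1:, 0] = 1
    ptr[0, 1:] = 2
    gp = np.float64(gap_penalty)
    for i in range(1, la + 1):
        diag = F[i - 1, :-1] + score[i - 1]
        # an up move leaves a gap in chain B: free once past B's last residue
        up = F[i - 1, 1:] - np.where(np.arange(1, lb + 1) < lb, gp, 0.0)
        row = F[i]
        left_pen = gp if i < la else 0.0
        for j in range(1, lb + 1):
            left = row[j - 1] - left_pen
            best = diag[j - 1]
            p = 0
            if up[j - 1] > best:
                best, p = up[j - 1], 1
            if left > best:
                best, p = left, 2
            row[j] = best
            ptr[i, j] = p
    pairs = []
    i, j = la, lb
    while i > 0 or j > 0:
        p = ptr[i, j]
        if p == 0 and i > 0 and j > 0:
            pairs.append((i - 1, j - 1))
            i -= 1; j -= 1
        elif p == 1 and i > 0:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    return pairs


def structural_align(
    a: ChainStructure,
    b: ChainStructure,
    identity_threshold: float = 0.99,
    l_norm_policy: str = "shorter",
    gap_penalty: float = DEFAULT_GAP_PENALTY,
) -> SuperpositionResult:
    """Structure-based alignment of two chains.

    Near-identical sequences (identity >= threshold) take the sequence
    alignment as the correspondence — the within-group case, where the RMSD
    is the pure Kabsch value over the matched residues.  Otherwise the
    correspondence is refined iteratively: superpose on the current pairs,
    re-derive pairs by dynamic programming on the inter-residue distances,
    and keep the iterate with the highest TM-score.
    """
    if len(a) < MIN_ALIGNED or len(b) < MIN_ALIGNED:
        raise ValueError("chains must have at least 10 residues")
    xa, xb = a.ca_coords(), b.ca_coords()
    l_norm = _norm_length(len(a), len(b), l_norm_policy)
    d0 = tm_d0(l_norm)

    row_a, row_b = align.pairwise_align(a.sequence, b.sequence)
    corr = _corr_from_rows(row_a, row_b)
    seq_based = align.identity(a.sequence, b.sequence) >= identity_threshold

    def evaluate(pairs):
        R, t, rmsd = _superpose_on_pairs(xa, xb, pairs)
        d = np.linalg.norm(xa[[p[0] for p in pairs]] - (xb[[p[1] for p in pairs]] @ R.T + t), axis=1)
        tm = compute_tm_score(d, l_norm)
        return R, t, rmsd, tm

    if len(corr.pairs) < 3:
        raise ValueError("alignment failed: fewer than 3 seed pairs")

    if seq_based:
        R, t, rmsd, tm = evaluate(corr.pairs)
        return SuperpositionResult(corr, R, t, rmsd, tm, len(corr.pairs), d0,
                                   a.structure_id, b.structure_id)

    pairs = list(corr.pairs)
    best = None  # (tm, pairs, R, t, rmsd)
    for _ in range(MAX_ITERATIONS):
        R, t, rmsd, tm = evaluate(pairs)
        if best is None or tm > best[0]:
            best = (tm, pairs, R, t, rmsd)
        dist = np.linalg.norm(xa[:, None, :] - (xb @ R.T + t)[None, :, :], axis=2)
        new_pairs = distance_dp(dist, d0, gap_penalty)
        if new_pairs == pairs:
            break
        pairs = new_pairs
    tm, pairs, R, t, rmsd = best
    if len(pairs) < MIN_ALIGNED:
        raise ValueError("alignment failed: fewer than 10 aligned pairs")
    corr = _corr_from_pairs(pairs, a.sequence, b.sequence)
    return SuperpositionResult(corr, R, t, rmsd, tm, len(pairs), d0,
                               a.structure_id, b.structure_id)
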