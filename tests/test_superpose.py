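import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from structflex import superpose
from structflex.synthetic import (
    GeneratorConfig,
    PHI_PSI,
    build_helix_chain,
    chain_from_dihedrals,
    generate_dataset,
)


def _random_rotation(rng):
    return Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()


def brute_force_rmsd(A, B, n_starts=40):
    """Independent oracle: minimize RMSD over rotations by multi-start local
    optimization on rotation vectors (translation handled by centering)."""
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)

    def cost(rotvec):
        R = Rotation.from_rotvec(rotvec).as_matrix()
        return np.sqrt(((Ac - Bc @ R.T) ** 2).sum(axis=1).mean())

    rng = np.random.default_rng(0)
    best = np.inf
    starts = [np.zeros(3)] + list(rng.uniform(-np.pi, np.pi, size=(n_starts, 3)))
    for x0 in starts:
        res = minimize(cost, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
        best = min(best, res.fun)
    return best


class TestKabsch:
    def test_rigid_motion_gives_zero_rmsd(self, rng):
        A = rng.normal(size=(20, 3))
        R = _random_rotation(rng)
        B = A @ R.T + np.array([1.0, -2.0, 3.0])
        _, _, rmsd = superpose.kabsch_superpose(A, B)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rotation_is_proper(self, rng):
        A = rng.normal(size=(10, 3))
        B = rng.normal(size=(10, 3))
        R, _, _ = superpose.kabsch_superpose(A, B)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(R @ R.T, np.eye(3), atol=1e-9)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            superpose.kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))
        with pytest.raises(ValueError):
            superpose.kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(12):
            n = int(rng.integers(4, 9))
            A = rng.normal(size=(n, 3))
            B = A + rng.normal(scale=0.4, size=(n, 3))
            _, _, ours = superpose.kabsch_superpose(A, B)
            oracle = brute_force_rmsd(A, B)
            assert ours <= oracle + 1e-9  # Kabsch is the optimum
            assert abs(ours - oracle) < 1e-3

    def test_single_displaced_point_vs_oracle(self):
        A = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]])
        B = A.copy()
        B[2] += [0.0, 0.0, 1.0]
        _, _, ours = superpose.kabsch_superpose(A, B)
        assert abs(ours - brute_force_rmsd(A, B)) < 1e-3


class TestTmScore:
    def test_perfect_match(self):
        assert superpose.compute_tm_score(np.zeros(40), 40) == pytest.approx(1.0)

    def test_d0_arithmetic(self):
        assert round(superpose.tm_d0(35), 3) == 1.566

    def test_all_pairs_at_d0_give_half(self):
        d0 = superpose.tm_d0(35)
        assert superpose.compute_tm_score([d0] * 35, 35) == pytest.approx(0.5)

    def test_d0_floor(self):
        assert superpose.tm_d0(10) == 0.5
        assert superpose.tm_d0(21) == 0.5

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            superpose.compute_tm_score([-1.0], 10)


class TestStructuralAlign:
    def test_identical_chains(self):
        cs = build_helix_chain(30)
        r = superpose.structural_align(cs, cs)
        assert r.rmsd == pytest.approx(0.0, abs=1e-9)
        assert r.tm_score == pytest.approx(1.0, abs=1e-9)
        assert r.n_aligned == 30
        assert [p for p in r.correspondence.pairs] == [(i, i) for i in range(30)]

    def test_identical_sequence_uses_full_kabsch(self, default_dataset):
        """Within a group the RMSD is the plain Kabsch value over all CAs."""
        families, truths = default_dataset
        g = families[truths[0].family_id][truths[0].group_ids[0]]
        a, b = g[0], g[1]
        r = superpose.structural_align(a, b)
        _, _, direct = superpose.kabsch_superpose(a.ca_coords(), b.ca_coords())
        assert r.rmsd == pytest.approx(direct, abs=1e-9)
        assert r.n_aligned == len(a)

    def test_rigid_motion_invariance(self, rng):
        cs = build_helix_chain(40)
        moved = chain_from_dihedrals(np.tile(PHI_PSI["H"], (40, 1)))
        R = _random_rotation(rng)
        t = np.array([5.0, -3.0, 2.0])
        for res in moved.residues:
            for k in res.atoms:
                res.atoms[k] = R @ res.atoms[k] + t
        r0 = superpose.structural_align(cs, cs)
        r1 = superpose.structural_align(cs, moved)
        assert r1.rmsd == pytest.approx(r0.rmsd, abs=1e-6)
        assert r1.tm_score == pytest.approx(r0.tm_score, abs=1e-6)

    def test_symmetry(self, default_dataset):
        families, truths = default_dataset
        fam = families[truths[0].family_id]
        a = fam[truths[0].group_ids[0]][0]
        b = fam[truths[0].group_ids[1]][0]
        rab = superpose.structural_align(a, b)
        rba = superpose.structural_align(b, a)
        assert rab.rmsd == pytest.approx(rba.rmsd, abs=1e-6)
        assert rab.tm_score == pytest.approx(rba.tm_score, abs=1e-6)

    def test_insertion_recovered(self, rng):
        """A 3-residue insertion: the aligner recovers >= 95% of the true pairing."""
        from copy import deepcopy

        from structflex.io import ChainStructure, ResidueRecord

        dih = np.vstack([
            np.tile(PHI_PSI["H"], (25, 1)),
            [[-90.0, 0.0], [-75.0, 150.0], [-90.0, 10.0], [-80.0, 140.0]],
            np.tile(PHI_PSI["H"], (31, 1)),
        ])
        seq_a = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), len(dih)))
        a = chain_from_dihedrals(dih, sequence=seq_a, structure_id="SA:A")
        # splice a 3-residue bulge in Cartesian space so the flanks of the
        # two chains are exactly congruent (the known true pairing)
        anchor = a.residues[28].atoms["CA"]
        bulge = []
        for k in range(3):
            off = np.array([2.0 + 2.5 * k, 6.0, 3.0 + (k % 2)])
            atoms = {name: anchor + off + d for name, d in
                     (("N", np.array([0.0, 0.6, 0.0])), ("CA", np.zeros(3)),
                      ("C", np.array([1.2, 0.0, 0.4])), ("O", np.array([1.4, 1.1, 0.5])))}
            bulge.append(ResidueRecord("A", 0, "0", "GSG"[k], atoms))
        residues = deepcopy(a.residues[:29]) + bulge + deepcopy(a.residues[29:])
        for i, res in enumerate(residues):
            res.seq_index = i + 1
        b = ChainStructure("SB:A", residues)
        r = superpose.structural_align(a, b, identity_threshold=1.01)
        true_pairs = {(i, i) for i in range(29)} | {(i, i + 3) for i in range(29, len(dih))}
        recovered = len(set(r.correspondence.pairs) & true_pairs)
        assert recovered / len(dih) >= 0.95

    def test_colinear_correspondence(self, default_dataset):
        families, truths = default_dataset
        fam = families[truths[0].family_id]
        a = fam[truths[0].group_ids[0]][0]
        b = fam[truths[0].group_ids[1]][1]
        r = superpose.structural_align(a, b)
        pairs = r.correspondence.pairs
        assert all(p1[0] < p2[0] and p1[1] < p2[1] for p1, p2 in zip(pairs, pairs[1:]))

    def test_short_chain_rejected(self):
        cs = build_helix_chain(8)
        with pytest.raises(ValueError):
            superpose.structural_align(cs, cs)


def enumerate_matchings(dist, d0, gap_penalty):
    """Exhaustive oracle for the distance DP on tiny chains: best score over
    all colinear matchings, internal gaps penalized per skipped residue,
    terminal gaps free."""
    la, lb = dist.shape
    score = 1.0 / (1.0 + (dist / d0) ** 2)
    best = 0.0  # empty matching

    def recurse(i, j, acc, started):
        nonlocal best
        # option: stop here (remaining residues are terminal gaps, free)
        best = max(best, acc)
        for ii in range(i, la):
            for jj in range(j, lb):
                gap = 0.0
                if started:
                    gap = gap_penalty * ((ii - i) + (jj - j))
                recurse(ii + 1, jj + 1, acc + score[ii, jj] - gap, True)

    recurse(0, 0, 0.0, False)
    return best


class TestDistanceDP:
    def test_matches_exhaustive_enumeration(self, rng):
        d0 = 2.0
        for _ in range(5):
            la, lb = int(rng.integers(4, 7)), int(rng.integers(4, 7))
            dist = rng.uniform(0.2, 8.0, size=(la, lb))
            pairs = superpose.distance_dp(dist, d0, 0.6)
            score = 1.0 / (1.0 + (dist / d0) ** 2)
            dp_score = sum(score[i, j] for i, j in pairs)
            for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
                dp_score -= 0.6 * ((i2 - i1 - 1) + (j2 - j1 - 1))
            oracle = enumerate_matchings(dist, d0, 0.6)
            assert dp_score == pytest.approx(oracle, abs=1e-9)
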