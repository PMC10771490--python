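import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from septkit.structure_io import Atom, Chain, Residue, Structure
from septkit.superpose import (
    InsufficientPairsError,
    assemble_by_grafting,
    kabsch_superpose,
    pair_residues,
    per_residue_rmsd,
    superpose_chains,
)
from septkit.synthetic_data import make_ideal_helix, make_transformed_pair


def ca_coords(structure, chain_idx=0):
    return np.array([r.ca.position for r in structure.chains[chain_idx].residues])


def chain_from_seq(seq, chain_id="A", numbers=None, spread=3.8):
    """A CA-only chain with the given one-letter sequence along a line."""
    one_to_three = {"A": "ALA", "G": "GLY", "C": "CYS", "V": "VAL", "L": "LEU",
                    "F": "PHE", "K": "LYS", "D": "ASP", "S": "SER", "T": "THR"}
    numbers = numbers or range(1, len(seq) + 1)
    residues = [
        Residue(number=n, name=one_to_three[c], atoms=[
            Atom(name="CA", element="C", position=np.array([spread * i, 0.0, 0.0]))])
        for i, (n, c) in enumerate(zip(numbers, seq))
    ]
    return Chain(chain_id=chain_id, residues=residues)


class TestKabsch:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(20, 3))
        res = kabsch_superpose(pts, pts)
        assert res.rmsd_ca == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(res.translation, np.zeros(3), atol=1e-12)

    def test_recovers_inverse_of_applied_transform(self):
        rng = np.random.default_rng(1)
        fixed = rng.normal(scale=10, size=(50, 3))
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        t = np.array([1.0, 2.0, 3.0])
        moving = fixed @ rot.T + t
        res = kabsch_superpose(fixed, moving)
        assert res.rmsd_ca == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(res.apply(moving), fixed, atol=1e-6)
        # recovered transform is the inverse of the applied one
        np.testing.assert_allclose(res.rotation, rot.T, atol=1e-8)

    def test_proper_rotations_on_random_point_sets(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            a = rng.normal(size=(6, 3))
            b = rng.normal(size=(6, 3))
            res = kabsch_superpose(a, b)
            assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-8)
            np.testing.assert_allclose(res.rotation @ res.rotation.T, np.eye(3),
                                       atol=1e-8)

    def test_reflection_forbidden_for_mirrored_input(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(30, 3))
        b = a * np.array([1.0, 1.0, -1.0])  # mirror image
        res = kabsch_superpose(a, b)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-8)
        assert res.rmsd_ca > 0.1  # a mirror cannot be superposed by rotation

    def test_optimality_against_random_rigid_transforms(self):
        rng = np.random.default_rng(4)
        fixed = rng.normal(scale=5, size=(40, 3))
        moving = fixed + rng.normal(scale=1.0, size=(40, 3))
        best = kabsch_superpose(fixed, moving).rmsd_ca
        for _ in range(100):
            rot = Rotation.random(rng=rng).as_matrix()
            t = rng.normal(scale=2, size=3)
            rmsd = np.sqrt(np.mean(np.sum(
                (moving @ rot.T + t - fixed) ** 2, axis=1)))
            assert best <= rmsd + 1e-9

    def test_matches_scipy_align_vectors(self):
        """Independent cross-check: scipy's Kabsch on centred point sets."""
        rng = np.random.default_rng(5)
        for _ in range(50):
            fixed = rng.normal(scale=4, size=(25, 3))
            moving = fixed + rng.normal(scale=0.5, size=(25, 3))
            res = kabsch_superpose(fixed, moving)
            rot, rssd = Rotation.align_vectors(fixed - fixed.mean(0),
                                               moving - moving.mean(0))
            np.testing.assert_allclose(res.rotation, rot.as_matrix(), atol=1e-6)
            assert res.rmsd_ca == pytest.approx(rssd / np.sqrt(25), abs=1e-8)

    def test_degenerate_collinear_warns(self):
        pts = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.warns(UserWarning, match="collinear"):
            res = kabsch_superpose(pts, pts + 1.0)
        assert res.rmsd_ca == pytest.approx(0.0, abs=1e-9)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))

    def test_noise_response(self):
        """Gaussian CA noise of sd sigma recovers RMSD near sigma*sqrt(3)."""
        rng = np.random.default_rng(11)
        sigma = 0.5
        fixed = rng.normal(scale=15, size=(200, 3))
        moving = fixed + rng.normal(scale=sigma, size=(200, 3))
        rmsd = kabsch_superpose(fixed, moving).rmsd_ca
        assert 0.8 * sigma * np.sqrt(3) <= rmsd <= 1.2 * sigma * np.sqrt(3)


def brute_force_alignment_score(a, b, match=1.0, mismatch=0.0, gap=-1.0):
    """Independent Needleman-Wunsch score for tiny sequences."""
    n, m = len(a), len(b)
    dp = np.zeros((n + 1, m + 1))
    dp[:, 0] = gap * np.arange(n + 1)
    dp[0, :] = gap * np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = match if a[i - 1] == b[j - 1] else mismatch
            dp[i, j] = max(dp[i - 1, j - 1] + sub, dp[i - 1, j] + gap,
                           dp[i, j - 1] + gap)
    return dp[n, m]


class TestPairResidues:
    def test_identical_chains_by_number(self):
        a = chain_from_seq("AGCVLFKDST")
        b = chain_from_seq("AGCVLFKDST", chain_id="B")
        pairing = pair_residues(a, b, method="by_number")
        assert pairing.pairs == [(i, i) for i in range(1, 11)]
        assert pairing.alignment_identity == 1.0

    def test_internal_deletion_by_alignment(self):
        full = "AGCVLFKDST"
        a = chain_from_seq(full)
        b = chain_from_seq(full[:4] + full[5:], chain_id="B")  # L at index 5 deleted
        pairing = pair_residues(a, b, method="by_alignment")
        assert (5, 5) not in pairing.pairs  # deleted position unpaired
        assert pairing.pairs == [(1, 1), (2, 2), (3, 3), (4, 4),
                                 (6, 5), (7, 6), (8, 7), (9, 8), (10, 9)]

    @pytest.mark.parametrize("seed", range(5))
    def test_alignment_score_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        letters = "AGCVLFKDST"
        sa = "".join(rng.choice(list(letters), size=rng.integers(5, 15)))
        sb = "".join(rng.choice(list(letters), size=rng.integers(5, 15)))
        from Bio import Align
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1.0
        aligner.mismatch_score = 0.0
        aligner.open_gap_score = -1.0
        aligner.extend_gap_score = -1.0
        assert aligner.score(sa, sb) == pytest.approx(
            brute_force_alignment_score(sa, sb))

    def test_insufficient_pairs(self):
        a = chain_from_seq("AG")
        b = chain_from_seq("AG", chain_id="B")
        with pytest.raises(InsufficientPairsError):
            pair_residues(a, b, method="by_number")


class TestPerResidueRmsd:
    def test_identical_chains_all_zero(self, helix30):
        chain = helix30.chains[0]
        pairing, result = superpose_chains(chain, chain, method="by_number")
        profile = per_residue_rmsd(pairing, chain, chain, result)
        assert np.all(profile.deviations < 1e-9)

    def test_single_displaced_residue_is_profile_maximum(self):
        fixed = make_ideal_helix(50).chains[0]
        moving_struct = make_ideal_helix(50)
        moving = moving_struct.chains[0]
        moving.residues[29].atom("CA").position += np.array([0.0, 0.0, 5.0])
        pairing, result = superpose_chains(fixed, moving, method="by_number")
        profile = per_residue_rmsd(pairing, fixed, moving, result)
        dev = profile.deviations
        assert profile.per_residue[int(np.argmax(dev))][0] == 30
        assert dev.max() > 3.0  # most of the 5 A displacement survives fitting

    def test_rms_of_profile_reproduces_global_rmsd(self):
        base = make_ideal_helix(40)
        _, moved, _ = make_transformed_pair(base, (10, 20, 30), (1, -2, 3),
                                            noise_sd=0.4, seed=2)
        fixed, moving = base.chains[0], moved.chains[0]
        pairing, result = superpose_chains(fixed, moving, method="by_number")
        profile = per_residue_rmsd(pairing, fixed, moving, result)
        assert profile.rms() == pytest.approx(result.rmsd_ca, rel=1e-9)

    def test_pairing_transform_mismatch(self, helix30):
        chain = helix30.chains[0]
        pairing, result = superpose_chains(chain, chain, method="by_number")
        short = pair_residues(
            Chain("A", chain.residues[:10]), Chain("B", chain.residues[:10]),
            method="by_number")
        with pytest.raises(ValueError):
            per_residue_rmsd(short, chain, chain, result)


def two_chain_structure(chain_a, chain_b, identifier="pair"):
    return Structure(identifier=identifier, chains=[chain_a, chain_b])


def copy_chain_as(chain, new_id):
    return Chain(chain_id=new_id, residues=[
        Residue(number=r.number, name=r.name, atoms=[
            Atom(name=a.name, element=a.element, position=a.position.copy())
            for a in r.atoms])
        for r in chain.residues
    ])


class TestGrafting:
    def test_untransformed_copy_grafts_with_zero_rmsd(self, helix30):
        a = copy_chain_as(helix30.chains[0], "A")
        b = copy_chain_as(helix30.chains[0], "B")
        for res in b.residues:
            for atom in res.atoms:
                atom.position = atom.position + np.array([20.0, 0.0, 0.0])
        base = two_chain_structure(a, b, "base")
        addon = two_chain_structure(copy_chain_as(b, "B"),
                                    copy_chain_as(a, "C"), "addon")
        result = assemble_by_grafting(base, addon, "B", "B")
        assert result.graft_rmsd_ca == pytest.approx(0.0, abs=1e-9)
        assert len(result.structure.chains) == 3  # base 2 + addon 2 - shared 1

    def test_addon_chain_lands_at_hand_computed_position(self, helix30):
        """A-B plus B'-C where B' is a rigidly moved B: C must land at the
        position given by applying the inverse transform by hand."""
        a = copy_chain_as(helix30.chains[0], "A")
        b = copy_chain_as(helix30.chains[0], "B")
        for res in b.residues:
            for atom in res.atoms:
                atom.position = atom.position + np.array([15.0, 0.0, 0.0])
        base = two_chain_structure(a, b, "base")

        rot = Rotation.from_euler("xyz", (25, -40, 110), degrees=True).as_matrix()
        t = np.array([-3.0, 7.0, 1.5])
        b_moved = copy_chain_as(b, "B")
        c = copy_chain_as(helix30.chains[0], "C")
        for chain in (b_moved, c):
            for res in chain.residues:
                for atom in res.atoms:
                    atom.position = rot @ atom.position + t
        addon = two_chain_structure(b_moved, c, "addon")

        result = assemble_by_grafting(base, addon, "B", "B")
        assert result.graft_rmsd_ca == pytest.approx(0.0, abs=1e-6)
        new_id = result.chain_id_map["C"]
        got = np.array([r.ca.position
                        for r in result.structure.chain(new_id).residues])
        # hand-computed: the graft must undo (rot, t) exactly
        expected = np.array([
            rot.T @ (r.ca.position - t)
            for r in addon.chain("C").residues
        ])
        np.testing.assert_allclose(got, expected, atol=1e-6)

    def test_refuses_unrelated_proteins(self, helix30):
        a = copy_chain_as(helix30.chains[0], "A")
        b = copy_chain_as(helix30.chains[0], "B")
        for res in b.residues:
            res.name = "GLY"  # different protein: zero sequence identity
        base = two_chain_structure(a, copy_chain_as(a, "B"), "base")
        addon = two_chain_structure(b, copy_chain_as(a, "C"), "addon")
        with pytest.raises(ValueError, match="identical"):
            assemble_by_grafting(base, addon, "A", "B")

    def test_palindromic_octamer_from_tetramer_and_dimer(self, helix30):
        """Stand-in for rod assembly: tetramer W-X-Y-Z plus Z-Z' dimer plus a
        second tetramer copy yields an 8-chain palindrome-ordered model."""
        template = helix30.chains[0]
        offsets = {cid: np.array([12.0 * i, 0.0, 0.0])
                   for i, cid in enumerate("WXYZ")}
        chains = []
        for cid, off in offsets.items():
            chain = copy_chain_as(template, cid)
            for res in chain.residues:
                for atom in res.atoms:
                    atom.position = atom.position + off
            chains.append(chain)
        tetramer = Structure(identifier="tetramer", chains=chains)

        # central homodimer: two copies of Z related by a 180-degree flip
        z = copy_chain_as(tetramer.chain("Z"), "P")
        z2 = copy_chain_as(tetramer.chain("Z"), "Q")
        flip = Rotation.from_euler("y", 180, degrees=True).as_matrix()
        pivot = np.array([48.0, 0.0, 0.0])
        for res in z2.residues:
            for atom in res.atoms:
                atom.position = flip @ (atom.position - pivot) + pivot + \
                    np.array([12.0, 0.0, 0.0])
        dimer = Structure(identifier="dimer", chains=[z, z2])

        step1 = assemble_by_grafting(tetramer, dimer, "Z", "P")
        assert len(step1.structure.chains) == 5
        second_z = step1.chain_id_map["Q"]
        step2 = assemble_by_grafting(step1.structure, tetramer, second_z, "Z")
        assert len(step2.structure.chains) == 8
        assert step1.graft_rmsd_ca == pytest.approx(0.0, abs=1e-6)
        assert step2.graft_rmsd_ca == pytest.approx(0.0, abs=1e-6)
        # mirrored tetramer: subunit order runs W-X-Y-Z | Z-Y-X-W by centroid
        def centroid_x(cid):
            return np.mean([r.ca.position[0]
                            for r in step2.structure.chain(cid).residues])
        merged_ids = step2.structure.chain_ids()
        ordered = sorted(merged_ids, key=centroid_x)
        assert ordered[0] == "W" and ordered[3] in ("Z", second_z)
        assert len(ordered) == 8
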