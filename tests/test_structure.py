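"""Structure I/O, interface geometry, mapping, transfer, superposition."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

import fdrscope as f
from fdrscope.errors import DegenerateGeometryError, DomainError
from fdrscope.msa import msa_from_strings
from fdrscope.structure import Atom, Residue, Structure


def _two_residue_pdb(tmp_path):
    p = tmp_path / "toy.pdb"
    p.write_text(
        "ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C\n"
        "ATOM      2  CA  GLY A   2       4.000   5.000   6.000  1.00  0.00           C\n"
        "HETATM    3  O   HOH A 101       9.000   9.000   9.000  1.00  0.00           O\n"
        "END\n"
    )
    return p


class TestReadWrite:
    def test_two_residue_file(self, tmp_path):
        s = f.read_structure(_two_residue_pdb(tmp_path))
        res = s.chain("A")
        assert [r.name for r in res] == ["ALA", "GLY"]  # HETATM skipped
        assert np.allclose(res[0].ca.coord, [1.0, 2.0, 3.0])

    def test_altloc_highest_occupancy(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.30  0.00           C\n"
            "ATOM      2  CA BALA A   1       9.000   9.000   9.000  0.70  0.00           C\n"
            "END\n"
        )
        s = f.read_structure(p)
        assert np.allclose(s.chain("A")[0].ca.coord, [9.0, 9.0, 9.0])

    def test_synthetic_roundtrip(self, tmp_path, planted_complex):
        s, _ = planted_complex
        path = tmp_path / "complex.pdb"
        f.write_structure(s, path)
        again = f.read_structure(path)
        for cid in ("A", "B"):
            assert np.allclose(again.ca_coords(cid), s.ca_coords(cid), atol=1e-3)
            assert [r.label for r in again.chain(cid)] == [r.label for r in s.chain(cid)]


class TestInterfaceResidues:
    def _pair(self, coords_a, coords_b):
        def mk(coords):
            return [
                Residue(number=i + 1, atoms=[Atom("CA", np.array(c, float))])
                for i, c in enumerate(coords)
            ]

        return Structure({"A": mk(coords_a), "B": mk(coords_b)})

    def test_far_apart_empty(self):
        s = self._pair([[0, 0, 0]] * 1 + [[1, 0, 0]] * 1, [[100, 0, 0], [103.8, 0, 0], [107.6, 0, 0]])
        assert f.interface_residues(s, "A", "B", cutoff=5.0).members == []

    def test_boundary_inclusive(self):
        s = self._pair([[0, 0, 0], [50, 0, 0], [53.8, 0, 0]], [[4.9, 0, 0], [100, 0, 0], [103.8, 0, 0]])
        iface = f.interface_residues(s, "A", "B", cutoff=5.0)
        assert iface.members == ["1"]

    def test_matches_brute_force(self, planted_complex):
        s, _ = planted_complex
        iface = f.interface_residues(s, "A", "B", cutoff=8.0)
        A, B = s.ca_coords("A"), s.ca_coords("B")
        want = [str(i + 1) for i in range(len(A)) if cdist(A[i:i + 1], B).min() <= 8.0]
        assert iface.members == want

    def test_contact_pairs_symmetric(self, planted_complex):
        s, _ = planted_complex
        A, B = s.ca_coords("A"), s.ca_coords("B")
        d = cdist(A, B)
        pairs_ab = {(i, j) for i, j in zip(*np.where(d <= 8.0))}
        pairs_ba = {(i, j) for j, i in zip(*np.where(d.T <= 8.0))}
        assert pairs_ab == pairs_ba

    def test_missing_chain(self, planted_complex):
        s, _ = planted_complex
        with pytest.raises(KeyError):
            f.interface_residues(s, "A", "Z")


class TestSeqStructureMap:
    def _structure_from_seq(self, seq, numbers=None):
        from Bio.SeqUtils import seq3

        numbers = numbers or range(1, len(seq) + 1)
        res = [
            Residue(number=num, name=seq3(ch).upper(),
                    atoms=[Atom("CA", np.array([i * 3.8, 0, 0]))])
            for i, (ch, num) in enumerate(zip(seq, numbers))
        ]
        return Structure({"A": res})

    def test_identity_map(self):
        s = self._structure_from_seq("ACDEFGHIKL")
        m = f.map_seq_to_structure("ACDEFGHIKL", s, "A")
        assert m.coverage == 1.0 and not m.low_identity
        assert m.pairs == [(i + 1, str(i + 1)) for i in range(10)]

    def test_missing_interior_residues_skipped(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        # structure lacks 5 interior residues (positions 8-12)
        observed = seq[:7] + seq[12:]
        numbers = list(range(1, 8)) + list(range(13, 21))
        s = self._structure_from_seq(observed, numbers)
        m = f.map_seq_to_structure(seq, s, "A")
        mapped_positions = {p for p, _ in m.pairs}
        assert mapped_positions == set(range(1, 8)) | set(range(13, 21))
        assert m.to_structure(8) is None
        assert m.to_structure(13) == "13"

    def test_unrelated_sequence_flagged(self):
        s = self._structure_from_seq("AAAAAAAAAAAAAAAAAAAA")
        m = f.map_seq_to_structure("WYWYWYWYWYWYWYWYWYWY", s, "A")
        assert m.low_identity

    def test_monotone_pairs(self, planted_complex):
        s, _ = planted_complex
        m = f.map_seq_to_structure("A" * 60, s, "A")
        pos = [p for p, _ in m.pairs]
        nums = [int(lab) for _, lab in m.pairs]
        assert pos == sorted(pos) and nums == sorted(nums)


class TestTransferResidues:
    MSA = msa_from_strings({
        "src": "AC-DEF",
        "dst": "GW-H-K",
        "oth": "MMMMMM",
    })

    def test_identity_transfer(self):
        out = f.transfer_residues(self.MSA, "src", "src", [1, 2, 5])
        assert out == [(1, "A"), (2, "C"), (5, "F")]

    def test_gap_in_destination(self):
        # src position 3 = column 4 ('D'); dst has 'H' there; src 4 ('E') hits dst gap
        out = f.transfer_residues(self.MSA, "src", "dst", [3, 4])
        assert out == [(3, "H"), (None, None)]

    def test_hand_worked_lookup(self):
        out = f.transfer_residues(self.MSA, "dst", "oth", [1, 2, 3, 4])
        assert out == [(1, "M"), (2, "M"), (4, "M"), (6, "M")]

    def test_out_of_range(self):
        with pytest.raises(DomainError):
            f.transfer_residues(self.MSA, "src", "dst", [6])


class TestSuperpose:
    POINTS = np.array(
        [[0.0, 0, 0], [3.8, 0, 0], [3.8, 2.1, 0], [1.0, 2.0, 3.0]]
    )

    @staticmethod
    def _random_rigid(seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(3, 3))
        Q, _ = np.linalg.qr(A)
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        t = rng.normal(scale=10, size=3)
        return Q, t

    def test_identical_sets_zero_rmsd(self):
        res = f.superpose(self.POINTS, self.POINTS)
        assert res.rmsd <= 1e-9
        assert np.allclose(res.rotation, np.eye(3), atol=1e-9)

    def test_rigid_motion_recovered(self):
        Q, t = self._random_rigid(3)
        moved = self.POINTS @ Q.T + t
        res = f.superpose(self.POINTS, moved)
        assert res.rmsd <= 1e-9
        assert np.allclose(res.rotation, Q, atol=1e-8)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0)

    def test_rmsd_invariant_to_mobile_pretransform(self):
        rng = np.random.default_rng(0)
        target = self.POINTS + rng.normal(scale=0.3, size=self.POINTS.shape)
        base = f.superpose(self.POINTS, target).rmsd
        Q, t = self._random_rigid(11)
        again = f.superpose(self.POINTS @ Q.T + t, target).rmsd
        assert again == pytest.approx(base, abs=1e-9)

    def test_matches_quaternion_oracle(self):
        """Kabsch result equals an independent quaternion (Horn) solution."""
        rng = np.random.default_rng(8)
        target = self.POINTS + rng.normal(scale=0.4, size=self.POINTS.shape)
        res = f.superpose(self.POINTS, target)

        # Horn's closed-form quaternion method, implemented independently
        P = self.POINTS - self.POINTS.mean(axis=0)
        Q = target - target.mean(axis=0)
        Sxx = P.T @ Q
        K = np.empty((4, 4))
        K[0, 0] = Sxx[0, 0] + Sxx[1, 1] + Sxx[2, 2]
        K[0, 1] = K[1, 0] = Sxx[1, 2] - Sxx[2, 1]
        K[0, 2] = K[2, 0] = Sxx[2, 0] - Sxx[0, 2]
        K[0, 3] = K[3, 0] = Sxx[0, 1] - Sxx[1, 0]
        K[1, 1] = Sxx[0, 0] - Sxx[1, 1] - Sxx[2, 2]
        K[1, 2] = K[2, 1] = Sxx[0, 1] + Sxx[1, 0]
        K[1, 3] = K[3, 1] = Sxx[0, 2] + Sxx[2, 0]
        K[2, 2] = -Sxx[0, 0] + Sxx[1, 1] - Sxx[2, 2]
        K[2, 3] = K[3, 2] = Sxx[1, 2] + Sxx[2, 1]
        K[3, 3] = -Sxx[0, 0] - Sxx[1, 1] + Sxx[2, 2]
        w, v = np.linalg.eigh(K)
        q = v[:, np.argmax(w)]
        a, b, c, d = q
        R_oracle = np.array([
            [a*a + b*b - c*c - d*d, 2*(b*c - a*d), 2*(b*d + a*c)],
            [2*(b*c + a*d), a*a - b*b + c*c - d*d, 2*(c*d - a*b)],
            [2*(b*d - a*c), 2*(c*d + a*b), a*a - b*b - c*c + d*d],
        ])
        rmsd_oracle = float(np.sqrt(((P @ R_oracle.T - Q) ** 2).sum(axis=1).mean()))
        assert res.rmsd == pytest.approx(rmsd_oracle, rel=1e-9)
        assert np.allclose(res.rotation, R_oracle, atol=1e-8)

    def test_too_few_points(self):
        with pytest.raises(DegenerateGeometryError):
            f.superpose(self.POINTS[:2], self.POINTS[:2])

    def test_collinear_points(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            f.superpose(line, line)
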