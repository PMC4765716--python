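"""Geometric kernel: PDB I/O, superposition, TM-score, alignment, contacts."""

import numpy as np
import pytest

from foldfunc.structure import (
    DegenerateGeometryError,
    PDBParseError,
    Structure,
    contact_pairs,
    geometry_stats,
    kabsch_superpose,
    radius_of_gyration,
    random_rotation,
    read_structure,
    structural_align,
    tm_d0,
    tm_score,
    write_structure,
)

from conftest import make_designed


def quaternion_superpose_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """Independent oracle: optimal RMSD via the quaternion eigenvalue method."""
    P0 = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)
    M = P0.T @ Q0
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    lam = np.linalg.eigvalsh(K)[-1]
    e2 = max(np.sum(P0 ** 2) + np.sum(Q0 ** 2) - 2.0 * lam, 0.0)
    return float(np.sqrt(e2 / len(P)))


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

class TestPdbIO:
    def test_minimal_single_residue(self):
        text = ("ATOM      1  CA  ALA A   1      11.000  22.000  33.000"
                "  1.00  0.00           C\n")
        s = read_structure(text)
        assert s.n_residues == 1
        assert s.residue_names() == ["ALA"]
        np.testing.assert_allclose(s.ca_coords()[0], [11.0, 22.0, 33.0])

    def test_round_trip_preserves_coordinates_and_chain_order(self, small_library):
        s = small_library[0]
        s2 = read_structure(write_structure(s))
        assert [c.chain_id for c in s2.chains] == [c.chain_id for c in s.chains]
        assert s2.residue_names() == s.residue_names()
        # PDB carries 3 decimals
        assert np.abs(s2.ca_coords() - s.ca_coords()).max() <= 5.1e-4
        # second round trip is exact
        assert write_structure(s2) == write_structure(read_structure(write_structure(s2)))

    def test_writes_one_ca_per_residue_plus_cb(self, small_library):
        s = small_library[1]
        text = write_structure(s)
        n_ca = sum(1 for line in text.splitlines()
                   if line.startswith("ATOM") and line[12:16].strip() == "CA")
        n_cb = sum(1 for line in text.splitlines()
                   if line.startswith("ATOM") and line[12:16].strip() == "CB")
        n_gly = sum(1 for n in s.residue_names() if n == "GLY")
        assert n_ca == s.n_residues
        assert n_cb == s.n_residues - n_gly

    def test_hetatm_only_is_parse_error(self):
        text = ("HETATM    1  O   HOH A   1      1.000   2.000   3.000"
                "  1.00  0.00           O\n")
        with pytest.raises(PDBParseError):
            read_structure(text)

    def test_insertion_code_rejected(self):
        text = ("ATOM      1  CA  ALA A   1A     1.000   2.000   3.000"
                "  1.00  0.00           C\n")
        with pytest.raises(PDBParseError):
            read_structure(text)

    def test_duplicate_atom_rejected(self):
        line = ("ATOM      1  CA  ALA A   1       1.000   2.000   3.000"
                "  1.00  0.00           C\n")
        with pytest.raises(PDBParseError):
            read_structure(line + line)


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

class TestKabsch:
    def test_identity(self):
        rng = np.random.default_rng(0)
        P = rng.normal(0, 5, (7, 3))
        _, _, rmsd = kabsch_superpose(P, P)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_invariance(self):
        rng = np.random.default_rng(1)
        P = rng.normal(0, 5, (9, 3))
        R = random_rotation(rng)
        t = rng.normal(0, 20, 3)
        R2, t2, rmsd = kabsch_superpose(P, P @ R.T + t)
        assert rmsd <= 1e-9
        assert np.linalg.det(R2) == pytest.approx(1.0, abs=1e-9)

    def test_matches_quaternion_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(40):
            n = int(rng.integers(3, 11))
            P = rng.normal(0, 4, (n, 3))
            Q = rng.normal(0, 4, (n, 3))
            _, _, rmsd = kabsch_superpose(P, Q)
            assert rmsd == pytest.approx(quaternion_superpose_rmsd(P, Q), abs=1e-6)

    def test_errors(self):
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(line, line)


# ---------------------------------------------------------------------------
# TM-score
# ---------------------------------------------------------------------------

class TestTmScore:
    def test_self_is_one(self):
        assert tm_score(np.zeros(80), 80) == 1.0

    def test_d0_formula(self):
        assert tm_d0(100) == pytest.approx(1.24 * 85 ** (1 / 3) - 1.8, abs=1e-9)
        assert tm_d0(21) == 0.5
        assert tm_d0(10) == 0.5

    def test_half_mapped_at_zero_distance(self):
        assert tm_score(np.zeros(50), 100) == pytest.approx(0.5)

    def test_empty_mapping_is_error(self):
        with pytest.raises(ValueError):
            tm_score(np.zeros(0), 10)


# ---------------------------------------------------------------------------
# structural alignment
# ---------------------------------------------------------------------------

class TestStructuralAlign:
    def test_self_alignment(self, small_library):
        s = small_library[0]
        res = structural_align(s, s)
        assert res.tm == pytest.approx(1.0, abs=1e-12)
        assert res.mapping == [(i, i) for i in range(s.n_residues)]

    def test_rigid_transform_invariance(self, small_library):
        rng = np.random.default_rng(3)
        s = small_library[1]
        moved = s.transformed(random_rotation(rng), rng.normal(0, 30, 3))
        assert structural_align(s, moved).tm >= 0.999

    def test_mapping_one_to_one_and_order_preserving(self, small_library):
        res = structural_align(small_library[2], small_library[3])
        ia = [a for a, _ in res.mapping]
        ib = [b for _, b in res.mapping]
        assert ia == sorted(ia) and len(set(ia)) == len(ia)
        assert ib == sorted(ib) and len(set(ib)) == len(ib)

    def test_direction_differs_only_through_normalization(self, small_library):
        a, b = small_library[4], small_library[5]
        ab = structural_align(a, b)
        ab_norm_a = structural_align(a, b, l_target=a.n_residues)
        ba = structural_align(b, a)
        # symmetric comparison once the same normalisation length is used:
        # scores agree to the tolerance of the heuristic search
        assert ab.l_target == b.n_residues
        assert ba.l_target == a.n_residues
        assert abs(ab_norm_a.tm - ba.tm) <= 0.05

    def test_beats_exhaustive_three_fragment_seeding(self):
        """Thorough alignment dominates a single-pass exhaustive-seed oracle."""
        from foldfunc.structure import _dp_trace, _score_mapping

        def oracle(A, B):
            ca_a, ca_b = A.ca_coords(), B.ca_coords()
            na, nb = len(ca_a), len(ca_b)
            lt = nb
            d0 = tm_d0(lt)
            best = 0.0
            for i in range(na - 2):
                for j in range(nb - 2):
                    try:
                        R, t, _ = kabsch_superpose(ca_a[i:i + 3], ca_b[j:j + 3])
                    except DegenerateGeometryError:
                        continue
                    moved = ca_a @ R.T + t
                    dist2 = np.sum((moved[:, None, :] - ca_b[None, :, :]) ** 2,
                                   axis=2)
                    pairs = _dp_trace(1.0 / (1.0 + dist2 / d0 ** 2), -0.6)
                    tm, _, _, _ = _score_mapping(ca_a, ca_b, pairs, lt)
                    best = max(best, tm)
            return best

        structs = [make_designed(seed + 40, n_residues=42, mc_steps=2000,
                                 design_steps=500) for seed in range(4)]
        for i in range(4):
            for j in range(i + 1, 4):
                impl = structural_align(structs[i], structs[j], thorough=True).tm
                assert impl >= oracle(structs[i], structs[j]) - 1e-9


# ---------------------------------------------------------------------------
# geometry statistics
# ---------------------------------------------------------------------------

class TestGeometryStats:
    def test_two_distant_residues_no_contacts(self):
        s = Structure.from_arrays(["ALA", "ALA"],
                                  np.array([[0.0, 0, 0], [20.0, 0, 0]]))
        rg, contacts = geometry_stats(s)
        assert contacts == []

    def test_rg_closed_form(self):
        assert radius_of_gyration(np.array([[0.0, 0, 0], [2.0, 0, 0]])) == \
            pytest.approx(1.0)

    def test_contacts_equal_brute_force(self, small_library):
        for s in small_library[:4]:
            coords = s.interaction_coords()
            n = len(coords)
            brute = []
            for i in range(n):
                for j in range(i + 1, n):
                    if abs(i - j) < 3:
                        continue
                    if np.linalg.norm(coords[i] - coords[j]) <= 8.0:
                        brute.append((i, j))
            assert contact_pairs(s) == brute
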