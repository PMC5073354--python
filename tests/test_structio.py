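import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from allopath import (
    Selection,
    bfactor_stats,
    kabsch_superpose,
    read_pdb,
    rmsd_between,
    write_pdb,
)
from allopath.errors import (
    AtomMismatchError,
    EmptyInputError,
    PDBParseError,
    SelectionError,
)
from allopath.structio import Ensemble, Structure, apply_transform

from conftest import random_rigid_transform

THREE_ATOM_PDB = """\
ATOM      1  N   ALA A   1      11.104  13.207   2.100  1.00 20.00           N
ATOM      2  CA  ALA A   1      12.560  13.300   2.300  0.90 21.50           C
ATOM      3  C   ALA A   1      13.100  14.650   2.750  1.00 19.25           C
END
"""

TWO_MODEL_PDB = """\
MODEL        1
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA  ALA A   1       1.500   0.000   0.000  1.00 10.00           C
ATOM      3  C   ALA A   1       2.000   1.400   0.000  1.00 10.00           C
ENDMDL
MODEL        2
ATOM      1  N   ALA A   1       0.000   0.000   1.000  1.00 10.00           N
ATOM      2  CA  ALA A   1       1.500   0.000   1.000  1.00 10.00           C
ATOM      3  C   ALA A   1       2.000   1.400   1.000  1.00 10.00           C
ENDMDL
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.60 10.00           C
ATOM      2  CA BALA A   1       1.000   0.000   0.000  0.40 10.00           C
END
"""


# ---------------------------------------------------------------------------
# read_pdb
# ---------------------------------------------------------------------------

class TestReadPDB:
    def test_three_atom_field_echo(self, tmp_path):
        p = tmp_path / "three.pdb"
        p.write_text(THREE_ATOM_PDB)
        s = read_pdb(p)
        assert isinstance(s, Structure)
        assert len(s) == 3
        a = s.atoms[0]
        assert a.atom_name == "N"
        assert a.res_name == "ALA"
        assert a.chain_id == "A"
        assert a.res_seq == 1
        assert a.element == "N"
        np.testing.assert_allclose(a.coords, [11.104, 13.207, 2.100])
        assert a.b_factor == 20.00
        assert s.atoms[1].occupancy == 0.90

    def test_two_models_become_ensemble(self, tmp_path):
        p = tmp_path / "two.pdb"
        p.write_text(TWO_MODEL_PDB)
        e = read_pdb(p)
        assert isinstance(e, Ensemble)
        assert len(e) == 2
        assert e.frames[1][0, 2] == 1.0

    def test_altloc_highest_occupancy(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(ALTLOC_PDB)
        s = read_pdb(p, altloc_policy="highest-occupancy")
        assert len(s) == 1
        assert s.atoms[0].altloc == "A"
        assert s.atoms[0].occupancy == 0.60

    def test_altloc_tie_prefers_label_order(self, tmp_path):
        text = ALTLOC_PDB.replace("0.60", "0.40")
        p = tmp_path / "tie.pdb"
        p.write_text(text)
        s = read_pdb(p)
        assert s.atoms[0].altloc == "A"

    def test_altloc_keep_all_and_specific(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(ALTLOC_PDB)
        assert len(read_pdb(p, altloc_policy="keep-all")) == 2
        s = read_pdb(p, altloc_policy="specific-label", altloc_label="B")
        assert len(s) == 1
        assert s.atoms[0].altloc == "B"

    def test_malformed_line_names_line_number(self, tmp_path):
        bad = THREE_ATOM_PDB.replace("12.560", "xx.560")
        p = tmp_path / "bad.pdb"
        p.write_text(bad)
        with pytest.raises(PDBParseError, match="line 2"):
            read_pdb(p)

    def test_zero_atoms_is_error(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("HEADER    NOTHING\nEND\n")
        with pytest.raises(EmptyInputError):
            read_pdb(p)

    def test_hetatm_flag_survives(self, tmp_path):
        text = (
            "HETATM    1 NI    NI A 301       1.000   2.000   3.000"
            "  1.00 30.00          NI\n"
        )
        p = tmp_path / "ni.pdb"
        p.write_text(text)
        s = read_pdb(p)
        assert s.atoms[0].is_hetatm
        assert s.atoms[0].element == "NI"


class TestRoundTrip:
    def test_structure_round_trip(self, helix20, tmp_path):
        p = tmp_path / "helix.pdb"
        write_pdb(helix20, p)
        back = read_pdb(p)
        assert len(back) == len(helix20)
        np.testing.assert_allclose(back.coords, helix20.coords, atol=5e-4)
        for a, b in zip(helix20.atoms, back.atoms):
            assert a.atom_key == b.atom_key
            assert a.res_name == b.res_name
            assert a.element == b.element

    def test_ensemble_round_trip(self, helix20, tmp_path):
        frames = [helix20.coords, helix20.coords + 1.0]
        e = Ensemble(helix20, frames)
        p = tmp_path / "ens.pdb"
        write_pdb(e, p)
        back = read_pdb(p)
        assert isinstance(back, Ensemble)
        assert len(back) == 2
        np.testing.assert_allclose(back.frames[1], frames[1], atol=5e-4)


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

def brute_force_min_rmsd(mobile, target):
    """Independent oracle: minimize RMSD over a rotation-vector
    parameterization from many starting points."""
    mu_m = mobile.mean(axis=0)
    mu_t = target.mean(axis=0)
    xm, xt = mobile - mu_m, target - mu_t

    def cost(rotvec):
        rot = Rotation.from_rotvec(rotvec).as_matrix()
        return np.sqrt(np.mean(np.sum((xm @ rot.T - xt) ** 2, axis=1)))

    best = np.inf
    rng = np.random.default_rng(0)
    starts = [np.zeros(3)] + [rng.uniform(-np.pi, np.pi, 3) for _ in range(20)]
    for x0 in starts:
        res = minimize(cost, x0, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14,
                                "maxiter": 5000})
        best = min(best, res.fun)
    return best


class TestKabsch:
    def test_identity(self, rng):
        pts = rng.standard_normal((10, 3))
        rot, trans, rmsd = kabsch_superpose(pts, pts)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(trans, 0.0, atol=1e-12)
        assert rmsd < 1e-12

    def test_known_rotation_recovered(self, rng):
        pts = rng.standard_normal((12, 3))
        theta = math.radians(30)
        rz = np.array([
            [math.cos(theta), -math.sin(theta), 0],
            [math.sin(theta), math.cos(theta), 0],
            [0, 0, 1],
        ])
        rotated = pts @ rz.T
        rot, trans, rmsd = kabsch_superpose(rotated, pts)
        np.testing.assert_allclose(rot, rz.T, atol=1e-10)
        assert rmsd < 1e-10

    def test_matches_brute_force_oracle(self, rng):
        mobile = rng.standard_normal((10, 3)) * 5
        target = rng.standard_normal((10, 3)) * 5
        _, _, rmsd = kabsch_superpose(mobile, target)
        oracle = brute_force_min_rmsd(mobile, target)
        assert abs(rmsd - oracle) < 1e-8

    def test_proper_rotation_always(self, rng):
        # include a mirrored cloud, where an improper solution would win
        pts = rng.standard_normal((8, 3))
        mirrored = pts * np.array([-1, 1, 1])
        rot, _, _ = kabsch_superpose(pts, mirrored)
        assert abs(np.linalg.det(rot) - 1.0) < 1e-9

    def test_rigid_transform_invariance(self, rng):
        a = rng.standard_normal((15, 3)) * 4
        b = rng.standard_normal((15, 3)) * 4
        _, _, base = kabsch_superpose(a, b)
        for _ in range(5):
            rot, trans = random_rigid_transform(rng)
            _, _, moved = kabsch_superpose(a @ rot.T + trans, b)
            assert abs(moved - base) < 1e-9
            _, _, moved2 = kabsch_superpose(a, b @ rot.T + trans)
            assert abs(moved2 - base) < 1e-9

    def test_weights_shift_solution(self, rng):
        a = rng.standard_normal((6, 3))
        b = a.copy()
        b[0] += 5.0
        w = np.array([100.0, 1, 1, 1, 1, 1])
        _, _, weighted = kabsch_superpose(a, b, weights=w)
        _, _, plain = kabsch_superpose(a, b)
        assert weighted != plain

    def test_errors(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            kabsch_superpose(rng.standard_normal((5, 3)),
                             rng.standard_normal((6, 3)))
        with pytest.raises(ValueError, match="3 points"):
            kabsch_superpose(rng.standard_normal((2, 3)),
                             rng.standard_normal((2, 3)))


# ---------------------------------------------------------------------------
# rmsd_between / bfactor_stats / selections
# ---------------------------------------------------------------------------

class TestRMSDBetween:
    def test_self_is_zero(self, helix20):
        assert rmsd_between(helix20, helix20, Selection.backbone()) < 1e-12

    def test_translation(self, helix20):
        moved = helix20.copy()
        moved.set_coords(moved.coords + np.array([1.0, 0, 0]))
        raw = rmsd_between(helix20, moved, superpose=False)
        assert abs(raw - 1.0) < 1e-12
        fit = rmsd_between(helix20, moved, superpose=True)
        assert fit < 1e-9

    def test_symmetry(self, helix20, rng):
        noisy = helix20.copy()
        noisy.set_coords(noisy.coords + rng.normal(0, 0.3, (len(noisy), 3)))
        ab = rmsd_between(helix20, noisy)
        ba = rmsd_between(noisy, helix20)
        assert abs(ab - ba) < 1e-9

    def test_unmatched_atoms_reported(self, helix20):
        shorter = Structure(
            [a for a in helix20.atoms if a.res_seq <= 18], helix20.metadata
        )
        with pytest.raises(AtomMismatchError) as err:
            rmsd_between(helix20, shorter)
        assert len(err.value.only_in_a) > 0
        # explicit opt-in works
        assert rmsd_between(helix20, shorter, allow_unmatched=True) < 1e-9


class TestBFactorStats:
    def _structure_with_b(self, bvals):
        import allopath.structio as sio

        atoms = [
            sio.AtomRecord("A", i + 1, "ALA", "CA", "C",
                           np.array([float(i), 0, 0]), b_factor=b)
            for i, b in enumerate(bvals)
        ]
        return Structure(atoms)

    def test_mean_and_zscores(self):
        s = self._structure_with_b([10.0, 20.0, 30.0])
        stats = bfactor_stats(s, normalize=True)
        assert stats.mean == 20.0
        np.testing.assert_allclose(
            stats.per_atom, [-1.224745, 0.0, 1.224745], atol=1e-6
        )

    def test_single_atom_normalize_errors(self):
        s = self._structure_with_b([10.0])
        with pytest.raises(ValueError):
            bfactor_stats(s, normalize=True)

    def test_degenerate_sd_errors(self):
        s = self._structure_with_b([10.0, 10.0, 10.0])
        with pytest.raises(ValueError):
            bfactor_stats(s, normalize=True)

    @given(st.lists(st.floats(0.0, 200.0), min_size=3, max_size=60))
    @settings(max_examples=25, deadline=None)
    def test_normalized_mean_zero_sd_one(self, bvals):
        if np.std(bvals) == 0:
            return
        s = self._structure_with_b(bvals)
        stats = bfactor_stats(s, normalize=True)
        assert abs(stats.per_atom.mean()) < 1e-9
        assert abs(stats.per_atom.std() - 1.0) < 1e-9


class TestSelection:
    def test_parse_and_order(self, helix20):
        sel = Selection.parse("backbone and resi 3-7")
        idx = sel.indices(helix20)
        assert list(idx) == sorted(idx)
        assert all(3 <= helix20.atoms[i].res_seq <= 7 for i in idx)
        assert all(helix20.atoms[i].atom_name in ("N", "CA", "C", "O")
                   for i in idx)

    def test_empty_selection_reportable(self, helix20):
        sel = Selection.chain("Z")
        assert sel.indices(helix20).size == 0
        with pytest.raises(SelectionError):
            sel.require(helix20)

    def test_parse_errors(self):
        with pytest.raises(SelectionError):
            Selection.parse("")
        with pytest.raises(SelectionError):
            Selection.parse("frobnicate 12")

    def test_combinators(self, helix20):
        ca = Selection.calpha()
        not_ca = ~ca
        assert ca.indices(helix20).size + not_ca.indices(helix20).size == len(
            helix20
        )

    def test_apply_transform_helper(self, helix20, rng):
        rot, trans = random_rigid_transform(rng)
        moved = apply_transform(helix20.coords, rot, trans)
        d_old = np.linalg.norm(helix20.coords[0] - helix20.coords[10])
        d_new = np.linalg.norm(moved[0] - moved[10])
        assert abs(d_old - d_new) < 1e-9
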