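"""Seed-deterministic synthetic fixtures with machine-readable planted truth.

Every generator returns ``(object, truth)`` where ``truth`` is a plain dict
recording exactly what was planted (segment location, displaced mode and
amplitudes, bond lists, clash frame range), so recovery tests consume the
truth record instead of hand-coding expected values a second time.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import AllopathError
from .structio import AtomRecord, Ensemble, Selection, Structure
from . import modes as modes_mod

HELIX_RISE = 1.5          # Angstrom per residue
HELIX_TWIST = 100.0       # degrees per residue
HELIX_RADIUS = 2.3        # Calpha helix radius

_HYDROPHOBIC = ("ILE", "LEU", "VAL")

# local-frame offsets (radial u, tangential t, axial z) for backbone atoms
_OFFSETS = {
    "N": (-0.45, -1.26, -0.50),
    "C": (-0.45, 1.26, 0.50),
    "O": (-1.45, 1.26, 1.05),
    "CB": (1.30, 0.00, -0.60),
}
_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}


def make_helix(n_res: int, seed: int = 0, chain_id: str = "A",
               residue_names=None) -> Structure:
    """Ideal alpha-helix backbone (rise 1.5 A, 100 deg/residue) with Cbeta
    pseudo-atoms. Residue identities are drawn from the 20 types unless
    given explicitly."""
    if n_res < 8:
        raise ValueError("need at least 8 residues for a useful helix")
    rng = np.random.default_rng(seed)
    if residue_names is None:
        from .frustration import AMINO_ACIDS_20

        residue_names = [str(rng.choice(AMINO_ACIDS_20)) for _ in range(n_res)]
    elif len(residue_names) != n_res:
        raise ValueError("residue_names length must equal n_res")
    atoms = []
    for i in range(n_res):
        theta = math.radians(HELIX_TWIST * i)
        u = np.array([math.cos(theta), math.sin(theta), 0.0])
        t = np.array([-math.sin(theta), math.cos(theta), 0.0])
        z = np.array([0.0, 0.0, 1.0])
        ca = HELIX_RADIUS * u + np.array([0.0, 0.0, HELIX_RISE * i])
        res_name = residue_names[i]
        placed = [("CA", ca)]
        for name, (du, dt, dz) in _OFFSETS.items():
            if name == "CB" and res_name == "GLY":
                continue
            placed.append((name, ca + du * u + dt * t + dz * z))
        for atom_name, coords in placed:
            atoms.append(
                AtomRecord(
                    chain_id=chain_id,
                    res_seq=i + 1,
                    res_name=res_name,
                    atom_name=atom_name,
                    element=_ELEMENTS[atom_name],
                    coords=coords,
                    b_factor=10.0,
                )
            )
    return Structure(atoms, {"source": f"synthetic helix n={n_res} seed={seed}"})


def make_deviation_triple(n_res: int = 60, segment=(20, 24), shift: float = 1.0,
                          seed: int = 0, noise_sd: float = 0.1):
    """(reference, query, third) with the query's ``segment`` residues rigidly
    displaced by ``shift`` Angstrom and the third structure noise-jittered."""
    start, end = segment
    if not (1 <= start <= end <= n_res):
        raise ValueError(f"segment {segment} outside residues 1..{n_res}")
    if shift < 0:
        raise ValueError("shift must be >= 0")
    rng = np.random.default_rng(seed)
    reference = make_helix(n_res, seed=seed)

    direction = rng.standard_normal(3)
    direction /= np.linalg.norm(direction)

    query = reference.copy()
    for atom in query.atoms:
        if start <= atom.res_seq <= end:
            atom.coords = atom.coords + shift * direction

    third = reference.copy()
    third.set_coords(
        third.coords + rng.normal(0.0, noise_sd, size=(len(third), 3))
    )
    truth = {
        "segment": (start, end),
        "shift": float(shift),
        "direction": direction.tolist(),
        "noise_sd": float(noise_sd),
        "seed": int(seed),
    }
    return reference, query, third, truth


def make_mode_ensemble(base: Structure, mode_number: int = 8,
                       amplitude_mean: float = 2.0, amplitude_sd: float = 0.5,
                       n_frames: int = 200, seed: int = 0,
                       noise_sd: float = 0.0, cutoff: float = 15.0):
    """Ensemble displaced along one internal elastic-network mode.

    Each frame moves every atom of residue i by that residue's Calpha mode
    displacement times an amplitude drawn from N(mean, sd), plus optional
    isotropic Gaussian noise.
    """
    if mode_number <= modes_mod.N_RIGID_BODY:
        raise AllopathError(
            f"mode {mode_number} is a rigid-body mode; pick > "
            f"{modes_mod.N_RIGID_BODY}"
        )
    rng = np.random.default_rng(seed)
    mode_set = modes_mod.compute_modes(base, cutoff=cutoff,
                                       n_modes=mode_number + 5)
    vec = mode_set.eigenvector(mode_number).reshape(-1, 3)
    node_of = {key: k for k, key in enumerate(mode_set.node_keys)}
    residue_index = np.array([node_of[a.residue_key] for a in base.atoms])

    base_coords = base.coords
    amplitudes = rng.normal(amplitude_mean, amplitude_sd, size=n_frames)
    frames = []
    for a in amplitudes:
        frame = base_coords + a * vec[residue_index]
        if noise_sd > 0:
            frame = frame + rng.normal(0.0, noise_sd, size=frame.shape)
        frames.append(frame)
    truth = {
        "mode_number": int(mode_number),
        "amplitude_mean": float(amplitude_mean),
        "amplitude_sd": float(amplitude_sd),
        "amplitudes": [float(a) for a in amplitudes],
        "noise_sd": float(noise_sd),
        "seed": int(seed),
        "cutoff": float(cutoff),
    }
    return Ensemble(base.copy(), frames), mode_set, truth


def _res(chain, seq, name, atom_coords):
    """Helper: list of AtomRecords for one residue from {atom: xyz}."""
    out = []
    for atom_name, xyz in atom_coords.items():
        element = atom_name[0] if atom_name[0] in "NOSC" else "C"
        out.append(
            AtomRecord(
                chain_id=chain,
                res_seq=seq,
                res_name=name,
                atom_name=atom_name,
                element=element,
                coords=np.array(xyz, dtype=float),
                b_factor=10.0,
            )
        )
    return out


def make_interface_complex(seed: int = 0):
    """Two short chains with a planted bond list.

    Three interface sites, well separated (8 Angstrom in x):
      * chain I Gly1 backbone N donates to chain A Ala1 backbone O (2.9 A,
        antecedent angle 180);
      * chain I Lys2 NZ to chain A Asp2 OD1 at 3.2 A — a salt bridge that
        also satisfies the H-bond criteria, as a real Lys-Asp pair would;
      * chain A Ser3 backbone N donates to chain I Ala3 backbone O (2.9 A).
    """
    atoms = []
    # --- chain A (receptor side, y < 0) ---
    atoms += _res("A", 1, "ALA", {
        "N": (-1.2, -3.8, 0.0), "CA": (0.0, -3.0, 0.0),
        "C": (0.0, -2.68, 1.3), "O": (0.0, -1.45, 0.0),
        "CB": (0.8, -3.6, -0.9),
    })
    atoms += _res("A", 2, "ASP", {
        "N": (6.9, -5.2, 0.0), "CA": (8.0, -4.5, 0.0),
        "C": (9.2, -5.0, 0.0), "O": (9.2, -6.23, 0.0),
        "CB": (8.0, -3.1, 0.0), "CG": (8.0, -1.9, 0.0),
        "OD1": (8.0, -0.7, 0.0), "OD2": (9.1, -1.6, 0.0),
    })
    atoms += _res("A", 3, "SER", {
        "N": (16.0, -1.45, 0.0), "CA": (16.0, -2.9, 0.0),
        "C": (17.2, -3.4, 0.0), "O": (17.2, -4.6, 0.0),
        "CB": (15.2, -3.5, 0.8), "OG": (15.2, -4.5, 1.5),
    })
    # --- chain I (inhibitor side, y > 0) ---
    atoms += _res("I", 1, "GLY", {
        "N": (0.0, 1.45, 0.0), "CA": (0.0, 2.9, 0.0),
        "C": (1.2, 3.4, 0.0), "O": (1.2, 4.63, 0.0),
    })
    atoms += _res("I", 2, "LYS", {
        "N": (6.9, 7.5, 0.0), "CA": (8.0, 7.0, 0.0),
        "C": (9.1, 7.6, 0.0), "O": (9.1, 8.8, 0.0),
        "CB": (8.0, 6.0, 1.0), "CG": (8.0, 6.7, -0.3),
        "CD": (8.0, 5.2, 0.0), "CE": (8.0, 3.9, 0.0),
        "NZ": (8.0, 2.5, 0.0),
    })
    atoms += _res("I", 3, "ALA", {
        "N": (14.9, 4.5, 0.5), "CA": (16.0, 3.9, 0.5),
        "C": (16.0, 2.68, 0.0), "O": (16.0, 1.45, 0.0),
        "CB": (17.0, 4.4, 1.2),
    })
    complex_structure = Structure(
        atoms, {"source": f"synthetic interface complex seed={seed}"}
    )
    truth = {
        "hbonds": [
            (("I", 1, "", "N"), ("A", 1, "", "O")),
            (("I", 2, "", "NZ"), ("A", 2, "", "OD1")),
            (("A", 3, "", "N"), ("I", 3, "", "O")),
        ],
        "salt_bridges": [(("I", 2, "", "NZ"), ("A", 2, "", "OD1"))],
        "seed": int(seed),
    }
    return complex_structure, truth


def make_helix_complex(n_res: int = 24, seed: int = 0,
                       ligand_offset: float = 9.5) -> Structure:
    """Helix receptor (chain A) with a two-residue ligand (chain I) floating
    ``ligand_offset`` Angstrom radially off the mid-helix surface — close
    enough to graft against, far enough that the reference pose is
    clash-free with an empty native-contact whitelist."""
    receptor = make_helix(n_res, seed=seed, chain_id="A")
    k = n_res // 2
    theta = math.radians(HELIX_TWIST * (k - 1))
    u = np.array([math.cos(theta), math.sin(theta), 0.0])
    t = np.array([-math.sin(theta), math.cos(theta), 0.0])
    z = np.array([0.0, 0.0, 1.0])
    ca_k = HELIX_RADIUS * u + np.array([0.0, 0.0, HELIX_RISE * (k - 1)])
    atoms = [a.copy() for a in receptor.atoms]
    for seq, dz in ((1, 0.0), (2, 3.8)):
        ca = ca_k + ligand_offset * u + dz * z
        for atom_name, offset in (
            ("N", -1.2 * t - 0.5 * z),
            ("CA", np.zeros(3)),
            ("C", 1.2 * t + 0.5 * z),
            ("O", 1.2 * t + 1.7 * z),
            ("CB", 1.0 * u - 0.9 * z),
        ):
            atoms.append(
                AtomRecord(
                    chain_id="I", res_seq=seq, res_name="ALA",
                    atom_name=atom_name, element=_ELEMENTS[atom_name],
                    coords=ca + offset, b_factor=10.0,
                )
            )
    return Structure(atoms, {"source": f"synthetic helix complex seed={seed}"})


def make_clash_trajectory(reference_complex: Structure | None = None,
                          intruding_residue=None,
                          clash_frames=range(10, 21), n_frames: int = 30,
                          depth: float = 1.0, seed: int = 0):
    """Receptor-only ensemble whose ``intruding_residue`` translates into the
    ligand volume during ``clash_frames``.

    ``depth`` in (0, 1] scales how far the residue travels toward the nearest
    ligand atom (1.0 lands an atom exactly on it). The default complex is
    :func:`make_helix_complex`; the default intruder is the receptor residue
    nearest the ligand.
    """
    if reference_complex is None:
        reference_complex = make_helix_complex(seed=seed)
    receptor_sel = Selection.chain("A")
    ligand_sel = Selection.chain("I")
    receptor = reference_complex.select(receptor_sel)
    ligand = reference_complex.select(ligand_sel)
    rc, lc = receptor.coords, ligand.coords
    if intruding_residue is None:
        d_all = np.linalg.norm(rc[:, None, :] - lc[None, :, :], axis=2)
        intruding_residue = receptor.atoms[
            int(np.unravel_index(np.argmin(d_all), d_all.shape)[0])
        ].residue_key
    res_idx = [i for i, a in enumerate(receptor.atoms)
               if a.residue_key == tuple(intruding_residue)]
    if not res_idx:
        raise AllopathError(f"residue {intruding_residue} not in the receptor")
    sub = rc[res_idx]
    d = np.linalg.norm(sub[:, None, :] - lc[None, :, :], axis=2)
    i_min, j_min = np.unravel_index(np.argmin(d), d.shape)
    displacement = depth * (lc[j_min] - sub[i_min])

    clash_set = set(int(f) for f in clash_frames)
    frames = []
    for f in range(n_frames):
        frame = rc.copy()
        if f in clash_set:
            frame[res_idx] += displacement
        frames.append(frame)
    truth = {
        "clash_frames": sorted(clash_set & set(range(n_frames))),
        "intruding_residue": tuple(intruding_residue),
        "depth": float(depth),
        "n_frames": int(n_frames),
        "seed": int(seed),
    }
    return Ensemble(receptor, frames), reference_complex, truth


def make_frustration_toy(n_res: int = 30, seed: int = 0,
                         planted_path=(5, 3, 4)):
    """Helix with hydrophobic identities (minimally frustrated background)
    and, optionally, a planted chain of like-charged residues whose mutual
    contacts are highly frustrated.

    ``planted_path = (start, step, length)`` puts LYS at residues start,
    start+step, ...; with step 3 on an ideal helix those residues form a
    connected chain of contacts. ``planted_path=None`` gives the clean
    well-folded fixture.
    """
    rng = np.random.default_rng(seed)
    names = [str(rng.choice(_HYDROPHOBIC)) for _ in range(n_res)]
    path_residues = []
    if planted_path is not None:
        start, step, length = planted_path
        for k in range(length):
            pos = start + k * step
            if not 1 <= pos <= n_res:
                raise ValueError("planted path runs outside the chain")
            names[pos - 1] = "LYS"
            path_residues.append(pos)
    structure = make_helix(n_res, seed=seed, residue_names=names)
    truth = {
        "path_residues": path_residues,
        "background": list(_HYDROPHOBIC),
        "seed": int(seed),
    }
    return structure, truth
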