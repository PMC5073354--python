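"""Ensemble clash screening of a grafted ligand.

The reference complex's ligand is posed onto each frame of a receptor
ensemble by Kabsch superposition of the matched receptor atoms, then
receptor-ligand van der Waals overlaps beyond a threshold are reported.
Native crystallographic contacts are whitelisted at grafting time so the
reference interface never self-reports as a clash.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import AllopathError
from .interface import vdw_radius
from .structio import (
    Ensemble,
    Selection,
    Structure,
    apply_transform,
    kabsch_superpose,
    match_atoms,
)

DEFAULT_OVERLAP_MIN = 0.4
WHITELIST_MARGIN = 0.5


@dataclass
class ClashPair:
    receptor_atom: tuple
    ligand_atom: tuple
    distance: float
    overlap: float                # r_vdw sum - distance, > 0


@dataclass
class ClashReport:
    pairs: list
    per_receptor_residue: dict    # residue key -> clash count
    per_ligand_residue: dict      # residue key -> clash count

    @property
    def n_clashes(self) -> int:
        return len(self.pairs)


@dataclass
class ClashTimecourse:
    reports: list                 # one ClashReport per frame
    clash_frames: list            # frame indices with >= 1 clash
    residue_by_position: dict     # (receptor residue, ligand residue) -> frames


def graft_ligand(frame: Structure, reference_complex: Structure,
                 receptor_sel: Selection, ligand_sel: Selection,
                 fit_sel: Selection | None = None):
    """Pose the reference ligand onto a frame by receptor superposition.

    Returns ``(ligand_structure, rotation, translation)``; the ligand's
    internal geometry is untouched (rigid transform only). ``fit_sel``
    restricts which receptor atoms drive the fit (default: all matched
    receptor atoms).
    """
    sel = receptor_sel if fit_sel is None else (receptor_sel & fit_sel)
    idx_ref, idx_frame = match_atoms(reference_complex, frame, sel,
                                     allow_unmatched=True)
    if len(idx_ref) < 3:
        raise AllopathError(
            f"only {len(idx_ref)} matched receptor atoms; need >= 3 to graft"
        )
    rot, trans, _ = kabsch_superpose(
        reference_complex.coords[idx_ref], frame.coords[idx_frame]
    )
    ligand = reference_complex.select(ligand_sel)
    if len(ligand) == 0:
        raise AllopathError("ligand selection matched no atoms")
    posed = ligand.copy()
    posed.set_coords(apply_transform(ligand.coords, rot, trans))
    return posed, rot, trans


def native_contact_whitelist(reference_complex: Structure,
                             receptor_sel: Selection, ligand_sel: Selection,
                             margin: float = WHITELIST_MARGIN) -> set:
    """Crystallographic receptor-ligand atom pairs within vdW sum + margin."""
    receptor = reference_complex.select(receptor_sel)
    ligand = reference_complex.select(ligand_sel)
    rc, lc = receptor.coords, ligand.coords
    rr = np.array([vdw_radius(a.element) for a in receptor.atoms])
    lr = np.array([vdw_radius(a.element) for a in ligand.atoms])
    tree = cKDTree(lc)
    whitelist = set()
    reach = lr.max() + margin
    for i, atom in enumerate(receptor.atoms):
        for j in tree.query_ball_point(rc[i], rr[i] + reach):
            if np.linalg.norm(rc[i] - lc[j]) <= rr[i] + lr[j] + margin:
                whitelist.add((atom.atom_key, ligand.atoms[j].atom_key))
    return whitelist


def detect_clashes(receptor: Structure, ligand: Structure,
                   overlap_min: float = DEFAULT_OVERLAP_MIN,
                   whitelist: set | None = None) -> ClashReport:
    """All receptor-ligand pairs with distance < r_i + r_j - overlap_min.

    Uses a KD-tree prefilter but is exactly equivalent to the O(N*M) double
    loop. Whitelisted (native-contact) atom pairs are never reported.
    """
    whitelist = whitelist or set()
    rc, lc = receptor.coords, ligand.coords
    rr = np.array([vdw_radius(a.element) for a in receptor.atoms])
    lr = np.array([vdw_radius(a.element) for a in ligand.atoms])
    tree = cKDTree(lc)
    reach = lr.max() - overlap_min
    pairs = []
    for i, r_atom in enumerate(receptor.atoms):
        for j in tree.query_ball_point(rc[i], max(rr[i] + reach, 0.0)):
            dist = float(np.linalg.norm(rc[i] - lc[j]))
            overlap = rr[i] + lr[j] - dist
            if overlap < overlap_min:
                continue
            key = (r_atom.atom_key, ligand.atoms[j].atom_key)
            if key in whitelist:
                continue
            pairs.append(
                ClashPair(
                    receptor_atom=r_atom.atom_key,
                    ligand_atom=ligand.atoms[j].atom_key,
                    distance=dist,
                    overlap=float(overlap),
                )
            )
    pairs.sort(key=lambda p: (-p.overlap, p.receptor_atom, p.ligand_atom))
    per_rec: dict = {}
    per_lig: dict = {}
    for p in pairs:
        per_rec[p.receptor_atom[:3]] = per_rec.get(p.receptor_atom[:3], 0) + 1
        per_lig[p.ligand_atom[:3]] = per_lig.get(p.ligand_atom[:3], 0) + 1
    return ClashReport(pairs=pairs, per_receptor_residue=per_rec,
                       per_ligand_residue=per_lig)


def clash_timecourse(e: Ensemble, reference_complex: Structure,
                     receptor_sel: Selection, ligand_sel: Selection,
                     overlap_min: float = DEFAULT_OVERLAP_MIN,
                     fit_sel: Selection | None = None,
                     position_labels: dict | None = None) -> ClashTimecourse:
    """Graft the ligand onto every frame and time-resolve the clashes.

    ``position_labels`` optionally maps ligand residue keys to substrate
    position labels (P4..P2'); unknown residues keep their own key.
    """
    whitelist = native_contact_whitelist(reference_complex, receptor_sel,
                                         ligand_sel)
    reports = []
    residue_by_position: dict = {}
    for f in range(len(e)):
        frame = e.frame_structure(f)
        posed, _, _ = graft_ligand(frame, reference_complex, receptor_sel,
                                   ligand_sel, fit_sel=fit_sel)
        receptor_frame = frame.select(receptor_sel)
        report = detect_clashes(receptor_frame, posed, overlap_min, whitelist)
        reports.append(report)
        for p in report.pairs:
            lig_res = p.ligand_atom[:3]
            label = (position_labels or {}).get(lig_res, lig_res)
            key = (p.receptor_atom[:3], label)
            residue_by_position.setdefault(key, []).append(f)
    clash_frames = [f for f, r in enumerate(reports) if r.n_clashes > 0]
    residue_by_position = {k: sorted(set(v)) for k, v in residue_by_position.items()}
    return ClashTimecourse(reports=reports, clash_frames=clash_frames,
                           residue_by_position=residue_by_position)
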