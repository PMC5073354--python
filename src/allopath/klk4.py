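"""Case-study measurements on the KLK4 / SFTI-1 structure set.

Each function takes parsed :class:`~allopath.structio.Structure` objects for
the deposited entries (KLK4-SFTI-1 complex, KLK4-PABA, KLK4-Ni, and the
trypsin/matriptase SFTI-1 complexes) and recomputes one headline structural
measurement. The deposited coordinate files are not shipped; obtain them
with ``allopath fetch 4K8Y 2BDG 4KGA 1SFI 3P8F`` (network required) and load
them with :func:`allopath.read_pdb`.

Chymotrypsin residue numbering is used verbatim from the files (catalytic
triad His57/Asp102/Ser195, exosite His25/Glu77).
"""

from __future__ import annotations

import numpy as np

from .errors import AllopathError
from .interface import buried_interface, find_hbonds, find_salt_bridges
from .modes import compute_modes, variance_fraction
from .structio import (
    Selection,
    Structure,
    apply_transform,
    bfactor_stats,
    kabsch_superpose,
    match_atoms,
)

EXOSITE_RESIDUES = (25, 77)
CATALYTIC_SER = 195
SFTI_CORE = (4, 10)          # Thr4-Ile10, the well-aligned bicycle half
P4_ARG = 2


def protein_chains(s: Structure) -> dict:
    """Map chain id -> residue count over protein (ATOM) records."""
    counts: dict = {}
    seen = set()
    for a in s.atoms:
        if a.is_hetatm:
            continue
        key = a.residue_key
        if key not in seen:
            seen.add(key)
            counts[a.chain_id] = counts.get(a.chain_id, 0) + 1
    return counts


def guess_ligand_chain(s: Structure, max_residues: int = 20) -> str:
    """The inhibitor chain is the shortest protein chain (SFTI-1 is 14 aa)."""
    counts = protein_chains(s)
    chain, n = min(counts.items(), key=lambda kv: kv[1])
    if n > max_residues:
        raise AllopathError(
            f"shortest chain {chain} has {n} residues; no peptide ligand found"
        )
    return chain


def guess_receptor_chain(s: Structure) -> str:
    counts = protein_chains(s)
    return max(counts.items(), key=lambda kv: kv[1])[0]


def _receptor_backbone(receptor_chain: str) -> Selection:
    return Selection.chain(receptor_chain) & Selection.backbone()


def backbone_rmsd(complex_structure: Structure, reference: Structure,
                  complex_chain: str | None = None,
                  reference_chain: str = "A") -> float:
    """Global backbone RMSD between the protease of two structures."""
    complex_chain = complex_chain or guess_receptor_chain(complex_structure)
    q = complex_structure.select(Selection.chain(complex_chain)).copy()
    r = reference.select(Selection.chain(reference_chain)).copy()
    # residue numbering is shared (chymotrypsin numbering), chain ids may not be
    for atom in q.atoms:
        atom.chain_id = "_"
    for atom in r.atoms:
        atom.chain_id = "_"
    idx_q, idx_r = match_atoms(q, r, Selection.backbone(), allow_unmatched=True)
    _, _, rmsd = kabsch_superpose(q.coords[idx_q], r.coords[idx_r])
    return rmsd


def interface_backbone_rmsd(complex_structure: Structure, reference: Structure,
                            complex_chain: str | None = None,
                            reference_chain: str = "A",
                            within: float = 5.0) -> float:
    """Backbone RMSD restricted to protease residues within ``within``
    Angstrom of the inhibitor, evaluated in the global superposition frame."""
    complex_chain = complex_chain or guess_receptor_chain(complex_structure)
    ligand_chain = guess_ligand_chain(complex_structure)
    receptor = complex_structure.select(Selection.chain(complex_chain))
    ligand = complex_structure.select(Selection.chain(ligand_chain))
    lig_coords = ligand.coords
    near = set()
    for key, _, atoms in receptor.residues():
        xyz = np.array([a.coords for a in atoms])
        d = np.linalg.norm(xyz[:, None, :] - lig_coords[None, :, :], axis=2)
        if d.min() <= within:
            near.add(key[1])

    q = complex_structure.select(Selection.chain(complex_chain)).copy()
    r = reference.select(Selection.chain(reference_chain)).copy()
    for atom in q.atoms:
        atom.chain_id = "_"
    for atom in r.atoms:
        atom.chain_id = "_"
    idx_q, idx_r = match_atoms(q, r, Selection.backbone(), allow_unmatched=True)
    rot, trans, _ = kabsch_superpose(q.coords[idx_q], r.coords[idx_r])
    moved = apply_transform(q.coords[idx_q], rot, trans)
    target = r.coords[idx_r]
    mask = np.array([q.atoms[i].res_seq in near for i in idx_q])
    if not mask.any():
        raise AllopathError("no interface residues matched")
    dif = moved[mask] - target[mask]
    return float(np.sqrt(np.mean(np.sum(dif ** 2, axis=1))))


def interface_bond_counts(complex_structure: Structure,
                          receptor_chain: str | None = None,
                          ligand_chain: str | None = None) -> dict:
    """H-bond and salt-bridge counts across the protease/inhibitor boundary."""
    receptor_chain = receptor_chain or guess_receptor_chain(complex_structure)
    ligand_chain = ligand_chain or guess_ligand_chain(complex_structure)
    side_r = Selection.chain(receptor_chain) & Selection.protein()
    side_l = Selection.chain(ligand_chain) & Selection.protein()
    hbonds = find_hbonds(complex_structure, side_r, side_l)
    bridges = find_salt_bridges(complex_structure, side_r, side_l)
    ligand_backbone = sum(
        1 for b in hbonds
        if (b.donor[0] == ligand_chain and b.donor_is_backbone)
        or (b.acceptor[0] == ligand_chain and b.acceptor_is_backbone)
    )
    return {
        "n_hbonds": len(hbonds),
        "n_salt_bridges": len(bridges),
        "n_ligand_backbone_hbonds": ligand_backbone,
        "hbonds": hbonds,
        "salt_bridges": bridges,
    }


def residue_burial_share(complex_structure: Structure, res_seq: int,
                         receptor_chain: str | None = None,
                         ligand_chain: str | None = None,
                         probe: float = 1.4, n_points: int = 960) -> float:
    """Percent of the inhibitor's total buried area contributed by one
    inhibitor residue (e.g. Phe12's share of the SFTI-1 buried surface)."""
    receptor_chain = receptor_chain or guess_receptor_chain(complex_structure)
    ligand_chain = ligand_chain or guess_ligand_chain(complex_structure)
    report = buried_interface(
        complex_structure,
        Selection.chain(receptor_chain) & Selection.protein(),
        Selection.chain(ligand_chain) & Selection.protein(),
        probe=probe, n_points=n_points,
    )
    share = 0.0
    for key, buried in report.per_residue_buried.items():
        if report.residue_side[key] == "B" and key[1] == res_seq:
            share += buried
    if report.total_buried_b <= 0:
        raise AllopathError("inhibitor buries no area")
    return 100.0 * share / report.total_buried_b


def exosite_to_active_site(structure: Structure, chain: str = "A",
                           mode: str = "ni") -> float:
    """Distance from the His25/Glu77 metal exosite to catalytic Ser195.

    ``mode='ni'`` measures from the Ni ion coordinated by the exosite
    residues (falling back to the sidechain centroid when no metal is
    present); ``mode='centroid'`` always uses the His25/Glu77 sidechain
    centroid. The endpoint is Ser195 OG (CA fallback).
    """
    sub = structure.select(Selection.chain(chain))
    exosite_atoms = [
        a for a in sub.atoms
        if a.res_seq in EXOSITE_RESIDUES and not a.is_hetatm
        and a.atom_name not in ("N", "CA", "C", "O")
    ]
    if not exosite_atoms:
        raise AllopathError("exosite residues His25/Glu77 not found")
    exo_centroid = np.mean([a.coords for a in exosite_atoms], axis=0)

    origin = exo_centroid
    if mode == "ni":
        metals = [a for a in sub.atoms if a.element in ("NI", "ZN")]
        if metals:
            nearest = min(
                metals, key=lambda a: np.linalg.norm(a.coords - exo_centroid)
            )
            if np.linalg.norm(nearest.coords - exo_centroid) < 6.0:
                origin = nearest.coords

    ser = [a for a in sub.atoms
           if a.res_seq == CATALYTIC_SER and a.atom_name == "OG"]
    if not ser:
        ser = [a for a in sub.atoms
               if a.res_seq == CATALYTIC_SER and a.atom_name == "CA"]
    if not ser:
        raise AllopathError("catalytic Ser195 not found")
    return float(np.linalg.norm(origin - ser[0].coords))


def _ligand_substructure(s: Structure) -> Structure:
    return s.select(Selection.chain(guess_ligand_chain(s)))


def arg2_guanidino_displacement(klk4_complex: Structure,
                                other_complexes) -> float:
    """Displacement of the inhibitor P4 Arg2 guanidino center (CZ) in the
    KLK4-bound pose relative to each other-protease-bound pose, after
    superposing on the inhibitor core backbone (Thr4-Ile10).

    Returns the minimum displacement over the comparison structures.
    """
    core = Selection.resid_range(*SFTI_CORE) & Selection.backbone()

    def core_coords(lig: Structure):
        idx = core.require(lig)
        keyed = {(lig.atoms[i].res_seq, lig.atoms[i].atom_name): i for i in idx}
        return keyed

    ref_lig = _ligand_substructure(klk4_complex)
    ref_keyed = core_coords(ref_lig)
    ref_cz = [a for a in ref_lig.atoms
              if a.res_seq == P4_ARG and a.atom_name == "CZ"]
    if not ref_cz:
        raise AllopathError("P4 Arg2 CZ not found in the KLK4 complex")

    displacements = []
    for other in other_complexes:
        lig = _ligand_substructure(other)
        keyed = core_coords(lig)
        shared = sorted(set(ref_keyed) & set(keyed))
        if len(shared) < 3:
            raise AllopathError("insufficient shared core backbone atoms")
        x_other = np.array([lig.atoms[keyed[k]].coords for k in shared])
        x_ref = np.array([ref_lig.atoms[ref_keyed[k]].coords for k in shared])
        rot, trans, _ = kabsch_superpose(x_other, x_ref)
        cz = [a for a in lig.atoms
              if a.res_seq == P4_ARG and a.atom_name == "CZ"]
        if not cz:
            raise AllopathError("P4 Arg2 CZ not found in comparison complex")
        moved = apply_transform(cz[0].coords[None, :], rot, trans)[0]
        displacements.append(float(np.linalg.norm(moved - ref_cz[0].coords)))
    return min(displacements)


def residue_displacement(query: Structure, reference: Structure, res_seq: int,
                         query_chain: str | None = None,
                         reference_chain: str = "A") -> dict:
    """Displacement of one protease residue after global backbone
    superposition: Calpha, max heavy-atom, and sidechain-max values."""
    query_chain = query_chain or guess_receptor_chain(query)
    q = query.select(Selection.chain(query_chain)).copy()
    r = reference.select(Selection.chain(reference_chain)).copy()
    for atom in q.atoms:
        atom.chain_id = "_"
    for atom in r.atoms:
        atom.chain_id = "_"
    idx_q, idx_r = match_atoms(q, r, Selection.backbone(), allow_unmatched=True)
    rot, trans, _ = kabsch_superpose(q.coords[idx_q], r.coords[idx_r])
    moved = apply_transform(q.coords, rot, trans)
    r_index = r.atom_index()
    out = {"ca": None, "max": 0.0, "sidechain_max": 0.0}
    for i, atom in enumerate(q.atoms):
        if atom.res_seq != res_seq or atom.element == "H":
            continue
        j = r_index.get(atom.atom_key)
        if j is None:
            continue
        d = float(np.linalg.norm(moved[i] - r.coords[j]))
        out["max"] = max(out["max"], d)
        if atom.atom_name == "CA":
            out["ca"] = d
        elif atom.atom_name not in ("N", "C", "O", "OXT"):
            out["sidechain_max"] = max(out["sidechain_max"], d)
    if out["max"] == 0.0 and out["ca"] is None:
        raise AllopathError(f"residue {res_seq} not matched between structures")
    return out


def chain_mean_bfactor(structure: Structure, chain: str = "A") -> float:
    """Mean B over the chain's protein (ATOM) records, waters/HETATM excluded."""
    sel = Selection.chain(chain) & Selection.protein()
    return bfactor_stats(structure, sel).mean


def low_mode_variance_fraction(structure: Structure, chain: str = "A",
                               k: int = 5, cutoff: float = 15.0) -> float:
    """Variance fraction of the first ``k`` internal elastic-network modes of
    one chain (Calpha network), as a percentage."""
    sub = structure.select(Selection.chain(chain) & Selection.protein())
    mode_set = compute_modes(sub, cutoff=cutoff)
    return 100.0 * variance_fraction(mode_set, k)
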