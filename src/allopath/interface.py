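"""Protein-peptide interface characterization.

Per-atom/per-residue solvent-accessible surface area (numerical
Shrake-Rupley), buried area upon complexation, percent burial, and geometric
hydrogen-bond / salt-bridge detection across a chain partition.

Geometry criteria are deliberately explicit and configurable: H-bond =
donor/acceptor heavy atoms within 3.5 Angstrom with antecedent-donor-acceptor
angle >= 90 degrees; salt bridge = basic N / acidic O within 4.0 Angstrom.
Crystal structures carry no hydrogens, so all criteria are heavy-atom based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import EmptyInputError, SelectionError
from .structio import Selection, Structure

#: Fixed van der Waals radius table (Angstrom), shipped for bit-reproducibility.
VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}

DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_N_POINTS = 960

# Donor heavy atom -> antecedent atom used for the angle test. Backbone N is
# handled separately (antecedent CA); PRO N has no H and is excluded.
_SIDECHAIN_DONORS = {
    "ARG": {"NE": "CD", "NH1": "CZ", "NH2": "CZ"},
    "ASN": {"ND2": "CG"},
    "GLN": {"NE2": "CD"},
    "HIS": {"ND1": "CG", "NE2": "CD2"},
    "LYS": {"NZ": "CE"},
    "SER": {"OG": "CB"},
    "THR": {"OG1": "CB"},
    "TRP": {"NE1": "CD1"},
    "TYR": {"OH": "CZ"},
    "CYS": {"SG": "CB"},
}

_SIDECHAIN_ACCEPTORS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "HIS": {"ND1", "NE2"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "MET": {"SD"},
}

_BASIC_ATOMS = {
    "LYS": {"NZ"},
    "ARG": {"NH1", "NH2", "NE"},
}
_BASIC_ATOMS_HIS = {"HIS": {"ND1", "NE2"}}
_ACIDIC_ATOMS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


def vdw_radius(element: str) -> float:
    try:
        return VDW_RADII[element.upper()]
    except KeyError:
        raise KeyError(
            f"no van der Waals radius for element {element!r}; "
            f"known elements: {sorted(VDW_RADII)}"
        ) from None


def sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere points (Fibonacci/golden-spiral lattice)."""
    k = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0))  # golden angle
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    theta = phi * k
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


@dataclass
class SASAResult:
    per_atom_area: np.ndarray
    per_residue_area: dict
    total: float
    probe_radius: float
    n_sphere_points: int
    atom_keys: list


def sasa(s: Structure, probe_radius: float = DEFAULT_PROBE_RADIUS,
         n_points: int = DEFAULT_N_POINTS, include_waters: bool = False,
         include_hetero: bool = False) -> SASAResult:
    """Shrake-Rupley numerical SASA.

    For each atom, the fraction of ``n_points`` quasi-uniform points on the
    sphere of radius ``r_vdw + probe`` not inside any neighbor's inflated
    sphere, times the sphere area. Waters and HETATM records are excluded by
    default (metals/ligands do not shadow the protein surface unless asked).
    """
    if n_points < 24:
        raise ValueError("n_points must be >= 24 for a meaningful estimate")
    atoms = [
        a for a in s.atoms
        if (include_waters or a.res_name not in WATER_NAMES)
        and (include_hetero or not a.is_hetatm)
    ]
    if not atoms:
        raise EmptyInputError("no atoms left for SASA after water/het filtering")
    coords = np.array([a.coords for a in atoms])
    radii = np.array([vdw_radius(a.element) + probe_radius for a in atoms])
    unit = sphere_points(n_points)

    tree = cKDTree(coords)
    rmax = radii.max()
    per_atom = np.zeros(len(atoms))
    for i in range(len(atoms)):
        pts = coords[i] + radii[i] * unit
        neighbors = [j for j in tree.query_ball_point(coords[i], radii[i] + rmax)
                     if j != i]
        if neighbors:
            nb = np.array(neighbors, dtype=int)
            # (n_points, n_neighbors) distance test against inflated spheres
            d2 = np.sum((pts[:, None, :] - coords[nb][None, :, :]) ** 2, axis=2)
            buried = np.any(d2 < (radii[nb] ** 2)[None, :], axis=1)
            exposed_frac = 1.0 - buried.mean()
        else:
            exposed_frac = 1.0
        per_atom[i] = exposed_frac * 4.0 * math.pi * radii[i] ** 2

    per_residue: dict = {}
    for a, area in zip(atoms, per_atom):
        per_residue[a.residue_key] = per_residue.get(a.residue_key, 0.0) + float(area)
    return SASAResult(
        per_atom_area=per_atom,
        per_residue_area=per_residue,
        total=float(per_atom.sum()),
        probe_radius=probe_radius,
        n_sphere_points=n_points,
        atom_keys=[a.atom_key for a in atoms],
    )


@dataclass
class HBond:
    donor: tuple
    acceptor: tuple
    distance: float
    angle: float | None
    donor_is_backbone: bool
    acceptor_is_backbone: bool


@dataclass
class SaltBridge:
    basic: tuple
    acidic: tuple
    distance: float


@dataclass
class InterfaceReport:
    per_residue_buried: dict
    per_residue_percent: dict
    per_residue_fraction: dict
    residue_side: dict
    total_buried_a: float
    total_buried_b: float
    hbonds: list
    salt_bridges: list
    probe_radius: float
    criteria: dict = field(default_factory=dict)


def _partition(s: Structure, side_a: Selection, side_b: Selection):
    ia = set(side_a.indices(s).tolist())
    ib = set(side_b.indices(s).tolist())
    ia = {i for i in ia if s.atoms[i].res_name not in WATER_NAMES}
    ib = {i for i in ib if s.atoms[i].res_name not in WATER_NAMES}
    if not ia or not ib:
        raise SelectionError("both interface sides must select at least one atom")
    overlap = ia & ib
    if overlap:
        raise SelectionError(
            f"interface sides overlap on {len(overlap)} atoms "
            f"(e.g. {s.atoms[next(iter(overlap))].atom_key})"
        )
    return sorted(ia), sorted(ib)


def buried_interface(complex_structure: Structure, side_a: Selection,
                     side_b: Selection, probe: float = DEFAULT_PROBE_RADIUS,
                     n_points: int = DEFAULT_N_POINTS) -> InterfaceReport:
    """Per-residue buried area (dASA) and percent burial across a partition.

    dASA = ASA of the residue in the isolated side minus ASA in the complex;
    small negative numerical noise is clamped to zero. Contribution fraction
    is the residue's share of its side's total buried area.
    """
    ia, ib = _partition(complex_structure, side_a, side_b)
    sub_a = Structure([complex_structure.atoms[i] for i in ia])
    sub_b = Structure([complex_structure.atoms[i] for i in ib])
    both = Structure([complex_structure.atoms[i] for i in sorted(set(ia) | set(ib))])

    sasa_a = sasa(sub_a, probe, n_points, include_hetero=True)
    sasa_b = sasa(sub_b, probe, n_points, include_hetero=True)
    sasa_ab = sasa(both, probe, n_points, include_hetero=True)

    side_of = {}
    for key in sasa_a.per_residue_area:
        side_of[key] = "A"
    for key in sasa_b.per_residue_area:
        side_of[key] = "B"

    buried, percent = {}, {}
    for key, iso in list(sasa_a.per_residue_area.items()) + list(
        sasa_b.per_residue_area.items()
    ):
        in_complex = sasa_ab.per_residue_area.get(key, 0.0)
        d = max(0.0, iso - in_complex)
        buried[key] = d
        percent[key] = 100.0 * d / iso if iso > 0 else 0.0

    total_a = sum(v for k, v in buried.items() if side_of[k] == "A")
    total_b = sum(v for k, v in buried.items() if side_of[k] == "B")
    fraction = {
        k: (v / total_a if side_of[k] == "A" and total_a > 0
            else v / total_b if side_of[k] == "B" and total_b > 0 else 0.0)
        for k, v in buried.items()
    }
    return InterfaceReport(
        per_residue_buried=buried,
        per_residue_percent=percent,
        per_residue_fraction=fraction,
        residue_side=side_of,
        total_buried_a=total_a,
        total_buried_b=total_b,
        hbonds=[],
        salt_bridges=[],
        probe_radius=probe,
        criteria={"n_points": n_points},
    )


def _donor_atoms(s: Structure, indices):
    """Yield (index, antecedent_index_or_None) for H-bond donor heavy atoms."""
    idx_map = s.atom_index()
    for i in indices:
        a = s.atoms[i]
        if a.res_name in WATER_NAMES:
            if a.element == "O":
                yield i, None
            continue
        if a.atom_name == "N" and a.res_name != "PRO" and not a.is_hetatm:
            ca = idx_map.get((a.chain_id, a.res_seq, a.insertion_code, "CA"))
            yield i, ca
            continue
        table = _SIDECHAIN_DONORS.get(a.res_name, {})
        if a.atom_name in table:
            ant = idx_map.get(
                (a.chain_id, a.res_seq, a.insertion_code, table[a.atom_name])
            )
            yield i, ant


def _acceptor_atoms(s: Structure, indices):
    for i in indices:
        a = s.atoms[i]
        if a.res_name in WATER_NAMES:
            if a.element == "O":
                yield i
            continue
        if a.atom_name in ("O", "OXT") and not a.is_hetatm:
            yield i
            continue
        if a.atom_name in _SIDECHAIN_ACCEPTORS.get(a.res_name, set()):
            yield i


def find_hbonds(s: Structure, side_a: Selection, side_b: Selection,
                d_max: float = 3.5, angle_min: float = 90.0,
                include_waters: bool = False) -> list[HBond]:
    """Inter-side hydrogen bonds under heavy-atom geometric criteria.

    A bond is a donor heavy atom (N/O/S bearing an implicit H) on one side
    and an acceptor (N/O/S) on the other, with distance <= ``d_max`` and,
    when the donor's antecedent atom is present, angle(antecedent, donor,
    acceptor) >= ``angle_min`` degrees. Sorted by distance; each unordered
    atom pair reported once.
    """
    def side_indices(sel):
        idx = sel.indices(s)
        return [i for i in idx
                if include_waters or s.atoms[i].res_name not in WATER_NAMES]

    ia, ib = side_indices(side_a), side_indices(side_b)
    coords = s.coords
    bonds = {}
    for src, dst in ((ia, ib), (ib, ia)):
        acceptors = list(_acceptor_atoms(s, dst))
        if not acceptors:
            continue
        acc_tree = cKDTree(coords[acceptors])
        for di, ant in _donor_atoms(s, src):
            hits = acc_tree.query_ball_point(coords[di], d_max)
            for h in hits:
                aj = acceptors[h]
                if s.atoms[di].residue_key == s.atoms[aj].residue_key:
                    continue
                dist = float(np.linalg.norm(coords[di] - coords[aj]))
                angle = None
                if ant is not None:
                    v1 = coords[ant] - coords[di]
                    v2 = coords[aj] - coords[di]
                    cosang = np.dot(v1, v2) / (
                        np.linalg.norm(v1) * np.linalg.norm(v2)
                    )
                    angle = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
                    if angle < angle_min:
                        continue
                pair = frozenset((di, aj))
                bond = HBond(
                    donor=s.atoms[di].atom_key,
                    acceptor=s.atoms[aj].atom_key,
                    distance=dist,
                    angle=angle,
                    donor_is_backbone=s.atoms[di].atom_name in ("N", "O", "OXT"),
                    acceptor_is_backbone=s.atoms[aj].atom_name in ("N", "O", "OXT"),
                )
                if pair not in bonds or bonds[pair].distance > dist:
                    bonds[pair] = bond
    return sorted(bonds.values(), key=lambda b: (b.distance, b.donor, b.acceptor))


def find_salt_bridges(s: Structure, side_a: Selection, side_b: Selection,
                      d_max: float = 4.0,
                      include_histidine: bool = False) -> list[SaltBridge]:
    """Inter-side basic-N / acidic-O pairs within ``d_max``, one bridge per
    residue pair (closest atom pair kept)."""
    basic_table = dict(_BASIC_ATOMS)
    if include_histidine:
        basic_table.update(_BASIC_ATOMS_HIS)

    def classify(indices):
        basics, acids = [], []
        for i in indices:
            a = s.atoms[i]
            if a.atom_name in basic_table.get(a.res_name, set()):
                basics.append(i)
            if a.atom_name in _ACIDIC_ATOMS.get(a.res_name, set()) or (
                a.atom_name == "OXT" and not a.is_hetatm
            ):
                acids.append(i)
        return basics, acids

    ia, ib = side_a.indices(s), side_b.indices(s)
    basics_a, acids_a = classify(ia)
    basics_b, acids_b = classify(ib)
    coords = s.coords
    best: dict = {}
    for basics, acids in ((basics_a, acids_b), (basics_b, acids_a)):
        for bi in basics:
            for aj in acids:
                dist = float(np.linalg.norm(coords[bi] - coords[aj]))
                if dist > d_max:
                    continue
                key = (s.atoms[bi].residue_key, s.atoms[aj].residue_key)
                bridge = SaltBridge(
                    basic=s.atoms[bi].atom_key,
                    acidic=s.atoms[aj].atom_key,
                    distance=dist,
                )
                if key not in best or best[key].distance > dist:
                    best[key] = bridge
    return sorted(best.values(), key=lambda b: (b.distance, b.basic, b.acidic))


def interface_report(complex_structure: Structure, side_a: Selection,
                     side_b: Selection, probe: float = DEFAULT_PROBE_RADIUS,
                     n_points: int = DEFAULT_N_POINTS, hbond_d_max: float = 3.5,
                     hbond_angle_min: float = 90.0, bridge_d_max: float = 4.0,
                     include_waters: bool = False) -> InterfaceReport:
    """Full interface table: burial + H-bonds + salt bridges with criteria."""
    report = buried_interface(complex_structure, side_a, side_b, probe, n_points)
    report.hbonds = find_hbonds(
        complex_structure, side_a, side_b, hbond_d_max, hbond_angle_min,
        include_waters=include_waters,
    )
    report.salt_bridges = find_salt_bridges(
        complex_structure, side_a, side_b, bridge_d_max
    )
    report.criteria.update(
        {
            "hbond_d_max": hbond_d_max,
            "hbond_angle_min": hbond_angle_min,
            "bridge_d_max": bridge_d_max,
            "probe_radius": probe,
        }
    )
    return report
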