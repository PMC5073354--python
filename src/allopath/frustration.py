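"""Decoy-based mutational local frustration and frustrated-contact paths.

Each residue-pair contact (Cbeta centers, Calpha for Gly) gets a frustration
index: the z-score of its native pair energy against decoy energies obtained
by re-assigning the two residues' identities at fixed geometry,

    F_ij = (<E_decoy> - E_native) / sd(E_decoy).

Sign convention: larger F means the native pair is more favorable than the
decoys (minimal frustration); strongly negative F means the native pair is
unfavorable (high frustration).

The pair potential is a simplified 20x20 statistical potential: burial of
hydrophobic surface (additive hydropathy term, so hydrophobic-hydrophobic
pairs are most favorable and polar-polar pairs cost energy) plus a formal
charge product (salt bridges favorable, like charges repulsive), modulated
by a smooth distance switch. It is shipped as data and fully deterministic;
it stands in for heavier knowledge-based energies — the decoy/z-score
machinery and the classification logic are independent of the table.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .errors import AllopathError, EmptyInputError
from .structio import Structure

AMINO_ACIDS_20 = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

# Kyte-Doolittle hydropathy (dimensionless) and formal side-chain charge.
_HYDROPATHY = {
    "ALA": 1.8, "ARG": -4.5, "ASN": -3.5, "ASP": -3.5, "CYS": 2.5,
    "GLN": -3.5, "GLU": -3.5, "GLY": -0.4, "HIS": -3.2, "ILE": 4.5,
    "LEU": 3.8, "LYS": -3.9, "MET": 1.9, "PHE": 2.8, "PRO": -1.6,
    "SER": -0.8, "THR": -0.7, "TRP": -0.9, "TYR": -1.3, "VAL": 4.2,
}
_CHARGE = {"ARG": 1.0, "LYS": 1.0, "HIS": 0.5, "ASP": -1.0, "GLU": -1.0}

_HSCALE = 4.5          # normalizes hydropathy to [-1, 1]
_ELEC_WEIGHT = 1.5

DEFAULT_CUTOFF = 9.5
DEFAULT_MIN_SEQ_SEP = 3
SWITCH_INNER = 6.5
SWITCH_OUTER = 10.0
MINIMAL_THRESHOLD = 0.78
HIGH_THRESHOLD = -1.0
DEFAULT_N_DECOYS = 1000

_AA_INDEX = {name: i for i, name in enumerate(AMINO_ACIDS_20)}


def _build_pair_table() -> np.ndarray:
    h = np.array([_HYDROPATHY[a] / _HSCALE for a in AMINO_ACIDS_20])
    q = np.array([_CHARGE.get(a, 0.0) for a in AMINO_ACIDS_20])
    # E(a, b) = -(h_a + h_b)/2 + w_e * q_a * q_b  (model units)
    return -0.5 * (h[:, None] + h[None, :]) + _ELEC_WEIGHT * np.outer(q, q)


#: 20x20 symmetric pair-energy table (model units) at full switch weight.
PAIR_ENERGY_TABLE = _build_pair_table()


def distance_switch(distance: float) -> float:
    """Smooth well: 1 inside SWITCH_INNER, cosine ramp to 0 at SWITCH_OUTER."""
    if distance <= SWITCH_INNER:
        return 1.0
    if distance >= SWITCH_OUTER:
        return 0.0
    x = (distance - SWITCH_INNER) / (SWITCH_OUTER - SWITCH_INNER)
    return 0.5 * (1.0 + np.cos(np.pi * x))


def contact_energy(res_i: str, res_j: str, distance: float) -> float:
    """Pairwise potential value, distance-modulated. Symmetric in (i, j)."""
    try:
        a, b = _AA_INDEX[res_i.upper()], _AA_INDEX[res_j.upper()]
    except KeyError as bad:
        raise KeyError(f"unknown residue type {bad}") from None
    return float(PAIR_ENERGY_TABLE[a, b] * distance_switch(distance))


@dataclass
class Contact:
    key_i: tuple
    key_j: tuple
    res_name_i: str
    res_name_j: str
    distance: float
    native_energy: float


@dataclass
class FrustratedContact:
    contact: Contact
    frustration_index: float      # NaN when decoys are degenerate
    frustration_class: str        # minimal | neutral | high


@dataclass
class FrustrationNetwork:
    contacts: list
    minimal_threshold: float
    high_threshold: float
    n_decoys: int | None          # None = exhaustive enumeration
    seed: int | None

    def class_fractions(self) -> dict:
        total = len(self.contacts)
        out = {"minimal": 0, "neutral": 0, "high": 0}
        for fc in self.contacts:
            out[fc.frustration_class] += 1
        return {k: (v / total if total else 0.0) for k, v in out.items()}


def _interaction_centers(s: Structure):
    """One center per residue: Cbeta, Calpha for Gly (Calpha fallback)."""
    centers = []
    for key, res_name, atoms in s.residues():
        if any(a.is_hetatm for a in atoms) and res_name not in AMINO_ACIDS_20:
            continue
        if res_name not in _AA_INDEX:
            continue
        by_name = {a.atom_name: a for a in atoms}
        atom = None
        if res_name != "GLY" and "CB" in by_name:
            atom = by_name["CB"]
        elif "CA" in by_name:
            atom = by_name["CA"]
        if atom is not None:
            centers.append((key, res_name, atom.coords))
    if len(centers) < 2:
        raise EmptyInputError("fewer than 2 usable residues for contacts")
    return centers


def build_contacts(s: Structure, cutoff: float = DEFAULT_CUTOFF,
                   min_seq_sep: int = DEFAULT_MIN_SEQ_SEP) -> list[Contact]:
    """All residue pairs with center distance <= cutoff and sequence
    separation >= ``min_seq_sep`` (inter-chain pairs always pass)."""
    centers = _interaction_centers(s)
    coords = np.array([c[2] for c in centers])
    tree = cKDTree(coords)
    contacts = []
    for i, j in sorted(tree.query_pairs(cutoff)):
        key_i, name_i, _ = centers[i]
        key_j, name_j, _ = centers[j]
        if key_i[0] == key_j[0] and abs(key_i[1] - key_j[1]) < min_seq_sep:
            continue
        d = float(np.linalg.norm(coords[i] - coords[j]))
        contacts.append(
            Contact(
                key_i=key_i, key_j=key_j,
                res_name_i=name_i, res_name_j=name_j,
                distance=d,
                native_energy=contact_energy(name_i, name_j, d),
            )
        )
    return contacts


def _decoy_energies(contact: Contact, n_decoys: int | None, rng) -> np.ndarray:
    w = distance_switch(contact.distance)
    if n_decoys is None:
        # exhaustive: all 400 ordered identity pairs, equally weighted
        return (PAIR_ENERGY_TABLE * w).ravel()
    if n_decoys < 100:
        raise ValueError("n_decoys must be >= 100 (or None for exhaustive)")
    ia = rng.integers(0, 20, size=n_decoys)
    ib = rng.integers(0, 20, size=n_decoys)
    return PAIR_ENERGY_TABLE[ia, ib] * w


def mutational_frustration(contact: Contact, n_decoys: int | None = DEFAULT_N_DECOYS,
                           seed: int | None = 0, rng=None) -> float:
    """Frustration index of one contact; NaN when the decoy set is degenerate.

    Decoys re-assign both residues' identities uniformly over the 20 types at
    fixed geometry. ``n_decoys=None`` enumerates all 400 identity pairs
    exactly instead of sampling.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    energies = _decoy_energies(contact, n_decoys, rng)
    sd = float(energies.std())
    if sd == 0.0:
        return float("nan")
    return float((energies.mean() - contact.native_energy) / sd)


def classify(f_index: float, minimal_threshold: float = MINIMAL_THRESHOLD,
             high_threshold: float = HIGH_THRESHOLD) -> str:
    """Map an index to minimal / neutral / high; NaN (degenerate) is neutral."""
    if np.isnan(f_index):
        return "neutral"
    if f_index >= minimal_threshold:
        return "minimal"
    if f_index <= high_threshold:
        return "high"
    return "neutral"


def compute_network(s: Structure, cutoff: float = DEFAULT_CUTOFF,
                    min_seq_sep: int = DEFAULT_MIN_SEQ_SEP,
                    n_decoys: int | None = DEFAULT_N_DECOYS, seed: int = 1,
                    minimal_threshold: float = MINIMAL_THRESHOLD,
                    high_threshold: float = HIGH_THRESHOLD) -> FrustrationNetwork:
    """Contacts -> frustration indices -> classes, under one seeded RNG."""
    contacts = build_contacts(s, cutoff, min_seq_sep)
    rng = np.random.default_rng(seed)
    scored = []
    degenerate = 0
    for contact in contacts:
        f = mutational_frustration(contact, n_decoys, rng=rng)
        if np.isnan(f):
            degenerate += 1
        scored.append(
            FrustratedContact(
                contact=contact,
                frustration_index=f,
                frustration_class=classify(f, minimal_threshold, high_threshold),
            )
        )
    if degenerate:
        import warnings

        warnings.warn(
            f"{degenerate} contacts had zero decoy variance; reported neutral",
            stacklevel=2,
        )
    return FrustrationNetwork(
        contacts=scored,
        minimal_threshold=minimal_threshold,
        high_threshold=high_threshold,
        n_decoys=n_decoys,
        seed=seed,
    )


@dataclass
class PathResult:
    found: bool
    residues: list = field(default_factory=list)
    n_edges: int = 0
    total_abs_f: float = 0.0


def _resolve_site(net: FrustrationNetwork, site) -> set:
    """A site is a set of residue keys and/or bare residue numbers."""
    if not site:
        raise EmptyInputError("empty site set")
    all_keys = set()
    for fc in net.contacts:
        all_keys.add(fc.contact.key_i)
        all_keys.add(fc.contact.key_j)
    resolved = set()
    for item in site:
        if isinstance(item, tuple):
            if item in all_keys:
                resolved.add(item)
        else:
            resolved.update(k for k in all_keys if k[1] == int(item))
    return resolved


def frustration_path(net: FrustrationNetwork, site_a, site_b) -> PathResult:
    """Shortest path through highly frustrated contacts linking two sites.

    Fewest edges wins; among equally short paths the one with the largest
    summed |F| is returned (the "most frustrated" shortest route).
    """
    keys_a = _resolve_site(net, site_a)
    keys_b = _resolve_site(net, site_b)
    graph = nx.Graph()
    for fc in net.contacts:
        if fc.frustration_class == "high":
            graph.add_edge(
                fc.contact.key_i, fc.contact.key_j,
                abs_f=abs(fc.frustration_index),
            )
    keys_a &= set(graph.nodes)
    keys_b &= set(graph.nodes)
    if not keys_a or not keys_b:
        return PathResult(found=False)

    best = None
    for a, b in itertools.product(sorted(keys_a), sorted(keys_b)):
        if not nx.has_path(graph, a, b):
            continue
        for path in nx.all_shortest_paths(graph, a, b):
            weight = sum(
                graph.edges[u, v]["abs_f"] for u, v in zip(path, path[1:])
            )
            candidate = (len(path) - 1, -weight, path)
            if best is None or candidate < best:
                best = candidate
    if best is None:
        return PathResult(found=False)
    n_edges, neg_weight, path = best
    return PathResult(found=True, residues=path, n_edges=n_edges,
                      total_abs_f=-neg_weight)
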