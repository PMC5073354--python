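"""Structure/ensemble I/O, atom selection, superposition and basic metrics.

The atom container is deliberately simple: an ordered list of
:class:`AtomRecord` grouped contiguously by residue, mirroring the layout of
a PDB file. Coordinates are materialized as an ``(N, 3)`` float array on
demand. Residue identity is the triple ``(chain_id, res_seq,
insertion_code)`` and residue numbering is always taken verbatim from the
file — no implicit renumbering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    AtomMismatchError,
    EmptyInputError,
    PDBParseError,
    SelectionError,
)

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: Standard amino acids (3-letter) recognised as protein residues.
AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

ALTLOC_POLICIES = ("highest-occupancy", "keep-all", "specific-label")


@dataclass
class AtomRecord:
    """One ATOM/HETATM record."""

    chain_id: str
    res_seq: int
    res_name: str
    atom_name: str
    element: str
    coords: np.ndarray
    b_factor: float = 0.0
    occupancy: float = 1.0
    altloc: str = ""
    insertion_code: str = ""
    is_hetatm: bool = False
    serial: int = 0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError("coords must be a 3-vector")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")
        if self.b_factor < 0:
            raise ValueError(f"negative B-factor {self.b_factor}")

    @property
    def residue_key(self) -> tuple:
        return (self.chain_id, self.res_seq, self.insertion_code)

    @property
    def atom_key(self) -> tuple:
        return (self.chain_id, self.res_seq, self.insertion_code, self.atom_name)

    def copy(self) -> "AtomRecord":
        return replace(self, coords=self.coords.copy())


class Structure:
    """Ordered atom container; the unit every analysis consumes."""

    def __init__(self, atoms, metadata=None):
        self.atoms: list[AtomRecord] = list(atoms)
        self.metadata: dict = dict(metadata or {})

    def __len__(self):
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float).reshape(-1, 3)

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError(f"coordinate array shape {xyz.shape} != ({len(self.atoms)}, 3)")
        for atom, row in zip(self.atoms, xyz):
            atom.coords = row.copy()

    def copy(self) -> "Structure":
        return Structure([a.copy() for a in self.atoms], dict(self.metadata))

    def select(self, sel: "Selection") -> "Structure":
        idx = sel.indices(self)
        return Structure([self.atoms[i] for i in idx], dict(self.metadata))

    def residues(self):
        """Yield ``(residue_key, res_name, [atoms])`` in file order."""
        current_key, group = None, []
        for atom in self.atoms:
            key = atom.residue_key
            if key != current_key:
                if group:
                    yield current_key, group[0].res_name, group
                current_key, group = key, []
            group.append(atom)
        if group:
            yield current_key, group[0].res_name, group

    def residue_keys(self):
        return [key for key, _, _ in self.residues()]

    def atom_index(self) -> dict:
        """Map (chain, res_seq, icode, atom_name) -> position; altloc-unique input assumed."""
        out = {}
        for i, a in enumerate(self.atoms):
            out.setdefault(a.atom_key, i)
        return out


class Ensemble:
    """Conformations sharing one topology (stand-in for MD snapshots)."""

    def __init__(self, topology: Structure, frames):
        self.topology = topology
        self.frames = [np.asarray(f, dtype=float) for f in frames]
        if not self.frames:
            raise EmptyInputError("an ensemble needs at least one frame")
        n = len(topology)
        for k, f in enumerate(self.frames):
            if f.shape != (n, 3):
                raise ValueError(
                    f"frame {k} has shape {f.shape}, topology has {n} atoms"
                )

    def __len__(self):
        return len(self.frames)

    def frame_structure(self, i: int) -> Structure:
        s = self.topology.copy()
        s.set_coords(self.frames[i])
        s.metadata["model"] = str(i + 1)
        return s


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

class Selection:
    """Composable atom predicate. Application preserves atom order."""

    def __init__(self, predicate, label="custom"):
        self._predicate = predicate
        self.label = label

    def __call__(self, atom: AtomRecord) -> bool:
        return bool(self._predicate(atom))

    def __and__(self, other: "Selection") -> "Selection":
        return Selection(lambda a: self(a) and other(a), f"({self.label} and {other.label})")

    def __or__(self, other: "Selection") -> "Selection":
        return Selection(lambda a: self(a) or other(a), f"({self.label} or {other.label})")

    def __invert__(self) -> "Selection":
        return Selection(lambda a: not self(a), f"(not {self.label})")

    def indices(self, s: Structure) -> np.ndarray:
        return np.array([i for i, a in enumerate(s.atoms) if self(a)], dtype=int)

    def require(self, s: Structure) -> np.ndarray:
        idx = self.indices(s)
        if idx.size == 0:
            raise SelectionError(f"selection {self.label!r} matched no atoms")
        return idx

    # -- constructors -------------------------------------------------------

    @staticmethod
    def all():
        return Selection(lambda a: True, "all")

    @staticmethod
    def chain(*chain_ids):
        ids = set(chain_ids)
        return Selection(lambda a: a.chain_id in ids, f"chain {','.join(sorted(ids))}")

    @staticmethod
    def atom_names(*names):
        nm = set(names)
        return Selection(lambda a: a.atom_name in nm, f"name {','.join(sorted(nm))}")

    @staticmethod
    def backbone():
        return Selection(
            lambda a: a.atom_name in BACKBONE_ATOMS and not a.is_hetatm, "backbone"
        )

    @staticmethod
    def calpha():
        return Selection(lambda a: a.atom_name == "CA" and not a.is_hetatm, "calpha")

    @staticmethod
    def protein():
        return Selection(
            lambda a: not a.is_hetatm and a.res_name in AMINO_ACIDS
            and a.res_name not in WATER_NAMES,
            "protein",
        )

    @staticmethod
    def hetero():
        return Selection(lambda a: a.is_hetatm, "hetero")

    @staticmethod
    def water():
        return Selection(lambda a: a.res_name in WATER_NAMES, "water")

    @staticmethod
    def resid_range(start, end, chain_id=None):
        def pred(a):
            if chain_id is not None and a.chain_id != chain_id:
                return False
            return start <= a.res_seq <= end

        where = f" chain {chain_id}" if chain_id else ""
        return Selection(pred, f"resi {start}-{end}{where}")

    @staticmethod
    def residues(keys):
        keyset = set(keys)
        return Selection(lambda a: a.residue_key in keyset, f"residues[{len(keyset)}]")

    @staticmethod
    def parse(expression: str) -> "Selection":
        """Parse a small selection language: terms joined by ``and``.

        Terms: ``all``, ``backbone``, ``calpha``, ``protein``, ``hetero``,
        ``water``, ``chain A[,B]``, ``resi 10-20`` or ``resi 57``,
        ``name CA[,CB]``. ``not`` may prefix any term.
        """
        expression = expression.strip()
        if not expression:
            raise SelectionError("empty selection expression")
        result = None
        for clause in expression.split(" and "):
            tokens = clause.split()
            negate = False
            if tokens and tokens[0] == "not":
                negate = True
                tokens = tokens[1:]
            if not tokens:
                raise SelectionError(f"malformed clause in {expression!r}")
            head, rest = tokens[0].lower(), tokens[1:]
            simple = {
                "all": Selection.all,
                "backbone": Selection.backbone,
                "calpha": Selection.calpha,
                "protein": Selection.protein,
                "hetero": Selection.hetero,
                "water": Selection.water,
            }
            if head in simple and not rest:
                term = simple[head]()
            elif head == "chain" and len(rest) == 1:
                term = Selection.chain(*rest[0].split(","))
            elif head == "name" and len(rest) == 1:
                term = Selection.atom_names(*rest[0].split(","))
            elif head == "resi" and len(rest) == 1:
                spec = rest[0]
                if "-" in spec.lstrip("-"):
                    lo, hi = spec.rsplit("-", 1)
                    term = Selection.resid_range(int(lo), int(hi))
                else:
                    term = Selection.resid_range(int(spec), int(spec))
            else:
                raise SelectionError(f"cannot parse selection clause {clause!r}")
            if negate:
                term = ~term
            result = term if result is None else (result & term)
        return result


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    if len(line.rstrip("\n")) < 54:
        raise PDBParseError("ATOM/HETATM record shorter than 54 columns", lineno)
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16].strip()
        res_name = line[17:20].strip()
        chain_id = line[21].strip()
        res_seq = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ = float(line[54:60]) if line[54:60].strip() else 1.0
        b = float(line[60:66]) if line[60:66].strip() else 0.0
        element = line[76:78].strip() if len(line) >= 78 else ""
    except ValueError as exc:
        raise PDBParseError(f"malformed ATOM/HETATM record ({exc})", lineno) from None
    if not element:
        # PDB convention: element right-justified in the name field
        element = "".join(c for c in name if c.isalpha())[:1]
    return AtomRecord(
        chain_id=chain_id,
        res_seq=res_seq,
        res_name=res_name,
        atom_name=name,
        element=element.upper(),
        coords=np.array([x, y, z]),
        b_factor=max(b, 0.0),
        occupancy=min(max(occ, 0.0), 1.0),
        altloc=altloc,
        insertion_code=icode,
        is_hetatm=line.startswith("HETATM"),
        serial=serial,
    )


def _resolve_altlocs(atoms, policy, label):
    if policy == "keep-all":
        return atoms
    best = {}
    order = []
    for atom in atoms:
        key = (*atom.atom_key, atom.res_name)
        if policy == "specific-label":
            if atom.altloc and atom.altloc != label:
                continue
            if key not in best:
                best[key] = atom
                order.append(key)
            continue
        # highest occupancy; ties broken by altloc label order ('A' first)
        if key not in best:
            best[key] = atom
            order.append(key)
        else:
            held = best[key]
            if (atom.occupancy, -ord(atom.altloc or "~")) > (
                held.occupancy,
                -ord(held.altloc or "~"),
            ):
                best[key] = atom
    return [best[k] for k in order]


def read_pdb(path, altloc_policy: str = "highest-occupancy", altloc_label: str = "A"):
    """Read a PDB file; return a :class:`Structure`, or an :class:`Ensemble`
    when more than one MODEL is present.

    HETATM records are retained with ``is_hetatm=True`` (bound metals must
    survive). Altloc duplicates are resolved per ``altloc_policy``.
    """
    if altloc_policy not in ALTLOC_POLICIES:
        raise ValueError(
            f"altloc_policy must be one of {ALTLOC_POLICIES}, got {altloc_policy!r}"
        )
    models: list[list[AtomRecord]] = []
    current: list[AtomRecord] = []
    in_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec in ("ATOM  ", "HETATM"):
                current.append(_parse_atom_line(line, lineno))
            elif rec.startswith("MODEL"):
                if current and not in_model:
                    models.append(current)
                    current = []
                in_model = True
            elif rec.startswith("ENDMDL"):
                models.append(current)
                current = []
                in_model = False
    if current:
        models.append(current)
    models = [m for m in models if m]
    if not models:
        raise EmptyInputError(f"{path}: no ATOM/HETATM records found")

    models = [_resolve_altlocs(m, altloc_policy, altloc_label) for m in models]
    meta = {"source": str(path)}
    if len(models) == 1:
        return Structure(models[0], meta)
    topo = Structure(models[0], meta)
    n = len(topo)
    for k, m in enumerate(models[1:], start=2):
        if len(m) != n:
            raise PDBParseError(
                f"MODEL {k} has {len(m)} atoms but MODEL 1 has {n}; "
                "multi-model files must share one topology"
            )
    return Ensemble(topo, [Structure(m).coords for m in models])


def _format_atom_line(atom: AtomRecord, serial: int) -> str:
    name = atom.atom_name
    # standard PDB alignment: 1-char elements start in column 14
    if len(name) < 4 and len(atom.element) == 1:
        name = " " + name
    record = "HETATM" if atom.is_hetatm else "ATOM  "
    return (
        f"{record}{serial:>5d} {name:<4s}{atom.altloc or ' ':1s}"
        f"{atom.res_name:>3s} {atom.chain_id or ' ':1s}{atom.res_seq:>4d}"
        f"{atom.insertion_code or ' ':1s}   "
        f"{atom.coords[0]:8.3f}{atom.coords[1]:8.3f}{atom.coords[2]:8.3f}"
        f"{atom.occupancy:6.2f}{atom.b_factor:6.2f}          "
        f"{atom.element:>2s}"
    )


def write_pdb(obj, path) -> None:
    """Write a Structure or Ensemble as (multi-model) PDB text."""
    with open(path, "w") as fh:
        if isinstance(obj, Ensemble):
            for k, frame in enumerate(obj.frames, start=1):
                fh.write(f"MODEL     {k:>4d}\n")
                s = obj.topology
                for serial, (atom, row) in enumerate(zip(s.atoms, frame), start=1):
                    shifted = replace(atom, coords=np.asarray(row, dtype=float))
                    fh.write(_format_atom_line(shifted, serial) + "\n")
                fh.write("ENDMDL\n")
        else:
            for serial, atom in enumerate(obj.atoms, start=1):
                fh.write(_format_atom_line(atom, serial) + "\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Superposition and metrics
# ---------------------------------------------------------------------------

def kabsch_superpose(mobile, target, weights=None):
    """Optimal weighted rigid superposition of ``mobile`` onto ``target``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimizes the weighted RMSD to
    ``target``. The rotation is proper (det +1); reflections are disallowed.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape:
        raise ValueError(f"point-count mismatch: {mobile.shape} vs {target.shape}")
    if mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("expected (N, 3) coordinate arrays")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("at least 3 points are required for superposition")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,):
            raise ValueError("weights must be a length-N vector")
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()

    mu_m = w @ mobile
    mu_t = w @ target
    xm = mobile - mu_m
    xt = target - mu_t
    h = (xm * w[:, None]).T @ xt
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = mu_t - rotation @ mu_m
    moved = mobile @ rotation.T + translation
    rmsd = float(np.sqrt(np.sum(w * np.sum((moved - target) ** 2, axis=1))))
    return rotation, translation, rmsd


def apply_transform(coords, rotation, translation):
    return np.asarray(coords, dtype=float) @ np.asarray(rotation).T + np.asarray(translation)


def match_atoms(a: Structure, b: Structure, sel: Selection | None = None,
                allow_unmatched: bool = False):
    """Pair atoms of two structures by (chain, res_seq, icode, atom_name).

    Returns index arrays ``(idx_a, idx_b)`` in the order of ``a``. Unmatched
    atoms raise :class:`AtomMismatchError` with a pairing report unless
    ``allow_unmatched`` is set.
    """
    sel = sel or Selection.all()
    ia = sel.indices(a)
    ib = sel.indices(b)
    keys_a = [a.atoms[i].atom_key for i in ia]
    keys_b = [b.atoms[i].atom_key for i in ib]
    map_b = {}
    for k, i in zip(keys_b, ib):
        map_b.setdefault(k, i)
    set_a = set(keys_a)
    only_a = [k for k in keys_a if k not in map_b]
    only_b = [k for k in keys_b if k not in set_a]
    if (only_a or only_b) and not allow_unmatched:
        raise AtomMismatchError(
            "structures do not share identical atom sets under the selection",
            only_in_a=only_a,
            only_in_b=only_b,
        )
    idx_a, idx_b = [], []
    for k, i in zip(keys_a, ia):
        j = map_b.get(k)
        if j is not None:
            idx_a.append(i)
            idx_b.append(j)
    if not idx_a:
        raise AtomMismatchError("no atoms could be paired under the selection")
    return np.array(idx_a, dtype=int), np.array(idx_b, dtype=int)


def rmsd_between(a: Structure, b: Structure, sel: Selection | None = None,
                 superpose: bool = True, allow_unmatched: bool = False) -> float:
    """RMSD between matched atoms of two structures, optionally after Kabsch."""
    idx_a, idx_b = match_atoms(a, b, sel, allow_unmatched=allow_unmatched)
    xa = a.coords[idx_a]
    xb = b.coords[idx_b]
    if superpose:
        _, _, rmsd = kabsch_superpose(xa, xb)
        return rmsd
    return float(np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=1))))


@dataclass
class BFactorStats:
    mean: float
    sd: float
    per_atom: np.ndarray
    per_residue: dict
    normalized: bool


def bfactor_stats(s: Structure, sel: Selection | None = None,
                  normalize: bool = False) -> BFactorStats:
    """Mean (and optionally z-scored) B-factors over a selection.

    Normalization is within-structure: z = (B - mean) / sd over the selected
    atoms. Per-residue values are means over each residue's selected atoms.
    """
    sel = sel or Selection.all()
    idx = sel.require(s)
    b = np.array([s.atoms[i].b_factor for i in idx], dtype=float)
    mean = float(b.mean())
    sd = float(b.std())
    values = b
    if normalize:
        if b.size < 2 or sd == 0.0:
            raise ValueError("cannot normalize B-factors with zero variance")
        values = (b - mean) / sd
    per_res: dict = {}
    for v, i in zip(values, idx):
        per_res.setdefault(s.atoms[i].residue_key, []).append(v)
    per_res = {k: float(np.mean(v)) for k, v in per_res.items()}
    return BFactorStats(mean=mean, sd=sd, per_atom=values,
                        per_residue=per_res, normalized=normalize)
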