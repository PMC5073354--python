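"""Calpha anisotropic elastic-network normal modes and derived quantities.

The Hessian is the standard anisotropic network model: for each node pair
within the cutoff, the off-diagonal 3x3 superelement is
``-gamma * (r_ij outer r_ij) / |r_ij|^2`` and diagonal superelements are the
negative sum of the row's off-diagonals. A connected network has exactly six
zero eigenvalues (rigid-body motions). Mode numbering includes those six, so
the first internal mode is mode 7 and "mode 8" is the second internal mode.

Derived quantities: per-node mean-square fluctuations (inverse-eigenvalue
weighted), cumulative variance fractions, projection of superposed ensemble
frames onto selected eigenvectors, per-mode population-shift statistics
between two projected ensembles, and the mode-reconstructed dynamical
cross-correlation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.linalg import eigh
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .errors import AllopathError, DisconnectedNetworkError
from .structio import (
    Ensemble,
    Selection,
    Structure,
    apply_transform,
    kabsch_superpose,
)

DEFAULT_CUTOFF = 15.0
DEFAULT_GAMMA = 1.0
N_RIGID_BODY = 6
ZERO_TOL = 1e-8


@dataclass
class Hessian:
    matrix: np.ndarray            # (3N, 3N)
    node_keys: list               # residue keys of the Calpha nodes
    node_coords: np.ndarray       # (N, 3) reference coordinates
    cutoff: float
    gamma: float


@dataclass
class ModeSet:
    node_keys: list
    node_coords: np.ndarray
    eigenvalues: np.ndarray       # ascending, length M
    eigenvectors: np.ndarray      # (3N, M), orthonormal columns
    n_zero: int
    cutoff: float
    gamma: float

    @property
    def n_nodes(self) -> int:
        return len(self.node_keys)

    @property
    def internal_indices(self) -> np.ndarray:
        """Column indices of internal (non-rigid-body) modes."""
        return np.arange(self.n_zero, len(self.eigenvalues))

    def mode_column(self, mode_number: int) -> int:
        """1-based mode number (rigid-body modes included) -> column index."""
        if not 1 <= mode_number <= len(self.eigenvalues):
            raise IndexError(f"mode {mode_number} out of range")
        return mode_number - 1

    def eigenvector(self, mode_number: int) -> np.ndarray:
        return self.eigenvectors[:, self.mode_column(mode_number)]


@dataclass
class ProjectionSet:
    mode_numbers: list            # 1-based, rigid-body modes counted
    coordinates: np.ndarray       # (frames, modes)


@dataclass
class ModeShift:
    mode_number: int
    mean_apo: float
    mean_holo: float
    mean_shift: float
    effect_size: float
    p_value: float


@dataclass
class DCCMatrix:
    node_keys: list
    matrix: np.ndarray
    n_modes: int


def _calpha_nodes(s: Structure):
    idx = Selection.calpha().indices(s)
    if idx.size == 0:  # Calpha-only synthetic nodes may be plain atoms
        idx = Selection.atom_names("CA").indices(s)
    if idx.size < 2:
        raise AllopathError(f"need >= 2 Calpha nodes, found {idx.size}")
    keys = [s.atoms[i].residue_key for i in idx]
    return keys, s.coords[idx]


def build_enm(s: Structure, cutoff: float = DEFAULT_CUTOFF,
              gamma: float = DEFAULT_GAMMA) -> Hessian:
    """Assemble the 3Nx3N anisotropic-network Hessian over Calpha nodes."""
    keys, coords = _calpha_nodes(s)
    n = len(keys)
    tree = cKDTree(coords)
    pairs = sorted(tree.query_pairs(cutoff))
    adjacency = np.zeros((n, n), dtype=bool)
    h = np.zeros((3 * n, 3 * n))
    for i, j in pairs:
        rij = coords[j] - coords[i]
        d2 = float(rij @ rij)
        if d2 == 0.0:
            raise AllopathError(f"coincident nodes {keys[i]} and {keys[j]}")
        block = -gamma * np.outer(rij, rij) / d2
        h[3 * i:3 * i + 3, 3 * j:3 * j + 3] = block
        h[3 * j:3 * j + 3, 3 * i:3 * i + 3] = block
        h[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= block
        h[3 * j:3 * j + 3, 3 * j:3 * j + 3] -= block
        adjacency[i, j] = adjacency[j, i] = True
    n_comp, labels = connected_components(adjacency, directed=False)
    if n_comp > 1:
        comps = [np.flatnonzero(labels == c).tolist() for c in range(n_comp)]
        raise DisconnectedNetworkError(
            [[keys[i] for i in comp] for comp in comps]
        )
    return Hessian(matrix=h, node_keys=keys, node_coords=coords,
                   cutoff=cutoff, gamma=gamma)


def diagonalize(h: Hessian, n_modes: int = 100) -> ModeSet:
    """Lowest ``n_modes`` eigenpairs (rigid-body modes included in the count).

    Exactly six near-zero eigenvalues are expected for a connected network;
    a different count raises, since every downstream quantity assumes it.
    """
    dim = h.matrix.shape[0]
    if n_modes > dim:
        raise ValueError(f"n_modes {n_modes} exceeds 3N = {dim}")
    if not np.allclose(h.matrix, h.matrix.T, atol=1e-10):
        raise AllopathError("Hessian is not symmetric")
    n_request = min(dim, max(n_modes, N_RIGID_BODY + 1))
    eigenvalues, eigenvectors = eigh(
        h.matrix, subset_by_index=(0, n_request - 1)
    )
    scale = max(abs(eigenvalues[-1]), 1.0)
    n_zero = int(np.sum(np.abs(eigenvalues) < ZERO_TOL * scale))
    if n_zero != N_RIGID_BODY:
        raise AllopathError(
            f"expected {N_RIGID_BODY} near-zero modes, found {n_zero}; "
            "network may be degenerate"
        )
    eigenvalues = eigenvalues[:n_modes]
    eigenvectors = eigenvectors[:, :n_modes]
    return ModeSet(
        node_keys=h.node_keys,
        node_coords=h.node_coords,
        eigenvalues=eigenvalues,
        eigenvectors=eigenvectors,
        n_zero=n_zero,
        cutoff=h.cutoff,
        gamma=h.gamma,
    )


def compute_modes(s: Structure, cutoff: float = DEFAULT_CUTOFF,
                  gamma: float = DEFAULT_GAMMA,
                  n_modes: int | None = None) -> ModeSet:
    """Convenience: build the network and return its lowest modes
    (all 3N when ``n_modes`` is None, clamped to 3N otherwise)."""
    h = build_enm(s, cutoff, gamma)
    dim = h.matrix.shape[0]
    n = dim if n_modes is None else min(n_modes, dim)
    return diagonalize(h, n_modes=n)


def variance_fraction(m: ModeSet, k: int, weighting: str = "thermal") -> float:
    """Fraction of total fluctuation carried by the first ``k`` internal modes.

    ``thermal`` weights each mode by 1/eigenvalue (classical amplitude);
    ``equal`` counts modes uniformly.
    """
    internal = m.eigenvalues[m.n_zero:]
    if k < 0 or k > internal.size:
        raise ValueError(f"k must be in [0, {internal.size}]")
    if k == 0:
        return 0.0
    if weighting == "thermal":
        weights = 1.0 / internal
    elif weighting == "equal":
        weights = np.ones_like(internal)
    else:
        raise ValueError("weighting must be 'thermal' or 'equal'")
    return float(weights[:k].sum() / weights.sum())


def mode_fluctuations(m: ModeSet, n_modes: int | None = None) -> np.ndarray:
    """Per-node mean-square fluctuation from the first ``n_modes`` internal modes.

    MSF_i = sum_k |v_k(i)|^2 / lambda_k. Rigid-body modes never contribute.
    """
    internal = m.internal_indices
    if n_modes is not None:
        if n_modes < 1:
            raise ValueError("n_modes must be >= 1")
        internal = internal[:n_modes]
    if internal.size == 0:
        raise AllopathError("no internal modes available")
    vec = m.eigenvectors[:, internal].reshape(m.n_nodes, 3, internal.size)
    lam = m.eigenvalues[internal]
    return np.einsum("nxk,nxk->nk", vec, vec) @ (1.0 / lam)


def _superpose_frames(frames, reference_coords, fit_idx):
    aligned = []
    for f in frames:
        rot, trans, _ = kabsch_superpose(f[fit_idx], reference_coords[fit_idx])
        aligned.append(apply_transform(f, rot, trans))
    return aligned


def project_ensemble(e: Ensemble, m: ModeSet, mode_numbers,
                     reference: Structure | None = None,
                     superpose: bool = True) -> ProjectionSet:
    """Project each frame's displacement from the reference onto eigenvectors.

    The ensemble topology must contain every mode node (matched by residue
    key, Calpha atom). Frames are Kabsch-superposed onto the reference node
    coordinates first, removing rigid-body content.
    """
    mode_numbers = list(mode_numbers)
    topo = e.topology
    node_pos = {}
    for i, atom in enumerate(topo.atoms):
        if atom.atom_name == "CA":
            node_pos.setdefault(atom.residue_key, i)
    try:
        idx = np.array([node_pos[k] for k in m.node_keys], dtype=int)
    except KeyError as missing:
        raise AllopathError(
            f"ensemble topology lacks a Calpha node for residue {missing}"
        ) from None
    ref_coords = m.node_coords if reference is None else (
        reference.coords[Selection.calpha().indices(reference)]
    )
    if ref_coords.shape != (m.n_nodes, 3):
        raise AllopathError("reference does not map onto the mode nodes")
    frames = [np.asarray(f, float)[idx] for f in e.frames]
    if superpose:
        frames = _superpose_frames(frames, ref_coords, np.arange(m.n_nodes))
    cols = [m.mode_column(num) for num in mode_numbers]
    vectors = m.eigenvectors[:, cols]          # (3N, M)
    coords = np.empty((len(frames), len(cols)))
    for f, frame in enumerate(frames):
        disp = (frame - ref_coords).ravel()
        coords[f] = disp @ vectors
    return ProjectionSet(mode_numbers=mode_numbers, coordinates=coords)


def population_shift(p_apo: ProjectionSet, p_holo: ProjectionSet,
                     warn_threshold: int = 10) -> list[ModeShift]:
    """Per-mode shift between two projected ensembles, ranked by effect size.

    Effect size is the pooled-SD standardized mean difference (Cohen's d);
    the p-value is a two-sided Welch t-test. Results are sorted by |d|.
    """
    if list(p_apo.mode_numbers) != list(p_holo.mode_numbers):
        raise AllopathError("projection sets cover different mode lists")
    n_a, n_h = len(p_apo.coordinates), len(p_holo.coordinates)
    if min(n_a, n_h) < 2:
        raise AllopathError("need at least 2 frames per ensemble")
    import warnings

    if min(n_a, n_h) < warn_threshold:
        warnings.warn(
            f"population shift estimated from {min(n_a, n_h)} frames; unstable",
            stacklevel=2,
        )
    shifts = []
    for j, mode_number in enumerate(p_apo.mode_numbers):
        a = p_apo.coordinates[:, j]
        h = p_holo.coordinates[:, j]
        pooled_var = (
            (n_a - 1) * a.var(ddof=1) + (n_h - 1) * h.var(ddof=1)
        ) / (n_a + n_h - 2)
        pooled_sd = float(np.sqrt(pooled_var))
        diff = float(h.mean() - a.mean())
        effect = diff / pooled_sd if pooled_sd > 0 else 0.0
        if np.allclose(a, h):
            p_value = 1.0
        else:
            p_value = float(stats.ttest_ind(a, h, equal_var=False).pvalue)
            if np.isnan(p_value):
                p_value = 0.0 if diff != 0 else 1.0
        shifts.append(
            ModeShift(
                mode_number=mode_number,
                mean_apo=float(a.mean()),
                mean_holo=float(h.mean()),
                mean_shift=diff,
                effect_size=effect,
                p_value=p_value,
            )
        )
    return sorted(shifts, key=lambda s: abs(s.effect_size), reverse=True)


def dcc(m: ModeSet, n_modes: int = 100) -> DCCMatrix:
    """Mode-reconstructed dynamical cross-correlation matrix.

    C(i,j) = sum_k v_k(i).v_k(j)/lambda_k over the first ``n_modes`` internal
    modes, normalized by sqrt(MSF_i * MSF_j). Symmetric, unit diagonal,
    invariant to uniform spring-constant scaling.
    """
    internal = m.internal_indices[:n_modes]
    if internal.size == 0:
        raise AllopathError("no internal modes available")
    vec = m.eigenvectors[:, internal].reshape(m.n_nodes, 3, internal.size)
    lam = m.eigenvalues[internal]
    # covariance superelements traced over x,y,z: (N, N)
    weighted = vec / lam[None, None, :]
    cov = np.einsum("ixk,jxk->ij", weighted, vec)
    msf = np.diag(cov).copy()
    norm = np.sqrt(np.outer(msf, msf))
    matrix = cov / norm
    np.fill_diagonal(matrix, 1.0)
    matrix = np.clip(matrix, -1.0, 1.0)
    matrix = 0.5 * (matrix + matrix.T)
    return DCCMatrix(node_keys=m.node_keys, matrix=matrix, n_modes=int(internal.size))
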