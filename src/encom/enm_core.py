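"""Stiffness-matrix construction and normal-mode decomposition.

Implements five C-alpha elastic network models over a common interface:

* ``ANM``    -- Hookean springs between all C-alpha pairs within a cutoff
  (18 A by default); 3N x 3N Hessian.
* ``GNM``    -- isotropic Kirchhoff (N x N) variant; magnitudes only.
* ``STEM``   -- Go-like four-term potential: virtual-bond stretching, angle
  bending, dihedral torsion and a 5-12/6-10 non-bonded term anchored at the
  native distances.
* ``ENCOM``  -- the STeM functional form with the non-bonded spring of each
  residue pair modulated by the surface-in-contact weight ``beta_ij``:
  the pair strength is ``alpha4 * (1 + beta_ij)``, so non-contacting pairs
  keep a weak distance-decaying baseline while residue pairs with large
  side-chain interfaces are stiffened in proportion.
* ``ENCOM_NS`` -- ENCoM with the all-ones atom-type matrix (beta reduces to
  the plain contact area).

All second derivatives are taken analytically at the reference (native)
geometry, where every term is at its minimum, so each term contributes a
positive-semidefinite rank-one block ``c * g g^T`` with ``g`` the Cartesian
gradient of the corresponding internal coordinate.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.sparse.csgraph import connected_components
from scipy.sparse import csr_matrix

from .structure_io import DimensionError, ProteinStructure
from .contacts import ContactModel

logger = logging.getLogger("encom")

__all__ = [
    "ModelKind",
    "ParameterSet",
    "SpectralDecomposition",
    "potential_energy",
    "build_hessian",
    "diagonalize",
    "compute_modes",
    "NotPositiveSemidefiniteError",
    "DEFAULT_ALPHA",
    "STEM_ALPHA",
    "BFACTOR_ALPHA",
]


class ModelKind(enum.Enum):
    ENCOM = "encom"
    ENCOM_NS = "encom-ns"
    STEM = "stem"
    ANM = "anm"
    GNM = "gnm"


#: Default ENCoM force-constant weights (bond, angle, dihedral, non-bonded).
#: A documented reconstruction of the overlap/mutation-optimal regime
#: (strong bond/angle constraints, non-bonded weight well below 1), not a
#: fitted set; override freely via ParameterSet or the config file.
DEFAULT_ALPHA = (1.0e3, 1.0e4, 1.0e4, 1.0e-2)

#: The Go-model weights used by STeM (bond 100, angle 20, dihedral 1,
#: non-bonded 1, in units of the non-bonded well depth).
STEM_ALPHA = (100.0, 20.0, 1.0, 1.0)

#: Reconstructed b-factor-optimal slot: non-bonded weight above 1 rigidifies
#: the network, the regime that favours crystallographic b-factor agreement.
BFACTOR_ALPHA = (1.0, 1.0, 1.0, 10.0)


class NotPositiveSemidefiniteError(ValueError):
    """A stiffness matrix produced genuinely negative eigenvalues."""


@dataclass
class ParameterSet:
    """Force-constant weights and model selection.

    alpha : (bond-stretch, angle-bend, dihedral, non-bonded) weights, all
        positive and unitless (energies are in model units).
    anm_cutoff : pair cutoff for the ANM spring network, Angstrom.
    gnm_cutoff : contact cutoff for the GNM Kirchhoff matrix, Angstrom.
    """

    alpha: tuple[float, float, float, float] = DEFAULT_ALPHA
    anm_cutoff: float = 18.0
    gnm_cutoff: float = 10.0
    model_kind: ModelKind = ModelKind.ENCOM

    def __post_init__(self) -> None:
        self.alpha = tuple(float(a) for a in self.alpha)
        if len(self.alpha) != 4 or any(a <= 0 for a in self.alpha):
            raise ValueError("alpha must be 4 positive weights")
        if self.anm_cutoff <= 0 or self.gnm_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        if isinstance(self.model_kind, str):
            self.model_kind = ModelKind(self.model_kind)

    @classmethod
    def for_model(cls, kind: ModelKind | str, **kwargs) -> "ParameterSet":
        kind = ModelKind(kind) if isinstance(kind, str) else kind
        if kind is ModelKind.STEM and "alpha" not in kwargs:
            kwargs["alpha"] = STEM_ALPHA
        if kind in (ModelKind.ANM, ModelKind.GNM) and "alpha" not in kwargs:
            kwargs["alpha"] = (1.0, 1.0, 1.0, 1.0)
        return cls(model_kind=kind, **kwargs)


@dataclass
class SpectralDecomposition:
    """Sorted spectrum of a stiffness matrix.

    Eigenvalues ascend; eigenvectors are the matching orthonormal columns.
    The first ``n_rigid`` modes (6 for 3D models, 1 for GNM) are rigid-body
    motions; the rest are internal modes.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    n_rigid: int
    model_kind: ModelKind
    n_residues: int

    @property
    def internal_eigenvalues(self) -> np.ndarray:
        return self.eigenvalues[self.n_rigid:]

    @property
    def internal_modes(self) -> np.ndarray:
        """Columns: internal-mode eigenvectors (mode 7 onward for 3D)."""
        return self.eigenvectors[:, self.n_rigid:]


# ---------------------------------------------------------------------------
# Internal-coordinate helpers
# ---------------------------------------------------------------------------

def _bond_pairs(structure: ProteinStructure) -> list[tuple[int, int]]:
    """Consecutive-residue virtual bonds, not crossing chain boundaries."""
    pairs = []
    for i in range(structure.n_residues - 1):
        a, b = structure.residues[i], structure.residues[i + 1]
        if a.chain_id == b.chain_id:
            pairs.append((i, i + 1))
    return pairs


def _angle_triples(structure: ProteinStructure) -> list[tuple[int, int, int]]:
    triples = []
    for i in range(structure.n_residues - 2):
        chain = {structure.residues[k].chain_id for k in (i, i + 1, i + 2)}
        if len(chain) == 1:
            triples.append((i, i + 1, i + 2))
    return triples


def _dihedral_quads(structure: ProteinStructure) -> list[tuple[int, ...]]:
    quads = []
    for i in range(structure.n_residues - 3):
        chain = {structure.residues[k].chain_id for k in range(i, i + 4)}
        if len(chain) == 1:
            quads.append((i, i + 1, i + 2, i + 3))
    return quads


def _angle(coords: np.ndarray, i: int, j: int, k: int) -> float:
    rij = coords[i] - coords[j]
    rkj = coords[k] - coords[j]
    c = float(np.dot(rij, rkj) / (np.linalg.norm(rij) * np.linalg.norm(rkj)))
    return math.acos(min(max(c, -1.0), 1.0))


def _dihedral(coords: np.ndarray, i: int, j: int, k: int, l: int) -> float:
    b1 = coords[j] - coords[i]
    b2 = coords[k] - coords[j]
    b3 = coords[l] - coords[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    return math.atan2(y, x)


def _angle_gradient(coords, i, j, k):
    """Cartesian gradient of the bond angle at (i, j, k); None if degenerate."""
    rij = coords[i] - coords[j]
    rkj = coords[k] - coords[j]
    nij = np.linalg.norm(rij)
    nkj = np.linalg.norm(rkj)
    uij = rij / nij
    ukj = rkj / nkj
    cos_t = float(np.dot(uij, ukj))
    sin_t = math.sqrt(max(1.0 - cos_t * cos_t, 0.0))
    if sin_t < 1e-8:
        return None
    gi = (cos_t * uij - ukj) / (nij * sin_t)
    gk = (cos_t * ukj - uij) / (nkj * sin_t)
    gj = -gi - gk
    return gi, gj, gk


def _dihedral_gradient(coords, i, j, k, l):
    """Cartesian gradient of the torsion at (i, j, k, l); None if degenerate."""
    b1 = coords[j] - coords[i]
    b2 = coords[k] - coords[j]
    b3 = coords[l] - coords[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1sq = float(np.dot(n1, n1))
    n2sq = float(np.dot(n2, n2))
    b2n = float(np.linalg.norm(b2))
    if n1sq < 1e-14 or n2sq < 1e-14 or b2n < 1e-8:
        return None
    gi = (b2n / n1sq) * n1
    gl = -(b2n / n2sq) * n2
    f1 = float(np.dot(b1, b2)) / (b2n * b2n)
    f3 = float(np.dot(b3, b2)) / (b2n * b2n)
    gj = -(1.0 + f1) * gi + f3 * gl
    gk = f1 * gi - (1.0 + f3) * gl
    return gi, gj, gk, gl


def _nonbonded_pairs(structure: ProteinStructure, params: ParameterSet,
                     contacts: ContactModel | None):
    """(i, j, strength) for every long-range pair |i - j| >= 2."""
    n = structure.n_residues
    a4 = params.alpha[3]
    use_beta = params.model_kind in (ModelKind.ENCOM, ModelKind.ENCOM_NS)
    out = []
    for i in range(n):
        for j in range(i + 2, n):
            if use_beta:
                k = a4 * (1.0 + contacts.beta[i, j])
            else:
                k = a4
            out.append((i, j, k))
    return out


# ---------------------------------------------------------------------------
# Potential energy (full nonlinear form, used by the finite-difference oracle)
# ---------------------------------------------------------------------------

def _lj_1012(r: float, r0: float) -> float:
    """Native-anchored 5-12/6-10 well, shifted to vanish at r = r0."""
    q = r0 / r
    return 5.0 * q ** 12 - 6.0 * q ** 10 + 1.0


def potential_energy(structure: ProteinStructure, conformation: np.ndarray,
                     params: ParameterSet,
                     contacts: ContactModel | None = None) -> float:
    """Energy of an arbitrary C-alpha conformation relative to the native one.

    The reference (equilibrium) geometry is taken from ``structure``; the
    potential is zero there and invariant under rigid motions of the
    conformation.  GNM has no Cartesian potential.
    """
    n = structure.n_residues
    conf = np.asarray(conformation, dtype=float).reshape(-1)
    if conf.size != 3 * n:
        raise DimensionError(
            f"conformation has {conf.size} coordinates, expected {3 * n}")
    conf = conf.reshape(n, 3)
    ref = structure.calpha_coords()
    kind = params.model_kind
    if kind is ModelKind.GNM:
        raise ValueError("GNM defines no Cartesian potential energy")
    a1, a2, a3, _a4 = params.alpha

    if kind is ModelKind.ANM:
        v = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                r0 = float(np.linalg.norm(ref[i] - ref[j]))
                if r0 <= params.anm_cutoff:
                    r = float(np.linalg.norm(conf[i] - conf[j]))
                    v += a1 * (r - r0) ** 2
        return v

    if kind in (ModelKind.ENCOM, ModelKind.ENCOM_NS) and contacts is None:
        raise ValueError(f"{kind.value} requires a ContactModel")

    v = 0.0
    for i, j in _bond_pairs(structure):
        r0 = float(np.linalg.norm(ref[i] - ref[j]))
        r = float(np.linalg.norm(conf[i] - conf[j]))
        v += a1 * (r - r0) ** 2
    for i, j, k in _angle_triples(structure):
        t0 = _angle(ref, i, j, k)
        t = _angle(conf, i, j, k)
        v += a2 * (t - t0) ** 2
    for i, j, k, l in _dihedral_quads(structure):
        if _dihedral_gradient(ref, i, j, k, l) is None:
            continue  # collinear reference: torsion undefined, no term
        p0 = _dihedral(ref, i, j, k, l)
        p = _dihedral(conf, i, j, k, l)
        d = p - p0
        v += a3 * ((1.0 - math.cos(d)) + 0.5 * (1.0 - math.cos(3.0 * d)))
    for i, j, k_ij in _nonbonded_pairs(structure, params, contacts):
        r0 = float(np.linalg.norm(ref[i] - ref[j]))
        r = float(np.linalg.norm(conf[i] - conf[j]))
        v += k_ij * _lj_1012(r, r0)
    return v


# ---------------------------------------------------------------------------
# Hessian construction
# ---------------------------------------------------------------------------

def _add_outer(H: np.ndarray, indices: tuple[int, ...], grads, c: float) -> None:
    """Accumulate c * g g^T for a sparse internal-coordinate gradient."""
    for a, idx_a in enumerate(indices):
        for b, idx_b in enumerate(indices):
            block = c * np.outer(grads[a], grads[b])
            H[3 * idx_a:3 * idx_a + 3, 3 * idx_b:3 * idx_b + 3] += block


def build_hessian(structure: ProteinStructure, params: ParameterSet,
                  contacts: ContactModel | None = None) -> np.ndarray:
    """Analytic stiffness matrix at the reference geometry.

    Returns the 3N x 3N Hessian (N x N Kirchhoff for GNM).  ENCoM and its
    non-specific variant require a :class:`ContactModel`; ANM, STeM and GNM
    ignore it.
    """
    n = structure.n_residues
    if n < 3:
        raise DimensionError(f"need at least 3 residues, got {n}")
    kind = params.model_kind
    ref = structure.calpha_coords()
    a1, a2, a3, _a4 = params.alpha

    if kind is ModelKind.GNM:
        G = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                if np.linalg.norm(ref[i] - ref[j]) <= params.gnm_cutoff:
                    G[i, j] = G[j, i] = -a1
        np.fill_diagonal(G, -G.sum(axis=1))
        _warn_if_disconnected(G != 0)
        return G

    H = np.zeros((3 * n, 3 * n))

    def add_pair_spring(i: int, j: int, c: float) -> None:
        # distance term with f'(r0) = 0: Hessian block is f''(r0) * u u^T
        u = ref[j] - ref[i]
        r0 = float(np.linalg.norm(u))
        u = u / r0
        _add_outer(H, (i, j), (-u, u), c)

    adjacency = np.zeros((n, n), dtype=bool)

    if kind is ModelKind.ANM:
        for i in range(n):
            for j in range(i + 1, n):
                r0 = float(np.linalg.norm(ref[i] - ref[j]))
                if r0 <= params.anm_cutoff:
                    add_pair_spring(i, j, 2.0 * a1)
                    adjacency[i, j] = adjacency[j, i] = True
        _warn_if_disconnected(adjacency)
        return H

    if kind in (ModelKind.ENCOM, ModelKind.ENCOM_NS):
        if contacts is None:
            raise ValueError(f"{kind.value} requires a ContactModel")
        if contacts.beta.shape != (n, n):
            raise DimensionError("ContactModel size does not match structure")

    for i, j in _bond_pairs(structure):
        add_pair_spring(i, j, 2.0 * a1)
        adjacency[i, j] = adjacency[j, i] = True
    for i, j, k in _angle_triples(structure):
        g = _angle_gradient(ref, i, j, k)
        if g is None:
            logger.warning("degenerate angle %d-%d-%d skipped", i, j, k)
            continue
        _add_outer(H, (i, j, k), g, 2.0 * a2)
    for quad in _dihedral_quads(structure):
        g = _dihedral_gradient(ref, *quad)
        if g is None:
            logger.warning("degenerate dihedral %s skipped", quad)
            continue
        # d2/dphi2 [(1 - cos d) + (1/2)(1 - cos 3d)] = 1 + 9/2 at d = 0
        _add_outer(H, quad, g, 5.5 * a3)
    for i, j, k_ij in _nonbonded_pairs(structure, params, contacts):
        if k_ij <= 0.0:
            continue
        r0 = float(np.linalg.norm(ref[i] - ref[j]))
        # f''(r0) of k * (5 q^12 - 6 q^10 + 1), q = r0/r
        add_pair_spring(i, j, 120.0 * k_ij / (r0 * r0))
        adjacency[i, j] = adjacency[j, i] = True
    _warn_if_disconnected(adjacency)
    return H


def _warn_if_disconnected(adjacency: np.ndarray) -> None:
    n_comp, _ = connected_components(csr_matrix(adjacency), directed=False)
    if n_comp > 1:
        logger.warning("network has %d disconnected components; extra zero "
                       "modes expected", n_comp)


# ---------------------------------------------------------------------------
# Diagonalization
# ---------------------------------------------------------------------------

def diagonalize(H: np.ndarray, model_kind: ModelKind | str
                ) -> SpectralDecomposition:
    """Full symmetric eigendecomposition, ascending eigenvalues.

    Rigid modes are identified by count (the 6 smallest for 3D models, the
    single smallest for GNM), not by thresholding.  Eigenvalues below
    -1e-8 * lambda_max indicate a genuinely indefinite matrix and raise.
    """
    model_kind = (ModelKind(model_kind) if isinstance(model_kind, str)
                  else model_kind)
    H = np.asarray(H, dtype=float)
    if H.ndim != 2 or H.shape[0] != H.shape[1]:
        raise DimensionError(f"stiffness matrix must be square, got {H.shape}")
    vals, vecs = scipy.linalg.eigh(H)
    lam_max = float(vals[-1]) if len(vals) else 0.0
    if lam_max > 0 and float(vals[0]) < -1e-8 * lam_max:
        raise NotPositiveSemidefiniteError(
            f"negative eigenvalue {vals[0]:g} (max {lam_max:g})")
    if model_kind is ModelKind.GNM:
        n_rigid, n_res = 1, H.shape[0]
    else:
        if H.shape[0] % 3:
            raise DimensionError("3D stiffness matrix size must be 3N")
        n_rigid, n_res = 6, H.shape[0] // 3
    return SpectralDecomposition(eigenvalues=vals, eigenvectors=vecs,
                                 n_rigid=n_rigid, model_kind=model_kind,
                                 n_residues=n_res)


def compute_modes(structure: ProteinStructure, params: ParameterSet,
                  contacts: ContactModel | None = None
                  ) -> SpectralDecomposition:
    """Build the stiffness matrix for the configured model and diagonalize."""
    H = build_hessian(structure, params, contacts)
    return diagonalize(H, params.model_kind)


def write_hessian_tsv(H: np.ndarray, path) -> None:
    """Dump a stiffness matrix as TSV (debugging aid)."""
    np.savetxt(path, np.asarray(H, float), delimiter="\t", fmt="%.12g")
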