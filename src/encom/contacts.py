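"""Atomic surfaces in contact and residue-pair interaction weights.

The sequence-sensitive part of the elastic network is the weight
``beta_ij`` assigned to each residue pair: a sum over all heavy-atom pairs
(a in residue i, b in residue j) of the surface area in contact between the
two atoms, multiplied by an 8x8 atom-type interaction matrix ``eps``.

Surfaces in contact follow a power-diagram construction: each atom sphere is
inflated by a solvent probe radius and every point of the inflated surface
that is covered by at least one neighbouring sphere is assigned to the
neighbour with the smallest power distance (the radical-plane criterion).
The area of the resulting spherical cell of neighbour b on atom a's surface
is the directed contact area of b on a; the symmetric contact surface is the
sum of the two directed areas.  The cell areas are computed analytically via
Gauss-Bonnet on spherical-cap intersections, with a uniform sphere-sampling
numeric estimator of the same partition serving as oracle and fallback.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import AtomType, ProteinStructure

__all__ = [
    "InteractionMatrix",
    "ContactModel",
    "contact_surfaces",
    "compute_beta",
    "spherical_cap_intersection_area",
    "DegenerateGeometryError",
    "ConfigurationError",
    "DEFAULT_PROBE_RADIUS",
]

#: Water-probe radius (Angstrom) added to each atomic radius when deciding
#: and measuring contacts.
DEFAULT_PROBE_RADIUS = 1.4

_TYPE_ORDER = [
    AtomType.HYDROPHILIC, AtomType.ACCEPTOR, AtomType.DONOR,
    AtomType.HYDROPHOBIC, AtomType.AROMATIC, AtomType.NEUTRAL,
    AtomType.NEUTRAL_DONOR, AtomType.NEUTRAL_ACCEPTOR,
]
_TYPE_LABELS = [t.name.lower() for t in _TYPE_ORDER]
_TYPE_INDEX = {t: k for k, t in enumerate(_TYPE_ORDER)}
# Atoms without a known class behave as the neutral class.
_TYPE_INDEX[AtomType.UNASSIGNED] = _TYPE_INDEX[AtomType.NEUTRAL]


class DegenerateGeometryError(ValueError):
    """Two distinct atoms at (numerically) identical coordinates."""


class ConfigurationError(ValueError):
    """Invalid interaction matrix or contact configuration."""


@dataclass
class InteractionMatrix:
    """Symmetric 8x8 matrix of unitless atom-type interaction weights."""

    epsilon: np.ndarray
    name: str = "custom"

    def __post_init__(self) -> None:
        eps = np.asarray(self.epsilon, dtype=float)
        if eps.shape != (8, 8):
            raise ConfigurationError(
                f"interaction matrix must be 8x8, got {eps.shape}")
        if not np.allclose(eps, eps.T, rtol=0, atol=1e-12):
            raise ConfigurationError("interaction matrix must be symmetric")
        if not np.all(np.isfinite(eps)) or np.any(eps <= 0):
            raise ConfigurationError(
                "interaction matrix entries must be finite and positive")
        self.epsilon = eps

    def weight(self, type_a: AtomType, type_b: AtomType) -> float:
        return float(self.epsilon[_TYPE_INDEX[type_a], _TYPE_INDEX[type_b]])

    @classmethod
    def nonspecific(cls) -> "InteractionMatrix":
        """The all-ones matrix of the type-insensitive model variant."""
        return cls(np.ones((8, 8)), name="nonspecific")

    @classmethod
    def default(cls) -> "InteractionMatrix":
        """Bundled default matrix (a documented reconstruction, not fitted)."""
        return cls.from_tsv(
            resources.files("encom") / "data" / "epsilon_default.tsv",
            name="default")

    @classmethod
    def from_tsv(cls, path, name: str | None = None) -> "InteractionMatrix":
        """Read an 8x8 matrix from a TSV with header row/column labels."""
        with open(path) as fh:
            lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
        header = lines[0].split("\t")[1:]
        if [h.lower() for h in header] != _TYPE_LABELS:
            raise ConfigurationError(
                f"unexpected column labels in {path}: {header}")
        rows = []
        for ln in lines[1:]:
            cells = ln.split("\t")
            rows.append([float(x) for x in cells[1:]])
        return cls(np.array(rows), name=name or Path(str(path)).stem)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("type\t" + "\t".join(_TYPE_LABELS) + "\n")
            for label, row in zip(_TYPE_LABELS, self.epsilon):
                fh.write(label + "\t" + "\t".join(f"{x:g}" for x in row) + "\n")


@dataclass
class ContactModel:
    """Atom-pair contact surfaces and the residue-pair weights built from them.

    ``atom_surfaces`` maps a canonically ordered global atom-index pair to
    its symmetric surface in contact (A^2).  ``beta`` is the dense symmetric
    N x N matrix of residue-pair weights (zero on the diagonal and for
    residue pairs without any atom contact).
    """

    atom_surfaces: dict[tuple[int, int], float]
    beta: np.ndarray
    interaction: InteractionMatrix = field(default_factory=InteractionMatrix.nonspecific)

    def surface(self, a: int, b: int) -> float:
        key = (a, b) if a < b else (b, a)
        return self.atom_surfaces.get(key, 0.0)


# ---------------------------------------------------------------------------
# Spherical geometry: area of an intersection of caps on the unit sphere
# ---------------------------------------------------------------------------

_TOL = 1e-9


def _cap_area(c: float) -> float:
    return 2.0 * math.pi * (1.0 - c)


def spherical_cap_intersection_area(axes: np.ndarray,
                                    cosines: np.ndarray) -> float:
    """Area of { x on unit sphere : axes[k] . x >= cosines[k] for all k }.

    Each constraint is a spherical cap given by its unit axis and the cosine
    of its angular radius.  Evaluated exactly via the Gauss-Bonnet theorem
    on the boundary arcs of the intersection region.
    """
    axes = np.asarray(axes, dtype=float)
    cosines = np.asarray(cosines, dtype=float)

    # Discard vacuous constraints; detect trivially empty ones.
    keep = cosines > -1.0 + _TOL
    if np.any(cosines >= 1.0 - _TOL):
        return 0.0
    axes, cosines = axes[keep], cosines[keep]
    # Deduplicate constraints with (near-)identical axes: keep the tighter cap.
    if len(cosines) > 1:
        dominated = np.zeros(len(cosines), dtype=bool)
        for i in range(len(cosines)):
            for j in range(i + 1, len(cosines)):
                if float(np.dot(axes[i], axes[j])) > 1.0 - 1e-10:
                    if cosines[i] >= cosines[j]:
                        dominated[j] = True
                    else:
                        dominated[i] = True
        axes, cosines = axes[~dominated], cosines[~dominated]
    m = len(cosines)
    if m == 0:
        return 4.0 * math.pi
    if m == 1:
        return _cap_area(cosines[0])

    sines = np.sqrt(np.clip(1.0 - cosines ** 2, 0.0, None))

    # Vertices: pairwise circle-circle intersections that satisfy all caps.
    verts: list[np.ndarray] = []
    vert_circles: list[tuple[int, int]] = []
    for i in range(m):
        for j in range(i + 1, m):
            dot = float(np.dot(axes[i], axes[j]))
            denom = 1.0 - dot * dot
            if denom < _TOL:
                continue  # parallel axes: nested or disjoint caps
            u = (cosines[i] - cosines[j] * dot) / denom
            v = (cosines[j] - cosines[i] * dot) / denom
            w2 = 1.0 - (u * u + v * v + 2.0 * u * v * dot)
            if w2 <= _TOL:
                continue  # circles do not cross (or are tangent)
            w = math.sqrt(w2)
            cross = np.cross(axes[i], axes[j])
            cross /= np.linalg.norm(cross)
            base = u * axes[i] + v * axes[j]
            for s in (+1.0, -1.0):
                x = base + s * w * cross
                if np.all(axes @ x >= cosines - 1e-7):
                    verts.append(x)
                    vert_circles.append((i, j))

    # Boundary arcs: on each circle, the valid vertices split it into arcs;
    # an arc belongs to the boundary iff its midpoint satisfies all caps.
    arcs = []  # (circle index, phi_start, phi_end, start point, end point)
    for i in range(m):
        on_circle = [k for k, (a, b) in enumerate(vert_circles)
                     if i in (a, b)]
        if not on_circle:
            # Unbroken circle: part of the boundary iff it lies inside all
            # other caps (then it bounds the region as a full loop).
            e = _orthonormal(axes[i])
            p = cosines[i] * axes[i] + sines[i] * e
            if all(float(np.dot(axes[k], p)) >= cosines[k] - 1e-7
                   for k in range(m) if k != i):
                arcs.append((i, 0.0, 2.0 * math.pi, None, None))
            continue
        e1 = _orthonormal(axes[i])
        e2 = np.cross(axes[i], e1)
        phis = []
        for k in on_circle:
            x = verts[k]
            phi = math.atan2(float(np.dot(x, e2)), float(np.dot(x, e1)))
            phis.append((phi % (2.0 * math.pi), k))
        phis.sort()
        nv = len(phis)
        for idx in range(nv):
            phi_a, ka = phis[idx]
            phi_b, kb = phis[(idx + 1) % nv]
            span = (phi_b - phi_a) % (2.0 * math.pi)
            if span < _TOL:
                span = 2.0 * math.pi if nv == 1 else span
            phi_mid = phi_a + 0.5 * span
            mid = (cosines[i] * axes[i]
                   + sines[i] * (math.cos(phi_mid) * e1 + math.sin(phi_mid) * e2))
            ok = True
            for k in range(m):
                if k == i:
                    continue
                if float(np.dot(axes[k], mid)) < cosines[k] - 1e-7:
                    ok = False
                    break
            if ok:
                arcs.append((i, phi_a, phi_a + span, verts[ka], verts[kb]))

    if not arcs:
        return 0.0

    # Gauss-Bonnet: area = 2*pi*chi - sum(arc k_g length) - sum(turning
    # angles), with chi = 2C - L for C connected components and L boundary
    # loops.  C is not known from the loops alone, but consecutive values of
    # C shift the area by exactly 4*pi, so the physical value is recovered
    # as the representative in [0, 4*pi).  For an arc of angular span dphi
    # on a cap of cosine c the geodesic curvature term integrates to
    # dphi * c (region kept on the left when traversing counterclockwise
    # around the cap axis).
    loops = _chain_arcs(arcs)
    total = 0.0
    n_loops = len(loops)
    for loop in loops:
        for (i, phi_a, phi_b, _pa, _pb) in loop:
            total += (phi_b - phi_a) * cosines[i]
        # turning angles between consecutive arcs
        nl = len(loop)
        for idx in range(nl):
            i_cur, _, phi_b, _, p_end = loop[idx]
            i_nxt = loop[(idx + 1) % nl][0]
            if p_end is None:
                continue  # full-circle loop, no vertex
            x = p_end
            t_in = np.cross(axes[i_cur], x)
            t_out = np.cross(axes[i_nxt], x)
            t_in /= np.linalg.norm(t_in)
            t_out /= np.linalg.norm(t_out)
            sin_e = float(np.dot(np.cross(t_in, t_out), x))
            cos_e = float(np.dot(t_in, t_out))
            total += math.atan2(sin_e, cos_e)
    area = (-2.0 * math.pi * n_loops - total) % (4.0 * math.pi)
    return area


def _orthonormal(a: np.ndarray) -> np.ndarray:
    """A unit vector orthogonal to ``a``."""
    h = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e = np.cross(a, h)
    return e / np.linalg.norm(e)


def _chain_arcs(arcs: list) -> list[list]:
    """Group boundary arcs into closed loops by matching endpoints."""
    loops: list[list] = []
    remaining = list(arcs)
    while remaining:
        arc = remaining.pop()
        loop = [arc]
        if arc[3] is None:  # full circle
            loops.append(loop)
            continue
        start = arc[3]
        end = arc[4]
        guard = 0
        while np.linalg.norm(end - start) > 1e-6 and guard < 10000:
            guard += 1
            best, best_d = None, 1e-5
            for k, cand in enumerate(remaining):
                if cand[3] is None:
                    continue
                d = float(np.linalg.norm(cand[3] - end))
                if d < best_d:
                    best, best_d = k, d
            if best is None:
                break  # dangling chain under tolerance; close as is
            arc = remaining.pop(best)
            loop.append(arc)
            end = arc[4]
        loops.append(loop)
    return loops


# ---------------------------------------------------------------------------
# Contact surfaces
# ---------------------------------------------------------------------------

def _gather_atoms(structure: ProteinStructure):
    coords, radii, res_idx, types, labels = [], [], [], [], []
    for ri, res in enumerate(structure.residues):
        for atom in res.atoms:
            coords.append(atom.coords)
            radii.append(atom.radius)
            res_idx.append(ri)
            types.append(atom.atom_type)
            labels.append(f"{res.label}:{atom.name}")
    return (np.array(coords, dtype=float), np.array(radii, dtype=float),
            np.array(res_idx, dtype=int), types, labels)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere point set."""
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    phi = k * math.pi * (3.0 - math.sqrt(5.0))
    s = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def contact_surfaces(structure: ProteinStructure,
                     method: Literal["analytic", "numeric"] = "analytic",
                     probe: float = DEFAULT_PROBE_RADIUS,
                     n_points: int = 2000,
                     seed: int = 0) -> dict[tuple[int, int], float]:
    """Pairwise atomic surfaces in contact (A^2), keyed by global atom index.

    ``analytic`` computes the exact power-diagram cell areas; ``numeric``
    estimates the same areas by assigning ``n_points`` uniformly distributed
    surface samples per atom to their minimum-power covering neighbour
    (deterministic given ``seed``) and serves as the oracle.
    """
    coords, radii, res_idx, _types, labels = _gather_atoms(structure)
    n_atoms = len(radii)
    R = radii + probe
    surfaces: dict[tuple[int, int], float] = {}
    if n_atoms < 2:
        return surfaces

    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=float(2.0 * R.max()), output_type="ndarray")
    neighbors: list[list[int]] = [[] for _ in range(n_atoms)]
    for a, b in pairs:
        d = float(np.linalg.norm(coords[a] - coords[b]))
        if d < 1e-6:
            raise DegenerateGeometryError(
                f"atoms {labels[a]} and {labels[b]} overlap (distance {d:g})")
        if d < R[a] + R[b]:
            neighbors[a].append(b)
            neighbors[b].append(a)

    if method == "numeric":
        rng = np.random.default_rng(seed)
        # one fixed random rotation decorrelates the lattice from the axes
        from scipy.spatial.transform import Rotation
        quat = rng.normal(size=4)
        rot = Rotation.from_quat(quat / np.linalg.norm(quat)).as_matrix()
        base_points = _fibonacci_sphere(n_points) @ rot.T

    directed_areas: dict[tuple[int, int], float] = {}
    for a in range(n_atoms):
        nbrs = neighbors[a]
        if not nbrs:
            continue
        if method == "analytic":
            cell = _cell_areas_analytic(a, nbrs, coords, R)
        else:
            cell = _cell_areas_numeric(a, nbrs, coords, R, base_points)
        for b, area in cell.items():
            if area > 0.0:
                directed_areas[(a, b)] = area

    for (a, b), area in directed_areas.items():
        key = (a, b) if a < b else (b, a)
        surfaces[key] = surfaces.get(key, 0.0) + area
    return surfaces


def _pair_caps(a: int, nbrs: list[int], coords: np.ndarray, R: np.ndarray):
    """Covering caps of each neighbour on atom a's unit sphere."""
    caps = {}
    for b in nbrs:
        v = coords[b] - coords[a]
        d = float(np.linalg.norm(v))
        t = (R[a] ** 2 + d * d - R[b] ** 2) / (2.0 * R[a] * d)
        caps[b] = (v / d, min(max(t, -1.0), 1.0))
    return caps


def _cell_areas_analytic(a: int, nbrs: list[int], coords: np.ndarray,
                         R: np.ndarray) -> dict[int, float]:
    caps = _pair_caps(a, nbrs, coords, R)
    areas: dict[int, float] = {}
    for b in nbrs:
        ax_b, c_b = caps[b]
        if c_b >= 1.0 - _TOL:
            continue
        axes = [ax_b]
        cosines = [c_b]
        th_b = math.acos(min(max(c_b, -1.0), 1.0))
        for l in nbrs:
            if l == b:
                continue
            ax_l, c_l = caps[l]
            # Only neighbours whose covering cap can overlap b's cap
            # constrain the cell.
            th_l = math.acos(min(max(c_l, -1.0), 1.0))
            gamma = math.acos(min(max(float(np.dot(ax_b, ax_l)), -1.0), 1.0))
            if gamma >= th_b + th_l:
                continue
            # power(b) <= power(l) half-space, restricted to the unit sphere
            w = (coords[b] - coords[l])
            db = float(np.linalg.norm(coords[b] - coords[a]))
            dl = float(np.linalg.norm(coords[l] - coords[a]))
            rhs = (db * db - R[b] ** 2 - dl * dl + R[l] ** 2) / (2.0 * R[a])
            nw = float(np.linalg.norm(w))
            axes.append(w / nw)
            cosines.append(min(max(rhs / nw, -1.0), 1.0))
        area_unit = spherical_cap_intersection_area(
            np.array(axes), np.array(cosines))
        areas[b] = area_unit * R[a] ** 2
    return areas


def _cell_areas_numeric(a: int, nbrs: list[int], coords: np.ndarray,
                        R: np.ndarray, base_points: np.ndarray
                        ) -> dict[int, float]:
    pts = coords[a] + R[a] * base_points  # world-frame surface samples
    n = len(pts)
    powers = np.empty((len(nbrs), n))
    for k, b in enumerate(nbrs):
        powers[k] = np.sum((pts - coords[b]) ** 2, axis=1) - R[b] ** 2
    covered = powers.min(axis=0) <= 0.0
    winner = powers.argmin(axis=0)
    areas: dict[int, float] = {}
    full = 4.0 * math.pi * R[a] ** 2
    for k, b in enumerate(nbrs):
        count = int(np.sum(covered & (winner == k)))
        if count:
            areas[b] = full * count / n
    return areas


# ---------------------------------------------------------------------------
# Residue-pair weights
# ---------------------------------------------------------------------------

def compute_beta(structure: ProteinStructure,
                 surfaces: dict[tuple[int, int], float],
                 eps: InteractionMatrix,
                 atoms: Literal["all", "sidechain"] = "all") -> ContactModel:
    """Aggregate atom-pair surfaces into residue-pair weights beta_ij.

    beta_ij = sum over atom pairs (a in residue i, b in residue j) of
    eps[type(a), type(b)] * surface(a, b).  With the all-ones matrix this is
    the plain summed contact area (the type-insensitive model variant).
    By default every heavy atom enters the sum; ``atoms="sidechain"``
    restricts it to side-chain atoms for sensitivity analyses.
    """
    if not isinstance(eps, InteractionMatrix):
        eps = InteractionMatrix(np.asarray(eps))
    coords, radii, res_idx, types, _labels = _gather_atoms(structure)
    n = structure.n_residues
    beta = np.zeros((n, n))
    if atoms == "sidechain":
        from .structure_io import BACKBONE_ATOMS
        is_side = []
        for res in structure.residues:
            for atom in res.atoms:
                is_side.append(atom.name not in BACKBONE_ATOMS)
        mask = np.array(is_side)
    else:
        mask = np.ones(len(types), dtype=bool)
    type_idx = np.array([_TYPE_INDEX[t] for t in types])
    for (a, b), area in surfaces.items():
        if not (mask[a] and mask[b]):
            continue
        i, j = int(res_idx[a]), int(res_idx[b])
        if i == j:
            continue
        w = eps.epsilon[type_idx[a], type_idx[b]] * area
        beta[i, j] += w
        beta[j, i] += w
    return ContactModel(atom_surfaces=dict(surfaces), beta=beta,
                        interaction=eps)


def build_contact_model(structure: ProteinStructure,
                        eps: InteractionMatrix | None = None,
                        method: Literal["analytic", "numeric"] = "analytic",
                        probe: float = DEFAULT_PROBE_RADIUS,
                        **kwargs) -> ContactModel:
    """Convenience pipeline: surfaces in contact followed by beta weights."""
    eps = eps if eps is not None else InteractionMatrix.default()
    surfaces = contact_surfaces(structure, method=method, probe=probe, **kwargs)
    return compute_beta(structure, surfaces, eps)
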