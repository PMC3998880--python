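"""Observables derived from normal-mode spectra.

Three quantities connect the elastic-network spectra to experiment:

* predicted b-factors -- per-residue mean-square fluctuations summed over
  internal modes, ``b_i = sum_n |v_n,i|^2 / lambda_n`` (shape only; the
  scale is arbitrary);
* conformational overlap -- the normalized projection of the displacement
  towards a target conformation onto single eigenvectors, with the "best
  overlap" taken over the 10 slowest internal modes;
* vibrational entropy differences -- computed from the internal eigenvalue
  spectra of two structures and used, with enthalpy ignored, as an entropic
  surrogate for the free-energy effect of a point mutation (ddG).

Entropies are reported in units of k_B (k_B = 1); the through-origin
regression against experiment absorbs the absolute scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .structure_io import DimensionError, ProteinStructure
from .contacts import ContactModel, InteractionMatrix, build_contact_model
from .enm_core import (ModelKind, ParameterSet, SpectralDecomposition,
                       compute_modes)

logger = logging.getLogger("encom")

__all__ = [
    "ModeObservables",
    "MutationRecord",
    "predict_bfactors",
    "overlap",
    "superpose",
    "entropy_difference",
    "predict_ddg",
    "delta_b_profile",
    "UndefinedOverlapError",
    "NEUTRAL_DDG_BAND",
]

#: Experimental ddG band (kcal/mol) classifying a mutation as neutral;
#: the interval is closed on both ends.
NEUTRAL_DDG_BAND = 0.5


class UndefinedOverlapError(ValueError):
    """Displacement between conformations is (numerically) zero."""


@dataclass
class ModeObservables:
    bfactors: Optional[np.ndarray] = None
    overlaps: Optional[np.ndarray] = None
    best_overlap: Optional[float] = None
    best_mode: Optional[int] = None  # 1-based mode number (7 = first internal)


@dataclass
class MutationRecord:
    """One mutation with its experimental and predicted effect."""

    wt_id: str
    mut_id: str
    mutation: tuple[str, int, str, str]  # (wt residue, position, chain, mutant)
    ddg_exp: float
    dds_pred: float = np.nan
    ddg_pred_scaled: float = np.nan

    @property
    def exp_class(self) -> str:
        if self.ddg_exp < -NEUTRAL_DDG_BAND:
            return "stabilizing"
        if self.ddg_exp > NEUTRAL_DDG_BAND:
            return "destabilizing"
        return "neutral"


def predict_bfactors(decomp: SpectralDecomposition) -> np.ndarray:
    """Per-residue predicted b-factors (arbitrary units).

    For 3D models: ``b_i = sum over internal modes of
    (v_n,ix^2 + v_n,iy^2 + v_n,iz^2) / lambda_n``.  For GNM, the diagonal of
    the Kirchhoff pseudoinverse (the same sum without spatial components).
    """
    lam = decomp.internal_eigenvalues
    if np.any(lam <= 0):
        raise ValueError("internal eigenvalues must be positive; "
                         "is the network connected?")
    vecs = decomp.internal_modes  # (dof, n_internal)
    weighted = (vecs ** 2) / lam[np.newaxis, :]
    per_dof = weighted.sum(axis=1)
    if decomp.model_kind is ModelKind.GNM:
        return per_dof
    return per_dof.reshape(decomp.n_residues, 3).sum(axis=1)


def superpose(mobile: np.ndarray, reference: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns (transformed coordinates, rotation, translation) via the Kabsch
    algorithm; both inputs are (N, 3).
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    P = mobile - mc
    Q = reference - rc
    U, s, Vt = np.linalg.svd(P.T @ Q)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = (U @ D @ Vt).T
    t = rc - R @ mc
    return mobile @ R.T + t, R, t


def _match_residues(start: ProteinStructure, target: ProteinStructure
                    ) -> tuple[list[int], list[int]]:
    """Indices of residues shared by both structures (chain + number + icode)."""
    target_map = {key: i for i, key in enumerate(target.residue_keys())}
    idx_start, idx_target = [], []
    for i, key in enumerate(start.residue_keys()):
        j = target_map.get(key)
        if j is not None:
            idx_start.append(i)
            idx_target.append(j)
    return idx_start, idx_target


def overlap(decomp: SpectralDecomposition, start: ProteinStructure,
            target: ProteinStructure, n_best: int = 10) -> ModeObservables:
    """Per-mode overlaps with the displacement towards a target conformation.

    The target is rigidly superposed onto the start over the residues the two
    structures share (matched by chain and residue number).  For each
    internal mode, ``O_n = |v_n . dr| / (|v_n| |dr|)``; ``best_overlap`` is
    the maximum over the ``n_best`` slowest internal modes.

    The decomposition must cover exactly the matched residues; subset the
    structures and rebuild the modes first if they differ.
    """
    idx_s, idx_t = _match_residues(start, target)
    if len(idx_s) < 3:
        raise ValueError(f"only {len(idx_s)} shared residues; need >= 3")
    if decomp.n_residues != len(idx_s):
        raise DimensionError(
            f"decomposition covers {decomp.n_residues} residues but the "
            f"conformations share {len(idx_s)}; rebuild on the common subset")
    xs = start.calpha_coords()[idx_s]
    xt = target.calpha_coords()[idx_t]
    xt_fit, _R, _t = superpose(xt, xs)
    dr = (xt_fit - xs).ravel()
    norm = float(np.linalg.norm(dr))
    if norm < 1e-8:
        raise UndefinedOverlapError(
            "conformations are identical after superposition")
    vecs = decomp.internal_modes
    overlaps = np.abs(vecs.T @ dr) / (np.linalg.norm(vecs, axis=0) * norm)
    k = min(n_best, overlaps.size)
    best_idx = int(np.argmax(overlaps[:k]))
    return ModeObservables(
        overlaps=overlaps,
        best_overlap=float(overlaps[best_idx]),
        best_mode=decomp.n_rigid + best_idx + 1,
    )


def entropy_difference(decomp_a: SpectralDecomposition,
                       decomp_b: SpectralDecomposition) -> float:
    """Vibrational entropy difference S(b) - S(a) in units of k_B.

    In the classical harmonic limit each internal mode contributes
    ``-1/2 ln(lambda)`` plus constants that cancel between conformations,
    so ``dS = 1/2 sum_n ln(lambda_a,n / lambda_b,n)`` over paired sorted
    internal modes.  Positive when b's spectrum is softer (lower
    frequencies, more accessible microstates) than a's.
    """
    if decomp_a.n_residues != decomp_b.n_residues:
        raise DimensionError("structures differ in residue count")
    if decomp_a.model_kind is not decomp_b.model_kind:
        raise ValueError("decompositions come from different models")
    la = decomp_a.internal_eigenvalues
    lb = decomp_b.internal_eigenvalues
    if la.size != lb.size:
        raise DimensionError("internal mode counts differ")
    if np.any(la <= 0) or np.any(lb <= 0):
        raise ValueError("internal eigenvalues must be positive")
    return float(0.5 * np.sum(np.log(la) - np.log(lb)))


def predict_ddg(wt: ProteinStructure, mutant: ProteinStructure,
                params: ParameterSet,
                eps: InteractionMatrix | None = None,
                contact_method: str = "analytic") -> float:
    """Entropic score for the effect of a mutation, from spectra of both forms.

    Builds contacts (for the contact-modulated models), stiffness matrix and
    spectrum for wild type and mutant and returns the vibrational-entropy
    score oriented so that a destabilizing mutation (stiffened mutant,
    reduced folded-state entropy) tends to a positive value.  The mutant must
    be a pre-built model with the same residue count as the wild type.
    """
    if wt.n_residues != mutant.n_residues:
        raise DimensionError(
            f"wild type has {wt.n_residues} residues, mutant "
            f"{mutant.n_residues}")
    if eps is None:
        if params.model_kind is ModelKind.ENCOM_NS:
            eps = InteractionMatrix.nonspecific()
        else:
            eps = InteractionMatrix.default()

    def spectrum(structure: ProteinStructure) -> SpectralDecomposition:
        contacts: ContactModel | None = None
        if params.model_kind in (ModelKind.ENCOM, ModelKind.ENCOM_NS):
            contacts = build_contact_model(structure, eps,
                                           method=contact_method)
        return compute_modes(structure, params, contacts)

    # destabilizing <=> mutant spectrum stiffer <=> S(mut) < S(wt)
    return -entropy_difference(spectrum(wt), spectrum(mutant))


def delta_b_profile(wt_decomp: SpectralDecomposition,
                    mut_decomp: SpectralDecomposition) -> np.ndarray:
    """Inverse normalized b-factor difference profile between two forms.

    Each predicted b-factor profile is z-scored (so the arbitrary model
    scale drops out) and the difference is sign-inverted: rigidity gain in
    the mutant gives a positive value, tracking NMR order-parameter (S^2)
    differences, which grow when a residue rigidifies while b-factors shrink.
    """
    b_wt = predict_bfactors(wt_decomp)
    b_mut = predict_bfactors(mut_decomp)
    if b_wt.size != b_mut.size:
        raise DimensionError("profiles differ in length")

    def zscore(x: np.ndarray) -> np.ndarray:
        sd = x.std()
        if sd == 0:
            return np.zeros_like(x)
        return (x - x.mean()) / sd

    return -(zscore(b_mut) - zscore(b_wt))
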