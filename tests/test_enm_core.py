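import subprocess
import sys

import numpy as np
import pytest

from encom.structure_io import DimensionError, write_pdb
from encom.contacts import InteractionMatrix, build_contact_model
from encom.enm_core import (ModelKind, ParameterSet, STEM_ALPHA,
                            build_hessian, compute_modes, diagonalize,
                            potential_energy)
from encom.fixtures import ToySpec, make_structure
from encom.observables import entropy_difference, overlap, predict_bfactors
from conftest import random_rotation


ALL_3D_MODELS = [ModelKind.ENCOM, ModelKind.ENCOM_NS, ModelKind.STEM,
                 ModelKind.ANM]


def params_and_contacts(kind, structure, eps=None):
    params = ParameterSet.for_model(kind)
    contacts = None
    if kind in (ModelKind.ENCOM, ModelKind.ENCOM_NS):
        eps = eps or (InteractionMatrix.nonspecific()
                      if kind is ModelKind.ENCOM_NS
                      else InteractionMatrix.default())
        contacts = build_contact_model(structure, eps)
    return params, contacts


class TestPotentialEnergy:
    def test_zero_at_reference(self, helix8, encom_params, helix8_contacts):
        ref = helix8.calpha_coords().ravel()
        assert potential_energy(helix8, ref, encom_params,
                                helix8_contacts) == 0.0

    def test_rigid_motion_invariance(self, helix8, encom_params,
                                     helix8_contacts, rng):
        R = random_rotation(rng)
        conf = (helix8.calpha_coords() @ R.T + np.array([1.0, -2.0, 0.5]))
        v = potential_energy(helix8, conf.ravel(), encom_params,
                             helix8_contacts)
        assert abs(v) < 1e-9

    def test_quadratic_growth_of_bond_stretch(self, helix8, encom_params,
                                              helix8_contacts):
        # stretch the terminal virtual bond by delta along its axis
        ref = helix8.calpha_coords()
        axis = ref[-1] - ref[-2]
        axis /= np.linalg.norm(axis)

        def energy(delta):
            conf = ref.copy()
            conf[-1] += delta * axis
            return potential_energy(helix8, conf.ravel(), encom_params,
                                    helix8_contacts)

        d = 1e-3
        ratio = energy(d) / energy(d / 2)
        assert ratio == pytest.approx(4.0, rel=0.01)

    def test_dimension_mismatch(self, helix8, encom_params, helix8_contacts):
        with pytest.raises(DimensionError):
            potential_energy(helix8, np.zeros(10), encom_params,
                             helix8_contacts)

    def test_gnm_has_no_potential(self, helix8):
        with pytest.raises(ValueError):
            potential_energy(helix8, helix8.calpha_coords().ravel(),
                             ParameterSet.for_model(ModelKind.GNM))


class TestHessian:
    def test_encom_with_ones_equals_nonspecific_variant(self, helix8):
        eps1 = InteractionMatrix(np.ones((8, 8)))
        contacts = build_contact_model(helix8, eps1)
        h_encom = build_hessian(
            helix8, ParameterSet(model_kind=ModelKind.ENCOM), contacts)
        h_ns = build_hessian(
            helix8, ParameterSet(model_kind=ModelKind.ENCOM_NS), contacts)
        np.testing.assert_array_equal(h_encom, h_ns)

    @pytest.mark.parametrize("kind", ALL_3D_MODELS)
    def test_symmetry(self, helix8, kind):
        params, contacts = params_and_contacts(kind, helix8)
        H = build_hessian(helix8, params, contacts)
        assert np.abs(H - H.T).max() <= 1e-10 * np.abs(H).max()

    def test_matches_finite_differences(self, helix5, encom_params):
        contacts = build_contact_model(helix5, InteractionMatrix.default())
        H = build_hessian(helix5, encom_params, contacts)
        ref = helix5.calpha_coords().ravel()
        h = 1e-5
        n = ref.size
        fd = np.zeros((n, n))

        def V(x):
            return potential_energy(helix5, x, encom_params, contacts)

        for a in range(n):
            for b in range(a, n):
                if a == b:
                    xp = ref.copy(); xp[a] += 2 * h
                    xm = ref.copy(); xm[a] -= 2 * h
                    val = (V(xp) - 2 * V(ref) + V(xm)) / (4 * h * h)
                else:
                    pp = ref.copy(); pp[a] += h; pp[b] += h
                    pm = ref.copy(); pm[a] += h; pm[b] -= h
                    mp = ref.copy(); mp[a] -= h; mp[b] += h
                    mm = ref.copy(); mm[a] -= h; mm[b] -= h
                    val = (V(pp) - V(pm) - V(mp) + V(mm)) / (4 * h * h)
                fd[a, b] = fd[b, a] = val
        assert np.abs(H - fd).max() / np.abs(H).max() <= 1e-5

    def test_too_few_residues_rejected(self):
        st = make_structure(ToySpec("linear_chain", 3)).subset([0, 1])
        with pytest.raises(DimensionError):
            build_hessian(st, ParameterSet.for_model(ModelKind.ANM))


class TestSpectrum:
    def test_collinear_chain_spring_eigenvalues(self):
        # bond-only triatomic: longitudinal stiffnesses k and 3k with
        # k = 2*alpha1 (angle/dihedral terms vanish on a collinear chain)
        st = make_structure(ToySpec("linear_chain", 3, side_chain="none"))
        a1 = 7.0
        params = ParameterSet(alpha=(a1, 1e-30, 1e-30, 1e-30),
                              model_kind=ModelKind.STEM)
        H = build_hessian(st, params, None)
        vals = np.linalg.eigvalsh(H)
        np.testing.assert_allclose(vals[-2:], [2 * a1, 6 * a1], rtol=1e-9)
        assert np.abs(vals[:-2]).max() < 1e-9 * a1

    @pytest.mark.parametrize("kind", ALL_3D_MODELS)
    def test_six_rigid_modes_and_positive_rest(self, helix8, kind):
        params, contacts = params_and_contacts(kind, helix8)
        decomp = diagonalize(build_hessian(helix8, params, contacts), kind)
        lam = decomp.eigenvalues
        assert lam.size == 3 * helix8.n_residues
        assert np.abs(lam[:6]).max() <= 1e-8 * lam[-1]
        assert np.all(lam[6:] > 0)

    def test_rigid_body_vectors_in_null_space(self, helix8, encom_params,
                                              helix8_contacts):
        H = build_hessian(helix8, encom_params, helix8_contacts)
        coords = helix8.calpha_coords() - helix8.calpha_coords().mean(axis=0)
        n = helix8.n_residues
        rigid = []
        for ax in range(3):
            t = np.zeros((n, 3)); t[:, ax] = 1.0
            rigid.append(t.ravel())
        for ax in range(3):
            e = np.zeros(3); e[ax] = 1.0
            rigid.append(np.cross(np.broadcast_to(e, (n, 3)), coords).ravel())
        h_norm = np.linalg.norm(H)
        for t in rigid:
            assert np.linalg.norm(H @ t) <= 1e-8 * h_norm

    def test_internal_spectrum_rotation_invariant(self, helix8, encom_params,
                                                  eps_default, rng):
        d0 = compute_modes(helix8, encom_params,
                           build_contact_model(helix8, eps_default))
        moved = helix8.transformed(random_rotation(rng),
                                   np.array([3.0, 1.0, -2.0]))
        d1 = compute_modes(moved, encom_params,
                           build_contact_model(moved, eps_default))
        np.testing.assert_allclose(d1.internal_eigenvalues,
                                   d0.internal_eigenvalues, rtol=1e-6)

    def test_orthonormal_eigenvectors(self, helix8_decomp):
        V = helix8_decomp.eigenvectors
        np.testing.assert_allclose(V.T @ V, np.eye(V.shape[1]), atol=1e-8)

    def test_gnm_single_rigid_mode(self, helix8):
        decomp = compute_modes(helix8, ParameterSet.for_model(ModelKind.GNM))
        assert decomp.n_rigid == 1
        assert decomp.eigenvalues.size == helix8.n_residues
        assert abs(decomp.eigenvalues[0]) <= 1e-10 * decomp.eigenvalues[-1]

    def test_indefinite_matrix_rejected(self):
        H = np.diag([1.0, 2.0, -1.0])
        from encom.enm_core import NotPositiveSemidefiniteError
        with pytest.raises(NotPositiveSemidefiniteError):
            diagonalize(H, ModelKind.GNM)


class TestScalingInvariance:
    def test_alpha_scaling_scales_eigenvalues_only(self, helix8, eps_default):
        contacts = build_contact_model(helix8, eps_default)
        c = 3.7
        p1 = ParameterSet(model_kind=ModelKind.ENCOM)
        p2 = ParameterSet(alpha=tuple(c * a for a in p1.alpha),
                          model_kind=ModelKind.ENCOM)
        H1 = build_hessian(helix8, p1, contacts)
        H2 = build_hessian(helix8, p2, contacts)
        np.testing.assert_allclose(H2, c * H1, rtol=1e-12)
        d1, d2 = diagonalize(H1, p1.model_kind), diagonalize(H2, p2.model_kind)
        np.testing.assert_allclose(d2.internal_eigenvalues,
                                   c * d1.internal_eigenvalues, rtol=1e-9)

    def test_scale_invariant_observables(self, helix8, eps_default):
        # b-factor correlations, overlaps and entropy differences are
        # unchanged when all four force constants are scaled together
        contacts = build_contact_model(helix8, eps_default)
        mut = helix8.copy()
        for atom in mut.residues[4].atoms:
            if atom.name == "CB":
                atom.radius *= 1.8
        contacts_mut = build_contact_model(mut, eps_default)
        c = 10.0
        p1 = ParameterSet(model_kind=ModelKind.ENCOM)
        p2 = ParameterSet(alpha=tuple(c * a for a in p1.alpha),
                          model_kind=ModelKind.ENCOM)
        d1 = compute_modes(helix8, p1, contacts)
        d2 = compute_modes(helix8, p2, contacts)
        m1 = compute_modes(mut, p1, contacts_mut)
        m2 = compute_modes(mut, p2, contacts_mut)
        np.testing.assert_allclose(predict_bfactors(d2),
                                   predict_bfactors(d1) / c, rtol=1e-9)
        assert entropy_difference(d1, m1) == pytest.approx(
            entropy_difference(d2, m2), rel=1e-9)


class TestCrossCheck:
    def test_anm_spectrum_matches_bio3d(self, tmp_path):
        """Independent ANM reference: the bio3d R package on the same toy
        structure (spring-constant conventions differ by a constant factor,
        so normalized internal spectra are compared)."""
        st = make_structure(ToySpec("ideal_helix", 8, side_chain="none"))
        pdb = tmp_path / "helix.pdb"
        write_pdb(st, pdb)
        script = (
            'suppressMessages(library(bio3d));'
            f'pdb <- read.pdb("{pdb}");'
            'm <- nma(pdb, ff="anm", cutoff=18, mass=FALSE, temp=NULL);'
            'cat("EIGENVALUES", sprintf("%.12g", m$L), "\\n")'
        )
        proc = subprocess.run(["Rscript", "-e", script],
                              capture_output=True, text=True, timeout=300)
        assert proc.returncode == 0, proc.stderr
        tokens = proc.stdout.split("EIGENVALUES", 1)[1].split()
        ref = np.array([float(x) for x in tokens])
        decomp = compute_modes(st, ParameterSet.for_model(ModelKind.ANM))
        ours = decomp.internal_eigenvalues
        theirs = np.sort(ref)[6:]
        np.testing.assert_allclose(ours / ours[0], theirs / theirs[0],
                                   rtol=1e-3)
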