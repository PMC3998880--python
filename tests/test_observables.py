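import numpy as np
import pytest

from encom.structure_io import DimensionError
from encom.contacts import InteractionMatrix, build_contact_model
from encom.enm_core import (ModelKind, ParameterSet, SpectralDecomposition,
                            build_hessian, compute_modes)
from encom.fixtures import ToySpec, make_mutation_pair, make_structure
from encom.observables import (UndefinedOverlapError, delta_b_profile,
                               entropy_difference, overlap, predict_bfactors,
                               predict_ddg, superpose)
from conftest import random_rotation


def displace(structure, delta):
    out = structure.copy()
    d = delta.reshape(structure.n_residues, 3)
    for i, res in enumerate(out.residues):
        for atom in res.atoms:
            atom.coords = atom.coords + d[i]
    return out


class TestBfactors:
    def test_equals_pseudoinverse_block_traces(self, helix8, encom_params,
                                               helix8_contacts,
                                               helix8_decomp):
        H = build_hessian(helix8, encom_params, helix8_contacts)
        Hp = np.linalg.pinv(H, rcond=1e-10)
        traces = np.array([np.trace(Hp[3 * i:3 * i + 3, 3 * i:3 * i + 3])
                           for i in range(helix8.n_residues)])
        b = predict_bfactors(helix8_decomp)
        np.testing.assert_allclose(b, traces, rtol=1e-8)

    def test_homogeneous_in_eigenvalues(self, helix8_decomp):
        import dataclasses
        c = 4.0
        scaled = dataclasses.replace(
            helix8_decomp, eigenvalues=c * helix8_decomp.eigenvalues)
        np.testing.assert_allclose(predict_bfactors(scaled),
                                   predict_bfactors(helix8_decomp) / c,
                                   rtol=1e-12)

    def test_single_soft_mode_dominates(self):
        # one internal mode far softer than the rest: b is proportional to
        # that mode's per-node squared amplitude (limit case of the sum)
        n = 5
        rng = np.random.default_rng(0)
        Q, _ = np.linalg.qr(rng.normal(size=(3 * n, 3 * n)))
        lam = np.concatenate([np.zeros(6), [1e-6],
                              np.full(3 * n - 7, 1e6)])
        decomp = SpectralDecomposition(lam, Q, 6, ModelKind.ENCOM, n)
        b = predict_bfactors(decomp)
        soft = Q[:, 6].reshape(n, 3)
        expected = (soft ** 2).sum(axis=1) / 1e-6
        np.testing.assert_allclose(b, expected, rtol=1e-4)

    def test_nonpositive_internal_eigenvalue_rejected(self, helix8_decomp):
        import dataclasses
        lam = helix8_decomp.eigenvalues.copy()
        lam[10] = -1.0
        bad = dataclasses.replace(helix8_decomp, eigenvalues=lam)
        with pytest.raises(ValueError):
            predict_bfactors(bad)


class TestOverlap:
    def test_displacement_along_mode7_gives_unit_overlap(
            self, helix8, helix8_decomp):
        mode7 = helix8_decomp.eigenvectors[:, 6]
        target = displace(helix8, 0.05 * mode7)
        obs = overlap(helix8_decomp, helix8, target)
        assert obs.best_overlap == pytest.approx(1.0, abs=1e-6)
        assert obs.best_mode == 7
        assert np.all(obs.overlaps[1:] <= 1e-4)

    def test_displacement_outside_slowest_ten_modes(self, helix8,
                                                    helix8_decomp):
        # constructed orthogonal to the 10 slowest internal modes
        v = helix8_decomp.internal_modes[:, 12]
        target = displace(helix8, 0.05 * v)
        obs = overlap(helix8_decomp, helix8, target, n_best=10)
        assert obs.best_overlap <= 1e-4

    def test_squared_overlaps_sum_to_one_for_internal_displacement(
            self, helix8, helix8_decomp, rng):
        coeffs = rng.normal(size=helix8_decomp.internal_modes.shape[1])
        dr = helix8_decomp.internal_modes @ coeffs
        dr *= 0.05 / np.linalg.norm(dr)
        target = displace(helix8, dr)
        obs = overlap(helix8_decomp, helix8, target)
        assert float(np.sum(obs.overlaps ** 2)) == pytest.approx(1.0,
                                                                 abs=1e-6)
        assert np.all(obs.overlaps <= 1.0 + 1e-12)

    def test_identical_conformations_rejected(self, helix8, helix8_decomp):
        with pytest.raises(UndefinedOverlapError):
            overlap(helix8_decomp, helix8, helix8.copy())

    def test_superposition_removes_rigid_motion(self, helix8, helix8_decomp,
                                                rng):
        mode7 = helix8_decomp.eigenvectors[:, 6]
        target = displace(helix8, 0.05 * mode7)
        moved = target.transformed(random_rotation(rng),
                                   np.array([4.0, 4.0, 4.0]))
        obs = overlap(helix8_decomp, helix8, moved)
        assert obs.best_overlap == pytest.approx(1.0, abs=1e-5)

    def test_partial_match_requires_rebuild(self, helix8, helix8_decomp):
        truncated = helix8.subset(range(6))
        with pytest.raises(DimensionError):
            overlap(helix8_decomp, helix8, truncated)


class TestSuperpose:
    def test_recovers_rigid_transform(self, helix8, rng):
        x = helix8.calpha_coords()
        R = random_rotation(rng)
        t = np.array([1.0, 2.0, 3.0])
        fitted, R_fit, t_fit = superpose(x @ R.T + t, x)
        np.testing.assert_allclose(fitted, x, atol=1e-10)


class TestEntropyDifference:
    def test_identical_zero(self, helix8_decomp):
        assert entropy_difference(helix8_decomp, helix8_decomp) == 0.0

    def test_antisymmetric(self, helix8, helix8_decomp, encom_params,
                           eps_default):
        mut = helix8.copy()
        for atom in mut.residues[3].atoms:
            if atom.name == "CB":
                atom.radius *= 1.6
        d_mut = compute_modes(mut, encom_params,
                              build_contact_model(mut, eps_default))
        ds = entropy_difference(helix8_decomp, d_mut)
        assert ds != 0.0
        assert entropy_difference(d_mut, helix8_decomp) == pytest.approx(
            -ds, rel=1e-12)

    def test_additive_over_three_states(self, helix8, encom_params,
                                        eps_default, helix8_decomp):
        decomps = [helix8_decomp]
        for scale in (1.4, 2.0):
            m = helix8.copy()
            for atom in m.residues[3].atoms:
                if atom.name == "CB":
                    atom.radius *= scale
            decomps.append(compute_modes(
                m, encom_params, build_contact_model(m, eps_default)))
        a, b, c = decomps
        assert (entropy_difference(a, b) + entropy_difference(b, c)
                == pytest.approx(entropy_difference(a, c), rel=1e-9))

    def test_softening_direction(self, helix8_decomp):
        import dataclasses
        for c in (1.5, 3.0, 10.0):
            stiffer = dataclasses.replace(
                helix8_decomp, eigenvalues=c * helix8_decomp.eigenvalues)
            ds = entropy_difference(helix8_decomp, stiffer)
            n_int = helix8_decomp.internal_eigenvalues.size
            assert ds == pytest.approx(-0.5 * n_int * np.log(c), rel=1e-9)

    def test_size_mismatch(self, helix8_decomp, helix5, encom_params,
                           eps_default):
        d5 = compute_modes(helix5, encom_params,
                           build_contact_model(helix5, eps_default))
        with pytest.raises(DimensionError):
            entropy_difference(helix8_decomp, d5)


class TestPredictDdg:
    def test_identical_structures_score_zero(self, helix8, encom_params):
        assert predict_ddg(helix8, helix8.copy(), encom_params) == 0.0

    def test_contact_change_scores_nonzero_and_rotation_stable(self, rng):
        wt, mut = make_mutation_pair(ToySpec("ideal_helix", 8), 4,
                                     radius_scale=2.0)
        params = ParameterSet(model_kind=ModelKind.ENCOM)
        score = predict_ddg(wt, mut, params)
        assert score != 0.0
        R = random_rotation(rng)
        t = np.array([2.0, -1.0, 7.0])
        score_rot = predict_ddg(wt.transformed(R, t), mut.transformed(R, t),
                                params)
        assert score_rot == pytest.approx(score, rel=1e-5)

    @pytest.mark.parametrize("kind", [ModelKind.ANM, ModelKind.STEM])
    def test_backbone_only_models_score_side_chain_changes_zero(self, kind):
        # side-chain-only changes are invisible to C-alpha-only potentials
        wt, mut = make_mutation_pair(ToySpec("ideal_helix", 8), 4,
                                     radius_scale=2.0)
        score = predict_ddg(wt, mut, ParameterSet.for_model(kind))
        assert abs(score) < 1e-8

    def test_residue_count_mismatch(self, helix8, helix5, encom_params):
        with pytest.raises(DimensionError):
            predict_ddg(helix8, helix5, encom_params)


class TestDeltaBProfile:
    def test_identical_inputs_zero(self, helix8_decomp):
        np.testing.assert_array_equal(
            delta_b_profile(helix8_decomp, helix8_decomp),
            np.zeros(helix8_decomp.n_residues))

    def test_invariant_under_profile_rescaling(self, helix8_decomp):
        # z-scoring removes the arbitrary model scale entirely
        import dataclasses
        scaled = dataclasses.replace(
            helix8_decomp, eigenvalues=5.0 * helix8_decomp.eigenvalues)
        np.testing.assert_allclose(
            delta_b_profile(helix8_decomp, scaled),
            np.zeros(helix8_decomp.n_residues), atol=1e-10)

    def test_softened_residue_is_profile_extremum(self):
        # constructed spectra: localized modes, one residue softened in the
        # mutant; the profile must dip (negative extremum) exactly there
        n, p = 6, 4
        lam_wt = np.concatenate([np.zeros(6), np.ones(3 * n - 6)])
        lam_mut = lam_wt.copy()
        soft_cols = [6 + 3 * (p - 2), 7 + 3 * (p - 2), 8 + 3 * (p - 2)]
        d_wt = SpectralDecomposition(lam_wt, np.eye(3 * n), 6,
                                     ModelKind.ENCOM, n)
        lam_mut[soft_cols] = 0.2
        d_mut = SpectralDecomposition(lam_mut, np.eye(3 * n), 6,
                                      ModelKind.ENCOM, n)
        db = delta_b_profile(d_wt, d_mut)
        assert int(np.argmin(db)) == p
        assert db[p] < 0
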