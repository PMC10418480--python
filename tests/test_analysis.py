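"""Superposition, subset RMSD, RMSF and circular summaries."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import torsionforge as tf
from torsionforge.analysis import (AnalysisError, KRAS_NON_SWITCH,
                                   make_selection, parse_selection)


def _rigid(model, rot=None, shift=(0, 0, 0)):
    rot = rot or Rotation.identity()
    return tf.ModelRecord(model_id=model.model_id, atoms=[
        tf.Atom(a.name, a.resid, a.resname, a.chain,
                tuple(rot.apply(np.asarray(a.xyz)) + np.asarray(shift)))
        for a in model.atoms
    ])


@pytest.fixture()
def helix():
    return tf.build_backbone([-60.0] * 8, [-45.0] * 8)


ALL = tf.SelectionSpec(fit_selection=lambda a: True,
                       measure_selection=lambda a: True)


class TestSuperpose:
    def test_self_fit_rmsd_zero(self, helix):
        _, rmsd = tf.superpose(helix, helix, ALL)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_translated_copy_fits_exactly(self, helix):
        moved = _rigid(helix, shift=(5.0, -3.0, 2.0))
        fitted, rmsd = tf.superpose(moved, helix, ALL)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(fitted.coords_array(), helix.coords_array(), atol=1e-9)

    def test_rotated_copy_fits_exactly(self, helix, rng):
        rot = Rotation.from_rotvec(rng.normal(size=3))
        moved = _rigid(helix, rot=rot, shift=(1.0, 2.0, 3.0))
        _, rmsd = tf.superpose(moved, helix, ALL)
        assert rmsd == pytest.approx(0.0, abs=1e-8)

    def test_known_rotation_vs_rotation_grid_oracle(self, rng):
        """Kabsch result beats/equals a brute-force rotation search."""
        pts = np.array([[0, 0, 0], [2, 0, 0], [0, 1.5, 0], [0.3, 0.2, 2.5]])
        ref = tf.ModelRecord(1, [tf.Atom("CA", i + 1, "ALA", "A", tuple(p))
                                 for i, p in enumerate(pts)])
        noisy = pts + rng.normal(0, 0.1, pts.shape)
        rot = Rotation.from_euler("zyx", [40, -25, 65], degrees=True)
        mob = tf.ModelRecord(1, [tf.Atom("CA", i + 1, "ALA", "A", tuple(p))
                                 for i, p in enumerate(rot.apply(noisy) + 4.0)])
        _, rmsd = tf.superpose(mob, ref, ALL)

        best = np.inf
        mob_c = noisy - noisy.mean(axis=0)  # rigid motion cancels after centering
        ref_c = pts - pts.mean(axis=0)
        for a in np.arange(0, 360, 4):
            for b in np.arange(0, 180, 4):
                for c in np.arange(0, 360, 4):
                    r = Rotation.from_euler("zyz", [a, b, c], degrees=True)
                    d = r.apply(mob_c) - ref_c
                    best = min(best, np.sqrt(np.mean(np.sum(d ** 2, axis=1))))
        assert rmsd <= best + 1e-3

    def test_fit_never_worse_than_no_fit(self, helix, rng):
        moved = tf.ModelRecord(1, [
            tf.Atom(a.name, a.resid, a.resname, a.chain,
                    tuple(np.asarray(a.xyz) + rng.normal(0, 0.5, 3)))
            for a in helix.atoms
        ])
        _, rmsd = tf.superpose(moved, helix, ALL)
        raw = np.sqrt(np.mean(np.sum(
            (moved.coords_array() - helix.coords_array()) ** 2, axis=1)))
        assert rmsd <= raw + 1e-12

    def test_too_few_atoms_rejected(self, helix):
        spec = tf.SelectionSpec(fit_selection=lambda a: a.resid == 1 and a.name == "N")
        with pytest.raises(AnalysisError):
            tf.superpose(helix, helix, spec)


class TestSubsetRMSD:
    def test_identical_ensemble_is_zero(self, helix):
        mean, std, vals = tf.subset_rmsd([helix] * 4, helix, ALL)
        assert mean == pytest.approx(0.0, abs=1e-9)
        assert std == pytest.approx(0.0, abs=1e-9)

    def test_injected_displacement_recovered(self, helix):
        # fit on residues 1-6, displace the measured residue-8 N by d
        d = 1.7
        spec = tf.SelectionSpec(
            fit_selection=make_selection(resids=range(1, 7)),
            measure_selection=make_selection(resids=[8], atom_names=["N"]),
        )
        moved = tf.ModelRecord(2, [
            tf.Atom(a.name, a.resid, a.resname, a.chain,
                    tuple(np.asarray(a.xyz) + (d if (a.resid == 8 and a.name == "N")
                                               else 0.0) * np.array([0, 0, 1.0])))
            for a in helix.atoms
        ])
        mean, std, _ = tf.subset_rmsd([moved], helix, spec)
        assert mean == pytest.approx(d, rel=1e-6)

    def test_centroid_of_single_atom_equals_its_deviation(self, helix):
        spec = tf.SelectionSpec(
            fit_selection=make_selection(resids=range(1, 7)),
            measure_selection=make_selection(resids=[8], atom_names=["N"]),
        )
        moved = _rigid(helix, shift=(0, 0, 0))
        moved.atoms = [tf.Atom(a.name, a.resid, a.resname, a.chain,
                               tuple(np.asarray(a.xyz) + ((0, 0, 0.9) if
                                     (a.resid == 8 and a.name == "N") else (0, 0, 0))))
                       for a in helix.atoms]
        m_rmsd, _, _ = tf.subset_rmsd([moved], helix, spec)
        m_cent, _, _ = tf.subset_rmsd([moved], helix, spec, centroid=True)
        assert m_cent == pytest.approx(m_rmsd, rel=1e-9)

    def test_invariant_to_rigid_pretransformation(self, helix, rng):
        spec = tf.SelectionSpec(
            fit_selection=make_selection(resids=range(1, 7)),
            measure_selection=make_selection(resids=[8]),
        )
        jittered = tf.ModelRecord(2, [
            tf.Atom(a.name, a.resid, a.resname, a.chain,
                    tuple(np.asarray(a.xyz) + rng.normal(0, 0.3, 3)))
            for a in helix.atoms
        ])
        m1, _, _ = tf.subset_rmsd([jittered], helix, spec)
        rot = Rotation.from_rotvec([0.3, -1.2, 0.8])
        m2, _, _ = tf.subset_rmsd([_rigid(jittered, rot=rot, shift=(9, 9, 9))],
                                  helix, spec)
        assert m1 == pytest.approx(m2, abs=1e-9)

    def test_missing_measure_selection_rejected(self, helix):
        spec = tf.SelectionSpec(fit_selection=lambda a: True)
        with pytest.raises(AnalysisError):
            tf.subset_rmsd([helix], helix, spec)


class TestRMSF:
    def test_identical_models_zero(self, helix):
        fit = tf.SelectionSpec(fit_selection=lambda a: True)
        rmsf = tf.per_residue_rmsf([helix] * 3, fit)
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in rmsf.values())

    def test_jittered_residue_matches_sigma(self, helix):
        """One CA jittered with isotropic sigma -> RMSF ~ sigma*sqrt(3)."""
        rng = np.random.default_rng(99)
        sigma = 0.4
        models = []
        for j in range(400):
            atoms = [tf.Atom(a.name, a.resid, a.resname, a.chain,
                             tuple(np.asarray(a.xyz) +
                                   (rng.normal(0, sigma, 3) if
                                    (a.resid == 8 and a.name == "CA") else 0.0)))
                     for a in helix.atoms]
            models.append(tf.ModelRecord(j + 1, atoms))
        fit = tf.SelectionSpec(fit_selection=make_selection(resids=range(1, 7)))
        rmsf = tf.per_residue_rmsf(models, fit)
        assert rmsf[8] == pytest.approx(sigma * np.sqrt(3), rel=0.1)
        assert rmsf[3] < 0.05

    def test_invariant_to_global_rigid_motion(self, helix, rng):
        models = [helix]
        for j in range(3):
            jit = tf.ModelRecord(j + 2, [
                tf.Atom(a.name, a.resid, a.resname, a.chain,
                        tuple(np.asarray(a.xyz) + rng.normal(0, 0.2, 3)))
                for a in helix.atoms])
            models.append(jit)
        fit = tf.SelectionSpec(fit_selection=lambda a: True)
        base = tf.per_residue_rmsf(models, fit)
        rot = Rotation.from_rotvec([1.0, 0.2, -0.5])
        moved = [_rigid(m, rot=rot, shift=(10, -5, 3)) for m in models]
        other = tf.per_residue_rmsf(moved, fit)
        for r in base:
            assert base[r] == pytest.approx(other[r], abs=1e-8)

    def test_single_model_rejected(self, helix):
        with pytest.raises(AnalysisError):
            tf.per_residue_rmsf([helix],
                                tf.SelectionSpec(fit_selection=lambda a: True))


def _samples(angles):
    return tf.DihedralSampleSet(residue_index=1, angle_kind="psi",
                                angles_deg=np.asarray(angles, dtype=float),
                                model_ids=[str(i) for i in range(len(angles))])


class TestCircularSummary:
    def test_degenerate_point_mass(self):
        cfg = tf.CircularKernelConfig.from_width(0.6, 10)
        s = tf.circular_summary(_samples([42.0] * 10), config=cfg)
        assert s.circular_mean_deg == pytest.approx(42.0)
        assert s.circular_std_deg == pytest.approx(0.0, abs=1e-6)
        assert s.multimodality == 1

    def test_antipodal_clusters_flag_undefined_mean(self):
        cfg = tf.CircularKernelConfig.from_width(0.6, 20)
        s = tf.circular_summary(_samples([90.0] * 10 + [-90.0] * 10), config=cfg)
        assert not s.mean_defined
        assert s.resultant_length < 1e-6
        assert s.multimodality == 2

    def test_von_mises_std_matches_kappa(self):
        rng = np.random.default_rng(21)
        kappa = 6.0
        draws = np.degrees(rng.vonmises(0.5, kappa, 4000))
        s = tf.circular_summary(_samples(draws))
        from scipy.special import i0, i1
        expected_R = i1(kappa) / i0(kappa)
        expected_std = np.degrees(np.sqrt(-2 * np.log(expected_R)))
        assert s.circular_std_deg == pytest.approx(expected_std, rel=0.05)

    def test_weighted_mean_shifts_toward_upweighted_cluster(self):
        angles = [-30.0] * 5 + [30.0] * 5
        cfg = tf.CircularKernelConfig.from_width(0.6, 10)
        w = np.array([10.0] * 5 + [1.0] * 5)
        s = tf.circular_summary(_samples(angles), weights=w, config=cfg)
        assert s.circular_mean_deg < -15.0


class TestSelectionsAndCSP:
    def test_parse_selection_grammar(self, helix):
        pred = parse_selection("resid 1-3,5 and backbone")
        resids = {a.resid for a in helix.atoms if pred(a)}
        assert resids == {1, 2, 3, 5}
        assert all(a.name in ("N", "CA", "C", "O")
                   for a in helix.atoms if pred(a))

    def test_kras_non_switch_preset(self):
        assert 9 in KRAS_NON_SWITCH and 18 in KRAS_NON_SWITCH
        for r in (10, 17, 28, 40, 60, 76):
            assert r not in KRAS_NON_SWITCH
        assert max(KRAS_NON_SWITCH) == 169

    @pytest.mark.parametrize("dh,dn,scale,expected", [
        (0.0, 0.0, 0.2, 0.0),
        (0.3, 0.0, 0.2, 0.3),
        (0.1, 0.5, 0.2, 0.14142135623730953),
    ])
    def test_combined_csp(self, dh, dn, scale, expected):
        assert tf.combined_csp(dh, dn, scale) == pytest.approx(expected, rel=1e-9)
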