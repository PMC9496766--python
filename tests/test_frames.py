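"""Superposition, pseudosymmetry-axis detection and reference frames."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from dimerframe.core import ConformationEnsemble, RigidTransform
from dimerframe.frames import (
    align_ensemble,
    build_drf,
    build_nrf,
    fold_equivalences,
    kabsch_superpose,
    pseudosymmetry_axis,
)
from dimerframe.synthetic import synthetic_dimer, synthetic_ncp_dna

from conftest import random_rotation


class TestKabsch:
    def test_identical_sets(self, rng):
        pts = rng.normal(size=(30, 3))
        transform, rmsd = kabsch_superpose(pts, pts)
        assert rmsd < 1e-12
        np.testing.assert_allclose(transform.rotation, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(transform.translation, 0.0, atol=1e-10)

    def test_recovers_known_transform(self, rng):
        pts = rng.normal(size=(25, 3))
        R = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        t = np.array([1.0, 2.0, 3.0])
        moved = pts @ R.T + t
        transform, rmsd = kabsch_superpose(pts, moved)
        assert rmsd < 1e-8
        np.testing.assert_allclose(transform.rotation, R, atol=1e-8)
        np.testing.assert_allclose(transform.translation, t, atol=1e-8)

    def test_mirror_image_keeps_proper_rotation(self, rng):
        # a chiral set cannot be superposed onto its mirror by any proper
        # rotation: verified against scipy's independent Kabsch solver
        pts = rng.normal(size=(12, 3))
        mirror = pts * np.array([-1.0, 1.0, 1.0])
        transform, rmsd = kabsch_superpose(pts, mirror)
        assert np.linalg.det(transform.rotation) == pytest.approx(1.0)
        assert rmsd > 0.1
        rot, best_rssd = Rotation.align_vectors(
            mirror - mirror.mean(0), pts - pts.mean(0))
        assert rmsd == pytest.approx(best_rssd / np.sqrt(len(pts)), rel=1e-6)

    def test_agrees_with_scipy_on_random_pairs(self, rng):
        for _ in range(5):
            a = rng.normal(size=(20, 3))
            b = rng.normal(size=(20, 3))
            _, rmsd = kabsch_superpose(a, b)
            rot, rssd = Rotation.align_vectors(b - b.mean(0), a - a.mean(0))
            assert rmsd == pytest.approx(rssd / np.sqrt(20), rel=1e-9)

    def test_rmsd_symmetric_and_rotation_invariant(self, rng):
        a = rng.normal(size=(15, 3))
        b = rng.normal(size=(15, 3))
        _, r_ab = kabsch_superpose(a, b)
        _, r_ba = kabsch_superpose(b, a)
        assert r_ab == pytest.approx(r_ba, rel=1e-9)
        R = random_rotation(rng)
        _, r_rot = kabsch_superpose(a @ R.T, b)
        assert r_rot == pytest.approx(r_ab, rel=1e-9)

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="at least 3"):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_points_rejected(self):
        line = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line)

    def test_weighted_superposition_prioritizes_heavy_points(self, rng):
        a = rng.normal(size=(10, 3))
        b = a.copy()
        b[0] += [5.0, 0, 0]  # outlier
        w = np.ones(10)
        w[0] = 1e-9
        _, rmsd = kabsch_superpose(a, b, weights=w)
        assert rmsd < 1e-4


class TestPseudosymmetryAxis:
    def test_exact_c2_dimer(self, dimer):
        est = pseudosymmetry_axis(dimer)
        assert est.rotation_angle == pytest.approx(180.0, abs=1e-6)
        assert est.fit_rmsd < 1e-9
        # planted axis is x
        assert abs(est.direction @ np.array([1.0, 0, 0])) > 1 - 1e-6

    def test_axis_robust_to_coordinate_noise(self):
        noisy = synthetic_dimer(angle=142.0, noise_sigma=0.3, seed=11)
        est = pseudosymmetry_axis(noisy)
        cos = abs(est.direction @ np.array([1.0, 0, 0]))
        assert np.degrees(np.arccos(min(cos, 1.0))) < 5.0

    def test_equivariance_under_rigid_motion(self, dimer, rng):
        R = random_rotation(rng)
        t = rng.normal(size=3)
        moved = dimer.transformed(RigidTransform(R, t))
        est0 = pseudosymmetry_axis(dimer)
        est1 = pseudosymmetry_axis(moved)
        assert abs(est1.direction @ (R @ est0.direction)) > 1 - 1e-9

    def test_requires_enough_pairs(self, dimer):
        pairs = fold_equivalences(dimer)[:10]
        with pytest.raises(ValueError, match="at least 20"):
            pseudosymmetry_axis(dimer, equivalences=pairs)

    def test_single_chain_rejected(self, dimer):
        from dataclasses import replace

        idx = [i for i, (c, _) in enumerate(dimer.labels) if c == "H2A"]
        single = replace(
            dimer,
            labels=[dimer.labels[i] for i in idx],
            coords=dimer.coords[idx],
            segments={"H2A": dimer.segments["H2A"]},
        )
        with pytest.raises(ValueError, match="2 chains"):
            pseudosymmetry_axis(single)


class TestBuildDrf:
    def test_axes_orthonormal_right_handed(self, dimer):
        frame = build_drf(dimer, pseudosymmetry_axis(dimer))
        np.testing.assert_allclose(frame.axes @ frame.axes.T, np.eye(3),
                                   atol=1e-9)
        np.testing.assert_allclose(np.cross(frame.x, frame.y), frame.z,
                                   atol=1e-9)

    @pytest.mark.parametrize("criterion", ["mean_abs", "variance"])
    def test_y_matches_brute_force_scan(self, dimer, criterion):
        """Y maximizes the projection criterion over a dense angular scan."""
        axis = pseudosymmetry_axis(dimer)
        frame = build_drf(dimer, axis, criterion=criterion)
        idx = np.concatenate([dimer.segment_indices(c, "alpha2")
                              for c in dimer.chains])
        pts = dimer.coords[idx] - frame.origin
        x = frame.x

        def crit(y):
            proj = pts @ y
            return np.mean(np.abs(proj)) if criterion == "mean_abs" else np.var(proj)

        # brute-force scan over 3600 in-plane candidates
        ref = np.array([0.0, 0.0, 1.0])
        e1 = np.cross(x, ref)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(x, e1)
        best = -np.inf
        best_y = None
        for phi in np.linspace(0, np.pi, 3600, endpoint=False):
            y = np.cos(phi) * e1 + np.sin(phi) * e2
            v = crit(y)
            if v > best:
                best, best_y = v, y
        assert crit(frame.y) >= best - 1e-9
        assert min(np.linalg.norm(frame.y - best_y),
                   np.linalg.norm(frame.y + best_y)) < 1e-3

    def test_equivariance_under_rigid_motion(self, dimer, rng):
        R = random_rotation(rng)
        t = rng.normal(size=3) * 10
        transform = RigidTransform(R, t)
        f0 = build_drf(dimer, pseudosymmetry_axis(dimer))
        f1 = build_drf(dimer.transformed(transform),
                       pseudosymmetry_axis(dimer.transformed(transform)))
        np.testing.assert_allclose(f1.origin, transform.apply(f0.origin),
                                   atol=1e-6)
        for a0, a1 in zip((f0.x, f0.y, f0.z), (f1.x, f1.y, f1.z)):
            np.testing.assert_allclose(a1, R @ a0, atol=1e-6)


class TestBuildNrf:
    def test_recovers_planted_superhelical_axis(self):
        _, ref = synthetic_ncp_dna(radius=42.0, pitch=25.0)
        frame = build_nrf(ref.centers)
        cos = abs(frame.z @ np.array([0.0, 0.0, 1.0]))
        assert np.degrees(np.arccos(min(cos, 1.0))) < 1.0

    def test_equivariance_under_rigid_motion(self, rng):
        _, ref = synthetic_ncp_dna()
        R = random_rotation(rng)
        t = rng.normal(size=3) * 20
        f0 = build_nrf(ref.centers)
        f1 = build_nrf(ref.centers @ R.T + t)
        np.testing.assert_allclose(f1.origin, R @ f0.origin + t, atol=1e-6)
        for a0, a1 in zip((f0.x, f0.y, f0.z), (f1.x, f1.y, f1.z)):
            np.testing.assert_allclose(a1, R @ a0, atol=1e-6)

    def test_too_few_base_pairs(self):
        with pytest.raises(ValueError, match="at least 20"):
            build_nrf(np.zeros((10, 3)))


class TestAlignEnsemble:
    def _rigid_copies(self, dimer, rng, n=6):
        frames = np.empty((n, dimer.n_atoms, 3))
        for i in range(n):
            R = random_rotation(rng)
            frames[i] = dimer.coords @ R.T + rng.normal(size=3) * 10
        return ConformationEnsemble(frames=frames, labels=list(dimer.labels))

    def test_rigid_motions_removed_exactly(self, dimer, rng):
        ens = self._rigid_copies(dimer, rng)
        sel = np.arange(dimer.n_atoms)
        aligned = align_ensemble(ens, dimer.coords, sel)
        assert aligned.aligned
        for frame in aligned.frames:
            assert np.abs(frame - dimer.coords).max() < 1e-8

    def test_out_of_selection_perturbation_does_not_change_fit(self, dimer, rng):
        sel = dimer.fold_indices("H2A")
        outside = [i for i in range(dimer.n_atoms) if i not in set(sel)][0]
        frames = np.stack([dimer.coords.copy()])
        perturbed = frames.copy()
        perturbed[0, outside] += [3.0, -2.0, 1.0]
        a0 = align_ensemble(
            ConformationEnsemble(frames=frames, labels=list(dimer.labels)),
            dimer.coords, sel)
        a1 = align_ensemble(
            ConformationEnsemble(frames=perturbed, labels=list(dimer.labels)),
            dimer.coords, sel)
        np.testing.assert_allclose(a0.frames[0][sel], a1.frames[0][sel],
                                   atol=1e-10)

    def test_post_alignment_rmsd_needs_no_resuperposition(self, dimer, rng):
        """Inter-frame RMSD after alignment equals plain coordinate RMSD."""
        ens = self._rigid_copies(dimer, rng, n=4)
        noisy = ens.frames + rng.normal(0, 0.2, ens.frames.shape)
        ens = ConformationEnsemble(frames=noisy, labels=list(dimer.labels))
        aligned = align_ensemble(ens, dimer.coords, np.arange(dimer.n_atoms))
        a, b = aligned.frames[0], aligned.frames[1]
        direct = np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1)))
        # no further superposition: metric equals the raw coordinate RMSD
        from dimerframe.plasticity import max_pairwise_rmsd

        two = ConformationEnsemble(frames=np.stack([a, b]),
                                   labels=list(dimer.labels), aligned=True)
        assert max_pairwise_rmsd(two) == pytest.approx(direct, rel=1e-12)

    def test_empty_or_invalid_selection(self, dimer):
        ens = ConformationEnsemble(frames=dimer.coords[None],
                                   labels=list(dimer.labels))
        with pytest.raises(ValueError, match="nonempty"):
            align_ensemble(ens, dimer.coords, np.array([], dtype=int))
        with pytest.raises(ValueError, match="missing"):
            align_ensemble(ens, dimer.coords, np.array([dimer.n_atoms + 5]))


@given(angle=st.floats(min_value=5.0, max_value=175.0))
def test_rigid_transform_roundtrip(angle):
    """Composing a transform with its inverse recovers the input points."""
    R = Rotation.from_euler("xyz", [angle, angle / 2, -angle]).as_matrix()
    t = np.array([angle, -1.0, 2.0])
    fwd = RigidTransform(R, t)
    inv = RigidTransform(R.T, -R.T @ t)
    pts = np.array([[1.0, 2, 3], [4, 5, 6], [-1, 0, 2]])
    np.testing.assert_allclose(inv.apply(fwd.apply(pts)), pts, atol=1e-8)
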