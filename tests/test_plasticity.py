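"""Bending angle, helix amplitudes, max RMSD, RMSF/RMSV profiles, projections."""

import numpy as np
import pytest
from dataclasses import replace

from dimerframe.core import ConformationEnsemble, ReferenceFrame, RigidTransform
from dimerframe.plasticity import (
    alpha2_angle,
    alpha2_angle_series,
    helix_amplitude,
    max_pairwise_rmsd,
    project_2d,
    rmsf_profile,
    rmsv_profile,
)

from conftest import random_rotation


def _two_vector_dimer(va, vb):
    """Minimal dimer whose α2 chords are exactly va and vb."""
    labels = []
    coords = []
    segments = {}
    for chain, v in (("H2A", va), ("H2B", vb)):
        first, last = (46, 49) if chain == "H2A" else (55, 58)
        segments[chain] = {"alpha2": (first, last)}
        base = np.zeros(3) if chain == "H2A" else np.array([10.0, 0, 0])
        pts = [base, base + v / 3, base + 2 * v / 3, base + np.asarray(v, float)]
        for k, p in enumerate(pts):
            labels.append((chain, first + k))
            coords.append(p)
    from dimerframe.core import DimerModel

    return DimerModel(labels=labels, coords=np.array(coords), segments=segments)


class TestAlpha2Angle:
    @pytest.mark.parametrize("va,vb,expected", [
        ([3.0, 0, 0], [3.0, 0, 0], 0.0),
        ([3.0, 0, 0], [-3.0, 0, 0], 180.0),
        ([3.0, 0, 0], [0, 3.0, 0], 90.0),
    ])
    def test_reference_geometries(self, va, vb, expected):
        dim = _two_vector_dimer(np.array(va), np.array(vb))
        assert alpha2_angle(dim) == pytest.approx(expected, abs=1e-9)

    def test_matches_arccos_oracle_on_random_vectors(self, rng):
        for _ in range(1000):
            va = rng.normal(size=3) * rng.uniform(1, 10)
            vb = rng.normal(size=3) * rng.uniform(1, 10)
            dim = _two_vector_dimer(va, vb)
            expected = np.degrees(np.arccos(np.clip(
                va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb)), -1, 1)))
            assert alpha2_angle(dim) == pytest.approx(expected, abs=1e-10)

    def test_invariant_under_common_rigid_motion(self, dimer, rng):
        theta0 = alpha2_angle(dimer)
        moved = dimer.transformed(
            RigidTransform(random_rotation(rng), rng.normal(size=3) * 10))
        assert alpha2_angle(moved) == pytest.approx(theta0, abs=1e-9)

    def test_series_matches_per_frame_scalar(self, dimer, rng):
        frames = np.stack([
            dimer.coords + rng.normal(0, 0.1, dimer.coords.shape)
            for _ in range(10)
        ])
        ens = ConformationEnsemble(frames=frames, labels=list(dimer.labels),
                                   aligned=True)
        series = alpha2_angle_series(ens, dimer)
        for i in range(10):
            assert series[i] == pytest.approx(
                alpha2_angle(replace(dimer, coords=frames[i])), abs=1e-10)


def _static_ensemble(dimer, n=5):
    return ConformationEnsemble(
        frames=np.repeat(dimer.coords[None], n, axis=0),
        labels=list(dimer.labels), aligned=True,
        segments=dict(dimer.segments))


class TestHelixAmplitude:
    def test_static_ensemble_zero(self, dimer):
        ens = _static_ensemble(dimer)
        assert helix_amplitude(ens, "H2A", 73) == 0.0

    def test_two_frame_displacement(self, dimer):
        frames = np.repeat(dimer.coords[None], 2, axis=0)
        idx = dimer.atom_index("H2A", 73)
        frames[1, idx] += [3.0, 0, 0]
        ens = ConformationEnsemble(frames=frames, labels=list(dimer.labels),
                                   aligned=True)
        assert helix_amplitude(ens, "H2A", 73) == pytest.approx(3.0)

    def test_random_walk_matches_all_pairs_oracle(self, dimer, rng):
        T = 200
        idx = dimer.atom_index("H2A", 73)
        frames = np.repeat(dimer.coords[None], T, axis=0)
        walk = np.cumsum(rng.normal(0, 0.3, (T, 3)), axis=0)
        frames[:, idx] += walk
        ens = ConformationEnsemble(frames=frames, labels=list(dimer.labels),
                                   aligned=True)
        pos = frames[:, idx]
        brute = max(np.linalg.norm(pos[i] - pos[j])
                    for i in range(T) for j in range(i + 1, T))
        assert helix_amplitude(ens, "H2A", 73) == pytest.approx(brute, rel=1e-12)

    def test_max_from_first_variant(self, dimer):
        frames = np.repeat(dimer.coords[None], 3, axis=0)
        idx = dimer.atom_index("H2A", 73)
        frames[1, idx] += [2.0, 0, 0]
        frames[2, idx] += [-1.0, 0, 0]
        ens = ConformationEnsemble(frames=frames, labels=list(dimer.labels),
                                   aligned=True)
        assert helix_amplitude(ens, "H2A", 73, mode="max_from_first") == \
            pytest.approx(2.0)
        assert helix_amplitude(ens, "H2A", 73) == pytest.approx(3.0)

    def test_unaligned_rejected(self, dimer):
        ens = ConformationEnsemble(
            frames=np.repeat(dimer.coords[None], 2, axis=0),
            labels=list(dimer.labels), aligned=False)
        with pytest.raises(ValueError, match="aligned"):
            helix_amplitude(ens, "H2A", 73)

    def test_monotone_under_adding_frames(self, dimer, rng):
        idx = dimer.atom_index("H2B", 82)
        frames = np.repeat(dimer.coords[None], 50, axis=0)
        frames[:, idx] += rng.normal(0, 1.0, (50, 3))
        full = ConformationEnsemble(frames=frames, labels=list(dimer.labels),
                                    aligned=True)
        half = ConformationEnsemble(frames=frames[:25],
                                    labels=list(dimer.labels), aligned=True)
        assert helix_amplitude(full, "H2B", 82) >= helix_amplitude(half, "H2B", 82)


class TestMaxPairwiseRmsd:
    def test_identical_frames_zero(self, dimer):
        assert max_pairwise_rmsd(_static_ensemble(dimer)) == 0.0

    def test_translated_frame_gives_translation_norm(self, dimer):
        frames = np.repeat(dimer.coords[None], 2, axis=0)
        frames[1] += [1.5, 0, 0]
        ens = ConformationEnsemble(frames=frames, labels=list(dimer.labels),
                                   aligned=True)
        assert max_pairwise_rmsd(ens) == pytest.approx(1.5, rel=1e-12)

    def test_matches_all_pairs_oracle(self, dimer, rng):
        T = 100
        frames = dimer.coords[None] + rng.normal(0, 0.5,
                                                 (T, dimer.n_atoms, 3))
        ens = ConformationEnsemble(frames=frames, labels=list(dimer.labels),
                                   aligned=True)
        brute = max(
            np.sqrt(np.mean(np.sum((frames[i] - frames[j]) ** 2, axis=1)))
            for i in range(T) for j in range(i + 1, T))
        assert max_pairwise_rmsd(ens) == pytest.approx(brute, rel=1e-12)

    def test_selection_restricts_metric(self, dimer):
        frames = np.repeat(dimer.coords[None], 2, axis=0)
        moved = dimer.atom_index("H2A", 73)
        frames[1, moved] += [6.0, 0, 0]
        ens = ConformationEnsemble(frames=frames, labels=list(dimer.labels),
                                   aligned=True)
        still = [i for i in range(dimer.n_atoms) if i != moved]
        assert max_pairwise_rmsd(ens, selection=np.array(still)) == 0.0


class TestFluctuationProfiles:
    def test_static_rmsf_zero(self, dimer):
        prof = rmsf_profile(_static_ensemble(dimer))
        assert np.all(prof.values <= 1e-12)
        assert prof.kind == "rmsf_traj"

    def test_alternating_displacement_closed_form(self, dimer):
        d = 0.7
        frames = np.repeat(dimer.coords[None], 4, axis=0)
        idx = dimer.atom_index("H2A", 50)
        frames[::2, idx, 0] += d
        frames[1::2, idx, 0] -= d
        prof = rmsf_profile(ConformationEnsemble(
            frames=frames, labels=list(dimer.labels), aligned=True))
        assert prof.values[idx] == pytest.approx(d, rel=1e-12)

    def test_matches_two_pass_oracle(self, dimer, rng):
        frames = dimer.coords[None] + rng.normal(0, 0.4, (20, dimer.n_atoms, 3))
        ens = ConformationEnsemble(frames=frames, labels=list(dimer.labels),
                                   aligned=True)
        prof = rmsf_profile(ens)
        mean = frames.mean(axis=0)
        oracle = np.sqrt(np.mean(np.sum((frames - mean) ** 2, axis=2), axis=0))
        np.testing.assert_allclose(prof.values, oracle, atol=1e-12)

    def test_rmsv_identical_structures_zero(self, dimer):
        prof = rmsv_profile([dimer.copy(), dimer.copy(), dimer.copy()])
        assert np.all(prof.values <= 1e-12)

    def test_rmsv_single_displacement_halved(self, dimer):
        other = dimer.copy()
        idx = dimer.atom_index("H2B", 60)
        d = 1.8
        other.coords[idx] += [d, 0, 0]
        prof = rmsv_profile([dimer, other])
        pos = prof.labels.index(("H2B", 60))
        assert prof.values[pos] == pytest.approx(d / 2, rel=1e-12)

    def test_rmsv_excludes_missing_residues(self, dimer):
        other = dimer.copy()
        drop = dimer.atom_index("H2A", 73)
        keep = [i for i in range(dimer.n_atoms) if i != drop]
        other = replace(other,
                        labels=[other.labels[i] for i in keep],
                        coords=other.coords[keep])
        prof = rmsv_profile([dimer, other])
        assert ("H2A", 73) not in prof.labels
        assert len(prof.labels) == dimer.n_atoms - 1

    def test_rmsv_equals_rmsf_on_same_frames(self, dimer, rng):
        """Definitional equivalence of the two fluctuation measures."""
        variants = []
        frames = []
        for _ in range(5):
            c = dimer.coords + rng.normal(0, 0.3, dimer.coords.shape)
            variants.append(replace(dimer, coords=c))
            frames.append(c)
        rmsv = rmsv_profile(variants)
        rmsf = rmsf_profile(ConformationEnsemble(
            frames=np.stack(frames), labels=list(dimer.labels), aligned=True))
        np.testing.assert_allclose(rmsv.values, rmsf.values, atol=1e-12)

    def test_too_few_inputs(self, dimer):
        with pytest.raises(ValueError):
            rmsv_profile([dimer])
        one = ConformationEnsemble(frames=dimer.coords[None],
                                   labels=list(dimer.labels), aligned=True)
        with pytest.raises(ValueError):
            rmsf_profile(one)


class TestProject2d:
    @pytest.fixture
    def frame(self):
        return ReferenceFrame(origin=np.array([1.0, 2.0, 3.0]),
                              x=np.array([1.0, 0, 0]),
                              y=np.array([0, 1.0, 0]),
                              z=np.array([0, 0, 1.0]))

    def test_origin_maps_to_zero(self, frame):
        np.testing.assert_allclose(project_2d(frame.origin, frame, "xy"),
                                   [0.0, 0.0], atol=1e-12)

    def test_axis_offset(self, frame):
        p = frame.origin + 2 * frame.x
        np.testing.assert_allclose(project_2d(p, frame, "xy"), [2.0, 0.0],
                                   atol=1e-12)

    def test_projection_never_longer_than_offset(self, frame, rng):
        pts = rng.normal(size=(100, 3)) * 5
        proj = project_2d(pts, frame, "yz")
        off = np.linalg.norm(pts - frame.origin, axis=1)
        assert np.all(np.linalg.norm(proj, axis=1) <= off + 1e-12)

    def test_invalid_plane(self, frame):
        with pytest.raises(ValueError, match="plane"):
            project_2d(np.zeros(3), frame, "xw")
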