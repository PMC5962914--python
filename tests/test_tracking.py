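"""Tractography: invariants, termination rules, geometry and determinism."""

import numpy as np
import pytest
from scipy.optimize import brentq

from svdnet.phantom import (
    ArcCenterline,
    StraightCenterline,
    TractSpec,
    TensorVolume,
    make_tensor_phantom,
)
from svdnet.tracking import (
    SeedRejected,
    StreamlineSet,
    TrackingParams,
    eligible_seeds,
    tensor_invariants,
    track_streamline,
    whole_volume_tractography,
)

from conftest import (
    BACKGROUND_D,
    TUBE_EIGS,
    fa_direct,
    make_straight_tube,
)


def tube_axial_fa_support(eig_along, eig_perp, background_d, fa_threshold,
                          voxel_mm, first_center, last_center):
    """Analytic extent of the FA >= threshold region along the tube axis.

    Between the last in-tube voxel center and the first background center the
    interpolated tensor is (1 - a) * D_tube + a * background_d * I; the FA of
    that blend is computed from its eigenvalues directly and the crossing
    fraction a* solved by bisection.
    """
    def blend_fa(a):
        lam = np.array([(1 - a) * eig_along + a * background_d,
                        (1 - a) * eig_perp + a * background_d,
                        (1 - a) * eig_perp + a * background_d])
        return fa_direct(lam)

    a_star = brentq(lambda a: blend_fa(a) - fa_threshold, 0.0, 1.0 - 1e-12)
    margin = a_star * voxel_mm
    return (last_center - first_center) + 2 * margin


class TestTensorInvariants:
    @pytest.mark.parametrize("eigs, fa_expected, md_expected", [
        ((1e-3, 1e-3, 1e-3), 0.0, 1e-3),
        ((1.0, 0.0, 0.0), 1.0, 1 / 3),
        ((1.7e-3, 0.2e-3, 0.2e-3), 0.870388, 0.7e-3),
    ])
    def test_closed_form_eigenvalue_cases(self, eigs, fa_expected, md_expected):
        # assemble a rotated tensor so the eigen-decomposition is exercised
        rng = np.random.default_rng(0)
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        d = q @ np.diag(eigs) @ q.T
        fa, md, axis = tensor_invariants(d)
        assert fa == pytest.approx(fa_expected, abs=1e-6)
        assert md == pytest.approx(md_expected, rel=1e-12)
        assert fa == pytest.approx(fa_direct(eigs), abs=1e-12)
        # principal axis is the eigenvector of the largest eigenvalue
        assert d @ axis == pytest.approx(max(eigs) * axis, abs=1e-9)

    def test_zero_tensor_fa_undefined(self):
        with pytest.raises(ValueError, match="zero tensor"):
            tensor_invariants(np.zeros((3, 3)))

    def test_asymmetric_tensor_rejected(self):
        t = np.eye(3)
        t[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            tensor_invariants(t)


class TestSingleStreamline:
    def test_straight_tube_length_matches_analytic_support(self, tube_volume):
        s = track_streamline(tube_volume, [40.0, 15.0, 15.0])
        expected = tube_axial_fa_support(*TUBE_EIGS, BACKGROUND_D, 0.2, 2.5,
                                         first_center=11.25, last_center=68.75)
        assert abs(s.length_mm - expected) <= 2 * 0.5 + 1e-9
        # endpoints fall in the two end caps (x below start cap-end, above end cap-start)
        xs = sorted([s.points[0][0], s.points[-1][0]])
        assert xs[0] < 10.1 + 5.0 and xs[1] > 69.9 - 5.0

    def test_point_spacing_equals_step(self, tube_volume):
        s = track_streamline(tube_volume, [40.0, 15.0, 15.0])
        gaps = np.linalg.norm(np.diff(s.points, axis=0), axis=1)
        assert np.allclose(gaps, 0.5, atol=1e-9)

    def test_recomputed_length_matches_stored(self, tube_volume):
        s = track_streamline(tube_volume, [40.0, 15.0, 15.0])
        assert s.length_mm == pytest.approx(
            np.linalg.norm(np.diff(s.points, axis=0), axis=1).sum())

    def test_seed_in_isotropic_background_rejected(self, tube_volume):
        with pytest.raises(SeedRejected):
            track_streamline(tube_volume, [40.0, 5.0, 5.0])

    def test_seed_outside_volume_rejected(self, tube_volume):
        with pytest.raises(SeedRejected):
            track_streamline(tube_volume, [-10.0, 15.0, 15.0])

    def test_raising_stop_threshold_never_lengthens(self, tube_volume):
        lengths = []
        for thr in (0.2, 0.4, 0.6, 0.85):
            p = TrackingParams(fa_stop_threshold=thr)
            lengths.append(track_streamline(tube_volume, [40.0, 15.0, 15.0], p).length_mm)
        assert all(a >= b - 1e-12 for a, b in zip(lengths, lengths[1:]))

    def test_tracked_length_converges_with_step(self, tube_volume):
        # smaller Euler steps cannot change the straight-tube length by more
        # than the step quantization at each end
        l_half = track_streamline(tube_volume, [40.0, 15.0, 15.0],
                                  TrackingParams(step_mm=0.5)).length_mm
        l_tenth = track_streamline(tube_volume, [40.0, 15.0, 15.0],
                                   TrackingParams(step_mm=0.1)).length_mm
        assert abs(l_half - l_tenth) <= 2 * 0.5 + 1e-9


def make_junction_volume():
    """Two half-volumes with perpendicular principal axes (abrupt 90 degree turn)."""
    shape = (24, 24, 4)
    lam_along, lam_perp = TUBE_EIGS
    t = np.empty(shape + (3, 3))
    x_axis = np.diag([lam_along, lam_perp, lam_perp])
    y_axis = np.diag([lam_perp, lam_along, lam_perp])
    t[:12] = x_axis
    t[12:] = y_axis
    return TensorVolume(t, (2.5, 2.5, 2.5), np.diag([2.5, 2.5, 2.5, 1.0]))


class TestTerminationRules:
    def test_ninety_degree_junction_terminates(self):
        vol = make_junction_volume()
        # junction plane at x = 30 mm; seed well inside the x-aligned half
        s = track_streamline(vol, [10.0, 30.0, 5.0])
        assert s.points[:, 0].max() <= 30.0 + 0.5  # never crosses the junction
        # and no streamline in the whole volume crosses it either
        ss = whole_volume_tractography(vol, TrackingParams(min_length_mm=5.0))
        crossing = [st for st in ss
                    if st.points[:, 0].min() < 27.0 and st.points[:, 0].max() > 33.0]
        assert crossing == []

    def test_short_tube_removed_by_length_gate(self):
        vol, _ = make_straight_tube(start_x=10.1, end_x=25.1, shape=(16, 12, 12))
        ss = whole_volume_tractography(vol)  # default min length 20 mm
        assert len(ss) == 0
        # same phantom with the gate lowered produces streamlines
        ss2 = whole_volume_tractography(vol, TrackingParams(min_length_mm=5.0))
        assert len(ss2) > 0


class TestWholeVolume:
    def test_seed_count_matches_bruteforce_oracle(self, tube_volume):
        params = TrackingParams()
        seeds = eligible_seeds(tube_volume, params)
        # independent oracle: manual trilinear interpolation + eigenvalues
        factors = 5
        shape = tube_volume.shape
        axes = [(np.arange(n * factors) + 0.5) / factors for n in shape]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        world = grid * 2.5
        idx = grid - 0.5
        t = tube_volume.tensors
        padded = np.zeros((shape[0] + 2, shape[1] + 2, shape[2] + 2, 3, 3))
        padded[1:-1, 1:-1, 1:-1] = t
        base = np.floor(idx).astype(int)
        frac = idx - base
        interp = np.zeros((len(grid), 3, 3))
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    wgt = (np.where(dx, frac[:, 0], 1 - frac[:, 0])
                           * np.where(dy, frac[:, 1], 1 - frac[:, 1])
                           * np.where(dz, frac[:, 2], 1 - frac[:, 2]))
                    interp += wgt[:, None, None] * padded[base[:, 0] + 1 + dx,
                                                          base[:, 1] + 1 + dy,
                                                          base[:, 2] + 1 + dz]
        lam = np.linalg.eigvalsh(interp)
        lbar = lam.mean(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            fa = np.sqrt(1.5) * np.linalg.norm(lam - lbar, axis=1) / np.linalg.norm(lam, axis=1)
        fa = np.nan_to_num(fa)
        oracle = world[fa >= params.fa_seed_threshold]
        assert len(seeds) == len(oracle)
        assert np.allclose(np.sort(seeds, axis=0), np.sort(oracle, axis=0))
        # at least 125 sub-seeds per interior tube voxel minus edge effects,
        # and no seeds outside the one-voxel interpolation support shell
        from scipy.ndimage import binary_dilation
        v = int(tube_volume.tube_mask.sum())
        v_dilated = int(binary_dilation(tube_volume.tube_mask,
                                        np.ones((3, 3, 3), bool)).sum())
        assert 0.9 * v * 125 <= len(seeds) <= v_dilated * 125

    def test_whole_volume_deterministic(self, tube_volume):
        a = whole_volume_tractography(tube_volume)
        b = whole_volume_tractography(tube_volume)
        assert len(a) == len(b)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.points, sb.points)


class TestArcPhantom:
    def test_arc_length_and_tube_confinement(self):
        arc = ArcCenterline([15.0, 15.0, 7.5], 40.0, [1, 0, 0], [0, 1, 0],
                            np.pi / 2)
        tract = TractSpec(arc, 2.2, *TUBE_EIGS, endpoint_region_ids=(1, 2))
        vol, _ = make_tensor_phantom([tract], shape=(28, 28, 6), voxel_size_mm=2.5,
                                     background_diffusivity=BACKGROUND_D)
        seed = arc.point(np.array([arc.length_mm / 2]))[0]
        s = track_streamline(vol, seed)
        # per-end error budget: one voxel of end-cap discretization, the
        # FA-blend margin into background, and one step of quantization
        blend_margin = (tube_axial_fa_support(*TUBE_EIGS, BACKGROUND_D, 0.2,
                                              2.5, 0.0, 0.0) / 2.0)
        budget = 2 * (2.5 + blend_margin + 0.5)
        assert s.length_mm >= arc.length_mm - 2 * 2.5
        assert abs(s.length_mm - arc.length_mm) <= budget
        # confined to the tube plus the one-voxel interpolation margin
        _, dist = arc.nearest(s.points)
        assert dist.max() <= 2.2 + 2.5

    def test_trk_tck_roundtrip(self, tmp_path, tube_volume):
        ss = StreamlineSet([track_streamline(tube_volume, [40.0, 15.0, 15.0])])
        for ext in ("trk", "tck"):
            path = tmp_path / f"tracts.{ext}"
            ss.save(str(path))
            back = StreamlineSet.load(str(path))
            assert len(back) == 1
            assert np.allclose(back[0].points, ss[0].points, atol=1e-4)


class TestIntegratorOption:
    def test_rk2_matches_euler_on_straight_tube(self, tube_volume):
        e = track_streamline(tube_volume, [40.0, 15.0, 15.0],
                             TrackingParams(integrator="euler"))
        r = track_streamline(tube_volume, [40.0, 15.0, 15.0],
                             TrackingParams(integrator="rk2"))
        assert abs(e.length_mm - r.length_mm) <= 2 * 0.5
        gaps = np.linalg.norm(np.diff(r.points, axis=0), axis=1)
        assert np.allclose(gaps, 0.5, atol=1e-9)

    def test_unknown_integrator_rejected(self):
        with pytest.raises(ValueError, match="integrator"):
            TrackingParams(integrator="rk4")
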