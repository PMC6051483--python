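"""jPCA plane extraction and areal-velocity algebra."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import subspace_angles

from lfpdecode import (
    LfpRecording,
    ProjectionPlane,
    areal_velocity_pairs,
    areal_velocity_plane,
    areal_velocity_vector3,
    banded_areal_velocity,
    fit_jpca,
    fit_pca,
    plane_decomposition_check,
)
from lfpdecode.io import ValidationError
from lfpdecode.preprocess import PcaBasis

from conftest import make_lfp


def _embedded_rotation(rng, n_ch=6, f=2.0, fs=250.0, dur=20.0, noise=1e-9):
    """Pure planar rotation embedded in channel space + tiny noise."""
    t = np.arange(int(dur * fs)) / fs
    Q, _ = np.linalg.qr(rng.standard_normal((n_ch, 2)))
    xy = np.column_stack([np.cos(2 * np.pi * f * t), np.sin(2 * np.pi * f * t)])
    x = xy @ Q.T + noise * rng.standard_normal((len(t), n_ch))
    return make_lfp(x, fs=fs), Q


def _random_plane(rng, n_ch):
    Q, _ = np.linalg.qr(rng.standard_normal((n_ch, 2)))
    return ProjectionPlane(u=Q[:, 0], v=Q[:, 1])


class TestJpca:
    def test_recovers_pure_rotation_plane(self, rng):
        lfp, Q = _embedded_rotation(rng)
        planes, _ = fit_jpca(lfp, n_pcs=4, n_planes=1)
        ang = subspace_angles(np.column_stack([planes[0].u, planes[0].v]), Q)
        assert ang.max() < 1e-3
        assert planes[0].freq_hz == pytest.approx(2.0, rel=0.01)

    def test_fitted_dynamics_exactly_skew_symmetric(self, rng):
        # the constraint is structural: check via the residual of the planes'
        # construction, i.e. refit and verify eigen-structure directly
        from lfpdecode.rotation import _skew_basis

        lfp, _ = _embedded_rotation(rng, noise=0.05)
        basis = fit_pca(lfp, 4)
        x = (lfp.samples - basis.mean) @ basis.components.T
        xdot = np.gradient(x, 1.0 / lfp.fs, axis=0)
        S = x.T @ x
        C = xdot.T @ x
        pairs = _skew_basis(4)
        B = np.zeros((len(pairs), 4, 4))
        for a, (i, j) in enumerate(pairs):
            B[a, i, j], B[a, j, i] = 1.0, -1.0
        H = np.einsum("aij,jk,bik->ab", B, S, B)
        rhs = np.array([C[i, j] - C[j, i] for (i, j) in pairs])
        M = np.einsum("a,aij->ij", np.linalg.solve(H, rhs), B)
        assert np.array_equal(M, -M.T)  # exact, not approximate
        ev = np.linalg.eigvals(M)
        assert np.max(np.abs(ev.real)) < 1e-10 * max(1.0, np.abs(ev.imag).max())

    def test_plane_orientation_gives_nonnegative_mean_av(self, rng):
        lfp, _ = _embedded_rotation(rng, noise=0.02)
        planes, _ = fit_jpca(lfp, n_pcs=4, n_planes=1)
        av = areal_velocity_plane(lfp, planes[0])
        assert av.values.mean() >= 0

    def test_too_many_planes_rejected(self, rng):
        lfp, _ = _embedded_rotation(rng)
        with pytest.raises(ValidationError, match="planes"):
            fit_jpca(lfp, n_pcs=4, n_planes=3)


class TestArealVelocityPlane:
    def test_circle_sweeps_half_r_squared_omega(self, rng):
        # AV of a circle r=1 at omega=2*pi is pi; the central-difference
        # derivative scales it by sin(omega*h)/(omega*h)
        fs = 100.0
        t = np.arange(int(20 * fs)) / fs
        Q, _ = np.linalg.qr(rng.standard_normal((5, 2)))
        xy = np.column_stack([np.cos(2 * np.pi * t), np.sin(2 * np.pi * t)])
        lfp = make_lfp(xy @ Q.T, fs=fs)
        av = areal_velocity_plane(lfp, ProjectionPlane(u=Q[:, 0], v=Q[:, 1]))
        om, h = 2 * np.pi, 1 / fs
        expected = np.pi * np.sin(om * h) / (om * h)
        np.testing.assert_allclose(av.values[1:-1], expected, rtol=1e-9)
        assert abs(av.values[1:-1].mean() - np.pi) < np.pi * (1 - np.sin(om * h) / (om * h)) * 1.1

    def test_common_waveform_across_channels_rejected(self, rng):
        # all channels scalar multiples of one waveform -> AV identically 0
        w = np.sin(np.arange(2000) * 0.07) + 0.3 * rng.standard_normal(2000)
        gains = rng.standard_normal(6)
        lfp = make_lfp(np.outer(w, gains))
        av = areal_velocity_plane(lfp, _random_plane(rng, 6))
        assert np.max(np.abs(av.values)) < 1e-9 * np.max(np.abs(w)) ** 2

    def test_time_reversal_negates_av(self, rng):
        lfp = make_lfp(rng.standard_normal((500, 4)))
        plane = _random_plane(rng, 4)
        fwd = areal_velocity_plane(lfp, plane).values
        rev = areal_velocity_plane(make_lfp(lfp.samples[::-1]), plane).values
        np.testing.assert_allclose(rev, -fwd[::-1], atol=1e-9)

    def test_non_orthonormal_plane_rejected(self):
        with pytest.raises(ValidationError):
            ProjectionPlane(u=np.array([1.0, 0.0]), v=np.array([0.7, 0.7]))

    def test_scale_law_quadratic(self, rng):
        lfp = make_lfp(rng.standard_normal((400, 4)))
        plane = _random_plane(rng, 4)
        av1 = areal_velocity_plane(lfp, plane).values
        av3 = areal_velocity_plane(make_lfp(3.0 * lfp.samples), plane).values
        np.testing.assert_allclose(av3, 9.0 * av1, rtol=1e-12)

    def test_rotation_invariance_of_channel_space(self, rng):
        lfp = make_lfp(rng.standard_normal((400, 5)))
        plane = _random_plane(rng, 5)
        R, _ = np.linalg.qr(rng.standard_normal((5, 5)))
        rotated = make_lfp(lfp.samples @ R.T)
        counter = ProjectionPlane(u=R @ plane.u, v=R @ plane.v)
        a = areal_velocity_plane(lfp, plane).values
        b = areal_velocity_plane(rotated, counter).values
        np.testing.assert_allclose(a, b, atol=1e-9 * max(1.0, np.abs(a).max()))


class TestArealVelocityPairs:
    def test_pair_count_is_n_choose_2(self, rng):
        lfp = make_lfp(rng.standard_normal((50, 22)))
        sigs = areal_velocity_pairs(lfp, "all")
        assert len(sigs) == 231  # 22*21/2
        assert [s.pair for s in sigs] == sorted(s.pair for s in sigs)

    def test_identical_indices_rejected(self, rng):
        lfp = make_lfp(rng.standard_normal((50, 3)))
        with pytest.raises(ValidationError):
            areal_velocity_pairs(lfp, [(1, 1)])

    def test_swap_antisymmetry_by_construction(self, rng):
        lfp = make_lfp(rng.standard_normal((200, 3)))
        ij = areal_velocity_pairs(lfp, [(0, 2)])[0].values
        ji_manual = areal_velocity_pairs(lfp, [(2, 0)])[0].values
        np.testing.assert_allclose(ij, -ji_manual, atol=1e-12)

    def test_independent_noise_has_zero_mean_av(self):
        rng = np.random.default_rng(99)
        lfp = make_lfp(rng.standard_normal((200000, 3)))
        for sig in areal_velocity_pairs(lfp, "all"):
            v = sig.values[1:-1]
            # autocorrelation-corrected standard error of the time mean
            g0 = np.var(v)
            g1 = np.mean((v[:-1] - v.mean()) * (v[1:] - v.mean()))
            g2 = np.mean((v[:-2] - v.mean()) * (v[2:] - v.mean()))
            se = np.sqrt((g0 + 2 * g1 + 2 * g2) / v.size)
            assert abs(v.mean()) < 3 * se


class TestPlaneDecomposition:
    def test_identity_on_random_planes(self, rng):
        lfp = make_lfp(rng.standard_normal((300, 5)))
        for _ in range(3):
            plane = _random_plane(rng, 5)
            scale = np.abs(areal_velocity_plane(lfp, plane).values).max()
            assert plane_decomposition_check(lfp, plane) < 1e-9 * max(scale, 1.0)

    def test_axis_aligned_plane_equals_single_pair(self, rng):
        lfp = make_lfp(rng.standard_normal((300, 4)))
        e = np.eye(4)
        plane = ProjectionPlane(u=e[1], v=e[3])
        av_plane = areal_velocity_plane(lfp, plane).values
        av_pair = areal_velocity_pairs(lfp, [(1, 3)])[0].values
        np.testing.assert_allclose(av_plane, av_pair, atol=1e-12)

    def test_identity_for_full_orthonormal_set(self, rng):
        lfp = make_lfp(rng.standard_normal((200, 4)))
        R, _ = np.linalg.qr(rng.standard_normal((4, 4)))
        for i in range(0, 4, 2):
            plane = ProjectionPlane(u=R[:, i], v=R[:, i + 1])
            assert plane_decomposition_check(lfp, plane) < 1e-9


class TestVector3:
    def _basis3(self, n_ch=3):
        return PcaBasis(
            mean=np.zeros(n_ch),
            components=np.eye(n_ch)[:3],
            explained_variance_fractions=np.array([0.5, 0.3, 0.2]),
        )

    def test_rotation_in_12_plane_is_pure_third_component(self):
        fs = 200.0
        t = np.arange(int(10 * fs)) / fs
        x = np.column_stack(
            [np.cos(2 * np.pi * t), np.sin(2 * np.pi * t), np.zeros_like(t)]
        )
        av3 = areal_velocity_vector3(make_lfp(x, fs=fs), self._basis3())
        assert np.max(np.abs(av3.values[:, :2])) < 1e-9
        assert av3.values[1:-1, 2].mean() > 0

    def test_magnitude_invariant_under_tilt(self, rng):
        fs = 200.0
        t = np.arange(int(10 * fs)) / fs
        xy = np.column_stack([np.cos(2 * np.pi * t), np.sin(2 * np.pi * t)])
        flat = np.column_stack([xy, np.zeros_like(t)])
        R, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        tilted = flat @ R.T
        m_flat = areal_velocity_vector3(make_lfp(flat, fs=fs), self._basis3()).magnitude()
        m_tilt = areal_velocity_vector3(make_lfp(tilted, fs=fs), self._basis3()).magnitude()
        np.testing.assert_allclose(m_tilt[1:-1], m_flat[1:-1], rtol=1e-9)

    def test_direction_is_plane_normal(self, rng):
        fs = 200.0
        t = np.arange(int(10 * fs)) / fs
        xy = np.column_stack([np.cos(2 * np.pi * t), np.sin(2 * np.pi * t)])
        R, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        if np.linalg.det(R) < 0:
            R[:, 2] = -R[:, 2]
        tilted = np.column_stack([xy, np.zeros_like(t)]) @ R.T
        av3 = areal_velocity_vector3(make_lfp(tilted, fs=fs), self._basis3())
        normal = np.cross(R[:, 0], R[:, 1])
        vecs = av3.values[1:-1]
        cos = vecs @ normal / np.linalg.norm(vecs, axis=1)
        assert np.all(cos > 1 - 1e-6)

    def test_wrong_component_count_rejected(self, rng):
        basis = PcaBasis(
            mean=np.zeros(4),
            components=np.eye(4)[:2],
            explained_variance_fractions=np.array([0.6, 0.4]),
        )
        with pytest.raises(ValidationError):
            areal_velocity_vector3(make_lfp(rng.standard_normal((100, 4))), basis)

    def test_components_equal_pairwise_av_of_projection(self, rng):
        lfp = make_lfp(rng.standard_normal((300, 3)))
        av3 = areal_velocity_vector3(lfp, self._basis3())
        pair_av = {s.pair: s.values for s in areal_velocity_pairs(lfp, "all")}
        np.testing.assert_allclose(av3.values[:, 0], pair_av[(1, 2)], atol=1e-12)
        np.testing.assert_allclose(av3.values[:, 1], -pair_av[(0, 2)], atol=1e-12)
        np.testing.assert_allclose(av3.values[:, 2], pair_av[(0, 1)], atol=1e-12)


class TestBandedAv:
    def test_band_isolates_one_of_two_rotations(self, rng):
        fs = 100.0
        t = np.arange(int(60 * fs)) / fs
        Q, _ = np.linalg.qr(rng.standard_normal((6, 4)))
        slow = np.column_stack([np.cos(2 * np.pi * 2 * t), np.sin(2 * np.pi * 2 * t)])
        fast = np.column_stack([np.cos(2 * np.pi * 8 * t), np.sin(2 * np.pi * 8 * t)])
        lfp = make_lfp(slow @ Q[:, :2].T + fast @ Q[:, 2:].T, fs=fs)
        slow_plane = ProjectionPlane(u=Q[:, 0], v=Q[:, 1])
        fast_plane = ProjectionPlane(u=Q[:, 2], v=Q[:, 3])
        in_band = banded_areal_velocity(lfp, slow_plane, (1.0, 4.0)).values
        cross = banded_areal_velocity(lfp, fast_plane, (1.0, 4.0)).values
        sl = slice(200, -200)
        assert np.abs(cross[sl]).mean() < 0.05 * np.abs(in_band[sl]).mean()

    def test_empty_band_has_near_zero_av(self, rng):
        fs = 100.0
        t = np.arange(int(30 * fs)) / fs
        Q, _ = np.linalg.qr(np.random.default_rng(3).standard_normal((4, 2)))
        lfp = make_lfp(
            np.column_stack([np.cos(2 * np.pi * 2 * t), np.sin(2 * np.pi * 2 * t)]) @ Q.T,
            fs=fs,
        )
        plane = ProjectionPlane(u=Q[:, 0], v=Q[:, 1])
        full = areal_velocity_plane(lfp, plane).values
        empty = banded_areal_velocity(lfp, plane, (10.0, 20.0)).values
        assert np.abs(empty[200:-200]).mean() < 1e-3 * np.abs(full[200:-200]).mean()

    def test_full_band_matches_unbanded(self, rng):
        fs = 100.0
        t = np.arange(int(30 * fs)) / fs
        Q, _ = np.linalg.qr(rng.standard_normal((4, 2)))
        lfp = make_lfp(
            np.column_stack([np.cos(2 * np.pi * 3 * t), np.sin(2 * np.pi * 3 * t)]) @ Q.T,
            fs=fs,
        )
        plane = ProjectionPlane(u=Q[:, 0], v=Q[:, 1])
        # interior margin outlasts the 0.5 Hz band-edge transient (~2 s tau)
        full = areal_velocity_plane(lfp, plane).values[800:-800]
        banded = banded_areal_velocity(lfp, plane, (0.5, 20.0)).values[800:-800]
        assert np.abs(banded - full).max() < 0.01 * np.abs(full).max()

    def test_invalid_band_rejected(self, rng):
        lfp = make_lfp(rng.standard_normal((200, 3)))
        plane = _random_plane(rng, 3)
        with pytest.raises(ValidationError):
            banded_areal_velocity(lfp, plane, (4.0, 1.0))


@settings(derandomize=True, max_examples=20, deadline=None)
@given(seed=st.integers(0, 2**31 - 1), n_ch=st.integers(2, 6))
def test_av_algebra_properties(seed, n_ch):
    """Antisymmetry, time-reversal, c^2 scaling and the pairwise
    decomposition identity on randomized inputs."""
    rng = np.random.default_rng(seed)
    lfp = make_lfp(rng.standard_normal((120, n_ch)))
    Q, _ = np.linalg.qr(rng.standard_normal((n_ch, 2)))
    plane = ProjectionPlane(u=Q[:, 0], v=Q[:, 1])
    av = areal_velocity_plane(lfp, plane).values
    scale = max(1.0, np.abs(av).max())
    # decomposition identity
    assert plane_decomposition_check(lfp, plane) < 1e-9 * scale
    # time reversal
    rev = areal_velocity_plane(make_lfp(lfp.samples[::-1]), plane).values
    np.testing.assert_allclose(rev, -av[::-1], atol=1e-9 * scale)
    # quadratic scaling
    av2 = areal_velocity_plane(make_lfp(2.0 * lfp.samples), plane).values
    np.testing.assert_allclose(av2, 4.0 * av, atol=1e-9 * scale)
    # swapped plane negates
    swapped = ProjectionPlane(u=Q[:, 1], v=Q[:, 0])
    np.testing.assert_allclose(
        areal_velocity_plane(lfp, swapped).values, -av, atol=1e-12 * scale
    )
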