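import numpy as np
import pytest

from duoview import (
    ConvergenceError,
    RigidTransform,
    ValidationError,
    VolumeStack,
    bead_phantom,
    flip_opposing_view,
    register_rigid,
    resample,
)


def phantom(seed=0, shape=(40, 64, 64)):
    stack, _ = bead_phantom(shape, 20, (0.8, 2.0), (1.0, 1.0, 1.0), seed=seed)
    return stack


class TestRigidTransform:
    @pytest.mark.parametrize("seed", range(5))
    def test_compose_with_inverse_is_identity(self, seed):
        rng = np.random.default_rng(seed)
        t = RigidTransform(
            rotation_deg=tuple(rng.uniform(-30, 30, 3)),
            translation=tuple(rng.uniform(-10, 10, 3)),
            center=tuple(rng.uniform(0, 50, 3)),
        )
        np.testing.assert_allclose(
            t.compose(t.inverse()).as_matrix(), np.eye(4), atol=1e-6
        )

    def test_pure_translation_has_zero_angles(self):
        t = RigidTransform(translation=(1.0, 2.0, 3.0))
        assert t.rotation_deg == (0.0, 0.0, 0.0)
        pts = np.array([[0.0, 0.0, 0.0], [5.0, 5.0, 5.0]])
        np.testing.assert_allclose(t.apply(pts), pts + [1.0, 2.0, 3.0])

    def test_matrix_roundtrip(self):
        t = RigidTransform((10.0, -5.0, 3.0), (1.0, 2.0, -3.0), (4.0, 5.0, 6.0))
        back = RigidTransform.from_matrix(t.as_matrix(), center=t.center)
        np.testing.assert_allclose(back.as_matrix(), t.as_matrix(), atol=1e-10)
        np.testing.assert_allclose(back.rotation_deg, t.rotation_deg, atol=1e-10)


class TestFlip:
    def test_double_flip_is_identity(self, small_stack):
        flipped = flip_opposing_view(flip_opposing_view(small_stack, ("z",)), ("z",))
        np.testing.assert_array_equal(flipped.data, small_stack.data)

    def test_empty_flip_set_is_identity(self, small_stack):
        np.testing.assert_array_equal(
            flip_opposing_view(small_stack, ()).data, small_stack.data
        )

    def test_z_flip_maps_plane_indices(self, small_stack):
        flipped = flip_opposing_view(small_stack, ("z",))
        nz = small_stack.n_planes
        for k in (0, 3, nz - 1):
            np.testing.assert_array_equal(
                flipped.data[k], small_stack.data[nz - 1 - k]
            )

    def test_invalid_axis_rejected(self, small_stack):
        with pytest.raises(ValidationError):
            flip_opposing_view(small_stack, ("y",))


class TestResample:
    def test_identity_is_bitwise(self, small_stack):
        out = resample(small_stack, RigidTransform())
        np.testing.assert_array_equal(out.data, small_stack.data)

    def test_integer_translation_equals_array_shift(self, small_stack):
        out = resample(small_stack, RigidTransform(translation=(1.0, 0.0, 0.0)))
        # out(z) samples input at z+1; interior planes are exact
        np.testing.assert_allclose(
            out.data[:-1], small_stack.data[1:], atol=1e-10
        )

    def test_half_voxel_twice_close_to_full_voxel_once(self):
        # smooth low-curvature field: trilinear interpolation error is second
        # order, so composed half-steps match the full step to 1e-3 of range
        zz, yy, xx = np.indices((12, 24, 24), dtype=float)
        data = xx / 24.0 + 0.2 * np.sin(2 * np.pi * xx / 100.0) + 0.1 * yy / 24.0
        stack = VolumeStack(data, (1.0, 1.0, 1.0))
        half = RigidTransform(translation=(0.0, 0.0, 0.5))
        full = RigidTransform(translation=(0.0, 0.0, 1.0))
        twice = resample(resample(stack, half), half)
        once = resample(stack, full)
        interior = (slice(None), slice(None), slice(2, -2))
        err = np.abs(twice.data[interior] - once.data[interior]).max()
        assert err <= 1e-3 * np.ptp(stack.data)

    def test_anisotropic_spacing_translation_in_um(self):
        data = np.zeros((10, 10, 10))
        data[5, 5, 5] = 1.0
        stack = VolumeStack(data, spacing=(2.0, 1.0, 1.0))
        # 2 µm along z is exactly one voxel at 2 µm spacing
        out = resample(stack, RigidTransform(translation=(2.0, 0.0, 0.0)))
        assert out.data[4, 5, 5] == pytest.approx(1.0)


class TestRegisterRigid:
    def test_self_registration_is_identity(self):
        stack = phantom(seed=3)
        t = register_rigid(stack, stack)
        assert np.all(np.abs(t.translation) < 0.05)
        assert np.all(np.abs(t.rotation_deg) < 0.05)

    def test_translation_recovery(self):
        fixed = phantom(seed=5)
        applied = RigidTransform(translation=(1.5, -2.0, 3.0))
        moving = resample(fixed, applied)
        recovered = register_rigid(moving, fixed)
        np.testing.assert_allclose(
            recovered.translation, applied.inverse().translation, atol=0.25
        )

    def test_rotation_recovery(self):
        fixed = phantom(seed=6)
        applied = RigidTransform(
            rotation_deg=(2.0, 0.0, 0.0), center=(19.5, 31.5, 31.5)
        )
        moving = resample(fixed, applied)
        recovered = register_rigid(moving, fixed)
        assert abs(recovered.rotation_deg[0] - (-2.0)) < 0.2

    def test_corner_rms_after_composition(self):
        fixed = phantom(seed=8)
        applied = RigidTransform(
            rotation_deg=(1.0, 0.0, 0.0),
            translation=(1.0, 1.0, -1.0),
            center=(19.5, 31.5, 31.5),
        )
        moving = resample(fixed, applied)
        recovered = register_rigid(moving, fixed)
        comp = recovered.compose(applied)
        corners = np.array(
            [[z, y, x] for z in (0, 39) for y in (0, 63) for x in (0, 63)],
            dtype=float,
        )
        rms = np.sqrt(np.mean(np.sum((comp.apply(corners) - corners) ** 2, axis=1)))
        assert rms < 0.3

    def test_constant_images_raise(self):
        stack = VolumeStack(np.ones((8, 8, 8)), (1, 1, 1))
        with pytest.raises(ConvergenceError):
            register_rigid(stack, stack)

    def test_spacing_mismatch_rejected(self, small_stack):
        other = VolumeStack(small_stack.data.copy(), (2.0, 1.0, 1.0))
        with pytest.raises(ValidationError):
            register_rigid(other, small_stack)
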