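"""Strain chain: node-grid median smoothing, hexahedral deformation
gradient, Green-Lagrange tensor, volumetric and max-shear measures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peridvc import (
    DisplacementField,
    DvcConfig,
    ParameterError,
    WarpSpec,
    apply_warp,
    deformation_gradient,
    green_lagrange,
    max_shear,
    run_dvc,
    run_strain,
    smooth_displacements,
    volumetric_strain,
)
from peridvc.strain import tensor_components


def synthetic_field(u_of_x, n=6, spacing=4):
    """DisplacementField with u = u_of_x(z, y, x) on a regular grid."""
    coords = tuple(np.arange(n) * spacing for _ in range(3))
    zz, yy, xx = np.meshgrid(*coords, indexing="ij")
    u = np.stack(u_of_x(zz.astype(float), yy.astype(float), xx.astype(float)), axis=-1)
    return DisplacementField(
        coords=coords, u=u, cc=np.ones((n, n, n)),
        status=np.zeros((n, n, n), dtype=np.int8), node_spacing_vox=spacing,
    )


class TestSmoothing:
    def test_constant_field_unchanged(self):
        fld = synthetic_field(lambda z, y, x: (np.full_like(z, 2.0),) * 3)
        out = smooth_displacements(fld, 1)
        assert np.array_equal(out.u, fld.u)

    def test_outlier_replaced(self):
        fld = synthetic_field(lambda z, y, x: (np.full_like(z, 2.0),) * 3)
        fld.u[3, 3, 3, :] = 50.0
        out = smooth_displacements(fld, 1)
        assert np.allclose(out.u[3, 3, 3], 2.0)

    def test_matches_bruteforce_cube_median(self, rng):
        fld = synthetic_field(lambda z, y, x: (np.zeros_like(z),) * 3)
        fld.u[:] = rng.random(fld.u.shape)
        out = smooth_displacements(fld, 1)
        n = fld.u.shape[0]
        for comp in range(3):
            for i, j, k in [(0, 0, 0), (2, 3, 1), (5, 5, 5), (1, 4, 2)]:
                vals = []
                for dz in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            z, y, x = i + dz, j + dy, k + dx
                            if 0 <= z < n and 0 <= y < n and 0 <= x < n:
                                vals.append(fld.u[z, y, x, comp])
                assert out.u[i, j, k, comp] == pytest.approx(np.median(vals))

    def test_radius_zero_identity(self):
        fld = synthetic_field(lambda z, y, x: (z, y, x))
        assert smooth_displacements(fld, 0) is fld


class TestDeformationGradient:
    def test_zero_displacement_gives_identity(self):
        fld = synthetic_field(lambda z, y, x: (np.zeros_like(z),) * 3)
        assert np.array_equal(deformation_gradient(fld, (0, 0, 0)), np.eye(3))

    def test_linear_field_exact(self):
        # u_x = 0.1 * X  (physical x = array axis 2)
        fld = synthetic_field(lambda z, y, x: (np.zeros_like(z), np.zeros_like(z), 0.1 * x))
        F = deformation_gradient(fld, (2, 2, 2))
        expected = np.eye(3)
        expected[2, 2] = 1.1
        assert np.allclose(F, expected, atol=1e-14)

    def test_quadratic_field_near_central_difference(self):
        a = 1e-3
        fld = synthetic_field(lambda z, y, x: (a * z ** 2, np.zeros_like(z), np.zeros_like(z)),
                              n=8)
        el = (3, 3, 3)
        F = deformation_gradient(fld, el)
        # central finite difference of u_z at the element-center z
        cz = fld.coords[0]
        zc = 0.5 * (cz[3] + cz[4])
        fd = ((a * (zc + 4) ** 2) - (a * (zc - 4) ** 2)) / 8.0
        assert F[0, 0] - 1.0 == pytest.approx(fd, rel=1e-9)  # trilinear = central FD here

    def test_missing_corner_flagged(self):
        fld = synthetic_field(lambda z, y, x: (np.zeros_like(z),) * 3)
        fld.status[1, 1, 1] = 2
        with pytest.raises(ParameterError):
            deformation_gradient(fld, (1, 1, 1))


class TestTensorMeasures:
    def test_identity_gives_zero_strain(self):
        E = green_lagrange(np.eye(3))
        assert np.allclose(E, 0.0)
        assert volumetric_strain(np.eye(3)) == 0.0
        assert max_shear(E) == 0.0

    def test_uniaxial_stretch_closed_form(self):
        F = np.eye(3)
        F[2, 2] = 1.1
        E = green_lagrange(F)
        assert tensor_components(E)[0] == pytest.approx(0.105)  # exx = (1.21-1)/2
        assert max_shear(E) == pytest.approx(0.07)

    def test_rotation_gives_zero_strain(self):
        th = np.deg2rad(10)
        R = np.array([[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        E = green_lagrange(R)
        assert np.abs(E).max() < 1e-12
        assert abs(volumetric_strain(R)) < 1e-12

    def test_uniform_dilation_volumetric(self):
        assert volumetric_strain(1.01 * np.eye(3)) == pytest.approx(0.030301)

    def test_isotropic_strain_zero_shear(self):
        E = 0.05 * np.eye(3)
        assert max_shear(E) == 0.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_max_shear_nonnegative_random_tensors(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(3, 3)) * 0.1
        E = 0.5 * (A + A.T)
        g = max_shear(E)
        assert g >= 0.0
        iso = np.trace(E) / 3 * np.eye(3)
        if not np.allclose(E, iso):
            assert g > 0.0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_objectivity_random_rotations(self, seed):
        from scipy.spatial.transform import Rotation

        R = Rotation.random(rng=np.random.default_rng(seed)).as_matrix()
        assert np.abs(green_lagrange(R)).max() < 1e-12


class TestRunStrain:
    def test_rigid_translation_gives_zero_strain(self):
        fld = synthetic_field(lambda z, y, x: (np.full_like(z, 1.3),
                                               np.full_like(z, -0.2),
                                               np.full_like(z, 0.7)))
        sf = run_strain(fld, 1)
        assert np.abs(sf.components[sf.ok]).max() < 1e-10
        assert np.abs(sf.volumetric[sf.ok]).max() < 1e-10

    def test_translation_invariance(self):
        fld = synthetic_field(lambda z, y, x: (0.01 * z, 0.002 * x, 0.005 * y), n=7)
        sf0 = run_strain(fld, 0)
        fld.u += np.array([3.0, -1.0, 2.0])
        sf1 = run_strain(fld, 0)
        assert np.allclose(sf0.components, sf1.components, atol=1e-12)

    def test_affine_field_reproduces_F_exactly(self):
        A = np.array([[0.02, 0.001, 0.0], [0.0, -0.01, 0.002], [0.003, 0.0, 0.015]])
        fld = synthetic_field(lambda z, y, x: (
            A[0, 0] * z + A[0, 1] * y + A[0, 2] * x,
            A[1, 0] * z + A[1, 1] * y + A[1, 2] * x,
            A[2, 0] * z + A[2, 1] * y + A[2, 2] * x,
        ))
        sf = run_strain(fld, 0)
        for idx in np.ndindex(sf.F.shape[:3]):
            assert np.allclose(sf.F[idx], np.eye(3) + A, atol=1e-12)

    def test_uniaxial_phantom_warp_recovers_volumetric_strain(self, texture_only):
        F = np.diag([1.02, 1.0, 1.0])
        moved = apply_warp(texture_only, WarpSpec(kind="affine", affine_matrix=F))
        fld = run_dvc(texture_only, moved, DvcConfig(search_radius_vox=2))
        sf = run_strain(fld, 1)
        vols = sf.volumetric[sf.ok]
        assert abs(np.median(vols) - 0.02) < 0.005

    def test_too_few_nodes_rejected(self):
        fld = synthetic_field(lambda z, y, x: (np.zeros_like(z),) * 3, n=3)
        fld.status[:] = 2
        fld.status[0, 0, 0] = 0
        with pytest.raises(ParameterError):
            run_strain(fld, 0)
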