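"""Sensor arrays, ellipsoid fitting, tangential frames and the dipole forward model."""

import numpy as np
import pytest

from betabeam.geometry import (
    DipoleSource,
    EllipsoidSurface,
    HeadModel,
    SensorArray,
    fit_ellipsoid,
    fit_local_spheres,
    fit_sphere,
    forward_field,
    lead_field,
    lead_field_matrix,
    make_helmet_array,
    shrink_surface,
    tangential_orientation,
)


def _sarvas_reference(q, r0, r, center):
    """Scalar transcription of the closed-form dipole field in a sphere.

    Independent of the vectorised implementation: plain floats, term by term.
    B(r) = mu0/(4 pi F^2) * (F (q x r0) - ((q x r0) . r) grad F), with
    F = a (r a + r^2 - r0 . r),
    grad F = (a^2/r + (a.r)/a + 2a + 2r) r - (a + 2r + (a.r)/a) r0,
    where a = r - r0 (positions relative to the sphere center).
    """
    q = np.asarray(q, dtype=float)
    rv = np.asarray(r, dtype=float) - np.asarray(center, dtype=float)
    r0v = np.asarray(r0, dtype=float) - np.asarray(center, dtype=float)
    av = rv - r0v
    a = float(np.sqrt(av @ av))
    rn = float(np.sqrt(rv @ rv))
    adotr = float(av @ rv)
    F = a * (rn * a + rn**2 - float(r0v @ rv))
    gradF = (a**2 / rn + adotr / a + 2 * a + 2 * rn) * rv - (a + 2 * rn + adotr / a) * r0v
    qxr0 = np.cross(q, r0v)
    return 1e-7 / F**2 * (F * qxr0 - float(qxr0 @ rv) * gradF)


# --------------------------------------------------------------------------
# helmet
# --------------------------------------------------------------------------


class TestHelmet:
    def test_constructor_contract(self):
        arr = make_helmet_array(n_channels=275, radius=0.12, coverage=0.5, seed=0)
        assert arr.n_channels == 275
        np.testing.assert_allclose(np.linalg.norm(arr.orientations, axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(np.linalg.norm(arr.positions, axis=1), 0.12, atol=1e-12)
        assert np.all(arr.positions[:, 2] >= -1e-9)  # upper hemisphere

    def test_minimal_and_determinism(self):
        a = make_helmet_array(n_channels=2, radius=0.1, seed=3)
        assert a.n_channels == 2
        b = make_helmet_array(n_channels=64, radius=0.12, seed=7)
        c = make_helmet_array(n_channels=64, radius=0.12, seed=7)
        np.testing.assert_array_equal(b.positions, c.positions)

    @pytest.mark.parametrize("kwargs,msg", [
        (dict(n_channels=1), "n_channels"),
        (dict(radius=-0.1), "radius"),
        (dict(coverage=0.0), "coverage"),
    ])
    def test_rejects_bad_parameters(self, kwargs, msg):
        with pytest.raises(ValueError, match=msg):
            make_helmet_array(**{"n_channels": 10, "radius": 0.12, **kwargs})

    def test_json_roundtrip(self):
        arr = make_helmet_array(n_channels=8, radius=0.11, seed=2)
        back = SensorArray.from_json(arr.to_json())
        np.testing.assert_allclose(back.positions, arr.positions)
        np.testing.assert_allclose(back.orientations, arr.orientations)
        assert back.names == arr.names


# --------------------------------------------------------------------------
# ellipsoid fitting and surfaces
# --------------------------------------------------------------------------


class TestEllipsoid:
    def test_exact_fit_identity(self, rng):
        truth = EllipsoidSurface(center=(0.01, -0.02, 0.03), semi_axes=(0.09, 0.07, 0.06))
        pts = truth.sample(200, rng)
        fitted, report = fit_ellipsoid(pts)
        np.testing.assert_allclose(fitted.center, truth.center, atol=1e-8)
        np.testing.assert_allclose(np.sort(fitted.semi_axes), np.sort(truth.semi_axes), rtol=1e-6)
        assert report["rms_residual"] < 1e-9

    def test_sphere_is_an_ellipsoid(self, rng):
        truth = EllipsoidSurface(center=np.zeros(3), semi_axes=(0.08, 0.08, 0.08))
        fitted, _ = fit_ellipsoid(truth.sample(100, rng))
        np.testing.assert_allclose(fitted.semi_axes, 0.08, atol=1e-6)

    def test_jittered_recovery_within_2mm(self, rng):
        truth = EllipsoidSurface(center=(0.0, 0.005, -0.01), semi_axes=(0.09, 0.07, 0.065))
        pts = truth.sample(500, rng) + rng.normal(0, 1e-3, size=(500, 3))
        fitted, _ = fit_ellipsoid(pts)
        assert np.linalg.norm(fitted.center - truth.center) < 2e-3
        assert np.all(np.abs(np.sort(fitted.semi_axes) - np.sort(truth.semi_axes)) < 2e-3)

    def test_coplanar_points_rejected(self):
        g = np.mgrid[0:5, 0:5].reshape(2, -1).T * 0.01
        pts = np.column_stack([g, np.zeros(len(g))])
        with pytest.raises(ValueError, match="degenerate|ellipsoid"):
            fit_ellipsoid(pts)

    def test_shrink_definition_identity_and_error(self):
        s = EllipsoidSurface(center=np.zeros(3), semi_axes=(0.09, 0.07, 0.06))
        np.testing.assert_allclose(
            shrink_surface(s, 0.015).semi_axes, (0.075, 0.055, 0.045), atol=1e-15
        )
        np.testing.assert_allclose(shrink_surface(s, 0.0).semi_axes, s.semi_axes)
        with pytest.raises(ValueError, match="semi-axis"):
            shrink_surface(s, 0.07)

    def test_sampled_points_satisfy_implicit_equation(self, rng):
        s = EllipsoidSurface(center=(0.01, 0.0, 0.02), semi_axes=(0.08, 0.06, 0.05))
        for pts in (s.sample(1000), s.sample(1000, rng)):
            assert np.max(np.abs(s.implicit(pts))) < 1e-9


class TestTangentialOrientation:
    def test_azimuth_pi_flips_sign(self):
        s = EllipsoidSurface(center=np.zeros(3), semi_axes=(0.08, 0.07, 0.06))
        p = s.sample(5)[2]
        u = tangential_orientation(s, p, 0.7)
        v = tangential_orientation(s, p, 0.7 + np.pi)
        np.testing.assert_allclose(u, -v, atol=1e-12)

    def test_north_pole_of_sphere_is_horizontal(self):
        s = EllipsoidSurface(center=np.zeros(3), semi_axes=(0.08, 0.08, 0.08))
        u = tangential_orientation(s, np.array([0.0, 0.0, 0.08]), 0.0)
        assert abs(u[2]) < 1e-12

    def test_orthogonality_and_unit_norm_bulk(self, rng):
        # module invariant: holds over many random draws
        s = EllipsoidSurface(center=(0.0, 0.01, 0.0), semi_axes=(0.09, 0.07, 0.065))
        pts = s.sample(10_000, rng)
        azi = rng.uniform(0, 2 * np.pi, size=len(pts))
        for p, a in zip(pts[::100], azi[::100]):
            u = tangential_orientation(s, p, a)
            assert abs(np.linalg.norm(u) - 1) < 1e-12
            assert abs(u @ s.normal(p)) < 1e-10

    def test_off_surface_rejected(self):
        s = EllipsoidSurface(center=np.zeros(3), semi_axes=(0.08, 0.07, 0.06))
        with pytest.raises(ValueError, match="surface"):
            tangential_orientation(s, np.array([0.0, 0.0, 0.01]), 0.0)


class TestLocalSpheres:
    def test_sphere_surface_fixed_point(self):
        sensors = make_helmet_array(n_channels=30, radius=0.12, seed=0)
        s = EllipsoidSurface(center=(0.0, 0.0, 0.01), semi_axes=(0.08, 0.08, 0.08))
        head = fit_local_spheres(s, sensors, patch_radius=0.04)
        np.testing.assert_allclose(
            head.sphere_centers, np.broadcast_to([0.0, 0.0, 0.01], (30, 3)), atol=1e-6
        )

    def test_ellipsoid_gives_varying_centers(self):
        sensors = make_helmet_array(n_channels=30, radius=0.12, seed=0)
        s = EllipsoidSurface(center=np.zeros(3), semi_axes=(0.09, 0.07, 0.065))
        head = fit_local_spheres(s, sensors, patch_radius=0.04)
        assert head.sphere_centers.shape == (30, 3)
        assert np.ptp(head.sphere_centers, axis=0).max() > 1e-3

    def test_single_sphere_mode_exact(self):
        sensors = make_helmet_array(n_channels=10, radius=0.12, seed=0)
        s = EllipsoidSurface(center=(0.0, -0.01, 0.0), semi_axes=(0.075, 0.075, 0.075))
        head = fit_local_spheres(s, sensors, mode="single_sphere")
        np.testing.assert_allclose(head.sphere_centers[0], [0.0, -0.01, 0.0], atol=1e-6)
        np.testing.assert_allclose(head.sphere_radii[0], 0.075, atol=1e-6)

    def test_tiny_patch_rejected(self):
        sensors = make_helmet_array(n_channels=5, radius=0.12, seed=0)
        s = EllipsoidSurface(center=np.zeros(3), semi_axes=(0.09, 0.07, 0.065))
        with pytest.raises(ValueError, match="patch"):
            fit_local_spheres(s, sensors, patch_radius=1e-4, n_surface_samples=50)

    def test_fit_sphere_recovers_exactly(self, rng):
        c, r = np.array([0.01, 0.02, -0.01]), 0.07
        u = rng.standard_normal((50, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        cc, rr = fit_sphere(c + r * u)
        np.testing.assert_allclose(cc, c, atol=1e-12)
        assert abs(rr - r) < 1e-12


# --------------------------------------------------------------------------
# forward model
# --------------------------------------------------------------------------


class TestForwardField:
    def test_matches_independent_scalar_transcription(self, sphere_head, rng):
        sensors = make_helmet_array(n_channels=12, radius=0.12, seed=4)
        for _ in range(20):
            pos = rng.uniform(-0.03, 0.03, 3) + np.array([0, 0, 0.02])
            q = rng.standard_normal(3)
            q /= np.linalg.norm(q)
            ours = lead_field(pos, q, sphere_head, sensors)
            ref = np.array([
                _sarvas_reference(q, pos, sensors.positions[i], np.zeros(3))
                @ sensors.orientations[i]
                for i in range(sensors.n_channels)
            ])
            np.testing.assert_allclose(ours, ref, rtol=1e-12, atol=1e-25)

    def test_matches_mne_sphere_model(self, sphere_head):
        mne = pytest.importorskip("mne")
        mne.set_log_level("ERROR")
        pos = np.array([[0.12, 0, 0.0], [0, 0.12, 0.02], [0.02, 0.01, 0.118],
                        [-0.08, 0.05, 0.07], [0.05, -0.07, 0.08], [0.0, 0.04, 0.11]])
        ori = -pos / np.linalg.norm(pos, axis=1, keepdims=True)
        info = mne.create_info([f"M{i}" for i in range(len(pos))], 600.0, "mag")
        with info._unlock():
            info["dev_head_t"] = mne.transforms.Transform("meg", "head")
            for i, ch in enumerate(info["chs"]):
                ez = ori[i]
                ref = np.array([0, 0, 1.0]) if abs(ez[2]) < 0.9 else np.array([1.0, 0, 0])
                ex = np.cross(ref, ez)
                ex /= np.linalg.norm(ex)
                ch["loc"] = np.concatenate([pos[i], ex, np.cross(ez, ex), ez])
                ch["coil_type"] = mne.io.constants.FIFF.FIFFV_COIL_POINT_MAGNETOMETER
        sphere = mne.make_sphere_model(r0=(0.0, 0.0, 0.0), head_radius=0.09)
        src = mne.setup_volume_source_space(
            pos={"rr": np.array([[0.0, 0.0, 0.05]]), "nn": np.array([[1.0, 0.0, 0.0]])}
        )
        fwd = mne.make_forward_solution(
            info, trans=mne.transforms.Transform("head", "mri"), src=src,
            bem=sphere, meg=True, eeg=False,
        )
        fwd = mne.convert_forward_solution(fwd, force_fixed=True)
        ours = lead_field(
            np.array([0, 0, 0.05]), np.array([1.0, 0, 0]), sphere_head,
            SensorArray(pos, ori, tuple(f"M{i}" for i in range(len(pos)))),
        )
        # mne stores solutions in float32; compare at that precision
        np.testing.assert_allclose(fwd["sol"]["data"][:, 0], ours, rtol=2e-6,
                                   atol=2e-6 * np.max(np.abs(ours)))

    def test_radial_dipole_silent_all_channels(self, sphere_head, rng):
        sensors = make_helmet_array(n_channels=50, radius=0.12, seed=5)
        for _ in range(200):
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            pos = u * rng.uniform(0.02, 0.07)
            src = DipoleSource(position=pos, orientation=u, amplitude_mean=31.0)
            assert np.max(np.abs(forward_field(src, sphere_head, sensors))) < 1e-20

    def test_radial_null_per_channel_local_spheres(self, small_geometry, rng):
        # a dipole radial w.r.t. one channel's own sphere is silent on that channel
        geo = small_geometry
        centers = geo.head_model.sphere_centers
        for i in (0, 17, 33):
            c = centers[i]
            u = np.array([0.2, -0.3, 0.8])
            u /= np.linalg.norm(u)
            pos = c + 0.035 * u
            lf = lead_field_matrix(pos[None, :], geo.head_model, geo.sensors,
                                   check_inside=False)[0]
            field_i = lf[i] @ u * 31e-9
            assert abs(field_i) < 1e-20

    def test_linearity_and_antisymmetry(self, sphere_head):
        sensors = make_helmet_array(n_channels=20, radius=0.12, seed=6)
        pos = np.array([0.01, 0.02, 0.05])
        u = np.array([0.0, 1.0, 0.0])
        s1 = DipoleSource(position=pos, orientation=u, amplitude_mean=31.0)
        s2 = DipoleSource(position=pos, orientation=u, amplitude_mean=62.0)
        np.testing.assert_allclose(
            forward_field(s2, sphere_head, sensors), 2 * forward_field(s1, sphere_head, sensors),
            rtol=1e-15,
        )
        np.testing.assert_array_equal(
            lead_field(pos, -u, sphere_head, sensors), -lead_field(pos, u, sphere_head, sensors)
        )

    def test_field_decays_with_depth(self, sphere_head):
        sensors = make_helmet_array(n_channels=40, radius=0.12, seed=7)
        u = np.array([1.0, 0.0, 0.0])
        mags = []
        for depth in (0.06, 0.05, 0.04, 0.03, 0.02):
            lf = lead_field(np.array([0.0, 0.0, depth]), u, sphere_head, sensors)
            mags.append(abs(lf[np.argmin(np.linalg.norm(
                sensors.positions - [0, 0, 0.12], axis=1))]))
        assert all(a > b for a, b in zip(mags, mags[1:]))

    def test_source_outside_sphere_rejected(self, sphere_head):
        sensors = make_helmet_array(n_channels=5, radius=0.12, seed=8)
        with pytest.raises(ValueError, match="MEG001|inside"):
            lead_field(np.array([0.0, 0.0, 0.095]), np.array([1.0, 0, 0]),
                       sphere_head, sensors)

    def test_source_at_center_rejected(self, sphere_head):
        sensors = make_helmet_array(n_channels=5, radius=0.12, seed=8)
        with pytest.raises(ValueError, match="center"):
            lead_field(np.zeros(3), np.array([1.0, 0, 0]), sphere_head, sensors)

    def test_lead_field_matrix_consistent_with_single(self, sphere_head):
        sensors = make_helmet_array(n_channels=15, radius=0.12, seed=9)
        pts = np.array([[0.0, 0.01, 0.05], [0.02, -0.01, 0.04]])
        L3 = lead_field_matrix(pts, sphere_head, sensors)
        for j, p in enumerate(pts):
            for k, e in enumerate(np.eye(3)):
                np.testing.assert_allclose(
                    L3[j, :, k], lead_field(p, e, sphere_head, sensors, check_inside=False),
                    rtol=1e-12,
                )
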