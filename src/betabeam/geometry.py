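"""Sensor geometry, ellipsoidal source surfaces and the spherical-conductor forward model.

This module provides the measurement-side scaffolding for MEG source
simulation and reconstruction:

* :class:`SensorArray` — a helmet-like arrangement of point magnetometers,
  each sensing the magnetic field component along its orientation.
* :class:`EllipsoidSurface` — an ellipsoid standing in for the brain surface;
  shrinking it by a fixed depth yields the surface on which simulated current
  dipoles sit, so all sources share a comparable depth (and hence SNR).
* :class:`HeadModel` — single-sphere or multiple-local-spheres conductor
  models fitted to the head surface.
* :func:`lead_field` / :func:`forward_field` — the closed-form magnetic field
  of a current dipole in a spherically symmetric conductor (Sarvas formula),
  projected onto each channel's sensing direction.

Everything is SI internally (metres, tesla, A·m).  Dipole moments are
accepted in nAm and noise amplitudes in fT at the public interfaces, the
units a MEG practitioner would quote, and converted exactly once.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SensorArray",
    "EllipsoidSurface",
    "HeadModel",
    "DipoleSource",
    "make_helmet_array",
    "fit_ellipsoid",
    "shrink_surface",
    "tangential_orientation",
    "fit_sphere",
    "fit_local_spheres",
    "lead_field",
    "lead_field_matrix",
    "forward_field",
]

MU0_OVER_4PI = 1e-7  # T·m/A
NAM = 1e-9  # nAm -> A·m


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SensorArray:
    """Positions, sensing orientations and labels of the field channels.

    Parameters
    ----------
    positions : (n, 3) float array, metres
    orientations : (n, 3) float array, unit vectors (sensing direction)
    names : sequence of n channel labels
    """

    positions: np.ndarray
    orientations: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        ori = np.asarray(self.orientations, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3 or pos.shape != ori.shape:
            raise ValueError("positions/orientations must be matching (n, 3) arrays")
        if pos.shape[0] < 2:
            raise ValueError("a sensor array needs at least 2 channels")
        norms = np.linalg.norm(ori, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-12):
            raise ValueError("orientation vectors must have unit norm (tol 1e-12)")
        if len(np.unique(pos, axis=0)) != pos.shape[0]:
            raise ValueError("sensor positions must be pairwise distinct")
        if len(self.names) != pos.shape[0]:
            raise ValueError("one name per channel required")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "orientations", ori)
        object.__setattr__(self, "names", tuple(self.names))

    @property
    def n_channels(self) -> int:
        return self.positions.shape[0]

    def to_json(self) -> str:
        """Serialise to the plain-text channel sidecar layout."""
        recs = [
            {"name": n, "position": p.tolist(), "orientation": o.tolist()}
            for n, p, o in zip(self.names, self.positions, self.orientations)
        ]
        return json.dumps({"channels": recs}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SensorArray":
        recs = json.loads(text)["channels"]
        return cls(
            positions=np.array([r["position"] for r in recs], dtype=float),
            orientations=np.array([r["orientation"] for r in recs], dtype=float),
            names=tuple(r["name"] for r in recs),
        )


@dataclass(frozen=True)
class EllipsoidSurface:
    """An ellipsoid ``{c + R (a ∘ u) : |u| = 1}`` with orthonormal frame R.

    ``implicit(p) = |diag(1/a) Rᵀ (p − c)|² − 1`` is zero on the surface,
    negative inside.
    """

    center: np.ndarray
    semi_axes: np.ndarray
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        c = np.asarray(self.center, dtype=float).reshape(3)
        a = np.asarray(self.semi_axes, dtype=float).reshape(3)
        r = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        if np.any(a <= 0):
            raise ValueError("semi_axes must be strictly positive")
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-10):
            raise ValueError("rotation must be orthonormal (RᵀR = I to 1e-10)")
        object.__setattr__(self, "center", c)
        object.__setattr__(self, "semi_axes", a)
        object.__setattr__(self, "rotation", r)

    # -- geometry helpers ---------------------------------------------------

    def _body(self, points: np.ndarray) -> np.ndarray:
        """Map to the body frame scaled by the semi-axes (unit sphere coords)."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        return (p - self.center) @ self.rotation / self.semi_axes

    def implicit(self, points: np.ndarray) -> np.ndarray:
        u = self._body(points)
        out = np.einsum("ij,ij->i", u, u) - 1.0
        return out if np.ndim(points) == 2 else out[0]

    def normal(self, point: np.ndarray) -> np.ndarray:
        """Outward unit normal at a surface point."""
        u = self._body(point)[0] / self.semi_axes  # R-frame gradient/2
        g = self.rotation @ u
        return g / np.linalg.norm(g)

    def project(self, points: np.ndarray) -> np.ndarray:
        """Radially (from the center) project points onto the surface."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        u = self._body(p)
        scale = 1.0 / np.linalg.norm(u, axis=1)
        out = self.center + (p - self.center) * scale[:, None]
        return out if np.ndim(points) == 2 else out[0]

    def sample(self, n: int, rng: np.random.Generator | None = None) -> np.ndarray:
        """n points on the surface: Fibonacci-uniform directions, or random ones."""
        if rng is None:
            k = np.arange(n)
            z = 1.0 - 2.0 * (k + 0.5) / n
            phi = np.pi * (3.0 - np.sqrt(5.0)) * k
            s = np.sqrt(1.0 - z**2)
            u = np.column_stack([s * np.cos(phi), s * np.sin(phi), z])
        else:
            u = rng.standard_normal((n, 3))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
        return self.center + (u * self.semi_axes) @ self.rotation.T


@dataclass(frozen=True)
class HeadModel:
    """Spherical conductor model: one global sphere or one sphere per channel.

    ``sphere_radii`` do not enter the dipole field formula (the field in a
    spherically symmetric conductor is independent of the conductivity
    profile); they are kept for provenance and for inside-the-head checks.
    """

    mode: str  # "single_sphere" | "local_spheres"
    sphere_centers: np.ndarray  # (1, 3) or (n_channels, 3)
    sphere_radii: np.ndarray  # (1,) or (n_channels,)
    # whole-head sphere used for the source-containment check in
    # local_spheres mode (a per-channel patch sphere need not contain
    # sources on the far side of the head, by construction)
    bounding_center: np.ndarray | None = None
    bounding_radius: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("single_sphere", "local_spheres"):
            raise ValueError(f"unknown head model mode {self.mode!r}")
        c = np.atleast_2d(np.asarray(self.sphere_centers, dtype=float))
        r = np.atleast_1d(np.asarray(self.sphere_radii, dtype=float))
        if c.shape[0] != r.shape[0]:
            raise ValueError("one radius per sphere center required")
        if self.mode == "single_sphere" and c.shape[0] != 1:
            raise ValueError("single_sphere mode takes exactly one center")
        object.__setattr__(self, "sphere_centers", c)
        object.__setattr__(self, "sphere_radii", r)
        if self.bounding_center is not None:
            object.__setattr__(
                self, "bounding_center", np.asarray(self.bounding_center, dtype=float).reshape(3)
            )

    def centers_for(self, n_channels: int) -> np.ndarray:
        """Per-channel sphere centers, broadcasting the single-sphere case."""
        if self.sphere_centers.shape[0] == 1:
            return np.broadcast_to(self.sphere_centers, (n_channels, 3))
        if self.sphere_centers.shape[0] != n_channels:
            raise ValueError(
                "local_spheres head model has "
                f"{self.sphere_centers.shape[0]} centers for {n_channels} channels"
            )
        return self.sphere_centers


@dataclass(frozen=True)
class DipoleSource:
    """A current dipole with an across-trial amplitude model.

    ``amplitude_mean``/``amplitude_sd`` are in nAm and describe the per-trial
    source strength distribution (each trial draws one strength).
    """

    position: np.ndarray
    orientation: np.ndarray
    amplitude_mean: float = 31.0
    amplitude_sd: float = 3.0

    def __post_init__(self) -> None:
        p = np.asarray(self.position, dtype=float).reshape(3)
        o = np.asarray(self.orientation, dtype=float).reshape(3)
        if abs(np.linalg.norm(o) - 1.0) > 1e-10:
            raise ValueError("orientation must be a unit vector")
        if self.amplitude_sd < 0:
            raise ValueError("amplitude_sd must be non-negative")
        object.__setattr__(self, "position", p)
        object.__setattr__(self, "orientation", o)


# --------------------------------------------------------------------------
# constructors
# --------------------------------------------------------------------------


def make_helmet_array(
    n_channels: int = 275,
    radius: float = 0.12,
    coverage: float = 0.5,
    seed: int = 0,
) -> SensorArray:
    """Quasi-uniform point magnetometers on the upper cap of a sphere.

    Stands in for a whole-head axial-gradiometer helmet: ``coverage`` is the
    fraction of the full sphere covered by the cap (0.5 = upper hemisphere).
    Channels are laid out on a Fibonacci spiral (rotated by a seed-dependent
    azimuth so distinct seeds give distinct but statistically equivalent
    arrays) and each channel senses the inward radial field component.
    """
    if n_channels < 2:
        raise ValueError(f"n_channels must be >= 2, got {n_channels}")
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    if not 0 < coverage <= 1:
        raise ValueError(f"coverage must be in (0, 1], got {coverage}")
    rng = np.random.default_rng(seed)
    phi0 = rng.uniform(0.0, 2.0 * np.pi)
    k = np.arange(n_channels)
    z = 1.0 - 2.0 * coverage * (k + 0.5) / n_channels
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k + phi0
    s = np.sqrt(1.0 - z**2)
    unit = np.column_stack([s * np.cos(phi), s * np.sin(phi), z])
    names = tuple(f"MEG{i + 1:03d}" for i in range(n_channels))
    return SensorArray(positions=radius * unit, orientations=-unit, names=names)


def fit_ellipsoid(points: np.ndarray) -> tuple[EllipsoidSurface, dict]:
    """Least-squares ellipsoid through a 3-D point cloud.

    Algebraic fit: the general quadric ``xᵀQx + 2bᵀx + j = 0`` minimising the
    algebraic residual under a unit-coefficient-norm constraint (smallest
    right singular vector of the design matrix), then converted to
    center/semi-axes/rotation.  Returns the surface and a residual report
    (rms and max of the implicit-equation values at the input points).
    """
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or p.shape[1] != 3 or p.shape[0] < 9:
        raise ValueError("need at least 9 points of shape (n, 3)")
    x, y, z = p.T
    design = np.column_stack(
        [x * x, y * y, z * z, 2 * x * y, 2 * x * z, 2 * y * z, 2 * x, 2 * y, 2 * z, np.ones_like(x)]
    )
    # scale for conditioning
    scale = np.max(np.abs(p))
    design_s = np.column_stack(
        [design[:, :6] / scale**2, design[:, 6:9] / scale, design[:, 9]]
    )
    _, sv, vt = np.linalg.svd(design_s, full_matrices=False)
    if sv[-2] < 1e-10 * sv[0]:
        raise ValueError("degenerate point cloud: quadric fit is not unique (coplanar points?)")
    v = vt[-1]
    coeff = np.concatenate([v[:6] / scale**2, v[6:9] / scale, v[9:]])
    a_, b_, c_, d_, e_, f_, g_, h_, i_, j_ = coeff
    quad = np.array([[a_, d_, e_], [d_, b_, f_], [e_, f_, c_]])
    lin = np.array([g_, h_, i_])
    try:
        center = -np.linalg.solve(quad, lin)
    except np.linalg.LinAlgError as exc:
        raise ValueError("degenerate point cloud: singular quadric") from exc
    k = center @ quad @ center - j_
    eigval, eigvec = np.linalg.eigh(quad)
    if k < 0:
        # normalise overall sign so that quad/k is positive definite
        eigval, k = -eigval, -k
    if k <= 0 or np.any(eigval <= 0):
        raise ValueError("degenerate point cloud: fitted quadric is not an ellipsoid")
    semi = np.sqrt(k / eigval)
    order = np.argsort(semi)[::-1]
    semi = semi[order]
    rot = eigvec[:, order]
    if np.linalg.det(rot) < 0:
        rot[:, 2] = -rot[:, 2]
    surface = EllipsoidSurface(center=center, semi_axes=semi, rotation=rot)
    res = surface.implicit(p)
    report = {"rms_residual": float(np.sqrt(np.mean(res**2))), "max_residual": float(np.max(np.abs(res)))}
    return surface, report


def shrink_surface(surface: EllipsoidSurface, depth: float) -> EllipsoidSurface:
    """Reduce every semi-axis by ``depth`` (same center and frame).

    This is the construction used to place all simulated dipoles a fixed
    distance beneath the brain-surface ellipsoid.
    """
    if depth < 0:
        raise ValueError("depth must be non-negative")
    if depth >= np.min(surface.semi_axes):
        raise ValueError(
            f"depth {depth} m must be smaller than the minimum semi-axis "
            f"{np.min(surface.semi_axes)} m"
        )
    return replace(surface, semi_axes=surface.semi_axes - depth)


def tangential_orientation(
    surface: EllipsoidSurface, point: np.ndarray, azimuth: float
) -> np.ndarray:
    """Unit vector tangential to ``surface`` at ``point``.

    ``azimuth`` rotates the vector within the tangent plane; the zero-azimuth
    direction is a fixed deterministic function of the surface normal.
    """
    point = np.asarray(point, dtype=float).reshape(3)
    if abs(surface.implicit(point)) > 1e-6:
        raise ValueError("point does not lie on the surface (implicit residual > 1e-6)")
    n = surface.normal(point)
    ref = np.array([0.0, 0.0, 1.0]) if abs(n[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(ref, n)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return np.cos(azimuth) * e1 + np.sin(azimuth) * e2


def fit_sphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares sphere (center, radius) through a point cloud."""
    p = np.asarray(points, dtype=float)
    if p.shape[0] < 4:
        raise ValueError("need at least 4 points to fit a sphere")
    design = np.column_stack([2 * p, np.ones(p.shape[0])])
    rhs = np.einsum("ij,ij->i", p, p)
    sol, *_ = np.linalg.lstsq(design, rhs, rcond=None)
    center = sol[:3]
    radius = float(np.sqrt(sol[3] + center @ center))
    return center, radius


def fit_local_spheres(
    head_surface: EllipsoidSurface,
    sensors: SensorArray,
    patch_radius: float = 0.04,
    mode: str = "local_spheres",
    n_surface_samples: int = 2000,
) -> HeadModel:
    """Fit the spherical conductor model(s) to the head surface.

    In ``local_spheres`` mode each channel gets a sphere fitted to the
    surface patch within ``patch_radius`` of the surface point closest to the
    channel; in ``single_sphere`` mode one sphere is fitted to the whole
    surface.
    """
    if patch_radius <= 0:
        raise ValueError("patch_radius must be positive")
    pts = head_surface.sample(n_surface_samples)
    if mode == "single_sphere":
        center, radius = fit_sphere(pts)
        return HeadModel(mode=mode, sphere_centers=center[None, :], sphere_radii=[radius])
    if mode != "local_spheres":
        raise ValueError(f"unknown head model mode {mode!r}")
    centers = np.empty((sensors.n_channels, 3))
    radii = np.empty(sensors.n_channels)
    for i, spos in enumerate(sensors.positions):
        nearest = pts[np.argmin(np.linalg.norm(pts - spos, axis=1))]
        patch = pts[np.linalg.norm(pts - nearest, axis=1) <= patch_radius]
        if patch.shape[0] < 4:
            raise ValueError(
                f"patch for channel {sensors.names[i]} contains {patch.shape[0]} "
                "points (< 4); increase patch_radius or surface sampling"
            )
        centers[i], radii[i] = fit_sphere(patch)
    g_center, g_radius = fit_sphere(pts)
    return HeadModel(
        mode=mode,
        sphere_centers=centers,
        sphere_radii=radii,
        bounding_center=g_center,
        bounding_radius=g_radius,
    )


# --------------------------------------------------------------------------
# forward model
# --------------------------------------------------------------------------


def _sarvas_field(
    position: np.ndarray, moments: np.ndarray, sensor_pos: np.ndarray, centers: np.ndarray
) -> np.ndarray:
    """Magnetic field (T) of current dipoles in spherically symmetric conductors.

    Closed form for the external field of a current dipole at ``position``
    with moment(s) ``moments`` (k, 3) in A·m, evaluated at ``sensor_pos``
    (n, 3) with per-sensor sphere ``centers`` (n, 3).  Returns (k, n, 3).
    """
    r_v = sensor_pos - centers  # (n, 3) sensor in sphere frame
    r0_v = position[None, :] - centers  # (n, 3) dipole in sphere frame
    a_v = r_v - r0_v
    a = np.linalg.norm(a_v, axis=1)
    r = np.linalg.norm(r_v, axis=1)
    if np.any(a < 1e-12):
        raise ValueError("dipole coincides with a sensor position")
    if np.any(np.linalg.norm(r0_v, axis=1) < 1e-12):
        raise ValueError("dipole lies at a sphere center; the field model is singular there")
    ar = np.einsum("ij,ij->i", a_v, r_v)
    f = a * (r * a + r**2 - np.einsum("ij,ij->i", r0_v, r_v))
    if np.any(np.abs(f) < 1e-300):
        raise ValueError("degenerate dipole/sensor configuration (F = 0)")
    grad_f = (
        (a**2 / r + ar / a + 2.0 * a + 2.0 * r)[:, None] * r_v
        - (a + 2.0 * r + ar / a)[:, None] * r0_v
    )
    q_x_r0 = np.cross(moments[:, None, :], r0_v[None, :, :])  # (k, n, 3)
    dot = np.einsum("knj,nj->kn", q_x_r0, r_v)
    b = MU0_OVER_4PI / f[None, :, None] ** 2 * (
        f[None, :, None] * q_x_r0 - dot[:, :, None] * grad_f[None, :, :]
    )
    return b


def _validate_inside(position: np.ndarray, head: HeadModel, sensors: SensorArray) -> None:
    if head.mode == "single_sphere":
        centers = head.centers_for(sensors.n_channels)
        radii = np.broadcast_to(head.sphere_radii, (sensors.n_channels,))
        dist = np.linalg.norm(position[None, :] - centers, axis=1)
        bad = np.nonzero(dist >= radii)[0]
        if bad.size:
            raise ValueError(
                f"source at {position} is not strictly inside the sphere of channel "
                f"{sensors.names[bad[0]]} (|r0| = {dist[bad[0]]:.4f} m >= radius "
                f"{radii[bad[0]]:.4f} m)"
            )
    elif head.bounding_center is not None and head.bounding_radius is not None:
        # local patch spheres need not individually contain far-side sources;
        # containment is checked against the whole-head sphere instead
        dist = float(np.linalg.norm(position - head.bounding_center))
        if dist >= head.bounding_radius:
            raise ValueError(
                f"source at {position} lies outside the fitted head sphere "
                f"(|r0| = {dist:.4f} m >= radius {head.bounding_radius:.4f} m)"
            )


def lead_field(
    position: np.ndarray,
    orientation: np.ndarray,
    head: HeadModel,
    sensors: SensorArray,
    check_inside: bool = True,
) -> np.ndarray:
    """Per-channel field (T) of a unit (1 A·m) dipole at ``position``/``orientation``.

    Each channel uses its own sphere center (local-spheres mode) and reads the
    projection of the dipole field onto its sensing orientation.  Linear in
    the dipole moment; a dipole oriented radially with respect to a channel's
    sphere center produces a null reading on that channel.
    """
    position = np.asarray(position, dtype=float).reshape(3)
    orientation = np.asarray(orientation, dtype=float).reshape(3)
    if check_inside:
        _validate_inside(position, head, sensors)
    centers = head.centers_for(sensors.n_channels)
    b = _sarvas_field(position, orientation[None, :], sensors.positions, centers)[0]
    return np.einsum("nj,nj->n", b, sensors.orientations)


def lead_field_matrix(
    positions: np.ndarray,
    head: HeadModel,
    sensors: SensorArray,
    check_inside: bool = True,
) -> np.ndarray:
    """Lead fields of the three Cartesian unit dipoles at many scan points.

    Returns (n_points, n_channels, 3): column m is the channel response to a
    unit dipole along axis m.  The radial component (rank deficiency of the
    spherical model) is retained; consumers restrict to the tangential
    subspace when optimising orientation.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    centers = head.centers_for(sensors.n_channels)
    eye = np.eye(3)
    out = np.empty((positions.shape[0], sensors.n_channels, 3))
    for i, pos in enumerate(positions):
        if check_inside:
            _validate_inside(pos, head, sensors)
        b = _sarvas_field(pos, eye, sensors.positions, centers)  # (3, n, 3)
        out[i] = np.einsum("knj,nj->nk", b, sensors.orientations)
    return out


def forward_field(source: DipoleSource, head: HeadModel, sensors: SensorArray) -> np.ndarray:
    """Sensor-space field (T) of ``source`` at its mean amplitude.

    Equals ``lead_field(...) * amplitude_mean`` with the amplitude converted
    from nAm; doubling the source amplitude doubles every channel reading.
    """
    lf = lead_field(source.position, source.orientation, head, sensors)
    return lf * (source.amplitude_mean * NAM)
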