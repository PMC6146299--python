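"""Sensor arrays, source grids and the spherical-conductor forward model.

A source space is a grid of points inside a homogeneously conducting
sphere; sensors are radial magnetometers on a spherical cap above it.
Leadfields are computed with the closed-form solution for the magnetic
field of a current dipole in a conducting sphere (Sarvas 1987).  Because
radial dipoles are externally silent in this geometry, the forward model
can be reduced from three free orientations to two orthonormal dipoles
tangential to the sphere without losing measurable signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SensorArray",
    "SourceSpace",
    "ForwardModel",
    "make_spherical_sensor_array",
    "make_spherical_source_grid",
    "sarvas_leadfield",
    "compute_forward",
    "forward_to_tangential",
    "select_vertices_in_sensor_range",
    "restrict_src_to_vertices",
    "restrict_forward_to_vertices",
    "to_common_order",
]

_MU0_OVER_4PI = 1e-7  # vacuum permeability / 4 pi, T m / A


@dataclass(frozen=True)
class SensorArray:
    """Positions (m), unit sensing orientations, and names of the sensors."""

    positions: np.ndarray  # (n_sensors, 3)
    orientations: np.ndarray  # (n_sensors, 3), unit norm
    names: list[str] = field(default_factory=list)

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        ori = np.asarray(self.orientations, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3 or len(pos) < 1:
            raise ValueError("positions must be an (n_sensors, 3) array")
        if not np.all(np.isfinite(pos)):
            raise ValueError("sensor positions must be finite")
        norms = np.linalg.norm(ori, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("sensor orientations must have unit norm")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "orientations", ori)
        if not self.names:
            object.__setattr__(
                self, "names", [f"MEG{i:03d}" for i in range(len(pos))]
            )

    @property
    def n_sensors(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class SourceSpace:
    """Candidate dipole locations with stable integer vertex identifiers.

    ``vertex_ids`` are expressed in a designated *common reference order*
    shared across subjects, so that group-level quantities indexed by
    vertex can be compared directly.
    """

    points: np.ndarray  # (n_vertices, 3), meters
    vertex_ids: np.ndarray  # (n_vertices,), int, unique
    sphere_origin: np.ndarray  # (3,)

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float).reshape(-1, 3)
        vids = np.asarray(self.vertex_ids, dtype=int).ravel()
        origin = np.asarray(self.sphere_origin, dtype=float).ravel()
        if len(vids) != len(pts):
            raise ValueError("vertex_ids and points length mismatch")
        if len(np.unique(vids)) != len(vids):
            raise ValueError("vertex_ids must be unique")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "vertex_ids", vids)
        object.__setattr__(self, "sphere_origin", origin)

    @property
    def n_vertices(self) -> int:
        return len(self.points)

    @property
    def is_empty(self) -> bool:
        return self.n_vertices == 0


@dataclass(frozen=True)
class ForwardModel:
    """Leadfields (source x orientation x sensor) plus the geometry.

    ``n_orient`` is 3 for free-orientation models (global x, y, z unit
    dipoles) or 2 for tangential models, where the two orientation
    vectors per source are orthonormal and orthogonal to the radial
    direction ``point - sphere_origin``.
    """

    leadfields: np.ndarray  # (n_sources, n_orient, n_sensors)
    n_orient: int
    orientation_vectors: np.ndarray  # (n_sources, n_orient, 3)
    source_space: SourceSpace
    sensor_array: SensorArray

    def __post_init__(self):
        if self.n_orient not in (2, 3):
            raise ValueError("n_orient must be 2 or 3")
        lf = np.asarray(self.leadfields, dtype=float)
        if not np.all(np.isfinite(lf)):
            raise ValueError("leadfields must be finite")
        object.__setattr__(self, "leadfields", lf)
        object.__setattr__(
            self,
            "orientation_vectors",
            np.asarray(self.orientation_vectors, dtype=float),
        )

    @property
    def n_sources(self) -> int:
        return self.leadfields.shape[0]


def _fibonacci_sphere(n: int, z_lo: float, z_hi: float) -> np.ndarray:
    """Quasi-uniform unit vectors with z uniformly stratified in [z_lo, z_hi]."""
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    i = np.arange(n)
    z = z_hi - (z_hi - z_lo) * (i + 0.5) / n
    phi = 2.0 * np.pi * i / golden
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def make_spherical_sensor_array(
    n_sensors: int, shell_radius: float, coverage: float = 0.55
) -> SensorArray:
    """Quasi-uniform radial sensors on a spherical cap centred on +z.

    Parameters
    ----------
    n_sensors : number of sensors (>= 1; quasi-uniform layout needs >= 8,
        a single sensor is placed at the pole).
    shell_radius : radius of the sensor shell in meters.
    coverage : fraction of the full sphere covered by the cap, i.e. the
        cap spans z in [1 - 2*coverage, 1] on the unit sphere.
    """
    if n_sensors < 1 or shell_radius <= 0:
        raise ValueError("n_sensors and shell_radius must be positive")
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    if n_sensors == 1:
        units = np.array([[0.0, 0.0, 1.0]])
    else:
        if n_sensors < 8:
            raise ValueError("quasi-uniform cap layout requires >= 8 sensors")
        units = _fibonacci_sphere(n_sensors, 1.0 - 2.0 * coverage, 1.0)
    return SensorArray(positions=shell_radius * units, orientations=units)


def make_spherical_source_grid(
    n_points: int, source_radius: float, sphere_origin=(0.0, 0.0, 0.0)
) -> SourceSpace:
    """Fibonacci-lattice source grid on a sphere of ``source_radius``.

    Vertex ids 0..n_points-1 in construction order define the common
    reference order used for group-level alignment.
    """
    if n_points < 2:
        raise ValueError("a source grid needs at least 2 points")
    if source_radius <= 0:
        raise ValueError("source_radius must be positive")
    origin = np.asarray(sphere_origin, dtype=float)
    units = _fibonacci_sphere(n_points, -1.0, 1.0)
    return SourceSpace(
        points=origin + source_radius * units,
        vertex_ids=np.arange(n_points),
        sphere_origin=origin,
    )


def sarvas_leadfield(source_point, moment, sensor_position, sensor_orientation,
                     sphere_origin) -> float:
    """Magnetic field of a current dipole in a conducting sphere.

    Closed-form (Sarvas) expression for the field outside a homogeneous
    spherical conductor, projected on the sensor's sensing direction.
    Returns tesla per unit dipole moment (A m).  The field is linear in
    ``moment`` and vanishes for radial dipoles and for a dipole at the
    sphere origin.
    """
    origin = np.asarray(sphere_origin, dtype=float)
    r0 = np.asarray(source_point, dtype=float) - origin
    r = np.asarray(sensor_position, dtype=float) - origin
    q = np.asarray(moment, dtype=float)
    r_norm = np.linalg.norm(r)
    if np.linalg.norm(r0) >= r_norm:
        raise ValueError("source must lie strictly inside the sensor radius")
    a_vec = r - r0
    a = np.linalg.norm(a_vec)
    f = a * (r_norm * a + r_norm**2 - r0 @ r)
    grad_f = (
        (a**2 / r_norm + (a_vec @ r) / a + 2.0 * a + 2.0 * r_norm) * r
        - (a + 2.0 * r_norm + (a_vec @ r) / a) * r0
    )
    q_x_r0 = np.cross(q, r0)
    b = _MU0_OVER_4PI / f**2 * (f * q_x_r0 - (q_x_r0 @ r) * grad_f)
    return float(b @ np.asarray(sensor_orientation, dtype=float))


def compute_forward(src: SourceSpace, sensors: SensorArray) -> ForwardModel:
    """Free-orientation forward model: unit dipoles along global x, y, z."""
    n_src, n_sens = src.n_vertices, sensors.n_sensors
    lf = np.empty((n_src, 3, n_sens))
    eye = np.eye(3)
    for s in range(n_src):
        for o in range(3):
            for k in range(n_sens):
                lf[s, o, k] = sarvas_leadfield(
                    src.points[s], eye[o], sensors.positions[k],
                    sensors.orientations[k], src.sphere_origin,
                )
    ori = np.broadcast_to(eye, (n_src, 3, 3)).copy()
    return ForwardModel(
        leadfields=lf, n_orient=3, orientation_vectors=ori,
        source_space=src, sensor_array=sensors,
    )


def _tangential_basis(radial: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal pair orthogonal to ``radial`` (unit)."""
    z = np.array([0.0, 0.0, 1.0])
    e1 = np.cross(z, radial)
    if np.linalg.norm(e1) < 1e-9:
        e1 = np.cross(np.array([1.0, 0.0, 0.0]), radial)
    e1 = e1 / np.linalg.norm(e1)
    e2 = np.cross(radial, e1)
    return e1, e2


def forward_to_tangential(fwd: ForwardModel) -> ForwardModel:
    """Reduce a free-orientation model to two tangential dipoles per source.

    The new rows are the linear combinations of the x/y/z rows given by
    the components of the tangential basis vectors; radial components
    are discarded (they are externally silent in this geometry anyway).
    """
    if fwd.n_orient != 3:
        raise ValueError("forward model must have 3 free orientations")
    src = fwd.source_space
    radials = src.points - src.sphere_origin
    norms = np.linalg.norm(radials, axis=1)
    if np.any(norms < 1e-12):
        raise ValueError("source at sphere origin has no tangential plane")
    radials = radials / norms[:, None]
    lf = np.empty((fwd.n_sources, 2, fwd.sensor_array.n_sensors))
    ori = np.empty((fwd.n_sources, 2, 3))
    for s in range(fwd.n_sources):
        e1, e2 = _tangential_basis(radials[s])
        ori[s, 0], ori[s, 1] = e1, e2
        lf[s, 0] = e1 @ fwd.leadfields[s]
        lf[s, 1] = e2 @ fwd.leadfields[s]
    return ForwardModel(
        leadfields=lf, n_orient=2, orientation_vectors=ori,
        source_space=src, sensor_array=fwd.sensor_array,
    )


def select_vertices_in_sensor_range(
    src: SourceSpace, sensors: SensorArray, dist: float
) -> np.ndarray:
    """Vertex ids whose distance to the nearest sensor is <= ``dist``.

    Sources farther than ``dist`` from every sensor are the "deep"
    sources to be discarded before connectivity analysis; a source at
    exactly ``dist`` is kept.
    """
    if dist <= 0:
        raise ValueError("dist must be positive")
    diff = src.points[:, None, :] - sensors.positions[None, :, :]
    min_d = np.sqrt((diff**2).sum(-1)).min(axis=1)
    keep = src.vertex_ids[min_d <= dist]
    if len(keep) == 0:
        warnings.warn("no source points within sensor range", stacklevel=2)
    return keep


def restrict_src_to_vertices(src: SourceSpace, keep) -> SourceSpace:
    """Keep only ``keep`` vertices, preserving the common reference order."""
    keep = np.asarray(sorted({int(v) for v in np.atleast_1d(list(keep))}), dtype=int)
    unknown = np.setdiff1d(keep, src.vertex_ids)
    if len(unknown):
        raise ValueError(f"unknown vertex ids: {unknown.tolist()}")
    # src.vertex_ids follow the common order; sorted membership keeps it
    mask = np.isin(src.vertex_ids, keep)
    return SourceSpace(
        points=src.points[mask],
        vertex_ids=src.vertex_ids[mask],
        sphere_origin=src.sphere_origin,
    )


def restrict_forward_to_vertices(fwd: ForwardModel, keep) -> ForwardModel:
    """Matching forward-model slice for :func:`restrict_src_to_vertices`."""
    new_src = restrict_src_to_vertices(fwd.source_space, keep)
    mask = np.isin(fwd.source_space.vertex_ids, new_src.vertex_ids)
    return ForwardModel(
        leadfields=fwd.leadfields[mask],
        n_orient=fwd.n_orient,
        orientation_vectors=fwd.orientation_vectors[mask],
        source_space=new_src,
        sensor_array=fwd.sensor_array,
    )


def to_common_order(values: np.ndarray, mapping: dict[int, int]) -> np.ndarray:
    """Reorder a vertex-indexed quantity from subject-local to common order.

    ``mapping`` sends subject-local position ``i`` to the common vertex
    id; entry ``i`` of the input lands at the rank of its common id
    among all mapped ids.  Must be a bijection over the shared set.
    """
    values = np.asarray(values)
    n = values.shape[0]
    if len(mapping) != n or len(set(mapping.values())) != n:
        raise ValueError("mapping must be a bijection over the vertex set")
    local = np.array(sorted(mapping.keys()))
    if not np.array_equal(local, np.arange(n)):
        raise ValueError("mapping keys must cover local positions 0..n-1")
    common_ids = np.array([mapping[i] for i in range(n)])
    order = np.argsort(common_ids)
    return values[order]
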