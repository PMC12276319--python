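"""Synthetic torso, spine, source-space and sensor-array generator.

The study geometry emulates a seated adult thorax instrumented with a grid of
triaxial magnetometers over the back:

* a closed torso surface with a superellipse cross-section (flat-ish back so
  orthographic ray casting is well posed) and rounded caps;
* a spinal-cord centreline expressed exactly as a 5th-order polynomial per
  coordinate, lying at a fixed depth (default 50 mm) from the back surface;
* a source space of medial sources every 10 mm of arc along the cord, each
  with a ring of 8 sources at 4 mm radius in the plane normal to the local
  tangent, oriented by rotation-minimising (parallel-transport) frames;
* capped tube meshes around the centreline for the spinal cord (8 mm) and a
  rotationally symmetric vertebral-column surrogate (16 mm);
* ellipsoidal heart and lung surrogates;
* a sensor array ray-cast onto the back at 10 mm standoff, three orthogonal
  channels per site (X inferior-superior, Y normal to the back, Z left-right).

Coordinate frame: +X superior, +Y posterior-to-anterior (the back faces -Y),
+Z toward the subject's left; origin near the torso centroid.  Everything is
deterministic for a fixed :class:`GeometryConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .mesh import TriMesh, _ensure_outward

__all__ = [
    "GeometryConfig",
    "SpineCurve",
    "SourceSpace",
    "SensorArray",
    "GeometryBundle",
    "build_torso_surface",
    "build_spine_curve",
    "build_source_space",
    "build_tube_mesh",
    "build_organ_meshes",
    "build_sensor_array",
    "build_geometry",
    "save_geometry",
    "load_geometry",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeometryConfig:
    """All tunable lengths (mm) and mesh-resolution controls.

    ``density`` scales vertex counts of every generated surface relative to
    the reference resolutions (torso ~3160 vertices, cord ~5160, ...); counts
    scale linearly with ``density`` (each direction by its square root).
    """

    torso_width: float = 320.0       # z extent
    torso_depth: float = 240.0       # y extent
    torso_height: float = 700.0      # x extent, thorax plus abdomen/neck margin
    cap_length: float = 30.0         # rounded-cap axial extent at each end
    superellipse_exponent: float = 2.5
    bow_amplitude: float = 20.0      # sagittal excursion of the kyphotic bow
    spine_span: float = 606.0        # x extent of the spine polynomial
    spine_depth: float = 50.0        # distance from back surface to the cord
    medial_spacing: float = 10.0     # arc spacing of medial sources
    ring_radius: float = 4.0
    cord_radius: float = 8.0
    bone_radius: float = 16.0
    grid_spacing: float = 30.0       # sensor grid pitch
    standoff: float = 10.0           # sensor distance from the torso surface
    density: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        lengths = (
            self.torso_width, self.torso_depth, self.torso_height,
            self.cap_length, self.bow_amplitude + 1.0, self.spine_span,
            self.spine_depth, self.medial_spacing, self.ring_radius,
            self.cord_radius, self.bone_radius, self.grid_spacing,
            self.standoff,
        )
        if any(not np.isfinite(v) or v <= 0 for v in lengths):
            raise ValueError("all geometry lengths must be positive and finite")
        if not (0.0 < self.density <= 2.0):
            raise ValueError("density factor must lie in (0, 2]")
        if self.spine_span >= self.torso_height:
            raise ValueError("spine span must fit within the torso height")

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeometryConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _scaled(count: int, density: float, minimum: int = 8) -> int:
    """Mesh-direction resolution under the density factor (monotone)."""
    return max(minimum, int(round(count * np.sqrt(density))))


# ---------------------------------------------------------------------------
# Spine centreline
# ---------------------------------------------------------------------------

_ARC_SAMPLES = 4097  # dense parameter samples for the arc-length table


@dataclass
class SpineCurve:
    """Degree-5 polynomial centreline c(t) = (x(t), y(t), z(t)), t in [0, 1].

    ``coefficients[d, k]`` multiplies t**k for coordinate d.  An arc-length
    table over a slightly extended parameter range supports even resampling
    and tube extrusion beyond the source span.
    """

    coefficients: np.ndarray            # (3, 6)
    t_table: np.ndarray = field(init=False, repr=False)
    arc_table: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=np.float64)
        if self.coefficients.shape != (3, 6):
            raise ValueError("coefficients must be (3, 6)")
        t = np.linspace(-0.12, 1.12, _ARC_SAMPLES)
        d = np.linalg.norm(self.tangent_raw(t), axis=1)
        if np.any(d <= 0):
            raise ValueError("curve tangent vanishes")
        # cumulative arc length with s = 0 at t = 0
        mid = 0.5 * (d[1:] + d[:-1]) * np.diff(t)
        arc = np.concatenate([[0.0], np.cumsum(mid)])
        arc -= np.interp(0.0, t, arc)
        self.t_table = t
        self.arc_table = arc

    # -- evaluation ----------------------------------------------------------

    def point(self, t: np.ndarray) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=np.float64))
        powers = t[:, None] ** np.arange(6)[None, :]
        return powers @ self.coefficients.T

    def tangent_raw(self, t: np.ndarray) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=np.float64))
        k = np.arange(1, 6)
        powers = k[None, :] * t[:, None] ** (k - 1)[None, :]
        return powers @ self.coefficients[:, 1:].T

    def tangent(self, t: np.ndarray) -> np.ndarray:
        d = self.tangent_raw(t)
        return d / np.linalg.norm(d, axis=1, keepdims=True)

    # -- arc length ----------------------------------------------------------

    @property
    def length(self) -> float:
        """Arc length of the nominal parameter range t in [0, 1]."""
        return float(np.interp(1.0, self.t_table, self.arc_table))

    def t_at_arc(self, s: np.ndarray) -> np.ndarray:
        return np.interp(np.atleast_1d(s), self.arc_table, self.t_table)

    def resample(self, spacing: float) -> tuple[np.ndarray, np.ndarray]:
        """Points and unit tangents at even arc spacing, starting at s = 0."""
        n = int(np.floor(self.length / spacing)) + 1
        s = np.arange(n) * spacing
        t = self.t_at_arc(s)
        return self.point(t), self.tangent(t)


def build_spine_curve(config: GeometryConfig) -> SpineCurve:
    """Kyphotic centreline at ``spine_depth`` from the back surface.

    The torso back at mid-sagittal plane lies at
    ``y_back(x) = y_c(x) - torso_depth / 2`` where ``y_c`` is the bowed
    cross-section centre (see :func:`build_torso_surface`); the spine is the
    same polynomial shifted anteriorly by ``spine_depth``, so its depth from
    the back along the inward normal (+Y) is constant by construction.
    """
    A = config.bow_amplitude
    half = config.spine_span / 2.0
    coeff = np.zeros((3, 6))
    coeff[0, 0] = -half
    coeff[0, 1] = config.spine_span
    # zero-mean single bow: y_c(t) = A*(8/15 - 16 t^2 (1-t)^2)
    coeff[1, 0] = A * (8.0 / 15.0) - config.torso_depth / 2.0 + config.spine_depth
    coeff[1, 2] = -16.0 * A
    coeff[1, 3] = 32.0 * A
    coeff[1, 4] = -16.0 * A
    return SpineCurve(coeff)


def _bow_centre(x: np.ndarray, config: GeometryConfig) -> np.ndarray:
    """Cross-section centre offset y_c(x), clamped beyond the spine span."""
    A = config.bow_amplitude
    half = config.spine_span / 2.0
    t = np.clip((np.asarray(x, dtype=np.float64) + half) / config.spine_span, 0.0, 1.0)
    return A * (8.0 / 15.0 - 16.0 * t**2 * (1.0 - t) ** 2)


# ---------------------------------------------------------------------------
# Torso surface
# ---------------------------------------------------------------------------

def build_torso_surface(config: GeometryConfig) -> TriMesh:
    """Closed superellipse-cylinder torso with rounded caps.

    Cross-sections are superellipses (exponent ~2.5: flat-ish back and front),
    whose centres follow the sagittal bow of the spine so the back-to-spine
    depth stays constant; near both ends the section shrinks to a pole over
    ``cap_length`` with a superelliptic cap profile.
    """
    a = config.torso_width / 2.0
    b = config.torso_depth / 2.0
    H = config.torso_height
    p = config.superellipse_exponent

    n_theta = _scaled(64, config.density, minimum=12)
    n_rings = _scaled(49, config.density, minimum=9)

    # rings clustered toward the caps
    sj = (np.arange(1, n_rings + 1)) / (n_rings + 1)
    x = -H / 2.0 + H * (0.5 - 0.5 * np.cos(np.pi * sj))

    straight = H / 2.0 - config.cap_length
    u = np.clip((np.abs(x) - straight) / config.cap_length, 0.0, 1.0)
    scale = (1.0 - u**p) ** (1.0 / p)

    theta = 2.0 * np.pi * np.arange(n_theta) / n_theta
    cz = np.sign(np.cos(theta)) * np.abs(np.cos(theta)) ** (2.0 / p)
    cy = np.sign(np.sin(theta)) * np.abs(np.sin(theta)) ** (2.0 / p)

    yc = _bow_centre(x, config)
    verts = np.empty((n_rings * n_theta + 2, 3))
    verts[0] = (-H / 2.0, _bow_centre(-H / 2.0, config)[()], 0.0)
    verts[-1] = (H / 2.0, _bow_centre(H / 2.0, config)[()], 0.0)
    ring = verts[1:-1].reshape(n_rings, n_theta, 3)
    ring[:, :, 0] = x[:, None]
    ring[:, :, 1] = yc[:, None] + (b * scale)[:, None] * cy[None, :]
    ring[:, :, 2] = (a * scale)[:, None] * cz[None, :]

    faces = _lathe_faces(n_rings, n_theta, bottom_pole=0,
                         top_pole=n_rings * n_theta + 1, ring_offset=1)
    faces = _ensure_outward(verts, faces)
    mesh = TriMesh(verts, faces, name="torso")
    mesh.validate()
    return mesh


def _lathe_faces(n_rings: int, n_theta: int, bottom_pole: int, top_pole: int,
                 ring_offset: int) -> np.ndarray:
    """Triangulation of a stack of rings closed by two pole fans."""
    idx = ring_offset + np.arange(n_rings * n_theta).reshape(n_rings, n_theta)
    nxt = np.roll(idx, -1, axis=1)
    faces = []
    faces.append(np.column_stack([
        np.full(n_theta, bottom_pole), nxt[0], idx[0]]))
    quad_a = np.column_stack([idx[:-1].ravel(), nxt[:-1].ravel(), idx[1:].ravel()])
    quad_b = np.column_stack([nxt[:-1].ravel(), nxt[1:].ravel(), idx[1:].ravel()])
    faces.extend([quad_a, quad_b])
    faces.append(np.column_stack([
        np.full(n_theta, top_pole), idx[-1], nxt[-1]]))
    return np.vstack(faces)


# ---------------------------------------------------------------------------
# Frames and source space
# ---------------------------------------------------------------------------

def parallel_transport_frames(tangents: np.ndarray,
                              initial_lr: np.ndarray | None = None
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Rotation-minimising (e_LR, e_AP) pair along a sequence of unit tangents.

    The first left-right axis is global +Z projected perpendicular to the
    first tangent; each subsequent frame is the previous one rotated by the
    minimal rotation mapping tangent i-1 onto tangent i, so frames never flip.
    """
    tangents = np.asarray(tangents, dtype=np.float64)
    n = len(tangents)
    if initial_lr is None:
        initial_lr = np.array([0.0, 0.0, 1.0])
    lr = np.empty((n, 3))
    e = initial_lr - np.dot(initial_lr, tangents[0]) * tangents[0]
    nrm = np.linalg.norm(e)
    if nrm < 1e-12:
        raise ValueError("initial left-right axis parallel to the tangent")
    lr[0] = e / nrm
    for i in range(1, n):
        t0, t1 = tangents[i - 1], tangents[i]
        axis = np.cross(t0, t1)
        s = np.linalg.norm(axis)
        c = float(np.dot(t0, t1))
        if s < 1e-14:
            lr[i] = lr[i - 1]
            continue
        axis = axis / s
        v = lr[i - 1]
        # Rodrigues rotation by the angle between consecutive tangents
        lr[i] = (v * c + np.cross(axis, v) * s
                 + axis * np.dot(axis, v) * (1.0 - c))
        lr[i] -= np.dot(lr[i], t1) * t1
        lr[i] /= np.linalg.norm(lr[i])
    ap = np.cross(lr, tangents)   # e_AP = e_LR x e_IS points anteriorly
    return lr, ap


#: ring position index of the source displaced +4 mm along e_LR (subject left)
LEFT_RING = 1
#: ring position index of the source displaced -4 mm along e_LR (subject right)
RIGHT_RING = 5


@dataclass
class SourceSpace:
    """Medial + ring dipole locations with local spine frames.

    Sources are ordered slice-major: source ``9 * s + r`` is ring position
    ``r`` (0 = medial) of slice ``s`` (0 = most inferior).  ``frames[i]`` rows
    are (e_IS, e_LR, e_AP) of the slice that source ``i`` belongs to.
    """

    positions: np.ndarray     # (n, 3) mm
    slice_index: np.ndarray   # (n,)
    ring_position: np.ndarray  # (n,) 0..8
    frames: np.ndarray        # (n, 3, 3), rows e_IS, e_LR, e_AP

    @property
    def n_sources(self) -> int:
        return len(self.positions)

    @property
    def n_slices(self) -> int:
        return int(self.slice_index.max()) + 1

    def medial_mask(self) -> np.ndarray:
        return self.ring_position == 0

    def index_of(self, slice_index: int, ring_position: int = 0) -> int:
        hit = np.flatnonzero((self.slice_index == slice_index)
                             & (self.ring_position == ring_position))
        if len(hit) != 1:
            raise KeyError(f"no source at slice {slice_index}, ring {ring_position}")
        return int(hit[0])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "x_mm": self.positions[:, 0],
            "y_mm": self.positions[:, 1],
            "z_mm": self.positions[:, 2],
            "slice_index": self.slice_index,
            "ring_position": self.ring_position,
        })
        for j, label in enumerate(("eIS", "eLR", "eAP")):
            for k, ax in enumerate("xyz"):
                df[f"{label}_{ax}"] = self.frames[:, j, k]
        return df


def build_source_space(curve: SpineCurve, config: GeometryConfig) -> SourceSpace:
    """61 medial sources at 10 mm arc spacing, each with an 8-point ring.

    Ring sources sit at 4 mm radius in the plane normal to the local tangent,
    at 45 degree steps starting from +e_LR; the ring plane follows the spine
    curvature through the parallel-transported frames.
    """
    if config.ring_radius >= config.cord_radius:
        raise ValueError("ring radius must be smaller than the cord radius")
    medial, tangents = curve.resample(config.medial_spacing)
    lr, ap = parallel_transport_frames(tangents)
    n = len(medial)

    angles = np.deg2rad(45.0 * np.arange(8))
    offsets = (np.cos(angles)[:, None, None] * lr[None]
               + np.sin(angles)[:, None, None] * ap[None])  # (8, n, 3)

    positions = np.empty((n * 9, 3))
    slice_index = np.repeat(np.arange(n), 9)
    ring_position = np.tile(np.arange(9), n)
    frames = np.empty((n * 9, 3, 3))
    for s in range(n):
        positions[9 * s] = medial[s]
        positions[9 * s + 1: 9 * s + 9] = (
            medial[s] + config.ring_radius * offsets[:, s, :])
        frames[9 * s: 9 * s + 9] = np.stack([tangents[s], lr[s], ap[s]])
    return SourceSpace(positions, slice_index, ring_position, frames)


# ---------------------------------------------------------------------------
# Tube meshes (cord / bone)
# ---------------------------------------------------------------------------

# reference (n_axial, n_circ) chosen to land near the study's mesh table
_TUBE_RESOLUTION = {"cord": (246, 21), "bone": (188, 22)}


def build_tube_mesh(curve: SpineCurve, radius: float, config: GeometryConfig,
                    name: str | None = None) -> TriMesh:
    """Capped tube of constant ``radius`` swept along the centreline.

    The tube extends 1.2 radii beyond both ends of the source span so every
    source is strictly interior, and is capped with flat fans.  Raises if the
    centreline curvature is too tight for the radius (self-intersection).
    """
    if radius <= 0:
        raise ValueError("tube radius must be positive")
    kind = "bone" if radius > 1.5 * config.cord_radius else "cord"
    if name is None:
        name = kind
    na0, nc0 = _TUBE_RESOLUTION[kind]
    n_axial = _scaled(na0, config.density, minimum=12)
    n_circ = _scaled(nc0, config.density, minimum=8)

    ext = 1.2 * radius
    s = np.linspace(-ext, curve.length + ext, n_axial)
    t = curve.t_at_arc(s)
    pts = curve.point(t)
    tan = curve.tangent(t)

    # curvature check from tangent finite differences
    dtan = np.linalg.norm(np.diff(tan, axis=0), axis=1)
    ds = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    kappa = dtan / np.maximum(ds, 1e-12)
    if np.any(kappa * radius >= 1.0):
        raise ValueError("tube self-intersects: curvature radius below tube radius")

    lr, ap = parallel_transport_frames(tan)
    theta = 2.0 * np.pi * (np.arange(n_circ) + 0.5) / n_circ
    ring = (np.cos(theta)[None, :, None] * lr[:, None, :]
            + np.sin(theta)[None, :, None] * ap[:, None, :])
    verts = np.empty((n_axial * n_circ + 2, 3))
    verts[0] = pts[0]
    verts[-1] = pts[-1]
    verts[1:-1] = (pts[:, None, :] + radius * ring).reshape(-1, 3)

    faces = _lathe_faces(n_axial, n_circ, bottom_pole=0,
                         top_pole=n_axial * n_circ + 1, ring_offset=1)
    faces = _ensure_outward(verts, faces)
    mesh = TriMesh(verts, faces, name=name)
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# Organ surrogates
# ---------------------------------------------------------------------------

def _uv_ellipsoid(center: np.ndarray, semi: np.ndarray, n_lat: int,
                  n_lon: int) -> tuple[np.ndarray, np.ndarray]:
    phi = np.pi * (np.arange(1, n_lat + 1)) / (n_lat + 1)
    lam = 2.0 * np.pi * np.arange(n_lon) / n_lon
    verts = np.empty((n_lat * n_lon + 2, 3))
    verts[0] = center + semi * np.array([0.0, 0.0, -1.0])
    verts[-1] = center + semi * np.array([0.0, 0.0, 1.0])
    ring = verts[1:-1].reshape(n_lat, n_lon, 3)
    # poles on the z axis of the ellipsoid frame; lat rings in x-y
    ring[:, :, 0] = center[0] + semi[0] * np.sin(phi)[:, None] * np.cos(lam)[None, :]
    ring[:, :, 1] = center[1] + semi[1] * np.sin(phi)[:, None] * np.sin(lam)[None, :]
    ring[:, :, 2] = center[2] + semi[2] * (-np.cos(phi))[:, None]
    faces = _lathe_faces(n_lat, n_lon, bottom_pole=0,
                         top_pole=n_lat * n_lon + 1, ring_offset=1)
    return verts, _ensure_outward(verts, faces)


# organ placement in the default frame; scaled with the torso dimensions
_HEART_CENTER = np.array([80.0, 10.0, 30.0])
_HEART_SEMI = np.array([55.0, 50.0, 35.0])
_LUNG_CENTER = np.array([60.0, -10.0, 108.0])   # mirrored in z for the right lung
_LUNG_SEMI = np.array([130.0, 60.0, 38.0])


def build_organ_meshes(config: GeometryConfig) -> tuple[TriMesh, TriMesh]:
    """Heart (single ellipsoid, left-anterior of the spine) and lungs (two
    lateral ellipsoids), both strictly inside the torso and clear of the
    vertebral tube.  Raises if either organ touches the bone tube."""
    sc = np.array([config.torso_height / 700.0,
                   config.torso_depth / 240.0,
                   config.torso_width / 320.0])

    hv, hf = _uv_ellipsoid(_HEART_CENTER * sc, _HEART_SEMI * sc,
                           _scaled(30, config.density, 6),
                           _scaled(35, config.density, 8))
    heart = TriMesh(hv, hf, name="heart")

    n_lat = _scaled(19, config.density, 5)
    n_lon = _scaled(24, config.density, 8)
    lv, lf = _uv_ellipsoid(_LUNG_CENTER * sc, _LUNG_SEMI * sc, n_lat, n_lon)
    rv = lv * np.array([1.0, 1.0, -1.0])
    rf = lf[:, ::-1]  # mirroring flips orientation; restore outward winding
    lungs = TriMesh(np.vstack([lv, rv]),
                    np.vstack([lf, rf + len(lv)]), name="lungs")

    heart.validate()
    lungs.validate()

    bone = build_tube_mesh(build_spine_curve(config), config.bone_radius,
                           replace(config, density=min(config.density, 0.5)))
    for organ in (heart, lungs):
        if organ.contains(bone.vertices).any() or bone.contains(organ.vertices).any():
            raise ValueError(f"{organ.name} surrogate intersects the bone tube")
    return heart, lungs


# ---------------------------------------------------------------------------
# Sensor array
# ---------------------------------------------------------------------------

AXES = ("X", "Y", "Z")


@dataclass
class SensorArray:
    """Triaxial point-magnetometer sites over the back.

    ``triads[i]`` rows are the unit orientations of the three channels of
    site ``i``: X along inferior-superior, Y along the outward back normal
    (the primary, sagittal axis), Z completing the right-handed frame
    (left-right).  Channels are ordered site-major, axes X, Y, Z.
    """

    positions: np.ndarray   # (s, 3) mm
    triads: np.ndarray      # (s, 3, 3)

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def n_channels(self) -> int:
        return 3 * self.n_sites

    def channel_positions(self) -> np.ndarray:
        return np.repeat(self.positions, 3, axis=0)

    def channel_orientations(self) -> np.ndarray:
        return self.triads.reshape(-1, 3)

    def channel_table(self) -> pd.DataFrame:
        s = self.n_sites
        pos = self.channel_positions()
        ori = self.channel_orientations()
        return pd.DataFrame({
            "site": np.repeat(np.arange(s), 3),
            "axis": np.tile(AXES, s),
            "x_mm": pos[:, 0], "y_mm": pos[:, 1], "z_mm": pos[:, 2],
            "ox": ori[:, 0], "oy": ori[:, 1], "oz": ori[:, 2],
        })


def build_sensor_array(torso: TriMesh, config: GeometryConfig) -> SensorArray:
    """Ray-cast a 30 mm grid onto the back, offset by the standoff.

    Rays run orthographically along +Y from a plane 200 mm behind the back;
    only rays that hit the torso produce sites.  Each site is the first hit
    offset ``standoff`` mm along the outward face normal.
    """
    from . import spatial

    lo = torso.vertices.min(axis=0)
    hi = torso.vertices.max(axis=0)
    step = config.grid_spacing

    def _axis(vmin: float, vmax: float) -> np.ndarray:
        k = np.arange(np.floor(vmin / step), np.ceil(vmax / step) + 1)
        return k * step

    gx = _axis(lo[0], hi[0])
    gz = _axis(lo[2], hi[2])
    X, Z = np.meshgrid(gx, gz, indexing="ij")
    origins = np.column_stack([
        X.ravel(), np.full(X.size, lo[1] - 200.0), Z.ravel()])

    hit_ray, hit_pts, hit_tri = spatial.raycast_first_hit(
        origins, np.array([0.0, 1.0, 0.0]), torso.vertices, torso.faces)
    if len(hit_ray) == 0:
        raise ValueError("sensor grid does not intersect the torso")
    normals = torso.face_normals[hit_tri]

    sites = hit_pts + config.standoff * normals
    y_axis = normals
    x_axis = np.tile([1.0, 0.0, 0.0], (len(sites), 1))
    x_axis = x_axis - np.sum(x_axis * y_axis, axis=1, keepdims=True) * y_axis
    x_axis /= np.linalg.norm(x_axis, axis=1, keepdims=True)
    z_axis = np.cross(x_axis, y_axis)
    triads = np.stack([x_axis, y_axis, z_axis], axis=1)
    return SensorArray(sites, triads)


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------

@dataclass
class GeometryBundle:
    """Everything the forward models consume, built from one config."""

    config: GeometryConfig
    torso: TriMesh
    heart: TriMesh
    lungs: TriMesh
    cord: TriMesh
    bone: TriMesh
    curve: SpineCurve
    sources: SourceSpace
    sensors: SensorArray

    @property
    def meshes(self) -> dict[str, TriMesh]:
        return {"torso": self.torso, "heart": self.heart, "lungs": self.lungs,
                "cord": self.cord, "bone": self.bone}


def build_geometry(config: GeometryConfig | None = None) -> GeometryBundle:
    """Build the complete study geometry deterministically."""
    config = config or GeometryConfig()
    torso = build_torso_surface(config)
    curve = build_spine_curve(config)
    sources = build_source_space(curve, config)
    cord = build_tube_mesh(curve, config.cord_radius, config, name="cord")
    bone = build_tube_mesh(curve, config.bone_radius, config, name="bone")
    heart, lungs = build_organ_meshes(config)
    sensors = build_sensor_array(torso, config)
    return GeometryBundle(config, torso, heart, lungs, cord, bone, curve,
                          sources, sensors)


def save_geometry(bundle: GeometryBundle, out_dir: str | Path) -> Path:
    """Write meshes (STL), source/sensor tables (TSV) and the config (YAML)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.config.to_yaml(out / "geometry.yaml")
    for name, mesh in bundle.meshes.items():
        mesh.save(out / f"{name}.stl")
    bundle.sources.to_frame().to_csv(out / "sources.tsv", sep="\t", index=False)
    bundle.sensors.channel_table().to_csv(out / "sensors.tsv", sep="\t", index=False)
    return out


def load_geometry(out_dir: str | Path) -> GeometryBundle:
    """Rebuild a bundle from a saved config (meshes are regenerated, which is
    exact because generation is deterministic)."""
    cfg = GeometryConfig.from_yaml(Path(out_dir) / "geometry.yaml")
    return build_geometry(cfg)
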