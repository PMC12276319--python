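"""Closed triangle surfaces used as conductor boundaries.

All geometry in this package is expressed in millimetres; conversion to SI
metres happens only inside the field computations.  A :class:`TriMesh` is a
thin, validated wrapper around a vertex/face array pair; heavy mesh machinery
(watertightness, winding, ray casting, signed distances, STL/PLY IO) is
delegated to :mod:`trimesh`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh


class MeshInvariantError(ValueError):
    """A surface violates the closed/oriented/non-degenerate contract."""


@dataclass
class TriMesh:
    """Closed, outward-oriented triangle surface in millimetres.

    May contain several connected components (the lung surrogate is a pair of
    closed surfaces); every component must individually be closed and manifold
    with Euler characteristic 2.
    """

    vertices: np.ndarray  # (n, 3) float64, mm
    faces: np.ndarray     # (m, 3) int
    name: str = ""
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshInvariantError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshInvariantError("faces must be (m, 3)")

    # -- trimesh bridge ----------------------------------------------------

    def as_trimesh(self) -> trimesh.Trimesh:
        """Return a cached :class:`trimesh.Trimesh` view (no reprocessing)."""
        tm = self._cache.get("tm")
        if tm is None:
            tm = trimesh.Trimesh(self.vertices, self.faces, process=False)
            self._cache["tm"] = tm
        return tm

    # -- derived quantities -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def face_normals(self) -> np.ndarray:
        return np.asarray(self.as_trimesh().face_normals)

    @property
    def face_areas(self) -> np.ndarray:
        return np.asarray(self.as_trimesh().area_faces)

    @property
    def volume(self) -> float:
        return float(self.as_trimesh().volume)

    def centroid(self) -> np.ndarray:
        return np.asarray(self.as_trimesh().center_mass)

    def vertex_normals(self) -> np.ndarray:
        return np.asarray(self.as_trimesh().vertex_normals)

    # -- queries -------------------------------------------------------------

    def contains(self, points: np.ndarray) -> np.ndarray:
        from . import spatial
        return spatial.contains(np.atleast_2d(points), self.vertices, self.faces)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed distance in mm, *negative inside* the surface."""
        from . import spatial
        return spatial.signed_distance(np.atleast_2d(points),
                                       self.vertices, self.faces)

    # -- validation ----------------------------------------------------------

    def validate(self, min_area: float = 1e-9) -> None:
        """Raise :class:`MeshInvariantError` on any broken invariant.

        Checks: every edge shared by exactly two faces, Euler characteristic 2
        per connected component, outward winding (positive signed volume per
        component) and no degenerate faces.
        """
        tm = self.as_trimesh()
        if not tm.is_watertight:
            raise MeshInvariantError(f"{self.name or 'mesh'}: not watertight")
        if np.any(self.face_areas <= min_area):
            raise MeshInvariantError(f"{self.name or 'mesh'}: degenerate faces")
        for comp in tm.split(only_watertight=False):
            if comp.euler_number != 2:
                raise MeshInvariantError(
                    f"{self.name or 'mesh'}: component Euler characteristic "
                    f"{comp.euler_number} != 2"
                )
            if comp.volume <= 0:
                raise MeshInvariantError(
                    f"{self.name or 'mesh'}: component signed volume <= 0 "
                    "(normals not outward)"
                )

    # -- IO -------------------------------------------------------------------

    def save(self, path: str | Path) -> Path:
        """Write STL or PLY (binary, little-endian); format from the suffix."""
        path = Path(path)
        self.as_trimesh().export(path)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "TriMesh":
        path = Path(path)
        tm = trimesh.load_mesh(path, process=False)
        return cls(np.asarray(tm.vertices), np.asarray(tm.faces), name=path.stem)


def _ensure_outward(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Flip the winding of all faces if the signed volume is negative."""
    tm = trimesh.Trimesh(vertices, faces, process=False)
    if tm.volume < 0:
        return faces[:, ::-1]
    return faces
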