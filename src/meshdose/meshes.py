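"""Triangular surface meshes in patient coordinates (mm).

``SurfaceMesh`` is the shared geometry container used by the refinement,
ray-casting, planning and collision modules.  It is a thin immutable wrapper
around vertex/face arrays; heavy mesh machinery (volume, topology, file
formats) is delegated to :mod:`trimesh`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh


@dataclass(frozen=True)
class SurfaceMesh:
    """A triangle mesh of one organ, vertices in mm.

    Degenerate (zero-area) faces are dropped at construction so downstream
    normal computations are well defined.
    """

    vertices: np.ndarray  # (V, 3) float64, mm
    faces: np.ndarray  # (F, 3) int, indices into vertices

    def __post_init__(self) -> None:
        v = np.ascontiguousarray(np.asarray(self.vertices, dtype=np.float64))
        f = np.ascontiguousarray(np.asarray(self.faces, dtype=np.int64))
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("vertices must be (V, 3)")
        if f.ndim != 2 or f.shape[1] != 3:
            raise ValueError("faces must be (F, 3)")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise ValueError("face index out of range")
        # drop zero-area faces
        if f.size:
            e1 = v[f[:, 1]] - v[f[:, 0]]
            e2 = v[f[:, 2]] - v[f[:, 0]]
            area2 = np.linalg.norm(np.cross(e1, e2), axis=1)
            keep = area2 > 0.0
            f = f[keep]
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def face_normals(self) -> np.ndarray:
        """Unit per-face normals n̂ (right-hand rule on vertex winding)."""
        v, f = self.vertices, self.faces
        n = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        return n / norm

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices.copy(), faces=self.faces.copy(), process=False
        )

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh) -> "SurfaceMesh":
        return cls(np.asarray(tm.vertices, dtype=np.float64), np.asarray(tm.faces))

    @property
    def volume(self) -> float:
        """Enclosed volume in mm^3 (signed divergence theorem, made positive)."""
        return float(abs(self.as_trimesh().volume))

    @property
    def area(self) -> float:
        return float(self.as_trimesh().area)

    def is_closed(self) -> bool:
        return bool(self.as_trimesh().is_watertight)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "SurfaceMesh":
        """Rigidly transformed copy: v -> R v + t."""
        r = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return SurfaceMesh(self.vertices @ r.T + t, self.faces)
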