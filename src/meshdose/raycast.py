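"""Ray casting through organ surface meshes.

A radiation beam axis is modeled as a single ray.  Intersections with the
triangulated organ surfaces give entry/exit points, from which the geometric
path length z through each organ and its water-equivalent length
z_eff = z * eta are derived.  The same-side point-in-triangle test and the
ray-plane solve are implemented directly (they are the primitive this engine
is built on); a brute-force all-faces sweep is the reference path, with an
optional axis-aligned box-tree acceleration that must produce identical hits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .meshes import SurfaceMesh

EPS = 1e-9  # mm; parallel-ray / behind-origin rejection
EPS_MERGE = 1e-6  # mm; duplicate hits at shared edges/vertices merge below this


class OpenMeshError(ValueError):
    """A closed organ mesh produced an odd crossing count along a ray."""


@dataclass(frozen=True)
class Ray:
    """Parametric ray P(t) = origin + t * direction, lengths in mm."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        o = np.asarray(self.origin, dtype=np.float64).reshape(3)
        d = np.asarray(self.direction, dtype=np.float64).reshape(3)
        n = np.linalg.norm(d)
        if abs(n - 1.0) > 1e-9:
            if n == 0:
                raise ValueError("ray direction must be nonzero")
            d = d / n
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "direction", d)

    def at(self, t: float) -> np.ndarray:
        return self.origin + t * self.direction


@dataclass(frozen=True)
class Hit:
    """One ray-surface crossing at parameter t (> 0)."""

    t: float
    point: np.ndarray
    face: int  # -1 for synthetic boundary hits created during overlap resolution
    entering: bool  # sign of d . n̂ with outward normals


@dataclass(frozen=True)
class PathSegment:
    """One traversal interval of the beam through a single organ."""

    label: int
    entry: Hit
    exit: Hit
    eta: float

    @property
    def length(self) -> float:
        """Geometric length z in mm."""
        return self.exit.t - self.entry.t

    @property
    def effective_length(self) -> float:
        """Water-equivalent length z_eff = z * eta in mm."""
        return self.length * self.eta


def ray_plane_t(ray: Ray, plane_point, normal) -> float | None:
    """Distance t to the plane through ``plane_point`` with unit normal.

    Returns None for rays parallel to the plane or intersections at/behind
    the origin (t <= EPS).
    """
    n = np.asarray(normal, dtype=float)
    denom = float(n @ ray.direction)
    if abs(denom) < EPS:
        return None
    t = float((n @ np.asarray(plane_point, dtype=float) - n @ ray.origin) / denom)
    if t <= EPS:
        return None
    return t


def point_in_triangle(p, p1, p2, p3) -> bool:
    """Same-side test: P is inside iff for every vertex i the cross products
    (P - Pi) x (P_{i-1} - Pi) and (P - Pi) x (P_{i+1} - Pi) point oppositely
    (their dot product is <= 0, cyclic indices).  Edge and vertex contact
    count as inside.  P must be (near-)coplanar with the triangle.
    """
    p = np.asarray(p, dtype=float)
    verts = [np.asarray(v, dtype=float) for v in (p1, p2, p3)]
    area2 = np.linalg.norm(np.cross(verts[1] - verts[0], verts[2] - verts[0]))
    if area2 < 1e-14:
        raise ValueError("degenerate (collinear) triangle")
    # tolerance scaled to triangle size: the cross-product dot scales as length^4
    tol = 1e-12 * area2 ** 2
    for i in range(3):
        vi = verts[i]
        prev_v = verts[(i - 1) % 3]
        next_v = verts[(i + 1) % 3]
        c1 = np.cross(p - vi, prev_v - vi)
        c2 = np.cross(p - vi, next_v - vi)
        if float(c1 @ c2) > tol:
            return False
    return True


def _mesh_hits_raw(ray: Ray, mesh: SurfaceMesh, face_index=None):
    """Vectorized all-faces ray-triangle sweep; returns (t, face, entering)."""
    v, f = mesh.vertices, mesh.faces
    if face_index is not None:
        f = f[face_index]
    else:
        face_index = np.arange(len(f))
    if len(f) == 0:
        return np.empty(0), np.empty(0, dtype=int), np.empty(0, dtype=bool)
    a, b, c = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    n = np.cross(b - a, c - a)
    nn = np.linalg.norm(n, axis=1)
    valid = nn > 0
    n_unit = np.zeros_like(n)
    n_unit[valid] = n[valid] / nn[valid, None]
    denom = n_unit @ ray.direction
    valid &= np.abs(denom) >= EPS
    t = np.full(len(f), np.nan)
    num = np.einsum("ij,ij->i", n_unit, a - ray.origin)
    t[valid] = num[valid] / denom[valid]
    valid &= t > EPS
    if not valid.any():
        return np.empty(0), np.empty(0, dtype=int), np.empty(0, dtype=bool)
    pts = ray.origin + t[:, None] * ray.direction
    # same-side containment test (vectorized form of point_in_triangle)
    inside = valid.copy()
    verts = (a, b, c)
    tol = 1e-12 * (nn ** 2)
    for i in range(3):
        vi = verts[i]
        prev_v = verts[(i - 1) % 3]
        next_v = verts[(i + 1) % 3]
        c1 = np.cross(pts - vi, prev_v - vi)
        c2 = np.cross(pts - vi, next_v - vi)
        inside &= np.einsum("ij,ij->i", c1, c2) <= tol
    t_hit = t[inside]
    order = np.argsort(t_hit, kind="stable")
    return t_hit[order], face_index[inside][order], (denom[inside][order] < 0)


def ray_mesh_intersections(
    ray: Ray, mesh: SurfaceMesh, candidate_faces=None
) -> list[Hit]:
    """All crossings of ``ray`` with ``mesh``, ascending in t.

    Hits closer than EPS_MERGE apart (shared edges/vertices crossed once)
    are merged to a single hit.
    """
    t, faces, entering = _mesh_hits_raw(ray, mesh, candidate_faces)
    hits: list[Hit] = []
    for ti, fi, ei in zip(t, faces, entering):
        if hits and ti - hits[-1].t < EPS_MERGE:
            continue
        hits.append(Hit(float(ti), ray.at(float(ti)), int(fi), bool(ei)))
    return hits


def trace_beam(
    ray: Ray,
    organs: list[tuple[int, SurfaceMesh, float]],
    priority: list[int] | None = None,
) -> list[PathSegment]:
    """Partition the beam path among possibly nested organ meshes.

    ``organs`` is a list of (label, mesh, eta).  Each organ's sorted hits are
    paired (entry, exit) by parity — for marching-cubes meshes local normal
    flips make the sign classification unreliable, so parity is authoritative
    and the entering/exiting flags are repaired to alternate.  Where organs
    overlap spatially (a tumor inside a lung), each infinitesimal interval is
    assigned the highest-priority label; by default smaller-volume organs win,
    or pass an explicit ``priority`` label order (first = highest).
    """
    intervals: dict[int, list[tuple[float, float]]] = {}
    etas = {label: eta for label, _, eta in organs}
    for label, mesh, _ in organs:
        hits = ray_mesh_intersections(ray, mesh)
        if len(hits) % 2 != 0:
            raise OpenMeshError(
                f"organ {label}: odd crossing count ({len(hits)}) — mesh open "
                "or ray grazing"
            )
        ivals = [(hits[i].t, hits[i + 1].t) for i in range(0, len(hits), 2)]
        if ivals:
            intervals[label] = ivals

    if not intervals:
        return []

    if priority is None:
        by_volume = sorted(
            (mesh.volume, label) for label, mesh, _ in organs if label in intervals
        )
        rank = {label: i for i, (_, label) in enumerate(by_volume)}
    else:
        rank = {label: i for i, label in enumerate(priority)}

    cuts = np.unique(
        np.concatenate([[a, b] for iv in intervals.values() for (a, b) in iv])
    )
    pieces: list[tuple[float, float, int]] = []
    for a, b in zip(cuts[:-1], cuts[1:]):
        if b - a < EPS_MERGE:
            continue
        mid = 0.5 * (a + b)
        covering = [
            label
            for label, iv in intervals.items()
            if any(lo <= mid <= hi for lo, hi in iv)
        ]
        if not covering:
            continue
        winner = min(covering, key=lambda l: rank.get(l, len(rank)))
        pieces.append((float(a), float(b), winner))

    # merge consecutive pieces with the same label
    segments: list[PathSegment] = []
    for a, b, label in pieces:
        if segments and segments[-1].label == label and abs(segments[-1].exit.t - a) < EPS_MERGE:
            prev = segments[-1]
            segments[-1] = PathSegment(
                label, prev.entry, Hit(b, ray.at(b), -1, False), etas[label]
            )
        else:
            segments.append(
                PathSegment(
                    label,
                    Hit(a, ray.at(a), -1, True),
                    Hit(b, ray.at(b), -1, False),
                    etas[label],
                )
            )
    return segments


def segments_to_rows(segments: list[PathSegment]) -> list[dict]:
    """Flatten segments for CSV export."""
    return [
        {
            "organ": s.label,
            "t_entry_mm": s.entry.t,
            "t_exit_mm": s.exit.t,
            "z_mm": s.length,
            "zeff_mm": s.effective_length,
        }
        for s in segments
    ]
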