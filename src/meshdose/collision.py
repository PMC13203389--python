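"""AABB-based collision detection for the treatment machine and patient.

Collision bodies are axis-aligned bounding boxes recomputed in the world
frame at every pose (a deliberately conservative scheme: a rotated part gets
an enlarged box, so near-misses inside the safety margin are flagged).  The
separating-axis theorem specialises, for AABBs, to interval overlap on the
three coordinate axes.  A bounding-volume hierarchy with median splits culls
candidate pairs; its output is required to be identical to all-pairs testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_MARGIN_MM = 50.0  # 5 cm clinical safety margin


@dataclass(frozen=True)
class AABB:
    """Axis-aligned box [min, max] in mm, componentwise min <= max."""

    min: np.ndarray
    max: np.ndarray

    def __post_init__(self) -> None:
        lo = np.asarray(self.min, dtype=float).reshape(3)
        hi = np.asarray(self.max, dtype=float).reshape(3)
        if np.any(lo > hi):
            raise ValueError("AABB min must be <= max componentwise")
        object.__setattr__(self, "min", lo)
        object.__setattr__(self, "max", hi)

    def inflated(self, margin: float) -> "AABB":
        return AABB(self.min - margin, self.max + margin)

    def union(self, other: "AABB") -> "AABB":
        return AABB(np.minimum(self.min, other.min), np.maximum(self.max, other.max))

    @property
    def center(self) -> np.ndarray:
        return 0.5 * (self.min + self.max)


@dataclass(frozen=True)
class Pose:
    """Rigid transform: x_world = R x_local + t."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-9) or np.linalg.det(r) < 0:
            raise ValueError("rotation must be orthonormal with det +1")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def compose(self, inner: "Pose") -> "Pose":
        """self ∘ inner (inner applied first)."""
        return Pose(self.rotation @ inner.rotation,
                    self.rotation @ inner.translation + self.translation)


@dataclass
class MachineComponent:
    """A rigid machine/patient part: local point geometry plus a kinematic parent."""

    name: str
    points: np.ndarray  # (N, 3) local mm
    parent: str | None = None  # kinematic parent name, or None for world

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.points) == 0:
            raise ValueError("component geometry must contain points")


def aabb_of(points, pose: Pose | None = None, margin: float = 0.0) -> AABB:
    """World-frame AABB of (optionally posed) points, inflated by ``margin``."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) == 0:
        raise ValueError("cannot bound an empty point set")
    if pose is not None:
        pts = pose.apply(pts)
    return AABB(pts.min(axis=0) - margin, pts.max(axis=0) + margin)


def sat_overlap(a: AABB, b: AABB) -> bool:
    """Separating-axis test for AABBs: overlap iff the projection intervals
    intersect on all three axes.  Touching faces count as overlap
    (safety-conservative tie-break)."""
    return bool(np.all(a.min <= b.max) and np.all(b.min <= a.max))


# ------------------------------------------------------------------ BVH

@dataclass
class BVHNode:
    box: AABB
    left: "BVHNode | None" = None
    right: "BVHNode | None" = None
    indices: np.ndarray | None = None  # leaf payload

    @property
    def is_leaf(self) -> bool:
        return self.indices is not None


def build_bvh(boxes: list[AABB], leaf_size: int = 2) -> BVHNode:
    """Binary tree over boxes; median split on the longest centroid-extent axis."""
    if not boxes:
        raise ValueError("need at least one box")
    idx = np.arange(len(boxes))
    return _build(boxes, idx, leaf_size)


def _build(boxes, idx, leaf_size) -> BVHNode:
    box = boxes[idx[0]]
    for i in idx[1:]:
        box = box.union(boxes[i])
    if len(idx) <= leaf_size:
        return BVHNode(box, indices=np.asarray(idx))
    centers = np.array([boxes[i].center for i in idx])
    axis = int(np.argmax(centers.max(axis=0) - centers.min(axis=0)))
    order = np.argsort(centers[:, axis], kind="stable")
    half = len(idx) // 2
    return BVHNode(
        box,
        left=_build(boxes, idx[order[:half]], leaf_size),
        right=_build(boxes, idx[order[half:]], leaf_size),
    )


def query_pairs(bvh_a: BVHNode, bvh_b: BVHNode, boxes_a, boxes_b) -> list[tuple[int, int]]:
    """Exact overlapping index pairs between two box sets (BVH-culled).

    The result equals brute-force all-pairs SAT testing.
    """
    out: list[tuple[int, int]] = []
    stack = [(bvh_a, bvh_b)]
    while stack:
        na, nb = stack.pop()
        if not sat_overlap(na.box, nb.box):
            continue
        if na.is_leaf and nb.is_leaf:
            for i in na.indices:
                for j in nb.indices:
                    if sat_overlap(boxes_a[i], boxes_b[j]):
                        out.append((int(i), int(j)))
        elif na.is_leaf:
            stack += [(na, nb.left), (na, nb.right)]
        elif nb.is_leaf:
            stack += [(na.left, nb), (na.right, nb)]
        else:
            stack += [(na.left, nb.left), (na.left, nb.right),
                      (na.right, nb.left), (na.right, nb.right)]
    return sorted(set(out))


def query_ray(bvh: BVHNode, origin, direction) -> np.ndarray:
    """Indices of boxes whose slab intervals intersect the ray (t >= 0)."""
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    with np.errstate(divide="ignore"):
        inv = 1.0 / direction
    out: list[int] = []
    stack = [bvh]
    while stack:
        node = stack.pop()
        if not _ray_box(origin, inv, node.box):
            continue
        if node.is_leaf:
            out.extend(int(i) for i in node.indices)
        else:
            stack += [node.left, node.right]
    return np.asarray(sorted(out), dtype=int)


def _ray_box(origin, inv_dir, box: AABB) -> bool:
    t1 = (box.min - origin) * inv_dir
    t2 = (box.max - origin) * inv_dir
    tmin = np.max(np.minimum(t1, t2))
    tmax = np.min(np.maximum(t1, t2))
    return tmax >= max(tmin, 0.0)


# --------------------------------------------------- machine kinematics

def rotation_about_z(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def machine_poses(
    gantry_angle_deg: float,
    couch_translation=(0.0, 0.0, 0.0),
    couch_yaw_deg: float = 0.0,
    isocenter=(0.0, 0.0, 0.0),
) -> dict[str, Pose]:
    """Forward kinematics of a schematic linac.

    The gantry (arm + head) rotates about the machine axis — the z axis
    through the isocenter, matching the beam-geometry convention.  The couch
    (with the patient on it) translates and yaws about the vertical (y) axis
    through the isocenter.
    """
    iso = np.asarray(isocenter, dtype=float)
    rg = rotation_about_z(gantry_angle_deg)
    gantry = Pose(rg, iso - rg @ iso)
    a = np.deg2rad(couch_yaw_deg)
    c, s = np.cos(a), np.sin(a)
    ry = np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])
    couch = Pose(ry, iso - ry @ iso + np.asarray(couch_translation, dtype=float))
    return {
        "gantry_arm": gantry,
        "gantry_head": gantry,
        "couch": couch,
        "patient": couch,
    }


def default_machine(
    sad_mm: float = 1000.0, isocenter=(0.0, 0.0, 0.0)
) -> list[MachineComponent]:
    """Schematic Versa-HD-like component set (boxes, local frame at the
    reference pose: gantry at 0 degrees, couch centred)."""
    iso = np.asarray(isocenter, dtype=float)

    def box(center, half):
        center = iso + np.asarray(center, dtype=float)
        half = np.asarray(half, dtype=float)
        corners = np.array(
            [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
        )
        return center + corners * half

    return [
        # head hangs below the arm toward the isocenter (beam from -y at 0 deg)
        MachineComponent("gantry_head", box((0, -sad_mm + 250, 0), (200, 250, 200))),
        MachineComponent(
            "gantry_arm", box((0, -sad_mm - 150, 0), (300, 150, 300)),
            parent="gantry_head",
        ),
        MachineComponent("couch", box((0, 150, -700), (250, 50, 1200))),
        MachineComponent(
            "patient", box((0, 0, -300), (200, 100, 900)), parent="couch"
        ),
    ]


def detect_collisions(
    components: list[MachineComponent],
    poses: dict[str, Pose],
    margin: float = DEFAULT_MARGIN_MM,
    use_bvh: bool = True,
) -> list[tuple[str, str]]:
    """Name pairs whose margin-inflated AABBs overlap.

    Each box is inflated by ``margin/2`` so a pair is flagged exactly when
    the axis-wise gap falls below ``margin``.  Pairs adjacent in the
    kinematic chain (parent/child) are excluded.  The BVH-accelerated result
    is identical to brute-force all-pairs.
    """
    names = [c.name for c in components]
    boxes = [
        aabb_of(c.points, poses.get(c.name, Pose()), margin=margin / 2.0)
        for c in components
    ]
    adjacent = {
        frozenset((c.name, c.parent)) for c in components if c.parent is not None
    }
    if use_bvh and len(boxes) > 1:
        tree = build_bvh(boxes)
        raw = query_pairs(tree, tree, boxes, boxes)
        candidate = {(i, j) for i, j in raw if i < j}
    else:
        candidate = {
            (i, j)
            for i in range(len(boxes))
            for j in range(i + 1, len(boxes))
            if sat_overlap(boxes[i], boxes[j])
        }
    out = [
        (names[i], names[j])
        for i, j in sorted(candidate)
        if frozenset((names[i], names[j])) not in adjacent
    ]
    return out
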