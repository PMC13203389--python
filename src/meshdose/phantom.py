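"""Synthetic thorax phantoms: analytic organ meshes, labeled point clouds
and noisy depth-dose samples.

Every organ is a sphere or ellipsoid, so beam entry/exit points, chord
lengths and organ volumes all have closed forms usable as independent
oracles.  The default phantom is a water-equivalent body ellipsoid
containing two lungs (eta = 0.275), a heart (eta ~ 1) and a spherical tumor
seated in the left lung.  All generators are deterministic under a fixed
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .dosimetry import PDDModel, pdd
from .io_formats import LabeledPointCloud
from .meshes import SurfaceMesh

ETA_WATER = 1.0
ETA_LUNG = 0.275  # mean lung density relative to water
ETA_HEART = 1.05  # myocardium density ~ 1.050 g/cm^3


@dataclass(frozen=True)
class OrganSpec:
    name: str
    shape: str  # "sphere" | "ellipsoid"
    center: tuple[float, float, float]  # mm
    semi_axes: tuple[float, float, float]  # mm
    label: int
    eta: float
    architecture: str = "parallel"  # "serial" | "parallel"

    def __post_init__(self) -> None:
        if self.label <= 0:
            raise ValueError("organ labels must be > 0 (0 is background)")
        if min(self.semi_axes) <= 0:
            raise ValueError("semi_axes must be positive")
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if self.shape not in ("sphere", "ellipsoid"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.architecture not in ("serial", "parallel"):
            raise ValueError(f"unknown architecture {self.architecture!r}")

    def contains(self, points: np.ndarray, shrink: float = 0.0) -> np.ndarray:
        """Analytic inside test (ellipsoid inequality), optionally shrunk by
        ``shrink`` mm on every semi-axis."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        axes = np.asarray(self.semi_axes) - shrink
        q = ((pts - np.asarray(self.center)) / axes) ** 2
        return q.sum(axis=1) <= 1.0

    def surface_distance(self, points: np.ndarray) -> np.ndarray:
        """Approximate signed distance to the organ surface (negative inside).

        Exact for spheres; for ellipsoids a normalized radial approximation
        scaled by the smallest semi-axis (sufficient for outlier placement).
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        rel = (pts - np.asarray(self.center)) / np.asarray(self.semi_axes)
        r = np.linalg.norm(rel, axis=1)
        return (r - 1.0) * min(self.semi_axes)


@dataclass(frozen=True)
class PhantomSpec:
    organs: tuple[OrganSpec, ...]
    tumor_center: tuple[float, float, float]
    seed: int = 0

    def __post_init__(self) -> None:
        labels = [o.label for o in self.organs]
        if len(set(labels)) != len(labels):
            raise ValueError("organ labels must be unique")

    def organ(self, name: str) -> OrganSpec:
        for o in self.organs:
            if o.name == name:
                return o
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "tumor_center": list(self.tumor_center),
            "seed": self.seed,
            "organs": [
                {
                    "name": o.name,
                    "shape": o.shape,
                    "center": list(o.center),
                    "semi_axes": list(o.semi_axes),
                    "label": o.label,
                    "eta": o.eta,
                    "architecture": o.architecture,
                }
                for o in self.organs
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        organs = tuple(
            OrganSpec(
                name=o["name"],
                shape=o["shape"],
                center=tuple(o["center"]),
                semi_axes=tuple(o["semi_axes"]),
                label=int(o["label"]),
                eta=float(o["eta"]),
                architecture=o.get("architecture", "parallel"),
            )
            for o in d["organs"]
        )
        return cls(organs, tuple(d["tumor_center"]), int(d.get("seed", 0)))


def make_ellipsoid_mesh(center, semi_axes, subdivisions: int = 3) -> SurfaceMesh:
    """Closed, consistently wound icosphere scaled to the ellipsoid.

    Vertex count grows with ``subdivisions``; the enclosed volume converges
    to the analytic 4/3 pi abc from below.
    """
    semi_axes = np.asarray(semi_axes, dtype=float)
    if np.any(semi_axes <= 0):
        raise ValueError("semi_axes must be positive")
    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    verts = np.asarray(ico.vertices) * semi_axes + np.asarray(center, dtype=float)
    return SurfaceMesh(verts, np.asarray(ico.faces))


# Default thorax dimensions (mm): clinically plausible nested quadrics that
# keep beam chord lengths inside the useful range of the depth-dose curve.
_THORAX = dict(
    body=dict(center=(0.0, 0.0, 0.0), semi=(175.0, 100.0, 200.0)),
    left_lung=dict(center=(85.0, 0.0, 0.0), semi=(50.0, 40.0, 100.0)),
    right_lung=dict(center=(-85.0, 0.0, 0.0), semi=(50.0, 40.0, 100.0)),
    heart=dict(center=(-5.0, 20.0, -30.0), semi=(30.0, 30.0, 45.0)),
    tumor=dict(center=(85.0, 0.0, 0.0), semi=(15.0, 15.0, 15.0)),
)

LABELS = {"body": 1, "left_lung": 2, "right_lung": 3, "heart": 4, "tumor": 5}


def make_thorax_phantom(
    seed: int = 0, subdivisions: int = 4
) -> tuple[PhantomSpec, dict[str, SurfaceMesh]]:
    """Nested-quadric thorax: tumor strictly inside the left lung, lungs and
    heart strictly inside the body.  Deterministic for a fixed seed (the
    geometry itself is analytic; the seed is recorded for downstream
    samplers)."""
    organs = (
        OrganSpec("body", "ellipsoid", _THORAX["body"]["center"],
                  _THORAX["body"]["semi"], LABELS["body"], ETA_WATER),
        OrganSpec("left_lung", "ellipsoid", _THORAX["left_lung"]["center"],
                  _THORAX["left_lung"]["semi"], LABELS["left_lung"], ETA_LUNG),
        OrganSpec("right_lung", "ellipsoid", _THORAX["right_lung"]["center"],
                  _THORAX["right_lung"]["semi"], LABELS["right_lung"], ETA_LUNG),
        OrganSpec("heart", "ellipsoid", _THORAX["heart"]["center"],
                  _THORAX["heart"]["semi"], LABELS["heart"], ETA_HEART,
                  architecture="serial"),
        OrganSpec("tumor", "sphere", _THORAX["tumor"]["center"],
                  _THORAX["tumor"]["semi"], LABELS["tumor"], ETA_WATER),
    )
    spec = PhantomSpec(organs, _THORAX["tumor"]["center"], seed)
    meshes = {
        o.name: make_ellipsoid_mesh(o.center, o.semi_axes, subdivisions)
        for o in organs
    }
    return spec, meshes


def _sample_inside(organ: OrganSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform samples inside the ellipsoid (unit-ball transform)."""
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    r = rng.random(n) ** (1.0 / 3.0)
    return np.asarray(organ.center) + (u * r[:, None]) * np.asarray(organ.semi_axes)


def make_labeled_cloud(
    spec: PhantomSpec,
    points_per_organ: int = 2000,
    noise_sd: float = 0.0,
    outlier_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[LabeledPointCloud, np.ndarray]:
    """Sample ``points_per_organ`` points per organ, perturbed by isotropic
    Gaussian noise, with a controllable fraction converted to outliers.

    Outliers are placed on a shell 5-10x ``noise_sd`` (at least 5-10 mm)
    beyond the organ surface so a 2-sigma neighborhood statistic can always
    separate them.  Returns the cloud and a ground-truth outlier mask.
    Byte-identical output for a fixed seed.
    """
    if points_per_organ < 1:
        raise ValueError("points_per_organ must be >= 1")
    if not 0.0 <= outlier_fraction < 1.0:
        raise ValueError("outlier_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    pts_all, labels_all, outlier_all = [], [], []
    shell_unit = max(noise_sd, 1.0)  # mm floor when noise_sd == 0
    for organ in spec.organs:
        n_out = int(round(outlier_fraction * points_per_organ))
        n_in = points_per_organ - n_out
        pts = _sample_inside(organ, n_in, rng)
        if noise_sd > 0:
            pts = pts + rng.normal(scale=noise_sd, size=pts.shape)
        outlier_flag = np.zeros(points_per_organ, dtype=bool)
        if n_out:
            u = rng.normal(size=(n_out, 3))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            dist = rng.uniform(5.0, 10.0, size=n_out) * shell_unit
            # normalized-space radius 1 + dist/min(semi) guarantees a
            # Euclidean clearance of at least ``dist`` from the surface
            delta = dist / min(organ.semi_axes)
            rel = u * (1.0 + delta[:, None]) * np.asarray(organ.semi_axes)
            out_pts = np.asarray(organ.center) + rel
            pts = np.vstack([pts, out_pts])
            outlier_flag[n_in:] = True
        pts_all.append(pts)
        labels_all.append(np.full(points_per_organ, organ.label))
        outlier_all.append(outlier_flag)
    cloud = LabeledPointCloud(
        np.vstack(pts_all), np.concatenate(labels_all)
    )
    return cloud, np.concatenate(outlier_all)


def sample_pdd_curve(
    model: PDDModel, depths, noise_sd: float = 0.0, seed: int = 0
) -> np.ndarray:
    """Noisy percentage-depth-dose samples: PDD(d) * (1 + N(0, noise_sd)).

    ``noise_sd = 0`` returns the exact model values.  Returns an (N, 2)
    array of (depth_cm, percent).
    """
    depths = np.asarray(depths, dtype=float)
    if np.any(depths < 0):
        raise ValueError("depths must be non-negative")
    values = pdd(depths, model)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values * (1.0 + rng.normal(scale=noise_sd, size=values.shape))
    return np.column_stack([depths, values])
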