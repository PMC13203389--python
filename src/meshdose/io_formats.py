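"""Point-cloud / mesh / label-volume I/O and CT-volume to point-cloud conversion.

Clouds are stored either as an ASCII ``.xyz`` dialect (whitespace-separated
``x y z [hu] [label]``, ``#`` comments) or as ASCII PLY with per-vertex
``hu`` / ``label`` properties.  Meshes go through :mod:`trimesh`
(OBJ / PLY / STL).  NIfTI label volumes are read with :mod:`nibabel`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from .meshes import SurfaceMesh

log = logging.getLogger(__name__)


class ParseError(ValueError):
    """Malformed cloud/mesh file; message names the offending line."""


@dataclass
class LabeledPointCloud:
    """Points in physical mm with integer organ labels and optional HU.

    ``labels == 0`` means background.  ``origin``/``spacing`` record the
    voxel grid the cloud came from (identity defaults for synthetic clouds).
    """

    points: np.ndarray  # (N, 3) float64, mm
    labels: np.ndarray  # (N,) int
    hu: np.ndarray | None = None  # (N,) float or None
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        self.labels = np.asarray(self.labels, dtype=np.int64).reshape(-1)
        if self.hu is not None:
            self.hu = np.asarray(self.hu, dtype=np.float64).reshape(-1)
            if len(self.hu) != len(self.points):
                raise ValueError("hu length mismatch")
        if len(self.labels) != len(self.points):
            raise ValueError("labels length mismatch")
        if np.any(self.labels < 0):
            raise ValueError("labels must be >= 0")
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")

    def __len__(self) -> int:
        return len(self.points)

    def subset(self, index: np.ndarray) -> "LabeledPointCloud":
        return LabeledPointCloud(
            self.points[index],
            self.labels[index],
            None if self.hu is None else self.hu[index],
            self.origin,
            self.spacing,
        )


@dataclass
class VoxelGrid:
    """Binary-occupancy or integer-label grid with affine metadata.

    Voxel-center convention: physical(i, j, k) = origin + (i, j, k) * spacing.
    """

    array: np.ndarray  # (nx, ny, nz)
    origin: np.ndarray
    spacing: np.ndarray

    def __post_init__(self) -> None:
        self.array = np.asarray(self.array)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        if self.array.ndim != 3:
            raise ValueError("voxel array must be 3-D")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")


def volume_to_cloud(
    label_volume: np.ndarray,
    hu_volume: np.ndarray | None,
    origin,
    spacing,
    target_labels,
    hu_range: tuple[float, float] = (-np.inf, -np.inf),
) -> LabeledPointCloud:
    """Dual-condition voxel filter producing a labeled physical-mm cloud.

    A voxel is retained when its label is in ``target_labels`` OR its HU lies
    in ``hu_range``; voxels retained only by the HU condition are masked to
    background (label 0).
    """
    label_volume = np.asarray(label_volume)
    origin = np.asarray(origin, dtype=float).reshape(3)
    spacing = np.asarray(spacing, dtype=float).reshape(3)
    if hu_volume is not None:
        hu_volume = np.asarray(hu_volume)
        if hu_volume.shape != label_volume.shape:
            raise ValueError("label and HU volumes must share shape")
    lo, hi = hu_range
    if lo > hi:
        raise ValueError("hu_range low must be <= high")
    target = np.isin(label_volume, list(target_labels))
    if hu_volume is not None:
        in_hu = (hu_volume >= lo) & (hu_volume <= hi)
    else:
        in_hu = np.zeros(label_volume.shape, dtype=bool)
    keep = target | in_hu
    idx = np.argwhere(keep)
    pts = origin + idx * spacing
    labels = np.where(target[keep], label_volume[keep], 0)
    hu = None if hu_volume is None else hu_volume[keep].astype(float)
    return LabeledPointCloud(pts, labels, hu, origin=origin, spacing=spacing)


# ---------------------------------------------------------------- clouds

def write_cloud(cloud: LabeledPointCloud, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".ply":
        _write_cloud_ply(cloud, path)
    else:
        _write_cloud_xyz(cloud, path)


def read_cloud(path) -> LabeledPointCloud:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".ply":
        return _read_cloud_ply(path)
    return _read_cloud_xyz(path)


def _write_cloud_xyz(cloud: LabeledPointCloud, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("# x y z hu label\n")
        hu = cloud.hu if cloud.hu is not None else np.zeros(len(cloud))
        for p, h, l in zip(cloud.points, hu, cloud.labels):
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g} {h:.9g} {int(l)}\n")


def _read_cloud_xyz(path: Path) -> LabeledPointCloud:
    pts, hu, labels = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tok = line.split()
            if len(tok) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 columns")
            try:
                xyz = [float(t) for t in tok[:3]]
                h = float(tok[3]) if len(tok) > 3 else 0.0
                l = int(float(tok[4])) if len(tok) > 4 else 0
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            pts.append(xyz)
            hu.append(h)
            labels.append(l)
    if not pts:
        return LabeledPointCloud(np.empty((0, 3)), np.empty(0, dtype=int))
    return LabeledPointCloud(np.array(pts), np.array(labels), np.array(hu))


def _write_cloud_ply(cloud: LabeledPointCloud, path: Path) -> None:
    n = len(cloud)
    hu = cloud.hu if cloud.hu is not None else np.zeros(n)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {n}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        fh.write("property double hu\nproperty int label\n")
        fh.write("end_header\n")
        for p, h, l in zip(cloud.points, hu, cloud.labels):
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g} {h:.9g} {int(l)}\n")


def _read_cloud_ply(path: Path) -> LabeledPointCloud:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise ParseError(f"{path}:1: not a PLY file")
    n = None
    props: list[str] = []
    body_at = None
    for i, line in enumerate(lines[1:], 2):
        tok = line.split()
        if not tok:
            continue
        if tok[0] == "format" and tok[1] != "ascii":
            raise ParseError(f"{path}:{i}: only ascii PLY supported")
        if tok[0] == "element":
            if tok[1] != "vertex":
                raise ParseError(f"{path}:{i}: unexpected element {tok[1]!r}")
            n = int(tok[2])
        elif tok[0] == "property":
            props.append(tok[-1])
        elif tok[0] == "end_header":
            body_at = i
            break
    if n is None or body_at is None:
        raise ParseError(f"{path}: missing vertex element or end_header")
    col = {name: k for k, name in enumerate(props)}
    for axis in "xyz":
        if axis not in col:
            raise ParseError(f"{path}: missing coordinate property {axis!r}")
    rows = []
    for i, line in enumerate(lines[body_at : body_at + n], body_at + 1):
        tok = line.split()
        if len(tok) != len(props):
            raise ParseError(f"{path}:{i}: expected {len(props)} values")
        rows.append([float(t) for t in tok])
    data = np.array(rows, dtype=float).reshape(n, len(props))
    pts = data[:, [col["x"], col["y"], col["z"]]]
    hu = data[:, col["hu"]] if "hu" in col else None
    if "label" in col:
        labels = data[:, col["label"]].astype(int)
    else:
        log.warning("%s: no 'label' property; defaulting labels to 0", path)
        labels = np.zeros(n, dtype=int)
    return LabeledPointCloud(pts, labels, hu)


# ---------------------------------------------------------------- meshes

def write_mesh(mesh: SurfaceMesh, path) -> None:
    mesh.as_trimesh().export(str(path))


def read_mesh(path) -> SurfaceMesh:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        tm = trimesh.load(str(path), force="mesh", process=False)
    except Exception as exc:  # noqa: BLE001 - normalize loader errors
        raise ParseError(f"{path}: not a readable mesh file ({exc})") from exc
    if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
        raise ParseError(f"{path}: file contains no triangular faces")
    # trimesh fan-triangulates polygonal faces on load; warn if that happened
    raw_faces = _count_obj_faces(path) if path.suffix.lower() == ".obj" else None
    if raw_faces is not None and raw_faces != len(tm.faces):
        warnings.warn(
            f"{path}: non-triangular faces were triangulated "
            f"({raw_faces} polygons -> {len(tm.faces)} triangles)",
            stacklevel=2,
        )
    return SurfaceMesh.from_trimesh(tm)


def _count_obj_faces(path: Path) -> int:
    n = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("f "):
                n += 1
    return n


# ---------------------------------------------------------------- NIfTI

def read_nifti_labels(path) -> VoxelGrid:
    """Read a NIfTI label volume; only axis-aligned affines are accepted.

    Direction cosines other than (a possibly negated) identity would make
    the simple origin+index*spacing convention silently wrong, so they are
    rejected.
    """
    import nibabel as nib

    img = nib.load(str(path))
    aff = img.affine
    lin = aff[:3, :3]
    spacing = np.abs(np.diag(lin))
    if not np.allclose(lin, np.diag(np.diag(lin)), atol=1e-6):
        raise ValueError(
            f"{path}: non-axis-aligned direction cosines are not supported; "
            "resample the volume to an identity orientation first"
        )
    return VoxelGrid(np.asarray(img.dataobj), origin=aff[:3, 3], spacing=spacing)
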