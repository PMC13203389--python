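"""Beam geometry, SSD/depth computation and gantry-angle sweeps.

Gantry convention (IEC-style, declared once here and in the config files):
patient axes are x = patient left, y = posterior, z = superior; the gantry
rotates about z through the isocenter.  At 0 degrees the source sits
anteriorly at isocenter + SAD * (0, -1, 0) and the beam travels +y; at
90 degrees the source is on the patient's left.  Beams are isocentric:
aimed exactly at the isocenter (placed at the tumor center by default).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .dosimetry import (
    MachineCalibration,
    MaterialMap,
    PDDModel,
    dose_at_point,
    effective_depth,
    mayneord_factor,
    pdd,
)
from .meshes import SurfaceMesh
from .radiobiology import SerialHit, serial_organ_hits
from .raycast import Ray, ray_mesh_intersections, trace_beam

log = logging.getLogger(__name__)


class BeamMissesPatientError(ValueError):
    """The beam axis does not intersect the body surface."""


@dataclass(frozen=True)
class BeamSpec:
    gantry_angle: float  # degrees, normalized to [0, 360)
    isocenter: tuple[float, float, float] = (0.0, 0.0, 0.0)  # mm
    sad: float = 1000.0  # mm
    field_size_cm: float = 10.0
    mu: float = 100.0
    energy_tag: str = "6MV"

    def __post_init__(self) -> None:
        if self.sad <= 0:
            raise ValueError("SAD must be positive")
        if self.mu < 0:
            raise ValueError("MU must be non-negative")
        object.__setattr__(self, "gantry_angle", float(self.gantry_angle) % 360.0)


@dataclass(frozen=True)
class BeamReport:
    angle: float
    ssd_mm: float | None
    depth_cm: float | None
    deff_cm: float | None
    pdd_pct: float | None
    dose_cgy: float | None
    serial_hits: tuple[SerialHit, ...] = ()
    missed: bool = False


def gantry_unit_vector(angle_deg: float) -> np.ndarray:
    """Unit vector from isocenter toward the source in the axial plane."""
    a = math.radians(angle_deg)
    return np.array([math.sin(a), -math.cos(a), 0.0])


def beam_ray(spec: BeamSpec) -> Ray:
    """Ray from the source toward the isocenter."""
    iso = np.asarray(spec.isocenter, dtype=float)
    source = iso + spec.sad * gantry_unit_vector(spec.gantry_angle)
    return Ray(source, iso - source)


def compute_ssd(ray: Ray, body_mesh: SurfaceMesh) -> float:
    """Source-to-surface distance: t of the first body-mesh hit (mm)."""
    hits = ray_mesh_intersections(ray, body_mesh)
    if not hits:
        raise BeamMissesPatientError("beam axis does not intersect the body")
    return hits[0].t


def tumor_depth(ray: Ray, body_mesh: SurfaceMesh, tumor_center) -> float:
    """Skin-entry to tumor-center distance along the ray, in cm.

    Off-axis targets are orthogonally projected onto the ray with a logged
    warning (isocentric setups aim the ray exactly at the target).
    """
    center = np.asarray(tumor_center, dtype=float)
    t_target = float((center - ray.origin) @ ray.direction)
    offset = np.linalg.norm(ray.at(t_target) - center)
    if offset > 1e-6:
        log.warning(
            "tumor center is %.3g mm off the beam axis; projected onto the ray",
            offset,
        )
    ssd = compute_ssd(ray, body_mesh)
    if t_target < ssd:
        raise ValueError("tumor center lies before the skin entry point")
    return (t_target - ssd) / 10.0


def percent_difference(model_dose: float, reference_dose: float) -> float:
    """100 * |model - reference| / reference (full precision; round for
    display)."""
    if reference_dose <= 0:
        raise ValueError("reference dose must be positive")
    return 100.0 * abs(model_dose - reference_dose) / reference_dose


def evaluate_beam(
    spec: BeamSpec,
    organs: list[tuple[int, SurfaceMesh, float]],
    body_label: int,
    cal: MachineCalibration,
    model: PDDModel,
    serial_organs: list[tuple[int, SurfaceMesh]] | None = None,
) -> BeamReport:
    """Single-beam dosimetric evaluation at the isocenter (= target).

    PDD is evaluated at the heterogeneity-corrected effective depth and
    rescaled from the calibration SSD0 to the actual SSD with the Mayneord
    factor; monitor units then convert to absorbed dose.
    """
    ray = beam_ray(spec)
    body_mesh = next(m for label, m, _ in organs if label == body_label)
    try:
        ssd = compute_ssd(ray, body_mesh)
    except BeamMissesPatientError:
        return BeamReport(spec.gantry_angle, None, None, None, None, None,
                          missed=True)
    t_target = float(
        (np.asarray(spec.isocenter, dtype=float) - ray.origin) @ ray.direction
    )
    depth_cm = (t_target - ssd) / 10.0
    segments = trace_beam(ray, organs)
    deff_cm = effective_depth(segments, up_to_mm=t_target)
    ssd_cm = ssd / 10.0
    pdd_pct = pdd(deff_cm, model) * mayneord_factor(
        cal.SSD0, ssd_cm, max(deff_cm, 1e-6), model.dmax
    )
    dose = dose_at_point(spec.mu, cal, pdd_pct, ssd_cm)
    hits = ()
    if serial_organs:
        hits = tuple(serial_organ_hits(ray, serial_organs, model,
                                       skin_entry_t_mm=ssd))
    return BeamReport(spec.gantry_angle, ssd, depth_cm, deff_cm, pdd_pct,
                      dose, hits)


def sweep_angles(
    template: BeamSpec,
    organs: list[tuple[int, SurfaceMesh, float]],
    body_label: int,
    cal: MachineCalibration,
    model: PDDModel,
    angles,
    serial_organs: list[tuple[int, SurfaceMesh]] | None = None,
) -> list[BeamReport]:
    """Evaluate the beam at every gantry angle; misses are reported, not
    fatal.  The (angle, depth) pairs feed ``depth_angle_auc``."""
    angles = list(angles)
    if not angles:
        raise ValueError("angles must be non-empty")
    reports = []
    for a in angles:
        spec = BeamSpec(
            gantry_angle=a,
            isocenter=template.isocenter,
            sad=template.sad,
            field_size_cm=template.field_size_cm,
            mu=template.mu,
            energy_tag=template.energy_tag,
        )
        report = evaluate_beam(spec, organs, body_label, cal, model,
                               serial_organs)
        # keep the caller's (unnormalized) angle so profiles over a full
        # 0..360 sweep stay strictly increasing
        reports.append(dataclasses.replace(report, angle=float(a)))
    return reports


def reports_to_profile(reports: list[BeamReport]) -> np.ndarray:
    """(angle, depth_cm) rows for beams that hit the patient."""
    rows = [(r.angle, r.depth_cm) for r in reports if not r.missed]
    return np.asarray(rows, dtype=float)


def load_rtplan(path) -> None:
    """DICOM-RT plan import is intentionally not provided; use the YAML/JSON
    plan format."""
    raise NotImplementedError(
        "DICOM-RT parsing is out of scope; describe the plan as YAML/JSON "
        "(see BeamSpec fields)"
    )
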