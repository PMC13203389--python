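"""Lyman-Kutcher-Burman (LKB) normal-tissue complication probability.

The DVH-reduction route: a dose-volume histogram is collapsed to an
effective volume

    Vol_eff = (1/Vol_ref) * sum_i Vol_i * (D_i / Dmax)^(1/n)

which, with the volume-scaled tolerance dose TD50(v) = TD50 * v^(-n),
yields the probit argument t = (Dmax - TD50(v)) / (m * TD50(v)) and
NTCP = Phi(t) = 0.5 + erf(t / sqrt 2) / 2.

Also provided: serial-organ beam-intersection flagging (max point dose
drives serial toxicity) and the depth-vs-gantry-angle area under the curve,
a proxy for irradiated volume in parallel organs (lower is better).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from .dosimetry import PDDModel, pdd
from .meshes import SurfaceMesh
from .raycast import Ray, ray_mesh_intersections


@dataclass(frozen=True)
class DVHBins:
    """Differential DVH: volumes (fraction or absolute) at doses D_i (Gy)."""

    volumes: np.ndarray
    doses: np.ndarray
    vol_ref: float = 1.0

    def __post_init__(self) -> None:
        v = np.asarray(self.volumes, dtype=float)
        d = np.asarray(self.doses, dtype=float)
        if v.shape != d.shape or v.ndim != 1:
            raise ValueError("volumes and doses must be equal-length 1-D")
        if np.any(v < 0) or np.any(d < 0) or self.vol_ref <= 0:
            raise ValueError("volumes, doses and vol_ref must be non-negative")
        if v.sum() > self.vol_ref * (1 + 1e-9):
            raise ValueError("bin volumes exceed the reference volume")
        object.__setattr__(self, "volumes", v)
        object.__setattr__(self, "doses", d)


@dataclass(frozen=True)
class LKBParams:
    """n: volume-effect exponent; m: slope; TD50: whole-organ 50% dose (Gy)."""

    n: float
    m: float
    td50: float

    def __post_init__(self) -> None:
        if self.n <= 0 or self.m <= 0 or self.td50 <= 0:
            raise ValueError("n, m and TD50 must be strictly positive")


def effective_volume(bins: DVHBins, dmax_gy: float, n: float) -> float:
    """LKB DVH reduction; in (0, 1] for a whole-organ DVH with Dmax = max D_i."""
    if n <= 0:
        raise ValueError("n must be positive")
    if dmax_gy <= 0 or dmax_gy < bins.doses.max() - 1e-12:
        raise ValueError("Dmax must be >= every bin dose and positive")
    ratio = bins.doses / dmax_gy
    return float(np.sum(bins.volumes * ratio ** (1.0 / n)) / bins.vol_ref)


def lkb_t(dmax_gy: float, params: LKBParams, vol_eff: float) -> float:
    """Probit argument t = (Dmax - TD50(v)) / (m * TD50(v)).

    The partial-volume tolerance follows the LKB power law
    TD50(v) = TD50 * v^(-n).
    """
    if vol_eff <= 0:
        raise ValueError("effective volume must be positive")
    td50_v = params.td50 * vol_eff ** (-params.n)
    return (dmax_gy - td50_v) / (params.m * td50_v)


def ntcp(t: float) -> float:
    """Complication probability Phi(t) = 0.5 + erf(t/sqrt 2)/2."""
    return 0.5 + erf(t / math.sqrt(2.0)) / 2.0


@dataclass(frozen=True)
class SerialHit:
    """Beam-axis intersection summary for one serial organ-at-risk."""

    label: int
    hit: bool
    entry_depth_cm: float | None = None
    exit_depth_cm: float | None = None
    max_dose_depth_cm: float | None = None  # PDD-maximal depth in the interval


def serial_organ_hits(
    ray: Ray,
    organs: list[tuple[int, SurfaceMesh]],
    model: PDDModel,
    skin_entry_t_mm: float = 0.0,
) -> list[SerialHit]:
    """Flag serial organs crossed by the beam axis and locate the depth of
    maximum dose inside each traversed interval.

    Depths are measured from the skin entry (``skin_entry_t_mm`` along the
    ray) in cm.  The PDD peak inside [d_in, d_out] is dmax when the interval
    straddles it, the interval entry past the peak (PDD decreasing) and the
    interval exit before it (PDD increasing).
    """
    out: list[SerialHit] = []
    for label, mesh in organs:
        hits = ray_mesh_intersections(ray, mesh)
        if len(hits) < 2:
            out.append(SerialHit(label, False))
            continue
        d_in = (hits[0].t - skin_entry_t_mm) / 10.0
        d_out = (hits[-1].t - skin_entry_t_mm) / 10.0
        if d_in <= model.dmax <= d_out:
            peak = model.dmax
        elif d_in > model.dmax:
            peak = d_in
        else:
            peak = d_out
        out.append(SerialHit(label, True, d_in, d_out, peak))
    return out


def depth_angle_auc(profile) -> float:
    """Trapezoidal integral of tumor depth (cm) over gantry angle (degrees).

    A scalar beam-selection score proportional to the irradiated-volume
    burden on parallel organs; lower is better.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.ndim != 2 or profile.shape[1] != 2 or len(profile) < 2:
        raise ValueError("profile must be a list of (angle, depth) pairs")
    angles, depths = profile[:, 0], profile[:, 1]
    if np.any(np.diff(angles) <= 0):
        raise ValueError("angles must be strictly increasing")
    if angles[-1] - angles[0] > 360.0 + 1e-9:
        raise ValueError("angle span must not exceed 360 degrees")
    return float(np.trapezoid(depths, angles))
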