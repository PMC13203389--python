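"""Correction-based photon dose engine.

Central-axis depth dose is modeled with a buildup-tail shape function

    f(d) = d / (d^2 + n) * exp(-mu * d)        [d in cm]

normalized to 100 % at its own maximum depth ``dmax`` (PDD).  SSD dependence
follows inverse-square practice (Mayneord factor), tissue heterogeneity is
handled by the equivalent-depth rescaling z_eff = z * eta along the beam, and
monitor units convert to absorbed dose through machine calibration factors.

Unit convention: dosimetry depths are cm, geometry is mm; the single mm->cm
conversion point is ``effective_depth``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from .raycast import PathSegment

_DMAX_SEARCH_CM = 50.0  # buildup peak searched on (0, 50] cm


def buildup_tail_raw(d, n: float, mu: float):
    """Unnormalized buildup-tail shape d/(d^2+n) * exp(-mu d); d in cm."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("depth must be non-negative")
    out = d / (d * d + n) * np.exp(-mu * d)
    return float(out) if out.ndim == 0 else out


def find_dmax(n: float, mu: float) -> float:
    """Depth of maximum dose: argmax of the buildup-tail shape on (0, 50] cm.

    Located by bounded scalar maximization; at mu -> 0 the peak approaches
    the stationary point sqrt(n) of d/(d^2+n).
    """
    if n <= 0 or mu < 0:
        raise ValueError("require n > 0 and mu >= 0")
    res = minimize_scalar(
        lambda d: -buildup_tail_raw(d, n, mu),
        bounds=(1e-9, _DMAX_SEARCH_CM),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x)


@dataclass(frozen=True)
class PDDModel:
    """Buildup-tail percentage-depth-dose model for one (energy, field size).

    n: dimensionless diffusion parameter; mu: attenuation coefficient (1/cm).
    ``dmax`` is derived and cached at construction.
    """

    n: float
    mu: float
    energy_tag: str = ""
    field_size_cm: float = 10.0
    dmax: float = field(init=False)

    def __post_init__(self) -> None:
        if self.n <= 0 or self.mu <= 0:
            raise ValueError("require n > 0 and mu > 0")
        object.__setattr__(self, "dmax", find_dmax(self.n, self.mu))


#: 6 MV-like demonstration parameters (dmax near 1.5 cm); not measured data.
DEFAULT_MODEL_PARAMS = {"n": 2.25, "mu": 0.0465}


@dataclass(frozen=True)
class MachineCalibration:
    """Linac calibration: Dref (cGy/MU) at depth dref (cm) and SSD0 (cm).

    Scrc / Spr are the collimator and phantom scatter factors; Ks is the
    scatter factor between d and dmax used by the SSD-explicit PDD form
    (set to 1 unless measured).
    """

    Dref: float = 1.0
    dref: float = 10.0
    SSD0: float = 100.0
    Scrc: float = 1.0
    Spr: float = 1.0
    Ks: float = 1.0

    def __post_init__(self) -> None:
        for name in ("Dref", "dref", "SSD0", "Scrc", "Spr", "Ks"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


class MaterialMap:
    """Organ label -> water-equivalent attenuation coefficient eta.

    Unlisted labels default to water (eta = 1).  Lung is conventionally 0.275
    (mean lung density relative to water); soft tissue/bone combined as 1.
    """

    def __init__(self, table: dict[int, float] | None = None):
        table = dict(table or {})
        for label, eta in table.items():
            if eta <= 0:
                raise ValueError(f"eta for label {label} must be > 0")
        self._table = table

    def eta(self, label: int) -> float:
        return self._table.get(label, 1.0)

    def __getitem__(self, label: int) -> float:
        return self.eta(label)


def pdd(d, model: PDDModel):
    """Percentage depth dose: 100 * f(d) / f(dmax); in [0, 100]."""
    peak = buildup_tail_raw(model.dmax, model.n, model.mu)
    return 100.0 * buildup_tail_raw(d, model.n, model.mu) / peak


def pdd_at_ssd(
    d: float,
    ssd: float,
    model: PDDModel,
    cal: MachineCalibration,
    clip: bool = False,
) -> float:
    """SSD-explicit PDD: 100 * ((SSD+dmax)/(SSD+d))^2 * exp(-mu(d-dmax)) * Ks.

    ``clip`` caps the value at 100 for d < dmax (raw by default).
    """
    if d < 0 or ssd <= 0:
        raise ValueError("require d >= 0 and ssd > 0")
    val = (
        100.0
        * ((ssd + model.dmax) / (ssd + d)) ** 2
        * math.exp(-model.mu * (d - model.dmax))
        * cal.Ks
    )
    if clip and d < model.dmax:
        val = min(val, 100.0)
    return val


def mayneord_factor(ssd1: float, ssd2: float, d: float, dmax: float) -> float:
    """Inverse-square correction converting PDD at SSD1 to SSD2:
    F = ((SSD2+dmax)/(SSD1+dmax))^2 * ((SSD1+d)/(SSD2+d))^2.
    """
    if min(ssd1, ssd2, d, dmax) <= 0:
        raise ValueError("all arguments must be positive")
    return ((ssd2 + dmax) / (ssd1 + dmax)) ** 2 * ((ssd1 + d) / (ssd2 + d)) ** 2


def ssd_factor(ssd: float, cal: MachineCalibration, exponent: float = 2.0) -> float:
    """Distance correction ((SSD0+dref)/(SSD+dref))^exponent.

    The exponent defaults to 2 (inverse-square, consistent with the Mayneord
    treatment); a first-power variant is selectable for comparison with
    conventions that quote the factor unsquared.
    """
    if ssd <= 0:
        raise ValueError("ssd must be positive")
    return ((cal.SSD0 + cal.dref) / (ssd + cal.dref)) ** exponent


def dose_at_point(
    mu_units: float,
    cal: MachineCalibration,
    pdd_percent: float,
    ssd: float,
    exponent: float = 2.0,
) -> float:
    """Absorbed dose (cGy) from monitor units:
    TD = MU * Dref * PDD/100 * Scrc * Spr * ssd_factor(SSD).
    """
    if mu_units < 0 or pdd_percent < 0:
        raise ValueError("MU and PDD must be non-negative")
    return (
        mu_units
        * cal.Dref
        * (pdd_percent / 100.0)
        * cal.Scrc
        * cal.Spr
        * ssd_factor(ssd, cal, exponent)
    )


def effective_depth(
    segments: list[PathSegment], up_to_mm: float | None = None
) -> float:
    """Water-equivalent depth (cm) accumulated along resolved beam segments.

    Sums z_i * eta_i over the traversed intervals from the first (skin) entry
    up to ``up_to_mm`` along the ray; gaps between segments (inside the body
    but covered by no organ mesh) count at eta = 1.  ``up_to_mm=None`` sums
    the full traversal.  Input lengths are mm; the return value is cm.
    """
    if not segments:
        raise ValueError("no segments: ray does not traverse the body")
    start = segments[0].entry.t
    end = segments[-1].exit.t if up_to_mm is None else float(up_to_mm)
    if end < start - 1e-9:
        raise ValueError("target lies before the body entry point")
    total_mm = 0.0
    cursor = start
    for seg in segments:
        if seg.entry.t >= end:
            break
        gap = max(0.0, min(seg.entry.t, end) - cursor)
        total_mm += gap  # uncovered interval: water
        lo = max(seg.entry.t, cursor)
        hi = min(seg.exit.t, end)
        if hi > lo:
            total_mm += (hi - lo) * seg.eta
        cursor = max(cursor, min(seg.exit.t, end))
    if end > cursor:
        total_mm += end - cursor
    return total_mm / 10.0


def fit_pdd(
    samples,
    init: tuple[float, float] = (2.0, 0.05),
    energy_tag: str = "",
) -> tuple[PDDModel, float]:
    """Least-squares fit of the normalized buildup-tail model to (depth, %).

    Requires >= 4 samples spanning both sides of the peak of the fitted
    curve.  Returns (model, residual RMS in percent).  Deterministic for a
    fixed ``init``.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[1] != 2 or len(samples) < 4:
        raise ValueError("need >= 4 (depth, percent) samples")
    depths, target = samples[:, 0], samples[:, 1]
    if np.ptp(depths) <= 0:
        raise RuntimeError("fit failed: samples at a single depth are unidentifiable")

    def resid(theta):
        n, mu = np.exp(theta)  # positivity via log-parameterization
        model = PDDModel(n=n, mu=mu)
        return pdd(depths, model) - target

    res = least_squares(resid, np.log(np.asarray(init, dtype=float)), method="lm")
    if not res.success:
        rms = float(np.sqrt(np.mean(res.fun**2)))
        raise RuntimeError(f"fit failed to converge (residual RMS {rms:.3g}%)")
    n, mu = np.exp(res.x)
    model = PDDModel(n=float(n), mu=float(mu), energy_tag=energy_tag)
    if depths.min() >= model.dmax or depths.max() <= model.dmax:
        raise RuntimeError(
            "fit failed: samples do not span both sides of the dose peak "
            f"(dmax = {model.dmax:.3g} cm)"
        )
    rms = float(np.sqrt(np.mean(res.fun**2)))
    return model, rms
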