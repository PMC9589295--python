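"""Analytic dose engine.

A deterministic ray-cast surrogate for a treatment planning system: several
coplanar parallel beams aimed at the target, exponentially attenuated by the
radiological depth (line integral of relative electron density derived from
the HU image), with a Gaussian-penumbra field aperture shaped to the target.
It deliberately models no scatter; what matters for sCT QA is that HU errors
propagate into dose errors, monotonically (more density upstream, less dose
downstream).

The prescription is sequential: a first plan delivering 50 Gy (median) to
CTV1, then a boost bringing the CTV2 median total to 78 Gy.  Beam weights and
apertures are calibrated once on the reference CT and then reused verbatim
for any synthetic CT, mirroring clinical practice of recomputing dose with
identical beam parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from scipy.special import erf

from .core import StructureError, StructureSet, VolumeGrid


@dataclass
class BeamConfig:
    n_beams: int = 7                      # coplanar, equally spaced gantry angles
    prescription_ctv1_gy: float = 50.0
    boost_ctv2_gy: float = 28.0
    mu_per_mm: float = 0.005              # linear attenuation per unit rel. e-density
    #: HU -> relative electron density, piecewise linear through these knots
    hu_knots: tuple = (-1000.0, 0.0, 1000.0)
    red_knots: tuple = (0.0, 1.0, 1.6)
    penumbra_sigma_mm: float = 5.0
    field_margin_mm: float = 6.0

    def __post_init__(self):
        if self.mu_per_mm < 0:
            raise ValueError("attenuation must be >= 0")

    @property
    def total_gy(self) -> float:
        return self.prescription_ctv1_gy + self.boost_ctv2_gy

    def electron_density(self, hu: np.ndarray) -> np.ndarray:
        return np.interp(hu, self.hu_knots, self.red_knots)


@dataclass
class Plan:
    """Calibrated beam parameters, reusable across images."""

    config: BeamConfig
    angles: np.ndarray                    # gantry angles, rad
    isocenter_mm: np.ndarray              # CTV2 centroid on the reference CT
    apertures: dict = field(default_factory=dict)  # plan -> (n_beams, 2) half-widths
    weights: dict = field(default_factory=dict)    # plan -> scalar beam weight


def _rotate_xy(vol: np.ndarray, angle_rad: float, cval: float = 0.0) -> np.ndarray:
    if abs(angle_rad) < 1e-12:
        return vol
    return ndimage.rotate(vol, np.degrees(angle_rad), axes=(0, 1),
                          reshape=False, order=1, mode="constant", cval=cval)


def _radiological_depth(red: np.ndarray, angle: float, dx: float) -> np.ndarray:
    """Line integral of electron density along the beam direction (+x after
    rotating the volume by -angle), midpoint rule, in mm-equivalent units."""
    r = _rotate_xy(red, -angle)
    depth = (np.cumsum(r, axis=0) - 0.5 * r) * dx
    return _rotate_xy(depth, angle)


def _field_profile(geo_axes, angle, iso, half_widths, sigma):
    """Smooth-box aperture in the plane perpendicular to the beam."""
    x, y, z = np.meshgrid(*geo_axes, indexing="ij")
    e1 = np.array([-np.sin(angle), np.cos(angle)])
    t1 = (x - iso[0]) * e1[0] + (y - iso[1]) * e1[1]
    t2 = z - iso[2]
    s = np.sqrt(2.0) * sigma

    def smooth_box(t, r):
        return 0.5 * (erf((r - t) / s) - erf((-r - t) / s))

    return smooth_box(t1, half_widths[0]) * smooth_box(t2, half_widths[1])


def _target_aperture(mask, geo, angle, iso, margin):
    idx = np.argwhere(mask)
    pts = idx * np.asarray(geo.spacing) + np.asarray(geo.origin)
    e1 = np.array([-np.sin(angle), np.cos(angle)])
    t1 = (pts[:, 0] - iso[0]) * e1[0] + (pts[:, 1] - iso[1]) * e1[1]
    t2 = pts[:, 2] - iso[2]
    return np.array([np.abs(t1).max() + margin, np.abs(t2).max() + margin])


def _unit_plan_dose(image: VolumeGrid, plan: Plan, plan_name: str) -> np.ndarray:
    """Sum over beams of aperture x exp(-mu * radiological depth), weight 1."""
    cfg = plan.config
    geo = image.geometry
    if abs(geo.spacing[0] - geo.spacing[1]) > 1e-9:
        raise ValueError("beam rotation requires isotropic in-plane spacing")
    red = cfg.electron_density(image.values)
    axes = geo.coordinate_axes()
    dose = np.zeros(geo.shape)
    for b, angle in enumerate(plan.angles):
        depth = _radiological_depth(red, angle, geo.spacing[0])
        prof = _field_profile(axes, angle, plan.isocenter_mm,
                              plan.apertures[plan_name][b], cfg.penumbra_sigma_mm)
        dose += prof * np.exp(-cfg.mu_per_mm * depth)
    return dose


def plan_beams(ct: VolumeGrid, structures: StructureSet,
               config: BeamConfig = BeamConfig()) -> Plan:
    """Calibrate beam weights on the reference CT.

    Plan-1 weight makes the CTV1 median dose equal the CTV1 prescription;
    the boost weight is solved so the CTV2 median *total* equals 78 Gy.
    """
    structures.require("ctv1", "ctv2")
    ctv1, ctv2 = structures["ctv1"], structures["ctv2"]
    if not ctv1.any() or not ctv2.any():
        raise StructureError("empty CTV mask")
    geo = ct.geometry
    iso = (np.argwhere(ctv2).mean(axis=0) * np.asarray(geo.spacing)
           + np.asarray(geo.origin))
    angles = 2.0 * np.pi * np.arange(config.n_beams) / config.n_beams
    plan = Plan(config=config, angles=angles, isocenter_mm=iso)
    for name, mask in (("ctv1", ctv1), ("ctv2", ctv2)):
        plan.apertures[name] = np.stack([
            _target_aperture(mask, geo, a, iso, config.field_margin_mm)
            for a in angles
        ])

    d1 = _unit_plan_dose(ct, plan, "ctv1")
    d2 = _unit_plan_dose(ct, plan, "ctv2")
    w1 = config.prescription_ctv1_gy / np.median(d1[ctv1])
    total = config.total_gy

    def gap(w2):
        return np.median(w1 * d1[ctv2] + w2 * d2[ctv2]) - total

    hi = 2.0 * total / np.median(d2[ctv2])
    while gap(hi) < 0:
        hi *= 2.0
    w2 = optimize.brentq(gap, 0.0, hi, xtol=1e-10)
    plan.weights = {"ctv1": float(w1), "ctv2": float(w2)}
    return plan


def compute_dose(image: VolumeGrid, structures: StructureSet | None = None,
                 config: BeamConfig = BeamConfig(),
                 plan: Plan | None = None) -> VolumeGrid:
    """Dose on ``image``; calibrates a plan on it unless one is supplied.

    For sCT evaluation, calibrate on the reference CT with :func:`plan_beams`
    and pass the same plan here for every image.
    """
    if image.unit != "HU":
        raise ValueError(f"dose engine expects an HU image, got {image.unit}")
    if plan is None:
        if structures is None:
            raise StructureError("either a calibrated plan or structures required")
        plan = plan_beams(image, structures, config)
    dose = (plan.weights["ctv1"] * _unit_plan_dose(image, plan, "ctv1")
            + plan.weights["ctv2"] * _unit_plan_dose(image, plan, "ctv2"))
    return VolumeGrid(dose, image.spacing, image.origin, "Gy")
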