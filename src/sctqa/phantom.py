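"""Synthetic pelvic phantom cohort.

Generates paired CT / MRI-like / structure data with controlled inter-patient
variability so the whole QA pipeline can be exercised without clinical data.
Anatomy is analytic: an elliptical body cylinder, a pelvic bone ring with a
dense cortical shell around a spongy core, a bladder and prostate ellipsoid,
two seminal-vesicle blobs fused to the prostate (CTV1), and a gently curved
rectum tube containing an air pocket.  Inter-patient variability combines
per-organ volume scaling, positional jitter, and a smooth random warp of the
whole body; the warp's analytic displacement field is retained on each case as
registration ground truth.

CT numbers are drawn per tissue class (soft tissue near water, heterogeneous
bone split into bright cortical shell and darker spongy interior, strongly
negative rectal air).  The MRI-like channel uses a different monotone map
(bone dark, bladder bright) times a smooth multiplicative bias field, so its
contrast is genuinely not CT-like.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
from scipy import ndimage

from .core import (
    Geometry,
    PatientCase,
    StructureSet,
    VectorField,
    VolumeGrid,
)

ORGAN_NAMES = ("body", "bones", "bladder", "rectum", "prostate", "ctv1", "ctv2")


class PhantomError(ValueError):
    pass


@dataclass
class TissueStats:
    mean: float
    sd: float


@dataclass
class PhantomParams:
    """Geometry (mm), tissue statistics (HU) and variability of the cohort."""

    shape: tuple[int, int, int] = (96, 96, 48)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)

    # organ base geometry, mm, relative to the grid centre
    body_semiaxes: tuple[float, float] = (80.0, 68.0)
    bone_inner: tuple[float, float] = (50.0, 44.0)
    bone_outer: tuple[float, float] = (64.0, 56.0)
    bone_z_frac: tuple[float, float] = (0.08, 0.92)
    cortical_thickness_mm: float = 3.5
    bladder_center: tuple[float, float, float] = (0.0, -21.0, 14.0)
    bladder_semiaxes: tuple[float, float, float] = (20.0, 16.0, 14.0)
    prostate_center: tuple[float, float, float] = (0.0, -2.0, -8.0)
    prostate_semiaxes: tuple[float, float, float] = (14.0, 12.0, 12.0)
    sv_offset: tuple[float, float, float] = (12.0, 4.0, 10.0)  # mirrored in x
    sv_semiaxes: tuple[float, float, float] = (8.0, 5.0, 6.0)
    rectum_center_y: float = 22.0
    rectum_radius: float = 10.0
    rectum_z_frac: tuple[float, float] = (0.12, 0.85)
    rectum_curve_mm: float = 4.0
    air_radius_frac: float = 0.5
    air_z_frac: tuple[float, float] = (0.35, 0.60)

    # tissue HU
    soft: TissueStats = dfield(default_factory=lambda: TissueStats(35.0, 30.0))
    cortical: TissueStats = dfield(default_factory=lambda: TissueStats(900.0, 150.0))
    spongy: TissueStats = dfield(default_factory=lambda: TissueStats(250.0, 180.0))
    rectal_air: TissueStats = dfield(default_factory=lambda: TissueStats(-750.0, 60.0))
    bladder_content: TissueStats = dfield(default_factory=lambda: TissueStats(5.0, 12.0))
    prostate_tissue: TissueStats = dfield(default_factory=lambda: TissueStats(40.0, 25.0))
    background_hu: float = -1000.0

    # inter-patient variability
    volume_cv: float = 0.15          # lognormal SD of organ volume scale
    bladder_volume_cv: float = 0.35  # bladder filling varies much more
    jitter_sd_mm: float = 3.0        # organ position jitter
    warp_amp_mm: float = 2.5         # RMS of smooth whole-body warp
    warp_corr_mm: float = 30.0

    # MRI-like channel
    mri_levels: dict = dfield(default_factory=lambda: {
        "air": 60.0, "cortical": 120.0, "spongy": 250.0,
        "soft": 420.0, "prostate": 480.0, "bladder": 950.0,
    })
    mri_noise_sd: float = 25.0
    mri_bias_amp: float = 0.15
    mri_bias_corr_mm: float = 60.0

    seed: int = 0

    def __post_init__(self):
        if self.volume_cv < 0 or self.bladder_volume_cv < 0 or self.jitter_sd_mm < 0:
            raise PhantomError("variation coefficients must be >= 0")
        if self.warp_amp_mm < 0:
            raise PhantomError("warp amplitude must be >= 0")
        for r in (self.rectum_radius, *self.bladder_semiaxes,
                  *self.prostate_semiaxes, *self.body_semiaxes):
            if r <= 0:
                raise PhantomError("all radii/semi-axes must be positive")

    @property
    def geometry(self) -> Geometry:
        return Geometry(self.shape, self.spacing)

    @property
    def fov_mm(self) -> np.ndarray:
        return np.asarray(self.shape) * np.asarray(self.spacing)


def _smooth_unit_field(shape, spacing, corr_mm, rng, n_channels=1):
    """Gaussian-correlated field(s) with unit pointwise variance.

    White noise is smoothed circularly (wrap mode), which keeps the field
    exactly stationary, so dividing by the circular kernel's l2 norm —
    measured on an impulse — restores unit variance at every voxel.
    """
    sigma_vox = [corr_mm / s for s in spacing]
    imp = np.zeros(shape)
    imp[tuple(s // 2 for s in shape)] = 1.0
    k = ndimage.gaussian_filter(imp, sigma=sigma_vox, mode="wrap")
    norm = float(np.sqrt((k**2).sum()))
    fields = []
    for _ in range(n_channels):
        w = rng.standard_normal(shape)
        f = ndimage.gaussian_filter(w, sigma=sigma_vox, mode="wrap")
        fields.append(f / norm)
    return fields


def _ellipsoid(coords, center, semiaxes):
    q = sum(((coords[a] - center[a]) / semiaxes[a]) ** 2 for a in range(3))
    return q <= 1.0


class _Draw:
    """One patient's sampled variability (scales, jitters, warp)."""

    def __init__(self, params: PhantomParams, rng: np.random.Generator):
        p = params
        def lin_scale(cv):
            # volume scale is lognormal(0, cv); linear dims scale by cube root
            return float(np.exp(rng.normal(0.0, cv)) ** (1.0 / 3.0))
        self.s_bladder = lin_scale(p.bladder_volume_cv)
        self.s_prostate = lin_scale(p.volume_cv)
        self.s_rectum = lin_scale(p.volume_cv)
        self.s_body = lin_scale(p.volume_cv * 0.3)
        self.j_bladder = rng.normal(0.0, p.jitter_sd_mm, 3)
        self.j_prostate = rng.normal(0.0, p.jitter_sd_mm, 3)
        self.j_rectum = np.array([rng.normal(0.0, p.jitter_sd_mm),
                                  rng.normal(0.0, p.jitter_sd_mm), 0.0])


def generate_patient(params: PhantomParams, patient_seed: int) -> PatientCase:
    """Build one synthetic patient; deterministic given (params, patient_seed)."""
    zero_variation = (params.volume_cv == 0 and params.bladder_volume_cv == 0
                      and params.jitter_sd_mm == 0 and params.warp_amp_mm == 0)
    # zero variation means identical patients, texture included, so the
    # degenerate cohort collapses to one anatomy regardless of patient seed
    rng = np.random.default_rng(params.seed if zero_variation else patient_seed)
    geo = params.geometry
    ax = geo.coordinate_axes()
    center = params.fov_mm / 2.0

    # smooth whole-body warp; primitives are evaluated at x + W(x)
    if params.warp_amp_mm > 0:
        per_axis = params.warp_amp_mm / np.sqrt(3.0)
        wf = _smooth_unit_field(geo.shape, geo.spacing, params.warp_corr_mm,
                                rng, n_channels=3)
        warp = np.stack([per_axis * f for f in wf], axis=-1)
    else:
        warp = np.zeros(geo.shape + (3,))
    X = np.meshgrid(*ax, indexing="ij")
    Xw = [X[a] + warp[..., a] for a in range(3)]

    last_err = None
    for _attempt in range(10):
        draw = _Draw(params, rng)
        try:
            masks = _build_masks(params, draw, Xw, center)
            break
        except PhantomError as err:
            last_err = err
    else:
        raise PhantomError(f"could not place organs after 10 attempts: {last_err}")

    structures = StructureSet(geo)
    for name, m in masks.items():
        structures.add(name, m)

    ct = _draw_ct(params, masks, rng, geo)
    mri = _draw_mri(params, masks, rng, geo)

    case = PatientCase(
        id=f"phantom-{patient_seed}",
        mri=mri, ct=ct, structures=structures,
        meta={"patient_seed": int(patient_seed),
              "warp_field": VectorField(warp, geo)},
    )
    return case


def _build_masks(params: PhantomParams, draw: _Draw, Xw, center) -> dict:
    p = params
    x, y, z = Xw
    cx, cy, cz = center
    fov_z = p.fov_mm[2]

    bax, bay = (a * draw.s_body for a in p.body_semiaxes)
    body = ((x - cx) / bax) ** 2 + ((y - cy) / bay) ** 2 <= 1.0

    z0, z1 = (f * fov_z for f in p.bone_z_frac)
    def ring(inner, outer):
        qi = ((x - cx) / inner[0]) ** 2 + ((y - cy) / inner[1]) ** 2
        qo = ((x - cx) / outer[0]) ** 2 + ((y - cy) / outer[1]) ** 2
        return (qo <= 1.0) & (qi > 1.0) & (z >= z0) & (z <= z1)
    bones = ring(p.bone_inner, p.bone_outer) & body

    coords = (x, y, z)
    blad_c = np.array([cx, cy, cz]) + np.asarray(p.bladder_center) + draw.j_bladder
    bladder = _ellipsoid(coords, blad_c,
                         np.asarray(p.bladder_semiaxes) * draw.s_bladder)
    pro_c = np.array([cx, cy, cz]) + np.asarray(p.prostate_center) + draw.j_prostate
    prostate = _ellipsoid(coords, pro_c,
                          np.asarray(p.prostate_semiaxes) * draw.s_prostate)
    sv = np.zeros_like(prostate)
    for sgn in (-1.0, 1.0):
        off = np.asarray(p.sv_offset) * np.array([sgn, 1.0, 1.0])
        sv |= _ellipsoid(coords, pro_c + off,
                         np.asarray(p.sv_semiaxes) * draw.s_prostate)

    rz0, rz1 = (f * fov_z for f in p.rectum_z_frac)
    ry = (cy + p.rectum_center_y + draw.j_rectum[1]
          + p.rectum_curve_mm * np.sin(np.pi * (z - rz0) / max(rz1 - rz0, 1e-9)))
    rr = p.rectum_radius * draw.s_rectum
    r2 = (x - (cx + draw.j_rectum[0])) ** 2 + (y - ry) ** 2
    rectum = (r2 <= rr**2) & (z >= rz0) & (z <= rz1)

    az0, az1 = (f * fov_z for f in p.air_z_frac)
    air = (r2 <= (rr * p.air_radius_frac) ** 2) & (z >= az0) & (z <= az1)

    # organs must stay off the bones and inside the body
    for name, m in [("bladder", bladder), ("prostate", prostate),
                    ("rectum", rectum), ("ctv1", prostate | sv)]:
        if (m & bones).any() or (m & ~body).any():
            raise PhantomError(f"{name} collides with bones or body boundary")
        if not m.any():
            raise PhantomError(f"{name} is empty")

    # precedence keeps the organ interiors pairwise disjoint
    bladder &= ~bones & body
    rectum &= ~bones & ~bladder & body
    prostate &= ~bones & ~bladder & ~rectum & body
    sv &= ~bones & ~bladder & ~rectum & body
    air &= rectum

    # cortical shell = bone voxels near the bone boundary, spongy = interior;
    # at coarse spacing the shell is at least the one-voxel boundary layer
    spacing = params.spacing
    d_in = ndimage.distance_transform_edt(bones, sampling=spacing)
    shell = max(p.cortical_thickness_mm, 1.01 * max(spacing))
    cortical = bones & (d_in <= shell)
    spongy = bones & ~cortical

    return {
        "body": body, "bones": bones, "bladder": bladder, "rectum": rectum,
        "prostate": prostate, "ctv1": prostate | sv, "ctv2": prostate.copy(),
        "cortical": cortical, "spongy": spongy, "rectal_air": air,
    }


def _draw_ct(params, masks, rng, geo) -> VolumeGrid:
    p = params
    ct = np.full(geo.shape, p.background_hu)
    body = masks["body"]
    def fill(mask, stats: TissueStats):
        n = int(mask.sum())
        if n:
            ct[mask] = stats.mean + stats.sd * rng.standard_normal(n)
    fill(body, p.soft)
    fill(masks["prostate"] | (masks["ctv1"] & ~masks["prostate"]), p.prostate_tissue)
    fill(masks["bladder"], p.bladder_content)
    fill(masks["spongy"], p.spongy)
    fill(masks["cortical"], p.cortical)
    fill(masks["rectal_air"], p.rectal_air)
    return VolumeGrid(ct, geo.spacing, geo.origin, "HU")


def _draw_mri(params, masks, rng, geo) -> VolumeGrid:
    p = params
    lv = p.mri_levels
    mri = np.zeros(geo.shape)
    mri[masks["body"]] = lv["soft"]
    mri[masks["cortical"]] = lv["cortical"]
    mri[masks["spongy"]] = lv["spongy"]
    mri[masks["bladder"]] = lv["bladder"]
    mri[masks["prostate"] | masks["ctv1"]] = lv["prostate"]
    mri[masks["rectal_air"]] = lv["air"]
    (bias,) = _smooth_unit_field(geo.shape, geo.spacing, p.mri_bias_corr_mm, rng)
    mri = mri * (1.0 + p.mri_bias_amp * bias)
    mri = mri + p.mri_noise_sd * rng.standard_normal(geo.shape)
    np.clip(mri, 0.0, None, out=mri)
    mri[~masks["body"]] = 0.0
    return VolumeGrid(mri, geo.spacing, geo.origin, "unitless")


def generate_cohort(params: PhantomParams, n_patients: int, seed: int | None = None
                    ) -> list[PatientCase]:
    """Deterministic cohort; patient seeds derive from the master seed."""
    if n_patients < 2:
        raise PhantomError(f"need at least 2 patients, got {n_patients}")
    master = params.seed if seed is None else seed
    child_seeds = np.random.SeedSequence(master).generate_state(n_patients)
    return [generate_patient(params, int(s) % (2**31)) for s in child_seeds]


def make_learned_like_sct(
    case: PatientCase,
    amplitude_hu: dict | None = None,
    correlation_mm: float = 12.0,
    seed: int = 0,
) -> VolumeGrid:
    """CT plus a smooth spatially-correlated error field scaled per tissue.

    Emulates the residual-error structure of a learned sCT: small smooth
    errors in soft tissue, larger in bone and near air.  The smoothed noise
    field is renormalised to unit pointwise variance, so the per-tissue
    amplitude is (up to sampling noise) the pointwise SD of sCT - CT there.
    Zero amplitude reproduces the CT exactly.
    """
    if correlation_mm < 0:
        raise PhantomError("correlation length must be >= 0")
    amplitude_hu = {"soft": 15.0, "bone": 60.0, "air": 40.0} | (amplitude_hu or {})
    if any(a < 0 for a in amplitude_hu.values()):
        raise PhantomError("amplitudes must be >= 0")
    geo = case.geometry
    rng = np.random.default_rng(seed)
    if correlation_mm > 0:
        (f,) = _smooth_unit_field(geo.shape, geo.spacing, correlation_mm, rng)
    else:
        f = rng.standard_normal(geo.shape)

    st = case.structures
    body, bones = st["body"], st["bones"]
    air = st["rectal_air"] if "rectal_air" in st else np.zeros(geo.shape, bool)
    amp = np.zeros(geo.shape)
    amp[body] = amplitude_hu["soft"]
    amp[bones] = amplitude_hu["bone"]
    amp[air] = amplitude_hu["air"]
    values = case.ct.values + amp * f
    return VolumeGrid(values, geo.spacing, geo.origin, "HU")
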