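"""Dose-domain QA in the common coordinate system.

Three complementary views of dose agreement between reference-CT and sCT
plans: the mean-absolute-dose-error volume histogram (MADE-VH, a cumulative
histogram over an ROI of the vMAE dose map, summarised by V0.5Gy and V1Gy),
DVH criteria differences (Dmean, D2%, D50%, D95%), and a 3D gamma analysis
(default local normalisation, 1%/1 mm, 10% low-dose threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
from scipy import ndimage

from .core import Geometry, StructureError, VolumeGrid


def crop_pelvis(body_mask: np.ndarray, rectum_mask: np.ndarray,
                geometry: Geometry, margin_mm: float = 20.0) -> np.ndarray:
    """Body mask restricted to 2 cm above/below the rectum along z."""
    rectum_mask = np.asarray(rectum_mask, dtype=bool)
    if not rectum_mask.any():
        raise StructureError("empty rectum mask")
    z = geometry.coordinate_axes()[2]
    zr = z[np.any(rectum_mask, axis=(0, 1))]
    keep = (z >= zr.min() - margin_mm) & (z <= zr.max() + margin_mm)
    out = np.asarray(body_mask, dtype=bool).copy()
    out[:, :, ~keep] = False
    return out


@dataclass
class CumulativeErrorHistogram:
    """% of ROI volume with mean absolute dose error >= threshold."""

    thresholds_gy: np.ndarray
    percent_volume: np.ndarray
    roi: str = ""
    _values: np.ndarray = dfield(default=None, repr=False)

    def V(self, threshold_gy: float) -> float:
        """Exact % of ROI volume with error >= threshold (not binned)."""
        return float(100.0 * (self._values >= threshold_gy).mean())


def made_vh(vmae_dose: VolumeGrid, roi_mask: np.ndarray,
            bin_width_gy: float = 0.05, roi: str = "") -> CumulativeErrorHistogram:
    """Cumulative histogram of the voxel-wise mean absolute dose error."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise StructureError("empty ROI mask")
    vals = vmae_dose.values[roi_mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise StructureError("ROI contains no valid error values")
    top = max(float(vals.max()), bin_width_gy)
    thresholds = np.arange(0.0, top + bin_width_gy, bin_width_gy)
    pct = 100.0 * (vals[None, :] >= thresholds[:, None]).mean(axis=1)
    return CumulativeErrorHistogram(thresholds, pct, roi=roi, _values=vals)


@dataclass
class DvhCriteria:
    dmean: float
    d2: float
    d50: float
    d95: float

    def as_dict(self) -> dict:
        return {"Dmean": self.dmean, "D2%": self.d2,
                "D50%": self.d50, "D95%": self.d95}


def dvh_criteria(dose: VolumeGrid, roi_mask: np.ndarray) -> DvhCriteria:
    """Dx% = minimum dose received by the hottest x% of the ROI, i.e. the
    (100 - x)th percentile (linear interpolation between order statistics)."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise StructureError("empty ROI mask")
    v = dose.values[roi_mask]
    return DvhCriteria(
        dmean=float(v.mean()),
        d2=float(np.percentile(v, 98.0)),
        d50=float(np.percentile(v, 50.0)),
        d95=float(np.percentile(v, 5.0)),
    )


def criteria_diff(ref_dose: VolumeGrid, pred_dose: VolumeGrid,
                  rois: dict) -> dict:
    """Per-ROI absolute DVH-criteria differences |metric(ref) - metric(pred)|."""
    out = {}
    for name, mask in rois.items():
        a = dvh_criteria(ref_dose, mask).as_dict()
        b = dvh_criteria(pred_dose, mask).as_dict()
        out[name] = {k: abs(a[k] - b[k]) for k in a}
    return out


@dataclass
class GammaResult:
    gamma: VolumeGrid            # NaN below the dose threshold
    pass_rate_pct: float
    mean_gamma: float
    dose_pct: float
    dta_mm: float
    normalization: str
    threshold_pct: float
    n_evaluated: int


def gamma_3d(ref_dose: VolumeGrid, eval_dose: VolumeGrid,
             dose_pct: float = 1.0, dta_mm: float = 1.0,
             normalization: str = "local", threshold_pct: float = 10.0,
             oversample: int = 3, search_factor: float = 3.0) -> GammaResult:
    """3D gamma index between two dose grids.

    gamma(i) = min over displacements r of sqrt((D_eval(i+r) - D_ref(i))^2 /
    delta_d(i)^2 + |r|^2 / dta^2), with delta_d a percentage of the local
    reference dose (``local``) or of its maximum (``global``).  The search
    covers a ball of radius ``search_factor * dta_mm`` sampled at
    spacing/oversample with trilinear interpolation of the evaluated dose;
    values are upper bounds beyond that radius.  Voxels with reference dose
    below ``threshold_pct`` % of the maximum are not evaluated.  Pass is
    gamma <= 1.
    """
    ref_dose.check_compatible(eval_dose)
    if normalization not in ("local", "global"):
        raise ValueError("normalization must be 'local' or 'global'")
    geo = ref_dose.geometry
    ref = ref_dose.values
    max_ref = float(ref.max())
    if max_ref <= 0:
        raise StructureError("reference dose is non-positive everywhere")
    evaluable = ref >= threshold_pct / 100.0 * max_ref
    if not evaluable.any():
        raise StructureError("no voxels above the dose threshold")

    if normalization == "local":
        delta = dose_pct / 100.0 * ref[evaluable]
    else:
        delta = np.full(int(evaluable.sum()), dose_pct / 100.0 * max_ref)

    spacing = np.asarray(geo.spacing)
    radius = search_factor * dta_mm
    steps = [np.arange(-np.floor(radius / h * oversample),
                       np.floor(radius / h * oversample) + 1) * h / oversample
             for h in spacing]
    offs = np.stack(np.meshgrid(*steps, indexing="ij"), axis=-1).reshape(-1, 3)
    norms = np.linalg.norm(offs, axis=1)
    keep = norms <= radius + 1e-9
    offs, norms = offs[keep], norms[keep]
    order = np.argsort(norms)
    offs, norms = offs[order], norms[order]

    coords0 = np.argwhere(evaluable).T.astype(float)  # (3, n)
    ref_vals = ref[evaluable]
    ev = np.asarray(eval_dose.values, dtype=float)

    gamma2 = np.full(ref_vals.shape, np.inf)
    for off, nrm in zip(offs, norms):
        dist2 = (nrm / dta_mm) ** 2
        active = gamma2 > dist2
        if not active.any():
            break
        coords = coords0[:, active] + (off / spacing)[:, None]
        de = ndimage.map_coordinates(ev, coords, order=1, mode="nearest")
        dd2 = ((de - ref_vals[active]) / delta[active]) ** 2
        gamma2[active] = np.minimum(gamma2[active], dd2 + dist2)

    g = np.sqrt(gamma2)
    gmap = np.full(geo.shape, np.nan)
    gmap[evaluable] = g
    return GammaResult(
        gamma=VolumeGrid(gmap, geo.spacing, geo.origin, "unitless"),
        pass_rate_pct=float(100.0 * (g <= 1.0).mean()),
        mean_gamma=float(g.mean()),
        dose_pct=dose_pct, dta_mm=dta_mm, normalization=normalization,
        threshold_pct=threshold_pct, n_evaluated=int(evaluable.sum()),
    )
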