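"""Bulk-density synthetic CT.

Assigns one Hounsfield value per segmented tissue class: water-equivalent
soft tissue (0 HU), bone (350 HU) and rectal air (-450 HU) — the latter two
being cohort-mean values for those regions in the clinical setting.  Rectal
air is segmented by thresholding the MRI inside the rectum contour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import StructureError, StructureSet, VolumeGrid


@dataclass
class BulkAssignment:
    soft_hu: float = 0.0
    bone_hu: float = 350.0
    air_hu: float = -450.0
    #: rectal-air MRI threshold, as a fraction of the body-median MRI intensity
    air_threshold: float = 0.3
    background_hu: float = -1000.0

    def __post_init__(self):
        if not (self.air_hu < self.soft_hu < self.bone_hu):
            raise ValueError("require air_hu < soft_hu < bone_hu")


def segment_rectal_air(
    mri: VolumeGrid,
    rectum_mask: np.ndarray,
    assignment: BulkAssignment = BulkAssignment(),
    body_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Air = rectum voxels darker than ``air_threshold`` x body-median MRI."""
    rectum_mask = np.asarray(rectum_mask, dtype=bool)
    if not rectum_mask.any():
        raise StructureError("rectum mask is empty")
    if body_mask is None:
        body_mask = mri.values > 0
    ref = mri.values[np.asarray(body_mask, dtype=bool)]
    if ref.size == 0:
        raise StructureError("body mask is empty")
    thresh = assignment.air_threshold * float(np.median(ref))
    return rectum_mask & (mri.values < thresh)


def generate_bulk_sct(
    structures: StructureSet,
    air_mask: np.ndarray | None = None,
    assignment: BulkAssignment = BulkAssignment(),
) -> VolumeGrid:
    """Piecewise-constant sCT; precedence on overlap is air > bone > soft."""
    structures.require("body", "bones")
    body = structures["body"]
    bones = structures["bones"]
    geo = structures.geometry
    sct = np.full(geo.shape, assignment.background_hu)
    sct[body] = assignment.soft_hu
    sct[bones & body] = assignment.bone_hu
    if air_mask is not None:
        sct[np.asarray(air_mask, dtype=bool) & body] = assignment.air_hu
    return VolumeGrid(sct, geo.spacing, geo.origin, "HU")


def cohort_mean_hu(cases, mask_name: str) -> float:
    """Optional helper: cohort-mean CT number inside a named structure."""
    vals = [case.ct.values[case.structures[mask_name]] for case in cases]
    return float(np.concatenate(vals).mean())
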