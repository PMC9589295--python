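"""Per-patient voxel error maps and regional summaries in native space.

Error sign convention: ``e = reference - prediction``, so positive error
means the synthetic image underestimates the reference.  The absolute
percent error divides by the reference value and is undefined where the
reference is (near) zero — HU crosses zero in soft tissue — so APE carries a
validity mask and MAPE averages only over valid voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import StructureError, VolumeGrid

#: |reference| below which APE is undefined, per unit
APE_EPS = {"HU": 1.0, "Gy": 0.01}


@dataclass
class ErrorVolume:
    ae: VolumeGrid
    e: VolumeGrid
    ape: VolumeGrid       # unitless ratio; NaN where invalid
    valid: np.ndarray     # where APE is defined
    unit: str


def voxel_errors(ref: VolumeGrid, pred: VolumeGrid,
                 eps: float | None = None) -> ErrorVolume:
    """AE/E/APE maps for one reference/prediction pair."""
    ref.check_compatible(pred)
    ref.check_same_unit(pred)
    if eps is None:
        eps = APE_EPS.get(ref.unit, 1e-6)
    e = ref.values - pred.values
    ae = np.abs(e)
    valid = np.abs(ref.values) >= eps
    ape = np.full(ref.values.shape, np.nan)
    ape[valid] = ae[valid] / np.abs(ref.values[valid])
    return ErrorVolume(
        ae=ref.like(ae), e=ref.like(e),
        ape=ref.like(ape, unit="unitless"),
        valid=valid, unit=ref.unit,
    )


def regional_summary(errs: ErrorVolume, mask: np.ndarray) -> dict:
    """MAE/ME/MAPE over a region, with the voxel counts actually averaged."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise StructureError("empty mask")
    vmask = mask & errs.valid
    return {
        "mae": float(errs.ae.values[mask].mean()),
        "me": float(errs.e.values[mask].mean()),
        "mape": float(errs.ape.values[vmask].mean()) if vmask.any() else float("nan"),
        "n": int(mask.sum()),
        "n_mape": int(vmask.sum()),
    }


def summary_table(errs: ErrorVolume, structures, regions) -> "list[dict]":
    """Per-region long-format rows (region, metric, value, n)."""
    rows = []
    for region in regions:
        s = regional_summary(errs, structures[region])
        for metric in ("mae", "me", "mape"):
            rows.append({
                "region": region, "metric": metric, "value": s[metric],
                "n": s["n_mape"] if metric == "mape" else s["n"],
            })
    return rows
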